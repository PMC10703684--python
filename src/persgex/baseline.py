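"""Per-gene elastic-net baseline: expression from cis common-variant dosages.

A regularized linear model per gene, trained on alternate-allele dosages of
common variants near the TSS, gives a floor on how much cross-individual
expression variation is linearly attributable to local genotype — the
standard transcriptome-imputation design.  Predictions are strictly
out-of-fold: an outer ten-fold split provides held-out predictions, and the
regularization penalty is chosen by an inner ten-fold cross-validation run
entirely inside each outer training set, so no individual ever influences
its own prediction.

The mixing parameter is fixed at 0.5, i.e. the penalty is
lambda * (0.5 * ||b||_1 + 0.25 * ||b||_2^2) in the usual alpha-mixing
parameterization.  Dosage columns are standardized and the response
centred using training-fold statistics only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .evaluation import spearman
from .io import GeneAnnotation, PhasedCohort

logger = logging.getLogger(__name__)


@dataclass
class DosageMatrix:
    """Individuals x cis-variants alt-allele dosages with variant metadata."""

    dosages: np.ndarray  # (n_individuals, n_variants) in {0,1,2}
    individuals: list[str]
    variant_ids: list[str]
    positions: np.ndarray  # 0-based
    mafs: np.ndarray
    tss_distances: np.ndarray  # signed bp, variant pos0 - tss0

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.n_variants == 0


@dataclass(frozen=True)
class CvScheme:
    """Nested cross-validation layout for penalty selection + holdout."""

    n_outer_folds: int = 10
    n_inner_folds: int = 10
    mixing: float = 0.5
    n_alphas: int = 50
    alpha_eps: float = 1e-4  # grid spans 4 orders of magnitude below lambda_max
    alphas: tuple[float, ...] | None = None  # explicit grid overrides the path
    seed: int = 0


@dataclass
class FitResult:
    predictions: np.ndarray  # out-of-fold, one per individual
    fold_alphas: list[float]
    selected_variants: list[str]  # nonzero-coefficient ids (union over folds)
    constant_response: bool = False


def build_dosage_matrix(
    cohort: PhasedCohort,
    gene: GeneAnnotation,
    window_bp: int = 98_300,
    maf_min: float = 0.05,
) -> DosageMatrix:
    """Cis dosage matrix: variants with |pos0 - tss0| <= window_bp and
    cohort MAF >= maf_min, dosages summed over the two haplotypes."""
    tss0 = gene.tss0
    idx = cohort.variants_in(gene.chrom, tss0 - window_bp, tss0 + window_bp + 1)
    dos = cohort.dosages(idx)  # (n, m)
    n = len(cohort.individuals)
    if n == 0 or dos.size == 0:
        return DosageMatrix(
            np.zeros((n, 0)), list(cohort.individuals), [], np.array([]),
            np.array([]), np.array([]),
        )
    freq = dos.sum(axis=0) / (2 * n)
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_min
    kept = [idx[i] for i in np.nonzero(keep)[0]]
    return DosageMatrix(
        dosages=dos[:, keep].astype(float),
        individuals=list(cohort.individuals),
        variant_ids=[cohort.variants[i].variant_id for i in kept],
        positions=np.array([cohort.variants[i].pos0 for i in kept]),
        mafs=maf[keep],
        tss_distances=np.array([cohort.variants[i].pos0 - tss0 for i in kept]),
    )


def fit_out_of_fold(X: DosageMatrix, y: np.ndarray, scheme: CvScheme) -> FitResult:
    """Out-of-fold elastic-net predictions under nested cross-validation.

    Outer folds are a seeded shuffled K-fold partition; within each outer
    training set an inner K-fold CV picks the penalty minimizing mean
    squared error on a log-spaced grid, the model is refit on the full
    outer training set, and predictions are emitted for the held-out fold.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 30:
        raise ValueError(f"need >= 30 individuals, got {n}")
    if X.is_empty:
        raise ValueError("empty dosage matrix")
    if X.dosages.shape[0] != n:
        raise ValueError("dosage/expression individual count mismatch")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X.dosages)):
        raise ValueError("non-finite values in inputs")

    if np.ptp(y) == 0:
        # intercept-only: every fold predicts its training mean, which is y[0]
        return FitResult(np.full(n, y[0]), [], [], constant_response=True)

    preds = np.empty(n)
    fold_alphas: list[float] = []
    selected: set[str] = set()
    outer = KFold(scheme.n_outer_folds, shuffle=True, random_state=scheme.seed)
    for fold, (train, test) in enumerate(outer.split(np.arange(n))):
        Xtr, Xte = X.dosages[train], X.dosages[test]
        ytr = y[train]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0  # monomorphic-in-fold columns contribute nothing
        Xtr_s, Xte_s = (Xtr - mu) / sd, (Xte - mu) / sd
        y_mu = ytr.mean()
        inner = KFold(
            scheme.n_inner_folds, shuffle=True, random_state=scheme.seed + 1
        )
        grid = (
            list(scheme.alphas) if scheme.alphas is not None else scheme.n_alphas
        )  # int = size of the log-spaced path from lambda_max
        model = ElasticNetCV(
            l1_ratio=scheme.mixing,
            alphas=grid,
            eps=scheme.alpha_eps,
            cv=inner,
            fit_intercept=True,
            max_iter=5000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Xtr_s, ytr - y_mu)
        preds[test] = model.predict(Xte_s) + y_mu
        fold_alphas.append(float(model.alpha_))
        selected.update(
            X.variant_ids[j] for j in np.nonzero(model.coef_)[0]
        )
    return FitResult(preds, fold_alphas, sorted(selected))


def baseline_eval(
    cohort: PhasedCohort,
    genes: list[GeneAnnotation],
    expression: pd.DataFrame,
    scheme: CvScheme,
    window_bp: int = 98_300,
    maf_min: float = 0.05,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene out-of-fold cross-individual rho for the elastic-net baseline.

    Genes with no qualifying cis variant are skipped (rho = NaN, counted).
    Returns (per-gene rho, out-of-fold prediction matrix).
    """
    rhos = {}
    pred = pd.DataFrame(
        index=[g.gene_id for g in genes], columns=list(expression.columns), dtype=float
    )
    n_skipped = 0
    for gene in genes:
        y = expression.loc[gene.gene_id].values
        X = build_dosage_matrix(cohort, gene, window_bp=window_bp, maf_min=maf_min)
        if X.is_empty:
            rhos[gene.gene_id] = float("nan")
            n_skipped += 1
            continue
        order = [X.individuals.index(i) for i in expression.columns]
        X = DosageMatrix(
            X.dosages[order], list(expression.columns), X.variant_ids,
            X.positions, X.mafs, X.tss_distances,
        )
        fit = fit_out_of_fold(X, y, scheme)
        pred.loc[gene.gene_id] = fit.predictions
        rhos[gene.gene_id] = (
            float("nan") if fit.constant_response else spearman(fit.predictions, y)
        )
    if n_skipped:
        logger.info("baseline skipped %d genes with no qualifying cis variants", n_skipped)
    return pd.Series(rhos, name="baseline_rho"), pred
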