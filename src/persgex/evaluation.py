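"""Cross-gene, cross-individual and reference performance metrics.

Three views of agreement between a predicted and an observed genes x
individuals expression matrix:

* cross-individual — per gene, Spearman rank correlation of predicted vs
  observed expression across individuals (the personal-genome question);
* cross-gene — per individual, Spearman correlation across genes (the
  classic reference-genome question, one column at a time);
* reference — Spearman correlation of reference-sequence predictions with
  per-gene median observed expression.

Undefined correlations (a constant vector) are reported as NaN and counted,
never imputed as zero: a zero-variance prediction is diagnostic.  Also here:
cross-model agreement (signed vs magnitude) and the stratification of
per-gene performance by eQTL strength, TSS distance, expression level and
prediction coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks; NaN when undefined.

    Requires equal lengths >= 3.  Returns NaN (the undefined marker) when
    either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class EvalResult:
    """Per-gene and per-individual rank-correlation distributions."""

    cross_individual: pd.Series
    cross_gene: pd.Series
    reference_corr: float
    summary: dict = field(default_factory=dict)

    @staticmethod
    def _summarize(s: pd.Series) -> dict:
        defined = s.dropna()
        return {
            "mean": float(defined.mean()) if len(defined) else float("nan"),
            "sd": float(defined.std(ddof=1)) if len(defined) > 1 else float("nan"),
            "n_defined": int(len(defined)),
            "n_undefined": int(s.isna().sum()),
        }

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = {
                "cross_individual": self._summarize(self.cross_individual),
                "cross_gene": self._summarize(self.cross_gene),
                "reference_corr": self.reference_corr,
            }


def _check_aligned(pred: pd.DataFrame, obs: pd.DataFrame) -> None:
    if not (pred.index.equals(obs.index) and pred.columns.equals(obs.columns)):
        raise ValueError("prediction and observation matrices must share indices")


def cross_individual(pred: pd.DataFrame, obs: pd.DataFrame) -> pd.Series:
    """Per-gene Spearman rho across individuals."""
    _check_aligned(pred, obs)
    return pd.Series(
        {g: spearman(pred.loc[g].values, obs.loc[g].values) for g in pred.index},
        name="cross_individual",
    ).reindex(pred.index)


def cross_gene(pred: pd.DataFrame, obs: pd.DataFrame) -> pd.Series:
    """Per-individual Spearman rho across genes."""
    _check_aligned(pred, obs)
    return pd.Series(
        {i: spearman(pred[i].values, obs[i].values) for i in pred.columns},
        name="cross_gene",
    ).reindex(pred.columns)


def reference_correlation(ref_pred: pd.Series, obs: pd.DataFrame) -> float:
    """Spearman rho of reference predictions vs per-gene median expression."""
    if len(ref_pred) < 3:
        raise ValueError("need at least 3 genes")
    medians = obs.median(axis=1).reindex(ref_pred.index)
    return spearman(ref_pred.values, medians.values)


def evaluate(
    pred: pd.DataFrame, obs: pd.DataFrame, ref_pred: pd.Series | None = None
) -> EvalResult:
    """Bundle the three metrics into an :class:`EvalResult`."""
    ci = cross_individual(pred, obs)
    cg = cross_gene(pred, obs)
    ref = (
        reference_correlation(ref_pred, obs) if ref_pred is not None else float("nan")
    )
    return EvalResult(ci, cg, ref)


def model_agreement(
    rho_a: pd.Series, rho_b: pd.Series
) -> tuple[float, float, int]:
    """Signed and magnitude Pearson correlation between two models' per-gene rhos.

    Models can agree on which genes carry detectable regulatory signal
    (|rho|) while disagreeing on the direction of that signal (signed rho);
    the pair of correlations quantifies the dissociation.  Undefined
    entries are dropped pairwise.  Returns (signed_r, magnitude_r, n_used).
    """
    joined = pd.concat([rho_a, rho_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 shared defined genes")
    a, b = joined.iloc[:, 0].values, joined.iloc[:, 1].values
    signed = float(stats.pearsonr(a, b).statistic)
    magnitude = float(stats.pearsonr(np.abs(a), np.abs(b)).statistic)
    return signed, magnitude, len(joined)


def top_eqtl_per_gene(eqtl: pd.DataFrame, max_tss_distance: int = 20_000) -> pd.DataFrame:
    """Most significant eQTL per gene within ``max_tss_distance`` of the TSS.

    Ties in p-value break by smaller |distance_to_tss|, then variant_id.
    Expects a 'distance_to_tss' column (signed bp).
    """
    df = eqtl[eqtl["distance_to_tss"].abs() <= max_tss_distance].copy()
    df["_absdist"] = df["distance_to_tss"].abs()
    df = df.sort_values(["gene_id", "pvalue", "_absdist", "variant_id"])
    return df.groupby("gene_id", sort=False).head(1).drop(columns="_absdist")


def _fit(x: np.ndarray, y: np.ndarray) -> dict:
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"pearson_r": float("nan"), "slope": float("nan"),
                "intercept": float("nan"), "n": int(len(x))}
    res = stats.linregress(x, y)
    return {
        "pearson_r": float(res.rvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "n": int(len(x)),
    }


def stratify(
    rho: pd.Series,
    eqtl: pd.DataFrame,
    obs: pd.DataFrame,
    pred: pd.DataFrame,
    max_tss_distance: int = 20_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relate per-gene cross-individual rho to gene-level covariates.

    Covariates: -log10 p of the top eQTL within ``max_tss_distance`` bp,
    |distance to TSS| of that eQTL, median observed expression, and the
    coefficient of variation (sd/mean) of predicted expression.  For each
    covariate an OLS fit of rho on the covariate is reported for all genes
    and for the positive- and negative-rho subsets.  Genes without an eQTL
    record in range are excluded (counted via the table length).

    Returns (per-gene covariate table, per-covariate fit table).
    """
    top = top_eqtl_per_gene(eqtl, max_tss_distance).set_index("gene_id")
    genes = [g for g in rho.index if g in top.index]
    mu = pred.mean(axis=1)
    sd = pred.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mu
    table = pd.DataFrame(
        {
            "rho": rho.reindex(genes),
            "neglog10_pvalue": -np.log10(top.loc[genes, "pvalue"].astype(float)),
            "abs_tss_distance": top.loc[genes, "distance_to_tss"].abs().astype(float),
            "median_expression": obs.loc[genes].median(axis=1),
            "prediction_cv": cv.reindex(genes),
            "zero_mean_prediction": (mu.reindex(genes) == 0),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    covariates = [
        "neglog10_pvalue", "abs_tss_distance", "median_expression", "prediction_cv",
    ]
    fits = []
    for cov in covariates:
        sub = table[["rho", cov]].dropna()
        subsets = {
            "all": sub,
            "positive": sub[sub["rho"] > 0],
            "negative": sub[sub["rho"] < 0],
        }
        for name, s in subsets.items():
            row = {"covariate": cov, "subset": name}
            row.update(_fit(s[cov].values, s["rho"].values))
            fits.append(row)
    return table, pd.DataFrame(fits)
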