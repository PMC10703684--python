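"""Synthetic cohort generator with known cis-regulatory truth.

Generates every artifact the pipeline consumes — reference genome, phased
SNV cohort, gene annotations, expression matrix, marginal eQTL table and
truth-consistent oracle predictor weights — under a simple additive model:

* genotypes: biallelic SNVs with MAF drawn uniformly from a common-variant
  spectrum, haplotype alleles i.i.d. Bernoulli(MAF) (Hardy-Weinberg, no
  linkage disequilibrium by default);
* expression: y_i = g_i + e_i with genetic value g_i = sum_j beta_j d_ij
  over a sparse set of causal window variants, and noise variance set from
  the realized Var(g) so that Var(g)/Var(y) hits the target heritability;
* oracle predictors: the causal effects placed as per-position sequence
  weights, optionally sign-corrupted at a configured rate, standing in for
  trained sequence models with a known relationship to the truth.

Everything is driven by one seed; identical configs produce byte-identical
fixture files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io import (
    GeneAnnotation,
    PhasedCohort,
    ReferenceGenome,
    VariantRecord,
    write_expression_table,
    write_fasta,
    write_gene_table,
    write_vcf,
)
from .personalize import WindowSpec, resolve_window
from .predictors import SyntheticOracleWeights
from .direction import FineMappedQtl

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the evaluated study design at desk scale: a cohort of
    ~400 phased individuals, a few hundred eQTL genes, common variants
    (MAF >= 0.05), sparse additive cis architectures and a symmetric TSS
    window standing in for a model receptive field.
    """

    n_individuals: int = 400
    n_genes: int = 200
    n_contigs: int = 2
    window: WindowSpec = field(default_factory=lambda: WindowSpec(1000, 1000, False))
    gene_spacing_bp: int = 200  # gap between adjacent gene windows
    variant_density: float = 0.01  # expected variants per bp
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_causal: int = 8
    effect_sd: float = 1.0
    h2: float | list[float] = 0.5
    sign_corruption_rate: float = 0.0
    noise_sd: float = 0.0  # deterministic oracle pseudo-noise
    seed: int = 0

    def __post_init__(self) -> None:
        h2s = self.h2 if isinstance(self.h2, (list, tuple)) else [self.h2]
        if any(not (0.0 <= h <= 1.0) for h in h2s):
            raise ValueError("h2 must lie in [0, 1]")
        if not (0.0 <= self.sign_corruption_rate <= 1.0):
            raise ValueError("sign_corruption_rate must lie in [0, 1]")
        if self.variant_density < 0 or self.n_causal < 0:
            raise ValueError("variant_density and n_causal must be non-negative")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")

    def h2_for_gene(self, gene_index: int) -> float:
        if isinstance(self.h2, (list, tuple)):
            return float(self.h2[gene_index % len(self.h2)])
        return float(self.h2)


@dataclass
class GeneTruth:
    causal_variant_ids: list[str]
    betas: np.ndarray
    genetic_values: np.ndarray
    target_h2: float
    realized_h2: float


@dataclass
class SyntheticTruth:
    """Per-gene causal architecture underlying a simulated expression matrix."""

    genes: dict[str, GeneTruth]
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "genes": {
                g: {
                    "causal_variant_ids": t.causal_variant_ids,
                    "betas": list(map(float, t.betas)),
                    "genetic_values": list(map(float, t.genetic_values)),
                    "target_h2": t.target_h2,
                    "realized_h2": t.realized_h2,
                }
                for g, t in self.genes.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        genes = {
            g: GeneTruth(
                d["causal_variant_ids"],
                np.asarray(d["betas"], dtype=float),
                np.asarray(d["genetic_values"], dtype=float),
                d["target_h2"],
                d["realized_h2"],
            )
            for g, d in payload["genes"].items()
        }
        return cls(genes, payload["seed"])


def simulate_cohort(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ReferenceGenome, PhasedCohort, list[GeneAnnotation]]:
    """Random reference genome, phased cohort and gene placements.

    Genes are laid out left to right with non-overlapping windows and
    alternating strands; variant positions are uniform without collision
    at ``variant_density``, redrawn (bounded retries) until every gene
    window holds at least ``n_causal`` variants.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genes_per_contig = int(np.ceil(cfg.n_genes / cfg.n_contigs))
    span = cfg.window.length + cfg.gene_spacing_bp
    margin = max(cfg.window.upstream_bp, cfg.window.downstream_bp) + cfg.gene_spacing_bp
    contig_len = 2 * margin + genes_per_contig * span

    contigs: dict[str, str] = {}
    genes: list[GeneAnnotation] = []
    gi = 0
    for c in range(cfg.n_contigs):
        name = f"chr{c + 1}"
        contigs[name] = "".join(rng.choice(_BASES, size=contig_len))
        for k in range(genes_per_contig):
            if gi >= cfg.n_genes:
                break
            tss0 = margin + k * span + cfg.window.upstream_bp
            strand = "+" if gi % 2 == 0 else "-"
            genes.append(GeneAnnotation(f"gene{gi:04d}", name, tss0 + 1, strand))
            gi += 1
    genome = ReferenceGenome(contigs)

    windows = [resolve_window(g, cfg.window, genome) for g in genes]
    for _attempt in range(20):
        variants: list[VariantRecord] = []
        mafs: list[float] = []
        for name, seq in contigs.items():
            n_var = int(round(cfg.variant_density * len(seq)))
            if n_var == 0:
                continue
            pos0 = np.sort(rng.choice(len(seq), size=n_var, replace=False))
            for p in pos0:
                ref = seq[p]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                variants.append(
                    VariantRecord(name, int(p) + 1, ref, alt, f"{name}:{p + 1}:{ref}:{alt}")
                )
                mafs.append(float(rng.uniform(cfg.maf_low, cfg.maf_high)))
        maf_arr = np.array(mafs)
        hap = (
            rng.random((len(variants), cfg.n_individuals, 2)) < maf_arr[:, None, None]
        ).astype(np.uint8)
        individuals = [f"IND{j:04d}" for j in range(cfg.n_individuals)]
        cohort = PhasedCohort(variants, individuals, hap)
        if cfg.n_causal == 0 or all(
            len(cohort.variants_in(w.chrom, w.start, w.end)) >= cfg.n_causal
            for w in windows
        ):
            return genome, cohort, genes
    raise RuntimeError(
        "could not place enough variants in every gene window; "
        "raise variant_density or shrink n_causal"
    )


def simulate_expression(
    cohort: PhasedCohort,
    genes: list[GeneAnnotation],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Additive-cis expression at the configured heritability.

    y = g + e with Var(e) = Var(g)(1 - h2)/h2 computed from the realized
    sample Var(g); h2 = 0 genes are pure noise.  Expression is shifted to
    be non-negative (rank-preserving affine shift).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    n = len(cohort.individuals)
    rows = {}
    truths: dict[str, GeneTruth] = {}
    for idx, gene in enumerate(genes):
        h2 = cfg.h2_for_gene(idx)
        w = resolve_window(gene, cfg.window)
        window_idx = cohort.variants_in(w.chrom, w.start, w.end)
        if h2 > 0 and len(window_idx) < cfg.n_causal:
            raise ValueError(
                f"{gene.gene_id}: window holds {len(window_idx)} variants "
                f"< n_causal={cfg.n_causal}"
            )
        g = np.zeros(n)
        causal_ids: list[str] = []
        betas = np.zeros(0)
        if h2 > 0:
            for _retry in range(20):
                chosen = rng.choice(window_idx, size=cfg.n_causal, replace=False)
                betas = rng.normal(0.0, cfg.effect_sd, size=cfg.n_causal)
                d = cohort.dosages(list(chosen)).astype(float)
                g = d @ betas
                if g.var() > 0:
                    causal_ids = [cohort.variants[i].variant_id for i in chosen]
                    break
            else:
                raise RuntimeError(f"{gene.gene_id}: Var(g)=0 after retries")
            var_g = g.var()
            if h2 < 1.0:
                e = rng.normal(0.0, np.sqrt(var_g * (1 - h2) / h2), size=n)
            else:
                e = np.zeros(n)
            y = g + e
        else:
            y = rng.normal(0.0, cfg.effect_sd, size=n)
        y = y - y.min()  # non-negative, rank-preserving
        realized = float(g.var() / y.var()) if y.var() > 0 else 0.0
        rows[gene.gene_id] = y
        truths[gene.gene_id] = GeneTruth(causal_ids, betas, g, h2, realized)
    expr = pd.DataFrame.from_dict(rows, orient="index", columns=list(cohort.individuals))
    return expr, SyntheticTruth(truths, cfg.seed)


def make_oracle_weights(
    truth: SyntheticTruth,
    cohort: PhasedCohort,
    genes: list[GeneAnnotation],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    baselines: dict[str, float] | None = None,
) -> dict[str, SyntheticOracleWeights]:
    """Per-gene oracle weights consistent with the simulation truth.

    Each causal variant's effect beta_j is placed on the alternate base at
    the variant's offset inside the gene window (gene orientation for
    strand-aware specs); the reference base scores zero, so the
    haplotype-averaged prediction equals baseline + 0.5 * sum_j beta_j d_ij.
    A seeded subset of positions gets its sign flipped at
    ``sign_corruption_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    by_id = {v.variant_id: v for v in cohort.variants}
    out: dict[str, SyntheticOracleWeights] = {}
    for gene in genes:
        gt = truth.genes[gene.gene_id]
        w = resolve_window(gene, cfg.window)
        flip = cfg.window.strand_aware and gene.strand == "-"
        contributions: dict[tuple[int, str], float] = {}
        corrupted: set[int] = set()
        for vid, beta in zip(gt.causal_variant_ids, gt.betas):
            v = by_id[vid]
            offset = v.pos0 - w.start
            base = v.alt_allele
            if flip:
                offset = w.length - 1 - offset
                base = _COMP[base]
            assert 0 <= offset < cfg.window.length
            contributions[(offset, base)] = float(beta)
            if rng.random() < cfg.sign_corruption_rate:
                corrupted.add(offset)
        out[gene.gene_id] = SyntheticOracleWeights(
            contributions=contributions,
            baseline=(baselines or {}).get(gene.gene_id, 0.0),
            corrupted_offsets=frozenset(corrupted),
            noise_sd=cfg.noise_sd,
            window_length=cfg.window.length,
        )
    return out


def marginal_eqtl_scan(
    cohort: PhasedCohort,
    expression: pd.DataFrame,
    genes: list[GeneAnnotation],
    window_bp: int = 1000,
    maf_min: float = 0.05,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Single-variant linear eQTL scan; one top record per gene plus an
    FDR flag.

    For every cis variant (|pos0 - tss0| <= window_bp, MAF >= maf_min) the
    expression vector is regressed on dosage; per gene the minimum-p
    variant is retained.  The per-gene minimum p-value is Bonferroni
    corrected for the number of variants tested in that gene, then
    Benjamini-Hochberg across genes defines the FDR < ``fdr`` eGene set.
    """
    n = len(cohort.individuals)
    records = []
    for gene in genes:
        tss0 = gene.tss0
        idx = cohort.variants_in(gene.chrom, tss0 - window_bp, tss0 + window_bp + 1)
        if not idx:
            continue
        y = expression.loc[gene.gene_id, list(cohort.individuals)].values.astype(float)
        d = cohort.dosages(idx).astype(float)
        freq = d.sum(axis=0) / (2 * n)
        maf = np.minimum(freq, 1 - freq)
        usable = (maf >= maf_min) & (d.std(axis=0) > 0)
        if not usable.any():
            continue
        d = d[:, usable]
        kept = [idx[i] for i in np.nonzero(usable)[0]]
        maf = maf[usable]
        dc = d - d.mean(axis=0)
        yc = y - y.mean()
        sxx = (dc**2).sum(axis=0)
        slope = (dc * yc[:, None]).sum(axis=0) / sxx
        syy = (yc**2).sum()
        with np.errstate(invalid="ignore"):
            r = (dc * yc[:, None]).sum(axis=0) / np.sqrt(sxx * syy)
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.maximum(p, np.finfo(float).tiny)
        best = int(np.argmin(p))
        v = cohort.variants[kept[best]]
        m_tests = len(kept)
        records.append(
            {
                "gene_id": gene.gene_id,
                "variant_id": v.variant_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "beta": float(slope[best]),
                "pvalue": float(p[best]),
                "pip": float("nan"),  # marginal scan, no fine-mapping posterior
                "maf": float(maf[best]),
                "distance_to_tss": int(v.pos0 - tss0),
                "n_tests": m_tests,
                "pvalue_gene_adj": float(min(1.0, p[best] * m_tests)),
            }
        )
    df = pd.DataFrame(records)
    if df.empty:
        return df
    df["qvalue"] = stats.false_discovery_control(df["pvalue_gene_adj"].values, method="bh")
    df["egene"] = df["qvalue"] < fdr
    return df


def fine_mapped_from_truth(
    truth: SyntheticTruth,
    cohort: PhasedCohort,
    rng: np.random.Generator | None = None,
    pip_low: float = 0.91,
    n_max: int | None = None,
) -> list[FineMappedQtl]:
    """Fine-mapped-style records for the true causal variants.

    Each causal (variant, gene) pair becomes a record with the true signed
    effect and a PIP drawn above the usual credible-set threshold.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed + 3)
    by_id = {v.variant_id: v for v in cohort.variants}
    records = []
    for gene_id, gt in truth.genes.items():
        for vid, beta in zip(gt.causal_variant_ids, gt.betas):
            if beta == 0:
                continue
            records.append(
                FineMappedQtl(
                    variant=by_id[vid],
                    target=gene_id,
                    signed_effect=float(beta),
                    pip=float(rng.uniform(pip_low, 1.0)),
                )
            )
    if n_max is not None and len(records) > n_max:
        pick = rng.choice(len(records), size=n_max, replace=False)
        records = [records[i] for i in sorted(pick)]
    return records


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def emit_fixtures(
    genome: ReferenceGenome,
    cohort: PhasedCohort,
    genes: list[GeneAnnotation],
    expression: pd.DataFrame,
    eqtl_table: pd.DataFrame,
    truth: SyntheticTruth,
    cfg: SimConfig,
    out_dir: str | Path,
) -> dict[str, str]:
    """Write the fixture file set and return a path -> sha256 manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, out / "genome.fa")
    write_vcf(cohort, genome, out / "cohort.vcf")
    write_gene_table(genes, out / "genes.tsv")
    write_expression_table(expression, out / "expression.tsv")
    eqtl_table.to_csv(out / "qtl.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(truth.to_json())
    cfg_echo = asdict(cfg)
    cfg_echo["window"] = {
        "upstream_bp": cfg.window.upstream_bp,
        "downstream_bp": cfg.window.downstream_bp,
        "strand_aware": cfg.window.strand_aware,
    }
    (out / "config-echo.yaml").write_text(yaml.safe_dump(cfg_echo, sort_keys=True))
    files = [
        "genome.fa", "cohort.vcf", "genes.tsv", "expression.tsv",
        "qtl.tsv", "truth.json", "config-echo.yaml",
    ]
    manifest = {f: _sha256(out / f) for f in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
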