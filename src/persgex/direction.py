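"""Direction-of-effect classification for fine-mapped QTL variants.

For each putatively causal variant, the predictor is run on the reference
sequence and on the same sequence with only that variant substituted; the
sign of the prediction delta (alt minus ref) is compared with the sign of
the measured QTL effect.  Two aggregation modes:

* eQTL mode — the window is anchored at the target gene's TSS and the
  delta is aggregated with the gene-level TSS-window configuration;
* caQTL mode — the window is anchored at the variant and the delta is
  the sum over the three bins whose centres are nearest the variant.

Accuracy is summarized with a seeded bootstrap over variants.  Variants
whose delta is exactly zero have no defined sign and are excluded (and
counted), not scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GeneAnnotation, ReferenceGenome, VariantRecord
from .personalize import WindowSpec, resolve_window
from .predictors import AggregationConfig, Predictor, aggregate_tss_window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FineMappedQtl:
    """A high-confidence causal variant with a signed (alt-direction) effect."""

    variant: VariantRecord
    target: str  # gene_id (eQTL) or a peak label (caQTL)
    signed_effect: float
    pip: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pip <= 1.0):
            raise ValueError(f"{self.variant.variant_id}: PIP outside [0,1]")


@dataclass
class DirectionResult:
    n_evaluated: int
    n_correct: int
    n_zero_delta: int
    accuracy: float
    bootstrap_mean: float | None = None
    bootstrap_sd: float | None = None
    bootstrap_ci: tuple[float, float] | None = None
    n_bootstrap: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "n_correct": self.n_correct,
            "n_zero_delta": self.n_zero_delta,
            "accuracy": self.accuracy,
            "bootstrap_mean": self.bootstrap_mean,
            "bootstrap_sd": self.bootstrap_sd,
            "bootstrap_ci": list(self.bootstrap_ci) if self.bootstrap_ci else None,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }


def filter_fine_mapped(
    records: list[FineMappedQtl], pip_min: float = 0.9
) -> list[FineMappedQtl]:
    """Keep PIP > pip_min; then drop every variant whose retained records
    carry opposite-signed effects on different target genes."""
    kept = [r for r in records if r.pip > pip_min]
    signs: dict[str, set[int]] = {}
    for r in kept:
        signs.setdefault(r.variant.variant_id, set()).add(int(np.sign(r.signed_effect)))
    consistent = {vid for vid, s in signs.items() if not ({1, -1} <= s)}
    out = [r for r in kept if r.variant.variant_id in consistent]
    if not out:
        logger.warning("fine-mapping filter retained no records")
    return out


def _toggle_variant(window_seq: str, start0: int, variant: VariantRecord) -> str:
    offset = variant.pos0 - start0
    if not (0 <= offset < len(window_seq)):
        raise ValueError(
            f"variant {variant.variant_id} at {variant.chrom}:{variant.pos} "
            "lies outside the predictor window"
        )
    if window_seq[offset] != variant.ref_allele:
        raise ValueError(
            f"variant {variant.variant_id}: window base {window_seq[offset]!r} "
            f"differs from REF {variant.ref_allele!r}"
        )
    return window_seq[:offset] + variant.alt_allele + window_seq[offset + 1 :]


def _sum_closest_bins(track, variant_offset_bp: int, n_bins: int = 3) -> float:
    """Sum of the n bins whose centres are nearest the variant (ties ->
    smaller bin index), measured in 0-based coordinates."""
    centers = (np.arange(track.n_bins) + 0.5) * track.bin_size_bp
    dist = np.abs(centers - variant_offset_bp)
    order = np.lexsort((np.arange(track.n_bins), dist))
    return float(track.values[order[:n_bins]].sum())


def variant_delta(
    predictor: Predictor,
    genome: ReferenceGenome,
    variant: VariantRecord,
    cfg: AggregationConfig,
    *,
    gene: GeneAnnotation | None = None,
    spec: WindowSpec | None = None,
    mode: str = "eqtl",
    caqtl_window_bp: int | None = None,
    caqtl_n_bins: int = 3,
) -> float:
    """Prediction delta (alt - ref) for a single variant on the reference
    background.

    eQTL mode anchors the window at ``gene``'s TSS (requires ``gene`` and
    ``spec``) and aggregates with the gene-level TSS-window config; caQTL
    mode anchors the window at the variant and sums the ``caqtl_n_bins``
    bins closest to it (track predictors only).
    """
    if mode == "eqtl":
        if gene is None or spec is None:
            raise ValueError("eQTL mode requires gene annotation and window spec")
        interval = resolve_window(gene, spec, genome)
        ref_seq = genome.sequence(gene.chrom)[interval.start : interval.end]
        alt_seq = _toggle_variant(ref_seq, interval.start, variant)
        tss_offset = (
            spec.upstream_bp
            if not (spec.strand_aware and gene.strand == "-")
            else spec.downstream_bp
        )
        if predictor.is_track:
            ref_val = aggregate_tss_window(predictor.predict_track(ref_seq), tss_offset, cfg)
            alt_val = aggregate_tss_window(predictor.predict_track(alt_seq), tss_offset, cfg)
        else:
            ref_val = predictor.predict_scalar(ref_seq)
            alt_val = predictor.predict_scalar(alt_seq)
        return alt_val - ref_val
    if mode == "caqtl":
        if not predictor.is_track:
            raise ValueError("caQTL mode requires a track predictor")
        half = caqtl_window_bp if caqtl_window_bp is not None else 1920
        contig = genome.sequence(variant.chrom)
        start = variant.pos0 - half
        end = variant.pos0 + half
        if start < 0 or end > len(contig):
            raise ValueError(
                f"variant {variant.variant_id}: caQTL window exceeds contig bounds"
            )
        ref_seq = contig[start:end]
        alt_seq = _toggle_variant(ref_seq, start, variant)
        off = variant.pos0 - start
        ref_val = _sum_closest_bins(predictor.predict_track(ref_seq), off, caqtl_n_bins)
        alt_val = _sum_closest_bins(predictor.predict_track(alt_seq), off, caqtl_n_bins)
        return alt_val - ref_val
    raise ValueError(f"unknown mode {mode!r}")


def direction_accuracy(
    deltas: np.ndarray, effects: np.ndarray
) -> DirectionResult:
    """Fraction of variants whose delta sign matches the measured effect sign."""
    deltas = np.asarray(deltas, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if deltas.shape != effects.shape:
        raise ValueError("deltas and effects must be matched lists")
    nonzero = deltas != 0
    n_zero = int((~nonzero).sum())
    d, e = deltas[nonzero], effects[nonzero]
    if d.size == 0:
        raise ValueError("no evaluable records (all deltas zero)")
    correct = np.sign(d) == np.sign(e)
    return DirectionResult(
        n_evaluated=int(d.size),
        n_correct=int(correct.sum()),
        n_zero_delta=n_zero,
        accuracy=float(correct.mean()),
    )


def bootstrap_accuracy(
    deltas: np.ndarray,
    effects: np.ndarray,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> DirectionResult:
    """Point accuracy plus a seeded bootstrap (resampling variants) summary."""
    point = direction_accuracy(deltas, effects)
    deltas = np.asarray(deltas, dtype=float)
    effects = np.asarray(effects, dtype=float)
    nonzero = deltas != 0
    correct = (np.sign(deltas[nonzero]) == np.sign(effects[nonzero])).astype(float)
    rng = np.random.default_rng(seed)
    n = correct.size
    accs = np.array(
        [correct[rng.integers(0, n, size=n)].mean() for _ in range(n_bootstrap)]
    )
    point.bootstrap_mean = float(accs.mean())
    point.bootstrap_sd = float(accs.std(ddof=1)) if n_bootstrap > 1 else 0.0
    point.bootstrap_ci = (
        float(np.percentile(accs, 2.5)),
        float(np.percentile(accs, 97.5)),
    )
    point.n_bootstrap = n_bootstrap
    point.seed = seed
    return point
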