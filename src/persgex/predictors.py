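"""Predictor contract, aggregation rules, and synthetic oracle predictors.

Sequence-to-expression models come in two flavours: track predictors that
emit a binned signal (e.g. CAGE in 128-bp bins) which is reduced over a
window of bins around the TSS, and scalar predictors that emit one
expression value per input sequence.  This module implements the
aggregation conventions used when evaluating such models on personal
genomes — forward/reverse-complement averaging, +/-1-nt shift averaging,
TSS-window bin reduction and haplotype averaging — plus cross-model
ensembling, behind a deterministic :class:`Predictor` contract.

Trained deep networks are out of scope; the synthetic linear oracles stand
in for them, scoring sequences by additive per-position contributions tied
to a simulation's causal-variant truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .personalize import reverse_complement


@dataclass(frozen=True)
class BinnedTrack:
    """A non-negative prediction signal in fixed-width bins."""

    values: np.ndarray
    bin_size_bp: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("track must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")
        if self.bin_size_bp < 1:
            raise ValueError("bin size must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class AggregationConfig:
    """How raw predictor output is reduced to one expression value per gene.

    rc_average      : also predict on the reverse complement and average.
    shift_bp        : average over sequence shifts -s..+s (0 disables).
    tss_window_bins : number of bins reduced around the TSS bin (track
                      predictors only); the window is centred on the TSS
                      bin with the extra bin downstream when even.
    window_reduce   : 'mean' or 'sum' over the TSS window.
    haplotype_average : average the two haplotype predictions (fixed true
                      in the pipeline).
    """

    rc_average: bool = False
    shift_bp: int = 0
    tss_window_bins: int = 10
    window_reduce: str = "mean"
    haplotype_average: bool = True

    def __post_init__(self) -> None:
        if self.tss_window_bins < 1:
            raise ValueError("tss_window_bins must be >= 1")
        if self.shift_bp < 0:
            raise ValueError("shift_bp must be >= 0")
        if self.window_reduce not in ("mean", "sum"):
            raise ValueError("window_reduce must be 'mean' or 'sum'")


class Predictor:
    """Deterministic map from a sequence to a prediction.

    Subclasses implement exactly one of :meth:`predict_scalar` or
    :meth:`predict_track`.  ``is_track`` tells the harness which.
    """

    name: str = "predictor"
    is_track: bool = False
    bin_size_bp: int | None = None
    deterministic: bool = True

    def predict_scalar(self, sequence: str) -> float:
        raise NotImplementedError

    def predict_track(self, sequence: str) -> BinnedTrack:
        raise NotImplementedError


@dataclass
class SyntheticOracleWeights:
    """Additive per-position scores for one gene's window.

    ``contributions`` maps (0-based window offset, base) to a score added
    when the sequence carries that base at that offset.  Offsets listed in
    ``corrupted_offsets`` have their contribution sign-flipped — emulating
    a model that detects a regulatory variant but mistakes its direction.
    ``noise_sd`` adds a deterministic, sequence-hash-seeded pseudo-noise
    term so the oracle remains a pure function of its input.
    """

    contributions: Mapping[tuple[int, str], float]
    baseline: float = 0.0
    corrupted_offsets: frozenset[int] = frozenset()
    noise_sd: float = 0.0
    window_length: int | None = None

    def score(self, sequence: str) -> float:
        if self.window_length is not None and len(sequence) != self.window_length:
            raise ValueError(
                f"sequence length {len(sequence)} != window {self.window_length}"
            )
        total = self.baseline
        for (offset, base), contrib in self.contributions.items():
            if sequence[offset] == base:
                total += -contrib if offset in self.corrupted_offsets else contrib
        if self.noise_sd > 0:
            total += self.noise_sd * _sequence_noise(sequence)
        return total


def _sequence_noise(sequence: str) -> float:
    """Standard-normal deviate derived from a hash of the sequence."""
    digest = hashlib.blake2b(sequence.encode(), digest_size=8).digest()
    seed = int.from_bytes(digest, "little") % (2**31)
    return float(np.random.default_rng(seed).standard_normal())


def oracle_score(sequence: str, weights: SyntheticOracleWeights) -> float:
    """Score a window sequence with a linear oracle (pure function)."""
    return weights.score(sequence)


class LinearScalarOracle(Predictor):
    """Scalar predictor wrapping one gene's oracle weights."""

    is_track = False

    def __init__(self, weights: SyntheticOracleWeights, name: str = "linear_oracle"):
        self.weights = weights
        self.name = name

    def predict_scalar(self, sequence: str) -> float:
        return self.weights.score(sequence)


class LinearTrackOracle(Predictor):
    """Track predictor: bin b carries the oracle contributions falling in it.

    Every bin gets ``baseline`` plus the summed (possibly sign-corrupted)
    contributions of the offsets inside the bin.  Mirrors the structure of
    binned CAGE/DNase outputs at toy scale.
    """

    is_track = True

    def __init__(
        self,
        weights: SyntheticOracleWeights,
        bin_size_bp: int = 128,
        name: str = "linear_track_oracle",
    ):
        self.weights = weights
        self.bin_size_bp = bin_size_bp
        self.name = name

    def predict_track(self, sequence: str) -> BinnedTrack:
        n_bins = len(sequence) // self.bin_size_bp
        if n_bins < 1:
            raise ValueError("sequence shorter than one bin")
        values = np.full(n_bins, self.weights.baseline, dtype=float)
        for (offset, base), contrib in self.weights.contributions.items():
            b = offset // self.bin_size_bp
            if b < n_bins and sequence[offset] == base:
                c = -contrib if offset in self.weights.corrupted_offsets else contrib
                values[b] += c
        if self.weights.noise_sd > 0:
            values = values + self.weights.noise_sd * _sequence_noise(sequence)
        return BinnedTrack(values, self.bin_size_bp)


class ConstantPredictor(Predictor):
    """Predicts the same value regardless of sequence (diagnostic)."""

    is_track = False

    def __init__(self, value: float, name: str = "constant"):
        self.value = float(value)
        self.name = name

    def predict_scalar(self, sequence: str) -> float:
        return self.value


def aggregate_tss_window(
    track: BinnedTrack, tss_offset_bp: int, cfg: AggregationConfig
) -> float:
    """Reduce the track over ``cfg.tss_window_bins`` bins around the TSS bin.

    With W bins the window is [t - floor((W-1)/2), t + ceil((W-1)/2)]
    inclusive, where t is the bin containing the TSS offset; the extra bin
    sits downstream when W is even.
    """
    t = tss_offset_bp // track.bin_size_bp
    if not (0 <= t < track.n_bins):
        raise ValueError(f"TSS bin {t} outside track of {track.n_bins} bins")
    w = cfg.tss_window_bins
    lo = t - (w - 1) // 2
    hi = t + w // 2  # inclusive
    if lo < 0 or hi >= track.n_bins:
        raise ValueError(
            f"TSS window [{lo}, {hi}] exceeds track bounds (0, {track.n_bins - 1})"
        )
    window = track.values[lo : hi + 1]
    return float(window.mean() if cfg.window_reduce == "mean" else window.sum())


def _shifted(sequence: str, delta: int) -> str:
    """Window content shifted by ``delta`` bp; vacated edge padded with N."""
    if delta == 0:
        return sequence
    if delta > 0:
        return sequence[delta:] + "N" * delta
    return "N" * (-delta) + sequence[:delta]


def _predict_one_sequence(
    predictor: Predictor, sequence: str, tss_offset_bp: int, cfg: AggregationConfig
) -> float:
    """Average predictor output over the shift/RC sequence variants."""
    length = len(sequence)
    values: list[float] = []
    for delta in range(-cfg.shift_bp, cfg.shift_bp + 1):
        seq = _shifted(sequence, delta)
        offset = tss_offset_bp - delta
        orientations = [(seq, offset)]
        if cfg.rc_average:
            orientations.append((reverse_complement(seq), length - 1 - offset))
        for s, off in orientations:
            if predictor.is_track:
                values.append(aggregate_tss_window(predictor.predict_track(s), off, cfg))
            else:
                values.append(predictor.predict_scalar(s))
    return float(np.mean(values))


def predict_gene(
    predictor: Predictor,
    sequences: Sequence[str],
    tss_offset_bp: int,
    cfg: AggregationConfig,
) -> float:
    """One expression value for a (gene, individual): haplotype-averaged,
    shift/RC-averaged, TSS-window-aggregated predictor output."""
    if not sequences:
        raise ValueError("no haplotype sequences given")
    if len({len(s) for s in sequences}) != 1:
        raise ValueError("haplotype sequences differ in length")
    per_hap = [
        _predict_one_sequence(predictor, s, tss_offset_bp, cfg) for s in sequences
    ]
    if cfg.haplotype_average:
        return float(np.mean(per_hap))
    return float(np.sum(per_hap))


def run_predictions(
    predictors: Mapping[str, Predictor] | Predictor,
    personal_sequences: Mapping[tuple[str, str], tuple[str, str]],
    reference_windows: Mapping[str, str],
    tss_offsets: Mapping[str, int],
    cfg: AggregationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Predict every (gene, individual) pair plus the reference sequence.

    ``predictors`` is either one Predictor used for all genes or a mapping
    gene_id -> Predictor (the oracle bank case).  Returns a genes x
    individuals DataFrame and a per-gene reference-prediction Series.
    """
    genes = list(reference_windows)
    individuals = sorted({ind for (_, ind) in personal_sequences})
    missing = [
        (g, i)
        for g in genes
        for i in individuals
        if (g, i) not in personal_sequences
    ]
    if missing:
        raise ValueError(f"missing personal sequences for pairs: {missing[:5]}...")

    def predictor_for(gene: str) -> Predictor:
        if isinstance(predictors, Predictor):
            return predictors
        return predictors[gene]

    values = np.empty((len(genes), len(individuals)))
    ref_values = np.empty(len(genes))
    for gi, gene in enumerate(genes):
        p = predictor_for(gene)
        off = tss_offsets[gene]
        for ii, ind in enumerate(individuals):
            values[gi, ii] = predict_gene(
                p, personal_sequences[(gene, ind)], off, cfg
            )
        ref_values[gi] = predict_gene(p, (reference_windows[gene],), off, cfg)
    matrix = pd.DataFrame(values, index=genes, columns=individuals)
    ref = pd.Series(ref_values, index=genes)
    return matrix, ref


def ensemble(matrices: Sequence[pd.DataFrame], mode: str = "raw_mean") -> pd.DataFrame:
    """Combine prediction matrices across models.

    raw_mean    : elementwise mean.
    zscore_mean : standardise each matrix per gene across individuals
                  (zero-variance rows pass through as zeros), then mean.
    """
    if not matrices:
        raise ValueError("no matrices to ensemble")
    first = matrices[0]
    for m in matrices[1:]:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise ValueError("ensemble inputs must share gene/individual indices")
    if mode == "raw_mean":
        stacked = np.stack([m.values for m in matrices])
    elif mode == "zscore_mean":
        zs = []
        for m in matrices:
            mu = m.values.mean(axis=1, keepdims=True)
            sd = m.values.std(axis=1, ddof=0, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (m.values - mu) / sd
            z[np.broadcast_to(sd == 0, z.shape)] = 0.0
            zs.append(z)
        stacked = np.stack(zs)
    else:
        raise ValueError(f"unknown ensemble mode {mode!r}")
    return pd.DataFrame(stacked.mean(axis=0), index=first.index, columns=first.columns)
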