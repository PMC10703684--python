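"""Construction of per-haplotype personal input sequences around gene TSSs.

Each gene gets a window anchored at its transcription start site; the
individual's phased SNVs inside the window are substituted into the
reference slice, one haplotype at a time.  Strand-aware asymmetric windows
(used by models with asymmetric receptive fields) are mirrored for
negative-strand genes and the personalised sequence is reverse-complemented
so that output is always in gene orientation; symmetric windows default to
genome orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

from .io import GeneAnnotation, PhasedCohort, ReferenceGenome

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class WindowSpec:
    """Input window size around the TSS, in gene orientation when strand_aware."""

    upstream_bp: int
    downstream_bp: int
    strand_aware: bool = False

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be non-negative")
        if self.upstream_bp + self.downstream_bp <= 0:
            raise ValueError("window must have positive total length")

    @property
    def length(self) -> int:
        return self.upstream_bp + self.downstream_bp


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PersonalSequence:
    gene_id: str
    individual_id: str
    haplotype: int
    sequence: str
    n_variants_applied: int


class WindowOutOfBoundsError(ValueError):
    """A gene window does not fit inside its contig."""


def resolve_window(
    gene: GeneAnnotation, spec: WindowSpec, genome: ReferenceGenome | None = None
) -> GenomicInterval:
    """Genomic interval covered by ``spec`` around the gene TSS.

    For strand-aware specs on the minus strand the upstream/downstream
    extents are mirrored in genome coordinates (the sequence is later
    reverse-complemented into gene orientation); plus-strand genes and
    non-strand-aware specs use [tss0 - upstream, tss0 + downstream).
    """
    tss0 = gene.tss0
    if spec.strand_aware and gene.strand == "-":
        start, end = tss0 - spec.downstream_bp, tss0 + spec.upstream_bp
    else:
        start, end = tss0 - spec.upstream_bp, tss0 + spec.downstream_bp
    if start < 0:
        raise WindowOutOfBoundsError(
            f"{gene.gene_id}: window start {start} < 0 on {gene.chrom}"
        )
    if genome is not None:
        contig_len = len(genome.sequence(gene.chrom))
        if end > contig_len:
            raise WindowOutOfBoundsError(
                f"{gene.gene_id}: window end {end} exceeds contig "
                f"{gene.chrom} length {contig_len}"
            )
    return GenomicInterval(gene.chrom, start, end)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over A/C/G/T/N."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def apply_haplotype(
    ref_window: str,
    interval: GenomicInterval,
    cohort: PhasedCohort,
    individual_id: str,
    haplotype: int,
) -> tuple[str, int]:
    """Substitute one haplotype's alt alleles into the reference window.

    ``ref_window`` must be the genome-orientation reference slice of
    ``interval``.  Returns the edited sequence and the number of
    substitutions applied.
    """
    if len(ref_window) != interval.length:
        raise ValueError("ref_window length does not match interval")
    ind_idx = cohort.individual_index(individual_id)
    out = list(ref_window)
    n_applied = 0
    for vi in cohort.variants_in(interval.chrom, interval.start, interval.end):
        v = cohort.variants[vi]
        offset = v.pos0 - interval.start
        if ref_window[offset] != v.ref_allele:
            raise ValueError(
                f"variant {v.variant_id}: window base {ref_window[offset]!r} "
                f"differs from REF {v.ref_allele!r}"
            )
        if cohort.haplotypes[vi, ind_idx, haplotype] == 1:
            out[offset] = v.alt_allele
            n_applied += 1
    return "".join(out), n_applied


def build_personal_sequences(
    genome: ReferenceGenome,
    genes: list[GeneAnnotation],
    cohort: PhasedCohort,
    spec: WindowSpec,
) -> Iterator[PersonalSequence]:
    """Emit two haplotype sequences per (gene, individual).

    Strand-aware minus-strand sequences are reverse-complemented after
    variant application, so output is in gene orientation.
    """
    for gene in genes:
        interval = resolve_window(gene, spec, genome)
        ref_window = genome.sequence(gene.chrom)[interval.start : interval.end]
        flip = spec.strand_aware and gene.strand == "-"
        # window variants are shared across individuals; resolve them once
        var_idx = cohort.variants_in(interval.chrom, interval.start, interval.end)
        edits = []
        for vi in var_idx:
            v = cohort.variants[vi]
            offset = v.pos0 - interval.start
            if ref_window[offset] != v.ref_allele:
                raise ValueError(
                    f"variant {v.variant_id}: window base {ref_window[offset]!r} "
                    f"differs from REF {v.ref_allele!r}"
                )
            edits.append((vi, offset, v.alt_allele))
        for individual in cohort.individuals:
            ind_idx = cohort.individual_index(individual)
            for hap in (0, 1):
                out = list(ref_window)
                n_applied = 0
                for vi, offset, alt in edits:
                    if cohort.haplotypes[vi, ind_idx, hap] == 1:
                        out[offset] = alt
                        n_applied += 1
                seq = "".join(out)
                if flip:
                    seq = reverse_complement(seq)
                yield PersonalSequence(gene.gene_id, individual, hap, seq, n_applied)


def collect_personal_sequences(
    genome: ReferenceGenome,
    genes: list[GeneAnnotation],
    cohort: PhasedCohort,
    spec: WindowSpec,
) -> dict[tuple[str, str], tuple[str, str]]:
    """Materialize both haplotype sequences per (gene, individual) pair."""
    out: dict[tuple[str, str], list[str | None]] = {}
    for ps in build_personal_sequences(genome, genes, cohort, spec):
        pair = out.setdefault((ps.gene_id, ps.individual_id), [None, None])
        pair[ps.haplotype] = ps.sequence
    return {k: (v[0], v[1]) for k, v in out.items()}


def reference_window_sequence(
    genome: ReferenceGenome, gene: GeneAnnotation, spec: WindowSpec
) -> str:
    """The gene's reference window sequence, oriented like personal sequences."""
    interval = resolve_window(gene, spec, genome)
    seq = genome.sequence(gene.chrom)[interval.start : interval.end]
    if spec.strand_aware and gene.strand == "-":
        seq = reverse_complement(seq)
    return seq


def write_personal_fasta(sequences, path) -> None:
    """Export personal sequences as FASTA, one record per (gene, individual, hap)."""
    with open(path, "w") as fh:
        for ps in sequences:
            fh.write(f">{ps.gene_id}|{ps.individual_id}|hap{ps.haplotype}\n")
            for i in range(0, len(ps.sequence), 60):
                fh.write(ps.sequence[i : i + 60] + "\n")
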