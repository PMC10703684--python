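"""Readers and writers for the formats the pipeline touches.

FASTA references, phased VCF cohorts and the three TSV table schemas
(gene annotation, expression matrix, QTL table) are loaded into validated
in-memory representations.  All external coordinates are 1-based (VCF /
annotation convention); the conversion to 0-based half-open happens here,
exactly once, and every internal interval computation downstream is
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
_SNV_BASES = set("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its expected format or content."""


@dataclass(frozen=True)
class ReferenceGenome:
    """Mapping from chromosome name to an uppercase A/C/G/T/N sequence."""

    contigs: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains non-IUPAC characters {sorted(bad)}"
                )

    def sequence(self, chrom: str) -> str:
        try:
            return self.contigs[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.contigs


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV. ``pos`` is 1-based; ``pos0`` is the 0-based coordinate."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_id: str

    def __post_init__(self) -> None:
        if self.ref_allele not in _SNV_BASES or self.alt_allele not in _SNV_BASES:
            raise FormatError(
                f"{self.variant_id}: alleles must be single bases in ACGT, "
                f"got {self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"{self.variant_id}: REF equals ALT")
        if self.pos < 1:
            raise FormatError(f"{self.variant_id}: position must be >= 1")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass
class PhasedCohort:
    """Phased SNV genotypes for a set of individuals.

    ``haplotypes`` has shape (n_variants, n_individuals, 2) with entries in
    {0, 1}: 0 = reference allele, 1 = alternate allele.  Variants are sorted
    by (chrom, pos) with no duplicate sites.
    """

    variants: list[VariantRecord]
    individuals: list[str]
    haplotypes: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        expected = (len(self.variants), len(self.individuals), 2)
        if self.haplotypes.shape != expected:
            raise ValueError(
                f"haplotype array shape {self.haplotypes.shape} != {expected}"
            )
        keys = [(v.chrom, v.pos) for v in self.variants]
        if keys != sorted(keys):
            raise FormatError("variants are not sorted by (chrom, pos)")
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (chrom, pos) among variants")
        # variants are sorted, so per-chrom index ranges are contiguous
        self._chrom_index: dict[str, list[int]] = {}
        for i, v in enumerate(self.variants):
            if v.chrom not in self._chrom_index:
                self._chrom_index[v.chrom] = [i, i + 1]
            else:
                self._chrom_index[v.chrom][1] = i + 1
        self._pos0_cache: dict[str, np.ndarray] = {}
        self._ind_index = {ind: j for j, ind in enumerate(self.individuals)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def chrom_slice(self, chrom: str) -> tuple[int, int]:
        """Index range [lo, hi) of variants on ``chrom``."""
        lo, hi = self._chrom_index.get(chrom, (0, 0))
        return lo, hi

    def individual_index(self, individual_id: str) -> int:
        try:
            return self._ind_index[individual_id]
        except KeyError:
            raise KeyError(f"unknown individual {individual_id!r}") from None

    def variants_in(self, chrom: str, start0: int, end0: int) -> list[int]:
        """Indices of variants with start0 <= pos0 < end0 on ``chrom``."""
        lo, hi = self.chrom_slice(chrom)
        if chrom not in self._pos0_cache:
            self._pos0_cache[chrom] = np.fromiter(
                (v.pos0 for v in self.variants[lo:hi]), dtype=np.int64, count=hi - lo
            )
        pos0 = self._pos0_cache[chrom]
        a = int(np.searchsorted(pos0, start0, side="left"))
        b = int(np.searchsorted(pos0, end0, side="left"))
        return list(range(lo + a, lo + b))

    def dosages(self, variant_indices: list[int]) -> np.ndarray:
        """Alt-allele dosage matrix (individuals x variants) in {0,1,2}."""
        if not variant_indices:
            return np.zeros((len(self.individuals), 0), dtype=np.int64)
        h = self.haplotypes[variant_indices]  # (m, n, 2)
        return h.sum(axis=2).T.astype(np.int64)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene id with TSS anchor. ``tss`` is 1-based; ``tss0`` is 0-based."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise FormatError(f"{self.gene_id}: TSS must be >= 1")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss0(self) -> int:
        return self.tss - 1


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file into a :class:`ReferenceGenome`.

    Sequences are uppercased; the header token before the first whitespace
    becomes the chromosome name.  Duplicate contig names, empty sequences
    and characters outside A/C/G/T/N are errors.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in contigs:
            raise FormatError(f"duplicate contig name {name!r} in {path}")
        contigs[name] = str(rec.seq).upper()
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return ReferenceGenome(contigs)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 60) -> None:
    """Write contigs in insertion order, wrapped at ``width`` columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_phased_vcf(path: str | Path, genome: ReferenceGenome) -> PhasedCohort:
    """Load phased biallelic SNVs from a VCF into a :class:`PhasedCohort`.

    Indels and multiallelic records are skipped (counted); unphased or
    missing genotype calls are hard errors naming the individual and site;
    REF alleles are validated against ``genome``.
    """
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                n_skipped += 1
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            if ref not in _SNV_BASES or alt not in _SNV_BASES:
                n_skipped += 1
                continue
            chrom, pos = rec.chrom, rec.pos
            genome_base = genome.sequence(chrom)[pos - 1]
            if genome_base != ref:
                raise FormatError(
                    f"REF mismatch at {chrom}:{pos}: VCF says {ref}, "
                    f"genome has {genome_base}"
                )
            vid = rec.id or f"{chrom}:{pos}:{ref}:{alt}"
            calls = np.empty((len(samples), 2), dtype=np.uint8)
            for j, sample in enumerate(samples):
                call = rec.samples[sample]
                gt = call.get("GT")
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    raise FormatError(
                        f"missing genotype for {sample} at {chrom}:{pos}"
                    )
                if not call.phased:
                    raise FormatError(
                        f"unphased genotype for {sample} at {chrom}:{pos}"
                    )
                calls[j, 0], calls[j, 1] = gt
            variants.append(VariantRecord(chrom, pos, ref, alt, vid))
            rows.append(calls)
    if n_skipped:
        logger.info("skipped %d non-SNV/multiallelic VCF records", n_skipped)
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    variants = [variants[i] for i in order]
    hap = (
        np.stack([rows[i] for i in order]).transpose(0, 1, 2)
        if rows
        else np.zeros((0, len(samples), 2), dtype=np.uint8)
    )
    return PhasedCohort(variants, samples, hap, n_skipped=n_skipped)


def write_vcf(cohort: PhasedCohort, genome: ReferenceGenome, path: str | Path) -> None:
    """Write the cohort as a minimal phased VCF v4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.individuals)
            + "\n"
        )
        for i, v in enumerate(cohort.variants):
            gts = "\t".join(
                f"{a}|{b}" for a, b in cohort.haplotypes[i]
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref_allele}\t"
                f"{v.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


_GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand"]
_QTL_COLUMNS = [
    "gene_id", "variant_id", "chrom", "pos", "ref", "alt",
    "beta", "pvalue", "pip", "maf",
]


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read genes.tsv (gene_id, chrom, tss, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"gene table missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene id {dup!r}")
    return [
        GeneAnnotation(r.gene_id, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples()
    ]


def read_expression_table(
    path: str | Path, cohort: PhasedCohort | None = None
) -> pd.DataFrame:
    """Read expression.tsv into a genes x individuals DataFrame.

    With ``cohort`` given, columns are realigned to the cohort's individual
    order; individuals present on only one side are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError("expression table missing 'gene_id' column")
    if df["gene_id"].duplicated().any():
        raise FormatError("duplicate gene id in expression table")
    df = df.set_index("gene_id")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        gene = df.index[df[col].isna()][0]
        raise FormatError(f"missing expression value at gene {gene!r}, individual {col!r}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"unparsable numeric cell in expression table: {exc}") from None
    if cohort is not None:
        values = align_expression(values, cohort)
    return values


def align_expression(expr: pd.DataFrame, cohort: PhasedCohort) -> pd.DataFrame:
    """Restrict and reorder expression columns to the cohort individuals."""
    shared = [i for i in cohort.individuals if i in expr.columns]
    dropped = (set(expr.columns) | set(cohort.individuals)) - set(shared)
    if dropped:
        logger.warning(
            "dropping %d individuals absent from the genotype/expression overlap",
            len(dropped),
        )
    return expr[shared]


def read_qtl_table(path: str | Path) -> pd.DataFrame:
    """Read qtl.tsv (gene_id, variant_id, chrom, pos, ref, alt, beta, pvalue, pip, maf)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_QTL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"QTL table missing columns {sorted(missing)}")
    for col in ("pos", "beta", "pvalue", "pip", "maf"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"QTL column {col!r} is not numeric")
    return df


def read_table(path: str | Path, schema: str, cohort: PhasedCohort | None = None):
    """Dispatch table reading by schema name: gene_annotation | expression | qtl."""
    if schema == "gene_annotation":
        return read_gene_table(path)
    if schema == "expression":
        return read_expression_table(path, cohort=cohort)
    if schema == "qtl":
        return read_qtl_table(path)
    raise ValueError(f"unknown table schema {schema!r}")


def write_expression_table(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def write_gene_table(genes: list[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss, "strand": g.strand}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)
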