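"""Shared fixtures: a tiny hand-built cohort and a small simulated study."""

import numpy as np
import pytest

from persgex.io import (
    GeneAnnotation,
    PhasedCohort,
    ReferenceGenome,
    VariantRecord,
)
from persgex.personalize import WindowSpec
from persgex.simulate import SimConfig, simulate_cohort, simulate_expression


@pytest.fixture
def tiny_genome():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    return ReferenceGenome({"chr1": seq, "chr2": seq[::-1]})


def make_cohort(genome, sites, genotypes, individuals=("A", "B")):
    """Build a PhasedCohort from (chrom, pos1, alt) sites and explicit
    per-individual haplotype pairs."""
    variants = []
    for chrom, pos, alt in sites:
        ref = genome.sequence(chrom)[pos - 1]
        variants.append(VariantRecord(chrom, pos, ref, alt, f"{chrom}:{pos}"))
    hap = np.array(genotypes, dtype=np.uint8)
    return PhasedCohort(variants, list(individuals), hap)


@pytest.fixture
def tiny_cohort(tiny_genome):
    def alt_of(chrom, pos):
        ref = tiny_genome.sequence(chrom)[pos - 1]
        return "A" if ref != "A" else "G"

    sites = [("chr1", p, alt_of("chr1", p)) for p in (50, 120, 200, 260, 330)]
    # genotypes[variant][individual] = (hap0, hap1)
    genotypes = [
        [(0, 1), (1, 1)],
        [(0, 0), (0, 1)],
        [(1, 0), (0, 0)],
        [(1, 1), (1, 0)],
        [(0, 1), (0, 0)],
    ]
    return make_cohort(tiny_genome, sites, genotypes)


@pytest.fixture(scope="session")
def small_study():
    """A 50-individual, 8-gene simulated study with moderate heritability."""
    cfg = SimConfig(
        n_individuals=50,
        n_genes=8,
        n_contigs=2,
        window=WindowSpec(300, 300, strand_aware=False),
        variant_density=0.02,
        n_causal=3,
        h2=0.8,
        seed=11,
    )
    rng = np.random.default_rng(cfg.seed)
    genome, cohort, genes = simulate_cohort(cfg, rng)
    expr, truth = simulate_expression(cohort, genes, cfg, rng)
    return cfg, genome, cohort, genes, expr, truth
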