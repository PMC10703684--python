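"""Synthetic cohort generator: genotypes, expression model, truth consistency."""

import json

import numpy as np
import pytest
from scipy import stats

from persgex.evaluation import spearman
from persgex.io import read_expression_table, read_fasta, read_gene_table, read_phased_vcf
from persgex.personalize import WindowSpec, collect_personal_sequences, reference_window_sequence
from persgex.predictors import AggregationConfig, LinearScalarOracle, run_predictions
from persgex.simulate import (
    SimConfig,
    SyntheticTruth,
    emit_fixtures,
    fine_mapped_from_truth,
    make_oracle_weights,
    marginal_eqtl_scan,
    simulate_cohort,
    simulate_expression,
)


def _study(**kw):
    cfg = SimConfig(**kw)
    rng = np.random.default_rng(cfg.seed)
    genome, cohort, genes = simulate_cohort(cfg, rng)
    expr, truth = simulate_expression(cohort, genes, cfg, rng)
    return cfg, genome, cohort, genes, expr, truth


class TestSimulateCohort:
    def test_zero_density_cohort_has_no_variants(self):
        cfg = SimConfig(
            n_individuals=2, n_genes=1, n_contigs=1, variant_density=0.0,
            n_causal=0, window=WindowSpec(100, 100, False), seed=1,
        )
        genome, cohort, genes = simulate_cohort(cfg)
        assert cohort.n_variants == 0
        seqs = collect_personal_sequences(genome, genes, cohort, cfg.window)
        ref = reference_window_sequence(genome, genes[0], cfg.window)
        assert all(pair == (ref, ref) for pair in seqs.values())

    def test_allele_frequencies_concentrate_near_maf(self):
        cfg = SimConfig(
            n_individuals=1000, n_genes=2, n_contigs=1, variant_density=0.01,
            n_causal=2, window=WindowSpec(300, 300, False), seed=2,
        )
        genome, cohort, genes = simulate_cohort(cfg)
        freq = cohort.haplotypes.reshape(cohort.n_variants, -1).mean(axis=1)
        assert np.all((freq > 0) & (freq < 1))
        # binomial concentration: sd of freq at n=2000 draws is < 0.012
        assert freq.min() > cfg.maf_low - 5 * 0.012
        assert freq.max() < cfg.maf_high + 5 * 0.012

    def test_hardy_weinberg_genotype_frequencies(self):
        cfg = SimConfig(
            n_individuals=1000, n_genes=2, n_contigs=1, variant_density=0.01,
            n_causal=2, window=WindowSpec(300, 300, False), seed=3,
        )
        genome, cohort, genes = simulate_cohort(cfg)
        dos = cohort.haplotypes.sum(axis=2)  # (m, n)
        n = dos.shape[1]
        n_reject = 0
        for row in dos:
            p = row.mean() / 2
            expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            observed = np.array([(row == k).sum() for k in (0, 1, 2)])
            chi2 = ((observed - expected) ** 2 / expected).sum()
            if stats.chi2.sf(chi2, df=1) < 0.001:
                n_reject += 1
        assert n_reject <= max(1, 0.01 * cohort.n_variants)

    def test_same_seed_byte_identical_fixtures(self, tmp_path):
        manifests = []
        for d in ("a", "b"):
            cfg, genome, cohort, genes, expr, truth = _study(
                n_individuals=20, n_genes=4, n_contigs=2, variant_density=0.02,
                n_causal=2, window=WindowSpec(200, 200, False), seed=9,
            )
            eqtl = marginal_eqtl_scan(cohort, expr, genes, window_bp=200)
            manifests.append(
                emit_fixtures(genome, cohort, genes, expr, eqtl, truth, cfg, tmp_path / d)
            )
        assert manifests[0] == manifests[1]

    def test_alternating_strands_and_window_fit(self):
        cfg, genome, cohort, genes, *_ = _study(
            n_individuals=10, n_genes=6, n_contigs=2, variant_density=0.02,
            n_causal=1, window=WindowSpec(150, 150, False), seed=4,
        )
        assert {g.strand for g in genes} == {"+", "-"}
        for g in genes:
            assert g.tss0 - 150 >= 0
            assert g.tss0 + 150 <= len(genome.sequence(g.chrom))


class TestSimulateExpression:
    def test_h2_one_expression_is_affine_in_genetic_value(self):
        cfg, genome, cohort, genes, expr, truth = _study(
            n_individuals=50, n_genes=4, n_contigs=1, variant_density=0.02,
            n_causal=3, h2=1.0, window=WindowSpec(300, 300, False), seed=5,
        )
        for g in genes:
            gt = truth.genes[g.gene_id]
            y = expr.loc[g.gene_id].values
            np.testing.assert_allclose(y - y.min(), gt.genetic_values - gt.genetic_values.min(), atol=1e-12)
            assert spearman(gt.genetic_values, y) == pytest.approx(1.0)

    def test_h2_zero_expression_independent_of_genotype(self):
        cfg, genome, cohort, genes, expr, truth = _study(
            n_individuals=400, n_genes=10, n_contigs=1, variant_density=0.02,
            n_causal=3, h2=0.0, window=WindowSpec(300, 300, False), seed=6,
        )
        # no causal architecture is recorded for pure-noise genes
        for g in genes:
            assert truth.genes[g.gene_id].causal_variant_ids == []

    def test_variance_ratio_matches_target_h2(self):
        cfg, genome, cohort, genes, expr, truth = _study(
            n_individuals=1000, n_genes=12, n_contigs=1, variant_density=0.02,
            n_causal=5, h2=0.5, window=WindowSpec(300, 300, False), seed=7,
        )
        realized = [truth.genes[g.gene_id].realized_h2 for g in genes]
        assert np.mean(realized) == pytest.approx(0.5, abs=0.05)

    def test_expression_non_negative(self, small_study):
        *_, expr, _ = small_study
        assert (expr.values >= 0).all()


class TestOracleWeights:
    def test_uncorrupted_oracle_ranks_match_genetic_value(self, small_study):
        cfg, genome, cohort, genes, expr, truth = small_study
        weights = make_oracle_weights(truth, cohort, genes, cfg)
        bank = {g: LinearScalarOracle(w) for g, w in weights.items()}
        seqs = collect_personal_sequences(genome, genes, cohort, cfg.window)
        refs = {g.gene_id: reference_window_sequence(genome, g, cfg.window) for g in genes}
        offs = {g.gene_id: cfg.window.upstream_bp for g in genes}
        pred, _ = run_predictions(bank, seqs, refs, offs, AggregationConfig())
        for g in genes:
            gt = truth.genes[g.gene_id]
            # haplotype averaging halves the genotype-space genetic value;
            # ulp-level float differences can reorder exact dosage ties, so
            # assert numeric equivalence rather than exact rank equality
            np.testing.assert_allclose(
                pred.loc[g.gene_id].values, 0.5 * np.asarray(gt.genetic_values),
                atol=1e-9,
            )
            assert spearman(pred.loc[g.gene_id].values, gt.genetic_values) > 0.99

    def test_full_corruption_single_causal_reverses_ranks(self):
        cfg, genome, cohort, genes, expr, truth = _study(
            n_individuals=40, n_genes=4, n_contigs=1, variant_density=0.02,
            n_causal=1, h2=1.0, sign_corruption_rate=1.0,
            window=WindowSpec(300, 300, False), seed=8,
        )
        weights = make_oracle_weights(truth, cohort, genes, cfg)
        bank = {g: LinearScalarOracle(w) for g, w in weights.items()}
        seqs = collect_personal_sequences(genome, genes, cohort, cfg.window)
        refs = {g.gene_id: reference_window_sequence(genome, g, cfg.window) for g in genes}
        offs = {g.gene_id: cfg.window.upstream_bp for g in genes}
        pred, _ = run_predictions(bank, seqs, refs, offs, AggregationConfig())
        for g in genes:
            gt = truth.genes[g.gene_id]
            assert spearman(pred.loc[g.gene_id].values, gt.genetic_values) == pytest.approx(-1.0)

    def test_weights_sparse_only_causal_positions(self, small_study):
        cfg, genome, cohort, genes, expr, truth = small_study
        weights = make_oracle_weights(truth, cohort, genes, cfg)
        for g in genes:
            assert len(weights[g.gene_id].contributions) == cfg.n_causal

    def test_minus_strand_strand_aware_weights_consistent(self):
        """With a strand-aware window, oracle scores through the pipeline
        still equal the genotype-space dosage computation on minus genes."""
        cfg, genome, cohort, genes, expr, truth = _study(
            n_individuals=30, n_genes=4, n_contigs=1, variant_density=0.02,
            n_causal=2, h2=1.0, window=WindowSpec(240, 120, True), seed=12,
        )
        assert any(g.strand == "-" for g in genes)
        weights = make_oracle_weights(truth, cohort, genes, cfg)
        bank = {g: LinearScalarOracle(w) for g, w in weights.items()}
        seqs = collect_personal_sequences(genome, genes, cohort, cfg.window)
        refs = {g.gene_id: reference_window_sequence(genome, g, cfg.window) for g in genes}
        offs = {g.gene_id: cfg.window.upstream_bp for g in genes}
        pred, _ = run_predictions(bank, seqs, refs, offs, AggregationConfig())
        vid = {v.variant_id: i for i, v in enumerate(cohort.variants)}
        for g in genes:
            gt = truth.genes[g.gene_id]
            d = cohort.dosages([vid[v] for v in gt.causal_variant_ids]).astype(float)
            np.testing.assert_allclose(
                pred.loc[g.gene_id].values, 0.5 * d @ gt.betas, atol=1e-9
            )


class TestEqtlScan:
    def test_monomorphic_cohort_gene_excluded(self):
        cfg = SimConfig(
            n_individuals=10, n_genes=2, n_contigs=1, variant_density=0.0,
            n_causal=0, h2=0.0, window=WindowSpec(100, 100, False), seed=13,
        )
        rng = np.random.default_rng(cfg.seed)
        genome, cohort, genes = simulate_cohort(cfg, rng)
        expr, _ = simulate_expression(cohort, genes, cfg, rng)
        scan = marginal_eqtl_scan(cohort, expr, genes, window_bp=100)
        assert scan.empty

    def test_strong_causal_variant_wins_scan_and_sign(self):
        """At h2 = 0.9, n = 400 with one causal variant, the scan's top hit
        is that variant with a slope matching sign(beta) in nearly all seeds."""
        top_hits, sign_hits = 0, 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg, genome, cohort, genes, expr, truth = _study(
                n_individuals=400, n_genes=1, n_contigs=1, variant_density=0.01,
                n_causal=1, h2=0.9, window=WindowSpec(300, 300, False), seed=1000 + seed,
            )
            scan = marginal_eqtl_scan(cohort, expr, genes, window_bp=300)
            gt = truth.genes[genes[0].gene_id]
            row = scan.iloc[0]
            if row.variant_id == gt.causal_variant_ids[0]:
                top_hits += 1
                if np.sign(row.beta) == np.sign(gt.betas[0]):
                    sign_hits += 1
        assert top_hits >= 0.95 * n_seeds
        assert sign_hits >= 0.94 * n_seeds

    def test_egene_flag_present_with_signal(self, small_study):
        cfg, genome, cohort, genes, expr, truth = small_study
        scan = marginal_eqtl_scan(cohort, expr, genes, window_bp=300)
        assert set(scan.columns) >= {
            "gene_id", "variant_id", "beta", "pvalue", "qvalue", "egene",
            "distance_to_tss", "maf",
        }
        assert scan.egene.any()


class TestFixturesRoundTrip:
    def test_emitted_files_reload_to_equal_artifacts(self, tmp_path, small_study):
        cfg, genome, cohort, genes, expr, truth = small_study
        eqtl = marginal_eqtl_scan(cohort, expr, genes, window_bp=300)
        manifest = emit_fixtures(genome, cohort, genes, expr, eqtl, truth, cfg, tmp_path)
        assert len(manifest) == 7
        genome2 = read_fasta(tmp_path / "genome.fa")
        assert genome2.contigs == dict(genome.contigs)
        cohort2 = read_phased_vcf(tmp_path / "cohort.vcf", genome2)
        np.testing.assert_array_equal(cohort2.haplotypes, cohort.haplotypes)
        assert [v.variant_id for v in cohort2.variants] == [
            v.variant_id for v in cohort.variants
        ]
        genes2 = read_gene_table(tmp_path / "genes.tsv")
        assert genes2 == genes
        expr2 = read_expression_table(tmp_path / "expression.tsv", cohort=cohort2)
        np.testing.assert_allclose(expr2.values, expr.values)
        truth2 = SyntheticTruth.from_json((tmp_path / "truth.json").read_text())
        assert truth2.genes.keys() == truth.genes.keys()
        for g in truth.genes:
            np.testing.assert_allclose(truth2.genes[g].betas, truth.genes[g].betas)

    def test_fine_mapped_from_truth_records(self, small_study):
        cfg, genome, cohort, genes, expr, truth = small_study
        recs = fine_mapped_from_truth(truth, cohort, np.random.default_rng(0))
        assert len(recs) == sum(len(t.causal_variant_ids) for t in truth.genes.values())
        assert all(r.pip > 0.9 for r in recs)
        by_gene = {r.target for r in recs}
        assert by_gene == set(truth.genes)
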