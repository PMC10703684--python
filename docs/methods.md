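# Methods

This note records the statistical models, parameter choices, and numerical
conventions behind `persgex`, and the limitations of each.

## Coordinates and windows

All internal coordinates are 0-based half-open; 1-based inputs (VCF `POS`,
gene-table `tss`) are converted exactly once at parse time (`pos0`, `tss0`).

A window spec `(upstream_bp, downstream_bp, strand_aware)` anchored at a TSS
resolves to:

- non-strand-aware, or `+` strand: `[tss0 − upstream, tss0 + downstream)`;
- `-` strand with `strand_aware=True`: `[tss0 − downstream, tss0 + upstream)`,
  and the extracted sequence is reverse-complemented.

With this mirrored-interval convention the TSS base of a minus-strand gene
sits at offset `upstream − 1` of the reverse-complemented window, one base
left of the plus-strand convention (offset `upstream`). This asymmetry is
inherent to mirroring a half-open interval around a single anchored base; we
keep the interval formula (it matches how window extraction is typically done
with standard tooling) and account for it wherever offsets are mapped, e.g.
a variant at reference offset `off` lands at `L − 1 − off` after
reverse-complementation of a length-`L` window.

Bundled presets: `enformer` 98,300/98,300; `basenji2` 27,500/27,500;
`expecto` 20,000/20,000; `xpresso` 7,000/3,500 strand-aware.

## Personal sequences

Only biallelic SNVs with `|`-phased genotypes are applied; indels and
multiallelic records are skipped at parse time with a count, and unphased or
missing genotypes are hard errors. Each substitution is validated against
the reference base at its position, so applying edits twice, or to the wrong
assembly, fails loudly instead of corrupting sequences.

## Predictor harness and aggregation

Predictions are made per haplotype and averaged. Optional aggregation steps
mirror how large sequence models are typically ensembled:

- forward/reverse-complement averaging (the RC pass re-mirrors the TSS
  offset to `L − 1 − off`);
- ±`s` bp shift averaging with `N`-padding at the window edges (the TSS
  offset shifts oppositely to the sequence);
- for binned track predictors, reduction (mean or sum) of a ten-bin window
  of 128-bp bins around the TSS bin `t = off // 128`, spanning
  `[t − (W−1)//2, t + W//2)`.

### Linear sequence oracles

Test and simulation predictors are linear in sequence content: a score is a
baseline plus `β_j` for every position `j` whose base equals a designated
alternate base. For a phased cohort this makes the haplotype-averaged
prediction exactly `baseline + ½ Σ_j β_j d_ij` with dosage `d_ij ∈ {0,1,2}`,
giving a closed-form target the whole sequence pipeline must match to
floating-point error (observed ≤ 4.5e−16). Oracles support per-variant sign
corruption (flip `β_j` with probability `q`) to model a predictor that gets
effect *magnitudes* right but *directions* wrong, and deterministic
hash-seeded pseudo-noise keyed on the sequence bytes, so noisy oracles are
still reproducible functions of their input.

## Evaluation metrics

Spearman correlation uses average ranks for ties (scipy implementation,
cross-checked in the tests against an independent brute-force average-rank
Pearson). Correlations of constant vectors are **undefined and reported as
NaN**, never imputed as 0; summaries carry explicit `n_defined` /
`n_undefined` counts. Metrics:

- **cross-individual**: per gene, across individuals — the personal-genome
  signal of interest;
- **cross-gene**: per individual, across genes — the conventional benchmark;
- **reference correlation**: a single reference-sequence prediction per gene
  against per-gene median observed expression;
- **model agreement**: Pearson of per-gene cross-individual rhos between two
  predictors, both signed and on |rho| (magnitude), which dissociates
  direction errors from magnitude errors;
- **stratification**: per-gene covariates (top-eQTL −log10 p within 20 kb of
  the TSS, |TSS distance|, median expression, prediction coefficient of
  variation) with ordinary-least-squares fits of rho on each covariate over
  all genes and over the positive-rho and negative-rho subsets separately.

## Elastic-net baseline

Per gene: cis dosages with |pos − TSS| ≤ 98,300 bp (inclusive) and cohort
MAF ≥ 0.05; outer 10-fold CV (shuffled, seeded); within each outer training
fold, predictors are standardized and the response centered using training
statistics only, and an inner 10-fold `ElasticNetCV` (mixing 0.5, 50-point
geometric penalty grid down to `eps = 1e−4` of the data-driven maximum)
selects the penalty. Out-of-fold predictions add back the training-fold
response mean. Genes with < 30 individuals are rejected; constant responses
are flagged and skipped in correlation summaries.

**Known artifact.** Out-of-fold predictions that include each fold's
training-mean intercept are *systematically anti-correlated* with the
held-out responses under the null: with n samples in k folds of size m,
empirical centering forces the fold-mean component's correlation with the
held-out response toward `−√((1 − 1/k)/m)` (≈ −0.39 at n = 60, k = 10). So
per-gene rhos for heritability-0 genes sit slightly below zero rather than
at zero. We keep the intercept because dropping it breaks the constant-
response and infinite-penalty limiting behaviours; the tests assert the true
(non-positive, bounded) null behaviour. At realistic heritabilities the
artifact is negligible relative to signal.

## Direction of effect

Fine-mapped records are filtered to PIP > 0.9 (strict), and variants with
opposite-signed effects on different cis genes are removed entirely. For
each remaining variant the predictor is run on the reference window with the
reference vs. alternate base toggled (single-variant in-silico mutagenesis,
no cohort background):

- **eQTL mode**: scalar prediction (or the ten-bin TSS reduction for track
  predictors) on the gene's TSS-anchored window;
- **caQTL mode**: a variant-centred window; the statistic is the sum of the
  3 bins whose centres are closest to the variant (ties resolved toward the
  smaller bin index).

Accuracy is the fraction of variants with `sign(Δ) = sign(effect)`;
zero deltas are excluded and counted separately. Uncertainty comes from a
seeded bootstrap over variants (default B = 100) reporting mean, SD and
2.5–97.5 percentile interval. By construction accuracy is antisymmetric
(`a → 1 − a`) under delta negation, which the tests check exactly.

## Synthetic cohort generator

- **Genotypes**: per variant, MAF ~ U(0.05, 0.5); haplotype alleles are
  i.i.d. Bernoulli(MAF) — Hardy–Weinberg equilibrium, *no linkage
  disequilibrium* (a deliberate non-goal; see limitations).
- **Genes**: laid out left-to-right with non-overlapping windows and
  alternating strands; variant placement is redrawn (bounded retries) until
  every window holds at least `n_causal` variants.
- **Expression**: `y = g + e` with `g = Σ β_j d_j`, `β ~ N(0, effect_sd²)`
  on `n_causal` (default 8) variants sampled per window, and
  `Var(e) = Var(g)(1 − h²)/h²`; `h² = 0` yields pure noise with no recorded
  causal architecture; a final affine shift makes expression non-negative.
  Realized h² is recorded in the truth file.
- **Expected metric level**: if prediction and expression were bivariate
  normal with Pearson r = √h², the population Spearman would be
  `(6/π)·asin(√h²/2)`. With 8 causal variants the genetic value is close
  enough to normal that the pipeline mean matches this within ±0.05 at
  n = 400 (observed 0.308/0.688/0.943 vs. theory 0.303/0.690/0.944 at
  h² = 0.1/0.5/0.9).
- **eQTL scan**: per gene, vectorized single-variant linear regressions
  (MAF ≥ 0.05, non-constant dosage); the per-gene minimum p-value is
  **Bonferroni-corrected within gene** (× number of tested variants, capped
  at 1) and the corrected minima are then Benjamini–Hochberg adjusted across
  genes at FDR 0.05 to call eGenes. The within-gene correction is required:
  raw minima of m tests are anti-conservative and would inflate the null
  eGene count well past the nominal rate (observed null mean: 0.05 eGenes
  per 20 genes over 100 seeds).

## Determinism

Every stochastic component takes an explicit seed. The CLI derives
independent per-stage seeds from the global seed via a named hash
(`blake2s("stage:seed") mod 2³¹`), records them in `run-metadata.json`, and
the `demo` command writes a SHA-256 manifest of every output file; two runs
with the same seed are byte-identical.

## Problem sizes

Package-level checks use desk-scale problems chosen to make the targeted
effect at least ~3 standard errors wide: oracle equivalence at 50 genes ×
100 individuals; heritability recovery at 200 genes × 400 individuals per
h²; direction calibration on 2,000 fine-mapped variants; the elastic-net
comparison on 50 genes × 300 individuals; null calibration at 100 genes ×
100 individuals plus 100 seeds × 20 genes for the eGene rate. The full
suite runs in about two minutes on one CPU.

## Limitations

- No linkage disequilibrium, population structure, or relatedness in the
  genotype simulator; tagging-variant effects cannot be studied.
- SNVs only — no indels, structural variants, or multiallelic sites.
- Expression is strictly additive cis; no dominance, epistasis, trans
  effects, or GxE.
- The linear oracles are exactly realizable by construction; conclusions
  about real nonlinear sequence models require plugging those models into
  the `Predictor` interface.
- Fine-mapped records in the synthetic pipeline come from simulation truth
  with PIP drawn uniformly above 0.9, not from an actual fine-mapping
  posterior.
- The bivariate-normal Spearman ceiling is an approximation that degrades
  for very sparse architectures (few causal variants, heavy dosage ties).
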