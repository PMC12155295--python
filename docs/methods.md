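# Methods

## Indices

The transcriptome age index of a sample is the expression-weighted mean
stratum, `TAI = Σ s_i e_i / Σ e_i`, over genes carrying a stratum
annotation; unannotated genes are dropped and counted, never imputed. The
index is invariant to rescaling a column, lies between the smallest and
largest stratum among contributing genes, and is non-decreasing in the
expression of the youngest contributing gene — all three properties are
asserted in the test suite, and the computation is checked against an
explicit per-gene loop to 1e-12.

TDI uses the same formula with divergence strata as weights. dN/dS ratios
are heavy-tailed, so they enter as balanced decile ranks: genes sorted by
dN/dS ascending (ties broken by lexicographic gene id, for platform-stable
reproducibility) are cut into ten contiguous blocks whose sizes differ by at
most one; when `n mod 10 = r > 0` the extra members go to the lowest strata,
so stratum 1 always holds the most conserved genes. The stratification is
invariant under strictly monotone transforms of the raw ratios. One dN/dS
value per gene is consumed; how multi-species estimates were aggregated is
the data producer's choice and is deliberately not second-guessed here.

Expression units: library sizes vary, so the pipeline normalizes each
column to counts-per-million before fitting (per-sample indices are scale
free, but the pooled stage aggregation is not). No log transform is applied
by default — the index is meant to weight strata by relative expression
mass — but `log2(1+x)` is available (`log_transform=True`), which compresses
the influence of the most highly expressed genes.

Stage aggregation: two modes are supported because both are defensible and
they answer slightly different questions. `mean-expression` (default) takes
the index of the across-sample mean expression vector of a stage — one
pooled transcriptome per stage. `mean-of-sample-indices` averages the
per-sample indices, matching boxplot-style per-stage displays. They agree
for a single sample and on expectation under our generator, but not in
general; every test-facing function takes the aggregation as a parameter.

Sub-stage labels ("Stage IIA", "stage iiib") are normalized to I–IV by
stripping the A/B/C suffix; NAT synonyms ("Solid Tissue Normal", "normal")
map to NAT. Anything else — "Stage X", "Stage 0" — is rejected rather than
guessed, with the raw label in the error message.

## Pattern tests

Three one-sided permutation tests share one null. Statistics on the ordered
tumor-stage profile (NAT never enters a statistic; the hourglass question
concerns progression stages I–IV):

- flat-line: population variance of the per-stage values. The profile's
  standard deviation is monotone-equivalent, so both induce identical
  permutation p-values; the variance saves a square root in the null loop.
- reductive hourglass: `min(e − m, l − m)` with `e, m, l` the means of the
  early ({I}), mid ({II, III}) and late ({IV}) stage modules (modules are
  configurable). Positive only when the mid module dips below both flanks.
- reverse hourglass: `min(m − e, m − l)`, the mirror image.

Null model: the gene→stratum assignment is permuted uniformly at random, B
times, with the expression matrix held fixed; the profile and statistic are
recomputed each time under the same aggregation. This conditions on the
complete expression structure (library sizes, gene–gene correlation,
stage-sample layout) and on the stratum multiset, and it is exact: when
strata are truly uninformative about expression, the observed assignment is
exchangeable with the permuted ones, so `p = (1 + #{null ≥ obs}) / (B + 1)`
is (discretely) uniform. The add-one correction keeps p in
`[1/(B+1), 1]`. A Gaussian fit to the null scores is reported alongside as
`parametric_p` for diagnostic use; the empirical p is authoritative.

Default B = 1000; calibration experiments in the acceptance suite use
B = 500 for throughput; 100,000 is a config value away for
publication-grade runs. By default the hourglass tests run only when the
flat-line test rejects at `alpha` (gating mirrors the analysis sequence the
indices are used in); `gated=False` / `--no-gate` runs everything.

Numerics: with degenerate inputs (e.g. every gene in one stratum) the
profile is constant and all statistics should be exactly zero, but BLAS
summation order leaves noise of order 1e-30. Statistics below 1e-9 in
magnitude are therefore snapped to zero and the null comparison uses a
1e-9 absolute cushion — far below any meaningful effect (index units are
O(1)) and enough to make the degenerate case return p = 1 exactly.

## Enrichment

For a DEG list against the annotated background universe: each stratum gets
the 2×2 table (DEG vs non-DEG background) × (in vs out of stratum), a
two-sided Fisher's exact test, and the cross-product odds ratio
`(a·d)/(b·c)` (infinite when `b·c = 0` with `a·d > 0`); Benjamini–Hochberg
q-values are computed across strata. Globally, observed stratum counts are
compared to expected counts `|DEG| × background proportions` with
`χ² = Σ (O − E)²/E`; strata absent from the background are dropped with the
degrees of freedom reduced.

The χ² is calibrated by resampling: gene sets of size |DEG| drawn from the
background **without replacement** (the null hypothesis is "a random subset
of the background", and the background is finite; the per-stratum counts of
such a draw are multivariate hypergeometric, which is how they are sampled),
with `bootstrap_p = (1 + #{χ²_b ≥ χ²_obs}) / (n_bootstrap + 1)` — "≥" plus
add-one keeps the p-value conservative and never zero. As the background
grows relative to |DEG| the null approaches the multinomial and the
analytic χ² tail with df = strata − 1; the acceptance suite verifies
agreement within ±0.02 at background 10,000, |DEG| 500, 20,000 resamples
(the residual gap is the finite-population correction, ≈ (N−n)/(N−1) on the
statistic's scale). Default 10,000 resamples; 100,000 via config.

`median_log2fc_by_stratum` reports the median log2 fold change per
(stratum, stage); empty cells are missing (NaN), never zero.
`naive_log2fc` is a fixture-grade pseudocounted ratio for synthetic data,
not a differential-expression method; DEG calling itself (DESeq2-style
modelling, batch covariates) is upstream of this package and DEG tables are
consumed as input.

## Synthetic data generator

The generator emulates the statistical shape of staged bulk RNA-seq
inputs. Defaults define the desk-scale study conditions used throughout the
tests: 2,000 genes, phylostrata uniform over 1..14, 10 samples per tumor
stage plus 10 NAT, log-normal gene baselines with mean 100 counts and
log-sd 1, negative-binomial counts with shape 5 (variance `μ + μ²/5`,
clearly overdispersed, the standard minimal model for RNA-seq counts),
dN/dS log-normal with median 0.2 and log-sd 0.8 (typical purifying-selection
range), independent of age by default.

Patterns are planted multiplicatively on count means — not additively on
the index — so normalization and index computation are exercised end to
end. Genes are split into age tertiles (sorted by stratum, ties by id);
under `hourglass` the youngest tertile's means are multiplied by
`f = 2^(δ·w)` in stages I and IV and the most ancient tertile's in stages
II–III; `reverse_hourglass` swaps the stage sets; NAT always stays at
baseline. The scaling is not guessed: `f` is solved numerically (Brent) at
generation time so that the *expected* TAI gap between a young-boosted and
an ancient-boosted transcriptome equals the requested effect size δ in
index units; an unattainable δ (the gap saturates as `f → ∞`) is an error
rather than a silent shortfall. Sampling noise around the planted gap at
the default cohort size is a few hundredths of an index unit.

DEG tables: per stage, gene membership is Bernoulli with rate 0.05,
multiplied by `enrichment_fold` (default 10) for genes in the enriched
strata (default {6, 7, 9}); log2FC values are Gaussian with
stratum-dependent location — positive (+1.0) for strata 1–2, negative
(−0.8) for 3–7, zero-centred with sd 2.5 (large magnitude, mixed sign) for
8–14. Adjusted p-values are drawn below 0.05 and are bookkeeping only.

The three generators draw from disjoint seed streams derived from
`config.seed`, so each is individually reproducible. What the generator
does **not** emulate: TCGA marginal count distributions, patient-level
pairing beyond a shared id for NAT columns, batch structure, gene–gene
correlation, or any realistic coupling between age, expression level and
differential expression. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under a known
truth — not that any particular real cohort shows (or lacks) an hourglass.

## Pipeline and reproducibility

`run_pipeline` validates cross-file consistency (expression samples must
appear in the metadata; errors name the file and identifier), computes the
profile, runs the gated tests, optionally the enrichment, and writes a
manifest with SHA-256 input hashes, the full configuration, the seed and
the package version. No output carries a timestamp, floats are written at
full round-trip precision and JSON keys are sorted, so identical inputs and
seed give byte-identical outputs — asserted end to end in the tests. The
output directory is deliberately excluded from the manifest so runs into
different directories remain comparable.

## Known limitations

- Gene ages and dN/dS values are consumed, never inferred; nothing here
  performs homology search, phylostratum assignment or codon-model fitting.
- The permutation null breaks any true age–expression association wholesale;
  it tests "strata are uninformative", not more refined nulls (e.g.
  age-matched gene swaps).
- Per-stage aggregation choices matter for small cohorts; both supported
  modes are exposed precisely because neither is canonical.
- The bootstrap χ² p-value is conditional on the DEG list size; lists of
  size comparable to the background inherit a noticeable finite-population
  shift relative to the analytic tail.
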