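# phylostage

Evolutionary transcriptomics of staged tumor expression data: transcriptome
age and divergence indices across pathological stages, permutation tests for
hourglass-shaped index profiles, and phylostratum enrichment of
differentially expressed gene (DEG) lists.

## The problem

Phylostratigraphy assigns every gene an integer *phylostratum* — the rank of
the oldest taxonomic node at which its homologs are detectable (the
Phylostratigraphic Age Index, PAI; higher = evolutionarily younger; for human
genes, 1 = Cellular Organisms … 14, with 6 = Vertebrata, 7 = Euteleostomi,
9 = Eutheria). Weighting these ranks by expression turns a transcriptome into
a single evolutionary summary, the **Transcriptome Age Index**

```
TAI_s = Σ_i PAI_i · e_is / Σ_i e_is
```

for sample *s* with expression `e_is`. The **Transcriptome Divergence Index
(TDI)** is the same weighted mean with decile ranks of per-gene dN/dS as
weights (divergence stratum 1 = the 10% most conserved genes). Tracking
TAI/TDI across AJCC tumor stages I–IV (with normal adjacent tissue, NAT, as
control) asks whether tumor progression transiently reactivates ancient gene
programs: an **hourglass** profile (high early/late, dipping mid) or its
mirror image, the **reverse hourglass**.

`phylostage` provides, as tested library code with a CLI:

- PAI / dN/dS tables, balanced decile stratification, TAI/TDI profiles
  (per sample and per stage, two stage-aggregation modes);
- one-sided permutation tests — **flat-line** (profile variance),
  **reductive hourglass** (`min(e−m, l−m)` over early/mid/late stage
  modules) and **reverse hourglass** (`min(m−e, m−l)`) — with a
  gene→stratum permutation null and add-one-corrected empirical p-values;
- phylostratum composition analysis of DEG lists: per-stratum Fisher's
  exact tests with Benjamini–Hochberg q-values, a global chi-square
  statistic against the background gene set calibrated by a
  without-replacement bootstrap null, and median-log2FC-by-stratum
  summaries;
- a synthetic-data generator (negative-binomial counts, planted
  hourglass/reverse/flat patterns with calibrated effect size, planted DEG
  enrichment) so every claim is testable without external data.

## Worked example

```python
from phylostage import (SimulationConfig, generate_universe,
                        generate_expression, TranscriptomeIndex)

cfg = SimulationConfig(pattern="hourglass", effect_size=2.0, seed=7)
ages, dnds = generate_universe(cfg)
data = generate_expression(cfg, ages)

res = TranscriptomeIndex(data, ages).fit()
print(res.summary())
tests = res.test_patterns(B=1000, seed=7)
for kind, r in tests.items():
    print(f"{kind}: statistic={r.statistic:.4f}  p={r.p_value:.4g}")
```

prints

```
Transcriptome Age Index (TAI)
==========================================================
Aggregation:      mean-expression
Genes used:       2000   (dropped, no annotation: 0)
Samples:          50

stage    n_samples       index
------------------------------
I               10      8.3754
II              10      6.3606
III             10      6.3461
IV              10      8.3554
NAT             10      7.3262

flat_line: statistic=1.0122  p=0.000999
reductive_hourglass: statistic=2.0021  p=0.000999
reverse_hourglass: statistic=-2.0221  p=1
```

The generator planted an hourglass of two TAI units: stages I and IV sit
about 2 index units above stages II–III, exactly the requested effect. The
flat-line test rejects constancy (p = 1/(B+1), the smallest value 1000
permutations can produce), the reductive hourglass test confirms the dip
direction, and the reverse test — correctly — sees nothing. With
`pattern="flat"` the flat-line p-value is uniform on (0,1] and the hourglass
tests are skipped under the default gated mode.

The same analysis from the shell:

```bash
phylostage simulate --pattern hourglass --seed 7 --out-dir sim/
phylostage run --expr sim/expr.tsv --meta sim/meta.tsv --ages sim/ages.tsv \
    --deg sim/deg.tsv --B 1000 --seed 7 --out-dir out/
```

writes `profile.tsv/json`, `pattern_tests.json`, `enrichment.tsv/json` and a
`manifest.json` with input hashes that makes the run reproducible
bit-for-bit. `phylostage tdi --dnds sim/dnds.tsv ...` computes the TDI
profile; `phylostage enrich` runs the enrichment analysis alone.

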