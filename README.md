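# dosepath

Dose-response transcriptomics analysis for short ordered dose series of
treated-vs-control expression ratios, aimed at studies that profile a
compound at a handful of increasing concentrations (e.g. a cytotoxic
botanical extract on a cancer cell line at 0, 1.25, 5 and 20 µg/mL, one
array per dose) and ask which genes, pathways and clinical risk signals
move monotonically with dose.

The package implements the full downstream chain as a tested library:

- **Preprocessing** — background filtering (signal ≥ 1.4× local
  background), quantile normalization, log2 treated/control ratios
  against the vehicle-control column, duplicate-probe averaging, and
  2-fold differential selection.
- **Pattern mining** — short-series model profiles: integer template
  trajectories anchored at 0 with bounded per-step change over the dose
  ranks; each gene is assigned to the profile maximising Pearson
  correlation, and per-profile significance is computed from 1,000
  within-gene permutations of the dose positions. Significant monotone
  profiles (FDR < 0.001) form the Down- and Up-pattern gene sets.
- **Enrichment** — one-sided Fisher (hypergeometric tail) over-
  representation of signed gene sets with Benjamini–Hochberg FDR.
- **Pathway impact analysis** — hypergeometric P_NDE; perturbation
  factors PF = (I − B)⁻¹ΔE over the out-degree-normalised signed
  topology B; bootstrap P_PERT (n = 3,000) for the net accumulation
  tA = Σ(PF − ΔE); Fisher-product global P_G = c − c·ln c classified at
  Bonferroni/FDR 1%.
- **Pathway activity** — per-sample A_p(s) = Σ_g w_g·x_gs with
  w_g = +1 for activators and −1 for repressors, a random-gene-set
  permutation FDR screen (n = 1,000, FDR < 0.05), z-scoring and
  average-linkage clustering into dose-decreasing vs dose-increasing
  sub-clusters.
- **Pathway similarity** — Jaccard matrix J(p,q) = |p∩q|/|p∪q| over
  gene memberships, clustered on 1 − J with top-dose activities merged
  onto the ordered output.
- **Survival screening** — univariate Cox proportional-hazards fits
  (Newton–Raphson, Breslow ties) with permutation p-values, selection
  at p < 0.05, and the pattern-vs-hazard reciprocity test: a 2×2
  cross-tabulation of pattern (down/up) against hazard-ratio direction
  (>1 / <1) under a two-sided Fisher exact test.
- **Synthetic data** — generators for every input (dose-series
  expression with planted monotone groups, overlapping signed gene
  sets, signed topologies, exponential-hazards survival cohorts), so
  the whole pipeline is testable without external downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write tables under `results/`:

```sh
python analysis/01_simulate.py           # inputs under results/data/
python analysis/02_patterns.py           # Down-/Up-pattern gene sets
python analysis/03_enrichment_spia.py    # enrichment + impact analysis
python analysis/04_activity_similarity.py
python analysis/05_survival.py
```

`05_survival.py` prints, for the packaged gene-level screening table of
dose-pattern genes:

```
published screen: 48 down / 50 up pattern genes
contingency (rows down/up, cols HR>1/HR<1):
[[32 16]
 [24 26]]
odds ratio 2.167, Fisher two-sided p 0.0697
```

i.e. 32 of the 48 screened Down-pattern genes are high-risk (hazard
ratio > 1) while 26 of the 50 Up-pattern genes are protective — a
reciprocal distribution with odds ratio 2.17 that is marginally
significant (p ≈ 0.069). The same chain run on the synthetic cohort
(130 subjects, planted down-risk/up-protective genes) reproduces the
direction of this association.

`02_patterns.py` on the default planted study (3,000 genes, 10%
monotone-up, 10% monotone-down, effect 3, noise 0.5) reports ~500
differential genes split into Down/Up patterns at FDR < 0.001;
`04_activity_similarity.py` screens in exactly the 20 planted pathways
at activity FDR < 0.05 and separates them into a dose-decreasing
metabolic cluster and a dose-increasing signaling cluster.

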