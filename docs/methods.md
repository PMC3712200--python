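# Methods

## Study design and data model

The pipeline analyses a genes × samples matrix of log2 treated/control
expression ratios over a short, strictly increasing dose series whose
first level is the vehicle control. The default design is four levels
(0, 1.25, 5, 20 µg/mL) with a single array per dose; replicates are
supported by the generators but are not the default, because the
analysis methods themselves (profile correlation, signed sums) operate
on one column per condition. Doses are treated as ordinal ranks
throughout — no log-dose or absolute-concentration model is fitted —
because with three treated points any parametric dose metameter would
be under-determined.

## Preprocessing

Probes are eliminated when foreground < 1.4 × local background; the
default reading requires the criterion in **every** sample (a probe
unreliable anywhere is dropped), with an any-sample mode behind a flag
since the opposite reading is equally defensible. Quantile
normalization maps each column's sorted values onto the row-wise mean
of all columns' sorted values; ties receive the mean of the sorted-mean
values across the tied ranks. Ratios are computed against the single
control column, and duplicate probes are averaged after ratio
computation (filter → normalize → ratio → collapse). The order is a
convention: collapsing before or after the ratio differs only when
duplicate probes disagree, and the chosen order averages on the ratio
scale where the downstream analysis lives. Differential genes are
those with |log2 ratio| ≥ 1 (2-fold) in at least one dose sample.

Quantile normalization assumes the columns share an intensity
distribution. When a large fraction of genes genuinely shifts with
dose, forcing a common distribution compresses those shifts; the
preprocessing tests therefore check structural recovery (correlation
with encoded ratios, differential selection of planted genes) rather
than numeric identity.

## Pattern mining

Model profiles are integer trajectories of length n_points anchored at
0 with successive differences in {−c, …, +c}; there are (2c+1)^(n−1)
candidates. Defaults c = 2 and m = 20 representatives follow common
short-series-miner practice; both are configurable because the right
granularity depends on the dynamic range of the data. Representatives
are chosen by deterministic greedy max–min (farthest-point) selection
starting from the profile farthest from flat, with lexicographic
tie-breaking, so the selection is independent of candidate order. The
vehicle control is prepended to every gene as a zero log-ratio anchor
and genes are assigned to the profile maximising Pearson correlation
(scale-invariant; ties to the lower profile id; zero-variance genes
fall back to a flat pseudo-profile with correlation 0).

Significance: each permutation round independently permutes every
gene's values across the dose positions (the control anchor stays at
zero, preserving each gene's value distribution) and re-runs the
assignment. The mean permuted member count estimates each profile's
null assignment rate r; the observed count is tested against
Binomial(n_genes, r) (genes are assigned independently), and the tail
p-values are BH-adjusted across profiles into the `fdr` column used
for thresholding (default 0.001). The expected/observed ratio is kept
as a descriptive diagnostic. Two calibration caveats are deliberate
and documented:

- the member count is a heterogeneous (Poisson-binomial) sum, whose
  variance is smaller than the matched binomial's, so the binomial
  tail is mildly conservative under the null;
- `perm_p`, a mid-p exchangeable permutation p-value on the count, is
  exactly calibrated and is the statistic used in null-uniformity
  diagnostics, but its resolution is floored at ~1/n_permutations, so
  thresholding far below that floor uses the binomial `fdr`.

Down-/Up-patterns are unions of members of significant monotone
profiles (all steps one-signed with nonzero net change).

## Enrichment and pathway impact

Over-representation uses the one-sided hypergeometric tail
P(X ≥ k) — the over-representation direction of Fisher's exact test —
with BH adjustment; an EASE-style (k−1) conservative variant is
available behind a flag. The universe defaults to the genes surviving
preprocessing, not the genome.

The impact analysis combines P_NDE (the same hypergeometric tail on
pathway membership of differential genes) with P_PERT. Perturbation
factors solve PF = ΔE + B·PF, where the raw signed adjacency (targets
× sources, entries ±1) is column-normalised by each source's
outgoing-edge count; tA = Σ(PF − ΔE). The bootstrap null (n = 3,000)
places the observed number of differential genes at random pathway
positions with fold-changes resampled from the pool of all
differential-gene log-ratios; because tA is linear in ΔE the null
reduces to resampled dot products with the column sums of
(I − B)⁻¹ − I. P_PERT is the two-sided tail around the null median,
floored at 1/n_boot so the Fisher product P_G = c − c·ln c (the
χ²₄ upper tail at −2 ln c) is always defined. Pathways with no
differential genes or singular (I − B) are reported as unanalyzable
rather than assigned P_G = 1. Classification: Bonferroni at α/M, else
BH-FDR at α, else not significant (α = 0.01).

## Pathway activity and similarity

Activity is the signed sum of a pathway's gene ratios per sample
(+1 activator, −1 repressor; the sign is an input contract carried by
the GMT annotation). The permutation screen's test statistic is the
maximum |activity| across samples (a top-dose variant is a flag); the
null draws size- and sign-matched random gene sets from the matrix's
universe, n = 1,000 rounds, and the empirical p is BH-adjusted across
pathways with FDR < 0.05 admitting a pathway to clustering. Random
gene sets — not sample-label shuffles — are the null because with
three treated samples only 3! = 6 label permutations exist. The null
stream for each pathway is derived from the global seed plus the
set's content, so identical sets receive identical FDRs. Screened
activities are z-scored per pathway (population sd; zero-variance
pathways zeroed and flagged) and clustered with average linkage on
correlation distance; a two-group cut is annotated with each group's
mean dose-trend sign, which in a reciprocal design yields one
dose-decreasing and one dose-increasing sub-cluster.

Similarity is plain Jaccard over gene memberships (signs ignored,
empty-union pairs 0) — joint absences never contribute, by the
definition of the index. Clustering is average linkage on 1 − J, with
each pathway's top-dose normalized activity attached to the ordered
output; the activity annotation never influences the ordering.

## Survival screening

Univariate Cox fits use Newton–Raphson on the Breslow partial
likelihood (score tolerance 1e−8, max 50 iterations, step clipping for
stability), vectorised across covariate columns so the permutation
null refits cheaply. Covariates are z-scored by default, making the
hazard ratio per standard deviation of expression. The default
screening p permutes the subject-to-expression assignment (two-sided
on |β|, floored at 1/n_permutations); Wald p-values are a flag.
Screened genes (p < 0.05) carrying a down/up pattern label are
cross-tabulated against hazard-ratio direction; genes with hazard
ratio exactly 1 are excluded with a warning. The two-sided Fisher
exact p sums all same-margin tables whose hypergeometric probability
does not exceed the observed table's (1e−7 relative tolerance for
float ties) — the minimum-likelihood convention, which on the packaged
98-gene screening table gives p = 0.0697 for the (32, 16; 24, 26)
table.

## Synthetic data: what it emulates and what it does not

Planted monotone genes rise (or fall) linearly in dose rank to
±effect_size at the top dose, with i.i.d. Gaussian noise on the log2
ratios; the defaults (3,000 genes, 10% up, 10% down, effect 3, noise
0.5) put planted genes at a 6:1 effect-to-noise ratio at the top dose.
Gene-set overlap is induced through a shared core pool sized like one
set; drawing a fraction f = sqrt(2J/(1+J)) of each set from the core
gives expected pairwise Jaccard J. Topologies are directed
Erdős–Rényi graphs with signed edges. Survival times are exponential
proportional hazards — rate h₀·exp(Σβ·x) — with independent
exponential censoring calibrated so the expected censored fraction
matches the requested rate under null coefficients; the default cohort
(130 subjects, 10 risk and 10 protective genes at |β| = 0.5,
censoring 0.2) keeps the log-hazard spread within a realistic range.

None of the generators emulate probe-level artifacts (dye bias,
spatial effects), gene–gene expression correlation, heavy-tailed
noise, or non-proportional hazards. Passing tests therefore
demonstrate that the analysis chain recovers the structure it assumes
when that structure is present and stays calibrated when it is absent
— not that it is robust to the full failure modes of real microarray
or clinical data.

## Problem sizes and numerical choices

The analysis scripts and end-to-end tests run the planted study at
3,000 genes with 1,000 pattern/activity permutations and 3,000
bootstrap rounds — the full method-level defaults. Null-calibration
checks use 50 seeds at reduced permutation counts (patterns 200,
activity 200, Cox 500), sizes at which the Kolmogorov–Smirnov
uniformity tests at α = 0.01 retain power while the whole suite runs
in well under a minute of permutation work. Linear solves use LAPACK
via numpy with an explicit ∞-norm residual check (1e−8); generated
topologies at the default density have spectral radius well below 1,
so (I − B) is comfortably invertible. All generators and permutation
schemes take explicit integer seeds and are bit-reproducible.
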