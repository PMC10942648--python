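# Methods

This note documents the statistical model, the synthetic-data generators,
and the numerical choices behind `mstarr`, in the order the pipeline runs.

## Windowing and counting

The genome is tiled into non-overlapping 600-bp windows (0-based,
half-open throughout; terminal partial windows are kept but flagged and,
by default, excluded from model fitting because their count scale
differs). A fragment counts toward every window it overlaps by ≥ 1 bp; a
boundary-spanning fragment therefore increments two windows. Rarefaction
operates by binomial thinning of the count matrix at a depth fraction,
which is distributionally equivalent to subsampling reads for detection
curves and keeps the package alignment-free.

## Inclusion filters

* **Detection** (per treatment): a window needs non-zero DNA counts in at
  least 3 replicates of *each* methylation condition and non-zero RNA in
  at least 3 replicates of *either* condition. The rule is monotone in
  counts.
* **Repeatability**: all pairwise differences of DNA abundance
  (log₂-CPM by default; raw counts optional) are pooled **across windows**
  into one reference distribution; a window is removed when ≥ 25% of its
  own pairs fall strictly outside the central 90% interval (boundary
  values are inside). The pooled reference is a deliberate choice: a
  per-window central-90% interval would leave ~10% of each window's own
  pairs outside by construction, making a ≥ 25% rule nearly impossible to
  trigger; only a pooled distribution makes the rule discriminating.
* **Sample QC**: libraries whose zero-count proportion exceeds
  median + 5·MAD are *reported* (with their DNA/RNA pair partner) for
  removal, not removed automatically — sample exclusion is an
  inspection-level decision.

## Normalization, weights, and the window model

Counts become log₂-CPM with a 0.5 prior count:
`log2((count + 0.5) / (library_size + 1) × 1e6)`. Library sizes are
rescaled by trimmed-mean-of-M-values factors (30% ratio trim, 5%
abundance trim, factors normalized to geometric mean 1); a config flag
disables this. Observation weights follow the voom construction: a
per-window OLS fit of the design yields residual SDs; a lowess curve
(span 0.5, 2 robustness iterations) of √SD against mean log₂ count is
inverted at each observation's fitted count scale into an
inverse-variance weight. Optional per-sample quality weights (default on
for the reporter path, off for the cohort path) are variance-inflation
factors estimated from leverage-adjusted standardized residuals across
windows, normalized to geometric mean 1 and refined over two re-weighted
passes.

Each window is then fit by weighted least squares to

    y = μ + m·β₁ + s·I(m=0)·β₂ + s·I(m=1)·β₃ + ε

(m: methylation, s: molecule). Per-window variances are moderated by
empirical-Bayes shrinkage toward a scaled-inverse-chi-square prior fit by
method of moments on the log scale (the inverse-trigamma solved by
bracketed root finding); t-tests then use `df_resid + df_prior` degrees
of freedom. Two-sided t-tests cover β₂, β₃ and the contrast β₂ − β₃,
with `var(c) = var(β₂) + var(β₃) − 2 cov`. Rank-deficient or saturated
(df = 0) windows are flagged and excluded downstream.

The **activity p-value** of a window is the minimum p over conditions
with a positive sample-type coefficient; windows with β₂ ≤ 0 and β₃ ≤ 0
get p = 1 and leave the analysis set. The identical statistic is applied
to permuted data, which is what keeps the empirical FDR valid under this
composite definition.

## Permutation empirical FDR

* **Activity null**: RNA/DNA labels are swapped within each replicate
  pair independently with probability ½, 100 times. Plans that leave one
  methylation condition entirely unswapped (or entirely swapped) are
  redrawn: with 6 pairs per condition such draws occur with probability
  2/64 per condition and replay the observed statistic (up to sign) into
  the null rather than breaking it — empirically they impose a ~1%
  floor on the achievable FDR. The restriction is data-independent, so
  the permutations remain exchangeable draws under the null.
* **Positive-beta subsampling**: each permutation is refit through the
  identical normalization/weighting/fitting path; N of its positive-beta
  windows (N = the observed count) are sampled without replacement and
  their p-values pooled. Permutations with fewer than N keep all windows
  and their null counts are rescaled by N/available; empty permutations
  contribute nothing.
* **Interaction null**: methylation labels are reshuffled across
  replicate pairs preserving the 6/6 balance (identity permitted), and
  the interaction p-values are collected on the *same* subsampled window
  sets selected for the activity null. Selecting positive-beta sets from
  the methylation-permuted fits instead would concentrate truly active
  windows into the null and destroy power for the interaction test.
* `FDR(t) = mean over permutations of the rescaled count of null p ≤ t,
  divided by max(1, #observed p ≤ t)`, evaluated at the observed
  p-values and monotonized by a running minimum from the largest p
  downward, capped at 1.

Classification at threshold 1%: *regulatory* = positive-beta with
activity q < 0.01; *methylation-dependent* = regulatory with interaction
q < 0.01; direction is `unmeth_higher` iff β₂ > β₃. Condition
specificity across treatments comes in a default mode (regulatory in
exactly one treatment) and a stringent mode (q < 1% in the focal
treatment and q > 10% in all others).

## Enrichment

Overlap tables are built over an explicit window universe with half-open
containment (a CpG at position 600 belongs to [600, 1200)). Fisher's
exact two-sided p sums hypergeometric outcomes no more probable than the
observed table; the point estimate is the sample log₂ odds ratio with
the Haldane–Anscombe 0.5 correction when a cell is zero, and the 95% CI
is Woolf (`log OR ± 1.96·√Σ1/cell`). Conditional-MLE odds ratios (the
default in some stats packages) can differ slightly from the sample OR
reported here.

## Cohort integration

CpGs require coverage ≥ 4 in at least half of the samples of either
condition; genes pass either the cohort preset (mean expression > 2 in
either condition) or the cell-line preset (> 3 in ≥ 3 samples of some
condition). Responses are unweighted differences of condition log-CPM
per individual (observation-weighted fold changes are out of scope and
noted as a divergence). Window methylation is the mean over contained
CpGs, optionally excluding CpGs with across-individual variance < 0.01.
Enhancers link to the nearest gene within 100 kb, measured window-edge
to gene-body-edge (0 if overlapping; ties link all nearest genes, and a
window's response is the mean over its linked genes); a supplied link
table overrides distance-based linking. Within-individual correlations
(Pearson r across enhancer–gene pairs) carry Fisher-z 95% CIs and
Bonferroni correction across individuals; locus-wise correlations
(across individuals, per pair) carry Storey q-values (π₀ from a cubic
spline over the λ grid 0.05…0.95, read at λ = 0.95, capped to (0, 1];
below 10 p-values π₀ = 1, where the procedure reduces to
Benjamini–Hochberg).

## Synthetic data

The reporter generator draws, per window, a DNA abundance scale
(log-normal around the mean depth, log-sd 0.5) and negative-binomial
counts (var = μ + φμ², φ = 0.2 by default — a replicate-to-replicate
CV of ~45%, at the noisier end of transfection-replicate variability)
with mild per-library depth factors (log-normal, log-sd 0.15). RNA means
are `abundance × (background + 2^effect · active)` where the effect
(default log₂ = 2) applies only in the treatments and methylation states
where the window is active; a methylation-dependent window is silenced
to background when methylated.

Background (leaky) transcription is **bursty**: drawn per RNA library
from a heavy-tailed log-normal (log-sd 1.5), mean-corrected so the
average background stays at 5% of the DNA scale. Two properties follow.
First, each RNA library is dominated by a minority of windows, so the
*typical* window is RNA-poor relative to its DNA input and only ~10% of
windows carry a positive sample-type beta — the regime the
positive-beta-subsampling FDR is designed for. Second, no window is
*consistently* elevated across replicates, so the binary truth labels
stay meaningful (a constant-per-window heavy tail would create windows
that are genuinely enhancer-like yet labelled inactive). The choice is
motivated by the heavy-tailed RNA coverage reporter assays show relative
to their DNA input. What the generator does **not** emulate: fragment-
level composition, capture efficiency, GC/CpG-density covariates,
between-window correlation, or partial methylation — so passing tests
demonstrate the statistical machinery, not robustness to those real-data
features.

The annotation generator plants point (CpG) or interval sets at a target
window coverage, with optional enrichment *e* implemented on the odds
scale (active windows' membership odds are e-fold the inactive odds; the
baseline odds solve the coverage constraint by bracketed root finding).

The cohort generator draws window methylation as bounded-logit Gaussians
(clipped to [0.001, 0.999]) around per-pair means, with the logit-scale
spread set so the raw-scale across-individual variance is ~0.02 (above
the 0.01 testability cut). The linked-gene response is `b·methylation +
noise`, with the slope solved from the realized methylation spread to
hit a target correlation — on the within-individual axis (across pairs;
the default, emulating the in vivo readout of −0.17 at IFNA-specific vs
−0.05 at shared enhancers) or on the per-pair axis (across individuals,
for locus-wise analyses). With `exact=True` the noise is orthogonalized
against methylation so a planted pair's *realized sample* correlation
equals its target exactly — the construction used to plant a locus of
known R² (0.38 in the acceptance run) among null pairs; without it the
realized correlation fluctuates by ~0.1 at n = 35.

## Problem sizes and determinism

All randomness descends from one master seed via deterministically
spawned child streams; the three generators use domain-separated seed
sequences so identical integer seeds cannot collide across generators.
The acceptance script runs the full pipeline at 5000 windows × 100
permutations (about 8 s per fit-plus-null on one CPU, vectorized across
windows), 10 null replicates for calibration, and 20/10 cohort
simulations; the test suite uses the same sizes for the acceptance-level
checks and much smaller fixtures elsewhere.

## Known limitations

* The empirical FDR floor scales with the number of degenerate-ish
  permutation plans; with very few replicate pairs (< 4 per condition)
  the redraw rule removes a large part of the permutation space and the
  null becomes coarse.
* TMM factors are computed against a single reference sample; extremely
  asymmetric RNA/DNA compositions can leave residual composition bias.
* The quality-weight scheme is a per-sample variance-factor
  approximation, not the full gene-by-sample REML of the reference
  implementation in the R ecosystem.
* Locus-wise cohort power at n = 35 is intrinsically modest; the planted
  R² = 0.38 locus is near the detection boundary (q ≈ 0.08 against a
  0.1 cut), which is faithful to the scale of the motivating study.
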