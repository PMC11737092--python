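# Methods

This note documents the models, numerical choices and limitations behind
`reefpls`, in the order the pipeline runs them.

## Synthetic survey generator (`reefpls.simulate`)

The generator emulates a multi-trip offshore reef survey: `n_trips = 4`
sampling trips × `sites_per_trip = 12` reef sites × `replicates_per_site = 4`
seawater replicates (192 samples), `n_taxa = 600` genera partitioned into
`n_go = 150` GO groups of `redundancy = 4` member taxa, and 17
physico-chemical variables per (trip, site).

**Environment.** Variables are generated as z-scores with two collinear
blocks — particulate nutrients + chlorophyll pigments (Chl-a, Phaeo, PN, POC,
PP, TSS, fluorescence) and dissolved nutrients (DOC, PO4, NH4, NO2, NO3, Si,
TDN, TDP) — with within-block correlation 0.7, plus a per-trip block-level
shift (SD 1, the seasonal signal) and per-variable trip noise.  Columns are
standardized to overall unit SD before mapping onto plausible measurement
scales, so planted slopes are "per SD" of each variable.  Trips occupy
latitudinal bands along the reef, deliberately confounding season with
geography; this is the confound that MINT integration and the per-trip
models exist to neutralize.

**Counts.** Abundance is hierarchical log-normal + multinomial:

1. Each GO group (and each unmapped taxon) has latent log-abundance
   `base ~ N(0, 1.5²)` + per-trip batch shift `N(0, batch_sd²)`
   (`batch_sd = 0.5`) + per-sample replicate noise `N(0, 0.6²)`.
   `n_indicator_go = 40` planted groups additionally gain
   `effect_size × z` (default 1.0 CLR units per SD) of a designated
   variable; designations cycle through the particulate/chlorophyll block,
   the coherent one-factor structure a first sPLS dimension can carry
   (mirroring the finding that productivity-linked variables drive the
   indicators).
2. Within a group the probability mass is split over the 4 member taxa by a
   softmax over member preferences `N(0, 1)` plus a dominance boost (+2 log
   units) for the site's *carrier*: each trip has a preferred carrier,
   rotated across trips, which a site adopts with probability 0.5
   (`carrier_fidelity`) or replaces with another member; per-sample
   membership noise (SD 0.75) is added on top.
3. One multinomial draw per sample over the taxon-level softmax at a
   Poisson(`library_size_mean = 50 000`) library size.  GO counts are exact
   member sums by construction.

This design makes every member taxon inherit the *full* environmental slope
of its group multiplicatively (its log-count is the group's log-count plus
its log-share), but with large site-level membership noise from carrier
turnover — which is precisely functional redundancy as a testable contrast:
GO-level CLR values recover the planted slope essentially unbiased, while
individual taxa are noisy, weakly reselected versions of the same signal.
An earlier variant that planted the slope on a single member taxon per trip
was rejected: it makes that taxon a cleaner within-trip indicator than its
diluted GO parent and biases GO-level slope recovery downward, inverting the
redundancy contrast the generator is meant to produce.

What the generator does *not* emulate: phylogenetic correlation between
taxa, many-to-many taxon→GO maps (each taxon maps to one group),
overdispersion beyond log-normal × multinomial, zero-inflation from
detection limits, and missing environment measurements (available as NaN
handling throughout but not planted by default).  Passing tests therefore
show the pipeline recovers structure *of this kind*; they do not certify
performance on real surveys with those extra features.

## Preprocessing

Filtering drops annotation classes {unannotated, eukaryote, virus,
domain-only} first; the rare-feature rule then removes features whose share
of the *remaining* grand total is strictly below `1e-6` (0.0001 %).  The
threshold is interpreted against the overall dataset rather than per sample
(a per-sample variant is available) because the rule describes a single
global feature count.  The CLR pseudocount defaults to 1 added to raw
counts — the common convention; natural log is used for CLR and Shannon.
Low-count features are attenuated toward zero by the pseudocount
(`d log(x+1)/d log x ≈ x/(x+1)`), which slightly biases slope recovery for
rare planted features; the recovery check uses the median over planted
features for this reason.  Heatmap scaling centers each variable at its
median and divides by the sample SD (n−1).  Missing environment cells are
excluded pairwise in distances and scaling; before sPLS they are imputed by
the within-trip median of the variable (configurable), falling back to the
overall median.

## Community statistics

Bray–Curtis is computed on per-sample proportions; within-site similarity is
`1 − d_BC` over all C(r, 2) replicate pairs per site after collapsing to the
requested rank.  PCA is column-centered SVD (scikit-learn).  PERMANOVA is
computed directly from the distance matrix (pseudo-F via the
total/within-group sum-of-squares identity), permuting group labels, with
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`; the in-package implementation
exists because per-pair R² and explicit seeding are needed, and it is
cross-checked against scikit-bio's PERMANOVA in the tests.  The distance for
trip comparisons defaults to Euclidean distance on PCA scores of CLR
profiles.  Wilcoxon rank-sum tests use exact enumeration when both n ≤ 8
with no ties, otherwise the tie-corrected normal approximation; batched
pairwise calls are Holm-adjusted by default (Bonferroni available).

## Partial Mantel screen

Community distance is Bray–Curtis on site-level mean proportions; each
variable's distance is |Δ| of z-scored site values (standardization keeps
units from dominating); geography is the haversine distance (Earth radius
6371.0 km).  The partial statistic ranks the lower-triangle vectors
(Spearman), projects out `[1, geo]` by least squares, and correlates the
residuals; the null permutes rows/columns of the community matrix
simultaneously (vectorized in blocks of 256 permutations).  The test is
one-sided for positive association by default (two-sided available), with
10 000 permutations and Bonferroni correction over the 17 tests of each
dataset's screen (a global 34-test family is available).  With a constant
geography matrix the projection reduces to centering and the statistic
equals the simple Mantel statistic exactly.

## Sparse PLS and MINT

Per dimension `h`: initialize `b` as the dominant right singular vector of
`M = XᵀY`; alternate `a ← soft(M b, keep_x)`, `b ← soft(Mᵀ a, keep_y)` with
unit-norm renormalization until the weight change falls below `tol = 1e-6`
(at most `max_iter = 100` iterations; non-convergence warns and returns the
model); scores `t = X a`; both blocks are deflated on `t` (regression mode).
`soft(v, k)` keeps the k largest-magnitude entries, shrinks them by the
(k+1)-th magnitude, and breaks boundary ties by index order (features are
carried in lexicographic order), so refits are deterministic; the gauge is
fixed by making the largest-magnitude X-weight positive.  Columns of X and Y
are centered and scaled to unit sample SD by default (Y-scaling is a flag).
Samples carry their site's environment row repeated across replicates.

MINT integration is within-study standardization: every column of X and Y
is centered/scaled separately per trip before one shared fit, so additive
trip effects cancel exactly and selection favors features covarying with
the environment consistently across trips.  A column constant within a
study is set to zero there with a warning.

The similarity heatmap is `sim(i, j) = Σ_h cor(Xᵢ, t_h)·cor(Yⱼ, t_h)` over
the retained dimensions (bounded by the dimension count via Cauchy–Schwarz),
computed for selected features only and ordered by complete-linkage
clustering on Euclidean distance; columns are cut at 3 clusters by default
for the indicator report.  X-scores serve both blocks (the single-variate
convention) — a deliberate choice where "partial correlations" admits
several readings.

## Stability scores

LOGOCV refits the MINT model once per held-out trip with unchanged keep
values; a feature's score is (#refits reselecting it on dimension 1) ÷
(number of trips), giving {0.25, 0.5, 0.75, 1} with four trips; ≥ 0.5 is
"shared across trips", 0.25 "trip-specific".  Dimension 1 is the scored
dimension (the headline indicators are defined there).

Per-trip repeated CV: the full-data fit defines the 50 dimension-1
indicators; each of 50 repeats partitions the trip's samples into 4 random
near-equal folds (unstratified), refits on each fold's complement, and
stability is the reselection frequency over the 200 runs.  Fold seeds derive
from one master seed via `SeedSequence.spawn`, so results are reproducible
and independent of sample order.  The per-trip blocks are disjoint, and the
taxa-vs-GO contrast is a two-sided rank-sum test on the two 50-value
stability vectors with the usual significance stars.  The per-trip sPLS
keeps the environment block as X and the microbial block as Y (selection of
50 microbial features per dimension), keeping the selection size identical
to the MINT analysis; the first PLS dimension maximizes block covariance
symmetrically, so the contrast does not depend on which block is called the
response.

Stability rises with effect size on the rising part of the curve and
plateaus once planted correlations saturate; near saturation, near-tied
indicators trade places across folds, so per-feature stability can wobble
slightly — the monotonicity test works at effect sizes 0.25–1.0 for this
reason.

## Problem sizes and determinism

Default analyses run at the full survey design (192 samples, 600 taxa, 150
GO terms).  Simulation-based validity checks use 500 null replicates with
199 permutations each; the multi-seed direction-of-effect analysis uses 5
generator seeds with 200 CV runs per model, the scale at which the
qualitative contrast is stable.  Every stochastic stage takes an explicit
seed (the pipeline derives per-stage seeds from one master seed and records
them in `run_log.json`); reruns are byte-identical.

## Known limitations

- The rare-feature threshold and pseudocount interact: very rare features
  that survive filtering still carry attenuated CLR signal.
- The permutation p-value floor is `1/(n_perm+1)`; Bonferroni-corrected
  screens need `n_perm ≳ 1000` per test to be able to reject at 0.05.
- MINT here is within-study standardization with shared loadings;
  study-weighted variants are out of scope.
- The heatmap cluster count (3) is a presentation default, not an inferred
  quantity.
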