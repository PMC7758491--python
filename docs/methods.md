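# Methods

This note documents the statistical machinery implemented in `qpref`: the
models, their assumptions, the defaults and why, what the synthetic
generator does and does not emulate, and the numerical choices that affect
results at the margin.

## The forced grid and its consequences

A Q-sort forces every participant's ranking into the same rank multiset
(the grid).  Two consequences drive the modeling choices downstream:

* every column of a valid dataset has the same sum, median and deviance,
  so there is no participant-level location or scale variation and the
  pooled preference model needs no random effects;
* for the canonical 32-stimulus grid the total sum of squares of any
  valid sort is fixed at 200, which makes the factor-score ANOVAs
  comparable across clusters by construction.

`default_grid(n_stimuli, n_ranks)` builds the canonical symmetric,
unimodal grid by allocating slots to rank positions proportionally to a
triangular weight decreasing from the center, with a minimum of one slot
per rank and the integer remainder distributed by deficit
(expected − assigned), center-out.  Unimodality is enforced by assigning
the sorted per-distance counts nearest the center.  For (32, 11) this
reproduces the canonical grid (1, 2, 3, 3, 4, 6, 4, 3, 3, 2, 1) exactly;
the property suite checks symmetry and unimodality across feasible sizes.
Asymmetric grids are accepted everywhere; only the builder is restricted
to symmetric shapes.

## Dominance statistics

For a score vector *s* over stimuli and a variable *v* with levels of
(ideally equal) size:

* D_v = max level sum − min level sum.  This equals the maximum over all
  unordered level pairs of the absolute difference of their sums, which
  the implementation cross-checks against brute-force enumeration in the
  tests.
* WD_v = D_v / maximal attainable difference.  The attainable maximum for
  an *n*-level variable is reached when one level occupies the top
  ⌊N/n⌋ slots and another the bottom ⌊N/n⌋; we use the floor when *n*
  does not divide *N*, because the bound must be attainable by an actual
  level of that size or smaller.  For asymmetric grids the top-k and
  bottom-k sums are combined explicitly rather than doubling the top-k.
* CSD_v = WD_v × (mean over variables of their attainable maxima).  With
  the worked design (2, 2, 2, 4 levels on the 32-slot grid) the scale
  factor is mean(64, 64, 64, 52) = 61.
* PD_v = WD_v / Σ WD.  If every WD is zero (constant scores) PD is
  undefined; the result is flagged (`defined=False`, PD = NaN) rather
  than dividing by zero.

Unbalanced designs violate the premise of the WD normalization (equal
level sizes); the statistics are still computed but the result is marked
approximate and a warning is emitted.

Factor-score mode accepts *continuous* z-score profiles, not only
grid-rounded integers.  Recomputing the worked study's cluster dominance
table from its grid-rounded scores does not reproduce the published
values (e.g. cluster 3's Texture weight comes out ≈ 0.07 instead of the
published 0.024), whereas continuous z-scores are consistent with them;
continuous profiles are therefore the canonical input for cluster
dominance, with rounded profiles available by simply passing them.

## By-person factor analysis

Extraction is principal components of the participants' Pearson
correlation matrix — the correlation of whole rank columns — so factors
are clusters of people, not of items.  Rotation is varimax with Kaiser
row-normalization, implemented as classical pairwise planar rotations
(the per-pair angle has a closed form) swept until the total rotation in
a sweep falls below 1e−6, capped at 1000 sweeps.  The pairwise form is
used deliberately: gradient/SVD iterations stall on the symmetric saddle
points that perfectly blocked toy data produce, while the planar angle
escapes them.  Rotation preserves each participant's communality to
1e−8 (tested).  Sign indeterminacy is resolved by flipping any factor
whose loading sum is negative; factors are then ordered by explained
variance.

Flagging is automatic and two-conditional: participant *p* is a defining
sort of their max-|loading| factor *k* iff

1. |loading_pk| > 1.96/√n_stimuli  (significance of a correlation at the
   5% level; ≈ 0.346 for 32 stimuli), and
2. loading_pk² > Σ_{j≠k} loading_pj²  (the factor explains more of the
   sort than all others combined).

This threshold is not a free parameter of the published study — it was
adopted because it exactly reproduces the study's defining-sort pattern,
including the one participant whose 0.54 loading fails condition 2.

Factor scores: each factor's defining sorts are averaged with weights
w = loading/(1 − loading²) (higher-loading sorts count more), then
standardized (population SD) to z-scores.  Loadings of exactly ±1 —
possible with duplicated sorts — are clipped just inside the unit
interval to keep the weight finite; equal clipped weights make the
degenerate cases exact.  Grid-rounded scores assign the grid's rank
multiset by descending z-score with ties broken by stimulus position,
so rounding is deterministic and always conserves the multiset.

The criteria report (the `Qfact.txt` analog) lists the scree series, the
Kaiser–Guttman count (eigenvalues > 1), and per candidate solution the
cumulative variance, flagged sorts per factor, the number of factors
retaining ≥ 2 defining sorts, and Humphrey's rule (product of the two
largest |loadings| > 2/√n_stimuli).  Parallel analysis is out of scope.

## Cumulative link models

The preference models are ordered probits fitted by maximum likelihood:

P(Y ≤ c_j | x) = Φ((θ_j + x_nomᵀγ_j − xᵀβ) / exp(zᵀζ))

with strictly increasing thresholds θ, location effects β, optional
threshold-specific (nominal) effects γ_j and optional log-scale effects
ζ.  The base model (γ = ζ = 0) matches `statsmodels`' ordered probit to
numerical precision (tested); the extensions exist to support the two
assumption diagnostics:

* the **nominal test** refits with one variable's coefficients free to
  vary across thresholds (LRT df = k(J−2) for k coefficients and J
  response categories) — a violation means the variable's effect is not
  constant across the scale (proportional-odds violation);
* the **scale test** refits with the variable entering the latent-scale
  dispersion (LRT df = k) — a violation means the variable changes
  response variability, not just location.

Numerics: parameters are optimized unconstrained (BFGS on the analytic
gradient, gtol 1e−7) and then polished with Newton steps using a
finite-difference Hessian of the analytic gradient until the gradient
sup-norm is below 1e−8 (fits report `converged` at 1e−6; above 1e−4 the
fit raises with diagnostics).  Thresholds are checked for monotonicity
after fitting rather than enforced by reparameterization, mirroring
common cumulative-link implementations; extended models warm-start from
the base fit.  The covariance is the inverse observed information
(central differences of the analytic gradient, symmetrized).  Per-variable
tests are joint Wald chi-squares on the coefficient block (a 1-df block
reduces to z²); a drop-one likelihood-ratio variant is provided because
Wald and LRT values can differ noticeably at these sample sizes and the
published study appears to have mixed the two for one variable.

Analysis 1 pools all participants' ranks (one observation per participant
× stimulus) with no random effects, which the forced grid justifies
exactly.  Analysis 4 models the stacked per-cluster score profiles (one
ordinal observation per stimulus per factor, e.g. 96 rows for 3 factors ×
32 stimuli) with variable × factor interactions; this observation set is
inferred from the published interaction degrees of freedom, and callers
preferring participant-level observations can stack flagged participants'
sorts by factor and pass those instead.

## Linear models of dominance weights

Analyses 2 and 5 are ordinary least squares on the long-format weight
table (one weight per unit × variable), treatment-coded with the first
design variable as reference; Analysis 5 keeps only flagged participants,
labels them by factor (first factor = reference) and adds variable ×
factor interactions.  Both delegate to `statsmodels` OLS/ANOVA; the
sums of squares are cross-checked against a closed-form one-way oracle in
the tests.  The factor-score ANOVAs are one-way per (factor, variable);
a grouping with zero residual variance returns F = ∞ with a `degenerate`
flag instead of crashing.

## Synthetic generator

Each cluster is a pair (attention weights over variables, level utilities
within variables); a participant's latent utility for a stimulus is the
attention-weighted sum of their cluster's level utilities plus
N(0, noise_sd) noise, and the sort is the grid multiset assigned by
descending utility (stable ties by stimulus position).  Noise enters the
utilities, never the ranks, so every generated column satisfies the grid
exactly.  A single integer seed drives one generator stream.

The packaged stand-in emulates the worked study's structure: the published
32-stimulus 2×2×2×4 design and 11-rank grid, 18 participants in three
clusters of 8, 6 and 4, noise SD 0.35 (roughly a third of the utility
range, enough to perturb mid-grid neighbors while keeping clusters
separable), and attention profiles qualitatively mirroring the published
cluster dominance pattern — cluster 1 splits attention between texture
and behavior, cluster 2 between behavior and contour, cluster 3 is
behavior-dominated.  These values were fixed once from the study's
description.  What the stand-in does *not* emulate: the study's actual
raw sorts (unavailable offline), participant idiosyncrasies beyond
i.i.d. utility noise, any sequential sorting behavior, and the exact
published loadings/weights.  A green pipeline test on the stand-in
therefore establishes that the machinery recovers a known structure, not
that it reproduces the study's raw-data numbers; those checks require the
supplementary `data.csv` and are reported as failures when it is absent.

One structural caveat: when a cluster's attention is concentrated on a
single variable with zero noise, that variable's WD reaches 1 exactly,
but its PD stays below 1 — the deterministic tie-break inside
equal-utility blocks leaves the remaining variables small incidental
level-sum differences.  PD = 1 would require all other raw dominances to
vanish exactly, which no tie-break guarantees.

## Known limitations

* Centroid extraction and judgmental rotation are not implemented; the
  factor engine is PCA + varimax only.
* Mixed-effects ordinal models and Bayesian estimation are out of scope;
  no multiple-comparison corrections are applied (raw p-values are
  reported).
* The published study's Table of factor-score ANOVAs contains two Texture
  cells that are inconsistent with its own printed grid-rounded scores
  (they match continuous z-score inputs); the test-suite asserts the
  reproducible cells and documents the two exceptions.
* Grid inference from data reads the multiset off the first participant's
  column; a dataset whose *first* column is corrupted will misreport the
  other columns as invalid.  Supplying the grid explicitly avoids this.
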