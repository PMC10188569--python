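# Methods

This note documents the models, numerical choices and limitations behind
`maxsdm`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The presence-background model

Presence-only SDM treats occurrence records as draws from an unknown
distribution over landscape cells and contrasts them with a background
sample of the landscape. The fitted object is a Gibbs density over the
background,

    q_lambda(x) = exp(lambda . f(x)) / Z,   Z = sum_bg exp(lambda . f(x)),

the maximum-entropy distribution subject to (regularized) feature-mean
constraints. Coefficients minimize

    f(lambda) = -(1/m) sum_i ln q_lambda(x_i) + sum_j beta_j |lambda_j|.

This is convex; any convergent convex method is acceptable. We use
cyclic coordinate-wise proximal Newton steps: for coordinate j the
gradient of the smooth part is E_q[f_j] − mean_presence[f_j], the local
curvature is Var_q[f_j] (floored at 1e-9), the Newton proposal is
soft-thresholded at beta_j / curvature, and a backtracking line search
(halving, ≤30 steps) guarantees monotone descent of the true objective.
Convergence is declared when a full sweep improves the objective by less
than `tol` (default 1e-4, the conventional "convergence threshold");
`max_iter` (default 5000) caps total coordinate updates. The softmax over
background is computed with a max-shift before exponentiation; the
partition sum is kept in log space.

Coordinate descent is chosen deliberately: each accepted update touches
one feature, which yields a *gain trace* — (update index, regularized
gain, feature id) — that percent-contribution accounting credits to
source variables, mirroring the sequential-update accounting of the
original MaxEnt software. The trace is path-dependent; permutation
importance is shipped as the path-independent cross-check.

Presence rows are appended to the background before normalization (the
standard "add samples to background" behaviour), so the background count
N includes them.

### Regularization

beta_j = RM · beta_class(m) · s_j / sqrt(m), with s_j the presence
standard deviation of feature j floored at 1/sqrt(m) (the scaled feature
range is 1, so the floor equals range/sqrt(m)); beta_class interpolates
the published per-class tables — linear/quadratic/product:
(0,1.0)→(10,1.0)→(30,0.2)→(100,0.05); threshold: (10,2.0)→(100,1.0);
hinge: 0.5 constant — clamped outside the tabulated range. beta is exactly
linear in the regularization multiplier RM, and the total |lambda| norm is
non-increasing in RM (tested on an RM ladder 0.5–5).

### Outputs

* raw: q_lambda with Z frozen from training; sums to 1 over the training
  background (conservation asserted to 1e-9 after every fit).
* cloglog: 1 − exp(−e^H · raw), H the entropy of the fitted background
  distribution. For the uniform model H = ln N and cloglog ≡ 1 − e⁻¹
  ≈ 0.6321 — a closed form used as a test anchor.

## Features

Scaling bounds come from pooled presence + background samples (the
estimation domain), not the full raster. L features are min-max scaled;
Q squares them; P multiplies scaled pairs; T is a step indicator
x > knot; hinges come in forward (x−k)/(max−k) and reverse (k−x)/(k−min)
pairs. Knots sit at evenly spaced quantiles of the pooled values
excluding the extremes — n_knots = 50 per direction by default; quantile
capping keeps the design matrix bounded where the original software
places per-value knots. Projection inputs are clamped to the fitted
bounds ("clamping", on by default), so features remain in [0,1] under
novel climates. Feature counts are exact: |L|=|Q|=V, |P|=V(V−1)/2,
|T|=V·k, |H|=2·V·k.

## Screening

Pearson correlations are computed complete-case over cells valid in every
layer; constant layers get r = 0 and a degeneracy warning. The greedy
screen scans an explicit priority order and keeps a variable iff
|r| < 0.8 (inclusive removal at the boundary) against everything already
kept. The priority list makes the otherwise-expert choice reproducible;
the default is descending univariate training gain, and callers may put
known biologically important variables first. The retained set is
order-dependent by construction — this is documented and tested rather
than hidden.

## Tuning and AICc

Candidates are all 31 non-empty subsets of {L,Q,P,T,H} × RM ∈
{0.5,…,5.0} (310 total). Cross-validation uses seeded random k-folds with
sizes differing by ≤1. The 10-percentile omission threshold is
count-based: the ceil(0.1·m)-th lowest training presence score
(inclusive). AICc follows the ENMeval convention: the model is refitted
on *all* occurrences, raw output is renormalized over every valid
landscape cell, lnL sums over presences, K counts |lambda| > 1e-12, and
AICc = 2K − 2lnL + 2K(K+1)/(n−K−1), undefined (NaN) when K ≥ n−1.
Selection takes ΔAICc = 0 with ties broken by parsimony (smallest K),
then smaller RM, then the feature-class string.

The full 310-candidate grid with 10-fold CV is exercised as an
enumeration; fitted tuning runs in the tests and the acceptance script
use reduced grids and the small landscape — the selection logic is
identical at any grid size.

## Evaluation metrics

* AUC is the rank (Mann-Whitney) statistic with ties at 1/2; invariant
  under monotone transforms (cross-checked against scikit-learn).
* maxSSS scans unique observed scores; presence counts as predicted
  positive at score ≥ t (inclusive), specificity is the fraction of
  background below t ("pseudo-specificity" — background cells stand in
  for the absences presence-only data lacks). The smallest maximizing
  threshold is returned.
* TSS = sensitivity + specificity − 1 at the maxSSS threshold.
* CBI uses 101 moving windows of width 10% of the landscape score range
  (common ecospat practice), drops empty-expectation windows, and
  rank-correlates P/E with the window center. Degenerate cases (constant
  scores, <3 usable windows, constant P/E) return 0 with a flag. Because
  the windows are equal-width in score units, CBI is exactly invariant
  under affine score rescaling but only approximately stable under
  nonlinear monotone transforms — the tests assert exactly that, rather
  than a blanket invariance the windowed statistic does not have. The
  background sample serves as the landscape reference in split
  evaluation.
* The 75:25 split puts ceil(0.25·n) records on the test side (32 of 125).

## Projection, classification, areas

Projection transforms every valid cell with the stored bounds/knots and
applies cloglog; nodata propagates, and projecting onto the training
stack reproduces training-cell predictions exactly. Ensembles are
unweighted cellwise means, nodata if any member is nodata. Five classes
derive from a threshold t (required < 0.25): breaks (t, 2t, 3t, 4t) with
band edges belonging to the upper class. The published bounds 0.195 /
0.389 / 0.584 / 0.778 are recovered, to 3 decimals, from t = 0.1945 —
the k·t rule inferred from those printed bounds; explicit break vectors
are also accepted. Cell areas use the spherical formula
R²·Δλ·(sin φ₂ − sin φ₁) with the authalic radius R = 6371.0088 km; class
areas partition the valid total exactly, and summing over a global grid
recovers 4πR² to well under 0.1%. Range change is reported as
100·(A_f − A_p)/A_p by default; the future-denominator convention is also
implemented and recorded in output metadata, since published change
percentages in this literature are sometimes closer to the latter.
Zero-to-nonzero transitions report a signed infinity, not a number.

## Synthetic landscapes

The generator emulates a WorldClim-style stack: each layer is a random
lat/lon linear gradient plus moving-average-smoothed white noise (kernel
5 cells), min-max rescaled into a role range — temperature-like 10–35,
precipitation-like 0–2500, seasonality-like 20–200. Planned correlations
build a clone as r·standardized(source) + sqrt(1−r²)·independent with the
independent field residualized against the source, so sample r matches
the target almost exactly and survives the affine rescale; the default
plan includes six pairs at |r| ≥ 0.8, exercising the screening stage.
Gradient weights are drawn at scale 0.6 against unit-variance noise so
*unplanned* pairs stay weakly correlated.

The truth surface multiplies plateau-Gaussian responses of three drivers:
suitability 1 inside the plateau, Gaussian falloff outside. Plateaus are
the niche ranges 22–28 (temperature, bio1), 300–1000 (annual
precipitation, bio12) and 70–160 (precipitation seasonality, bio15);
falloff widths default to 1.5 / 150 / 12 — about 6% of each role range —
so the jointly suitable core occupies a minority of the landscape, i.e.
a species with a defined climatic niche rather than one for which most of
the map is habitat. Occurrence cells are drawn without replacement with
probability proportional to suitability, points uniform within the cell;
125 points and a 100×100 grid at 2.5 arc-minutes are the default
conditions. Scenario deltas are layerwise affine maps (factor × layer +
offset), a deliberate simplification that does not emulate GCM anomaly
physics.

What passing recovery tests show — and do not show. On these landscapes
the full pipeline (screen at |r| ≥ 0.8, fit L+H+T at RM 2) tracks the
truth surface (landscape Spearman > 0.8), concentrates contribution on
the true drivers, and peaks the temperature response inside the plateau
± one falloff width. Real occurrence data add sampling bias, spatial
autocorrelation of errors, non-climatic drivers and observation noise
that this generator does not model; passing here validates the machinery,
not field accuracy.

## Pipeline order matters

The screening stage is not cosmetic: with r ≈ 0.9 clones of the
temperature driver left in, L1 fitting spreads the thermal signal across
the clones and the driver's marginal response curve flattens or shifts.
The recovery runs therefore screen first and fit second — the order the
workflow prescribes. Screening priority in those runs places the known
drivers first (the reproducible stand-in for the expert "biologically
important" choice) with the remaining variables in descending univariate
gain order.

## Problem sizes

Tests and the acceptance script run on 40×40 to 100×100 grids, 600 to
10,000 background cells, and reduced tuning grids; these sizes give
stable statistics for every assertion while keeping the whole suite
around a minute. All of them are parameters, not constants.

## Known limitations

* Percent contribution is reproducible only conditional on the optimizer
  path (as in the original software); use permutation importance for a
  path-independent view.
* No categorical features, sample-bias grids, logistic/cumulative output
  formats, spatial-block CV, or map reprojection.
* The ESRI ASCII reader/writer is the only raster codec; grids must share
  geometry exactly (no resampling).
* maxSSS thresholds above 0.25 cannot drive the five-class k·t scheme
  (breaks would exceed 1); supply explicit breaks in that case.
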