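# Methods

## The disruption model

D-Def treats a pass as effective to the degree that it forces the defending
team to reorganise. The defensive organisation at an instant is summarised
by ten quantities, all computed over the defending team's ten outfield
players: the team centroid (C_x, C_y), the centroid of each of three
formation lines, the surface area of the smallest convex hull containing
the players (S_area, in m²), and the spread (S_spread, in m), the Frobenius
norm of the position matrix after centring on the team centroid. The score
of a pass is formed from the change of each quantity between the pass
moment and a 3 s horizon, pushed through fixed principal-component
loadings (PC1 and PC2 weight the eight centroid changes, PC3 the area and
spread changes at 0.71 each) and combined as |PC1| + |PC2| + |PC3|, clipped
to the score's nominal 0–150 range.

Two conventions here are deliberate choices the source formulas leave open:

- **Unsigned deltas by default.** The composite is read as a disruption
  *magnitude*; absolute component changes guarantee a nonnegative score
  that is zero exactly when nothing changes. A signed mode is available
  (`org_delta(..., mode="signed")`) for directional analyses.
- **No rescaling between m and m² terms.** PC3 mixes area (m²) and spread
  (m) through the printed 0.71 coefficients without standardisation; in
  practice hull-area changes dominate the composite's variance, which is
  worth keeping in mind when comparing components.

Useful analytic anchors (these are asserted by the test suite): a unit
change of the team centroid alone scores 0.72; a unit change of area and
spread together scores 1.42; a *rigid* lateral shift of the whole defense
by δ metres moves all four centroids equally and scores
(0.46+0.43+0.43+0.41)·δ + (0.26+0.24+0.25+0.24)·δ = 2.72·δ.

## Formation lines

Lines are depth strata. Each team's outfield players are clustered by
k-means (k = 3, 10 restarts, fixed seed) on the longitudinal coordinate of
their average position over first-half frames, computed separately for the
in-possession and out-of-possession phases; D-Def uses the out-of-possession
assignment because it measures the defending side. Clustering on depth only
(not x, y) keeps lines from splitting laterally. The goalkeeper is excluded
from clustering and from all organisation measures: a keeper forced into
the defensive line drags its centroid ~15 m goalward and distorts exactly
the quantity the score differentiates.

## Possessions, attacks, success

A possession opens at a team's first controlled action (pass, reception,
interception, shot) and closes when the opponent gains control or play
stops (ball out of bounds, free kick, corner, goal kick, goal, foul);
stoppage events belong to neither side. Deliberate attacks are possessions
lasting strictly more than 5 s with at least three completed passes.
Passes pair each pass event with the next same-team reception inside the
possession; unreceived passes count as incomplete.

Attack success is danger-based, not goal-based. Each reception receives a
danger value in [0, 1]: a zone value from a 5 m grid covering the last
35 m in front of the opponent goal (a linear depth ramp times a lateral
decay, each grid cell carrying its ramp maximum), minus 0.5·(ρ − d)/ρ for
every defender within ρ = 4 m of the ball on the goal side (±90° of the
ball-to-goal bearing), clipped to [0, 1]. An attack is successful iff its
peak reception danger exceeds 0. The zone/pressure parametrisation is this
package's concrete instantiation of a qualitatively specified model; every
constant is exposed in `DangerConfig` so alternatives can be plugged in.

## Pass features

Length is the Euclidean distance between release and reception, velocity is
length over flight time, and the angle is the full-circle direction of the
displacement (two-argument arctangent) in attack-normalised coordinates, so
0° always means "toward the opponent goal". The single-argument slope form
arctan(Δy/Δx) is recovered as the restriction to (−90°, 90°); full-circle
angles are used because backward passes are real and a folded angle cannot
distinguish them.

## Statistics

Per dependent variable (D-Def, length, velocity) a 2 × 4 mixed-design ANOVA
(between: success; within: pass index 1–4 counted back from the final pass)
runs on complete cases — attacks with all four passes measured — since the
repeated-measures decomposition requires them. Mauchly's test at α = 0.05
triggers the Greenhouse–Geisser correction of the within and interaction
degrees of freedom. Partial η² is SS_effect/(SS_effect + SS_error-of-that-
effect). Group comparisons are independent t-tests with Levene's test
(mean-centred) choosing pooled vs Welch; Holm's step-down correction is
applied per variable family (the six comparisons of one block: pass 1–4,
per-attack mean, per-attack max), plus one family for the attack
descriptives. Cohen's d always uses the pooled SD, also when Welch's t was
selected — this is the convention that reproduces published effect sizes
from summary statistics. Pass directions are compared per pass index by the
Watson–Williams F-test, F = K(N−2)(R1+R2−R)/(N−R1−R2) on F(1, N−2), with
K = 1 + 3/(8κ̂) and κ̂ the maximum-likelihood von Mises concentration at the
mean resultant length (Newton-free bracketed inversion of I₁/I₀); a guard
requires n ≥ 10 per group. All tests are two-sided at α = 0.05.

## The synthetic generator

No public tracking data exists at this level, so the generator is a
first-class module producing the statistical structure the analysis
assumes, with ground truth:

- **Player motion**: each player holds a formation anchor (4-4-2 by
  default) with mean-reverting (Ornstein–Uhlenbeck) jitter, exact
  discretisation, reversion 0.4 s⁻¹ and diffusion 1.2 m/√s (stationary SD
  ≈ 1.3 m). Anchoring keeps the three-line structure that formation
  detection assumes.
- **Possessions** alternate between teams; pass counts are 3 + Poisson
  (mean 4.0 for the successful class, 2.2 otherwise, echoing the reported
  asymmetry in pass counts), inter-pass gaps are gamma-distributed
  (mean 3.5 s), lengths lognormal (median 16 m), velocities normal
  (12 ± 3 m/s). Event times are snapped to the 10 Hz tracking grid, as
  when events are annotated on the tracking stream.
- **Attack classes**: a possession is drawn "successful by construction"
  with probability 0.45; its final reception is placed inside the danger
  zone at a point that keeps a 6 m clearance from every defender's
  movement segment over the disruption window, so at zero motion noise the
  classification recovers the class exactly. Unsuccessful-class receptions
  stay at least 3 m outside the zone.
- **Disruption response**: selected passes (probability 0.8 / 0.5 per
  class) rigidly shift the defending team's anchors toward their own goal,
  ramped linearly over the 3 s window, held 0.5 s, decayed over 2.5 s;
  magnitudes are gamma with class means 4 / 2.5 m. Because the ramp is
  deterministic, the D-Def signature of a shift is analytically 2.72·δ.
- **`SimConfig.analytic`** is the validation preset: zero motion noise,
  every successful-class pass disrupted with a pure retreat shift,
  inter-pass gaps ≥ 6.2 s so disruption windows never overlap the next
  measurement window. The effect-recovery suite runs on this preset and
  skips the smoothing step, which would only blur the ramp endpoints of
  the injected displacement; recovered group differences then match the
  analytic prediction to within sampling error of the injected magnitudes.

What the generator does **not** emulate: ball-flight physics, player
interactions with the ball carrier, tactically coherent off-ball runs,
realistic turnover geometry, or measurement noise with the autocorrelation
structure of optical tracking. Passing tests on synthetic cohorts therefore
demonstrates the correctness of the computation chain and its statistical
calibration, not that real defenses behave like shifted anchor lattices.
With the default (noisy) conditions the absolute D-Def level runs higher
than in published elite-match data — independent player jitter produces
large hull-area deltas, and unsigned deltas fold noise into a positive
baseline — so synthetic cohorts support *relative* comparisons, not
absolute score calibration.

## Numerical and problem-size choices

- Nearest-frame lookup with tolerance of half a frame period; no
  interpolation of organisation states. Windows crossing a half-time
  boundary or the end of the series are flagged missing and excluded.
- Convex hulls come from Qhull; fewer than three non-collinear players give
  S_area = 0. K-means ties are broken by the fixed seed; line labels are
  ordered by centre depth.
- The smoothing default (Gaussian window 7, σ = 1 frame) is a standard
  functional replacement for vendor preprocessing filters, with edge
  renormalisation so constants are preserved.
- Test problem sizes: the ANOVA type-I-error calibration uses 1000
  replicates of 200-attack null cohorts; effect recovery uses a 4-point
  shift grid with 3 matches per point; end-to-end tests use 2–3 matches of
  120–300 s. These sizes give stable calibration estimates (binomial SE
  ≈ 0.7% at 1000 replicates) while keeping the whole suite in a few
  minutes.

## Known limitations

- The principal-component loadings are used as printed constants; they are
  not re-derived, and whether the original pipeline standardised features
  before projection is unknowable from the outside. Absolute scores are
  therefore comparable within this implementation, not across
  implementations.
- The 0–150 score range is enforced by clipping, not by construction.
- Formation assignment is static per phase and half; teams that change
  shape mid-half are averaged over.
- The danger model is a transparent stand-in for richer pass-value models;
  it orders receptions sensibly but has no probabilistic interpretation.
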