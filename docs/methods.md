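# Methods

## Model

Walking speed is modelled per terrain class as
`v = exp(a + b·φ + c·θ + d·θ²)` with `v` in km/h and both slopes in
degrees. The log-linear form guarantees positive predictions, makes
speed multiplicatively separable in hill slope and walking slope, and
yields interpretable coefficients: `exp(a)` is flat-ground speed, `b`
the proportional slow-down per degree of hillside steepness, and `c`,
`d` a log-quadratic in walking slope whose maximum sits at the mild
descent `θ* = −c/(2d)`. The model describes an average walker under
average conditions; individual effects (fitness, group size, weather,
load) are deliberately out of scope and must be handled by rescaling.

Terrain enters as five classes: paved road, unpaved road
(ways tagged path/bridleway/track), and off-road split by obstruction
height — the DSM − DTM difference, floored at zero — into light
(≤ 10 cm), heavy (> 10 cm) and unknown (no surface-model coverage).
The 10 cm cutoff reflects the observed drop in speed once ground
vegetation exceeds ankle height.

## Terrain variables

* **Elevation** is sampled from the terrain raster by bilinear
  interpolation of the four surrounding cell centres; with 5 m cells and
  ~60 m sections, nearest-cell sampling would add avoidable noise.
  Points inside the extent but outside the cell-centre hull are clamped
  to the hull (edge extension); nodata propagates.
* **Walking slope** is `arctan(Δz / planimetric distance)`, so 45°
  corresponds to a 1:1 rise over map distance and the value is
  antisymmetric under reversing the direction of travel.
* **Hill slope** uses the quadratic-surface method: a least-squares fit
  of `z = A·u² + B·w² + C·u·w + D·u + E·w + F` over the 3×3 cell
  neighbourhood (window size configurable), with
  `φ = arctan(√(D² + E²))`. The fit reproduces any plane exactly, so φ
  is aspect-invariant and exact on planar terrain.
* **Road class** is decided by the nearest recognised way within a 50 m
  search radius (GPS drift and map error make a radius necessary);
  nearest-way tie-breaking keeps the result deterministic and
  independent of the order ways are stored. The highway-tag → class map
  is a JSON config; path/bridleway/track are fixed as unpaved.

## Cleaning pipeline

Cleaning removes three artefact types from crowdsourced tracks: breaks
(stationary periods), non-walking travel (drives), and recording
glitches. Thresholds: 10 km/h speed cap, 1 km maximum step, 3 min
maximum gap, breaks over 30 s excised, 50 m minimum section length,
2.5 min minimum segment duration, 0.5% pooled speed trim.

Break finding combines pointwise rules (zero speed; over-limit steps or
gaps; an over-cap step immediately after a long pause) with spatial
cluster detection. Where the procedure leaves the functional details
open, this package makes the following documented choices:

* **Break likelihood** of a point is
  `0.5·max(0, 1 − speed/s_median) + 0.5·(turn_angle/180°)`, forced to 1
  at zero speed; "low likelihood" means < 0.5. It depends on speed only
  through the ratio to the segment median, so it is scale-free. Weights
  and threshold are configurable.
* **Cluster definition**: the neighbourhood of a point (5 points each
  side; configurable) is a cluster when its maximum pairwise planimetric
  extent is at most 2 × the median step distance — again scale-free.
  Clusters grow by absorbing overlapping cluster neighbourhoods, are
  trimmed of low-likelihood end points, gap-filled to a contiguous run,
  and accepted only if at least half their points look break-like *and*
  the run contains travel in opposite compass quadrants (Q1 & Q3 or
  Q2 & Q4), the signature of stationary jitter rather than
  through-travel.
* **Filtering bounds** for the uncurated corpus are empirical
  percentiles of per-segment summaries of the known-walking corpus:
  99th percentile of segment median, minimum and upper-quartile speeds
  (upper bounds) and 1st percentile of upper-whisker speeds
  (Q3 + 1.5·IQR; a lower bound). All percentiles are configurable.
* **Key points** in the uncurated branch are sections at or below the
  median-speed bound; single non-key sections between key points are
  dropped, fast runs between key points are dropped, and the segment is
  iteratively edge-trimmed and re-screened until stable (with a 100-pass
  safety stop).

Merging accumulates consecutive surviving steps until 50 m is reached;
distance and duration are sums over constituents, slope and obstruction
values are duration-weighted means, and a short trailing remainder is
folded into the preceding section. The pooled 0.5% speed trim is applied
at section level with stable tie-breaking; the realised trim thresholds
are recorded so that re-filtering a previous output removes nothing.

## Fitting and inference

The default estimator is a Gaussian-family GLM with log link, so the
fitted mean is exactly the model above. Because sections from one track
share a walker, weather and route, standard errors use a cluster
sandwich covariance with clusters = tracks, and term significance uses
cluster-robust Wald tests (joint chi-square for the road and obstruction
factor blocks).

An alternative estimator (`estimator="logols"`) fits ordinary least
squares to log speed. The two differ under multiplicative log-normal
error: the log-link GLM estimates the conditional *mean*, which for
`v = exp(Xβ)·exp(ε)`, ε ~ N(0, σ²), equals `exp(Xβ + σ²/2)` — an
intercept offset of σ²/2 (≈ 0.03 at σ = 0.25). Log-OLS is the matched,
unbiased estimator for that noise model and is therefore what the
parameter-recovery experiments use; on real data the choice is a
modelling judgement (mean versus median speed).

Backward elimination removes one term per refit — the least significant
removable term with p ≥ 0.05 — until everything remaining is
significant. Factor blocks are removed whole; road×slope interactions
are separate terms per road level, which is what allows the collapsed
per-terrain coefficient table to share values across classes whose
interactions were eliminated. Main effects are shielded while any of
their interactions survive; ties break on larger p, then term name, so
elimination is deterministic.

Fitted models are screened for physical plausibility per terrain class:
speed must not increase with hill slope (b ≤ 0), must eventually
decrease with walking-slope magnitude (d < 0), and the implied uphill
critical gradient must fall below 21°; models failing the screen are
treated as overfitted.

Cross-validation is 10-fold with folds split by track, never by
section, to respect within-track correlation; fold assignment is a
seeded permutation, so results are reproducible and independent of row
order.

## Critical gradient

On a hillside of slope φ ascended directly (θ = φ), the vertical ascent
rate is `v(φ, θ)·g(θ)`. Because φ is fixed by the hill, the optimal
walking slope satisfies `c + 2·d·θ + g′(θ)/g(θ) = 0`, independent of φ;
the root (found by bracketed Brent iteration on (0°, 45°], with
"no root" reported as > 45°) is the critical gradient above which
zig-zagging beats direct ascent. Two conventions are implemented for g:
`sin` (speed measured along the surface, the default) and `tan` (speed
planimetric); they differ by a fraction of a degree at walking
gradients. Descent is handled symmetrically with the sign of c flipped.

## Synthetic data

The generator emulates UK hill-walking country at 5 m raster
resolution: smooth correlated relief (Gaussian-filtered noise, 40 m
amplitude, 400 m correlation length), vegetation patches of 0.3–2 m
height added to the surface model (whose tiles cover only 70% of the
extent, so the obstruction-unknown class occurs), and a sparse network
of tagged ways. Walkers either wander with a smoothly-turning heading or
(35% of tracks) follow a way and are steered back when they stray.
Speeds are drawn as `exp(log v_model + ε)`, ε ~ N(0, 0.25), at 10–30 s
logging intervals over 20–60 min tracks; positions carry 3 m isotropic
GPS noise. Breaks are stationary (observed scatter is the GPS noise; an
extra wander term exists for tests that disable GPS noise) at about one
rest stop per hour of 3–15 min; 20% of tracks gain a high-speed
(30–80 km/h) drive prefix and/or suffix. Every point is labelled
walk/break/drive, and all draws flow from one seeded generator, so
fixtures are bit-reproducible.

What the generator does *not* emulate: device-specific GPS error
spectra (multipath, canopy degradation), altimeter error, route choice
driven by the terrain itself, heterogeneous walker populations, and
map-versus-ground misregistration of the road network. Passing
recovery tests therefore demonstrate the pipeline's correctness under
the stated noise model, not robustness to every failure mode of real
recordings.

## Problem sizes and numerical choices

Statistical tests run at deliberately chosen scales: parameter recovery
at 200 tracks × 50 sections (σ = 0.25), its replicate-bias check over
50 such replicates, cleaning recovery on 100 synthetic tracks, and
distributional checks on ~6,000 single-step sections. The coverage
rendering of the 2-SE recovery check (each coefficient inside its band
in at least 6 of 8 replicates) reflects that a joint assertion over 14
marginal 95% intervals fails by chance alone in roughly half of single
draws.

Degenerate inputs are contracts, not crashes: zero planimetric distance
makes walking slope undefined (error), a raster query outside the extent
or a quadratic window touching the boundary raises a coverage error,
missing DSM coverage is a valid class, and an empty cleaning result is a
valid output. Rank-deficient designs (a terrain class absent from the
data) are reported with the aliased columns named rather than silently
dropped. GLM iterations start from log-OLS estimates, which makes the
noise-free fit converge to the exact coefficients.

## Known limitations

* The local equirectangular projection is accurate for hike-scale
  extents (tens of km); continental-scale inputs should be projected
  externally.
* Off-road obstruction uses the surface-minus-terrain height at single
  points; sparse trees over open ground can therefore misclassify
  individual sections.
* Road classification within a 50 m radius over-classifies points as
  on-road near any mapped way; the fitted off-road coefficients are
  correspondingly conservative.
* The cleaning stage cannot distinguish very slow walking from a
  drifting pause shorter than the cluster window; recall of sub-minute
  breaks is limited by the logging interval.
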