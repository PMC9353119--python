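# Methods

## The measurement problem

The effective terminal velocity `Vt` of a diaspore — the maximum falling
speed at which aerodynamic drag balances weight — is the key trait in
mechanistic models of seed dispersal by wind. Classical drop tests measure
mean speed over a short fall and underestimate `Vt` badly for fast-falling
seeds, because such seeds are still accelerating when they reach the floor:
under quadratic drag a seed with `Vt = 6.4 m/s` first reaches 99% of `Vt`
only after 8.2 m of free fall, and after a typical 0.45 m drop it is at just
44% of `Vt`. `seedfall` implements the video-based alternative: film the
drop in a short backlit corridor with a single high-speed camera plus a
mirror, reconstruct the 3-D trajectory, and estimate `Vt` by fitting the
physics of drag-limited fall to the whole observed position series, so the
estimate does not require the seed ever to reach terminal speed.

## The fall model

A sphere at Reynolds number above ~10 experiences drag proportional to the
square of its speed. Starting from rest,

    v(t) = Vt * tanh(g t / Vt)
    z(t) = z0 - (Vt^2 / g) * ln cosh(g t / Vt)

with `g = 9.81 m/s^2` and `z0` the vertical position at `t = 0`. The free
parameters `(Vt, z0)` are estimated by nonlinear least squares on the
observed `(t, z)` series (`scipy.optimize.least_squares`, analytic Jacobian,
positivity bound on `Vt`, parameter tolerance 1e-10). The time origin is the
recording clock — the camera starts when the release flap opens — so
`v(0) = 0` holds by construction and no time-offset parameter is fitted.
Start values: `z0` from the first observed position plus the drag-free drop
accumulated by that frame time; `Vt` from the mean inter-frame speed over
the last three intervals (floored at 0.1 m/s). `ln cosh` is computed as
`logaddexp(u, -u) - ln 2`, which never overflows (the naive form fails
beyond `u ~ 710`, easily reached by slow seeds). The relaxation timescale is
`tau = Vt / g`, the standard form for this drag law.

Model adequacy is judged in velocity space: observed interval-average
velocities `(z_i - z_{i+1}) / dt` are compared with the model's
interval-average velocities (finite differences of predicted positions —
chosen over instantaneous midpoint velocities so a noise-free model
trajectory scores exactly zero), summarised as an RMSE and available
unaggregated for diagnostic plots. Residuals are unweighted.

## Geometry, calibration and reconstruction

The corridor is 0.25 x 0.25 x 0.33 m, camera 0.58 m from its centre,
1920 x 1200 px, 130 fps default (hardware supports up to 150). A mirror at
62 degrees from the camera plane provides a second view in the same frame;
the seed appears at `(x_d, z_d)` directly and `(y_m, z_m)` in the mirror.
Three 4-coefficient linear models with interaction convert pixels to
metres — `x` and `y` from `(x_d, y_m)`, `z` from `(z_d, z_m)` — fitted by
ordinary least squares to grid-board observations. No explicit camera model
is used; the interaction term absorbs the perspective coupling. Pixel origin
is top-left; the fitted coefficient signs map image rows to upward metric z
with no hard-coded flip. Extrapolation beyond the calibrated pixel ranges is
allowed but flagged.

The synthetic apparatus projects through a pinhole model: the direct view
along +y, the mirror as a virtual camera along -x (the 62-degree mirror
makes the reflected view nearly perpendicular; the residual obliquity is
exactly what the fitted conversion functions absorb, so the perpendicular
approximation is the default and the view angle is configurable). The
mirror's folded optical path is 0.81 m (camera to the mirror on the adjacent
side, then to the corridor centre), so the mirror view magnifies ~30% less
than the direct view. Focal length is derived so the corridor fills 85% of
each half-frame.

The default calibration design is 35 marks (7 x 5, spanning 0.12 m
horizontally and 0.28 m vertically) imaged at 5 parallel x 5 perpendicular
board placements (offsets over 0.06 m, depths over 0.12 m): the calibrated
volume is the measurement volume — the full corridor height and the central
column that seeds released through the 10-cm drop tube traverse, with
margin. On this design each conversion model explains >99% of the variance
(the z map ~99.8%). The residual of the z map is a property of the model
class, not of the fit: two scalar image coordinates cannot encode the
seed's depth, so perspective leaves a smooth ~2 mm-scale error field over
the calibrated volume, below 1 mm on the central column.

## Detection and cleaning

Detection follows the classic backlit-blob recipe: invert, subtract the
first (seed-free) frame, binarise at a fixed absolute threshold (default
25/255 — explicit here where interactive tools use adaptive defaults),
label 8-connected components, and report centroid, area and circularity
(`4 pi A / P^2`, Crofton perimeter, clamped to 1) for components of at least
10 px^2, assigned to the direct or mirror half by the frame midline.

Cleaning reduces the object table to one trajectory in four steps: discard
objects within 5 px of the frame edge; keep the largest object per frame
half (ties: first in input order); accept a frame as holding a putative seed
when the two halves' vertical coordinates agree within `z_match_tol`
(inclusive); return the longest run of consecutive putative-seed frames
(ties: earliest). `z_match_tol` defaults to 280 px: the two views magnify
differently, so the same seed's vertical coordinates legitimately diverge as
it moves away from mid-height — by up to ~260 px over the corridor under the
default geometry — while clutter at a genuinely different height still
fails the check. Dropout frames break runs by design; no gap interpolation.

## Sphere theory

For validation against first principles, the terminal velocity of a smooth
sphere solves `Vt = sqrt((4/3) g d (rho_s - rho_a) / (Cd(Re) rho_a))` with
`Re = rho_a Vt d / mu`, by a bracketing root finder (tolerance 1e-8 m/s,
force-balance residual checked to 1e-6). The drag correlation is pluggable:
Clift-Gauvin (default; standard drag curve, Stokes limit through the Newton
plateau, valid to `Re ~ 2e5`), Schiller-Naumann (viscous branch only), or a
constant. Buoyancy enters through `rho_s - rho_a`; the effect is
`~rho_a / (2 rho_s)` — negligible for dense materials, worth keeping for
light foams. Air defaults to 20 degC sea level (1.204 kg/m^3, 1.825e-5 Pa s).

## Repeatability statistics

Replicated measurements (default design: 5 species x 10 seeds x 4 drops)
are analysed on natural-log `Vt` (any base gives identical variance ratios).
Variance components for the nested model
`log Vt = mu + species + seed(species) + error` are estimated by REML
(`statsmodels` MixedLM); a method-of-moments estimator from the balanced
expected mean squares serves as a cross-check and errors out on unbalanced
data, pointing to REML. Species is treated as a random effect despite few
levels, matching the standard design of such repeatability studies; the
species-level component is accordingly the noisiest (4 df). Within-species
seed effects are summarised by one-way ANOVA R^2, and repeatability by the
one-way ANOVA ICC with the `k0` group-size adjustment for unbalanced data,
either pooling all seeds across species as groups or grouping by species.
Negative ICCs are reported as computed, with a note.

The dataset generator draws Gaussian species, seed and residual effects on
the log scale; defaults put the variance fractions at 98.4 : 1.0 : 0.6 of a
unit total — the regime of strong between-species separation in which the
pooled-seed ICC sits near 0.993.

## What the synthetic data does and does not emulate

Emulated: drag-law kinematics, the two-view projection geometry with
perspective, anti-aliased dark blobs (radius 8 px, contrast 180) on a
backlit background (level 230), Gaussian pixel noise (sd 2 grey levels),
centroid jitter (sd 0.3 px), frame dropouts, and a seed-free first frame.
Not emulated: motion blur, autorotation and attitude changes of winged or
plumed diaspores, lens distortion beyond perspective, lighting gradients,
and air turbulence. Passing the end-to-end tests therefore demonstrates
that the *reconstruction and estimation chain* is correct and unbiased at
realistic noise levels; it does not certify accuracy for seeds whose
aerodynamics violate the sphere model — on real data the velocity-RMSE
diagnostic exists precisely to flag those.

## Accuracy of the full pipeline and problem sizes

With defaults, the end-to-end chain (simulate -> render -> detect -> clean
-> reconstruct -> fit) recovers `Vt` with median relative error ~0.6% at
0.3 m/s and ~1.0% at 1.5 m/s (17 replicate drops each in the test suite;
16 at 6.4 m/s). At 6.4 m/s the median error is ~10% and systematic: within
the 0.33 m corridor such a seed reaches only ~52% of `Vt`, so the estimate
rests entirely on the small `t^4` curvature term that separates drag from
free fall, and the millimetre-scale depth-coupling residual of the
conversion-model class aliases directly into it. This mirrors the physical
instrument, whose published sphere validations show accuracy down to ~92%
for the fastest spheres. Fast-seed estimates should be read with that
systematic uncertainty in mind; a taller corridor or higher release (so the
seed enters nearer terminal speed) is the physical remedy.

Monte-Carlo sizes used in the tests (100 replicates for noise-recovery, 200
for ICC recovery, 50 total end-to-end drops) were chosen to make medians
stable; tolerances are stated per test.

## Known limitations

* Single seed per drop; no multi-target tracking.
* The conversion-model class cannot correct depth-dependent magnification;
  accuracy degrades toward the corridor's horizontal extremes.
* The orthographic projection mode makes the two vertical image coordinates
  exactly collinear, so the z map is deliberately rejected as rank-deficient
  there; it exists as a degenerate test case for the horizontal maps.
* ICC confidence intervals are not implemented.
* Video containers are not decoded; the input contract is an image-sequence
  directory plus a frame rate.
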