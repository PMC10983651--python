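# Methods

`rootkin` reconstructs and analyses the 3D movement of a plant root tip
grown in hydroponics, observed by a calibrated pair of time-lapse cameras
through a flat air/water interface. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
tests do and do not demonstrate.

Units are fixed package-wide: millimetres, minutes, Hz, hours for
periods. The world frame is the left-camera frame; `z` is depth along the
left optical axis, assumed perpendicular to the flat refractive
interface. Pixel coordinates have the origin at the top-left, `u` right,
`v` down; tracks are assumed lens-undistorted upstream (distortion
coefficients are stored for provenance only).

## Stereo reconstruction

Projection matrices are composed as `P = K [R | t]` from each camera's
intrinsics and the stereo extrinsics; calibration estimation itself is out
of scope — parameters are inputs. A 3D point is triangulated from a
left/right pixel pair by the direct linear transformation: the 4x4
homogeneous system stacked from both views is solved by SVD
(smallest-singular-vector, dehomogenized), with no iterative refinement.
Degeneracy is declared when the camera centres coincide (baseline
< 1e-9 mm) or the system's third singular value falls below 1e-10 of the
largest (parallel rays); a homogeneous solution with `w ~ 0` is reported
as a point at infinity. Left/right timestamps must pair within 1 s, the
acquisition system's synchronization bound.

### Water-depth correction

Refraction at the flat interface displaces the virtual image of a
submerged point toward the camera along the depth axis; in the paraxial
limit the apparent depth is `z_a = z_i + (z_t - z_i)/n` for interface
depth `z_i` and refractive index `n`, i.e. an affine map of true depth.
The compensation is therefore modelled as one linear map
`z' = slope * z_a + intercept` applied to the depth coordinate only
(x, y untouched), fitted from a submerged 10x7 chessboard with 8 mm
squares tilted ~30 deg about the vertical axis. The tilt spreads the
board's columns across depth by `square_size * sin(tilt)` per column, so
the board's known geometry provides true depth *differences*; the fit's
slope (~n) comes entirely from them.

The absolute anchor of the line is genuinely underdetermined by the board
alone, so two conventions are offered:

* **nearest-corner anchoring** (default): the corner with the smallest
  apparent depth is taken as true. This leaves a constant depth offset of
  roughly `(1 - 1/n)` times the anchor's distance behind the interface —
  harmless for kinematic features (which are differences) but visible in
  absolute depth.
* **interface anchoring** (`interface_z=` argument): the line is pinned at
  its physical fixed point, the interface itself, whose position is known
  at rig-design time. This removes the constant offset and is the
  recommended workflow when the tank geometry is known.

Because the apparent-depth factor varies weakly with ray angle, a fit at
one board depth extrapolates imperfectly; `fit_water_correction_sweep`
pools per-depth fits over a board sweep spanning the working volume. With
the default synthetic rig, the sweep-fitted, interface-anchored
correction leaves a median 3D reconstruction error of ~0.1 mm over a
7-day trajectory (uncorrected: ~25 mm).

## Kinematic features

The **main growth component** is the per-coordinate centred moving
average of the trajectory over the samples acquired in 4 h (80 samples at
the 3-min default interval) — long enough to cancel circumnutation
(30–120 min periods) while following the slower drift of growth. Even
windows use the standard centred form with half-weighted end samples
(N+1 points), which keeps the filter symmetric: straight lines pass
through unchanged and a sinusoid completing whole cycles inside the
window cancels exactly. At the record boundaries the window shrinks
symmetrically (`edge="shrink"`, output keeps the input length) or the
incomplete-window samples are dropped (`edge="trim"`).

Shrunken edge windows leave up to ~22% of the oscillation amplitude in
the trend near the record ends (the worst Dirichlet-kernel leakage occurs
around 1.4 cycles per window), which would inflate path lengths and the
maximum nutation amplitude. `extract_features` therefore computes all
trend-based features on the trimmed interior by default
(`trim_edges=True`); the half-window (2 h) at each end of a 7-day record
is a 2.4% loss of data.

Features, with `p(i)` the trend samples:

* overall length `L = sum ||p(i+1) - p(i)||` (sum of 3D segment lengths);
* absolute growth rate: the same sum over an interval of `d` samples
  starting at `a` (0-based internally; the interval is preserved as a
  start + count pair);
* relative growth rate: absolute rate divided by the trend length
  accumulated from the start of the record to the interval's end
  (length-to-date, not final length);
* daily rates: consecutive non-overlapping 24-h intervals from the first
  sample (not clock midnight); a trailing partial day is dropped;
* average tip velocity: hourly path length of the **raw** trajectory over
  a sliding 60-min window evaluated every 15 min, averaged; raw because
  the quantity is the distance travelled by the tip, oscillation
  included. Window and step are configurable, and the trend can be
  substituted via an argument. This estimator is the most noise-sensitive
  of the set: tracking noise adds a random-walk component to raw path
  length;
* nutation distance series: XY-plane distance between each raw sample and
  the trend at the same time index (no closest-point search; depth
  ignored); its maximum is the maximum nutation amplitude.

## Spectral analysis

The nutation-distance series is non-negative with a large mean, so its
mean is subtracted before the FFT and the DC bin is excluded from the
one-sided amplitude spectrum (scaled so a sinusoid of amplitude A peaks
at ~A). No taper is applied, matching the plain-DFT protocol; a Hann
option exists for users. The **main period** is the reciprocal of the
frequency with the maximum amplitude (ties break toward the lower
frequency); peak search uses the raw spectrum — the 8-sample moving
average is a display convention. Periods are reported unrounded: a peak
at 0.00027 Hz is 1.029 h, at 0.000062 Hz 4.480 h.

Cross-plant averaging interpolates all spectra linearly onto the grid of
the spectrum with the coarsest resolution, restricted to the common
frequency range, then averages bin-by-bin. Records of equal length share
a grid and the operation reduces to an element-wise mean.

## Operator reliability

Agreement between two operators' feature values over the same plants is
quantified with the intraclass correlation in its two-way
random-effects, absolute-agreement, **single-measure** form,

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E)/n),

computed from the two-way ANOVA mean squares of the n x k ratings matrix.
Single-measure is chosen because individual operators (not their average)
are compared; values are reported to 3 decimals. Absolute agreement
penalizes systematic per-rater offsets, unlike the consistency form — a
property the tests verify explicitly. A zero-variance matrix returns 1.0
with a warning (trivial agreement). Confidence intervals are out of
scope.

## Synthetic scene generator

The simulator provides ground truth for every stage. A root tip is

    x(t) = x0 + v t g + sum_c A_c (1 + m_c cos th_c) [cos th_c e1
           + eps_c sin th_c e2] + (drift terms) + noise,

with `th_c = 2 pi t / T_c + phi_c`, `e1, e2` orthonormal and
perpendicular to the growth direction `g`, ellipticity `eps` in [0, 1]
and **radial modulation** `m` (default 0.1). The modulation makes each
loop slightly lopsided — the loop radius varies over a cycle. It exists
because a perfectly centred loop hides its own period from the
distance-based analysis: the tip's distance from the growth axis is
constant for a circular loop and folds to twice the frequency for an
elliptic or 1-D one. Real circumnutation traces irregular, off-centre
loops; `m = 0.1` puts a distance oscillation of amplitude ~A m/2 at the
orbit frequency while raising the true maximum deviation only to
A (1 + m/2). Setting `m = 0` recovers the perfectly centred textbook
loop. Note that with *several* coplanar components the distance series
also contains intermodulation terms at the difference frequencies (e.g. a
77-min beat between 60-min and 270-min components), which can dominate
the component fundamentals — the default is therefore a single
circumnutation component, with drift components (periods > 4 h) available
explicitly.

Default study-scale conditions: growth 1.2 mm/h for 7 days sampled every
3 min (3361 samples), one 1 mm / 60 min circumnutation component,
tracking noise added in pixel space (0.3 px default) — the real error
source is the 2D tracker, not 3D jitter.

The default rig is a plausible reconstruction, not a published geometry:
two identical 1920x1080 cameras, 3000 px focal length, 100 mm baseline
with parallel axes, mounted above the tank looking straight down at the
water surface 250 mm away, the root growing downward along the optical
axis and circumnutating in the horizontal (XY) plane. Looking down the
growth axis is what makes the XY plane the circumnutation plane, so the
XY distance series carries the full oscillation. A single flat air/water
interface is modelled; the vessel wall's finite thickness is folded into
the linear correction, as the linear model implicitly does.

Refraction is exact, not paraxial: for each camera-point pair the Snell
crossing on the interface plane solves the stationary-optical-path
condition `n1 r / sqrt(r^2 + h1^2) = n2 (d - r) / sqrt((d - r)^2 + h2^2)`
by 80 bisection iterations on `r` in `[0, d]` (the residual is monotone),
vectorized over all samples; the pinhole projection of the crossing point
is the observed pixel. With index 1 this reduces to plain projection.
Tests verify Fermat's principle against a dense independent search.

### What the synthetic tests do and do not show

The generator emulates the *geometry* of the measurement chain —
projective observation, refraction, tracking noise, oscillation-plus-
growth kinematics — and the recovery tests show the pipeline's estimators
are unbiased at study scale under that model. They do not emulate
tracking failures (label swaps, occlusion by lateral roots), non-circular
irregular nutation, growth-rate fluctuations, lens-distortion residuals,
or camera synchronization drift; accuracy claims on real footage rest on
the original system's validation, not on these simulations.

## Problem sizes and determinism

Default test and acceptance problem sizes are chosen to exercise the full
study scale while staying cheap: 7-day scenes (3361 samples), 10 seeded
scenes for end-to-end recovery, 1000 random configurations for the
projection round trip. All randomness flows through explicit integer
seeds (`numpy.random.default_rng`); re-running any stage with the same
inputs is bit-identical.

## Known limitations

* The linear depth correction is a first-order model; its residual grows
  with ray angle and with extrapolation outside the calibrated depth
  range (use a board sweep spanning the working volume).
* Absolute depth requires either the interface anchor or a board touching
  the interface; nearest-corner anchoring alone leaves a constant offset.
* The average tip velocity inflates with tracking noise (random-walk path
  length); compare operators or conditions at equal noise levels.
* The main-period estimator returns the single dominant bin; bimodal
  spectra (growth drift plus circumnutation) are better read from the
  full spectrum, and time-resolved methods (wavelets) are out of scope.
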