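# Methods

`mothfan` analyses how a wing-fanning male silkworm moth (*Bombyx mori*)
samples odour-laden air. A fanning moth stands still and flaps its wings
without flying; the induced current draws air — and any pheromone it
carries — past the antennae. The package reconstructs the wing kinematics
that drive this current, evaluates a time-periodic flow field at a virtual
antenna, traces pheromone particles backward in time to find where sampled
air came from, and summarises that *sampling volume* statistically. A
synthetic-data generator with exactly known ground truth replaces the two
experimental inputs (stereo high-speed video landmarks and flow-simulation
snapshots), so the entire chain is testable offline.

## Coordinate conventions

Lab frame: right-handed, `x` anterior (where the head points at rest), `y`
toward the animal's left, `z` up, floor at `z = 0`. Angles are radians
internally and degrees at every I/O boundary. The stroke plane passes
through the wing pivot, contains the lab `y` axis, and is inclined from
horizontal by the stroke-plane angle `beta` (typical fanning value
99.5 deg, slightly past vertical). Within it, the positional angle `phi`
is measured from the horizontal line of the plane; the elevation angle
`theta` is the out-of-plane deviation, positive anterior (fanning wings
sit posterior of the plane on average, `theta ~ -24 deg`); the feathering
angle `alpha(r)` rotates each spanwise cross-section about the spanwise
axis, with `alpha = 90 deg` meaning the chord is perpendicular to the
stroke plane.

## Kinematic reconstruction

* **Body angle** is the signed inclination of the abdomen-tip to head-tip
  axis against the horizontal plane, positive head-up. The sign convention
  is an assumption (the measurement itself only defines the magnitude).
* **Stroke-plane angle** is fitted by total least squares (first principal
  direction) of the wingtip path projected onto the sagittal `x-z` plane.
  TLS rather than ordinary regression keeps near-vertical stroke planes
  (the typical case) well posed.
* **Positional/elevation angles** follow from exact trigonometry of the
  pivot-to-tip vector in the stroke-plane basis. Samples whose tip vector
  is normal to the plane have undefined `phi`; they are flagged, logged
  and excluded from averages.
* **Feathering** is fitted per frame by posing a model wing (elliptic
  planform, thickness 1% of wing length) with candidate station twists,
  reprojecting its contour through the calibrated cameras and minimising
  the summed squared 2D distance to the observed contour points
  (`scipy.optimize.least_squares`). A quadratic penalty on second spanwise
  differences regularises the profile; because the penalty annihilates
  linear functions, a noise-free linear twist is recovered exactly. When
  3D contour points are available directly (the synthetic path), the twist
  is inverted in closed form instead.
* **Cycle averaging.** Cycles are delimited at maxima of `phi` (start of
  downstroke, so the downstroke occupies normalised time [0, 0.5)),
  detected on a zero-phase low-pass-filtered series (4th-order
  Butterworth, cutoff 3f) with sub-frame quadratic peak refinement. Each
  cycle is resampled by cubic spline onto a common 200-point grid and
  averaged; right-wing series are expressed in the sagittally mirrored
  frame before averaging with the left. Amplitude and frequency are
  recomputed from the averaged series.
* **Angular rates** use spectral differentiation of the phase-averaged
  periodic series (exact for band-limited signals on the periodic grid);
  second-order central differences are the fallback for raw series.
* **Angle of attack.** Section-relative speeds are
  `v_h = r(-phi_dot cos(alpha) cos(theta) + theta_dot sin(alpha))` and
  `v_v = r(-theta_dot cos(alpha) + phi_dot cos(theta) sin(alpha))`, and
  `AoA = arccos(v_h / sqrt(v_h^2 + v_v^2))` in [0, pi]. Values above 90 deg
  are additionally reported folded to `pi - AoA`, the convention used for
  plots; zero-speed samples yield a NaN sentinel and drop out of averages.
* **Sagittal deconfliction.** When averaged kinematics make the wing
  interfere with the sagittal (symmetry) plane, the motion is rigidly
  rotated about the horizontal, posteriorly directed axis through the wing
  root by the smallest angle restoring the requested clearance (coarse
  0.01-deg scan bracketing a root solve). A rigid rotation preserves wing
  speed exactly; rotations above 15 deg are rejected as mis-registered
  input.

### Stroke-plane identifiability

The inclination obtained by regressing the tip path in `x-z` is not the
same quantity as the frame angle used to *generate* a motion whose
elevation angle oscillates: the in-plane and out-of-plane coordinates of
the projected path correlate at second order in the elevation amplitude,
tilting the principal direction by `O(amplitude^2)`. No estimator based on
the projected cloud alone can remove this (the decomposition is
frame-covariant), so the regression convention — the field's standard — is
kept, and the synthetic generator's default elevation amplitude (3 deg,
consistent with the nearly flat elevation traces of fanning) keeps the
generation-reconstruction mismatch near 0.07 deg, inside the 0.1 deg
identity budget the test suite asserts. Larger elevation amplitudes grow
the mismatch quadratically (about 0.2 deg at 5 deg amplitude).

## Dimensionless numbers

Mean wingtip speed is `2 * amplitude * f * R` (exact for a sinusoidal
positional angle); the Reynolds number uses it with the mean chord,
`Re = 2*amplitude*f*R * c_m / nu`; the Schmidt number is `Sc = nu / D`
with air viscosity `nu = 1.5e-5 m^2/s` and bombykol diffusivity
`D = 2.5e-6 m^2/s`, giving `Sc = 6.0`: advection dominates molecular
diffusion, which motivates treating pheromone transport as pure advection.

## Flow fields and interpolation

A `FlowField` is one converged wingbeat cycle of velocity snapshots on a
structured Cartesian grid (default 50 snapshots/cycle), treated as
periodic. Evaluation at `(x, t)` is trilinear in space on each of the four
temporally nearest snapshots (indices wrapped periodically, two back and
two forward of the query) followed by third-order Lagrangian interpolation
in time — exact for fields trilinear in space and cubic in time, with the
classic `(2*pi/S)^4` error scale for sinusoidal time dependence at `S`
snapshots. Out-of-domain queries either raise (default for tracing, where
the trajectory is then truncated and flagged) or freeze at the boundary
value with a counter (default for probing).

The **probe** reports, per antenna station (21 stations from base to tip by
default), the cycle-mean speed, the oscillation amplitude, and a spectral
diagnostic. Amplitude is half the peak-to-peak excursion of the *signed*
projection of the velocity onto its principal oscillation direction, so a
reversing sinusoid `A sin(2 pi t/T)` has amplitude `A` at frequency `f`,
while a pulsating non-reversing jet registers at `2f`. The diagnostic
reports `f`, `2f`, `other`, or `none` for steady flow.

## Synthetic data

**Landmarks.** Harmonic kinematics: `phi` is a single sinusoid (downstroke
starting at the cycle origin), `theta` a single sinusoid in quadrature,
and `alpha` two harmonics per station with amplitudes growing toward the
tip — the simplest family exercising the spanwise-twist asymmetry of real
wings. Defaults are typical fanning values (R 17.3 mm, f 48.9 Hz,
amplitude 98 deg, stroke plane 99.5 deg, body angle -0.6 deg, mean
elevation -23.8 deg; 8 cycles at 2000 frames/s). The body is static;
landmark noise is isotropic 3D Gaussian (manual tracking has no preferred
axis), seeded and bit-reproducible. Pinhole cameras with exact intrinsics
provide projection/triangulation fixtures; camera placement is plausible
rather than calibrated to any particular rig, since only round-trip
properties are tested.

**Analytic flows.** Uniform, point-sink and Rankine-vortex kinds are
steady and divergence-free away from their singular sets (checked by
complex-step differentiation of the analytic evaluator, which is exact to
round-off — the discrete snapshot stack itself has ordinary `O(h^2)`
finite-difference divergence). A pulsed Gaussian jet provides a simple
periodic kind.

**Induced flow.** The flapping-induced current is modelled as a pulsed
momentum jet: air is expelled along the posterior stroke-plane normal from
a Gaussian envelope (radial width R, axial width 2R) centred at the
mirror-averaged mid-stroke 70%-span point, with instantaneous strength
`efficiency * R * |phi_dot(t)|` plus a stroke-direction component
`-efficiency_osc * R * phi_dot(t)` that reverses between downstroke and
upstroke. Consequences: zero motion induces zero flow; the cycle-mean
core speed is `efficiency * 2*amplitude*f*R` (exactly linear in wingtip
speed); the speed pulses at `2f`; intake is anterior of the head, so
back-traced particles originate in front of the moth; and the vertical
oscillation makes air arrive alternately from above and below the
antenna. The entrainment efficiencies default to 0.13, placing the
antenna-tip cycle mean at a few tenths of m/s — the scale reported for
real fanning. This jet reproduces the qualitative structure of the
fanning flow but is not a Navier-Stokes solution: it is not
divergence-free, has no vortex wake, no clap-and-fling transient and no
floor boundary layer, so quantitative flow values downstream of it
characterise the model, not the insect.

## Backward tracing and the sampling volume

Pheromone molecules are weightless tracers advected by the local velocity;
diffusion is neglected (defensible at Sc = 6). Because the question is
where sampled air *came from*, trajectories are integrated backward:
from each of 21 antenna stations, at each of 21 release phases evenly
spaced over the wingbeat, `dx/dt = -u(x, t)` is stepped with explicit
Euler at 500 steps per wingbeat for 40 wingbeats (defaults; RK4 is
available for convergence checks — measured global orders are 1 and 4 on
smooth fields, while trilinear fields limit RK4 in practice because the
interpolant is only C0 across cell faces). The union of backward path
lines over the release phases approximates the streak surface of arriving
particles. Positions at whole-cycle offsets (1..40 wingbeats before
arrival) form the sampling volume; trajectories that exit the grid box are
truncated, flagged, and excluded from statistics by default (the desk-
scale default box, 300 x 200 x 150 mm at 5 mm spacing, retains essentially
all 40-cycle paths of the default jet). The floor is part of the domain
boundary; body surfaces are not modelled as obstacles.

Euler with 500 steps/wingbeat mirrors the quoted step rule of the
measurement pipeline this package emulates; `forward_check` re-advects an
origin forward with the same scheme and reports the closure distance
(zero to round-off in constant fields, below 1e-3 of the path length with
RK4 on smooth fields at default resolution).

## Statistics

Origins are summarised relative to the head: Euclidean distance;
horizontal angle = signed azimuth of the head-to-origin vector from the
heading (heading at rest, i.e. the abdomen-to-head axis; 0 deg dead
ahead, positive toward the left wing — the side simulated); vertical
angle = elevation above the horizontal plane. Origins straight above or
below the head have undefined azimuth and are excluded from horizontal
statistics with a log record; origins coincident with the head are
dropped.

Violin summaries per arrival-time bin (5-wingbeat bins by default) use
linearly interpolated quantiles and Tukey whiskers: the extreme values
inside the 1.5*IQR fences, clipped to the quartiles so the ordering
`lo <= p25 <= median <= p75 <= hi` holds even when an interpolated
quartile exceeds every in-fence value.

The **angular extent** at coverage `q` (default 0.9) is anchored at the
sagittal direction: the one-sided extent is the `q`-quantile of |azimuth|
(a single-wing volume concentrated in 0-30 deg reads ~30 deg), and the
two-sided extent of a mirrored two-wing volume is exactly twice the
one-sided value. The **anisotropy test** is a Kolmogorov-Smirnov test of
the azimuths against uniformity on the covered support; an isotropic sink
volume passes (p uniform under the null), a forward-focused jet volume
fails at any practical level.

## Pipeline, formats, reproducibility

The `mothfan` CLI exposes each stage (`synth-kin`, `reconstruct`,
`synth-flow`, `probe`, `trace`, `stats`, `report`) and a `run-all` chain
driven by one YAML configuration; all randomness flows through its single
seed, and every run writes a provenance record (configuration hash,
package versions, seed). Formats: landmark CSV (one row per landmark per
frame), flow NetCDF (dims time/z/y/x, variables u/v/w, written through
xarray's scipy backend; an `.npz` archive is the fallback dialect),
kinematics JSON (degrees at the boundary), sampling-volume and stats CSV.
`mothfan validate` checks any of these against its dialect and reports
every violation.

Default problem sizes (8 synthetic wingbeats at 2000 frames/s; a
300 x 200 x 150 mm grid at 5 mm spacing with 50 snapshots/cycle; 21 x 21
trajectories x 500 steps x 40 cycles) were chosen so a complete `run-all`
finishes in a few minutes on a single core while keeping the tracer's
discretisation at the emulated pipeline's own density.

## What passing tests do and do not show

The synthetic generator provides exact ground truth, so the test suite
demonstrates *internal consistency*: the reconstruction inverts the
generator, the interpolants meet their order guarantees, the tracer
matches closed-form oracles and measured convergence orders, and the
statistics match hand-computed order statistics. Real data add manual
tracking noise, non-harmonic kinematics, body motion, and genuinely
turbulent, vortical induced flow — none of which the analytic jet
represents. Quantities that depend on the detailed flow structure (probe
magnitudes, the width of the sampling cone) are therefore model
illustrations; quantities that do not (angle definitions, dimensionless
numbers, interpolation and tracer mechanics, statistical summaries) carry
over directly.

## Known limitations

* The induced-flow jet is kinematically driven and not incompressible;
  no quantitative aerodynamic claims (forces, power, vortex structure)
  can be made from it.
* Feathering reconstruction assumes known 2D-3D contour correspondence;
  real contour clicking has occlusion and correspondence error.
* The stroke-plane angle inherits the `O(elevation amplitude^2)`
  regression bias discussed above.
* Trajectories ignore molecular diffusion and treat the floor as a
  truncating boundary rather than a no-slip wall.
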