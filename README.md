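# mothfan

Analysis pipeline for the olfactory aerodynamics of a wing-fanning
silkworm moth (*Bombyx mori*). A fanning male flaps its wings without
flying; the induced air current draws pheromone-laden air past the
antennae, letting the moth sample odour from a specific region of space.
`mothfan` reconstructs the flapping kinematics from 3D landmark tracks,
evaluates a time-periodic induced-flow field at a virtual antenna, traces
pheromone particles backward in time, and quantifies the resulting
three-dimensional, anisotropic **sampling volume** — the cloud of
positions from which sampled air originated, tagged by how many wingbeats
it needed to arrive.

The package is aimed at researchers in biomechanics and chemical ecology
who have (or want to emulate) stereo high-speed landmark tracks and
gridded periodic flow snapshots. A synthetic-data generator with exact
ground truth stands in for both experimental inputs, so the full chain
runs and is tested with no external data.

## The model in brief

Wing motion relative to the stroke plane (inclination `β` from horizontal,
fitted by total least squares of the wingtip path in the sagittal plane)
is described by the positional angle `φ(t̂)`, elevation angle `θ(t̂)` and
spanwise feathering angle `α(r, t̂)`. Section-relative speeds follow

```
v_h = r (−φ̇ cos α cos θ + θ̇ sin α)
v_v = r (−θ̇ cos α + φ̇ cos θ sin α)
AoA = arccos( v_h / √(v_h² + v_v²) )
```

and the study's dimensionless numbers are the mean wingtip speed `2ΦfR`,
`Re = 2ΦfR·c_m/ν` and `Sc = ν/D`. Pheromone molecules are weightless
tracers advected by the periodic flow `u(x, t)` (trilinear in space,
4-node Lagrange in time between snapshots); their history is obtained by
integrating `dx/dt = −u(x, t)` backward from 21 antenna stations at 21
release phases per wingbeat, 500 explicit-Euler steps per wingbeat over
40 wingbeats. See `docs/methods.md` for conventions, assumptions and
limitations.

## Worked example

```python
import numpy as np
import mothfan as mf
from mothfan.sampling import TraceConfig, backtrace, assemble_sampling_volume
from mothfan.stats import head_relative_coordinates, angular_extent

spec = mf.KinematicsSpec()                      # typical fanning parameters
track = mf.generate_landmarks(spec, noise_sd=0.0, seed=0)
kin = mf.reconstruct(track)
print(f"f = {kin.f:.1f} Hz, amplitude = {np.degrees(kin.amplitude):.1f} deg, "
      f"stroke plane = {np.degrees(kin.beta):.1f} deg, "
      f"tip speed = {kin.tip_speed():.2f} m/s, Sc = {mf.schmidt():.1f}")

field = mf.generate_induced_flow(kin, mf.AnalyticFlowSpec(kind="flapping_dipole",
                                                          frequency=kin.f))
antenna = mf.VirtualAntenna(track.landmark("antenna_base", "L").mean(axis=0),
                            track.landmark("antenna_tip", "L").mean(axis=0))
trajs = backtrace(field, antenna, TraceConfig(n_release_phases=7, n_cycles=20))
head = track.landmark("head_tip", "C").mean(axis=0)
vol = assemble_sampling_volume(trajs, head, heading=(1, 0, 0))
co = head_relative_coordinates(vol)
ten = co[co.cycles_to_arrival <= 10].distance_m.median() * 1e3
print(f"median source distance after <=10 wingbeats: {ten:.1f} mm")
print(f"90% horizontal extent (single wing): "
      f"{angular_extent(co.h_angle_deg, 0.9):.1f} deg")
```

prints

```
f = 48.9 Hz, amplitude = 98.0 deg, stroke plane = 99.4 deg, tip speed = 2.89 m/s, Sc = 6.0
median source distance after <=10 wingbeats: 30.5 mm
90% horizontal extent (single wing): 10.0 deg
```

The reconstruction returns the generator's parameters (noise-free input,
so the small residuals are method discretisation); sampled air reaches
the antenna from a few centimetres in front of the head within ten
wingbeats, and from a narrow horizontal cone — the sampling volume is
strongly anisotropic, which is what makes fanning useful for directional
odour search.

The same chain runs from the shell:

```sh
mothfan run-all --out out/            # full synthetic pipeline + report
mothfan validate out/landmarks.csv landmarks
```

`run-all` writes `landmarks.csv`, `kinematics.json`, `flow.nc`,
`probe.csv`, `volume.csv`, `stats.csv`, a markdown report with figures,
and a provenance record (config hash, versions, seed).

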