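"""Backward-in-time pheromone tracing and the olfactory sampling volume.

Pheromone molecules are modelled as infinitesimal, weightless tracers that
move with the local air velocity; molecular diffusion is neglected. Because
a molecule must *arrive* at the antenna, its history is obtained by
integrating the reversed flow: starting from each virtual-antenna station,
at each of a set of release phases spread evenly over the wingbeat cycle,
the path is stepped backward through the time-periodic flow field. The
union of backward path lines over all release phases approximates the
streak surface of arriving particles.

The sampling volume is the cloud of particle positions a whole number of
wingbeats before arrival, referenced to the head of the moth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, OutOfDomainError
from .flowfield import FlowField, VirtualAntenna

__all__ = [
    "TraceConfig",
    "ParticleTrajectory",
    "SamplingVolume",
    "backtrace",
    "backtrace_points",
    "forward_check",
    "assemble_sampling_volume",
]


@dataclass(frozen=True)
class TraceConfig:
    """Discretisation of the backward-tracing problem.

    Defaults follow the study conditions: 21 antenna stations, 21 release
    phases per cycle, 500 explicit-Euler steps per wingbeat, 40 wingbeat
    cycles of backward horizon. ``rk4`` is available for convergence
    checks.
    """

    n_stations: int = 21
    n_release_phases: int = 21
    steps_per_cycle: int = 500
    n_cycles: int = 40
    integrator: str = "euler"
    out_of_domain: str = "truncate"  # truncate | freeze

    def __post_init__(self):
        for name in ("n_stations", "n_release_phases", "steps_per_cycle", "n_cycles"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"TraceConfig: {name} must be >= 1")
        if self.integrator not in ("euler", "rk4"):
            raise ConfigurationError("TraceConfig: integrator must be 'euler' or 'rk4'")


@dataclass
class ParticleTrajectory:
    """Backward path of one tracer released at an antenna station.

    ``positions[0]`` is the antenna station; ``positions[k]`` the position
    k backward steps before arrival. ``cycle_origins[c]`` is the position
    c + 1 whole cycles before arrival (NaN beyond a truncation).
    """

    station: int
    phase_index: int
    t0: float
    positions: np.ndarray
    cycle_origins: np.ndarray
    dt: float
    period: float
    truncated: bool = False
    truncation_step: int | None = None

    @property
    def origin(self) -> np.ndarray:
        return self.positions[-1]

    @property
    def path_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.positions, axis=0), axis=1)))


def _stepper(integrator: str):
    if integrator == "euler":

        def step(fn, x, t, dt):
            return x + dt * fn(x, t)

    else:  # rk4

        def step(fn, x, t, dt):
            k1 = fn(x, t)
            k2 = fn(x + 0.5 * dt * k1, t + 0.5 * dt)
            k3 = fn(x + 0.5 * dt * k2, t + 0.5 * dt)
            k4 = fn(x + dt * k3, t + dt)
            return x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    return step


def backtrace_points(
    velocity_fn,
    points: np.ndarray,
    t0: float,
    cfg: TraceConfig,
    period: float,
    inside_fn=None,
):
    """Integrate dx/dt = -u(x, t) backward from ``points`` released at ``t0``.

    Core tracer shared by grid-backed and analytic fields. ``velocity_fn``
    maps ((n, 3) points, time) to (n, 3) velocities; ``inside_fn``
    (optional) flags points still inside the valid domain — a particle
    leaving it is frozen at its last inside position and marked truncated.

    Returns (positions, truncation_step): positions has shape
    (n_points, n_steps + 1, 3); truncation_step is -1 where untruncated.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    n = pts.shape[0]
    dt = period / cfg.steps_per_cycle
    n_steps = cfg.n_cycles * cfg.steps_per_cycle
    step = _stepper(cfg.integrator)
    out = np.empty((n, n_steps + 1, 3))
    out[:, 0] = pts
    trunc = np.full(n, -1, dtype=int)
    active = np.ones(n, dtype=bool)
    x = pts.copy()
    for k in range(n_steps):
        t = t0 - k * dt
        if np.any(active):
            xa = _backward_step(step, velocity_fn, x[active], t, dt)
            if inside_fn is not None:
                ok = inside_fn(xa)
                if not np.all(ok):
                    idx = np.flatnonzero(active)
                    newly_out = idx[~ok]
                    trunc[newly_out] = k + 1
                    active[newly_out] = False
                    xa = xa[ok] if np.any(ok) else xa[:0]
                    idx_ok = idx[ok]
                    x[idx_ok] = xa
                else:
                    x[active] = xa
            else:
                x[active] = xa
        out[:, k + 1] = x
    return out, trunc


def _backward_step(step, velocity_fn, x, t, dt):
    """One backward step: advance by -dt along the forward velocity."""
    return step(velocity_fn, x, t, -dt)


def backtrace(
    field: FlowField,
    antenna: VirtualAntenna,
    cfg: TraceConfig = TraceConfig(),
    t_ref: float = 0.0,
) -> list[ParticleTrajectory]:
    """Backward streak-line tracing from the virtual antenna.

    For each of ``cfg.n_stations`` antenna stations and
    ``cfg.n_release_phases`` arrival phases spread evenly over the cycle,
    the tracer path is integrated backward for ``cfg.n_cycles`` wingbeats.
    Fully deterministic: identical inputs give bit-identical trajectories.
    """
    ant = antenna
    if ant.n_stations != cfg.n_stations:
        ant = VirtualAntenna(antenna.base, antenna.tip, cfg.n_stations)
    stations = ant.stations
    if not np.all(field.contains(stations)):
        bad = int(np.argmin(field.contains(stations)))
        raise OutOfDomainError(
            f"antenna station {bad} lies outside the flow domain", point=stations[bad]
        )
    T = field.period
    fn = field.as_callable(policy="freeze")
    inside = field.contains
    trajs: list[ParticleTrajectory] = []
    dt = T / cfg.steps_per_cycle
    for p in range(cfg.n_release_phases):
        t0 = t_ref + p * T / cfg.n_release_phases
        paths, trunc = backtrace_points(fn, stations, t0, cfg, T, inside_fn=inside)
        for s in range(cfg.n_stations):
            truncated = trunc[s] >= 0
            pos = paths[s, : trunc[s] + 1] if truncated else paths[s]
            origins = np.full((cfg.n_cycles, 3), np.nan)
            for c in range(cfg.n_cycles):
                k = (c + 1) * cfg.steps_per_cycle
                if not truncated or k <= trunc[s]:
                    origins[c] = paths[s, k]
            trajs.append(
                ParticleTrajectory(
                    station=s,
                    phase_index=p,
                    t0=t0,
                    positions=pos,
                    cycle_origins=origins,
                    dt=dt,
                    period=T,
                    truncated=truncated,
                    truncation_step=int(trunc[s]) if truncated else None,
                )
            )
    return trajs


def forward_check(field_or_fn, traj: ParticleTrajectory, integrator: str = "euler") -> float:
    """Round-trip error of the tracer: re-advect the origin forward.

    The recorded origin is advected forward with the same scheme and
    horizon; the return value is the final distance (m) to the original
    antenna station. Exact (to round-off) in constant fields.
    """
    if traj.truncated:
        raise ConfigurationError("forward_check: trajectory was truncated")
    fn = field_or_fn.as_callable(policy="freeze") if isinstance(field_or_fn, FlowField) else field_or_fn
    step = _stepper(integrator)
    n_steps = traj.positions.shape[0] - 1
    x = traj.origin[None, :].copy()
    t = traj.t0 - n_steps * traj.dt
    for k in range(n_steps):
        x = step(fn, x, t, traj.dt)
        t += traj.dt
    return float(np.linalg.norm(x[0] - traj.positions[0]))


@dataclass
class SamplingVolume:
    """Cloud of particle origins tagged by whole-cycle arrival-time offset."""

    points: np.ndarray  # (n, 3)
    cycles: np.ndarray  # (n,) cycles-to-arrival, integers >= 1
    head: np.ndarray
    heading: np.ndarray
    mirrored: bool = False

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.cycles = np.asarray(self.cycles)
        self.head = np.asarray(self.head, dtype=float).reshape(3)
        h = np.asarray(self.heading, dtype=float).reshape(3)
        norm = np.linalg.norm(h)
        if norm == 0:
            raise ConfigurationError("SamplingVolume: heading must be non-zero")
        self.heading = h / norm
        if self.points.shape[0] != self.cycles.size:
            raise ConfigurationError("SamplingVolume: points/cycles length mismatch")

    def __len__(self) -> int:
        return self.points.shape[0]

    def mirror(self) -> "SamplingVolume":
        """Union with the sagittal mirror image (two-wing volume)."""
        m = self.points * np.array([1.0, -1.0, 1.0])
        return SamplingVolume(
            points=np.vstack([self.points, m]),
            cycles=np.concatenate([self.cycles, self.cycles]),
            head=self.head,
            heading=self.heading,
            mirrored=True,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycles_to_arrival": self.cycles,
                "x_m": self.points[:, 0],
                "y_m": self.points[:, 1],
                "z_m": self.points[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.attrs["head"] = self.head.tolist()
        df.to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, head, heading, mirrored=False) -> "SamplingVolume":
        return cls(
            points=df[["x_m", "y_m", "z_m"]].to_numpy(),
            cycles=df["cycles_to_arrival"].to_numpy(),
            head=head,
            heading=heading,
            mirrored=mirrored,
        )


def assemble_sampling_volume(
    trajs: list[ParticleTrajectory],
    head,
    heading,
    include_truncated: bool = False,
) -> SamplingVolume:
    """Collect per-cycle origin positions into a sampling volume.

    Each trajectory contributes its position after 1, 2, ... n_cycles
    whole wingbeats before arrival, tagged with that cycle count.
    Truncated trajectories are excluded by default.
    """
    if not trajs:
        raise InsufficientDataError("assemble_sampling_volume: no trajectories")
    pts = []
    cyc = []
    for tr in trajs:
        if tr.truncated and not include_truncated:
            continue
        for c in range(tr.cycle_origins.shape[0]):
            if np.all(np.isfinite(tr.cycle_origins[c])):
                pts.append(tr.cycle_origins[c])
                cyc.append(c + 1)
    if not pts:
        raise InsufficientDataError(
            "assemble_sampling_volume: every trajectory was truncated"
        )
    return SamplingVolume(
        points=np.asarray(pts), cycles=np.asarray(cyc, dtype=int), head=head, heading=heading
    )


def trajectories_to_dataframe(trajs: list[ParticleTrajectory]) -> pd.DataFrame:
    """Long-form table (station, phase, step, t_s, x_m, y_m, z_m, truncated)."""
    frames = []
    for tr in trajs:
        n = tr.positions.shape[0]
        frames.append(
            pd.DataFrame(
                {
                    "station": tr.station,
                    "phase": tr.phase_index,
                    "step": np.arange(n),
                    "t_s": tr.t0 - np.arange(n) * tr.dt,
                    "x_m": tr.positions[:, 0],
                    "y_m": tr.positions[:, 1],
                    "z_m": tr.positions[:, 2],
                    "truncated": tr.truncated,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
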