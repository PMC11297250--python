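"""Time-periodic gridded velocity fields and virtual-antenna probing.

A :class:`FlowField` holds one converged wingbeat cycle of velocity
snapshots on a structured Cartesian grid and is treated as periodic in
time. Evaluation at an arbitrary space-time point uses trilinear
interpolation in space on each of the four temporally nearest snapshots
(periodic wrap of the snapshot index) followed by third-order (4-node)
Lagrangian interpolation in time — exact for fields trilinear in space
and cubic in time.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, OutOfDomainError

__all__ = [
    "FlowField",
    "VirtualAntenna",
    "ProbeResult",
    "lagrange_weights",
    "probe_antenna",
]


def lagrange_weights(frac: float) -> np.ndarray:
    """Cubic Lagrange basis at nodes (-1, 0, 1, 2) evaluated at ``frac`` in [0, 1)."""
    x = float(frac)
    return np.array(
        [
            -x * (x - 1.0) * (x - 2.0) / 6.0,
            (x + 1.0) * (x - 1.0) * (x - 2.0) / 2.0,
            -(x + 1.0) * x * (x - 2.0) / 2.0,
            (x + 1.0) * x * (x - 1.0) / 6.0,
        ]
    )


def _trilinear(snap: np.ndarray, i0: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Trilinear interpolation on one snapshot.

    ``snap`` has shape (nz, ny, nx, 3); ``i0`` integer cell indices (n, 3)
    ordered (ix, iy, iz); ``f`` fractional offsets (n, 3) in [0, 1].
    """
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0:1], f[:, 1:2], f[:, 2:3]
    c000 = snap[iz, iy, ix]
    c100 = snap[iz, iy, ix + 1]
    c010 = snap[iz, iy + 1, ix]
    c110 = snap[iz, iy + 1, ix + 1]
    c001 = snap[iz + 1, iy, ix]
    c101 = snap[iz + 1, iy, ix + 1]
    c011 = snap[iz + 1, iy + 1, ix]
    c111 = snap[iz + 1, iy + 1, ix + 1]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@dataclass
class FlowField:
    """One periodic wingbeat cycle of gridded velocity snapshots.

    ``u`` has shape (S, nz, ny, nx, 3) with components ordered (u, v, w);
    snapshot s holds the field at time ``s * period / S``. ``origin`` is
    the (x, y, z) position of grid node (0, 0, 0) and ``spacing`` the
    (dx, dy, dz) grid step.
    """

    u: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    period: float
    periodic: bool = True
    out_of_domain: str = "error"  # default policy: "error" | "freeze"
    n_frozen: int = field(default=0, init=False, repr=False)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        if self.u.ndim != 5 or self.u.shape[-1] != 3:
            raise ConfigurationError("FlowField: u must have shape (S, nz, ny, nx, 3)")
        if self.u.shape[0] < 4:
            raise ConfigurationError(
                "FlowField: need >= 4 snapshots for third-order temporal interpolation"
            )
        if self.period <= 0 or np.any(self.spacing <= 0):
            raise ConfigurationError("FlowField: period and spacing must be positive")

    # -- geometry ----------------------------------------------------------
    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        S, nz, ny, nx, _ = self.u.shape
        return nx, ny, nz

    @property
    def box(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny, nz = self.shape_xyz
        hi = self.origin + self.spacing * (np.array([nx, ny, nz]) - 1)
        return self.origin.copy(), hi

    @property
    def times(self) -> np.ndarray:
        S = self.u.shape[0]
        return np.arange(S) * self.period / S

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        lo, hi = self.box
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_callable(cls, fn, origin, spacing, shape_xyz, period, snapshots, **kw) -> "FlowField":
        """Sample an analytic velocity callable ``fn(points, t)`` onto a grid."""
        origin = np.asarray(origin, dtype=float)
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        nx, ny, nz = shape_xyz
        x = origin[0] + spacing[0] * np.arange(nx)
        y = origin[1] + spacing[1] * np.arange(ny)
        z = origin[2] + spacing[2] * np.arange(nz)
        Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        data = np.empty((snapshots, nz, ny, nx, 3))
        for s in range(snapshots):
            t = s * period / snapshots
            data[s] = np.asarray(fn(nodes, t), dtype=float).reshape(nz, ny, nx, 3)
        return cls(u=data, origin=origin, spacing=spacing.copy(), period=period, **kw)

    # -- evaluation --------------------------------------------------------
    def velocity_at(self, points, t: float, policy: str | None = None) -> np.ndarray:
        """Velocity at ``points`` (one point or (n, 3)) and time ``t``.

        Out-of-domain handling follows ``policy`` (default the field's own):
        ``"error"`` raises :class:`OutOfDomainError` carrying the first
        offending point; ``"freeze"`` clamps to the nearest boundary value
        and counts the event.
        """
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        policy = policy or self.out_of_domain

        S = self.u.shape[0]
        s = (t / self.period) % 1.0 * S if self.periodic else np.clip(t / self.period, 0, 1) * S
        j = int(np.floor(s))
        frac = s - j
        w = lagrange_weights(frac)
        idx = [(j - 1 + m) % S for m in range(4)]

        g = (pts - self.origin) / self.spacing
        nx, ny, nz = self.shape_xyz
        nvec = np.array([nx, ny, nz], dtype=float) - 1.0
        eps = 1e-9
        outside = np.any((g < -eps) | (g > nvec + eps), axis=1)
        if np.any(outside):
            if policy == "error":
                bad = pts[np.argmax(outside)]
                raise OutOfDomainError(
                    f"point {bad.tolist()} outside grid box", point=bad
                )
            self.n_frozen += int(np.sum(outside))
        g = np.clip(g, 0.0, nvec)
        i0 = np.minimum(np.floor(g).astype(int), (nvec - 1).astype(int))
        i0 = np.maximum(i0, 0)
        f = g - i0
        val = np.zeros((pts.shape[0], 3))
        for m in range(4):
            val += w[m] * _trilinear(self.u[idx[m]], i0, f)
        return val[0] if single else val

    def as_callable(self, policy: str | None = None):
        """A ``fn(points, t)`` view of the field, for the tracer."""

        def fn(points, t):
            return self.velocity_at(points, t, policy=policy)

        return fn

    # -- I/O ---------------------------------------------------------------
    def to_netcdf(self, path) -> None:
        import xarray as xr

        S, nz, ny, nx, _ = self.u.shape
        ds = xr.Dataset(
            {
                "u": (("time", "z", "y", "x"), self.u[..., 0]),
                "v": (("time", "z", "y", "x"), self.u[..., 1]),
                "w": (("time", "z", "y", "x"), self.u[..., 2]),
            },
            coords={
                "time": self.times,
                "x": self.origin[0] + self.spacing[0] * np.arange(nx),
                "y": self.origin[1] + self.spacing[1] * np.arange(ny),
                "z": self.origin[2] + self.spacing[2] * np.arange(nz),
            },
            attrs={
                "period_s": self.period,
                "origin_m": self.origin.tolist(),
                "spacing_m": self.spacing.tolist(),
            },
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "FlowField":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            u = np.stack([ds["u"].values, ds["v"].values, ds["w"].values], axis=-1)
            return cls(
                u=u,
                origin=np.asarray(ds.attrs["origin_m"]),
                spacing=np.asarray(ds.attrs["spacing_m"]),
                period=float(ds.attrs["period_s"]),
            )

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            u=self.u,
            origin=self.origin,
            spacing=self.spacing,
            period=np.array(self.period),
        )

    @classmethod
    def from_npz(cls, path) -> "FlowField":
        with np.load(path) as z:
            return cls(
                u=z["u"], origin=z["origin"], spacing=z["spacing"], period=float(z["period"])
            )


@dataclass(frozen=True)
class VirtualAntenna:
    """Line of probe points from the antenna base to its tip."""

    base: np.ndarray
    tip: np.ndarray
    n_stations: int = 21

    def __post_init__(self):
        object.__setattr__(self, "base", np.asarray(self.base, dtype=float).reshape(3))
        object.__setattr__(self, "tip", np.asarray(self.tip, dtype=float).reshape(3))
        if self.n_stations < 2:
            raise ConfigurationError("VirtualAntenna: need >= 2 stations")
        if np.allclose(self.base, self.tip):
            raise ConfigurationError("VirtualAntenna: base and tip coincide")

    @property
    def stations(self) -> np.ndarray:
        frac = np.linspace(0.0, 1.0, self.n_stations)[:, None]
        return self.base + frac * (self.tip - self.base)


@dataclass
class ProbeResult:
    """Per-station induced-flow time series over one wingbeat cycle."""

    t_hat: np.ndarray
    vectors: np.ndarray  # (n_t, n_stations, 3)
    speeds: np.ndarray  # (n_t, n_stations)
    means: np.ndarray
    amplitudes: np.ndarray  # half peak-to-peak of the phase-averaged cycle
    dominant: list  # "f" | "2f" | "none" | "other" per station

    def to_dataframe(self) -> pd.DataFrame:
        n_t, n_st = self.speeds.shape
        rows = {
            "station": np.repeat(np.arange(n_st), n_t),
            "t_hat": np.tile(self.t_hat, n_st),
            "speed_m_s": self.speeds.T.ravel(),
            "u": self.vectors[..., 0].T.ravel(),
            "v": self.vectors[..., 1].T.ravel(),
            "w": self.vectors[..., 2].T.ravel(),
        }
        return pd.DataFrame(rows)


def probe_antenna(
    field: FlowField,
    antenna: VirtualAntenna,
    samples_per_cycle: int = 200,
    policy: str = "freeze",
    rel_tol: float = 1e-9,
) -> ProbeResult:
    """Sample the induced flow along the virtual antenna over one cycle.

    Returns per-station speed and vector series, the cycle mean, the
    amplitude (half peak-to-peak of the phase-averaged series) and a
    spectral diagnostic reporting whether the dominant oscillation is at
    the wingbeat frequency (``"f"``), its double (``"2f"``), neither, or
    absent for steady flow (``"none"``).
    """
    pts = antenna.stations
    inside = field.contains(pts)
    if policy == "error" and not np.all(inside):
        bad = int(np.argmin(inside))
        raise OutOfDomainError(f"antenna station {bad} outside flow domain", point=pts[bad])
    t_hat = np.arange(samples_per_cycle) / samples_per_cycle
    vectors = np.empty((samples_per_cycle, pts.shape[0], 3))
    for k, th in enumerate(t_hat):
        vectors[k] = field.velocity_at(pts, th * field.period, policy=policy)
    speeds = np.linalg.norm(vectors, axis=2)
    means = speeds.mean(axis=0)
    # oscillation is characterised on the signed projection onto the principal
    # oscillation direction, so a reversing sinusoid u = A sin(2 pi t/T) has
    # amplitude A at frequency f while a pulsating non-reversing jet shows 2f
    amplitudes = np.empty(pts.shape[0])
    dominant = []
    for j in range(pts.shape[0]):
        centred = vectors[:, j, :] - vectors[:, j, :].mean(axis=0)
        scale = max(means[j], speeds[:, j].max(), 1e-300)
        if np.max(np.abs(centred)) <= rel_tol * scale:
            amplitudes[j] = 0.0
            dominant.append("none")
            continue
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        signed = centred @ vt[0]
        amplitudes[j] = 0.5 * (signed.max() - signed.min())
        spec = np.abs(np.fft.rfft(signed))
        k = int(np.argmax(spec[1:]) + 1)
        dominant.append({1: "f", 2: "2f"}.get(k, "other"))
    return ProbeResult(
        t_hat=t_hat,
        vectors=vectors,
        speeds=speeds,
        means=means,
        amplitudes=amplitudes,
        dominant=dominant,
    )
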