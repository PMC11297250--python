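"""Synthetic landmark tracks and analytic flow fields.

This module replaces the two experimental inputs of the pipeline — manually
tracked high-speed video landmarks and simulated flow snapshots — with
parametric stand-ins of known ground truth, so every downstream stage can
be exercised and checked without recordings.

The default kinematic parameters are typical of a fanning *Bombyx mori*
male: wing length 17.3 mm, wingbeat frequency 48.9 Hz, amplitude 98 deg,
stroke-plane angle 99.5 deg (slightly past vertical), body angle -0.6 deg
and mean elevation angle -23.8 deg.

The induced-flow stand-in is a pulsed momentum jet: air is expelled along
the posterior stroke-plane normal with instantaneous strength proportional
to the wingtip speed, plus a component along the stroke direction that
reverses between half-strokes. It reproduces the qualitative structure of
the fanning flow (intake from anterior of the head, oscillation at twice
the wingbeat frequency, linear scaling with wingtip speed 2*amplitude*f*R)
but is not a substitute for a Navier-Stokes solution.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigurationError, ProjectionError
from .flowfield import FlowField
from .geometry import stroke_plane_basis, wing_surface_points, wing_tip_direction
from .kinematics import WingKinematics, WingMorphology

LANDMARK_COLUMNS = ["time_s", "side", "landmark", "x_m", "y_m", "z_m"]


# ---------------------------------------------------------------------------
# kinematics specification


@dataclass(frozen=True)
class FeatheringProfile:
    """Two-harmonic spanwise feathering model alpha(s, t_hat).

    alpha = mean + amp1*cos(2 pi t_hat + phase1) + amp2*cos(4 pi t_hat + phase2),
    with all coefficients defined per spanwise station. Amplitudes growing
    toward the tip mimic the spanwise twist of a real wing, and the second
    harmonic breaks downstroke/upstroke symmetry.
    """

    stations: np.ndarray = field(default_factory=lambda: np.array([0.2, 0.4, 0.6, 0.8, 1.0]))
    mean: np.ndarray | float = np.pi / 2
    amp1: np.ndarray | float | None = None
    phase1: np.ndarray | float = -np.pi / 2
    amp2: np.ndarray | float | None = None
    phase2: np.ndarray | float = 0.0

    def coefficients(self):
        s = np.asarray(self.stations, dtype=float)
        mean = np.broadcast_to(np.asarray(self.mean, dtype=float), s.shape)
        amp1 = np.radians(25.0) * s if self.amp1 is None else np.broadcast_to(np.asarray(self.amp1, float), s.shape)
        amp2 = np.radians(10.0) * s if self.amp2 is None else np.broadcast_to(np.asarray(self.amp2, float), s.shape)
        p1 = np.broadcast_to(np.asarray(self.phase1, float), s.shape)
        p2 = np.broadcast_to(np.asarray(self.phase2, float), s.shape)
        return s, mean, amp1, p1, amp2, p2

    def evaluate(self, t_hat) -> np.ndarray:
        """alpha at span stations for normalised cycle times; shape (n_t, n_stations)."""
        th = np.atleast_1d(np.asarray(t_hat, dtype=float))[:, None]
        _, mean, amp1, p1, amp2, p2 = self.coefficients()
        return mean + amp1 * np.cos(2 * np.pi * th + p1) + amp2 * np.cos(4 * np.pi * th + p2)


class KinematicsSpec(BaseModel):
    """Prescribed harmonic wing kinematics (SI units, radians).

    ``phi = phi0 + amplitude/2 * cos(2 pi f t)`` so that the downstroke
    (decreasing positional angle) starts at t_hat = 0, and
    ``theta = theta0 + elevation_amplitude * cos(2 pi f t + elevation_phase)``.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    wing_length: float = 17.3e-3
    frequency: float = 48.9
    amplitude: float = np.radians(98.0)
    stroke_plane_angle: float = np.radians(99.5)
    body_angle: float = np.radians(-0.6)
    mean_elevation: float = np.radians(-23.8)
    elevation_amplitude: float = np.radians(3.0)
    mean_positional: float = np.radians(30.0)
    elevation_phase: float = np.radians(90.0)
    feathering: FeatheringProfile = FeatheringProfile()
    n_cycles: int = 8
    frame_rate: float = 2000.0

    @model_validator(mode="after")
    def _check(self):
        if self.wing_length <= 0:
            raise ConfigurationError("KinematicsSpec: wing_length must be positive")
        if self.frequency <= 0:
            raise ConfigurationError("KinematicsSpec: frequency must be positive")
        if not (0.0 < self.amplitude < np.pi):
            raise ConfigurationError("KinematicsSpec: amplitude must lie in (0, pi)")
        if self.frame_rate < 20.0 * self.frequency:
            raise ConfigurationError(
                "KinematicsSpec: frame_rate must be >= 20 * frequency to resolve each cycle"
            )
        if self.n_cycles < 1:
            raise ConfigurationError("KinematicsSpec: n_cycles must be >= 1")
        return self

    @classmethod
    def from_degrees(cls, **kw) -> "KinematicsSpec":
        conv = {
            "amplitude_deg": "amplitude",
            "stroke_plane_angle_deg": "stroke_plane_angle",
            "body_angle_deg": "body_angle",
            "mean_elevation_deg": "mean_elevation",
            "elevation_amplitude_deg": "elevation_amplitude",
            "mean_positional_deg": "mean_positional",
            "elevation_phase_deg": "elevation_phase",
        }
        out = {}
        for k, v in kw.items():
            if k in conv:
                out[conv[k]] = np.radians(v)
            else:
                out[k] = v
        return cls(**out)

    def times(self) -> np.ndarray:
        n = int(round(self.n_cycles * self.frame_rate / self.frequency)) + 1
        return np.arange(n) / self.frame_rate

    def angles(self, t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Ground-truth (phi, theta, alpha) series at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        th = (t * self.frequency) % 1.0
        phi = self.mean_positional + 0.5 * self.amplitude * np.cos(2 * np.pi * th)
        theta = self.mean_elevation + self.elevation_amplitude * np.cos(
            2 * np.pi * th + self.elevation_phase
        )
        alpha = self.feathering.evaluate(th)
        return phi, theta, alpha

    def tip_speed_scale(self) -> float:
        return 2.0 * self.amplitude * self.frequency * self.wing_length


@dataclass(frozen=True)
class BodyGeometry:
    """Static body pose of the fanning moth (it stands still on the floor)."""

    body_length: float = 20e-3
    body_height: float = 10e-3  # body-centre height above the floor
    wing_root_axial: float = 0.25  # fraction of body length anterior of centre
    wing_root_lateral: float = 2e-3
    wing_root_dorsal: float = 3e-3
    antenna_length: float = 6e-3
    antenna_elevation: float = np.radians(50.0)
    antenna_lateral: float = 2e-3

    def landmarks(self, body_angle: float) -> dict:
        c, s = np.cos(body_angle), np.sin(body_angle)
        axis = np.array([c, 0.0, s])
        up = np.array([-s, 0.0, c])
        centre = np.array([0.0, 0.0, self.body_height])
        head = centre + 0.5 * self.body_length * axis
        abdomen = centre - 0.5 * self.body_length * axis
        roots = {}
        bases = {}
        tips = {}
        for side, sgn in (("L", 1.0), ("R", -1.0)):
            roots[side] = (
                centre
                + self.wing_root_axial * self.body_length * axis
                + self.wing_root_dorsal * up
                + np.array([0.0, sgn * self.wing_root_lateral, 0.0])
            )
            base = head + np.array([0.0, sgn * self.antenna_lateral, 1e-3])
            ce, se = np.cos(self.antenna_elevation), np.sin(self.antenna_elevation)
            tips[side] = base + self.antenna_length * np.array([ce, 0.3 * sgn, se]) / np.linalg.norm(
                [ce, 0.3 * sgn, se]
            )
            bases[side] = base
        return {
            "head_tip": head,
            "abdomen_tip": abdomen,
            "wing_root": roots,
            "antenna_base": bases,
            "antenna_tip": tips,
        }


# ---------------------------------------------------------------------------
# landmark track


@dataclass
class LandmarkTrack:
    """Timestamped 3D positions of named body and wing landmarks.

    ``frames`` is a long-form table with columns time_s, side (L|R|C),
    landmark, x_m, y_m, z_m — one row per landmark per frame. ``truth``
    optionally carries the generating spec and exact angle series for
    parameter-recovery tests.
    """

    frames: pd.DataFrame
    truth: dict | None = None

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LandmarkTrack":
        df = pd.read_csv(path)
        missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"landmark CSV missing column(s): {missing}")
        return cls(frames=df)

    def landmark(self, name: str, side: str = "C") -> np.ndarray:
        sub = self.frames[(self.frames["landmark"] == name) & (self.frames["side"] == side)]
        return sub.sort_values("time_s")[["x_m", "y_m", "z_m"]].to_numpy()


def generate_landmarks(
    spec: KinematicsSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    body: BodyGeometry | None = None,
    morphology: WingMorphology | None = None,
) -> LandmarkTrack:
    """Generate a landmark track from prescribed harmonic kinematics.

    With ``noise_sd = 0`` the track is exactly consistent with the
    prescribed angles; otherwise isotropic Gaussian noise of standard
    deviation ``noise_sd`` (m) is added to every coordinate, reproducibly
    for a fixed ``seed``.
    """
    if noise_sd < 0:
        raise ConfigurationError("generate_landmarks: noise_sd must be >= 0")
    body = body if body is not None else BodyGeometry()
    morph = morphology if morphology is not None else WingMorphology(R=spec.wing_length)
    t = spec.times()
    phi, theta, alpha = spec.angles(t)
    marks = body.landmarks(spec.body_angle)
    s_pts, c_pts = morph.contour_offsets()
    a_pts = np.apply_along_axis(
        lambda row: np.interp(s_pts, spec.feathering.stations, row), 1, alpha
    )

    rows = []
    for side in ("L", "R"):
        pivot = marks["wing_root"][side]
        tips = pivot + spec.wing_length * wing_tip_direction(
            phi, theta, spec.stroke_plane_angle, side=side
        )
        contours = wing_surface_points(
            pivot, spec.wing_length, phi, theta, spec.stroke_plane_angle,
            s_pts, c_pts, a_pts, side=side,
        )
        for k, tk in enumerate(t):
            rows.append((tk, "C", "head_tip", *marks["head_tip"]))
            rows.append((tk, "C", "abdomen_tip", *marks["abdomen_tip"]))
        for k, tk in enumerate(t):
            rows.append((tk, side, "antenna_base", *marks["antenna_base"][side]))
            rows.append((tk, side, "antenna_tip", *marks["antenna_tip"][side]))
            rows.append((tk, side, "wing_root", *pivot))
            rows.append((tk, side, "wing_tip", *tips[k]))
            for j in range(s_pts.size):
                rows.append((tk, side, f"contour_{j}", *contours[k, j]))
    df = pd.DataFrame(rows, columns=LANDMARK_COLUMNS)
    # head/abdomen rows are duplicated once per side loop; drop the copies
    df = df.drop_duplicates(subset=["time_s", "side", "landmark"], ignore_index=True)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        df[["x_m", "y_m", "z_m"]] += rng.normal(0.0, noise_sd, size=(len(df), 3))
    truth = {
        "spec": spec,
        "body": body,
        "time_s": t,
        "phi": phi,
        "theta": theta,
        "alpha": alpha,
        "stroke_plane_angle": spec.stroke_plane_angle,
        "body_angle": spec.body_angle,
        "pivots": marks["wing_root"],
    }
    return LandmarkTrack(frames=df, truth=truth)


# ---------------------------------------------------------------------------
# cameras


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: image = K (R X + t), points required in front (z > 0)."""

    K: np.ndarray
    R: np.ndarray
    t: np.ndarray
    image_size: tuple[int, int] = (1024, 1024)

    def __post_init__(self):
        object.__setattr__(self, "K", np.asarray(self.K, dtype=float).reshape(3, 3))
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float).reshape(3, 3))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))
        if abs(np.linalg.det(self.K)) < 1e-12:
            raise ConfigurationError("CameraModel: intrinsic matrix must be invertible")

    @classmethod
    def looking_at(
        cls,
        position,
        target,
        focal_px: float = 4000.0,
        image_size: tuple[int, int] = (1024, 1024),
        up=(0.0, 0.0, 1.0),
    ) -> "CameraModel":
        position = np.asarray(position, dtype=float)
        z = np.asarray(target, dtype=float) - position
        z = z / np.linalg.norm(z)
        up = np.asarray(up, dtype=float)
        x = np.cross(z, up)
        if np.linalg.norm(x) < 1e-9:
            x = np.cross(z, [0.0, 1.0, 0.0])
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        R = np.stack([x, y, z])
        t = -R @ position
        K = np.array(
            [
                [focal_px, 0.0, image_size[0] / 2.0],
                [0.0, focal_px, image_size[1] / 2.0],
                [0.0, 0.0, 1.0],
            ]
        )
        return cls(K=K, R=R, t=t, image_size=image_size)

    @property
    def P(self) -> np.ndarray:
        return self.K @ np.column_stack([self.R, self.t])

    def project(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        flat = pts.reshape(-1, 3)
        cam = flat @ self.R.T + self.t
        behind = cam[:, 2] <= 0
        if np.any(behind):
            k = int(np.argmax(behind))
            raise ProjectionError(f"point index {k} at {flat[k].tolist()} is behind the camera")
        uv = (cam @ self.K.T)
        uv = uv[:, :2] / uv[:, 2:3]
        out = uv.reshape(pts.shape[:-1] + (2,))
        return out[0] if single else out


def triangulate(obs_2d, cameras) -> np.ndarray:
    """Linear (DLT) triangulation of per-camera image points.

    ``obs_2d`` has shape (n_cameras, n_points, 2). Returns (n_points, 3).
    """
    obs = np.asarray(obs_2d, dtype=float)
    if len(cameras) < 2:
        raise ConfigurationError("triangulate: need >= 2 cameras")
    Ps = [cam.P for cam in cameras]
    n = obs.shape[1]
    out = np.empty((n, 3))
    for i in range(n):
        rows = []
        for c, P in enumerate(Ps):
            u, v = obs[c, i]
            rows.append(u * P[2] - P[0])
            rows.append(v * P[2] - P[1])
        A = np.stack(rows)
        _, _, vt = np.linalg.svd(A)
        X = vt[-1]
        out[i] = X[:3] / X[3]
    return out


def project_landmarks(track: LandmarkTrack, cameras) -> list[pd.DataFrame]:
    """Pinhole-project every landmark row through every camera.

    Returns one DataFrame per camera with the same row order as
    ``track.frames`` and columns time_s, side, landmark, u_px, v_px.
    Triangulating the outputs with the same cameras returns the 3D input
    to numerical precision.
    """
    if len(cameras) < 2:
        raise ConfigurationError("project_landmarks: need >= 2 cameras for triangulation")
    pts = track.frames[["x_m", "y_m", "z_m"]].to_numpy()
    out = []
    for cam in cameras:
        try:
            uv = cam.project(pts)
        except ProjectionError as err:
            k = int(str(err).split("index ")[1].split(" ")[0])
            row = track.frames.iloc[k]
            raise ProjectionError(
                f"landmark {row['landmark']!r} (side {row['side']}) at t={row['time_s']} "
                "is behind a camera"
            ) from err
        df = track.frames[["time_s", "side", "landmark"]].copy()
        df["u_px"] = uv[:, 0]
        df["v_px"] = uv[:, 1]
        out.append(df)
    return out


# ---------------------------------------------------------------------------
# analytic flow fields


FlowKind = Literal["uniform", "point_sink", "rankine_vortex", "pulsed_jet", "flapping_dipole"]


class AnalyticFlowSpec(BaseModel):
    """Analytic velocity field sampled onto a periodic snapshot stack.

    Kinds: ``uniform`` (constant vector), ``point_sink`` (radial inflow of
    volumetric strength Q, speed Q/(4 pi d^2) at radius d),
    ``rankine_vortex`` (solid-body core of radius ``core_radius``,
    irrotational exterior), ``pulsed_jet`` (sinusoidally pulsed Gaussian
    jet) and ``flapping_dipole`` (wingbeat-driven jet; built from a
    :class:`WingKinematics` via :func:`generate_induced_flow`).
    """

    model_config = ConfigDict(frozen=True)

    kind: FlowKind = "uniform"
    speed: tuple[float, float, float] = (0.0, 0.0, 0.0)
    strength: float = 1e-6  # m^3/s, point sink
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    circulation: float = 1e-3  # m^2/s, vortex
    core_radius: float = 5e-3
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    jet_amplitude: float = 0.3  # m/s
    jet_direction: tuple[float, float, float] = (-1.0, 0.0, 0.0)
    width_radial: float = 17.3e-3
    width_axial: float = 35e-3
    frequency: float = 48.9
    phase: float = 0.0
    efficiency: float = 0.13  # entrainment efficiency of the flapping jet
    efficiency_osc: float = 0.13
    domain_lo: tuple[float, float, float] = (-0.10, -0.10, 0.0)
    domain_hi: tuple[float, float, float] = (0.20, 0.10, 0.15)
    spacing: float = 5e-3
    snapshots_per_cycle: int = 50

    @model_validator(mode="after")
    def _check(self):
        if self.spacing <= 0:
            raise ConfigurationError("AnalyticFlowSpec: spacing must be positive")
        if self.snapshots_per_cycle < 4:
            raise ConfigurationError("AnalyticFlowSpec: snapshots_per_cycle must be >= 4")
        if not all(h > l for l, h in zip(self.domain_lo, self.domain_hi)):
            raise ConfigurationError("AnalyticFlowSpec: domain_hi must exceed domain_lo")
        if self.frequency <= 0:
            raise ConfigurationError("AnalyticFlowSpec: frequency must be positive")
        return self

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def grid(self) -> tuple[np.ndarray, float, tuple[int, int, int]]:
        lo = np.asarray(self.domain_lo)
        hi = np.asarray(self.domain_hi)
        shape = tuple(int(np.floor((hi[i] - lo[i]) / self.spacing)) + 1 for i in range(3))
        return lo, self.spacing, shape


def analytic_velocity(spec: AnalyticFlowSpec, points, t: float) -> np.ndarray:
    """Closed-form velocity of an analytic kind; supports complex points.

    Complex coordinates propagate through every kind, enabling
    complex-step differentiation (used by :func:`divergence`).
    """
    pts = np.atleast_2d(np.asarray(points))
    out = np.zeros(pts.shape, dtype=pts.dtype if np.iscomplexobj(pts) else float)
    c = np.asarray(spec.center)
    if spec.kind == "uniform":
        out[:] = np.asarray(spec.speed)
    elif spec.kind == "point_sink":
        rel = pts - c
        r2 = np.sum(rel * rel, axis=1)
        r3 = r2 ** 1.5
        safe = np.abs(r3) > 1e-30
        out[safe] = -spec.strength / (4.0 * np.pi) * rel[safe] / r3[safe, None]
    elif spec.kind == "rankine_vortex":
        a_hat = np.asarray(spec.axis, dtype=float)
        a_hat = a_hat / np.linalg.norm(a_hat)
        rel = pts - c
        xi = rel @ a_hat
        rho_vec = rel - xi[:, None] * a_hat
        rho2 = np.sum(rho_vec * rho_vec, axis=1)
        tang = np.cross(np.broadcast_to(a_hat, rel.shape), rho_vec)
        om_in = spec.circulation / (2.0 * np.pi * spec.core_radius**2)
        inside = np.real(rho2) < spec.core_radius**2
        out[inside] = om_in * tang[inside]
        outside = ~inside & (np.abs(rho2) > 1e-30)
        out[outside] = spec.circulation / (2.0 * np.pi) * tang[outside] / rho2[outside, None]
    elif spec.kind == "pulsed_jet":
        out[:] = _gaussian_jet(pts, c, spec.jet_direction, spec.width_radial, spec.width_axial) * (
            spec.jet_amplitude * np.sin(2 * np.pi * t / spec.period + spec.phase)
        )
    else:
        raise ConfigurationError(
            f"analytic_velocity: kind {spec.kind!r} requires wing kinematics; "
            "use generate_induced_flow"
        )
    return out


def _gaussian_jet(pts, center, direction, w_r, w_a):
    """Gaussian-envelope unit jet profile times its direction; complex-safe."""
    j = np.asarray(direction, dtype=float)
    j = j / np.linalg.norm(j)
    rel = pts - np.asarray(center)
    xi = rel @ j
    rho_vec = rel - xi[:, None] * j
    rho2 = np.sum(rho_vec * rho_vec, axis=1)
    g = np.exp(-rho2 / (2.0 * w_r**2) - xi**2 / (2.0 * w_a**2))
    return g[:, None] * j


def velocity_callable(spec: AnalyticFlowSpec):
    def fn(points, t):
        return analytic_velocity(spec, points, t)

    return fn


def divergence(fn, points, t: float, h: float = 1e-20) -> np.ndarray:
    """Velocity divergence by complex-step differentiation (machine precision)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    div = np.zeros(pts.shape[0])
    for i in range(3):
        p = pts.astype(complex)
        p[:, i] += 1j * h
        div += np.imag(np.atleast_2d(fn(p, t))[:, i]) / h
    return div


def generate_flow(spec: AnalyticFlowSpec) -> FlowField:
    """Sample an analytic kind onto a periodic snapshot stack.

    Steady kinds (uniform, point_sink, rankine_vortex) produce identical
    snapshots; pulsed kinds are exactly periodic over one cycle.
    """
    lo, h, shape = spec.grid()
    fn = velocity_callable(spec)
    return FlowField.from_callable(
        fn, origin=lo, spacing=h, shape_xyz=shape, period=spec.period,
        snapshots=spec.snapshots_per_cycle,
    )


def induced_flow_callable(
    kin: WingKinematics,
    efficiency: float = 0.13,
    efficiency_osc: float = 0.13,
    width_radial: float | None = None,
    width_axial: float | None = None,
):
    """Analytic flapping-induced jet driven by reconstructed kinematics.

    The jet axis passes through the mirror-averaged mid-stroke 70 %-span
    point along the posterior stroke-plane normal. Its instantaneous
    strength is ``efficiency * R * |phi_dot(t)|`` (cycle mean
    ``efficiency * 2 * amplitude * f * R``), with an additional
    stroke-direction component ``-efficiency_osc * R * phi_dot(t)`` that
    reverses between downstroke and upstroke.
    """
    kin.assert_periodic()
    e1, _, a_hat = stroke_plane_basis(kin.beta)
    exhaust = -a_hat  # posterior stroke-plane normal
    phi_mid = 0.5 * (np.max(kin.phi) + np.min(kin.phi))
    theta_mean = float(np.mean(kin.theta))
    p_left = kin.pivot + 0.7 * kin.R * wing_tip_direction(phi_mid, theta_mean, kin.beta, "L")
    center = p_left * np.array([1.0, 0.0, 1.0])  # mirror-average of the two wings
    w_r = width_radial if width_radial is not None else kin.R
    w_a = width_axial if width_axial is not None else 2.0 * kin.R
    phidot = kin.phi_dot()
    t_hat_ext = np.concatenate([kin.t_hat, [1.0]])
    phidot_ext = np.concatenate([phidot, [phidot[0]]])

    def fn(points, t):
        pts = np.atleast_2d(points)
        th = (t * kin.f) % 1.0
        pd_t = float(np.interp(th, t_hat_ext, phidot_ext))
        profile = _gaussian_jet(pts, center, exhaust, w_r, w_a)  # envelope * exhaust
        env = (profile @ exhaust)[:, None]  # scalar Gaussian envelope
        return (
            efficiency * kin.R * abs(pd_t) * profile
            - efficiency_osc * kin.R * pd_t * env * e1
        )

    return fn


def generate_induced_flow(kin: WingKinematics, spec: AnalyticFlowSpec) -> FlowField:
    """Sample the flapping-induced jet onto the grid described by ``spec``."""
    fn = induced_flow_callable(
        kin,
        efficiency=spec.efficiency,
        efficiency_osc=spec.efficiency_osc,
        width_radial=spec.width_radial,
        width_axial=spec.width_axial,
    )
    lo, h, shape = spec.grid()
    return FlowField.from_callable(
        fn, origin=lo, spacing=h, shape_xyz=shape, period=kin.period,
        snapshots=spec.snapshots_per_cycle,
    )
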