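"""Reconstruction of flapping-wing kinematics from 3D landmark tracks.

The moth fans while standing still, so the body frame and lab frame differ
only by the conventions fixed in :mod:`mothfan.geometry`. Wing motion is
described by three angles relative to the stroke plane:

* positional angle ``phi`` — wingtip angle from the horizontal, measured
  within the stroke plane;
* elevation angle ``theta`` — wingtip deviation out of the stroke plane
  (positive anterior);
* feathering angle ``alpha(r)`` — rotation of the wing cross-section about
  the spanwise axis, per spanwise station ``r``.

From the angle rates the section-relative velocity components are

    v_h = r (-phi_dot cos(alpha) cos(theta) + theta_dot sin(alpha))
    v_v = r (-theta_dot cos(alpha) + phi_dot cos(theta) sin(alpha))

and the angle of attack is ``arccos(v_h / sqrt(v_h^2 + v_v^2))``.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, least_squares
from scipy.signal import butter, filtfilt, find_peaks

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    InsufficientDataError,
)
from .geometry import stroke_plane_basis, wing_section_frame, wing_surface_points

log = logging.getLogger(__name__)

DEFAULT_STATIONS = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
N_GRID = 200  # samples on the normalised stroke-cycle grid t_hat in [0, 1)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FluidConstants:
    """Air and odorant constants (20 degC, 101.3 kPa).

    ``nu`` is the kinematic viscosity of air and ``D`` the molecular
    diffusion coefficient of bombykol in air, both in m^2/s.
    """

    nu: float = 1.5e-5
    D: float = 2.5e-6

    def __post_init__(self):
        if self.nu <= 0 or self.D <= 0:
            raise ConfigurationError("FluidConstants: nu and D must be positive")


def _default_contour() -> np.ndarray:
    # (span fraction, signed chord offset as a fraction of the local chord);
    # leading/trailing edge pairs at four stations -> 8 contour points
    rows = []
    for s in (0.25, 0.5, 0.75, 0.95):
        rows.append((s, +0.5))
        rows.append((s, -0.5))
    return np.array(rows)


@dataclass(frozen=True)
class WingMorphology:
    """Planform model of one wing.

    The contour is a set of (span fraction, chord fraction) points on an
    elliptic planform of mean chord ``mean_chord``; the section is elliptic
    with thickness 1% of the wing length.
    """

    R: float = 17.3e-3
    mean_chord: float = 8.0e-3
    thickness_ratio: float = 0.01
    contour: np.ndarray = field(default_factory=_default_contour)

    def __post_init__(self):
        if self.R <= 0 or self.mean_chord <= 0:
            raise ConfigurationError("WingMorphology: R and mean_chord must be positive")

    def chord_at(self, s) -> np.ndarray:
        """Local chord length (m) of the elliptic planform at span fraction s."""
        s = np.asarray(s, dtype=float)
        return (4.0 / np.pi) * self.mean_chord * np.sqrt(np.clip(1.0 - (2.0 * s - 1.0) ** 2, 0.0, None))

    def contour_offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """Spanwise stations and chordwise offsets (m) of the contour points."""
        s = self.contour[:, 0]
        c = self.contour[:, 1] * self.chord_at(s)
        return s, c


@dataclass
class WingKinematics:
    """One phase-averaged wingbeat cycle of wing and body angles.

    Series live on a uniform grid ``t_hat = arange(n)/n`` over [0, 1) with
    the downstroke occupying [0, 0.5). ``alpha`` has shape
    ``(n, n_stations)``. Angles are radians; ``f`` is Hz.
    """

    t_hat: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    stations: np.ndarray
    beta: float
    chi: float
    f: float
    R: float
    pivot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sagittal_rotation: float = 0.0
    raw_cycles: dict | None = None

    def __post_init__(self):
        self.t_hat = np.asarray(self.t_hat, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        self.stations = np.asarray(self.stations, dtype=float)
        self.pivot = np.asarray(self.pivot, dtype=float)
        n = self.t_hat.size
        if self.phi.size != n or self.theta.size != n or self.alpha.shape[0] != n:
            raise ConfigurationError("WingKinematics: series lengths disagree")
        if self.f <= 0 or self.R <= 0:
            raise ConfigurationError("WingKinematics: f and R must be positive")

    @property
    def amplitude(self) -> float:
        """Wingbeat amplitude: peak-to-peak excursion of the positional angle."""
        return float(np.max(self.phi) - np.min(self.phi))

    @property
    def period(self) -> float:
        return 1.0 / self.f

    def assert_periodic(self, tol_factor: float = 3.0) -> None:
        """Raise unless the series closes smoothly over the cycle wrap."""
        for name in ("phi", "theta"):
            y = getattr(self, name)
            step = np.max(np.abs(np.diff(y))) + 1e-12
            if abs(y[0] - y[-1]) > tol_factor * step:
                raise ConfigurationError(
                    f"{name} series is not periodic over the cycle; "
                    "average over whole wingbeats first"
                )

    def phi_dot(self) -> np.ndarray:
        return periodic_derivative(self.phi, self.period)

    def theta_dot(self) -> np.ndarray:
        return periodic_derivative(self.theta, self.period)

    def alpha_dot(self) -> np.ndarray:
        return np.stack(
            [periodic_derivative(self.alpha[:, j], self.period) for j in range(self.alpha.shape[1])],
            axis=1,
        )

    def alpha_at(self, s) -> np.ndarray:
        """Feathering angle linearly interpolated to span fractions ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        return np.apply_along_axis(lambda row: np.interp(s, self.stations, row), 1, self.alpha)

    def tip_speed(self, R: float | None = None) -> float:
        """Mean wingtip speed 2*amplitude*f*R (m/s)."""
        return mean_tip_speed(self.amplitude, self.f, self.R if R is None else R)

    def reynolds(self, morph: WingMorphology, fluids: FluidConstants = FluidConstants()) -> float:
        return self.tip_speed(morph.R) * morph.mean_chord / fluids.nu

    # -- serialisation (degrees at the boundary) ---------------------------
    def to_dict(self) -> dict:
        return {
            "t_hat": self.t_hat.tolist(),
            "phi_deg": np.degrees(self.phi).tolist(),
            "theta_deg": np.degrees(self.theta).tolist(),
            "alpha_deg": np.degrees(self.alpha).tolist(),
            "stations": self.stations.tolist(),
            "stroke_plane_angle_deg": float(np.degrees(self.beta)),
            "body_angle_deg": float(np.degrees(self.chi)),
            "wingbeat_frequency_hz": float(self.f),
            "wingbeat_amplitude_deg": float(np.degrees(self.amplitude)),
            "wing_length_m": float(self.R),
            "pivot_m": self.pivot.tolist(),
            "sagittal_rotation_deg": float(np.degrees(self.sagittal_rotation)),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "WingKinematics":
        return cls(
            t_hat=np.asarray(d["t_hat"]),
            phi=np.radians(d["phi_deg"]),
            theta=np.radians(d["theta_deg"]),
            alpha=np.radians(d["alpha_deg"]),
            stations=np.asarray(d["stations"]),
            beta=np.radians(d["stroke_plane_angle_deg"]),
            chi=np.radians(d["body_angle_deg"]),
            f=d["wingbeat_frequency_hz"],
            R=d["wing_length_m"],
            pivot=np.asarray(d.get("pivot_m", [0.0, 0.0, 0.0])),
            sagittal_rotation=np.radians(d.get("sagittal_rotation_deg", 0.0)),
        )

    @classmethod
    def from_json(cls, path) -> "WingKinematics":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def periodic_derivative(y: np.ndarray, period: float) -> np.ndarray:
    """Spectral time derivative of a periodic series sampled uniformly over one period."""
    y = np.asarray(y, dtype=float)
    n = y.size
    k = np.fft.rfftfreq(n, d=1.0 / n)  # cycles per period
    return np.fft.irfft(2j * np.pi * k * np.fft.rfft(y), n=n) / period


# ---------------------------------------------------------------------------
# angle operations


def body_angle(head_tip, abdomen_tip) -> float:
    """Signed angle of the abdomen->head axis against the horizontal plane.

    Positive when the head is above the abdomen; range (-pi/2, pi/2].
    """
    v = np.asarray(head_tip, dtype=float) - np.asarray(abdomen_tip, dtype=float)
    horiz = np.hypot(v[0], v[1])
    if horiz == 0.0 and v[2] == 0.0:
        raise DegenerateGeometryError("body_angle: head and abdomen tips coincide")
    ang = np.arctan2(v[2], horiz)
    if ang == -np.pi / 2:
        ang = np.pi / 2
    return float(ang)


def fit_stroke_plane(wingtip_track, pivot) -> float:
    """Stroke-plane angle from the wingtip path, total-least-squares in x-z.

    The wingtip positions are projected onto the sagittal (x-z) plane and
    the first principal direction of the centred cloud gives the stroke
    line; its inclination from the horizontal, in [0, pi), is returned.
    TLS keeps near-vertical stroke planes well posed.
    """
    pts = np.asarray(wingtip_track, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise InsufficientDataError("fit_stroke_plane: need >= 3 wingtip samples")
    xz = pts[:, [0, 2]] - pts[:, [0, 2]].mean(axis=0)
    if np.allclose(xz, 0.0):
        raise DegenerateGeometryError("fit_stroke_plane: wingtip path has no x-z extent")
    # first right singular vector = direction of maximal variance
    _, _, vt = np.linalg.svd(xz, full_matrices=False)
    dx, dz = vt[0]
    ang = np.arctan2(dz, dx) % np.pi
    return float(ang)


def positional_elevation(wingtip, pivot, beta: float, side: str = "L"):
    """Positional and elevation angles of pivot->tip vectors.

    ``wingtip`` may be one point or an (n, 3) track. Elevation is positive
    anterior of the stroke plane; positional is measured from the stroke
    plane's horizontal line. Samples where the pivot->tip vector is normal
    to the stroke plane have undefined ``phi`` and are returned as NaN.
    """
    tips = np.atleast_2d(np.asarray(wingtip, dtype=float))
    v = tips - np.asarray(pivot, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateGeometryError("positional_elevation: wingtip coincides with pivot")
    e1, e2, a = stroke_plane_basis(beta)
    if side == "R":
        e2 = -e2  # mirror through the sagittal plane
    u = v / norms[:, None]
    s1 = u @ e1
    s2 = u @ e2
    sa = np.clip(u @ a, -1.0, 1.0)
    theta = np.arcsin(sa)
    in_plane = np.hypot(s1, s2)
    phi = np.where(in_plane > 1e-12, np.arctan2(s1, s2), np.nan)
    if np.any(~np.isfinite(phi)):
        log.warning(
            "positional_elevation: %d sample(s) normal to the stroke plane flagged degenerate",
            int(np.sum(~np.isfinite(phi))),
        )
    if np.isscalar(wingtip[0]) and tips.shape[0] == 1:
        return float(phi[0]), float(theta[0])
    return phi, theta


def wing_velocity_components(r, phi_dot, theta_dot, alpha, theta):
    """Section-parallel (v_h) and section-normal (v_v) wing speed at span r."""
    r = np.asarray(r, dtype=float)
    v_h = r * (-phi_dot * np.cos(alpha) * np.cos(theta) + theta_dot * np.sin(alpha))
    v_v = r * (-theta_dot * np.cos(alpha) + phi_dot * np.cos(theta) * np.sin(alpha))
    return v_h, v_v


def angle_of_attack(v_h, v_v, folded: bool = False):
    """Angle of attack arccos(v_h / |v|), in [0, pi].

    Samples with zero speed are undefined and returned as NaN (they are
    excluded from cycle averages). With ``folded=True`` values above pi/2
    are reflected to pi - AoA, the convention used for plotting.
    """
    v_h = np.asarray(v_h, dtype=float)
    v_v = np.asarray(v_v, dtype=float)
    speed = np.sqrt(v_h**2 + v_v**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        aoa = np.where(speed > 0, np.arccos(np.clip(v_h / np.where(speed > 0, speed, 1.0), -1, 1)), np.nan)
    if folded:
        aoa = np.where(aoa > np.pi / 2, np.pi - aoa, aoa)
    if np.ndim(v_h) == 0:
        return float(aoa)
    return aoa


# ---------------------------------------------------------------------------
# cycle segmentation and averaging


def estimate_frequency(t: np.ndarray, phi: np.ndarray) -> float:
    """Dominant-frequency estimate of a positional-angle series via FFT."""
    t = np.asarray(t, dtype=float)
    phi = np.asarray(phi, dtype=float)
    dt = np.mean(np.diff(t))
    y = phi - phi.mean()
    spec = np.abs(np.fft.rfft(y * np.hanning(y.size)))
    freqs = np.fft.rfftfreq(y.size, d=dt)
    k = int(np.argmax(spec[1:]) + 1)
    return float(freqs[k])


def segment_cycles(t: np.ndarray, phi: np.ndarray, f_hint: float | None = None) -> np.ndarray:
    """Cycle boundaries as refined times of positional-angle maxima.

    The series is low-pass filtered (zero-phase Butterworth, cutoff 3f) and
    discrete maxima are refined by quadratic interpolation so that the
    downstroke starts at t_hat = 0.
    """
    t = np.asarray(t, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if t.size < 8:
        raise InsufficientDataError("segment_cycles: too few samples")
    f_est = f_hint if f_hint is not None else estimate_frequency(t, phi)
    fs = 1.0 / np.mean(np.diff(t))
    wn = min(3.0 * f_est / (fs / 2.0), 0.95)
    b, a = butter(4, wn)
    ph = filtfilt(b, a, phi)
    min_dist = max(int(0.6 * fs / f_est), 1)
    peaks, _ = find_peaks(ph, distance=min_dist)
    if peaks.size < 2:
        raise InsufficientDataError("segment_cycles: fewer than one complete wingbeat")
    dt = np.mean(np.diff(t))
    times = []
    for i in peaks:
        if 0 < i < ph.size - 1:
            denom = ph[i - 1] - 2 * ph[i] + ph[i + 1]
            delta = 0.5 * (ph[i - 1] - ph[i + 1]) / denom if denom != 0 else 0.0
            times.append(t[i] + delta * dt)
        else:
            times.append(t[i])
    return np.asarray(times)


def _resample_cycle(t, y, t0, t1, n=N_GRID):
    mask = (t >= t0 - 2 * (t[1] - t[0])) & (t <= t1 + 2 * (t[1] - t[0]))
    cs = CubicSpline(t[mask], y[mask] if y.ndim == 1 else y[mask], axis=0)
    grid = t0 + (t1 - t0) * np.arange(n) / n
    return cs(grid)


def average_cycles(
    series_by_side: dict,
    beta: float,
    chi: float,
    R: float,
    stations: np.ndarray = DEFAULT_STATIONS,
    pivot: np.ndarray | None = None,
    n_grid: int = N_GRID,
    f_hint: float | None = None,
) -> WingKinematics:
    """Phase-align, cycle-average and left/right-average raw angle series.

    ``series_by_side`` maps side ("L"/"R", either or both) to a dict with
    keys ``time`` (s), ``phi``, ``theta`` (rad arrays) and optionally
    ``alpha`` (rad, shape (n_frames, n_stations)). Right-wing series are
    assumed already expressed in the mirrored frame so the two sides are
    directly comparable. Frequency and amplitude are recomputed from the
    averaged series.
    """
    if not series_by_side:
        raise InsufficientDataError("average_cycles: no series given")
    per_side_means = {"phi": [], "theta": [], "alpha": []}
    freqs = []
    raw = {}
    for side, ser in series_by_side.items():
        t = np.asarray(ser["time"], dtype=float)
        bounds = segment_cycles(t, ser["phi"], f_hint=f_hint)
        freqs.append(1.0 / np.mean(np.diff(bounds)))
        cyc = {"phi": [], "theta": [], "alpha": []}
        for t0, t1 in zip(bounds[:-1], bounds[1:]):
            cyc["phi"].append(_resample_cycle(t, np.asarray(ser["phi"]), t0, t1, n_grid))
            cyc["theta"].append(_resample_cycle(t, np.asarray(ser["theta"]), t0, t1, n_grid))
            if "alpha" in ser and ser["alpha"] is not None:
                cyc["alpha"].append(_resample_cycle(t, np.asarray(ser["alpha"]), t0, t1, n_grid))
        raw[side] = cyc
        per_side_means["phi"].append(np.mean(cyc["phi"], axis=0))
        per_side_means["theta"].append(np.mean(cyc["theta"], axis=0))
        if cyc["alpha"]:
            per_side_means["alpha"].append(np.mean(cyc["alpha"], axis=0))
    phi = np.mean(per_side_means["phi"], axis=0)
    theta = np.mean(per_side_means["theta"], axis=0)
    if per_side_means["alpha"]:
        alpha = np.mean(per_side_means["alpha"], axis=0)
    else:
        alpha = np.full((n_grid, stations.size), np.pi / 2)
    f = float(np.mean(freqs))
    return WingKinematics(
        t_hat=np.arange(n_grid) / n_grid,
        phi=phi,
        theta=theta,
        alpha=alpha,
        stations=stations,
        beta=beta,
        chi=chi,
        f=f,
        R=R,
        pivot=pivot if pivot is not None else np.zeros(3),
        raw_cycles=raw,
    )


# ---------------------------------------------------------------------------
# feathering from camera contours


def fit_feathering(
    contour_tracks_2d,
    cameras,
    morphology: WingMorphology,
    pivot,
    beta: float,
    phi,
    theta,
    stations: np.ndarray = DEFAULT_STATIONS,
    side: str = "L",
    smoothing: float = 1e-3,
    max_nfev: int = 200,
) -> np.ndarray:
    """Per-frame spanwise feathering profile from 2D contour observations.

    For each frame the model wing is posed by the known ``phi``/``theta``
    and a candidate twist profile ``alpha(stations)`` (linearly interpolated
    to the contour stations), reprojected through every camera, and the
    summed squared 2D distance to the observed contour points is minimised.
    A quadratic penalty on second spanwise differences (weight
    ``smoothing``, in pixel/rad units) regularises the profile without
    biasing linear twists. Frames where the optimiser fails are returned as
    NaN rows and logged.

    ``contour_tracks_2d`` has shape (n_cameras, n_frames, n_points, 2) with
    points in the order of ``morphology.contour``.
    """
    obs = np.asarray(contour_tracks_2d, dtype=float)
    if len(cameras) < 2:
        raise ConfigurationError("fit_feathering: need >= 2 cameras")
    if obs.shape[2] < 4:
        raise ConfigurationError("fit_feathering: need >= 4 contour points per frame")
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    n_frames = phi.size
    s_pts, c_pts = morphology.contour_offsets()
    n_st = stations.size

    d2 = np.zeros((n_st - 2, n_st))
    for i in range(n_st - 2):
        d2[i, i : i + 3] = (1.0, -2.0, 1.0)

    def residual(alpha_st, k):
        a_pts = np.interp(s_pts, stations, alpha_st)
        pts3 = wing_surface_points(
            pivot, morphology.R, phi[k], theta[k], beta, s_pts, c_pts, a_pts, side=side
        )
        res = []
        for c, cam in enumerate(cameras):
            proj = cam.project(pts3)
            res.append((proj - obs[c, k]).ravel())
        res.append(smoothing * (d2 @ alpha_st))
        return np.concatenate(res)

    out = np.full((n_frames, n_st), np.nan)
    x0 = np.full(n_st, np.pi / 2)
    for k in range(n_frames):
        sol = least_squares(residual, x0, args=(k,), max_nfev=max_nfev)
        if sol.success or sol.cost < 1e-16:
            out[k] = sol.x
            x0 = sol.x  # warm start the next frame
        else:
            log.warning("fit_feathering: frame %d did not converge; excluded", k)
    return out


def feathering_from_3d_contours(points3d, pivot, beta, phi, theta, contour_spans, side="L"):
    """Feathering angles directly from 3D leading/trailing contour pairs.

    ``points3d`` has shape (n_frames, n_points, 3) with contour points in
    leading/trailing pairs per station (the layout of
    ``WingMorphology.contour``). Returns (n_frames, n_contour_stations).
    """
    pts = np.asarray(points3d, dtype=float)
    phi = np.atleast_1d(phi)
    theta = np.atleast_1d(theta)
    span, chord_ref, n = wing_section_frame(phi, theta, beta, side=side)
    lead = pts[:, 0::2, :]
    trail = pts[:, 1::2, :]
    v = lead - trail
    return np.arctan2(
        np.einsum("fpc,fc->fp", v, n),
        np.einsum("fpc,fc->fp", v, chord_ref),
    )


# ---------------------------------------------------------------------------
# sagittal deconfliction


def pose_wing_surface(kin: WingKinematics, morphology: WingMorphology, side: str = "L") -> np.ndarray:
    """3D wing surface (tip + contour points) over the averaged cycle.

    Applies the stored sagittal deconfliction rotation, if any. Returns
    shape (n_t, n_points, 3).
    """
    s_pts, c_pts = morphology.contour_offsets()
    s_all = np.concatenate([s_pts, [1.0]])
    c_all = np.concatenate([c_pts, [0.0]])
    a_interp = np.apply_along_axis(lambda row: np.interp(s_all, kin.stations, row), 1, kin.alpha)
    pts = wing_surface_points(
        kin.pivot, morphology.R, kin.phi, kin.theta, kin.beta, s_all, c_all, a_interp, side=side
    )
    if kin.sagittal_rotation != 0.0:
        pts = _rotate_about_back_axis(pts, kin.pivot, kin.sagittal_rotation, side)
    return pts


def _rotate_about_back_axis(points, pivot, delta, side):
    """Rotate points about the horizontal axis through the pivot pointing posteriorly.

    The sign convention moves the named wing away from the sagittal plane
    for positive ``delta``.
    """
    rel = np.asarray(points, dtype=float) - pivot
    c, s = np.cos(delta), np.sin(delta)
    if side == "R":
        s = -s
    y = rel[..., 1] * c + rel[..., 2] * s
    z = -rel[..., 1] * s + rel[..., 2] * c
    out = rel.copy()
    out[..., 1] = y
    out[..., 2] = z
    return out + pivot


def deconflict_sagittal(
    kin: WingKinematics,
    clearance: float = 0.0,
    morphology: WingMorphology | None = None,
    max_rotation_deg: float = 15.0,
    scan_step_deg: float = 0.01,
) -> tuple[WingKinematics, float]:
    """Smallest rotation keeping the posed wing clear of the sagittal plane.

    The averaged left-wing surface is rotated about the horizontal
    back-pointing axis through the wing root until every surface point
    keeps at least ``clearance`` from the sagittal plane at every time
    step. The rotation is rigid, so wing speed is unchanged. Returns the
    rotated kinematics and the rotation angle (rad); identity if the wing
    is already clear.
    """
    if clearance < 0:
        raise ConfigurationError("deconflict_sagittal: clearance must be >= 0")
    morph = morphology if morphology is not None else WingMorphology(R=kin.R)
    base = pose_wing_surface(kin, morph, side="L")
    rel = base - kin.pivot

    def min_y(delta):
        c, s = np.cos(delta), np.sin(delta)
        return float(np.min(kin.pivot[1] + rel[..., 1] * c + rel[..., 2] * s))

    if min_y(0.0) >= clearance:
        return kin, 0.0
    step = np.radians(scan_step_deg)
    max_rot = np.radians(max_rotation_deg)
    delta = step
    while delta <= max_rot and min_y(delta) < clearance:
        delta += step
    if delta > max_rot:
        raise ConfigurationError(
            f"deconflict_sagittal: required rotation exceeds {max_rotation_deg} deg; "
            "input kinematics are likely mis-registered"
        )
    lo = delta - step
    try:
        delta = brentq(lambda d: min_y(d) - clearance, lo, delta, xtol=1e-10)
    except ValueError:
        pass  # keep the scanned value if the bracket degenerates
    out = dataclasses.replace(kin, sagittal_rotation=kin.sagittal_rotation + delta)
    return out, float(delta)


# ---------------------------------------------------------------------------
# dimensionless numbers


def mean_tip_speed(amplitude: float, f: float, R: float) -> float:
    """Mean wingtip speed 2*amplitude*f*R (amplitude in rad) in m/s."""
    return 2.0 * amplitude * f * R


def reynolds(amplitude: float, f: float, morph: WingMorphology, fluids: FluidConstants = FluidConstants()) -> float:
    """Reynolds number on the mean wingtip speed and mean chord."""
    return mean_tip_speed(amplitude, f, morph.R) * morph.mean_chord / fluids.nu


def schmidt(fluids: FluidConstants = FluidConstants()) -> float:
    """Schmidt number nu/D: ratio of momentum to mass diffusivity."""
    return fluids.nu / fluids.D


# ---------------------------------------------------------------------------
# full reconstruction pipeline


def reconstruct(track, stations: np.ndarray = DEFAULT_STATIONS, n_grid: int = N_GRID) -> WingKinematics:
    """Reconstruct averaged wing kinematics from a landmark track.

    Pipeline: wing pivots from the wing-root landmarks; body angle from
    head/abdomen tips; stroke-plane angle by total least squares on the
    wingtip path (both wings, right mirrored); per-frame positional and
    elevation angles; feathering from 3D contour pairs when present;
    cycle segmentation at positional-angle maxima; phase averaging over
    cycles and sides.
    """
    frames = track.frames
    times = np.sort(frames["time_s"].unique())
    chi_samples = []
    per_side = {}
    betas = []
    pivots = {}
    for side in ("L", "R"):
        sub = frames[frames["side"] == side]
        if sub.empty:
            continue
        root = sub[sub["landmark"] == "wing_root"][["x_m", "y_m", "z_m"]].to_numpy()
        tips = sub[sub["landmark"] == "wing_tip"][["x_m", "y_m", "z_m"]].to_numpy()
        if root.size == 0 or tips.shape[0] < 3:
            continue
        pivot = root.mean(axis=0)
        pivots[side] = pivot
        tips_f = tips.copy()
        if side == "R":
            tips_f[:, 1] *= -1
            pivot_f = pivot * np.array([1, -1, 1])
        else:
            pivot_f = pivot
        betas.append(fit_stroke_plane(tips_f, pivot_f))
        per_side[side] = {"tips": tips}
    if not per_side:
        raise InsufficientDataError("reconstruct: no wing landmarks found")
    beta = float(np.mean(betas))

    head = frames[frames["landmark"] == "head_tip"][["x_m", "y_m", "z_m"]].to_numpy()
    abdo = frames[frames["landmark"] == "abdomen_tip"][["x_m", "y_m", "z_m"]].to_numpy()
    for h, a in zip(head, abdo):
        chi_samples.append(body_angle(h, a))
    chi = float(np.mean(chi_samples)) if chi_samples else 0.0

    series_by_side = {}
    R_est = []
    for side, d in per_side.items():
        pivot = pivots[side]
        phi, theta = positional_elevation(d["tips"], pivot, beta, side=side)
        ser = {"time": times, "phi": phi, "theta": theta}
        sub = frames[(frames["side"] == side) & frames["landmark"].str.startswith("contour_")]
        if not sub.empty:
            n_pts = sub["landmark"].nunique()
            pts = (
                sub.sort_values(["time_s", "landmark"], key=_contour_sort_key)[["x_m", "y_m", "z_m"]]
                .to_numpy()
                .reshape(len(times), n_pts, 3)
            )
            morph = WingMorphology(R=float(np.linalg.norm(d["tips"] - pivot, axis=1).mean()))
            spans = morph.contour[0::2, 0]
            a_contour = feathering_from_3d_contours(pts, pivot, beta, phi, theta, spans, side=side)
            # interpolate contour stations -> requested stations, extrapolating
            # linearly so spanwise-linear twist profiles survive the edges
            a_full = np.apply_along_axis(
                lambda row: _interp_linear_extrap(stations, spans, row), 1, a_contour
            )
            ser["alpha"] = a_full
        series_by_side[side] = ser
        R_est.append(np.linalg.norm(d["tips"] - pivot, axis=1).mean())
    kin = average_cycles(
        series_by_side,
        beta=beta,
        chi=chi,
        R=float(np.mean(R_est)),
        stations=stations,
        pivot=pivots.get("L", next(iter(pivots.values()))),
        n_grid=n_grid,
    )
    return kin


def _interp_linear_extrap(x, xp, fp):
    """np.interp with linear (not constant) extrapolation beyond the ends."""
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    if np.any(lo):
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y = np.where(lo, fp[0] + slope * (x - xp[0]), y)
    hi = x > xp[-1]
    if np.any(hi):
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(hi, fp[-1] + slope * (x - xp[-1]), y)
    return y


def _contour_sort_key(col):
    import pandas as pd

    if col.name == "landmark":
        return col.str.extract(r"contour_(\d+)")[0].astype(int)
    return col
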