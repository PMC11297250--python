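"""Shared frame conventions and the rigid wing-pose model.

Lab frame: right-handed, ``x`` anterior (the direction the head points at
rest), ``y`` toward the animal's left, ``z`` up, floor at ``z = 0``.

The stroke plane passes through the wing pivot and is inclined by the
stroke-plane angle ``beta`` from horizontal; it contains the lab ``y`` axis.
Within-plane coordinates use two unit vectors:

* ``e1(beta) = (cos beta, 0, sin beta)`` — "up along the stroke plane",
* ``e2 = (0, 1, 0)`` — the horizontal line of the stroke plane (left),

and the anterior unit normal ``a(beta) = (sin beta, 0, -cos beta)``.

A left-wing tip at positional angle ``phi`` (from the horizontal, within the
stroke plane) and elevation angle ``theta`` (out of the stroke plane,
positive anterior) sits at::

    tip = pivot + R * (cos(theta) * (sin(phi) e1 + cos(phi) e2)
                       + sin(theta) * a)

Right-wing geometry is the mirror image through the sagittal (x-z) plane.
All angles are radians internally; degrees appear only at I/O boundaries.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "stroke_plane_basis",
    "wing_tip_direction",
    "wing_section_frame",
    "wing_surface_points",
]


def stroke_plane_basis(beta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (e1, e2, anterior_normal) of the stroke plane inclined ``beta``."""
    e1 = np.array([np.cos(beta), 0.0, np.sin(beta)])
    e2 = np.array([0.0, 1.0, 0.0])
    a = np.array([np.sin(beta), 0.0, -np.cos(beta)])
    return e1, e2, a


def _mirror(v: np.ndarray) -> np.ndarray:
    out = np.array(v, dtype=float, copy=True)
    out[..., 1] *= -1.0
    return out


def wing_tip_direction(phi, theta, beta: float, side: str = "L") -> np.ndarray:
    """Unit vector from the pivot toward the wing tip.

    ``phi``/``theta`` may be scalars or arrays (broadcast to a trailing
    xyz axis). ``side`` is ``"L"`` or ``"R"``; the right wing is the
    sagittal mirror of the left.
    """
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    e1, e2, a = stroke_plane_basis(beta)
    d = (
        np.cos(theta)[..., None] * (np.sin(phi)[..., None] * e1 + np.cos(phi)[..., None] * e2)
        + np.sin(theta)[..., None] * a
    )
    if side == "R":
        d = _mirror(d)
    elif side != "L":
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    return d


def wing_section_frame(phi, theta, beta: float, side: str = "L"):
    """Orthonormal (span, chord_ref, section_normal) frame of a wing.

    ``chord_ref`` is the zero-feathering chord direction: perpendicular to
    the span and lying in the stroke plane. ``section_normal`` completes the
    right-handed triad; a section feathered by ``alpha`` has chord direction
    ``cos(alpha) * chord_ref + sin(alpha) * section_normal``, so
    ``alpha = pi/2`` means the chord is perpendicular to the stroke plane.
    """
    span = wing_tip_direction(phi, theta, beta, side=side)
    _, _, a = stroke_plane_basis(beta)
    if side == "R":
        a = _mirror(a)
    # normal to the stroke plane, re-orthogonalised against the span
    n = np.broadcast_to(a, span.shape).copy()
    n -= (np.sum(n * span, axis=-1, keepdims=True)) * span
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("wing span is normal to the stroke plane; section frame undefined")
    n /= norm
    chord_ref = np.cross(n, span)
    return span, chord_ref, n


def wing_surface_points(
    pivot: np.ndarray,
    R: float,
    phi,
    theta,
    beta: float,
    stations: np.ndarray,
    chord_offsets: np.ndarray,
    alpha_stations,
    side: str = "L",
) -> np.ndarray:
    """Pose wing-contour points in 3D.

    Parameters
    ----------
    stations : spanwise fractions ``s`` in (0, 1] where sections are posed.
    chord_offsets : signed chordwise offsets (m) of each contour point from
        the spanwise axis, one per station (positive toward the leading edge).
    alpha_stations : feathering angle (rad) at each station; scalars
        broadcast. May carry a leading time axis matching ``phi``.

    Returns array of shape ``phi.shape + (n_stations, 3)``.
    """
    pivot = np.asarray(pivot, dtype=float)
    stations = np.asarray(stations, dtype=float)
    chord_offsets = np.asarray(chord_offsets, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha_stations, dtype=float), np.shape(phi) + stations.shape)
    span, chord_ref, n = wing_section_frame(phi, theta, beta, side=side)
    chord_dir = (
        np.cos(alpha)[..., None] * chord_ref[..., None, :]
        + np.sin(alpha)[..., None] * n[..., None, :]
    )
    pts = (
        pivot
        + (stations * R)[:, None] * span[..., None, :]
        + chord_offsets[:, None] * chord_dir
    )
    return pts
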