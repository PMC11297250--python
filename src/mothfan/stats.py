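"""Head-relative statistics of the sampling volume.

Particle origins are summarised, per arrival-time bin, by their distance
from the head and by the horizontal (azimuth from the heading, positive
toward the animal's left) and vertical (elevation above the horizontal
plane) angles of the head-to-origin vector. Violin-style order statistics
use linearly interpolated quantiles with Tukey 1.5*IQR whiskers.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import InsufficientDataError
from .sampling import SamplingVolume

log = logging.getLogger(__name__)

__all__ = [
    "head_relative_coordinates",
    "violin_summary",
    "angular_extent",
    "anisotropy_test",
]


def head_relative_coordinates(volume: SamplingVolume, pole_tol: float = 1e-12) -> pd.DataFrame:
    """Per-particle (distance, horizontal angle, vertical angle) from the head.

    Horizontal angle is measured in the horizontal plane from the heading
    (0 deg = dead ahead), positive toward +y (the animal's left, the wing
    side simulated); vertical angle is the elevation of the head-to-origin
    vector. Particles directly above/below the head have undefined azimuth
    and get NaN there; particles coincident with the head are dropped with
    a log record.
    """
    if len(volume) == 0:
        raise InsufficientDataError("head_relative_coordinates: empty sampling volume")
    v = volume.points - volume.head
    dist = np.linalg.norm(v, axis=1)
    keep = dist > pole_tol
    if not np.all(keep):
        log.warning(
            "head_relative_coordinates: %d origin(s) coincide with the head; excluded",
            int(np.sum(~keep)),
        )
    v = v[keep]
    dist = dist[keep]
    cycles = volume.cycles[keep]
    fwd = volume.heading.copy()
    fwd[2] = 0.0
    n = np.linalg.norm(fwd)
    if n == 0:  # heading straight up: fall back to +x as the azimuth reference
        fwd = np.array([1.0, 0.0, 0.0])
    else:
        fwd /= n
    left = np.cross([0.0, 0.0, 1.0], fwd)
    horiz = np.hypot(v @ fwd, v @ left)
    with np.errstate(invalid="ignore"):
        h_ang = np.degrees(np.arctan2(v @ left, v @ fwd))
    h_ang = np.where(horiz > pole_tol, h_ang, np.nan)
    v_ang = np.degrees(np.arctan2(v[:, 2], horiz))
    return pd.DataFrame(
        {
            "cycles_to_arrival": cycles,
            "distance_m": dist,
            "h_angle_deg": h_ang,
            "v_angle_deg": v_ang,
        }
    )


def violin_summary(values, cycles=None, bin_edges=None) -> pd.DataFrame:
    """Order statistics per arrival-time bin with Tukey whiskers.

    Quantiles interpolate linearly between order statistics; whiskers are
    the extreme values within the 1.5*IQR fences, so outliers never set
    them. With no ``cycles``/``bin_edges`` everything falls in one bin.
    Empty bins are omitted with a warning.
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    values = values[ok]
    if cycles is None:
        groups = {"all": values}
    else:
        cycles = np.asarray(cycles)[ok]
        if bin_edges is None:
            bin_edges = np.arange(0, int(cycles.max()) + 5, 5)
        groups = {}
        for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
            key = f"({lo}, {hi}]"
            groups[key] = values[(cycles > lo) & (cycles <= hi)]
    rows = []
    for key, vals in groups.items():
        if vals.size == 0:
            log.warning("violin_summary: bin %s is empty; omitted", key)
            continue
        p25, med, p75 = np.quantile(vals, [0.25, 0.5, 0.75])
        iqr = p75 - p25
        fence_lo, fence_hi = p25 - 1.5 * iqr, p75 + 1.5 * iqr
        inliers = vals[(vals >= fence_lo) & (vals <= fence_hi)]
        # whiskers extend from the box, so they never cross the quartiles even
        # when an interpolated quartile exceeds every in-fence data value
        rows.append(
            {
                "arrival_bin": key,
                "median": med,
                "p25": p25,
                "p75": p75,
                "lo": min(inliers.min(), p25),
                "hi": max(inliers.max(), p75),
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def angular_extent(horizontal_angles_deg, coverage: float = 0.9, two_sided: bool = False) -> float:
    """Width of the angular range holding ``coverage`` of the particles.

    Angles are measured from the sagittal direction (0 deg dead ahead), so
    the extent is anchored there: one-sided extent is the ``coverage``
    quantile of |angle| (a single-wing volume concentrated in 0-30 deg
    yields ~30); ``two_sided=True`` doubles it, the convention for
    sagittally mirrored two-wing volumes.
    """
    a = np.asarray(horizontal_angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 10:
        raise InsufficientDataError("angular_extent: need >= 10 particles")
    if not (0.0 < coverage < 1.0):
        raise ValueError("angular_extent: coverage must be in (0, 1)")
    one_sided = float(np.quantile(np.abs(a), coverage))
    return 2.0 * one_sided if two_sided else one_sided


def anisotropy_test(horizontal_angles_deg, support: tuple[float, float] = (-180.0, 180.0)) -> float:
    """p-value of a Kolmogorov-Smirnov test against angular uniformity.

    Small p means the sampling volume draws particles from a preferred
    direction (anisotropic); an isotropic volume gives a uniform azimuth
    distribution over ``support``.
    """
    a = np.asarray(horizontal_angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 50:
        raise InsufficientDataError("anisotropy_test: need >= 50 particles")
    lo, hi = support
    res = sstats.kstest(a, sstats.uniform(loc=lo, scale=hi - lo).cdf)
    return float(res.pvalue)


def stats_table(volume: SamplingVolume, bin_width: int = 5) -> pd.DataFrame:
    """Violin summaries of distance and both angles, per arrival-time bin."""
    coords = head_relative_coordinates(volume)
    edges = np.arange(0, int(coords["cycles_to_arrival"].max()) + bin_width, bin_width)
    out = []
    for metric, col, scale in (
        ("distance", "distance_m", 1.0),
        ("h_angle", "h_angle_deg", 1.0),
        ("v_angle", "v_angle_deg", 1.0),
    ):
        tab = violin_summary(coords[col] * scale, coords["cycles_to_arrival"], edges)
        tab.insert(1, "metric", metric)
        out.append(tab)
    return pd.concat(out, ignore_index=True)
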