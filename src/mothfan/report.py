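"""Human-readable run report: markdown summary plus figure panels.

The report mirrors the figures a kinematics-and-flow study would show:
wing-angle time series, spanwise angle of attack, induced-flow probe
series, violin summaries of the sampling volume and its 3D scatter. The
markdown body is deterministic for identical inputs (no timestamps).
"""
from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kinematics import WingKinematics, angle_of_attack, wing_velocity_components
from .stats import head_relative_coordinates, stats_table

__all__ = ["report"]


def _fig_angles(kin: WingKinematics, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    th = kin.t_hat
    ax.axvspan(0, 0.5, color="0.9", label="downstroke")
    ax.plot(th, np.degrees(kin.phi), label="positional")
    ax.plot(th, np.degrees(kin.theta), label="elevation")
    tip = np.argmin(np.abs(kin.stations - 0.8))
    ax.plot(th, np.degrees(kin.alpha[:, tip]) - 90.0, label="feathering - 90 (0.8R)")
    ax.set_xlabel("stroke cycle")
    ax.set_ylabel("angle (deg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _fig_aoa(kin: WingKinematics, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.axvspan(0, 0.5, color="0.9")
    pd_, td_ = kin.phi_dot(), kin.theta_dot()
    for j, s in enumerate(kin.stations):
        vh, vv = wing_velocity_components(s * kin.R, pd_, td_, kin.alpha[:, j], kin.theta)
        aoa = angle_of_attack(vh, vv, folded=True)
        ax.plot(kin.t_hat, np.degrees(aoa), label=f"{s:.1f}R")
    ax.set_xlabel("stroke cycle")
    ax.set_ylabel("angle of attack (deg, folded)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _fig_probe(probe, path: Path) -> None:
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5), sharey=True)
    n_st = probe.speeds.shape[1]
    cmap = plt.get_cmap("viridis")
    for j in range(n_st):
        ax1.plot(probe.t_hat, probe.speeds[:, j], color=cmap(j / max(n_st - 1, 1)), lw=0.8)
    ax1.set_xlabel("stroke cycle")
    ax1.set_ylabel("speed (m/s)")
    ax1.set_title("antenna stations (base: dark, tip: light)", fontsize=8)
    frac = np.linspace(0, 1, n_st)
    ax2.plot(frac, probe.means, "o-", label="cycle mean")
    ax2.plot(frac, probe.amplitudes, "s-", label="amplitude")
    ax2.set_xlabel("antenna fraction (base to tip)")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _fig_violin(volume, path: Path) -> None:
    coords = head_relative_coordinates(volume)
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.5))
    edges = np.arange(0, int(coords["cycles_to_arrival"].max()) + 5, 5)
    panels = (
        ("distance (mm)", coords["distance_m"] * 1e3),
        ("horizontal angle (deg)", coords["h_angle_deg"]),
        ("vertical angle (deg)", coords["v_angle_deg"]),
    )
    for ax, (label, vals) in zip(axes, panels):
        data, pos = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (coords["cycles_to_arrival"] > lo) & (coords["cycles_to_arrival"] <= hi)
            chunk = np.asarray(vals[sel].dropna())
            if chunk.size:
                data.append(chunk)
                pos.append((lo + hi) / 2)
        if data:
            ax.violinplot(data, positions=pos, widths=4, showmedians=True)
        ax.set_xlabel("wingbeats before arrival")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _fig_volume3d(volume, path: Path) -> None:
    fig = plt.figure(figsize=(5, 4.5))
    ax = fig.add_subplot(projection="3d")
    p = volume.points * 1e3
    sc = ax.scatter(p[:, 0], p[:, 1], p[:, 2], c=volume.cycles, s=3, cmap="plasma")
    h = volume.head * 1e3
    ax.scatter(*h, color="k", marker="^", s=40)
    fig.colorbar(sc, label="wingbeats before arrival", shrink=0.7)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_zlabel("z (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def report(volume, kinematics, probes, outdir, config: dict | None = None) -> Path:
    """Write ``report.md`` and its figures to ``outdir``; returns the md path.

    Any of ``volume``/``kinematics``/``probes`` may be None; missing
    stages are noted in the document. An empty sampling volume produces an
    explicit "no particles" notice instead of figures.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["# Fanning-analysis report", ""]
    if kinematics is not None:
        _fig_angles(kinematics, outdir / "fig_angles.png")
        _fig_aoa(kinematics, outdir / "fig_aoa.png")
        lines += [
            "## Wing kinematics",
            "",
            f"- wingbeat frequency: {kinematics.f:.2f} Hz",
            f"- wingbeat amplitude: {np.degrees(kinematics.amplitude):.1f} deg",
            f"- stroke-plane angle: {np.degrees(kinematics.beta):.1f} deg",
            f"- body angle: {np.degrees(kinematics.chi):.2f} deg",
            f"- mean elevation angle: {np.degrees(np.mean(kinematics.theta)):.1f} deg",
            f"- mean wingtip speed 2*amplitude*f*R: {kinematics.tip_speed():.2f} m/s",
            "",
            "![wing angles](fig_angles.png)",
            "",
            "![angle of attack](fig_aoa.png)",
            "",
        ]
    if probes is not None:
        _fig_probe(probes, outdir / "fig_probe.png")
        lines += [
            "## Induced flow at the antenna",
            "",
            f"- cycle-mean speed at the tip station: {probes.means[-1]:.3f} m/s",
            f"- amplitude at the tip station: {probes.amplitudes[-1]:.3f} m/s",
            f"- dominant oscillation: {probes.dominant[-1]} (tip), {probes.dominant[0]} (base)",
            "",
            "![probe series](fig_probe.png)",
            "",
        ]
    if volume is None or len(volume) == 0:
        lines += ["## Sampling volume", "", "No particles: the sampling volume is empty.", ""]
    else:
        _fig_violin(volume, outdir / "fig_violin.png")
        _fig_volume3d(volume, outdir / "fig_volume3d.png")
        tab = stats_table(volume)
        lines += [
            "## Sampling volume",
            "",
            f"- particles: {len(volume)}",
            "",
            tab.to_markdown(index=False),
            "",
            "![violin summaries](fig_violin.png)",
            "",
            "![3D sampling volume](fig_volume3d.png)",
            "",
        ]
        tab.to_csv(outdir / "stats.csv", index=False)
    if config is not None:
        lines += [
            "## Configuration",
            "",
            "```json",
            json.dumps(config, indent=1, sort_keys=True, default=str),
            "```",
            "",
        ]
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
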