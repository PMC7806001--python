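"""Static 3D snapshot rendering of a simulated organ.

Conventions: the subapical growth zone is drawn in green and the mature
zone in gray; the apex carries the local tangent (red), normal (blue) and
bi-normal (green) arrows; a blue line traces the history of the normal
direction along the organ (offset by one radius from the centerline),
which visualizes rotational movements such as circumnutation.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .geometry import OrganState, frenet_from_natural

__all__ = ["plot_snapshot"]


def plot_snapshot(
    state: OrganState,
    frames: np.ndarray,
    positions: np.ndarray,
    path: str | Path,
    stimulus: dict | None = None,
) -> None:
    """Render one organ state to an image file.

    ``stimulus`` optionally marks the stimulus geometry: a dict with kind
    "constant" (direction), "point" (source_point) or "line" (line_base,
    direction), drawn in red.
    """
    n = state.n_segments
    n_gz = min(n, int(round(state.growth_zone_length / state.ds)))
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")

    mature = positions[: n - n_gz + 1]
    green = positions[max(n - n_gz, 0) :]
    if mature.shape[0] > 1:
        ax.plot(*mature.T, color="0.5", lw=2.5, label="mature zone")
    ax.plot(*green.T, color="tab:green", lw=2.5, label="growth zone")

    # normal-direction history line, offset one radius along N
    kappa, phi, _ = frenet_from_natural(state.kappa1, state.kappa2, state.ds)
    defined = np.isfinite(phi)
    if defined.any():
        m1 = frames[:, 0]
        m2 = frames[:, 1]
        normals = np.where(
            defined[:, None],
            np.cos(np.nan_to_num(phi))[:, None] * m1
            + np.sin(np.nan_to_num(phi))[:, None] * m2,
            np.nan,
        )
        trace = positions[:n] + state.radius * normals
        ax.plot(*trace.T, color="tab:blue", lw=1.0, label="normal history")

    tip = positions[n]
    tip_frame = frames[n - 1]
    arrow = 0.25 * max(state.length, 1.0)
    t_hat = tip_frame[2]
    if defined[-1]:
        n_hat = np.cos(phi[-1]) * tip_frame[0] + np.sin(phi[-1]) * tip_frame[1]
    else:
        n_hat = tip_frame[0]
    b_hat = np.cross(t_hat, n_hat)
    for vec, color in ((t_hat, "red"), (n_hat, "blue"), (b_hat, "green")):
        ax.quiver(*tip, *(arrow * vec), color=color, lw=1.5)

    if stimulus:
        kind = stimulus.get("kind")
        if kind == "constant":
            d = np.asarray(stimulus["direction"], dtype=float)
            ax.quiver(*tip, *(0.5 * state.length * d), color="red", lw=2)
        elif kind == "point":
            ax.scatter(*np.asarray(stimulus["source_point"]), color="red", s=40)
        elif kind == "line":
            base = np.asarray(stimulus["line_base"], dtype=float)
            d = np.asarray(stimulus["direction"], dtype=float)
            span = np.linspace(0, 1.2 * state.length, 2)
            line = base[None] + span[:, None] * d[None]
            ax.plot(*line.T, color="red", lw=2)

    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_zlabel("z")
    ax.legend(loc="upper left", fontsize=8)
    _equal_aspect(ax, positions)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _equal_aspect(ax, points: np.ndarray) -> None:
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    center = (lo + hi) / 2
    half = max((hi - lo).max() / 2, 1e-3)
    ax.set_xlim(center[0] - half, center[0] + half)
    ax.set_ylim(center[1] - half, center[1] + half)
    ax.set_zlim(center[2] - half, center[2] + half)
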