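"""Minimal visualization: morphospace scatters with group hulls and
disparity-through-time curves with their simulation envelope."""
from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ordination import DttResult, Ordination  # noqa: E402

__all__ = ["plot_morphospace", "plot_dtt"]


def plot_morphospace(ordination: Ordination, groups: dict[str, str] | None,
                     path, axes=(0, 1)) -> None:
    """Scatter of two ordination axes with convex-hull outlines per group."""
    i, j = axes
    fig, ax = plt.subplots(figsize=(6, 5))
    xs, ys = ordination.scores[:, i], ordination.scores[:, j]
    if groups is None:
        groups = {sid: "all" for sid in ordination.specimen_ids}
    levels = sorted(set(groups.values()))
    colors = plt.get_cmap("tab10")
    for g_idx, level in enumerate(levels):
        mask = np.array([groups[s] == level for s in ordination.specimen_ids])
        ax.scatter(xs[mask], ys[mask], label=level, color=colors(g_idx), s=30)
        pts = np.column_stack([xs[mask], ys[mask]])
        if pts.shape[0] >= 3:
            try:
                from scipy.spatial import ConvexHull

                hull = ConvexHull(pts)
                poly = pts[np.append(hull.vertices, hull.vertices[0])]
                ax.fill(poly[:, 0], poly[:, 1], alpha=0.15, color=colors(g_idx))
            except Exception:
                pass
    for sid, x, y in zip(ordination.specimen_ids, xs, ys):
        ax.annotate(sid, (x, y), fontsize=6, alpha=0.7)
    pv = ordination.proportion_variance
    ax.set_xlabel(f"{ordination.kind} {i + 1} ({100 * pv[i]:.1f}%)")
    ax.set_ylabel(f"{ordination.kind} {j + 1} ({100 * pv[j]:.1f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dtt(result: DttResult, path) -> None:
    """Observed mean relative subclade disparity with the BM envelope."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(result.times, result.envelope_lo, result.envelope_hi,
                    color="0.8", label="95% BM envelope")
    ax.plot(result.times, result.sim_mean, "--", color="0.4", label="BM mean")
    ax.plot(result.times, result.observed, "-", color="C3", lw=2, label="observed")
    ax.set_xlabel("relative time")
    ax.set_ylabel("mean relative subclade disparity")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
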