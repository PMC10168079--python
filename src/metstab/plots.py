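"""Matplotlib renderings of the standard trial-analysis views.

Every figure has a plain-text coordinate table produced elsewhere in the
pipeline; these plots are visual companions, written as vector graphics.
"""

from __future__ import annotations

import math

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ammi import AmmiFit, ammi1_coordinates
from .gge import GgeFit, SectorPartition, environment_diagnostics

__all__ = [
    "plot_ammi1",
    "plot_gge",
    "plot_discrimination",
    "plot_which_won_where",
]


def _annotate(ax, xs, ys, labels, color):
    for x, y, lab in zip(xs, ys, labels):
        ax.annotate(lab, (x, y), fontsize=7, color=color,
                    xytext=(2, 2), textcoords="offset points")


def plot_ammi1(fit: AmmiFit, path: str) -> None:
    """AMMI1 biplot: mean yield (x) against IPCA1 score (y)."""
    gen, env = ammi1_coordinates(fit)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(gen["mean_yield"], gen["ipca1"], marker="o", color="tab:blue",
               label="genotypes")
    ax.scatter(env["mean_yield"], env["ipca1"], marker="^", color="tab:red",
               label="environments")
    _annotate(ax, gen["mean_yield"], gen["ipca1"], gen.index, "tab:blue")
    _annotate(ax, env["mean_yield"], env["ipca1"], env.index, "tab:red")
    ax.axvline(fit.mu, color="grey", lw=0.8, ls="--")
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    pct = fit.pct_explained[0]
    ax.set_xlabel("mean grain yield (t/ha)")
    ax.set_ylabel(f"IPCA1 score ({pct:.1f}% of GxE)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _gge_axes(fit: GgeFit):
    fig, ax = plt.subplots(figsize=(6.5, 6))
    pct = fit.pct_explained
    ax.set_xlabel(f"PC1 ({pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pct[1]:.1f}%)")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_aspect("equal", adjustable="datalim")
    return fig, ax


def plot_gge(fit: GgeFit, path: str) -> None:
    """Plain genotype + environment GGE biplot."""
    fig, ax = _gge_axes(fit)
    gs, es = fit.gen_scores, fit.env_scores
    ax.scatter(gs[:, 0], gs[:, 1], marker="o", color="tab:blue")
    ax.scatter(es[:, 0], es[:, 1], marker="^", color="tab:red")
    _annotate(ax, gs[:, 0], gs[:, 1], fit.genotypes, "tab:blue")
    _annotate(ax, es[:, 0], es[:, 1], fit.environments, "tab:red")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_discrimination(fit: GgeFit, path: str) -> None:
    """Discrimination / representativeness view: environment vectors,
    average-environment axis and concentric guide circles."""
    diag = environment_diagnostics(fit)
    fig, ax = _gge_axes(fit)
    es = fit.env_scores
    aea = es.mean(axis=0)
    aea_hat = aea / np.linalg.norm(aea)
    rmax = float(diag["vector_length"].max())
    for frac in (0.25, 0.5, 0.75, 1.0):
        ax.add_patch(plt.Circle((0, 0), frac * rmax, fill=False,
                                color="lightgrey", lw=0.7))
    for (x, y), env in zip(es, fit.environments):
        ax.plot([0, x], [0, y], color="tab:red", lw=0.9)
    _annotate(ax, es[:, 0], es[:, 1], fit.environments, "tab:red")
    span = 1.2 * rmax
    ax.plot([-span * aea_hat[0], span * aea_hat[0]],
            [-span * aea_hat[1], span * aea_hat[1]],
            color="tab:green", lw=1.2, label="AEA")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_which_won_where(fit: GgeFit, partition: SectorPartition,
                         path: str) -> None:
    """Polygon (convex hull) view with perpendicular sector rays."""
    fig, ax = _gge_axes(fit)
    gs, es = fit.gen_scores, fit.env_scores
    ax.scatter(gs[:, 0], gs[:, 1], marker="o", color="tab:blue")
    ax.scatter(es[:, 0], es[:, 1], marker="^", color="tab:red")
    _annotate(ax, gs[:, 0], gs[:, 1], fit.genotypes, "tab:blue")
    _annotate(ax, es[:, 0], es[:, 1], fit.environments, "tab:red")
    idx = [fit.genotypes.index(g) for g in partition.hull_vertices]
    poly = gs[idx + [idx[0]]]
    ax.plot(poly[:, 0], poly[:, 1], color="tab:blue", lw=1.0)
    rmax = 1.3 * float(np.abs(np.concatenate([gs, es])).max())
    for theta in partition.rays:
        ax.plot([0, rmax * math.cos(theta)], [0, rmax * math.sin(theta)],
                color="grey", lw=0.8, ls=":")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
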