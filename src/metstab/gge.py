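"""GGE (genotype main effect + genotype x environment) biplot analysis.

Centering a means matrix by environment means only leaves G + GE, the part
of the variation relevant to genotype evaluation. Its rank-2 SVD supports
the classic biplot views:

* *discrimination / representativeness* — an environment's vector length
  measures how strongly it separates genotypes; its angle with the
  average-environment axis (AEA, the direction of the mean environment
  vector) measures how representative it is of the whole trial set;
* *which-won-where* — the convex hull of the genotype markers with rays
  from the origin perpendicular to each hull edge; environments falling in
  a sector share the sector's vertex genotype as their winner.

Scaling (singular-value partitioning) modes: ``"symmetric"`` (default,
both sides carry sqrt(sigma)), ``"genotype"`` (genotype scores carry
sigma), ``"environment"`` (environment scores carry sigma). Sector
membership is checked against a scaling-free oracle — the argmax of the
rank-2 reconstruction — in the test-suite, because hull winners are a
statement about the reconstructed yields, not about any one scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .trial_data import MeansMatrix, ValidationError

__all__ = [
    "GgeFit",
    "SectorPartition",
    "fit_gge",
    "environment_diagnostics",
    "which_won_where",
    "GeometryError",
]

_SCALINGS = ("symmetric", "genotype", "environment")


class GeometryError(ValueError):
    """Degenerate biplot geometry (collinear points, zero-length axis...)."""


@dataclass
class GgeFit:
    """Rank-2 view of the environment-centered decomposition."""

    genotypes: list[str]
    environments: list[str]
    centered: np.ndarray             # G x E, zero column means
    singular_values: np.ndarray      # full spectrum
    gen_scores: np.ndarray           # G x 2 under `scaling`
    env_scores: np.ndarray           # E x 2 under `scaling`
    scaling: str

    @property
    def pct_explained(self) -> np.ndarray:
        s2 = self.singular_values ** 2
        total = s2.sum()
        return 100.0 * s2 / total if total > 0 else np.zeros_like(s2)

    def rank2_reconstruction(self) -> np.ndarray:
        """Scaling-independent rank-2 approximation of the centered matrix."""
        u, s, vt = np.linalg.svd(self.centered, full_matrices=False)
        return (u[:, :2] * s[:2]) @ vt[:2]


def fit_gge(means: MeansMatrix, scaling: str = "symmetric",
            standardize: bool = False) -> GgeFit:
    """Environment-centered SVD of a means matrix.

    ``standardize=True`` additionally divides each column by its standard
    deviation (correlation-style biplot); default is centering only, since
    yields across these trials share units and scale.
    """
    if scaling not in _SCALINGS:
        raise ValidationError(
            f"unknown scaling {scaling!r}; expected one of {_SCALINGS}"
        )
    Y = means.values.astype(float)
    Z = Y - Y.mean(axis=0, keepdims=True)
    if standardize:
        sd = Y.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValidationError("cannot standardize a constant environment")
        Z = Z / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt.T
    for n in range(2):
        k = int(np.argmax(np.abs(v[:, n])))
        if v[k, n] < 0:
            v[:, n] = -v[:, n]
            u[:, n] = -u[:, n]
    if scaling == "symmetric":
        gs, es = u[:, :2] * np.sqrt(s[:2]), v[:, :2] * np.sqrt(s[:2])
    elif scaling == "genotype":
        gs, es = u[:, :2] * s[:2], v[:, :2]
    else:
        gs, es = u[:, :2], v[:, :2] * s[:2]
    return GgeFit(list(means.genotypes), list(means.environments), Z, s,
                  gs, es, scaling)


def environment_diagnostics(fit: GgeFit) -> pd.DataFrame:
    """Vector length, AEA angle and ranks for each test environment.

    Columns: ``vector_length`` (discriminating ability, long = rank 1),
    ``angle_to_aea`` (radians in [0, pi]; representativeness, small =
    rank 1), ``discriminating_rank``, ``representativeness_rank``.
    """
    es = fit.env_scores
    aea = es.mean(axis=0)
    norm = np.linalg.norm(aea)
    scale = max(float(np.linalg.norm(es, axis=1).max()), 1e-300)
    if norm < 1e-8 * scale:
        raise GeometryError("average-environment axis has zero length")
    aea = aea / norm
    lengths = np.linalg.norm(es, axis=1)
    if np.any(lengths < 1e-12):
        angles = np.where(lengths < 1e-12, np.nan,
                          np.arccos(np.clip(es @ aea / np.maximum(lengths, 1e-300),
                                            -1, 1)))
    else:
        angles = np.arccos(np.clip(es @ aea / lengths, -1, 1))
    from scipy.stats import rankdata
    return pd.DataFrame({
        "vector_length": lengths,
        "angle_to_aea": angles,
        "discriminating_rank": rankdata(-lengths).astype(int),
        "representativeness_rank": rankdata(angles).astype(int),
    }, index=pd.Index(fit.environments, name="environment"))


@dataclass
class SectorPartition:
    """Which-won-where geometry: hull, rays, sector membership, winners."""

    hull_vertices: list[str]          # counter-clockwise genotype labels
    rays: list[float]                 # ray angles (radians, [0, 2pi)), one per edge
    env_sector: dict[str, int]        # environment -> sector index
    sector_winner: dict[int, str]     # sector index -> winning vertex genotype

    @property
    def winners_by_environment(self) -> dict[str, str]:
        return {e: self.sector_winner[s] for e, s in self.env_sector.items()}

    @property
    def occupied_sectors(self) -> dict[str, list[str]]:
        """winner genotype -> environments, for sectors holding >= 1
        environment (the mega-environment summary)."""
        out: dict[str, list[str]] = {}
        for e, s in self.env_sector.items():
            out.setdefault(self.sector_winner[s], []).append(e)
        return out


def _angle(v: np.ndarray) -> float:
    return math.atan2(float(v[1]), float(v[0])) % (2 * math.pi)


def which_won_where(fit: GgeFit) -> SectorPartition:
    """Convex-hull / sector partition of the rank-2 GGE plane.

    Sector *k* lies between the perpendicular rays of the two hull edges
    adjacent to hull vertex *k*, so vertex *k* is its winner. Environments
    are assigned to sectors by the angular position of their score vector;
    an environment exactly on a ray joins the counter-clockwise sector.
    Raises :class:`GeometryError` when the genotype markers are collinear.
    """
    gs = fit.gen_scores
    if len(fit.genotypes) < 3:
        raise GeometryError("need >= 3 genotypes for a hull")
    spread = np.linalg.svd(gs - gs.mean(axis=0), compute_uv=False)
    if spread[1] <= 1e-6 * max(spread[0], 1e-300):
        raise GeometryError("genotype markers are collinear in PC space")
    try:
        hull = ConvexHull(gs)
    except QhullError as exc:
        raise GeometryError(f"degenerate genotype configuration: {exc}") from None
    hv = list(hull.vertices)          # counter-clockwise in 2-D
    n = len(hv)

    # outward normal ray of each hull edge (hv[k] -> hv[k+1])
    rays = []
    centroid = gs[hv].mean(axis=0)
    for k in range(n):
        a, b = gs[hv[k]], gs[hv[(k + 1) % n]]
        edge = b - a
        normal = np.array([edge[1], -edge[0]])
        if normal @ ((a + b) / 2 - centroid) < 0:
            normal = -normal
        rays.append(_angle(normal))

    # sector k spans rays[k-1] -> rays[k] (ccw) and belongs to vertex hv[k]
    winners = {k: fit.genotypes[hv[k]] for k in range(n)}
    env_sector: dict[str, int] = {}
    for j, env in enumerate(fit.environments):
        a = _angle(fit.env_scores[j])
        for k in range(n):
            lo, hi = rays[k - 1], rays[k]
            span = (hi - lo) % (2 * math.pi)
            if span == 0:
                continue
            # on-ray ties (offset 0) go to the counter-clockwise sector
            if 0 <= (a - lo) % (2 * math.pi) < span:
                env_sector[env] = k
                break
        else:                          # pragma: no cover - spans cover the circle
            raise GeometryError(f"could not place environment {env!r}")
    return SectorPartition([fit.genotypes[i] for i in hv], rays,
                           env_sector, winners)
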