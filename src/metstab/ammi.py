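"""AMMI: additive main effects and multiplicative interaction.

The model for the cell-mean yield of genotype *i* in environment *j* is

    Y_ij = mu + g_i + e_j + sum_n lambda_n * alpha_ni * gamma_nj + R_ij

where ``mu`` is the grand mean, ``g``/``e`` are zero-sum additive genotype
and environment effects, and the interaction axes come from the singular
value decomposition of the double-centered matrix
``Z_ij = Y_ij - gbar_i - ebar_j + mu``. Scores are reported under symmetric
scaling — both the genotype and environment score of axis *n* carry
``sqrt(lambda_n)`` — so the per-genotype sum of squared axis-n scores equals
``lambda_n`` and the product of a genotype and environment score is the
axis-n interaction contribution.

Signs of an SVD are arbitrary; per axis we flip so that the
largest-magnitude environment score is positive. All arithmetic happens on
the cell-mean scale; sums of squares on the replicated scale (comparable to
the combined ANOVA) are ``r * lambda_n^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import MeansMatrix, ValidationError

__all__ = [
    "AmmiFit",
    "double_center",
    "fit_ammi",
    "gollob_df",
    "axis_significance",
    "ammi1_coordinates",
]


@dataclass
class AmmiFit:
    """Fitted AMMI decomposition of a genotype x environment means matrix."""

    genotypes: list[str]
    environments: list[str]
    mu: float
    g_effects: np.ndarray            # length G, sum 0
    e_effects: np.ndarray            # length E, sum 0
    singular_values: np.ndarray      # non-increasing, full spectrum kept
    gen_scores: np.ndarray           # G x n_axes_kept, symmetric scaling
    env_scores: np.ndarray           # E x n_axes_kept, symmetric scaling
    residual: np.ndarray             # G x E after the kept axes
    n_axes_kept: int
    reps: int

    @property
    def pct_explained(self) -> np.ndarray:
        """Per-axis percent of the interaction sum of squares."""
        s2 = self.singular_values ** 2
        total = s2.sum()
        return 100.0 * s2 / total if total > 0 else np.zeros_like(s2)

    @property
    def ss_axes_replicated(self) -> np.ndarray:
        """Per-axis interaction SS on the replicated (ANOVA) scale."""
        return self.reps * self.singular_values ** 2

    def reconstruct(self) -> np.ndarray:
        """mu + g + e + kept multiplicative axes + residual == data, exactly."""
        return (self.mu + self.g_effects[:, None] + self.e_effects[None, :]
                + self.gen_scores @ self.env_scores.T + self.residual)

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"IPCA{n+1}": self.gen_scores[:, n]
                for n in range(self.n_axes_kept)}
        return pd.DataFrame(cols, index=pd.Index(self.genotypes, name="genotype"))

    def env_scores_frame(self) -> pd.DataFrame:
        cols = {f"IPCA{n+1}": self.env_scores[:, n]
                for n in range(self.n_axes_kept)}
        return pd.DataFrame(cols, index=pd.Index(self.environments,
                                                 name="environment"))


def double_center(means: MeansMatrix) -> np.ndarray:
    """Interaction (residual-from-additivity) matrix
    ``Z_ij = Y_ij - gbar_i - ebar_j + mu``; all row and column sums are 0."""
    Y = means.values
    return Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) \
        + Y.mean()


def fit_ammi(means: MeansMatrix, reps: int = 1,
             n_axes: int | None = None) -> AmmiFit:
    """Fit the AMMI model to a complete means matrix.

    ``n_axes`` multiplicative axes are kept in the scores (default: all
    ``min(G-1, E-1)`` axes, leaving a zero residual); the full singular-value
    spectrum is always retained for explained-variance accounting.
    """
    Y = means.values
    G, E = Y.shape
    max_axes = min(G - 1, E - 1)
    if n_axes is None:
        n_axes = max_axes
    if not 1 <= n_axes <= max_axes:
        raise ValidationError(
            f"n_axes must lie in [1, {max_axes}] for a {G}x{E} matrix"
        )
    mu = float(Y.mean())
    g = Y.mean(axis=1) - mu
    e = Y.mean(axis=0) - mu
    Z = double_center(means)

    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    s = s[:max_axes]
    u = u[:, :max_axes]
    v = vt.T[:, :max_axes]
    # sign convention: largest-|.| environment score positive per axis
    for n in range(max_axes):
        k = int(np.argmax(np.abs(v[:, n])))
        if v[k, n] < 0:
            v[:, n] = -v[:, n]
            u[:, n] = -u[:, n]

    scale = np.sqrt(s[:n_axes])
    gen_scores = u[:, :n_axes] * scale
    env_scores = v[:, :n_axes] * scale
    residual = Z - gen_scores @ env_scores.T
    return AmmiFit(list(means.genotypes), list(means.environments), mu, g, e,
                   s, gen_scores, env_scores, residual, n_axes, reps)


def gollob_df(axis: int, n_genotypes: int, n_environments: int) -> int:
    """Gollob degrees of freedom ``G + E - 1 - 2n`` for interaction axis n
    (1-based)."""
    max_axes = min(n_genotypes - 1, n_environments - 1)
    if not 1 <= axis <= max_axes:
        raise ValidationError(
            f"axis must lie in [1, {max_axes}] for a "
            f"{n_genotypes}x{n_environments} matrix"
        )
    return n_genotypes + n_environments - 1 - 2 * axis


def axis_significance(fit: AmmiFit, error_ms: float | None = None,
                      error_df: int | None = None) -> pd.DataFrame:
    """Per-axis SS (replicated scale), Gollob df, MS and — when a pooled
    error term is available — the F-test against it.

    With means-only input there is no error term; F and p are reported as
    missing and flagged in the ``tested`` column.
    """
    G, E = len(fit.genotypes), len(fit.environments)
    rows = []
    for n in range(len(fit.singular_values)):
        df_n = gollob_df(n + 1, G, E)
        ss_n = float(fit.ss_axes_replicated[n])
        ms_n = ss_n / df_n if df_n > 0 else np.nan
        f = p = np.nan
        tested = error_ms is not None and error_df is not None and error_ms > 0
        if tested:
            f = ms_n / error_ms
            p = float(stats.f.sf(f, df_n, error_df))
        rows.append({"axis": f"IPCA{n+1}", "df": df_n, "SS": ss_n,
                     "MS": ms_n, "F": f, "p": p,
                     "pct_of_interaction": float(fit.pct_explained[n]),
                     "tested": bool(tested)})
    return pd.DataFrame(rows)


def ammi1_coordinates(fit: AmmiFit) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coordinates of the AMMI1 biplot: x = mean yield, y = IPCA1 score.

    Returns (genotype points, environment points); the grand mean ``fit.mu``
    is the conventional vertical reference line.
    """
    gen = pd.DataFrame({
        "mean_yield": fit.mu + fit.g_effects,
        "ipca1": fit.gen_scores[:, 0],
    }, index=pd.Index(fit.genotypes, name="genotype"))
    env = pd.DataFrame({
        "mean_yield": fit.mu + fit.e_effects,
        "ipca1": fit.env_scores[:, 0],
    }, index=pd.Index(fit.environments, name="environment"))
    return gen, env
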