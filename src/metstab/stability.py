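"""Yield-stability indices from a fitted AMMI model.

The AMMI stability value (ASV) of a genotype is its weighted distance from
the origin in the (IPCA1, IPCA2) score plane,

    ASV = sqrt( (w * IPCA1)^2 + IPCA2^2 ),   w = SS_IPCA1 / SS_IPCA2,

where the weight compensates for axis 1 carrying a larger share of the
interaction sum of squares (with symmetric score scaling
``w = sigma_1^2 / sigma_2^2``). Small ASV = stable across environments.

The genotype selection index combines stability and productivity:
``GSI = rank(ASV ascending) + rank(mean yield descending)``; a low GSI
flags a variety that is simultaneously stable and high-yielding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ammi import AmmiFit
from .trial_data import ValidationError

__all__ = ["asv", "rank_yield", "rank_asv", "gsi", "stability_table"]


def asv(ipca1: float | np.ndarray, ipca2: float | np.ndarray,
        ss_ipca1: float, ss_ipca2: float) -> float | np.ndarray:
    """AMMI stability value(s); invariant to sign flips of either score."""
    if ss_ipca2 <= 0:
        raise ValidationError(
            "ASV requires a positive second-axis sum of squares "
            "(degenerate rank-1 decomposition)"
        )
    w = ss_ipca1 / ss_ipca2
    out = np.sqrt((w * np.asarray(ipca1)) ** 2 + np.asarray(ipca2) ** 2)
    return float(out) if out.ndim == 0 else out


def rank_yield(mean_yields: np.ndarray) -> np.ndarray:
    """Ranks with the highest yield first (rank 1); ties share the average."""
    return rankdata(-np.asarray(mean_yields, dtype=float))


def rank_asv(asvs: np.ndarray) -> np.ndarray:
    """Ranks with the smallest (most stable) ASV first; ties averaged."""
    return rankdata(np.asarray(asvs, dtype=float))


def gsi(r_asv: np.ndarray, r_ysi: np.ndarray) -> np.ndarray:
    """Genotype selection index: elementwise rank sum, lower is better."""
    a = np.asarray(r_asv, dtype=float)
    y = np.asarray(r_ysi, dtype=float)
    if a.shape != y.shape:
        raise ValidationError("rank vectors must cover the same genotype set")
    return a + y


def stability_table(fit: AmmiFit) -> pd.DataFrame:
    """Per-genotype stability report, sorted by GSI ascending
    (ties broken by mean yield descending).

    Columns: mean_yield, ipca1, ipca2, asv, r_asv, r_ysi, gsi.
    """
    if fit.n_axes_kept < 2:
        raise ValidationError("stability table needs an AMMI fit with >= 2 axes")
    s2 = fit.singular_values[:2] ** 2
    scores = fit.gen_scores
    values = asv(scores[:, 0], scores[:, 1], float(s2[0]), float(s2[1]))
    means = fit.mu + fit.g_effects
    r_a = rank_asv(values)
    r_y = rank_yield(means)
    table = pd.DataFrame({
        "mean_yield": means,
        "ipca1": scores[:, 0],
        "ipca2": scores[:, 1],
        "asv": values,
        "r_asv": r_a,
        "r_ysi": r_y,
        "gsi": gsi(r_a, r_y),
    }, index=pd.Index(fit.genotypes, name="genotype"))
    return table.sort_values(["gsi", "mean_yield"], ascending=[True, False])
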