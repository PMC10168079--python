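"""Combined-trial ANOVA: sum-of-squares partition, F-tests, LSD/CV and
the homogeneity-of-variance check that licenses pooling environments.

Two entry points cover the two input realities of published trials:

* :func:`anova_replicated` — replicate-level data; the full combined RCBD
  table with replication-within-environment and pooled-error rows and
  F-tests against the pooled error.
* :func:`partition_ss` — a cell-means matrix plus the replicate count; only
  the treatment rows (genotype, environment, interaction) can be formed, on
  the replicated scale ``SS = r * sum of squared mean deviations``.

Percent-explained is reported over the treatment total SS_G + SS_E + SS_GEI
(excluding replication and error), so the three shares sum to 100 exactly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import (
    MeansMatrix,
    TrialObservation,
    ValidationError,
    observations_to_frame,
)

__all__ = [
    "partition_ss",
    "anova_replicated",
    "lsd_cv",
    "homogeneity_test",
    "homogeneity_test_samples",
    "per_environment_error",
    "format_anova",
]

_COLUMNS = ["source", "df", "SS", "MS", "F", "p", "pct_explained"]


def _table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return df


def partition_ss(means: MeansMatrix, reps: int) -> pd.DataFrame:
    """Treatment sum-of-squares partition from a cell-means matrix.

    ``SS_G = E*r*sum_i (gbar_i - mu)^2``, ``SS_E = G*r*sum_j (ebar_j - mu)^2``,
    ``SS_GEI = r * sum_ij (Y_ij - gbar_i - ebar_j + mu)^2``. No error or
    replication rows are possible from means alone, so F and p are absent.
    """
    if reps < 1:
        raise ValidationError("replicate count must be >= 1")
    Y = means.values
    G, E = Y.shape
    mu = Y.mean()
    gbar = Y.mean(axis=1)
    ebar = Y.mean(axis=0)
    ss_g = E * reps * float(np.sum((gbar - mu) ** 2))
    ss_e = G * reps * float(np.sum((ebar - mu) ** 2))
    Z = Y - gbar[:, None] - ebar[None, :] + mu
    ss_gei = reps * float(np.sum(Z ** 2))
    total = ss_g + ss_e + ss_gei

    def row(src, df_, ss):
        return {
            "source": src, "df": df_, "SS": ss,
            "MS": ss / df_ if df_ > 0 else np.nan,
            "F": np.nan, "p": np.nan,
            "pct_explained": 100.0 * ss / total if total > 0 else 0.0,
        }

    return _table([
        row("Genotypes", G - 1, ss_g),
        row("Environments", E - 1, ss_e),
        row("Interactions", (G - 1) * (E - 1), ss_gei),
        {"source": "Treatment total", "df": G * E - 1, "SS": total,
         "MS": np.nan, "F": np.nan, "p": np.nan,
         "pct_explained": 100.0 if total > 0 else 0.0},
    ])


def _pivot_balanced(obs: Sequence[TrialObservation]) -> np.ndarray:
    """G x E x R array; raises if the layout is incomplete or unbalanced."""
    df = observations_to_frame(obs)
    gens = list(dict.fromkeys(df["genotype"]))
    envs = list(dict.fromkeys(df["environment"]))
    reps = sorted(df["replicate"].unique())
    R = len(reps)
    cube = np.full((len(gens), len(envs), R), np.nan)
    gi = {g: i for i, g in enumerate(gens)}
    ej = {e: j for j, e in enumerate(envs)}
    rk = {r: k for k, r in enumerate(reps)}
    for o in obs:
        cube[gi[o.genotype], ej[o.environment], rk[o.replicate]] = o.yield_t_ha
    if np.isnan(cube).any():
        raise ValidationError(
            "unbalanced data: every genotype x environment x replicate cell "
            "must be present exactly once"
        )
    return cube


def anova_replicated(obs: Sequence[TrialObservation]) -> pd.DataFrame:
    """Combined RCBD-over-environments ANOVA from replicate-level data.

    Rows: environments, replication within environments (blocks), genotypes,
    genotype x environment, pooled error, total. F for genotypes,
    environments and the interaction is taken against the pooled error MS.
    """
    cube = _pivot_balanced(obs)
    G, E, R = cube.shape
    mu = cube.mean()
    gbar = cube.mean(axis=(1, 2))
    ebar = cube.mean(axis=(0, 2))
    cellbar = cube.mean(axis=2)
    blockbar = cube.mean(axis=0)          # E x R

    ss_g = E * R * float(np.sum((gbar - mu) ** 2))
    ss_e = G * R * float(np.sum((ebar - mu) ** 2))
    ss_gei = R * float(np.sum(
        (cellbar - gbar[:, None] - ebar[None, :] + mu) ** 2))
    ss_rep = G * float(np.sum((blockbar - ebar[:, None]) ** 2))
    ss_total = float(np.sum((cube - mu) ** 2))
    ss_err = ss_total - ss_g - ss_e - ss_gei - ss_rep

    df_g, df_e = G - 1, E - 1
    df_rep = E * (R - 1)
    df_gei = (G - 1) * (E - 1)
    df_total = G * E * R - 1
    df_err = df_total - df_g - df_e - df_rep - df_gei

    ms_err = ss_err / df_err if df_err > 0 else np.nan
    treat_total = ss_g + ss_e + ss_gei

    def row(src, df_, ss, tested=False, pct=False):
        ms = ss / df_ if df_ > 0 else np.nan
        f = p = np.nan
        if tested and df_err > 0 and ms_err > 0:
            f = ms / ms_err
            p = float(stats.f.sf(f, df_, df_err))
        return {"source": src, "df": df_, "SS": ss, "MS": ms, "F": f, "p": p,
                "pct_explained": (100.0 * ss / treat_total
                                  if pct and treat_total > 0 else np.nan)}

    return _table([
        row("Environments", df_e, ss_e, tested=True, pct=True),
        row("Replication(Environment)", df_rep, ss_rep),
        row("Genotypes", df_g, ss_g, tested=True, pct=True),
        row("Interactions", df_gei, ss_gei, tested=True, pct=True),
        row("Error", df_err, ss_err),
        {"source": "Total", "df": df_total, "SS": ss_total, "MS": np.nan,
         "F": np.nan, "p": np.nan, "pct_explained": np.nan},
    ])


def _single_env_rcbd(obs: Sequence[TrialObservation]) -> tuple[float, int, float]:
    """(MS_error, df_error, grand mean) of a one-environment RCBD."""
    envs = {o.environment for o in obs}
    if len(envs) != 1:
        raise ValidationError(
            f"expected observations from a single environment, got {sorted(envs)}"
        )
    cube = _pivot_balanced(obs)          # G x 1 x R
    G, _, R = cube.shape
    if R < 2:
        raise ValidationError("need >= 2 replicates for an error term")
    y = cube[:, 0, :]
    mu = y.mean()
    ss_total = float(np.sum((y - mu) ** 2))
    ss_gen = R * float(np.sum((y.mean(axis=1) - mu) ** 2))
    ss_block = G * float(np.sum((y.mean(axis=0) - mu) ** 2))
    ss_err = ss_total - ss_gen - ss_block
    df_err = (G - 1) * (R - 1)
    return max(ss_err, 0.0) / df_err, df_err, float(mu)


def lsd_cv(obs: Sequence[TrialObservation], alpha: float = 0.05
           ) -> tuple[float, float]:
    """Least significant difference and CV% for one environment's RCBD.

    ``LSD = t(1 - alpha/2, df_err) * sqrt(2 * MS_err / r)``;
    ``CV = 100 * sqrt(MS_err) / mean``.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    ms_err, df_err, mu = _single_env_rcbd(obs)
    R = len({o.replicate for o in obs})
    lsd = float(stats.t.ppf(1 - alpha / 2, df_err) * np.sqrt(2 * ms_err / R))
    cv = 100.0 * float(np.sqrt(ms_err)) / mu if mu != 0 else np.nan
    return lsd, cv


def per_environment_error(obs: Sequence[TrialObservation]
                          ) -> pd.DataFrame:
    """Per-environment RCBD error variance and df (inputs to the
    homogeneity test)."""
    df = observations_to_frame(obs)
    rows = []
    for env, sub in df.groupby("environment", sort=False):
        sub_obs = [TrialObservation(r.genotype, r.environment,
                                    int(r.replicate), r.yield_t_ha)
                   for r in sub.itertuples()]
        ms, dferr, _ = _single_env_rcbd(sub_obs)
        rows.append({"environment": env, "error_variance": ms, "df": dferr})
    return pd.DataFrame(rows)


def homogeneity_test(variances: Sequence[float], dfs: Sequence[int]
                     ) -> tuple[float, float]:
    """Bartlett's test for equality of k error variances from summaries.

    Given per-environment error variances ``s_i^2`` with ``df_i`` degrees of
    freedom, the statistic is

        T = [N ln(s_p^2) - sum_i df_i ln(s_i^2)] / C,
        C = 1 + (sum_i 1/df_i - 1/N) / (3 (k - 1)),  N = sum_i df_i,

    compared to chi-square with k - 1 df. A large p-value supports pooling
    environments into one combined analysis.
    """
    v = np.asarray(variances, dtype=float)
    d = np.asarray(dfs, dtype=float)
    if v.shape != d.shape or v.ndim != 1 or len(v) < 2:
        raise ValidationError("need >= 2 (variance, df) pairs of equal length")
    if np.any(d < 1):
        raise ValidationError("every df must be >= 1")
    if np.any(v <= 0):
        raise ValidationError("variances must be positive for Bartlett's test")
    k = len(v)
    n = d.sum()
    pooled = float((d * v).sum() / n)
    c = 1.0 + (np.sum(1.0 / d) - 1.0 / n) / (3.0 * (k - 1))
    t = float((n * np.log(pooled) - np.sum(d * np.log(v))) / c)
    t = max(t, 0.0)      # guard tiny negative round-off at equality
    return t, float(stats.chi2.sf(t, k - 1))


def homogeneity_test_samples(groups: Sequence[Sequence[float]],
                             method: str = "bartlett") -> tuple[float, float]:
    """Homogeneity test from raw residual samples; ``method`` is
    ``"bartlett"`` (default) or the outlier-robust ``"levene"``."""
    if method == "bartlett":
        stat, p = stats.bartlett(*groups)
    elif method == "levene":
        stat, p = stats.levene(*groups)
    else:
        raise ValidationError(f"unknown homogeneity method {method!r}")
    return float(stat), float(p)


def format_anova(table: pd.DataFrame, title: str = "Analysis of variance"
                 ) -> str:
    """Aligned plain-text rendering of an ANOVA table."""
    out = [title, "-" * len(title)]
    hdr = f"{'Source':<28}{'df':>5}{'SS':>10}{'MS':>9}{'F':>9}{'p':>9}{'%SS':>7}"
    out.append(hdr)
    for _, r in table.iterrows():
        def fmt(x, w, nd=2):
            return f"{x:>{w}.{nd}f}" if np.isfinite(x) else " " * (w - 1) + "."
        out.append(
            f"{r['source']:<28}{int(r['df']):>5}"
            + fmt(r["SS"], 10) + fmt(r["MS"], 9)
            + fmt(r["F"], 9) + fmt(r["p"], 9, 4) + fmt(r["pct_explained"], 7, 1)
        )
    return "\n".join(out)
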