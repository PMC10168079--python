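"""End-to-end analysis pipeline: means -> ANOVA -> AMMI -> stability -> GGE.

:func:`run_pipeline` drives every stage in order and writes, next to each
figure, the machine-readable table it was drawn from, so no result exists
only as a picture. Stage failures are re-raised with the stage name
attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ammi import ammi1_coordinates, axis_significance, fit_ammi
from .anova import (
    anova_replicated,
    format_anova,
    homogeneity_test,
    lsd_cv,
    partition_ss,
    per_environment_error,
)
from .gge import environment_diagnostics, fit_gge, which_won_where
from .plots import (
    plot_ammi1,
    plot_discrimination,
    plot_gge,
    plot_which_won_where,
)
from .stability import stability_table
from .trial_data import MeansMatrix, TrialObservation, ValidationError

log = logging.getLogger("metstab")

__all__ = ["RunConfig", "StageError", "run_pipeline"]


@dataclass
class RunConfig:
    """Options shared by all pipeline stages."""

    output_dir: Path
    reps: int = 2
    alpha: float = 0.05
    n_axes: int | None = None
    scaling: str = "symmetric"
    figure_format: str = "svg"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        self.output_dir = Path(self.output_dir)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, path: Path, float_format="%.6g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def run_pipeline(
    config: RunConfig,
    means: MeansMatrix,
    observations: Sequence[TrialObservation] | None = None,
) -> dict[str, object]:
    """Run all stages; returns the in-memory results keyed by stage.

    ``observations`` (replicate level) unlock the error-based stages:
    full combined ANOVA with F-tests, per-environment LSD/CV and the
    homogeneity-of-variance check. With means only, the treatment SS
    partition is computed with ``config.reps`` for scaling.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    fmt = config.figure_format
    results: dict[str, object] = {}

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("means")
        _write(means.to_frame(), out / "means_matrix.tsv", "%.4f")
        summary = means.to_frame()
        summary["combined_mean"] = means.genotype_means
        env_row = pd.DataFrame(
            [list(means.environment_means) + [means.grand_mean]],
            index=pd.Index(["Environment mean"], name="genotype"),
            columns=summary.columns)
        _write(pd.concat([summary, env_row]), out / "means_summary.tsv", "%.2f")
        results["means"] = means
    except Exception as exc:                     # noqa: BLE001
        raise StageError("means", exc) from exc

    try:
        stage("anova")
        if observations is not None:
            anova = anova_replicated(observations)
            err = per_environment_error(observations)
            bart_stat, bart_p = homogeneity_test(err["error_variance"],
                                                 err["df"])
            env_rows = []
            obs_by_env: dict[str, list[TrialObservation]] = {}
            for o in observations:
                obs_by_env.setdefault(o.environment, []).append(o)
            for env, sub in obs_by_env.items():
                lsd, cv = lsd_cv(sub, config.alpha)
                env_rows.append({"environment": env, "lsd": lsd, "cv_pct": cv})
            _write(pd.DataFrame(env_rows).set_index("environment"),
                   out / "environment_lsd_cv.tsv")
            (out / "homogeneity.txt").write_text(
                f"Bartlett statistic\t{bart_stat:.6g}\np_value\t{bart_p:.6g}\n")
            results["homogeneity"] = (bart_stat, bart_p)
        else:
            anova = partition_ss(means, config.reps)
        _write(anova.set_index("source"), out / "anova.tsv")
        (out / "anova.txt").write_text(format_anova(anova) + "\n")
        results["anova"] = anova
    except Exception as exc:                     # noqa: BLE001
        raise StageError("anova", exc) from exc

    try:
        stage("ammi")
        fit = fit_ammi(means, reps=config.reps, n_axes=config.n_axes)
        _write(fit.scores_frame(), out / "ammi_genotype_scores.tsv")
        _write(fit.env_scores_frame(), out / "ammi_environment_scores.tsv")
        err_ms = err_df = None
        if observations is not None:
            err_row = anova.loc[anova["source"] == "Error"].iloc[0]
            err_ms, err_df = float(err_row["MS"]), int(err_row["df"])
        _write(axis_significance(fit, err_ms, err_df).set_index("axis"),
               out / "ammi_axes.tsv")
        gen_xy, env_xy = ammi1_coordinates(fit)
        _write(gen_xy, out / "ammi1_genotype_coordinates.tsv")
        _write(env_xy, out / "ammi1_environment_coordinates.tsv")
        plot_ammi1(fit, str(out / f"ammi1_biplot.{fmt}"))
        results["ammi"] = fit
    except Exception as exc:                     # noqa: BLE001
        raise StageError("ammi", exc) from exc

    try:
        stage("stability")
        stab = stability_table(fit)
        _write(stab, out / "stability_table.tsv")
        results["stability"] = stab
    except Exception as exc:                     # noqa: BLE001
        raise StageError("stability", exc) from exc

    try:
        stage("gge")
        gfit = fit_gge(means, scaling=config.scaling)
        diag = environment_diagnostics(gfit)
        part = which_won_where(gfit)
        _write(diag, out / "gge_environment_diagnostics.tsv")
        _write(pd.DataFrame(gfit.gen_scores, columns=["PC1", "PC2"],
                            index=pd.Index(gfit.genotypes, name="genotype")),
               out / "gge_genotype_scores.tsv")
        _write(pd.DataFrame(gfit.env_scores, columns=["PC1", "PC2"],
                            index=pd.Index(gfit.environments,
                                           name="environment")),
               out / "gge_environment_scores.tsv")
        sector = pd.DataFrame({
            "sector": [part.env_sector[e] for e in gfit.environments],
            "winner": [part.winners_by_environment[e]
                       for e in gfit.environments],
        }, index=pd.Index(gfit.environments, name="environment"))
        _write(sector, out / "gge_sectors.tsv")
        plot_gge(gfit, str(out / f"gge_biplot.{fmt}"))
        plot_discrimination(gfit, str(out / f"gge_discrimination.{fmt}"))
        plot_which_won_where(gfit, part, str(out / f"gge_which_won_where.{fmt}"))
        results["gge"] = gfit
        results["sectors"] = part
    except Exception as exc:                     # noqa: BLE001
        raise StageError("gge", exc) from exc

    (out / "run_log.txt").write_text(
        "metstab version\t{v}\nnumpy\t{np}\nseed\t{seed}\nreps\t{r}\n"
        "alpha\t{a}\nscaling\t{s}\n".format(
            v=__version__, np=np.__version__, seed=config.seed,
            r=config.reps, a=config.alpha, s=config.scaling))
    return results
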