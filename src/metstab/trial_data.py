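"""Trial data containers and delimited-text I/O for multi-environment variety trials.

The two central objects are :class:`TrialObservation` (one replicate-level
plot yield) and :class:`MeansMatrix` (the complete genotype × environment
table of cell-mean yields that every downstream decomposition consumes).
A bundled 12-variety × 9-location irrigated bread-wheat trial from the
Ethiopian lowlands ships as the worked example (:func:`load_wheat_fixture`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialObservation",
    "MeansMatrix",
    "WheatFixture",
    "ValidationError",
    "ParseError",
    "ConfigurationError",
    "read_long",
    "write_long",
    "read_means",
    "write_means",
    "cell_means",
    "observations_to_frame",
    "load_wheat_fixture",
    "ENVIRONMENT_ALIASES",
    "GENOTYPE_ALIASES",
]


class ValidationError(ValueError):
    """Input data violate a structural invariant (duplicates, missing cells...)."""


class ParseError(ValueError):
    """A field could not be parsed; carries the offending line number."""


class ConfigurationError(ValueError):
    """A requested column, mode or option does not exist."""


# Canonical spellings for labels that appear in several variants in field
# reports of the bundled trial. Matching is otherwise exact (whitespace
# stripped, case preserved): silent fuzzy matching hides data errors.
ENVIRONMENT_ALIASES: Mapping[str, str] = {
    "Daro Labu": "Daro Lebu",
    "Daro labu": "Daro Lebu",
    "Daro lebu": "Daro Lebu",
    "Yabelo": "Yabello",
    "Sawena": "Sewena",
}
GENOTYPE_ALIASES: Mapping[str, str] = {
    "Ga'ambo-2": "Ga'ambo 2",
    "Ga 'ambo 2": "Ga'ambo 2",
    "Ga'ambo‐2": "Ga'ambo 2",
    "ETBW 9573": "ETBW 9578",
    "ETBW9578": "ETBW 9578",
    "ETBW9554": "ETBW 9554",
}


@dataclass(frozen=True)
class TrialObservation:
    """One replicate-level yield record.

    Parameters
    ----------
    genotype, environment : str
        Labels; stripped of surrounding whitespace, otherwise verbatim.
    replicate : int
        Positive replicate (block) index within the environment.
    yield_t_ha : float
        Grain yield in tonnes per hectare; must be non-negative.
    """

    genotype: str
    environment: str
    replicate: int
    yield_t_ha: float

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"replicate index must be >= 1, got {self.replicate}"
            )
        if not np.isfinite(self.yield_t_ha) or self.yield_t_ha < 0:
            raise ValidationError(
                f"yield must be finite and >= 0 t/ha, got {self.yield_t_ha}"
            )


@dataclass
class MeansMatrix:
    """Complete genotype × environment table of cell-mean yields (t/ha).

    ``values[i, j]`` is the mean yield of ``genotypes[i]`` in
    ``environments[j]``. The table must be complete: AMMI and GGE both
    require a full two-way array and this package deliberately does not
    impute missing cells.
    """

    genotypes: list[str]
    environments: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g, e = len(self.genotypes), len(self.environments)
        if self.values.shape != (g, e):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{g} genotypes x {e} environments"
            )
        if g < 2 or e < 2:
            raise ValidationError("need at least 2 genotypes and 2 environments")
        if len(set(self.genotypes)) != g or len(set(self.environments)) != e:
            raise ValidationError("genotype and environment labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("means matrix contains non-finite cells")

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    @property
    def grand_mean(self) -> float:
        return float(self.values.mean())

    @property
    def genotype_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    @property
    def environment_means(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def cell(self, genotype: str, environment: str) -> float:
        i = self.genotypes.index(genotype)
        j = self.environments.index(environment)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.genotypes, name="genotype"),
            columns=pd.Index(self.environments, name="environment"),
        )


@dataclass
class WheatFixture:
    """The bundled lowland irrigated bread-wheat trial: 12 varieties,
    9 locations, cell means of 2 replicates."""

    means: MeansMatrix
    replicates: int = 2


_DEFAULT_COLUMNS = {
    "genotype": "genotype",
    "environment": "environment",
    "replicate": "replicate",
    "yield": "yield_t_ha",
}


def _delimiter_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


def read_long(
    path: str | Path,
    *,
    delimiter: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> list[TrialObservation]:
    """Read replicate-level observations from a delimited long-format file.

    The file must carry a header row naming the genotype, environment,
    replicate and yield columns; ``columns`` remaps the expected names,
    e.g. ``{"yield": "GY"}``. The delimiter is inferred from the extension
    (``.csv`` → comma, otherwise tab) unless given. Row order is preserved.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(colmap)
        if unknown:
            raise ConfigurationError(f"unknown column roles: {sorted(unknown)}")
        colmap.update(columns)
    sep = _delimiter_for(path, delimiter)

    with open(path, newline="") as fh:
        header = fh.readline()
        if not header:
            raise ParseError(f"{path}: empty file")
        names = [h.strip() for h in header.rstrip("\n").split(sep)]
        for role, col in colmap.items():
            if col not in names:
                raise ConfigurationError(
                    f"{path}: required column {col!r} (role {role!r}) "
                    f"not found in header {names}"
                )
        idx = {role: names.index(col) for role, col in colmap.items()}

        obs: list[TrialObservation] = []
        seen: set[tuple[str, str, int]] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.rstrip("\n").split(sep)]
            if len(parts) < len(names):
                raise ParseError(f"{path}:{lineno}: expected {len(names)} fields")
            g = parts[idx["genotype"]]
            e = parts[idx["environment"]]
            try:
                rep = int(parts[idx["replicate"]])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer replicate "
                    f"{parts[idx['replicate']]!r}"
                ) from None
            try:
                y = float(parts[idx["yield"]])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric yield {parts[idx['yield']]!r}"
                ) from None
            key = (g, e, rep)
            if key in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate observation for "
                    f"genotype {g!r}, environment {e!r}, replicate {rep}"
                )
            seen.add(key)
            obs.append(TrialObservation(g, e, rep, y))
    return obs


def write_long(
    obs: Iterable[TrialObservation],
    path: str | Path,
    *,
    delimiter: str | None = None,
) -> None:
    """Write observations as long-format delimited text (inverse of read_long)."""
    sep = _delimiter_for(path, delimiter)
    with open(path, "w", newline="") as fh:
        fh.write(sep.join(_DEFAULT_COLUMNS[k] for k in
                          ("genotype", "environment", "replicate", "yield")) + "\n")
        for o in obs:
            fh.write(sep.join([o.genotype, o.environment, str(o.replicate),
                               repr(float(o.yield_t_ha))]) + "\n")


def observations_to_frame(obs: Iterable[TrialObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.genotype, o.environment, o.replicate, o.yield_t_ha) for o in obs],
        columns=["genotype", "environment", "replicate", "yield_t_ha"],
    )


def cell_means(
    obs: Sequence[TrialObservation],
    *,
    genotype_order: Sequence[str] | None = None,
    environment_order: Sequence[str] | None = None,
) -> MeansMatrix:
    """Average replicates into a complete genotype × environment means matrix.

    Label order defaults to first appearance in ``obs``. Every cell must have
    at least one observation; empty cells are a hard error listing the
    missing (genotype, environment) pairs.
    """
    obs = list(obs)
    if not obs:
        raise ValidationError("no observations supplied")
    gens = list(genotype_order) if genotype_order else list(
        dict.fromkeys(o.genotype for o in obs))
    envs = list(environment_order) if environment_order else list(
        dict.fromkeys(o.environment for o in obs))
    gi = {g: i for i, g in enumerate(gens)}
    ej = {e: j for j, e in enumerate(envs)}

    total = np.zeros((len(gens), len(envs)))
    count = np.zeros((len(gens), len(envs)), dtype=int)
    for o in obs:
        if o.genotype not in gi or o.environment not in ej:
            raise ValidationError(
                f"observation ({o.genotype!r}, {o.environment!r}) outside the "
                "requested label order"
            )
        total[gi[o.genotype], ej[o.environment]] += o.yield_t_ha
        count[gi[o.genotype], ej[o.environment]] += 1
    if np.any(count == 0):
        missing = [(gens[i], envs[j]) for i, j in zip(*np.nonzero(count == 0))]
        raise ValidationError(f"empty genotype x environment cells: {missing}")
    return MeansMatrix(gens, envs, total / count)


def read_means(path: str | Path, *, delimiter: str | None = None) -> MeansMatrix:
    """Read a genotype × environment matrix file: genotype labels in the
    first column, environment labels in the header row."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric matrix cell ({exc})") from None
    if df.isna().any().any():
        raise ValidationError(f"{path}: matrix contains missing cells")
    return MeansMatrix([str(g).strip() for g in df.index],
                       [str(e).strip() for e in df.columns], values)


def write_means(means: MeansMatrix, path: str | Path,
                *, delimiter: str | None = None) -> None:
    sep = _delimiter_for(path, delimiter)
    means.to_frame().to_csv(path, sep=sep)


def load_wheat_fixture() -> WheatFixture:
    """Load the bundled 12 × 9 irrigated bread-wheat yield matrix (t/ha).

    Mean grain yields of 12 released bread-wheat varieties grown with
    irrigation at 9 lowland locations of the Oromia region (Ethiopia) in a
    randomized complete block design with 2 replications; cell values are
    the replicate means to two decimals.
    """
    text = resources.files("metstab").joinpath(
        "data/wheat_oromia_yield.tsv").read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    means = MeansMatrix(list(df.index), list(df.columns),
                        df.to_numpy(dtype=float))
    return WheatFixture(means=means, replicates=2)
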