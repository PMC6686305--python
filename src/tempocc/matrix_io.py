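"""Species x year community matrices: reading, validation, and transforms.

The central container is :class:`AbundanceMatrix`, a species-by-year table of
breeding densities (territories / breeding pairs per 10 ha) from long-term
territory-mapping censuses.  Cells recorded in the source tables as ``"+"``
mark *tracing species* -- breeders too scarce to census (< 0.5 territories per
plot) -- and are carried as boolean flags until :func:`impute_tracing` replaces
them with small fixed density constants that depend on the species' body-size
class.

All downstream analyses (binary and quantitative null models, guild splits,
meta-regression covariates) consume the types defined here.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GUILDS",
    "SIZE_CLASSES",
    "TRACING_DENSITY",
    "AbundanceMatrix",
    "BinaryMatrix",
    "GuildTable",
    "DatasetCharacteristics",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "impute_tracing",
    "binarize",
    "characteristics",
    "split_by_guild",
    "exclude_rare",
    "strip_degenerate",
]

#: The nine foraging guilds used to partition assemblages.
GUILDS = frozenset(
    {
        "trunk_forager",
        "foliage_forager",
        "aerial_forager",
        "ground_forager",
        "nectar_sap_feeder",
        "omnivore",
        "plant_seed_eater",
        "raptor",
        "water_forager",
    }
)

#: Density constants (pairs per 10 ha) assumed for tracing species, by size
#: class: woodpeckers and smaller passerines, smaller raptors and corvids,
#: and large raptors respectively.
TRACING_DENSITY: Mapping[str, float] = {
    "small": 0.1,
    "medium_raptor_corvid": 0.05,
    "large_raptor": 0.004,
}

SIZE_CLASSES = frozenset(TRACING_DENSITY)


class MatrixParseError(ValueError):
    """Raised when a matrix file violates the input contract."""


@dataclass
class AbundanceMatrix:
    """A species x year density matrix with tracing metadata.

    Parameters
    ----------
    species_ids
        Row labels (unique species names).
    year_labels
        Column labels, strictly increasing integers.  Gaps are allowed and
        the years are treated as adjacent samples.
    values
        ``(S, T)`` array of non-negative densities in pairs per 10 ha.
    tracing_flags
        ``(S, T)`` boolean array marking cells that came from ``"+"`` entries.
    plot_size_ha
        Census plot area in hectares (meta-analysis covariate only).
    dataset_id
        Free-form dataset label.
    """

    species_ids: list[str]
    year_labels: list[int]
    values: np.ndarray
    tracing_flags: np.ndarray | None = None
    plot_size_ha: float = 10.0
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D species x year array")
        S, T = self.values.shape
        if self.tracing_flags is None:
            self.tracing_flags = np.zeros((S, T), dtype=bool)
        self.tracing_flags = np.asarray(self.tracing_flags, dtype=bool)
        self.species_ids = [str(s) for s in self.species_ids]
        self.year_labels = [int(y) for y in self.year_labels]
        if len(self.species_ids) != S or len(self.year_labels) != T:
            raise ValueError("label lengths inconsistent with values shape")
        if self.tracing_flags.shape != (S, T):
            raise ValueError("tracing_flags shape inconsistent with values")
        if len(set(self.species_ids)) != S:
            raise ValueError("duplicate species labels")
        if any(b <= a for a, b in zip(self.year_labels, self.year_labels[1:])):
            raise ValueError("year labels must be strictly increasing")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("densities must be finite and non-negative")
        if not self.plot_size_ha > 0:
            raise ValueError("plot_size_ha must be positive")

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "AbundanceMatrix":
        return replace(
            self,
            species_ids=list(self.species_ids),
            year_labels=list(self.year_labels),
            values=self.values.copy(),
            tracing_flags=self.tracing_flags.copy(),
        )

    def select_species(self, rows: Sequence[int]) -> "AbundanceMatrix":
        """Return the sub-matrix restricted to the given row indices."""
        rows = list(rows)
        return replace(
            self,
            species_ids=[self.species_ids[i] for i in rows],
            year_labels=list(self.year_labels),
            values=self.values[rows, :].copy(),
            tracing_flags=self.tracing_flags[rows, :].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.species_ids, columns=self.year_labels
        )


@dataclass
class BinaryMatrix:
    """Presence/absence view of an :class:`AbundanceMatrix` (x > 0 -> 1)."""

    species_ids: list[str]
    year_labels: list[int]
    values: np.ndarray
    plot_size_ha: float = 10.0
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary matrix values must be 0 or 1")
        self.values = self.values.astype(np.int8)
        if len(self.species_ids) != self.values.shape[0]:
            raise ValueError("species label length mismatch")
        if len(self.year_labels) != self.values.shape[1]:
            raise ValueError("year label length mismatch")

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GuildTable:
    """Species -> foraging guild map, with optional tracing size classes."""

    guild: dict[str, str]
    size_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g for g in self.guild.values() if g not in GUILDS}
        if bad:
            raise ValueError(f"unknown guild categories: {sorted(bad)}")
        bad = {c for c in self.size_class.values() if c not in SIZE_CLASSES}
        if bad:
            raise ValueError(f"unknown size classes: {sorted(bad)}")

    @classmethod
    def read_csv(cls, path: str | Path) -> "GuildTable":
        df = pd.read_csv(path, comment="#")
        if not {"species", "guild"} <= set(df.columns):
            raise MatrixParseError("guild table needs columns species,guild")
        guild = dict(zip(df["species"].astype(str), df["guild"].astype(str)))
        size_class: dict[str, str] = {}
        if "size_class" in df.columns:
            for sp, sc in zip(df["species"].astype(str), df["size_class"]):
                if isinstance(sc, str) and sc:
                    size_class[sp] = sc
        return cls(guild=guild, size_class=size_class)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"species": sp, "guild": g, "size_class": self.size_class.get(sp, "")}
            for sp, g in self.guild.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class DatasetCharacteristics:
    """Per-dataset covariates used in the outcome meta-analysis."""

    plot_size_ha: float
    matrix_size: int
    n_years: int
    n_species: int
    prop_zeros: float
    mean_density: float
    cv_density: float

    def as_dict(self) -> dict[str, float]:
        return {
            "plot_size_ha": self.plot_size_ha,
            "matrix_size": self.matrix_size,
            "n_years": self.n_years,
            "n_species": self.n_species,
            "prop_zeros": self.prop_zeros,
            "mean_density": self.mean_density,
            "cv_density": self.cv_density,
        }


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_matrix(
    path: str | Path,
    plot_size_ha: float,
    dataset_id: str | None = None,
) -> AbundanceMatrix:
    """Read a delimited species x year matrix.

    First column holds species labels, the header row the (integer) year
    labels.  Numeric cells are parsed exactly; the literal ``"+"`` marks a
    tracing presence and is stored as value 0 with the tracing flag set,
    pending :func:`impute_tracing`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise MatrixParseError(f"{path}: need a header row and at least one species")
    delim = _sniff_delimiter(lines[0])
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter=delim)
    rows = list(reader)
    header = rows[0][1:]
    try:
        years = [int(y) for y in header]
    except ValueError as exc:
        raise MatrixParseError(f"{path}: non-integer year label in header") from exc
    species: list[str] = []
    values = np.zeros((len(rows) - 1, len(years)))
    flags = np.zeros_like(values, dtype=bool)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(years) + 1:
            raise MatrixParseError(f"{path}: row {i + 2} has {len(row)} fields")
        sp = row[0].strip()
        if sp in species:
            raise MatrixParseError(f"{path}: duplicate species label {sp!r}")
        species.append(sp)
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "+":
                flags[i, j] = True
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise MatrixParseError(
                    f"{path}: cell ({sp}, year {years[j]}) is not numeric: {cell!r}"
                ) from exc
            if v < 0:
                raise MatrixParseError(
                    f"{path}: negative density at ({sp}, year {years[j]}): {v}"
                )
            values[i, j] = v
    return AbundanceMatrix(
        species_ids=species,
        year_labels=years,
        values=values,
        tracing_flags=flags,
        plot_size_ha=plot_size_ha,
        dataset_id=dataset_id or path.stem,
    )


def write_matrix(matrix: AbundanceMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write a matrix in the format :func:`read_matrix` reads.

    Tracing cells are written back as ``"+"`` (imputed values are not
    preserved; re-impute after reading).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["species"] + [str(y) for y in matrix.year_labels])
        for i, sp in enumerate(matrix.species_ids):
            row: list[str] = [sp]
            for j in range(matrix.n_years):
                if matrix.tracing_flags[i, j]:
                    row.append("+")
                else:
                    row.append(repr(float(matrix.values[i, j])))
            writer.writerow(row)


def impute_tracing(
    matrix: AbundanceMatrix, size_class: Mapping[str, str]
) -> AbundanceMatrix:
    """Replace tracing presences with the fixed density constants.

    ``size_class`` maps each tracing species to ``small`` (0.1 p/10 ha),
    ``medium_raptor_corvid`` (0.05) or ``large_raptor`` (0.004).  Non-tracing
    cells are never altered.
    """
    out = matrix.copy()
    tracing_rows = np.where(out.tracing_flags.any(axis=1))[0]
    for i in tracing_rows:
        sp = out.species_ids[i]
        cls = size_class.get(sp)
        if cls is None:
            raise ValueError(f"tracing species {sp!r} has no size class")
        if cls not in TRACING_DENSITY:
            raise ValueError(f"unknown size class {cls!r} for species {sp!r}")
        out.values[i, out.tracing_flags[i]] = TRACING_DENSITY[cls]
    return out


def binarize(matrix: AbundanceMatrix | BinaryMatrix) -> BinaryMatrix:
    """Presence/absence reduction: cell = 1 iff density > 0.  Idempotent."""
    return BinaryMatrix(
        species_ids=list(matrix.species_ids),
        year_labels=list(matrix.year_labels),
        values=(np.asarray(matrix.values) > 0).astype(np.int8),
        plot_size_ha=matrix.plot_size_ha,
        dataset_id=matrix.dataset_id,
    )


def characteristics(matrix: AbundanceMatrix) -> DatasetCharacteristics:
    """Dataset-level covariates (means/CV over all cells, zeros included)."""
    v = matrix.values
    mean = float(v.mean())
    if mean == 0:
        raise ValueError("all-zero matrix: CV of density undefined")
    sd = float(v.std())
    return DatasetCharacteristics(
        plot_size_ha=float(matrix.plot_size_ha),
        matrix_size=int(v.size),
        n_years=matrix.n_years,
        n_species=matrix.n_species,
        prop_zeros=float((v == 0).sum() / v.size),
        mean_density=mean,
        cv_density=sd / mean,
    )


def split_by_guild(
    matrix: AbundanceMatrix, guilds: GuildTable
) -> dict[str, AbundanceMatrix]:
    """Partition rows by foraging guild.

    Returns one sub-matrix per guild present.  Sub-matrices with fewer than
    two species are returned as well but are not analyzable by the pairwise
    null models; callers should check ``n_species >= 2``.
    """
    missing = [sp for sp in matrix.species_ids if sp not in guilds.guild]
    if missing:
        raise ValueError(f"species without guild assignment: {missing}")
    out: dict[str, AbundanceMatrix] = {}
    for g in sorted({guilds.guild[sp] for sp in matrix.species_ids}):
        rows = [i for i, sp in enumerate(matrix.species_ids) if guilds.guild[sp] == g]
        out[g] = matrix.select_species(rows)
    return out


def exclude_rare(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Drop every species whose row contains any tracing-imputed value.

    This reproduces the reduced analysis restricted to species with
    measurable (censused) abundances.
    """
    keep = [i for i in range(matrix.n_species) if not matrix.tracing_flags[i].any()]
    if len(keep) < 2:
        raise ValueError("fewer than 2 species remain after excluding rare species")
    return matrix.select_species(keep)


def strip_degenerate(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Remove all-zero rows and columns before a null-model run.

    Fixed marginals of zero admit only zero rows/columns, which freeze the
    fixed-fixed algorithms; stripping them is a no-op for the indices on the
    remaining cells.  A warning is emitted when anything is removed.
    """
    v = matrix.values
    keep_rows = np.where(v.sum(axis=1) > 0)[0]
    keep_cols = np.where(v.sum(axis=0) > 0)[0]
    if len(keep_rows) == matrix.n_species and len(keep_cols) == matrix.n_years:
        return matrix
    warnings.warn(
        f"{matrix.dataset_id}: stripping {matrix.n_species - len(keep_rows)} "
        f"all-zero rows and {matrix.n_years - len(keep_cols)} all-zero columns",
        stacklevel=2,
    )
    out = matrix.select_species(keep_rows)
    return replace(
        out,
        year_labels=[out.year_labels[j] for j in keep_cols],
        values=out.values[:, keep_cols].copy(),
        tracing_flags=out.tracing_flags[:, keep_cols].copy(),
    )
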