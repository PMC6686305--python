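"""Classify and tabulate null-model outcomes across datasets and guilds.

Each null-model run yields one of three outcomes -- aggregation (observed
co-occurrence significantly higher than the null ensemble), segregation
(significantly lower), or random.  This module collects those outcomes into
long-format records, runs the full algorithm x index grids per dataset, and
produces the frequency tables the meta-analysis consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .binary_null import binary_null_suite
from .matrix_io import (
    AbundanceMatrix,
    DatasetCharacteristics,
    GuildTable,
    binarize,
    characteristics,
    split_by_guild,
    strip_degenerate,
)
from .quant_null import quant_null_suite, scale_to_counts

__all__ = [
    "BINARY_GRID",
    "QUANT_GRID",
    "OutcomeRecord",
    "records_to_frame",
    "tabulate",
    "binary_combination_grid",
    "quant_combination_grid",
    "guild_outcome_records",
]

log = logging.getLogger(__name__)

#: The five valid binary (algorithm, index) combinations.  SIM9 cannot be
#: paired with the V-ratio because fixed marginals do not randomize it.
BINARY_GRID = (
    ("SIM2", "CHECKER"),
    ("SIM2", "C_SCORE"),
    ("SIM2", "V_RATIO"),
    ("SIM9", "CHECKER"),
    ("SIM9", "C_SCORE"),
)

#: The six quantitative combinations.
QUANT_GRID = tuple(
    (alg, idx) for alg in ("IT", "IA") for idx in ("CA_ST", "AA_ST", "MA")
)

OUTCOMES = ("aggregation", "segregation", "random")


@dataclass
class OutcomeRecord:
    """One (dataset, level, guild, algorithm, index) -> outcome row."""

    dataset_id: str
    level: str  # assemblage | guild
    guild: str | None
    model_type: str  # binary | quantitative
    algorithm: str
    index: str
    outcome: str
    covariates: DatasetCharacteristics | None = None
    #: the underlying null-model run, when available (not serialized by
    #: default; see ``records_to_frame(details=True)``)
    result: object | None = None

    def __post_init__(self) -> None:
        if self.level not in ("assemblage", "guild"):
            raise ValueError(f"unknown level {self.level!r}")
        if (self.guild is not None) != (self.level == "guild"):
            raise ValueError("guild must be set iff level == 'guild'")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


def records_to_frame(
    records: Iterable[OutcomeRecord], details: bool = False
) -> pd.DataFrame:
    """Long-format outcome table; ``details=True`` adds the observed index
    value and tail probabilities of each underlying null-model run."""
    rows = []
    for r in records:
        row = {
            "dataset_id": r.dataset_id,
            "level": r.level,
            "guild": r.guild,
            "model_type": r.model_type,
            "algorithm": r.algorithm,
            "index": r.index,
            "outcome": r.outcome,
        }
        if details and r.result is not None:
            row.update(
                observed=r.result.observed,
                p_low=r.result.p_low,
                p_high=r.result.p_high,
                p_two=r.result.p_two,
                n_sim=r.result.n_sim,
            )
        if r.covariates is not None:
            row.update(r.covariates.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def tabulate(
    records: Iterable[OutcomeRecord] | pd.DataFrame,
    by: Sequence[str] = ("model_type",),
) -> pd.DataFrame:
    """Outcome counts and percentages per group.

    Percentages are rounded to 0.1 and sum to 100 within each group up to
    that rounding.  Groups with no records are omitted with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no outcome records to tabulate")
    by = list(by)
    rows = []
    for key, grp in df.groupby(by, dropna=False):
        if grp.empty:  # pragma: no cover - groupby drops empty groups
            warnings.warn(f"empty group {key!r} omitted")
            continue
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        row = dict(zip(by, key))
        row["n"] = n
        for oc in OUTCOMES:
            cnt = int((grp["outcome"] == oc).sum())
            row[f"n_{oc}"] = cnt
            row[f"pct_{oc}"] = round(100.0 * cnt / n, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def binary_combination_grid(
    matrix: AbundanceMatrix,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    level: str = "assemblage",
    guild: str | None = None,
    covariates: DatasetCharacteristics | None = None,
) -> list[OutcomeRecord]:
    """Run all five binary combinations on one dataset -> 5 records.

    Over 19 assemblages this yields the 95 binary simulations of the full
    protocol.
    """
    clean = strip_degenerate(matrix)
    if covariates is None:
        covariates = characteristics(matrix)
    B = binarize(clean)
    results = binary_null_suite(B, n_sim=n_sim, alpha=alpha, rng=rng)
    return [
        OutcomeRecord(
            dataset_id=matrix.dataset_id,
            level=level,
            guild=guild,
            model_type="binary",
            algorithm=alg,
            index=idx,
            outcome=results[(alg, idx)].outcome,
            covariates=covariates,
            result=results[(alg, idx)],
        )
        for alg, idx in BINARY_GRID
    ]


def quant_combination_grid(
    matrix: AbundanceMatrix,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    scale_factor: float = 250.0,
    level: str = "assemblage",
    guild: str | None = None,
    covariates: DatasetCharacteristics | None = None,
) -> list[OutcomeRecord]:
    """Run all six quantitative combinations on one dataset -> 6 records.

    Over 19 assemblages this yields the 114 quantitative simulations of the
    full protocol.
    """
    clean = strip_degenerate(matrix)
    if covariates is None:
        covariates = characteristics(matrix)
    counts = scale_to_counts(clean, scale_factor=scale_factor)
    results = quant_null_suite(counts, n_sim=n_sim, alpha=alpha, rng=rng)
    return [
        OutcomeRecord(
            dataset_id=matrix.dataset_id,
            level=level,
            guild=guild,
            model_type="quantitative",
            algorithm=alg,
            index=idx,
            outcome=results[(alg, idx)].outcome,
            covariates=covariates,
            result=results[(alg, idx)],
        )
        for alg, idx in QUANT_GRID
    ]


def guild_outcome_records(
    matrix: AbundanceMatrix,
    guilds: GuildTable,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    scale_factor: float = 250.0,
) -> tuple[list[OutcomeRecord], list[tuple[str, str]]]:
    """Quantitative grid per analyzable guild sub-matrix.

    Guild sub-matrices with fewer than two species or two occupied years are
    skipped; the returned eligibility log lists ``(guild, reason)`` for each
    skipped unit.
    """
    covariates = characteristics(matrix)
    records: list[OutcomeRecord] = []
    skipped: list[tuple[str, str]] = []
    for g, sub in split_by_guild(matrix, guilds).items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clean = strip_degenerate(sub) if sub.values.sum() > 0 else sub
        if clean.n_species < 2:
            skipped.append((g, f"{clean.n_species} species"))
            log.info("%s: guild %s skipped (%d species)", matrix.dataset_id, g,
                     clean.n_species)
            continue
        if clean.n_years < 2:
            skipped.append((g, f"{clean.n_years} occupied years"))
            continue
        records.extend(
            quant_combination_grid(
                clean,
                n_sim=n_sim,
                alpha=alpha,
                rng=rng,
                scale_factor=scale_factor,
                level="guild",
                guild=g,
                covariates=covariates,
            )
        )
    return records, skipped
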