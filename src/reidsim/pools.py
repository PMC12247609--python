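"""Candidate-pool sizes from census strata.

The realistic gallery sizes for a reidentification attack come from
demography, not from the study sample: everyone in the surrounding
population who matches the demographics shared with the data (age
range, gender, race/ethnicity) is a candidate.  Pool size is simply
``base_population x stratum fraction``, rounded to a stated
granularity.  A packaged example table carries the 2022 census figures
for the Pittsburgh metropolitan area (base population 2,349,172) used
by the reference sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Stratum",
    "StratumTable",
    "PoolSize",
    "pool_size",
    "pools_to_sweep_sizes",
    "read_strata_csv",
    "example_strata",
    "EXAMPLE_BASE_POPULATION",
]

# Base population of the packaged example table (Pittsburgh MSA, 2022).
EXAMPLE_BASE_POPULATION = 2_349_172

_ROUNDING_GRANULARITY = {"nearest-1000": 1000, "nearest-5000": 5000, "none": None}


@dataclass(frozen=True)
class Stratum:
    label: str
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")


@dataclass(frozen=True)
class StratumTable:
    base_population: int
    strata: tuple[Stratum, ...]

    def __post_init__(self) -> None:
        if self.base_population < 1:
            raise ValueError("base_population must be >= 1")

    @classmethod
    def from_pairs(
        cls, base_population: int, pairs: Iterable[tuple[str, float]]
    ) -> "StratumTable":
        return cls(
            base_population=base_population,
            strata=tuple(Stratum(label, float(f)) for label, f in pairs),
        )


@dataclass(frozen=True)
class PoolSize:
    label: str
    exact: float
    rounded: int
    rounding_rule: str


def pool_size(base: int, fraction: float, rounding: str = "nearest-1000", label: str = "") -> PoolSize:
    """Candidate-pool size for one stratum.

    ``rounding`` is one of ``nearest-1000``, ``nearest-5000`` or
    ``none``; both the exact product and the rounded figure are kept,
    because published pool sizes mix granularities.
    """
    if base < 1:
        raise ValueError("base must be >= 1")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if rounding not in _ROUNDING_GRANULARITY:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    exact = base * fraction
    gran = _ROUNDING_GRANULARITY[rounding]
    rounded = int(round(exact)) if gran is None else int(round(exact / gran) * gran)
    return PoolSize(label=label, exact=exact, rounded=rounded, rounding_rule=rounding)


def pools_to_sweep_sizes(
    table: StratumTable,
    extra_sizes: Sequence[int] = (),
    rounding: str = "nearest-1000",
    per_stratum_rounding: dict[str, str] | None = None,
) -> list[int]:
    """Sorted, deduplicated union of stratum pool sizes and extra sizes.

    ``extra_sizes`` carries gallery sizes that do not come from a
    stratum fraction (the study sample size, or published figures with
    no printed fraction).
    """
    sizes = set(int(s) for s in extra_sizes)
    for stratum in table.strata:
        rule = (per_stratum_rounding or {}).get(stratum.label, rounding)
        sizes.add(pool_size(table.base_population, stratum.fraction, rule, stratum.label).rounded)
    return sorted(sizes)


def read_strata_csv(path: str | Path) -> pd.DataFrame:
    """Read a stratum table CSV with columns ``label, fraction``."""
    df = pd.read_csv(path)
    missing = {"label", "fraction"} - set(df.columns)
    if missing:
        raise ValueError(f"stratum CSV missing columns: {sorted(missing)}")
    return df


def example_strata() -> StratumTable:
    """The packaged Pittsburgh-area example table."""
    with resources.files("reidsim.data").joinpath("pittsburgh_strata.csv").open() as fh:
        df = read_strata_csv(fh)
    return StratumTable.from_pairs(
        EXAMPLE_BASE_POPULATION, zip(df["label"], df["fraction"])
    )
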