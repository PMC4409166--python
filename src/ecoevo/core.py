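"""Shared domain types, growth computations and table I/O.

The experiment's unit of observation is the *microcosm*: one tube holding a
defined species composition in one environment.  Biomass yield of a growth
period is measured as maximum optical density (595 nm) minus the starting
optical density; generations are counted as summed log2 fold-changes of OD
over serial-transfer periods.  All tables are plain CSV (UTF-8, header row,
"." decimal separator) and are handled as pandas DataFrames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The three selection environments: standard beech-leaf tea, beech tea
#: buffered to pH 5, and spruce-needle tea.
ENVIRONMENTS = ("beech", "ph5", "spruce")

#: Weeks at which yields were recorded after transfer into the environments
#: (0 = first growth period in the new environment, 5 = final week).
OBSERVED_WEEKS = (0, 1, 2, 4, 5)


def normalize_environment(label: str) -> str:
    """Return the canonical lowercase environment label.

    Labels are case-insensitive on input ("pH5" -> "ph5"); anything outside
    the three known environments raises ``ValueError``.
    """
    canon = str(label).strip().lower()
    if canon not in ENVIRONMENTS:
        raise ValueError(
            f"unknown environment label {label!r}; expected one of {ENVIRONMENTS}"
        )
    return canon


@dataclass(frozen=True)
class Composition:
    """A species composition: which species co-occur in a community.

    ``partition_set`` records which random partition the composition came
    from ("mono" for monocultures, "full" for the 12-species mixture,
    otherwise e.g. "2a"/"2b" for the two independent partitions at
    richness 2).
    """

    composition_id: str
    members: frozenset = field(default_factory=frozenset)
    partition_set: str = "mono"

    def __post_init__(self):
        if not self.members:
            raise ValueError("composition must have at least one member")
        object.__setattr__(self, "members", frozenset(self.members))

    @property
    def richness(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Microcosm:
    """One culture tube: a composition grown in one environment, one replicate."""

    microcosm_id: str
    composition_id: str
    environment: str
    replicate: int

    def __post_init__(self):
        object.__setattr__(self, "environment", normalize_environment(self.environment))


@dataclass(frozen=True)
class TransferRecord:
    """Summary of one serial-transfer growth period of one microcosm."""

    microcosm_id: str
    period_index: int
    od_start: float
    od_max: float
    od_end: float

    def __post_init__(self):
        if self.od_max < self.od_start:
            raise ValueError("od_max must be >= od_start")
        if self.od_end <= 0:
            raise ValueError("od_end must be positive (needed for log ratio)")

    @classmethod
    def from_readings(
        cls, microcosm_id: str, period_index: int, readings: Sequence[float]
    ) -> "TransferRecord":
        if len(readings) == 0:
            raise ValueError("no OD readings")
        return cls(
            microcosm_id=microcosm_id,
            period_index=int(period_index),
            od_start=float(readings[0]),
            od_max=float(max(readings)),
            od_end=float(readings[-1]),
        )


def compute_yield(readings: Sequence[float]) -> float:
    """Biomass yield of one growth period: max OD minus starting OD.

    The first reading is the starting OD.  Negative raw yields (max below
    start, measurement noise) are clamped to zero since yields are biomass
    gains and downstream additive sums assume non-negativity.
    """
    readings = list(readings)
    if not readings:
        raise ValueError("no OD readings")
    return max(0.0, float(max(readings)) - float(readings[0]))


def count_generations(
    transfer_history: Iterable[TransferRecord], floor_zero: bool = False
) -> float:
    """Number of doublings over a transfer history: sum of log2(OD.end/OD.start).

    Periods where the culture shrank contribute negatively by default,
    applying the log-ratio formula literally; with ``floor_zero=True``
    per-period contributions are floored at zero instead.
    """
    total = 0.0
    for rec in transfer_history:
        if rec.od_start <= 0:
            raise ValueError(
                f"undefined doubling count: od_start={rec.od_start} in period "
                f"{rec.period_index} of {rec.microcosm_id}"
            )
        contrib = math.log2(rec.od_end / rec.od_start)
        if floor_zero:
            contrib = max(0.0, contrib)
        total += contrib
    return total


# ---------------------------------------------------------------------------
# Table I/O.  All tables are comma-separated, UTF-8, one header row.
# ---------------------------------------------------------------------------

YIELD_COLUMNS = ["microcosm_id", "composition_id", "environment", "replicate", "week", "yield"]
DESIGN_COLUMNS = ["composition_id", "species_id", "richness", "partition_set"]
SURVIVAL_COLUMNS = ["microcosm_id", "composition_id", "environment", "species_id", "survived"]
ISOLATE_COLUMNS = [
    "microcosm_id", "composition_id", "environment", "species_id", "yield", "ancestral_yield",
]
TRANSFER_COLUMNS = ["microcosm_id", "period_index", "reading_index", "od"]

_FLOAT_FORMAT = "%.6f"


def _require_columns(frame: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def read_yield_table(path) -> pd.DataFrame:
    """Read yields.csv: one row per microcosm per week.

    Community yields (A) and monoculture yields (a) share this layout;
    richness is recovered by joining on the design table.  Environment
    labels are normalised to canonical lowercase; duplicate
    (microcosm, week) rows raise.
    """
    frame = pd.read_csv(path)
    _require_columns(frame, YIELD_COLUMNS, "yield table")
    frame = frame.copy()
    frame["environment"] = frame["environment"].map(normalize_environment)
    frame["week"] = frame["week"].astype(int)
    frame["replicate"] = frame["replicate"].astype(int)
    frame["yield"] = frame["yield"].astype(float)
    dup = frame.duplicated(subset=["microcosm_id", "week"])
    if dup.any():
        bad = frame.loc[dup, ["microcosm_id", "week"]].iloc[0]
        raise ValueError(
            f"duplicate yield row for microcosm {bad['microcosm_id']!r} week {bad['week']}"
        )
    if (frame["yield"] < 0).any():
        raise ValueError("yield table contains negative yields")
    return frame[YIELD_COLUMNS]


def write_yield_table(frame: pd.DataFrame, path) -> None:
    _require_columns(frame, YIELD_COLUMNS, "yield table")
    frame[YIELD_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_design_table(path) -> pd.DataFrame:
    """Read design.csv: one row per (composition, member species)."""
    frame = pd.read_csv(path)
    _require_columns(frame, DESIGN_COLUMNS, "design table")
    frame = frame.copy()
    frame["richness"] = frame["richness"].astype(int)
    sizes = frame.groupby("composition_id")["species_id"].nunique()
    declared = frame.groupby("composition_id")["richness"].first()
    bad = sizes[sizes != declared.loc[sizes.index]]
    if len(bad):
        raise ValueError(
            f"declared richness disagrees with member count for {list(bad.index)[:5]}"
        )
    return frame[DESIGN_COLUMNS]


def write_design_table(frame: pd.DataFrame, path) -> None:
    _require_columns(frame, DESIGN_COLUMNS, "design table")
    frame[DESIGN_COLUMNS].to_csv(path, index=False)


def read_survival_table(path) -> pd.DataFrame:
    """Read survival.csv: end-of-experiment persistence, one row per
    (microcosm, member species), ``survived`` in {0, 1}."""
    frame = pd.read_csv(path)
    _require_columns(frame, SURVIVAL_COLUMNS, "survival table")
    frame = frame.copy()
    frame["environment"] = frame["environment"].map(normalize_environment)
    frame["survived"] = frame["survived"].astype(int)
    if not frame["survived"].isin([0, 1]).all():
        raise ValueError("survived must be 0 or 1")
    return frame[SURVIVAL_COLUMNS]


def write_survival_table(frame: pd.DataFrame, path) -> None:
    _require_columns(frame, SURVIVAL_COLUMNS, "survival table")
    frame[SURVIVAL_COLUMNS].to_csv(path, index=False)


def read_isolate_table(path) -> pd.DataFrame:
    """Read isolates.csv: week-5 monoculture yields of isolates regrown
    alone (b), with the matched ancestral yield, for surviving species only."""
    frame = pd.read_csv(path)
    _require_columns(frame, ISOLATE_COLUMNS, "isolate table")
    frame = frame.copy()
    frame["environment"] = frame["environment"].map(normalize_environment)
    frame["yield"] = frame["yield"].astype(float)
    frame["ancestral_yield"] = frame["ancestral_yield"].astype(float)
    return frame[ISOLATE_COLUMNS]


def write_isolate_table(frame: pd.DataFrame, path) -> None:
    _require_columns(frame, ISOLATE_COLUMNS, "isolate table")
    frame[ISOLATE_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_transfer_table(path) -> pd.DataFrame:
    """Read transfers.csv: long-format OD readings per microcosm-period."""
    frame = pd.read_csv(path)
    _require_columns(frame, TRANSFER_COLUMNS, "transfer table")
    return frame[TRANSFER_COLUMNS]


def write_transfer_table(frame: pd.DataFrame, path) -> None:
    _require_columns(frame, TRANSFER_COLUMNS, "transfer table")
    frame[TRANSFER_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def transfer_records(transfer_frame: pd.DataFrame) -> list[TransferRecord]:
    """Collapse long-format OD readings to one TransferRecord per period."""
    records = []
    grouped = transfer_frame.sort_values("reading_index").groupby(
        ["microcosm_id", "period_index"], sort=True
    )
    for (mid, period), grp in grouped:
        records.append(TransferRecord.from_readings(mid, period, grp["od"].to_numpy()))
    return records
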