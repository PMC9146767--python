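"""Exhaustive sweeps and current-interval calibration statistics.

An exhaustive sweep solves the forward model for every penetration
combination of one sheet pair (2^(2n) solves for n-tip sheets) and collects
the inter-sheet currents.  From the sweep this module derives the material
of a calibration table: nested current distributions (by total unpenetrated
count, by transdermal state, or by single-sheet maximum), per-state mean
currents, and the midpoint interval division that maps a measured current
back to a state.  Counting heat maps and per-interval summaries quantify how
much information each current interval retains as arrays grow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import SolverConfig
from .solver import CurrentRecord, GridModel, solve_pair_current
from .states import (
    PenetrationState,
    TransdermalState,
    all_states,
    canonical_state,
    conductive_states,
    pair_flags_from_index,
    state_rank,
    substate_count,
)

__all__ = [
    "SweepResult",
    "IntervalRow",
    "CalibrationTable",
    "sweep_pair",
    "group_by",
    "state_means",
    "interval_boundaries",
    "heatmap_counts",
    "interval_summary",
    "distinct_totals_per_interval",
]

GroupKey = Literal["N_total", "state", "N_max_s"]


@dataclass
class SweepResult:
    """All 2^(2n) inter-sheet currents for one sheet pair."""

    pair: tuple[int, int]
    n: int  # tips per sheet
    records: list[CurrentRecord]

    def validate_complete(self) -> None:
        expected = 4**self.n
        if len(self.records) != expected:
            raise ValueError(
                f"incomplete sweep: {len(self.records)} records, expected {expected}"
            )
        indices = {r.combination_index for r in self.records}
        if indices != set(range(expected)):
            raise ValueError("sweep combination indices are not unique/complete")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": [f"{r.pair[0]}-{r.pair[1]}" for r in self.records],
                "combination_index": [r.combination_index for r in self.records],
                "state_low": [r.state.low for r in self.records],
                "state_high": [r.state.high for r in self.records],
                "current_uA": [r.current_uA for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path, n: int) -> "SweepResult":
        df = pd.read_csv(path)
        records = []
        for row in df.itertuples(index=False):
            a, b = row.pair.split("-")
            records.append(
                CurrentRecord(
                    pair=(int(a), int(b)),
                    state=TransdermalState(int(row.state_low), int(row.state_high), n),
                    combination_index=int(row.combination_index),
                    current_uA=float(row.current_uA),
                )
            )
        pair = records[0].pair if records else (0, 1)
        return cls(pair=pair, n=n, records=records)


def sweep_pair(
    grid: GridModel,
    source: int,
    ground: int,
    config: SolverConfig | None = None,
    floating: bool = True,
) -> SweepResult:
    """Solve the forward model for every penetration combination of a pair.

    Tips of non-tested sheets are held penetrated (flag 0); those sheets
    float by default.  Combinations are enumerated in binary-counting order
    so the record ordering is reproducible.
    """
    g = grid.geometry
    n = g.tips_per_sheet
    records = []
    for index in range(4**n):
        pf = pair_flags_from_index(index, n)
        flags = np.zeros((g.n_sheets, n), dtype=np.int8)
        flags[source] = pf[0]
        flags[ground] = pf[1]
        records.append(
            solve_pair_current(
                grid,
                PenetrationState(flags),
                source,
                ground,
                config=config,
                combination_index=index,
                floating=floating,
            )
        )
    return SweepResult(pair=(source, ground), n=n, records=records)


def _pooled_label(state: TransdermalState) -> str:
    return state.label  # "n+" already pools all nonconductive states


def group_by(sweep: SweepResult, key: GroupKey) -> pd.DataFrame:
    """Nest sweep currents by total count, state, or single-sheet maximum.

    Returns the record table with a ``group`` column; nonconductive states
    pool into the "n+" class when keying by state.
    """
    sweep.validate_complete()
    df = sweep.to_frame()
    if key == "N_total":
        df["group"] = df.state_low + df.state_high
    elif key == "N_max_s":
        df["group"] = df.state_high
    elif key == "state":
        df["group"] = [
            TransdermalState(lo, hi, sweep.n).label
            for lo, hi in zip(df.state_low, df.state_high)
        ]
    else:
        raise ValueError(f"unknown grouping key {key!r}")
    return df


def state_means(sweep: SweepResult) -> pd.DataFrame:
    """Mean current per canonical state, in rank order; "n+" pooled last."""
    df = group_by(sweep, "state")
    order = [s.label for s in all_states(sweep.n)]
    means = df.groupby("group")["current_uA"].mean()
    out = pd.DataFrame(
        {"state": order, "mean_uA": [means[label] for label in order]}
    )
    return out


@dataclass(frozen=True)
class IntervalRow:
    """One current interval and the state (or state group) it maps to."""

    interval: int
    label: str                     # e.g. "1-2", "0-1, 1-1", "3+"
    current_low: float
    current_high: float | None     # None: half-open first interval
    interval_length: float | None

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(s.strip() for s in self.label.split(","))

    def member_states(self, n: int) -> list[TransdermalState]:
        """Canonical states mapped to this interval ("n+" expands fully)."""
        out: list[TransdermalState] = []
        for lab in self.states:
            if lab.endswith("+"):
                out.extend(TransdermalState(k, n, n) for k in range(n + 1))
            else:
                lo, hi = lab.split("-")
                out.append(TransdermalState(int(lo), int(hi), n))
        return out

    def contains(self, current: float) -> bool:
        if current < self.current_low:
            return False
        return self.current_high is None or current < self.current_high


@dataclass
class CalibrationTable:
    """Ordered current intervals mapping test currents to transdermal states.

    Intervals are ordered by descending current; interval 1 is half-open
    above.  ``source`` records whether the table was transcribed from the
    reference device study ("packaged") or computed from a sweep.
    """

    array: str               # e.g. "3x3"
    n: int                   # tips per sheet
    pair_distance: int       # in sheet pitches (1 = adjacent)
    rows: list[IntervalRow]
    source: str = "computed"

    def __post_init__(self) -> None:
        lows = [r.current_low for r in self.rows]
        if any(b <= a for a, b in zip(lows, lows[1:])):
            pass  # rows are descending in current; ascending order is invalid
        if lows != sorted(lows, reverse=True):
            raise ValueError("intervals must be ordered by descending current")
        labels = [s for r in self.rows for s in r.states]
        if len(labels) != len(set(labels)):
            raise ValueError("each state may appear in exactly one interval")

    def find_intervals(self, current: float) -> list[IntervalRow]:
        """All intervals containing the current (printed tables may overlap)."""
        if current < 0:
            raise ValueError("current must be nonnegative")
        return [r for r in self.rows if r.contains(current)]

    # --- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "array": self.array,
            "n": self.n,
            "pair_distance": self.pair_distance,
            "source": self.source,
            "rows": [
                {
                    "interval": r.interval,
                    "label": r.label,
                    "current_low": r.current_low,
                    "current_high": r.current_high,
                    "interval_length": r.interval_length,
                }
                for r in self.rows
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationTable":
        return cls(
            array=d["array"],
            n=d["n"],
            pair_distance=d["pair_distance"],
            source=d.get("source", "computed"),
            rows=[
                IntervalRow(
                    interval=r["interval"],
                    label=r["label"],
                    current_low=r["current_low"],
                    current_high=r["current_high"],
                    interval_length=r["interval_length"],
                )
                for r in d["rows"]
            ],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationTable":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": [r.interval for r in self.rows],
                "state": [r.label for r in self.rows],
                "current_low_uA": [r.current_low for r in self.rows],
                "current_high_uA": [r.current_high for r in self.rows],
                "interval_length_uA": [r.interval_length for r in self.rows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def interval_boundaries(
    means: pd.DataFrame,
    array: str = "",
    pair_distance: int = 1,
) -> CalibrationTable:
    """Midpoint interval division from a table of per-state mean currents.

    Adjacent ranked states split at the midpoint of their mean currents.
    The first interval is half-open above; the pooled nonconductive class
    closes at 0 below and at the midpoint between the lowest conductive mean
    and the pooled nonconductive mean above.
    """
    labels = list(means["state"])
    mu = list(means["mean_uA"])
    if any(b >= a for a, b in zip(mu, mu[1:])):
        raise ValueError("adjacent state means tie or invert: degenerate calibration")
    boundaries = [(a + b) / 2 for a, b in zip(mu, mu[1:])]
    n = max(
        int(lab[:-1]) if lab.endswith("+") else int(lab.split("-")[1])
        for lab in labels
    )
    rows = []
    for k, lab in enumerate(labels):
        high = None if k == 0 else boundaries[k - 1]
        low = boundaries[k] if k < len(boundaries) else 0.0
        rows.append(
            IntervalRow(
                interval=k + 1,
                label=lab,
                current_low=low,
                current_high=high,
                interval_length=None if high is None else high - low,
            )
        )
    return CalibrationTable(
        array=array or f"?x{n}", n=n, pair_distance=pair_distance, rows=rows
    )


def _axis_value(state: TransdermalState, axis: GroupKey):
    if axis == "state":
        return state.label
    if axis == "N_total":
        return state.n_total
    if axis == "N_max_s":
        return state.n_max_s
    raise ValueError(f"unknown axis {axis!r}")


def heatmap_counts(
    table: CalibrationTable,
    n: int,
    axis: GroupKey = "N_total",
    mode: Literal["combinatorial", "by_current"] = "combinatorial",
    sweep: SweepResult | None = None,
) -> pd.DataFrame:
    """Event counts per (current interval × axis value).

    ``combinatorial`` mode counts position-specific assignments exactly from
    the table's state→interval mapping (solver-independent, deterministic);
    ``by_current`` bins an actual sweep's records by their computed current,
    reproducing the solver's occasional interval bleed-over for large arrays.
    Rows: interval numbers; columns: axis values; grand total 2^(2n).
    """
    if axis == "state":
        cols: list = [s.label for s in all_states(n)]
    elif axis == "N_total":
        cols = list(range(2 * n + 1))
    else:
        cols = list(range(n + 1))
    counts = pd.DataFrame(
        0, index=[r.interval for r in table.rows], columns=cols, dtype=int
    )
    counts.index.name = "interval"

    if mode == "combinatorial":
        for row in table.rows:
            for st in row.member_states(n):
                counts.loc[row.interval, _axis_value(st, axis)] += substate_count(st)
    elif mode == "by_current":
        if sweep is None:
            raise ValueError("by_current mode needs a SweepResult")
        sweep.validate_complete()
        for rec in sweep.records:
            hits = table.find_intervals(rec.current_uA)
            if not hits:
                raise ValueError(
                    f"current {rec.current_uA:.3f} μA falls outside the table"
                )
            counts.loc[hits[0].interval, _axis_value(rec.state, axis)] += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return counts


def interval_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-interval probability distribution, mean and deviation of the axis.

    Probabilities are each row normalized by its total; mean and deviation
    are the mean and population standard deviation of the (numeric) axis
    value under that distribution.  Empty intervals are flagged.
    """
    values = np.asarray(counts.columns, dtype=float)
    out = []
    for interval, row in counts.iterrows():
        total = row.sum()
        if total == 0:
            out.append(
                {"interval": interval, "mean": np.nan, "deviation": np.nan,
                 "empty": True, "probabilities": {}}
            )
            continue
        p = row.to_numpy(dtype=float) / total
        mean = float(np.sum(p * values))
        dev = float(np.sqrt(np.sum(p * (values - mean) ** 2)))
        out.append(
            {
                "interval": interval,
                "mean": mean,
                "deviation": dev,
                "empty": False,
                "probabilities": {
                    int(v): float(q) for v, q in zip(values, p) if q > 0
                },
            }
        )
    return pd.DataFrame(out).set_index("interval")


def distinct_totals_per_interval(table: CalibrationTable, n: int) -> pd.Series:
    """Number of distinct N_total values mapped to each current interval."""
    return pd.Series(
        {
            row.interval: len({st.n_total for st in row.member_states(n)})
            for row in table.rows
        },
        name="distinct_totals",
    )
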