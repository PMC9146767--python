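"""Packaged reference calibration tables for the 3x3, 4x4 and 6x6 arrays.

The tables map current intervals (μA, under a 1 V drive) to transdermal
states or state groups, one block per tested pair distance.  They are
transcribed verbatim from the reference device study, including printed
inconsistencies (an overlapping interval pair in the 3x3 adjacent-pair block
and a few interval-length entries that disagree with the printed bounds);
interval lookup resolves overlaps in favour of the higher-current interval
and flags the ambiguity.
"""

from __future__ import annotations

import json
from importlib import resources

from .stats import CalibrationTable, IntervalRow

__all__ = ["ARRAY_LABELS", "packaged_table", "packaged_distances"]

ARRAY_LABELS = ("3x3", "4x4", "6x6")


def _load_raw(array: str) -> dict:
    if array not in ARRAY_LABELS:
        raise ValueError(f"no packaged table for array {array!r}; choose from {ARRAY_LABELS}")
    ref = resources.files("penrate.data").joinpath(f"table_{array}.json")
    return json.loads(ref.read_text())


def packaged_distances(array: str) -> list[int]:
    """Pair distances (in sheet pitches) covered by the packaged table."""
    return sorted(int(k) for k in _load_raw(array)["distances"])


def packaged_table(array: str, pair_distance: int = 1) -> CalibrationTable:
    """The reference calibration table for one array and pair distance.

    ``pair_distance`` is the tested sheet separation in sheet pitches
    (1 = adjacent, e.g. the A-B pair; 2 = A-C; ...).
    """
    raw = _load_raw(array)
    key = str(pair_distance)
    if key not in raw["distances"]:
        raise ValueError(
            f"packaged {array} table has no pair distance {pair_distance} "
            f"(available: {sorted(raw['distances'])})"
        )
    rows = [
        IntervalRow(
            interval=r["interval"],
            label=r["label"],
            current_low=float(r["current_low"]),
            current_high=None if r["current_high"] is None else float(r["current_high"]),
            interval_length=None
            if r["interval_length"] is None
            else float(r["interval_length"]),
        )
        for r in raw["distances"][key]
    ]
    return CalibrationTable(
        array=raw["array"],
        n=int(raw["n"]),
        pair_distance=pair_distance,
        rows=rows,
        source="packaged",
    )
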