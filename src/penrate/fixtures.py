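"""Seeded synthetic measurement fixtures.

Stands in for bench measurements of the assembled device: draws a random
penetration truth (each tip unpenetrated with probability ``p``), then emits
per-pair test currents either as representative currents of the packaged
calibration intervals ("table_means") or from the forward solver ("solver"),
plus optional Gaussian measurement noise.  Everything is driven by one seeded
generator, so a fixed spec reproduces its output bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .geometry import ArrayGeometry, SkinModel, SolverConfig
from .states import PenetrationState, TransdermalState
from .stats import CalibrationTable, IntervalRow
from .tables import packaged_distances, packaged_table

__all__ = ["FixtureSpec", "generate_fixture", "representative_current", "state_interval"]


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one synthetic measurement set."""

    array: str = "3x3"                  # "3x3", "4x4" or "6x6"
    p_unpenetrated: float = 0.2         # per-tip Bernoulli probability
    noise_uA: float = 0.0               # Gaussian noise s.d. on each current
    source: str = "table_means"         # "table_means" or "solver"
    seed: int = 0
    replicates: int = 1
    voxel_size: float = 100.0           # solver source only

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_unpenetrated <= 1.0:
            raise ValueError("p_unpenetrated must be in [0, 1]")
        if self.noise_uA < 0:
            raise ValueError("noise_uA must be >= 0")
        if self.source not in ("table_means", "solver"):
            raise ValueError("source must be 'table_means' or 'solver'")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def state_interval(table: CalibrationTable, state: TransdermalState) -> IntervalRow:
    """The interval row a transdermal state is mapped to."""
    for row in table.rows:
        if state.label in row.states:
            return row
        if state.nonconductive and any(lab.endswith("+") for lab in row.states):
            return row
    raise KeyError(f"state {state.label} not present in the table")


def representative_current(table: CalibrationTable, state: TransdermalState) -> float:
    """A noise-free current guaranteed to classify back into the state's interval.

    Closed intervals use their midpoint.  The half-open first interval has no
    upper bound; its representative sits half the neighbouring interval's
    width above the boundary.
    """
    row = state_interval(table, state)
    if row.current_high is not None:
        return (row.current_low + row.current_high) / 2.0
    neighbour = table.rows[1]
    width = (neighbour.current_high or row.current_low) - neighbour.current_low
    return row.current_low + width / 2.0


def _array_dims(array: str) -> tuple[int, int]:
    ns, n = array.split("x")
    return int(ns), int(n)


def generate_fixture(spec: FixtureSpec) -> tuple[PenetrationState, pd.DataFrame]:
    """Draw a penetration truth and its (noisy) pairwise currents.

    Returns the truth and a table with columns ``replicate``, ``pair``
    (e.g. "A-B"), ``distance`` and ``current_uA``, covering every unordered
    sheet pair the packaged calibration knows a distance for.  Currents are
    clipped at 0 (a measured current cannot be negative).
    """
    n_sheets, n = _array_dims(spec.array)
    rng = np.random.default_rng(spec.seed)
    flags = (rng.random((n_sheets, n)) < spec.p_unpenetrated).astype(np.int8)
    truth = PenetrationState(flags)

    distances = set(packaged_distances(spec.array))
    tables = {d: packaged_table(spec.array, d) for d in distances}

    if spec.source == "solver":
        from .solver import discretize, solve_pair_current

        grid = discretize(
            ArrayGeometry.square(n_sheets) if n_sheets == n else ArrayGeometry(
                n_sheets=n_sheets, tips_per_sheet=n
            ),
            SkinModel(),
            SolverConfig(voxel_size=spec.voxel_size),
        )

    rows = []
    for rep in range(spec.replicates):
        for i, j in combinations(range(n_sheets), 2):
            dist = j - i
            if dist not in distances:
                continue
            state = truth.pair_state(i, j)
            if spec.source == "table_means":
                base = representative_current(tables[dist], state)
            else:
                base = solve_pair_current(grid, truth, i, j).current_uA
            current = base + rng.normal(0.0, spec.noise_uA) if spec.noise_uA else base
            rows.append(
                {
                    "replicate": rep,
                    "pair": f"{chr(ord('A') + i)}-{chr(ord('A') + j)}",
                    "distance": dist,
                    "current_uA": max(float(current), 0.0),
                }
            )
    return truth, pd.DataFrame(rows)
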