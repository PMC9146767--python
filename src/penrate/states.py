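"""Penetration-state algebra for pairwise microneedle-sheet tests.

A *penetration state* records, tip by tip, which microneedles of an array
failed to pierce the stratum corneum (flag 1 = unpenetrated, 0 = penetrated).
A *transdermal state* compresses one pairwise inter-sheet test into the
unordered pair of unpenetrated-tip counts of the two tested sheets, e.g. the
"1-2 state".  When one sheet is fully unpenetrated the conductive pathway
between the pair collapses and the test current carries no per-state
information; those states are pooled into a single nonconductive class
labelled "n+" (3+, 4+, 6+ for 3-, 4- and 6-tip sheets).

Everything in this module is pure combinatorics: no solver, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "PenetrationState",
    "TransdermalState",
    "canonical_state",
    "enumerate_pair_states",
    "substate_count",
    "conductive_states",
    "all_states",
    "state_rank",
]


@dataclass(frozen=True)
class TransdermalState:
    """Unordered pair of unpenetrated-tip counts for two tested sheets.

    ``low <= high`` always; ``n`` is the number of tips per sheet.  The state
    is nonconductive iff ``high == n`` (one sheet fully unpenetrated).
    """

    low: int
    high: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.low <= self.high <= self.n):
            raise ValueError(
                f"invalid transdermal state ({self.low}, {self.high}) "
                f"for {self.n}-tip sheets"
            )

    @property
    def nonconductive(self) -> bool:
        return self.high == self.n

    @property
    def n_total(self) -> int:
        """Summed unpenetrated-tip count over the pair (N_total)."""
        return self.low + self.high

    @property
    def n_max_s(self) -> int:
        """Maximum unpenetrated-tip count on a single sheet (N_max-s)."""
        return self.high

    @property
    def label(self) -> str:
        if self.nonconductive:
            return f"{self.n}+"
        return f"{self.low}-{self.high}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def canonical_state(a: int, b: int, n: int) -> TransdermalState:
    """Canonicalize a pair of per-sheet unpenetrated counts.

    The pair is unordered with respect to the sheets: (2, 0) and (0, 2)
    describe the same transdermal condition and canonicalize to the 0-2 state.

    Parameters
    ----------
    a, b : int
        Unpenetrated-tip counts of the two tested sheets, each in ``0..n``.
    n : int
        Tips per sheet.
    """
    if not (0 <= a <= n and 0 <= b <= n):
        raise ValueError(f"counts ({a}, {b}) out of range 0..{n}")
    return TransdermalState(min(a, b), max(a, b), n)


@dataclass(frozen=True)
class PenetrationState:
    """Binary per-tip flags for a whole array; 1 = unpenetrated."""

    flags: np.ndarray  # shape (n_sheets, tips_per_sheet), entries in {0, 1}

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=np.int8)
        if flags.ndim != 2:
            raise ValueError("flags must be a (n_sheets, tips_per_sheet) matrix")
        if not np.isin(flags, (0, 1)).all():
            raise ValueError("flags must be 0 (penetrated) or 1 (unpenetrated)")
        object.__setattr__(self, "flags", flags)

    @property
    def n_sheets(self) -> int:
        return self.flags.shape[0]

    @property
    def tips_per_sheet(self) -> int:
        return self.flags.shape[1]

    def sheet_count(self, sheet: int) -> int:
        """Unpenetrated-tip count of one sheet."""
        return int(self.flags[sheet].sum())

    def pair_state(self, i: int, j: int) -> TransdermalState:
        """Canonical transdermal state of the (i, j) sheet pair."""
        return canonical_state(
            self.sheet_count(i), self.sheet_count(j), self.tips_per_sheet
        )

    @property
    def total_unpenetrated(self) -> int:
        return int(self.flags.sum())


def pair_flags_from_index(index: int, n: int) -> np.ndarray:
    """Decode a combination index into (2, n) tip flags.

    Binary counting with sheet A's tips as the most-significant bits: tip A1
    is the highest bit, tip Bn the lowest.
    """
    if not 0 <= index < 4**n:
        raise ValueError(f"combination index {index} out of range for n={n}")
    bits = [(index >> (2 * n - 1 - k)) & 1 for k in range(2 * n)]
    return np.array([bits[:n], bits[n:]], dtype=np.int8)


def enumerate_pair_states(n: int) -> Iterator[np.ndarray]:
    """Enumerate all 2^(2n) penetration combinations of a sheet pair.

    Yields (2, n) flag matrices in deterministic binary-counting order
    (sheet A tips as most-significant bits), so a pair of 3-tip sheets yields
    64 combinations and a pair of 6-tip sheets 4096.
    """
    if n < 1:
        raise ValueError("tips_per_sheet must be >= 1")
    for index in range(4**n):
        yield pair_flags_from_index(index, n)


def substate_count(state: TransdermalState, n: int | None = None) -> int:
    """Number of position-specific tip assignments realizing a state.

    Counted over an *ordered* sheet pair, matching how exhaustive sweeps
    enumerate events: an unequal pair (low, high) is realized both ways round,
    giving ``2 * C(n, low) * C(n, high)`` events; an equal pair gives
    ``C(n, low)^2``.
    """
    if n is None:
        n = state.n
    if n != state.n:
        raise ValueError("tips-per-sheet mismatch between state and n")
    if state.low == state.high:
        return comb(n, state.low) ** 2
    return 2 * comb(n, state.low) * comb(n, state.high)


def conductive_states(n: int) -> list[TransdermalState]:
    """All conductive canonical states, in ascending rank order.

    Rank order is lexicographic on (high, low): the dominant driver of the
    test current is the maximum unpenetrated count on a single sheet, with
    the other sheet's count as tie-break.  This reproduces the row order of
    the packaged calibration tables (0-0, 0-1, 1-1, 0-2, 1-2, 2-2, ...).
    """
    states = [
        TransdermalState(low, high, n)
        for high in range(n)  # high == n is nonconductive
        for low in range(high + 1)
    ]
    return states


def all_states(n: int) -> list[TransdermalState]:
    """Conductive states in rank order plus the pooled nonconductive class.

    The nonconductive class is represented by its (0, n) member; all
    (k, n) states share the "n+" label and pool together.
    """
    return conductive_states(n) + [TransdermalState(0, n, n)]


def state_rank(state: TransdermalState) -> int:
    """Ordinal of a state under the (high, low) lexicographic order.

    Conductive states are strictly ordered; every nonconductive state ranks
    last (they are indistinguishable by current).
    """
    if state.nonconductive:
        return len(conductive_states(state.n))
    rank = 0
    for high in range(state.high):
        rank += high + 1
    return rank + state.low


def pooled_label(state: TransdermalState) -> str:
    """Label with all nonconductive states pooled to "n+"."""
    return state.label
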