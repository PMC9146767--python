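"""Decoding pairwise inter-sheet currents into per-sheet penetration counts.

Each measured inter-sheet current is classified into a calibration-table
interval, yielding the transdermal state of that pair — an *unordered* pair
of unpenetrated-tip counts.  Two decoding strategies then recover array-wide
information:

* the **exact method** (small arrays, where current ↔ state is one-to-one):
  branch logic over the three states of sheets A, B, C pins down each
  sheet's count, and a chain of adjacent-pair comparisons extends the
  solution sheet by sheet;
* the **fuzzy method** (large arrays, where only the per-pair maximum
  survives the interval grouping): pairwise maxima are combined into the
  array total either as N = 1.5 × Σ(disjoint-pair maxima) or, from a sheet
  triple, as N = N_MAX + 1.5 × N_MED, the half-weight standing in for the
  unknown minimum.

The transdermal rate is 1 − N / (total tips).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .states import TransdermalState, canonical_state
from .stats import CalibrationTable, IntervalRow

__all__ = [
    "DecodeError",
    "InconsistencyError",
    "NonconductiveError",
    "DecodeWarning",
    "DecodeResult",
    "lookup_state",
    "exact_decode_three",
    "exact_extend",
    "exact_decode_chain",
    "fuzzy_max_med",
    "fuzzy_estimate",
    "transdermal_rate",
    "decode_currents",
]


class DecodeError(ValueError):
    """Base class for decoding failures."""


class InconsistencyError(DecodeError):
    """The pairwise states admit no consistent per-sheet assignment."""


class NonconductiveError(DecodeError):
    """A tested pair is nonconductive: per-state information is lost."""


class DecodeWarning(UserWarning):
    """Recoverable decode anomaly (e.g. physically invalid fuzzy inputs)."""


def _sheet_name(i: int) -> str:
    return chr(ord("A") + i)


def _pair_name(pair: tuple[int, int]) -> str:
    return f"{_sheet_name(pair[0])}-{_sheet_name(pair[1])}"


def lookup_state(
    current: float, table: CalibrationTable
) -> tuple[IntervalRow, bool]:
    """Classify a test current into its calibration interval.

    Intervals are half-open ``[low, high)`` with the first interval unbounded
    above.  Printed tables may overlap; a current inside an overlap resolves
    to the higher-current (lower-numbered) interval and the returned flag is
    True.  Returns ``(interval row, ambiguous)``.
    """
    if current < 0:
        raise ValueError("current must be nonnegative")
    hits = table.find_intervals(current)
    if not hits:
        raise DecodeError(f"current {current:.6g} μA matches no interval")
    return hits[0], len(hits) > 1


def _single_state(row: IntervalRow, n: int) -> TransdermalState:
    states = row.member_states(n)
    labels = row.states
    if len(labels) > 1:
        raise DecodeError(
            f"interval {row.interval} maps to a state group ({row.label}); "
            "the exact method needs a one-to-one table"
        )
    if labels[0].endswith("+"):
        raise NonconductiveError(
            f"interval {row.interval} is the nonconductive class {row.label}"
        )
    return states[0]


def _match_other(pair: tuple[int, int], value: int, pair_id: str) -> int:
    """Element of an unordered pair complementary to a matched value.

    Multiset semantics: a matched element is used up, so a doubled pair
    returns its repeated value.
    """
    if pair[0] == value:
        return pair[1]
    if pair[1] == value:
        return pair[0]
    raise InconsistencyError(
        f"count {value} does not occur in the {pair_id} state {pair}"
    )


def exact_decode_three(
    s_ab: TransdermalState, s_bc: TransdermalState, s_ac: TransdermalState
) -> tuple[int, int, int]:
    """Per-sheet unpenetrated counts of sheets A, B, C from their pair states.

    Branch logic: if the two A-C numbers agree, A = C = that number and B is
    the A-B element not matched by it.  Otherwise the value shared between
    the A-B and B-C states is B (test BC1 against the A-B pair, fall back to
    BC2), and A, C follow as the unmatched elements.  Inputs that admit no
    consistent assignment raise, naming the offending pair.
    """
    for pid, s in (("A-B", s_ab), ("B-C", s_bc), ("A-C", s_ac)):
        if s.nonconductive:
            raise NonconductiveError(
                f"pair {pid} is nonconductive; exact decoding is impossible"
            )
    ab = (s_ab.low, s_ab.high)
    bc = (s_bc.low, s_bc.high)
    ac = (s_ac.low, s_ac.high)

    if ac[0] == ac[1]:
        a = c = ac[0]
        b = _match_other(ab, a, "A-B")
    else:
        b = bc[0] if bc[0] in ab else bc[1]
        a = _match_other(ab, b, "A-B")
        c = _match_other(bc, b, "B-C")

    for pid, pair, s in (("A-B", (a, b), s_ab), ("B-C", (b, c), s_bc), ("A-C", (a, c), s_ac)):
        if tuple(sorted(pair)) != (s.low, s.high):
            raise InconsistencyError(
                f"assignment {pair} contradicts the {pid} state {s.label}"
            )
    return a, b, c


def exact_extend(prev: int, s_xy: TransdermalState) -> int:
    """Count of the next sheet from the previous sheet's count and the pair state.

    The element of the X-Y state matched by the previous count is used up;
    the complementary element is the next sheet's count (a doubled pair
    returns its repeated value).
    """
    if s_xy.nonconductive:
        raise NonconductiveError("nonconductive pair; exact decoding is impossible")
    return _match_other((s_xy.low, s_xy.high), prev, "X-Y")


def exact_decode_chain(states: Sequence[TransdermalState]) -> list[int]:
    """Per-sheet counts for an m-sheet array from 3 + (m − 3) pair states.

    ``states`` holds the A-B, B-C, A-C states followed by one state per
    additional adjacent pair (C-D, D-E, ...).
    """
    if len(states) < 3:
        raise ValueError("need at least the A-B, B-C and A-C states")
    a, b, c = exact_decode_three(states[0], states[1], states[2])
    counts = [a, b, c]
    for k, s in enumerate(states[3:]):
        pid = _pair_name((k + 2, k + 3))
        try:
            counts.append(exact_extend(counts[-1], s))
        except DecodeError as exc:
            raise type(exc)(f"pair {pid}: {exc}") from None
    return counts


def fuzzy_max_med(m_ab: int, m_bc: int, m_ac: int) -> tuple[int, int]:
    """Largest and median per-sheet counts from three pairwise maxima.

    Three pairwise comparisons: the larger of AB and BC seeds MAX and the
    smaller seeds MED; MED is then compared with AC (larger to a temporary,
    smaller back to MED); finally the temporary and MAX compare into MAX.
    Valid inputs — pairwise maxima of a real count triple — have their two
    largest values equal; anything else is physically impossible and emits a
    warning, but the flow result is still returned.
    """
    top_two = sorted((m_ab, m_bc, m_ac), reverse=True)[:2]
    if top_two[0] != top_two[1]:
        warnings.warn(
            f"pairwise maxima ({m_ab}, {m_bc}, {m_ac}) cannot arise from any "
            "count triple; result is unreliable",
            DecodeWarning,
            stacklevel=2,
        )
    n_max, n_med = max(m_ab, m_bc), min(m_ab, m_bc)
    m = max(n_med, m_ac)
    n_med = min(n_med, m_ac)
    n_max = max(m, n_max)
    return n_max, n_med


def fuzzy_estimate(
    inputs: Sequence[int], scheme: str = "pairs"
) -> float:
    """Estimated total unpenetrated count N from fuzzy inputs.

    ``pairs``: inputs are the maxima of disjoint sheet pairs;
    N = 1.5 × Σ maxima (the half stands in for each pair's unknown minimum).
    ``three_sheet``: inputs are (N_MAX, N_MED) from a sheet triple;
    N = N_MAX + 1.5 × N_MED.
    """
    if scheme == "pairs":
        return 1.5 * float(sum(inputs))
    if scheme == "three_sheet":
        n_max, n_med = inputs
        if n_med > n_max:
            raise ValueError("median count cannot exceed maximum count")
        return float(n_max) + 1.5 * float(n_med)
    raise ValueError(f"unknown fuzzy scheme {scheme!r}")


def transdermal_rate(n_unpenetrated: float, total_tips: int) -> float:
    """Fraction of tips that pierced the stratum corneum: 1 − N/total."""
    if total_tips <= 0:
        raise ValueError("total_tips must be positive")
    if n_unpenetrated < 0:
        raise ValueError("unpenetrated count cannot be negative")
    if n_unpenetrated > total_tips:
        warnings.warn(
            f"estimated unpenetrated count {n_unpenetrated} exceeds the "
            f"{total_tips} tips; clamping the rate to 0",
            DecodeWarning,
            stacklevel=2,
        )
        return 0.0
    return 1.0 - n_unpenetrated / total_tips


@dataclass
class DecodeResult:
    """Outcome of decoding one set of pairwise currents."""

    method: str                              # "exact" or "fuzzy"
    scheme: str | None                       # fuzzy: "pairs" or "three_sheet"
    per_sheet_counts: list[int | None]
    estimated_total: float
    transdermal_rate: float
    n_max: int | None = None
    n_med: int | None = None
    pair_maxima: dict[str, int] = field(default_factory=dict)
    ambiguous_pairs: list[str] = field(default_factory=list)

    @property
    def uncertainty_rate(self) -> float:
        """Fraction of per-sheet counts the method leaves undetermined."""
        if self.method == "exact":
            return 0.0
        return 0.5 if self.scheme == "pairs" else 1.0 / 3.0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "scheme": self.scheme,
            "per_sheet_counts": self.per_sheet_counts,
            "estimated_total": self.estimated_total,
            "transdermal_rate": self.transdermal_rate,
            "n_max": self.n_max,
            "n_med": self.n_med,
            "pair_maxima": self.pair_maxima,
            "ambiguous_pairs": self.ambiguous_pairs,
            "uncertainty_rate": self.uncertainty_rate,
        }


def _group_n_max(row: IntervalRow, n: int) -> int:
    """Single-sheet maximum count represented by an interval's state group."""
    return max(st.high for st in row.member_states(n))


def decode_currents(
    currents: Mapping[tuple[int, int], float],
    tables: Mapping[int, CalibrationTable],
    n_sheets: int,
    method: str = "exact",
) -> DecodeResult:
    """Decode a set of pairwise inter-sheet currents into a DecodeResult.

    ``currents`` maps sheet-index pairs (0-based) to currents in μA;
    ``tables`` maps pair distance (in sheet pitches) to the calibration
    table to use for pairs at that distance.

    The exact method needs the A-B, B-C, A-C currents plus one adjacent-pair
    current per additional sheet, and a one-to-one (small-array) table.  The
    fuzzy method uses the A-B, B-C, A-C triple when present (N_MAX/N_MED
    scheme), otherwise the disjoint adjacent pairs A-B, C-D, E-F
    (1.5 × Σ maxima scheme).
    """
    n = next(iter(tables.values())).n
    total_tips = n_sheets * n
    ambiguous: list[str] = []

    def row_for(pair: tuple[int, int]) -> IntervalRow:
        dist = abs(pair[1] - pair[0])
        if dist not in tables:
            raise DecodeError(f"no calibration table for pair distance {dist}")
        try:
            current = currents[pair]
        except KeyError:
            raise DecodeError(f"missing current for pair {_pair_name(pair)}") from None
        row, amb = lookup_state(current, tables[dist])
        if amb:
            ambiguous.append(_pair_name(pair))
        return row

    if method == "exact":
        chain_pairs = [(0, 1), (1, 2), (0, 2)] + [
            (k, k + 1) for k in range(2, n_sheets - 1)
        ]
        states = [_single_state(row_for(p), n) for p in chain_pairs]
        counts = exact_decode_chain(states)
        total = float(sum(counts))
        return DecodeResult(
            method="exact",
            scheme=None,
            per_sheet_counts=list(counts),
            estimated_total=total,
            transdermal_rate=transdermal_rate(total, total_tips),
            ambiguous_pairs=ambiguous,
        )

    if method != "fuzzy":
        raise ValueError(f"unknown method {method!r}")

    # Only the two published schemes exist: the sheet-triple formula for a
    # 3-sheet area and the disjoint-pairs formula for even sheet counts.
    triple = [(0, 1), (1, 2), (0, 2)]
    if n_sheets == 3 and all(p in currents for p in triple):
        maxima = {_pair_name(p): _group_n_max(row_for(p), n) for p in triple}
        n_max, n_med = fuzzy_max_med(*maxima.values())
        total = fuzzy_estimate((n_max, n_med), scheme="three_sheet")
        return DecodeResult(
            method="fuzzy",
            scheme="three_sheet",
            per_sheet_counts=[None] * n_sheets,
            estimated_total=total,
            transdermal_rate=transdermal_rate(total, total_tips),
            n_max=n_max,
            n_med=n_med,
            pair_maxima=maxima,
            ambiguous_pairs=ambiguous,
        )

    if n_sheets % 2 != 0:
        raise DecodeError(
            "fuzzy decoding is defined for a 3-sheet area (A-B/B-C/A-C triple) "
            "or an even number of sheets split into disjoint adjacent pairs"
        )
    disjoint = [(k, k + 1) for k in range(0, n_sheets - 1, 2)]
    missing = [p for p in disjoint if p not in currents]
    if missing:
        raise DecodeError(
            "fuzzy decoding needs either the A-B/B-C/A-C triple or all "
            f"disjoint adjacent pairs; missing {[_pair_name(p) for p in missing]}"
        )
    maxima = {_pair_name(p): _group_n_max(row_for(p), n) for p in disjoint}
    total = fuzzy_estimate(list(maxima.values()), scheme="pairs")
    return DecodeResult(
        method="fuzzy",
        scheme="pairs",
        per_sheet_counts=[None] * n_sheets,
        estimated_total=total,
        transdermal_rate=transdermal_rate(total, total_tips),
        pair_maxima=maxima,
        ambiguous_pairs=ambiguous,
    )
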