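"""Decoders: interval lookup, exact branch logic, fuzzy max/median, rates."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from penrate.decoder import (
    DecodeWarning,
    InconsistencyError,
    NonconductiveError,
    decode_currents,
    exact_decode_chain,
    exact_decode_three,
    exact_extend,
    fuzzy_estimate,
    fuzzy_max_med,
    lookup_state,
    transdermal_rate,
)
from penrate.fixtures import FixtureSpec, generate_fixture, representative_current
from penrate.states import canonical_state
from penrate.tables import packaged_distances, packaged_table


def s(a, b, n=3):
    return canonical_state(a, b, n)


class TestLookup:
    @pytest.mark.parametrize(
        "current,label", [(250, "1-1"), (400, "0-0"), (50, "3+"), (301, "0-1")]
    )
    def test_3x3_adjacent(self, current, label):
        row, ambiguous = lookup_state(current, packaged_table("3x3", 1))
        assert row.label == label
        assert not ambiguous

    def test_overlap_resolves_high_with_flag(self):
        row, ambiguous = lookup_state(174.0, packaged_table("3x3", 1))
        assert row.interval == 5 and ambiguous

    def test_negative_current_rejected(self):
        with pytest.raises(ValueError):
            lookup_state(-1.0, packaged_table("3x3", 1))


class TestExactThree:
    @pytest.mark.parametrize(
        "ab,bc,ac,expected",
        [
            ((1, 2), (1, 2), (2, 2), (2, 1, 2)),
            ((0, 0), (0, 0), (0, 0), (0, 0, 0)),
            ((1, 2), (2, 2), (1, 2), (1, 2, 2)),   # both B-C elements equal B
            ((0, 1), (0, 2), (1, 2), (1, 0, 2)),   # unequal A-C branch
        ],
    )
    def test_examples(self, ab, bc, ac, expected):
        assert exact_decode_three(s(*ab), s(*bc), s(*ac)) == expected

    @pytest.mark.parametrize("n", [3, 4])
    def test_recovers_every_conductive_triple(self, n):
        """Brute-force oracle: for every true count triple whose three pair
        states are all conductive, decoding the states returns the triple."""
        for a, b, c in product(range(n + 1), repeat=3):
            states = [s(a, b, n), s(b, c, n), s(a, c, n)]
            if any(x.nonconductive for x in states):
                continue
            assert exact_decode_three(*states) == (a, b, c)

    def test_inconsistent_inputs_raise(self):
        # A-C says A == C == 2 but neither A-B element is 2
        with pytest.raises(InconsistencyError, match="A-B"):
            exact_decode_three(s(0, 1), s(0, 1), s(2, 2))

    def test_nonconductive_input_raises(self):
        with pytest.raises(NonconductiveError):
            exact_decode_three(s(0, 3), s(0, 1), s(0, 1))


class TestExactExtend:
    def test_matched_element_is_used_up(self):
        assert exact_extend(2, s(0, 2)) == 0

    def test_doubled_pair(self):
        assert exact_extend(1, s(1, 1)) == 1

    def test_unmatched_previous_count_raises(self):
        with pytest.raises(InconsistencyError):
            exact_extend(0, s(1, 2))


class TestExactChain:
    def test_four_sheets(self):
        states = [s(0, 1), s(0, 2), s(1, 2), s(2, 2)]
        assert exact_decode_chain(states) == [1, 0, 2, 2]

    def test_all_zero(self):
        assert exact_decode_chain([s(0, 0)] * 3) == [0, 0, 0]

    def test_exhaustive_four_sheet_recovery(self):
        """Chain decoding recovers every conductive 4-sheet truth vector."""
        n = 3
        for counts in product(range(n), repeat=4):
            a, b, c, d = counts
            states = [s(a, b), s(b, c), s(a, c), s(c, d)]
            if any(x.nonconductive for x in states):
                continue
            assert exact_decode_chain(states) == list(counts)


class TestFuzzy:
    @pytest.mark.parametrize(
        "maxima,expected", [((2, 3, 3), (3, 2)), ((0, 0, 0), (0, 0)), ((2, 2, 2), (2, 2))]
    )
    def test_max_med_examples(self, maxima, expected):
        assert fuzzy_max_med(*maxima) == expected

    def test_max_med_equals_sort_oracle_on_all_triples(self):
        for a, b, c in product(range(7), repeat=3):
            got = fuzzy_max_med(max(a, b), max(b, c), max(a, c))
            top, med, _ = sorted((a, b, c), reverse=True)
            assert got == (top, med)

    @given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6))
    def test_max_med_hypothesis(self, a, b, c):
        got = fuzzy_max_med(max(a, b), max(b, c), max(a, c))
        top, med, _ = sorted((a, b, c), reverse=True)
        assert got == (top, med)

    def test_invalid_triple_warns_but_returns(self):
        with pytest.warns(DecodeWarning):
            assert fuzzy_max_med(3, 1, 0) == (3, 0)

    @pytest.mark.parametrize(
        "inputs,scheme,expected",
        [
            ((2, 0, 1), "pairs", 4.5),
            ((3, 2), "three_sheet", 6.0),
            ((0, 0, 0), "pairs", 0.0),
        ],
    )
    def test_estimate(self, inputs, scheme, expected):
        assert fuzzy_estimate(inputs, scheme) == expected


class TestTransdermalRate:
    @pytest.mark.parametrize("n,total,rate", [(4.5, 36, 0.875), (0, 9, 1.0), (9, 9, 0.0)])
    def test_definition(self, n, total, rate):
        assert transdermal_rate(n, total) == pytest.approx(rate)

    def test_overflow_clamps_with_warning(self):
        with pytest.warns(DecodeWarning):
            assert transdermal_rate(10, 9) == 0.0


def _currents_from_counts(counts, array, n):
    """Noise-free pairwise currents for a given per-sheet truth vector."""
    tables = {d: packaged_table(array, d) for d in packaged_distances(array)}
    currents = {}
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            d = j - i
            if d not in tables:
                continue
            currents[(i, j)] = representative_current(
                tables[d], canonical_state(counts[i], counts[j], n)
            )
    return currents, tables


class TestEndToEnd:
    def test_zero_noise_exact_recovers_all_conductive_3x3(self):
        """Representative currents decode back to the exact truth for every
        conductive 3x3 configuration, including through the printed
        interval overlap."""
        for counts in product(range(4), repeat=3):
            pairs = [(0, 1), (1, 2), (0, 2)]
            if any(
                canonical_state(counts[i], counts[j], 3).nonconductive
                for i, j in pairs
            ):
                continue
            currents, tables = _currents_from_counts(counts, "3x3", 3)
            res = decode_currents(currents, tables, n_sheets=3, method="exact")
            assert res.per_sheet_counts == list(counts)
            assert res.estimated_total == sum(counts)
            assert res.transdermal_rate == pytest.approx(1 - sum(counts) / 9)

    def test_fuzzy_three_sheet_on_3x3(self):
        counts = (2, 1, 2)
        currents, tables = _currents_from_counts(counts, "3x3", 3)
        res = decode_currents(currents, tables, n_sheets=3, method="fuzzy")
        assert res.scheme == "three_sheet"
        assert (res.n_max, res.n_med) == (2, 2)
        assert res.estimated_total == 2 + 1.5 * 2
        assert res.uncertainty_rate == pytest.approx(1 / 3)

    def test_fuzzy_pairs_on_6x6(self):
        counts = (2, 1, 0, 0, 3, 1)
        currents, tables = _currents_from_counts(counts, "6x6", 6)
        res = decode_currents(currents, tables, n_sheets=6, method="fuzzy")
        assert res.scheme == "pairs"
        assert res.pair_maxima == {"A-B": 2, "C-D": 0, "E-F": 3}
        assert res.estimated_total == 1.5 * (2 + 0 + 3)
        assert res.uncertainty_rate == 0.5

    def test_exact_rejects_grouped_table(self):
        counts = (1, 1, 1, 0, 0, 0)
        currents, tables = _currents_from_counts(counts, "6x6", 6)
        with pytest.raises(ValueError, match="group"):
            decode_currents(currents, tables, n_sheets=6, method="exact")

    def test_noise_degrades_monotonically(self):
        """Exact-decode failure rate grows with measurement noise: mild noise
        (25% of the narrowest interval) fails less often than severe noise
        (100% of it)."""
        tables = {d: packaged_table("3x3", d) for d in packaged_distances("3x3")}
        narrowest = min(
            r.current_high - r.current_low
            for t in tables.values()
            for r in t.rows
            if r.current_high is not None
        )
        rng = np.random.default_rng(42)

        def failure_rate(noise):
            fails = 0
            trials = 60
            for _ in range(trials):
                counts = tuple(rng.integers(0, 3, size=3))
                currents, _ = _currents_from_counts(counts, "3x3", 3)
                noisy = {
                    k: max(v + rng.normal(0, noise), 0.0) for k, v in currents.items()
                }
                try:
                    res = decode_currents(noisy, tables, n_sheets=3, method="exact")
                    if res.per_sheet_counts != list(counts):
                        fails += 1
                except ValueError:
                    fails += 1
            return fails / trials

        assert failure_rate(0.25 * narrowest) < failure_rate(1.0 * narrowest)
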