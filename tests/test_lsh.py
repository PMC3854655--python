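"""The randomized w-mer hash, its similarity filter, and the collision bound."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lshotu import (
    HashFunctionSpec,
    HashKey,
    SequenceRecord,
    allowed_mismatches,
    collision_probability_lower_bound,
    empirical_collision_probability,
    extract_key,
    is_similar,
    mismatch_count,
    sample_indices,
    window_mismatch_budget,
)


def key(*symbols, w=None):
    return HashKey(symbols=tuple(symbols), w=w or len(symbols[0]))


class TestSampleIndices:
    def test_exhaustive_case_forces_all_positions(self, rng):
        spec = sample_indices(10, 10, 1, rng)
        assert spec.indices == tuple(range(10))

    def test_standard_setting_bounds(self, rng):
        spec = sample_indices(100, 30, 3, rng)
        assert len(set(spec.indices)) == 30
        assert all(1 <= c <= 98 for c in spec.indices)
        assert list(spec.indices) == sorted(spec.indices)

    def test_deterministic_given_seed(self):
        a = sample_indices(200, 30, 3, np.random.default_rng(7))
        b = sample_indices(200, 30, 3, np.random.default_rng(7))
        assert a.indices == b.indices

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="k too large"):
            sample_indices(10, 11, 1, rng)
        with pytest.raises(ValueError, match="k too large"):
            sample_indices(20, 8, 3, rng)  # k*w = 24 > 20

    def test_even_w_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            sample_indices(100, 10, 2, rng)

    def test_spec_invariants_enforced(self):
        with pytest.raises(ValueError):
            HashFunctionSpec(k=2, w=3, indices=(0, 5), n_eff=10)  # window off edge
        with pytest.raises(ValueError):
            HashFunctionSpec(k=2, w=1, indices=(3, 3), n_eff=10)  # not distinct


class TestExtractKey:
    def test_single_base_windows(self):
        rec = SequenceRecord("r", "ACGTACGT")
        spec = HashFunctionSpec(k=2, w=1, indices=(1, 5), n_eff=8)
        assert extract_key(rec, spec).symbols == ("C", "C")

    def test_wmer_windows(self):
        rec = SequenceRecord("r", "ACGTACGT")
        spec = HashFunctionSpec(k=2, w=3, indices=(1, 5), n_eff=8)
        assert extract_key(rec, spec).symbols == ("ACG", "ACG")

    def test_full_width_key_spells_sequence(self, rng):
        seq = "GATTACAGAT"
        rec = SequenceRecord("r", seq)
        spec = sample_indices(len(seq), len(seq), 1, rng)
        assert "".join(extract_key(rec, spec).symbols) == seq

    def test_short_sequence_rejected_by_name(self):
        spec = HashFunctionSpec(k=1, w=1, indices=(5,), n_eff=8)
        with pytest.raises(ValueError, match="sequence too short.*shorty"):
            extract_key(SequenceRecord("shorty", "ACGT"), spec)


class TestMismatchBudgets:
    def test_worked_example(self):
        assert allowed_mismatches(64, 0.10) == 6

    def test_zero_fraction_requires_exact_match(self):
        assert allowed_mismatches(30, 0.0) == 0
        assert allowed_mismatches(1000, 0.0) == 0

    def test_floor_evaluation(self):
        assert allowed_mismatches(30, 0.10) == 3

    def test_fraction_domain(self):
        with pytest.raises(ValueError):
            allowed_mismatches(10, -0.1)
        with pytest.raises(ValueError):
            allowed_mismatches(10, 1.5)

    def test_divergence_budget_reduces_to_zero_at_p0(self):
        assert window_mismatch_budget(30, 3, 0.0) == 0

    def test_divergence_budget_monotone_in_p(self):
        budgets = [window_mismatch_budget(30, 3, p) for p in (0.0, 0.02, 0.04, 0.1, 0.5)]
        assert budgets == sorted(budgets)
        assert window_mismatch_budget(30, 3, 1.0) == 30


class TestSimFilter:
    def test_identical_keys_zero_mismatch(self):
        a = key("AC", "GG", "TT", "AA")
        assert mismatch_count(a, a) == 0
        assert is_similar(a, a, 0.0)

    def test_antipodal_keys(self):
        a = key("A", "C", "G", "T")
        b = key("C", "G", "T", "A")
        assert mismatch_count(a, b) == 4

    def test_single_position_difference(self):
        a = key("AC", "GG", "TT", "AA")
        b = key("AC", "GA", "TT", "AA")
        assert mismatch_count(a, b) == 1
        assert mismatch_count(b, a) == 1

    def test_threshold_boundary_k64_p10(self):
        syms_a = tuple("A" for _ in range(64))
        for n_bad, expected in [(6, True), (7, False)]:
            syms_b = tuple("C" if i < n_bad else "A" for i in range(64))
            assert is_similar(key(*syms_a), key(*syms_b), 0.10) is expected

    def test_p_zero_rejects_any_mismatch(self):
        a = key("A", "A")
        b = key("A", "C")
        assert not is_similar(a, b, 0.0)

    def test_incompatible_keys_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            mismatch_count(key("A", "C"), key("A", "C", "G"))
        with pytest.raises(ValueError, match="incompatible"):
            mismatch_count(key("A", "C"), key("AAA", "CCC"))

    def test_ambiguous_base_never_matches(self):
        assert mismatch_count(key("AN", "CC"), key("AN", "CC")) == 1


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_w1_p0_filter_equals_direct_position_comparison(data):
    """At w=1, p=0 the filter is exactly positional string agreement."""
    n = data.draw(st.integers(4, 12))
    k = data.draw(st.integers(1, 4))
    x = data.draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
    y = data.draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
    seed = data.draw(st.integers(0, 1000))
    spec = sample_indices(n, k, 1, np.random.default_rng(seed))
    ka = extract_key(SequenceRecord("x", x), spec)
    kb = extract_key(SequenceRecord("y", y), spec)
    assert is_similar(ka, kb, 0.0) == all(x[c] == y[c] for c in spec.indices)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_wider_windows_strictly_more_stringent(data):
    """With identical centers and p=0, a collision at w+2 implies one at w."""
    n = 20
    w = data.draw(st.sampled_from([1, 3]))
    x = data.draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
    y = data.draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
    half_wide = (w + 2) // 2
    centers = data.draw(
        st.lists(
            st.integers(half_wide, n - 1 - half_wide),
            min_size=1, max_size=4, unique=True,
        ).map(lambda cs: tuple(sorted(cs)))
    )
    keys = {}
    for width in (w, w + 2):
        spec = HashFunctionSpec(k=len(centers), w=width, indices=centers, n_eff=n)
        keys[width] = (
            extract_key(SequenceRecord("x", x), spec),
            extract_key(SequenceRecord("y", y), spec),
        )
    if mismatch_count(*keys[w + 2]) == 0:
        assert mismatch_count(*keys[w]) == 0


def test_mismatch_count_is_a_metric_on_small_keys():
    """Identity, symmetry, triangle inequality by enumeration (k=2, w=1)."""
    keys = [key(*pair) for pair in itertools.product("ACG", repeat=2)]
    for a, b, c in itertools.product(keys, repeat=3):
        dab = mismatch_count(a, b)
        assert dab == mismatch_count(b, a)
        assert (dab == 0) == (a.symbols == b.symbols)
        assert dab <= mismatch_count(a, c) + mismatch_count(c, b)


class TestCollisionBound:
    def test_identical_strings_always_collide(self):
        assert collision_probability_lower_bound(100, 30, 0) == 1.0

    def test_k1_exact_by_enumeration(self):
        """For k=1 the bound equals the exact single-index collision rate."""
        n, m = 20, 7
        x = "A" * n
        y = "C" * m + "A" * (n - m)
        hits = sum(x[i] == y[i] for i in range(n))
        assert collision_probability_lower_bound(n, 1, m) == pytest.approx(hits / n)

    def test_direct_evaluation(self):
        assert collision_probability_lower_bound(100, 30, 3) == pytest.approx(
            0.97**30
        )
        assert 0.97**30 == pytest.approx(0.4010, abs=5e-4)

    def test_monte_carlo_agrees_within_3se(self):
        draws = 100_000
        bound = collision_probability_lower_bound(100, 30, 3)
        freq = empirical_collision_probability(
            100, 30, 3, draws, np.random.default_rng(0)
        )
        se = math.sqrt(bound * (1 - bound) / draws)
        assert abs(freq - bound) <= 3 * se

    def test_parameter_domain(self):
        with pytest.raises(ValueError):
            collision_probability_lower_bound(10, 11, 0)
        with pytest.raises(ValueError):
            collision_probability_lower_bound(10, 5, 11)
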