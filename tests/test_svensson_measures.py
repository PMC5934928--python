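import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rand36val.svensson import (
    PairedOrdinalTable,
    augmented_mean_ranks,
    percentage_agreement,
    relative_concentration,
    relative_position,
    relative_rank_variance,
)

from _oracles import random_table, rp_double_sum, rv_expansion_sort


def table_of(counts, categories=None):
    counts = np.asarray(counts)
    cats = categories or tuple(range(1, counts.shape[0] + 1))
    return PairedOrdinalTable(counts, cats)


# hypothesis strategy: small non-empty square count matrices
@st.composite
def small_tables(draw):
    C = draw(st.integers(2, 5))
    cells = draw(
        st.lists(st.integers(0, 6), min_size=C * C, max_size=C * C).filter(
            lambda xs: sum(xs) >= 1
        )
    )
    return table_of(np.array(cells).reshape(C, C))


class TestPercentageAgreement:
    def test_diagonal_proportion(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0], counts[1, 2], counts[2, 2] = 3, 1, 1
        assert percentage_agreement(table_of(counts)) == pytest.approx(0.8)

    def test_all_on_diagonal_is_one_and_off_is_zero(self):
        assert percentage_agreement(table_of(np.diag([2, 3]))) == 1.0
        off = np.array([[0, 5], [2, 0]])
        assert percentage_agreement(table_of(off)) == 0.0

    def test_within_one_step_includes_adjacent_cells(self):
        counts = np.array([[1, 1, 0], [0, 0, 1], [1, 0, 0]])
        assert percentage_agreement(table_of(counts), within_steps=1) == pytest.approx(3 / 4)

    def test_step_spanning_scale_warns_and_returns_one(self):
        t = table_of(np.array([[0, 2], [3, 0]]))
        with pytest.warns(UserWarning, match="trivially 1"):
            assert percentage_agreement(t, within_steps=2) == 1.0


class TestRelativePosition:
    def test_worked_example_is_0_43(self):
        # occasion-1 degenerate at category 2 of 3; occasion-2 (0.27, 0.03, 0.70)
        counts = np.zeros((3, 3), dtype=int)
        counts[1] = [27, 3, 70]
        assert relative_position(table_of(counts)) == pytest.approx(0.43, abs=1e-12)

    def test_identical_marginals_give_zero(self):
        assert relative_position(table_of(np.diag([3, 1, 4]))) == pytest.approx(0.0)

    def test_extreme_shift_is_plus_one(self):
        counts = np.array([[0, 6], [0, 0]])
        assert relative_position(table_of(counts)) == pytest.approx(1.0)

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(200):
            counts = random_table(rng, max_categories=5)
            assert relative_position(table_of(counts)) == pytest.approx(
                rp_double_sum(counts), abs=1e-12
            )


class TestRelativeConcentration:
    def test_identical_marginals_give_zero(self):
        assert relative_concentration(table_of(np.diag([2, 5, 2]))) == pytest.approx(0.0)

    def test_maximal_central_concentration_is_one(self):
        # half/half extremes at occasion 1, everything central at occasion 2
        counts = np.array([[0, 3, 0], [0, 0, 0], [0, 3, 0]])
        assert relative_concentration(table_of(counts)) == pytest.approx(1.0)
        assert relative_concentration(table_of(counts.T)) == pytest.approx(-1.0)


class TestAugmentedRanks:
    def test_single_cell_mean_rank(self):
        counts = np.zeros((2, 2), dtype=int)
        counts[0, 1] = 5
        ranks = augmented_mean_ranks(table_of(counts))
        assert ranks.rbar1[0, 1] == 3.0
        assert ranks.rbar2[0, 1] == 3.0

    def test_staircase_pattern_has_matching_ranks(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 1], counts[1, 2] = 2, 3
        ranks = augmented_mean_ranks(table_of(counts))
        nonempty = counts > 0
        assert np.allclose(ranks.rbar1[nonempty], ranks.rbar2[nonempty])

    def test_weighted_mean_rank_is_centre(self, rng):
        for _ in range(50):
            counts = random_table(rng, min_n=2)
            t = table_of(counts)
            ranks = augmented_mean_ranks(t)
            n = counts.sum()
            for rbar in (ranks.rbar1, ranks.rbar2):
                vals = rbar[counts > 0]
                assert np.all((vals >= 1) & (vals <= n))
                mean = np.sum(counts[counts > 0] * vals) / n
                assert mean == pytest.approx((n + 1) / 2)


class TestRelativeRankVariance:
    def test_diagonal_table_is_zero(self):
        assert relative_rank_variance(table_of(np.diag([4, 2, 3]))) == 0.0

    def test_two_by_two_crossing_pattern(self):
        counts = np.array([[2, 1], [1, 2]])
        assert relative_rank_variance(counts_table := table_of(counts)) == pytest.approx(
            6 * 2 / 216
        )
        assert counts_table.n == 6

    def test_staircase_is_zero(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 1], counts[1, 2] = 2, 3
        assert relative_rank_variance(table_of(counts)) == 0.0

    def test_matches_expansion_sort_oracle(self, rng):
        for _ in range(200):
            counts = random_table(rng, max_categories=5)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rv = relative_rank_variance(table_of(counts))
            assert rv == pytest.approx(rv_expansion_sort(counts), abs=1e-9)

    def test_heterogeneity_warning_above_threshold(self):
        counts = np.array([[0, 5], [5, 0]])  # full reversal
        with pytest.warns(UserWarning, match="departures from a common pattern"):
            relative_rank_variance(table_of(counts))

    def test_merging_adjacent_categories_never_increases_rv(self, rng):
        for _ in range(200):
            counts = random_table(rng, max_categories=6, min_n=2)
            C = counts.shape[0]
            if C == 2:
                continue
            k = int(rng.integers(0, C - 1))
            merged = counts.copy()
            merged[k] += merged[k + 1]
            merged = np.delete(merged, k + 1, axis=0)
            merged[:, k] += merged[:, k + 1]
            merged = np.delete(merged, k + 1, axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rv_full = relative_rank_variance(table_of(counts))
                rv_merged = relative_rank_variance(table_of(merged))
            assert rv_merged <= rv_full + 1e-9


class TestSymmetries:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(small_tables())
    def test_transposition_flips_rp_and_rc_preserves_pa_and_rv(self, table):
        swapped = table.transposed()
        assert relative_position(swapped) == pytest.approx(
            -relative_position(table), abs=1e-12
        )
        assert relative_concentration(swapped) == pytest.approx(
            -relative_concentration(table), abs=1e-12
        )
        assert percentage_agreement(swapped) == pytest.approx(
            percentage_agreement(table), abs=1e-12
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert relative_rank_variance(swapped) == pytest.approx(
                relative_rank_variance(table), abs=1e-12
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(small_tables(), st.integers(0, 2**31 - 1))
    def test_monotone_relabelling_leaves_all_measures_unchanged(self, table, seed):
        rng = np.random.default_rng(seed)
        # strictly increasing relabelling: random positive gaps
        gaps = rng.integers(1, 10, size=table.n_categories)
        labels = tuple(np.cumsum(gaps))
        relabelled = table.relabelled(labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for measure in (
                percentage_agreement,
                relative_position,
                relative_concentration,
                relative_rank_variance,
            ):
                assert measure(relabelled) == measure(table)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(small_tables())
    def test_measure_ranges(self, table):
        assert 0.0 <= percentage_agreement(table) <= 1.0
        assert -1.0 <= relative_position(table) <= 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert relative_rank_variance(table) >= 0.0
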