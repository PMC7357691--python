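"""Contingency tests: chi-square/Fisher selection, enumeration oracle, odds ratios."""

from itertools import product

import numpy as np
import pytest
from scipy import stats

from trialkit import (
    ContingencyTable,
    collapse,
    fisher_exact_2xc,
    load_packaged_table,
    odds_ratio_2x2,
)
from trialkit.contingency import test_association as assoc_test
from trialkit.errors import ValidationError


def _table(rows, row_labels=("a", "b"), col_labels=None):
    rows = np.asarray(rows)
    if col_labels is None:
        col_labels = tuple(f"c{i}" for i in range(rows.shape[1]))
    return ContingencyTable(rows, tuple(row_labels), tuple(col_labels))


def _fisher_oracle(counts):
    """Independent brute force: multivariate hypergeometric over all top rows."""
    counts = np.asarray(counts, dtype=int)
    col = counts.sum(axis=0)
    r1 = counts[0].sum()
    dist = stats.multivariate_hypergeom(m=col.tolist(), n=int(r1))
    p_obs = dist.pmf(counts[0])
    total = 0.0
    for head in product(*[range(m + 1) for m in col[:-1]]):
        tail = r1 - sum(head)
        if 0 <= tail <= col[-1]:
            p = dist.pmf(list(head) + [tail])
            if p <= p_obs * (1 + 1e-7):
                total += p
    return min(total, 1.0)


class TestAssociation:
    def test_mortality_table_takes_chi_square_path(self):
        res = assoc_test(load_packaged_table("cao_mortality"))
        assert res.test == "chi_square" and res.df == 2

    def test_perfect_independence(self):
        res = assoc_test(_table([[5, 5], [5, 5]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_improvement_table_takes_fisher_path_matching_oracle(self):
        table = load_packaged_table("cao_improvement")
        res = assoc_test(table)
        assert res.test == "fisher"
        assert res.p_value == pytest.approx(_fisher_oracle(table.counts), abs=1e-10)

    @pytest.mark.parametrize(
        "counts",
        [
            [[2, 7], [8, 2]],
            [[1, 3, 4], [4, 2, 1]],
            [[0, 5, 3, 2], [4, 1, 0, 6]],
        ],
    )
    def test_fisher_2xc_matches_enumeration_oracle(self, counts):
        assert fisher_exact_2xc(np.asarray(counts)) == pytest.approx(
            _fisher_oracle(counts), abs=1e-10
        )

    @pytest.mark.parametrize("counts", [[[2, 7], [8, 2]], [[1, 4], [4, 1]], [[0, 6], [3, 3]]])
    def test_fisher_2x2_matches_scipy(self, counts):
        _, p_scipy = stats.fisher_exact(counts, alternative="two-sided")
        assert fisher_exact_2xc(np.asarray(counts)) == pytest.approx(p_scipy, abs=1e-10)

    def test_single_nonzero_column_p_is_one(self):
        assert fisher_exact_2xc(np.array([[4, 0, 0], [7, 0, 0]])) == pytest.approx(1.0)

    def test_chi_square_invariant_under_row_swap(self):
        table = load_packaged_table("cao_mortality")
        swapped = _table(table.counts[::-1], row_labels=table.row_labels[::-1],
                         col_labels=table.col_labels)
        assert assoc_test(table).statistic == pytest.approx(
            assoc_test(swapped).statistic
        )

    def test_zero_row_rejected(self):
        with pytest.raises(ValidationError):
            _table([[0, 0], [1, 2]])


class TestOddsRatio:
    def test_mortality_collapse_reproduces_published_2x2(self):
        table = load_packaged_table("cao_mortality")
        two = collapse(table, {"deaths": [0, 1], "survivors": [2]})
        np.testing.assert_array_equal(two.counts, [[19, 80], [25, 75]])
        res = odds_ratio_2x2(two)
        assert res.odds_ratio == pytest.approx(0.71, abs=0.005)
        assert res.or_ci_low == pytest.approx(0.36, abs=0.005)
        assert res.or_ci_high == pytest.approx(1.40, abs=0.005)

    def test_identical_rows_give_unit_odds_ratio(self):
        res = odds_ratio_2x2(_table([[7, 13], [7, 13]]))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_ci_symmetric_on_log_scale(self):
        res = odds_ratio_2x2(_table([[10, 10], [10, 10]]))
        se = np.sqrt(4 / 10)
        assert np.log(res.or_ci_high) == pytest.approx(1.96 * se, abs=1e-3)
        assert np.log(res.or_ci_low) == pytest.approx(-np.log(res.or_ci_high), abs=1e-10)

    def test_inverts_under_row_swap(self):
        a = odds_ratio_2x2(_table([[19, 80], [25, 75]]))
        b = odds_ratio_2x2(_table([[25, 75], [19, 80]]))
        assert a.odds_ratio == pytest.approx(1.0 / b.odds_ratio)

    def test_zero_cell_haldane_corrected_and_flagged(self):
        res = odds_ratio_2x2(_table([[0, 10], [5, 5]]))
        assert res.continuity_corrected
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 0

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValidationError):
            odds_ratio_2x2(load_packaged_table("cao_mortality"))


class TestCollapse:
    def test_improvement_collapse_arithmetic(self):
        table = load_packaged_table("cao_improvement")
        two = collapse(table, {"improved": [0, 1, 2], "no_improvement": [3]})
        np.testing.assert_array_equal(two.counts, [[78, 22], [70, 30]])
        assert two.counts.sum() == table.counts.sum()

    def test_identity_partition_unchanged(self):
        table = load_packaged_table("cao_mortality")
        same = collapse(table, {c: [i] for i, c in enumerate(table.col_labels)})
        np.testing.assert_array_equal(same.counts, table.counts)

    def test_overlapping_partition_rejected(self):
        table = load_packaged_table("cao_mortality")
        with pytest.raises(ValidationError):
            collapse(table, {"x": [0, 1], "y": [1, 2]})
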