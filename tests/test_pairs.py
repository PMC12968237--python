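"""Pairwise association statistics: counts, lift, chi-square, filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from distortnet import (
    AssociationConfig,
    LabelMatrix,
    concat,
    filter_edges,
    pair_counts,
    pair_stats,
)
from distortnet.pairs import chi2_contingency_2x2, expected_and_lift

from conftest import matrix_from_sets, oracle_chi2, oracle_pair_stats, random_matrix


class TestCounts:
    def test_18_labels_give_153_pairs(self):
        m = matrix_from_sets([{0, 1}], 18)
        assert len(pair_counts(m)) == 153

    def test_hand_counted_overlap(self):
        # A in texts {0,1,2}, B in texts {0,1,3}, 6 texts
        m = matrix_from_sets([{0, 1}, {0, 1}, {0}, {1}, set(), set()], 2)
        row = pair_counts(m).iloc[0]
        assert row.observed == 2 and row.n_i == 3 and row.n_j == 3

    def test_absent_label_has_zero_observed(self):
        m = matrix_from_sets([{0}, {0, 1}], 3)
        df = pair_counts(m)
        assert (df[(df.label_i == "C") | (df.label_j == "C")].observed == 0).all()

    def test_observed_bounded_by_marginals(self, rng):
        m = random_matrix(rng, 80, 6)
        df = pair_counts(m)
        assert (df.observed <= np.minimum(df.n_i, df.n_j)).all()


class TestExpectedLift:
    def test_hand_arithmetic(self):
        m = matrix_from_sets([{0, 1}, {0, 1}, {0}, {1}, set(), set()], 2)
        df = expected_and_lift(pair_counts(m), 6)
        assert df.iloc[0].expected == pytest.approx(1.5)
        assert df.iloc[0].lift == pytest.approx(2 / 1.5)

    def test_lift_one_when_observed_equals_expected(self):
        # A and B independent by construction: A in half, B in half, both in quarter
        sets = [{0, 1}, {0}, {1}, set()] * 5
        df = expected_and_lift(pair_counts(matrix_from_sets(sets, 2)), 20)
        assert df.iloc[0].lift == pytest.approx(1.0)

    def test_zero_expected_reported_missing_not_infinite(self):
        m = matrix_from_sets([{0}, {0}], 3)
        df = expected_and_lift(pair_counts(m), 2)
        bc = df[(df.label_i == "B") & (df.label_j == "C")].iloc[0]
        assert np.isnan(bc.lift)

    def test_lift_invariant_under_corpus_duplication(self, rng):
        m = random_matrix(rng, 60, 5)
        doubled = concat([m, m])
        a = pair_stats(m)["lift"].to_numpy()
        b = pair_stats(doubled)["lift"].to_numpy()
        np.testing.assert_allclose(a, b, equal_nan=True)

    def test_oracle_agreement(self, rng):
        m = random_matrix(rng, 100, 6)
        df = pair_stats(m)
        oracle = oracle_pair_stats(m.incidence)
        labels = list(m.taxonomy.labels)
        for row in df.itertuples():
            key = (labels.index(row.label_i), labels.index(row.label_j))
            assert row.observed == oracle[key]["observed"]
            assert row.expected == pytest.approx(oracle[key]["expected"], abs=1e-12)


class TestChi2:
    def test_closed_form_example(self):
        # 2x2 table [[30,20],[20,30]], n = 100 -> chi2 = 4
        chi2, p = chi2_contingency_2x2(
            np.array([30]), np.array([50]), np.array([50]), 100
        )
        assert chi2[0] == pytest.approx(4.0)
        assert p[0] == pytest.approx(sps.chi2.sf(4.0, 1))

    def test_independence_gives_zero_statistic(self):
        chi2, p = chi2_contingency_2x2(
            np.array([25]), np.array([50]), np.array([50]), 100
        )
        assert chi2[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)

    def test_zero_margin_yields_p_one(self):
        chi2, p = chi2_contingency_2x2(
            np.array([0]), np.array([0]), np.array([10]), 50
        )
        assert chi2[0] == 0.0 and p[0] == 1.0

    def test_against_scipy_on_random_tables(self, rng):
        """1,000 random 2x2 tables agree with the scipy contingency test
        to 1e-9 in both statistic and p-value."""
        for _ in range(1000):
            n = int(rng.integers(10, 500))
            ni = int(rng.integers(1, n))
            nj = int(rng.integers(1, n))
            o = int(rng.integers(max(0, ni + nj - n), min(ni, nj) + 1))
            table = np.array([[o, ni - o], [nj - o, n - ni - nj + o]])
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            expect = sps.chi2_contingency(table, correction=False)
            chi2, p = chi2_contingency_2x2(
                np.array([o]), np.array([ni]), np.array([nj]), n
            )
            assert chi2[0] == pytest.approx(expect.statistic, abs=1e-9)
            assert p[0] == pytest.approx(expect.pvalue, abs=1e-9)

    def test_oracle_closed_form(self, rng):
        m = random_matrix(rng, 120, 5)
        df = pair_stats(m)
        for row in df.itertuples():
            assert row.chi2 == pytest.approx(
                oracle_chi2(row.observed, row.n_i, row.n_j, 120), abs=1e-9
            )


class TestFilter:
    def test_corrected_alpha_is_alpha_over_153(self):
        assert AssociationConfig().corrected_alpha(18) == pytest.approx(0.05 / 153)

    def test_lift_exactly_one_excluded(self):
        df = pd.DataFrame(
            {
                "label_i": ["A"], "label_j": ["B"], "n_i": [10], "n_j": [10],
                "observed": [5], "expected": [5.0], "lift": [1.0],
                "chi2": [50.0], "p_value": [1e-12],
            }
        )
        cfg = AssociationConfig()
        assert len(filter_edges(df, cfg, 18)) == 0

    def test_significance_flag_semantics(self):
        df = pd.DataFrame(
            {
                "label_i": ["A"], "label_j": ["B"], "n_i": [10], "n_j": [10],
                "observed": [8], "expected": [5.0], "lift": [1.6],
                "chi2": [6.0], "p_value": [0.01],
            }
        )
        strict = AssociationConfig()  # corrected alpha ~3.27e-4 < 0.01
        loose = AssociationConfig(apply_significance_filter=False)
        assert len(filter_edges(df, strict, 18)) == 0
        assert len(filter_edges(df, loose, 18)) == 1

    def test_nan_lift_never_passes(self):
        df = pd.DataFrame(
            {
                "label_i": ["A"], "label_j": ["B"], "n_i": [0], "n_j": [10],
                "observed": [0], "expected": [0.0], "lift": [np.nan],
                "chi2": [0.0], "p_value": [1.0],
            }
        )
        assert len(filter_edges(df, AssociationConfig(apply_significance_filter=False), 18)) == 0
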