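"""Synthetic corpus generator: forced structures, determinism, realised
statistics, and the misclassification noise model."""

import numpy as np
import pytest

from distortnet import (
    Bundle,
    NoiseSpec,
    SyntheticConfig,
    generate,
    independent_config,
    inject_noise,
    pair_stats,
    study_config,
    summarize_counts,
)
from distortnet.synthetic import (
    PLANTED_PAIR,
    study_count_distribution,
    study_prevalences,
)
from distortnet.taxonomy import DistortionTaxonomy


def small_config(**kw):
    d = DistortionTaxonomy(("A", "B", "C", "D"))
    defaults = dict(
        n_texts=200,
        prevalences=[0.4, 0.3, 0.2, 0.1],
        count_distribution={1: 0.6, 2: 0.4},
        seed=0,
        taxonomy=d,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestGenerate:
    def test_forced_single_label_rows(self):
        m = generate(small_config(count_distribution={1: 1.0}))
        assert (m.labels_per_text == 1).all()

    def test_forced_bundle_cooccurrence(self):
        cfg = small_config(
            count_distribution={2: 1.0}, bundles=(Bundle(("A", "B"), 1.0),)
        )
        m = generate(cfg)
        assert (m.incidence[:, 0] == 1).all() and (m.incidence[:, 1] == 1).all()

    def test_bit_reproducible_per_seed(self):
        a = generate(small_config(seed=7))
        b = generate(small_config(seed=7))
        c = generate(small_config(seed=8))
        np.testing.assert_array_equal(a.incidence, b.incidence)
        assert not np.array_equal(a.incidence, c.incidence)

    def test_count_exceeding_taxonomy_rejected(self):
        with pytest.raises(ValueError):
            small_config(count_distribution={5: 1.0})

    def test_bundle_weights_capped_at_one(self):
        with pytest.raises(ValueError):
            small_config(
                bundles=(Bundle(("A", "B"), 0.7), Bundle(("C", "D"), 0.7))
            )

    def test_group_assignment_covers_all_texts(self):
        m = generate(small_config(group_count=5))
        assert m.groups is not None and m.groups.shape == (200,)
        assert set(np.unique(m.groups)) <= set(range(5))


class TestRealizedStructure:
    def test_bucket_proportions_match_targets(self):
        """A study-shaped config with one planted pair reproduces the
        published count buckets to within one percentage point."""
        bundles = (Bundle(PLANTED_PAIR, 0.02),)
        cfg = SyntheticConfig(
            n_texts=100_000,
            prevalences=study_prevalences(bundles=bundles),
            count_distribution=study_count_distribution(),
            bundles=bundles,
            seed=11,
        )
        s = summarize_counts(generate(cfg))
        assert s.proportion_by_bucket["1-2"] == pytest.approx(0.823, abs=0.01)
        assert s.proportion_by_bucket["3"] == pytest.approx(0.127, abs=0.01)
        assert s.proportion_by_bucket["4+"] == pytest.approx(0.050, abs=0.01)
        assert s.skewness > 0

    def test_planted_pair_has_top_lift(self):
        bundles = (Bundle(PLANTED_PAIR, 0.02),)
        cfg = SyntheticConfig(
            n_texts=100_000,
            prevalences=study_prevalences(bundles=bundles),
            count_distribution=study_count_distribution(),
            bundles=bundles,
            seed=11,
        )
        ps = pair_stats(generate(cfg))
        top = ps.sort_values("lift", ascending=False).iloc[0]
        assert {top.label_i, top.label_j} == set(PLANTED_PAIR)

    def test_independent_config_lift_converges_to_one(self):
        """Under the exact-independence configuration every pair's lift is
        near 1 (exchangeable null)."""
        m = generate(independent_config(50_000, p=0.25, seed=5))
        ps = pair_stats(m)
        assert np.nanmean(np.abs(ps["lift"] - 1)) < 0.02

    def test_study_config_mean_near_printed(self):
        s = summarize_counts(generate(study_config(50_000, seed=3)))
        assert s.mean_per_text == pytest.approx(1.78, abs=0.08)


class TestInjectNoise:
    def test_zero_noise_is_identity(self):
        m = generate(small_config())
        out = inject_noise(m, NoiseSpec(0.0, seed=1))
        np.testing.assert_array_equal(out.incidence, m.incidence)

    def test_exact_flip_counts_at_half_noise(self):
        """eps = 0.5 with L = 100 positives: exactly 25 deletions and 25
        additions, positive count preserved."""
        rng = np.random.default_rng(0)
        inc = np.zeros((50, 10), dtype=np.uint8)
        pos = rng.choice(500, size=100, replace=False)
        inc.ravel()[pos] = 1
        from conftest import letter_taxonomy
        from distortnet import LabelMatrix

        m = LabelMatrix(inc, letter_taxonomy(10))
        out = inject_noise(m, NoiseSpec(0.5, seed=2))
        deleted = ((m.incidence == 1) & (out.incidence == 0)).sum()
        added = ((m.incidence == 0) & (out.incidence == 1)).sum()
        assert deleted == 25 and added == 25
        assert out.incidence.sum() == 100

    @pytest.mark.parametrize("eps", [0.05, 0.2, 0.5])
    def test_positive_cell_count_preserved(self, eps):
        m = generate(small_config(seed=3))
        out = inject_noise(m, NoiseSpec(eps, seed=4))
        assert abs(int(out.incidence.sum()) - int(m.incidence.sum())) <= 1
        assert set(np.unique(out.incidence)) <= {0, 1}

    def test_original_matrix_unmodified(self):
        m = generate(small_config(seed=5))
        before = m.incidence.copy()
        inject_noise(m, NoiseSpec(0.3, seed=6))
        np.testing.assert_array_equal(m.incidence, before)

    def test_seed_contract(self):
        m = generate(small_config(seed=7))
        a = inject_noise(m, NoiseSpec(0.1, seed=1))
        b = inject_noise(m, NoiseSpec(0.1, seed=1))
        c = inject_noise(m, NoiseSpec(0.1, seed=2))
        np.testing.assert_array_equal(a.incidence, b.incidence)
        assert not np.array_equal(a.incidence, c.incidence)

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            NoiseSpec(0.6)
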