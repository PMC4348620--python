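"""Discretization, FP-growth mining, discriminative screening, features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from irscore import (
    DiscriminativeConfig,
    MiningConfig,
    Pattern,
    compute_pattern_features,
    discretize,
    enumerate_frequent_patterns,
    fit_discretizer,
    mine_frequent_patterns,
    pattern_support,
    select_discriminative_patterns,
    subject_pattern_frequencies,
)
from irscore.patterns import _mannwhitney_vectorized
from irscore.tissue import MetricMatrix


def matrix_from(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"m{j}" for j in range(values.shape[1])]
    return MetricMatrix(np.arange(len(values)), names, values)


class TestDiscretizer:
    def test_unit_range_20_bins(self):
        mat = matrix_from(np.linspace(0, 1, 101)[:, None])
        scheme = fit_discretizer(mat, 20)
        assert scheme.bin_of(0, 0.53) == 10
        assert scheme.representatives[0][10] == pytest.approx(0.525)

    def test_internal_edge_goes_to_upper_bin(self):
        mat = matrix_from(np.linspace(0, 1, 101)[:, None])
        scheme = fit_discretizer(mat, 20)
        assert scheme.bin_of(0, 0.05) == 1  # half-open [lo, hi)

    def test_out_of_range_clips_to_extreme_bins(self):
        mat = matrix_from(np.linspace(0, 1, 101)[:, None])
        scheme = fit_discretizer(mat, 20)
        assert scheme.bin_of(0, 1.7) == 19
        assert scheme.bin_of(0, -2.0) == 0

    def test_discretize_matrix_matches_bin_of(self, rng):
        vals = rng.normal(size=(200, 3))
        mat = matrix_from(vals)
        scheme = fit_discretizer(mat, 20)
        disc = discretize(vals, scheme)
        for i in (0, 57, 199):
            for j in range(3):
                assert disc[i, j] == scheme.bin_of(j, vals[i, j])

    def test_rebinning_representatives_is_idempotent(self, rng):
        vals = rng.uniform(-2, 3, size=(300, 2))
        scheme = fit_discretizer(matrix_from(vals), 20)
        disc = discretize(vals, scheme)
        reps = np.column_stack([
            scheme.representatives[j][disc[:, j]] for j in range(2)
        ])
        assert np.array_equal(discretize(reps, scheme), disc)

    def test_constant_metric_degenerate_bin_with_warning(self):
        mat = matrix_from(np.ones((10, 1)))
        with pytest.warns(UserWarning, match="constant"):
            scheme = fit_discretizer(mat, 20)
        assert np.all(discretize(np.ones((5, 1)), scheme) == 0)

    def test_column_mismatch_rejected(self, rng):
        scheme = fit_discretizer(matrix_from(rng.normal(size=(10, 2))), 5)
        with pytest.raises(ValueError):
            discretize(rng.normal(size=(4, 3)), scheme)


class TestMining:
    def test_worked_example_four_pixels(self):
        # rows over 2 metrics: {(0,0),(0,0),(0,1),(1,1)}, theta = 0.5
        disc = np.array([[0, 0], [0, 0], [0, 1], [1, 1]])
        found = mine_frequent_patterns(disc, MiningConfig(theta=0.5, max_len=None,
                                                          n_bins=2))
        as_dict = {p.sorted_items: p.support_case for p in found}
        assert as_dict == {
            ((0, 0),): 0.75,
            ((1, 0),): 0.5,
            ((1, 1),): 0.5,
            ((0, 0), (1, 0)): 0.5,
        }

    def test_theta_one_identical_rows(self):
        disc = np.tile([2, 0, 1], (5, 1))
        found = mine_frequent_patterns(disc, MiningConfig(theta=1.0, max_len=None,
                                                          n_bins=3))
        # the full row itemset and every sub-itemset, all support 1.0
        assert len(found) == 7
        assert all(p.support_case == 1.0 for p in found)

    def test_theta_above_max_support_empty(self):
        disc = np.array([[0], [1], [0], [1]])
        found = mine_frequent_patterns(disc, MiningConfig(theta=0.75, n_bins=2))
        assert found == []

    def test_matches_enumeration_oracle_random(self, rng):
        for _ in range(10):
            n = int(rng.integers(20, 80))
            k = int(rng.integers(2, 5))
            disc = rng.integers(0, 3, size=(n, k))
            theta = float(rng.choice([0.1, 0.2, 0.4]))
            cfg = MiningConfig(theta=theta, max_len=None, n_bins=3)
            mined = mine_frequent_patterns(disc, cfg)
            oracle = enumerate_frequent_patterns(disc, cfg)
            assert [(p.sorted_items, p.support_case) for p in mined] == \
                   [(p.sorted_items, p.support_case) for p in oracle]

    def test_anti_monotonicity(self, rng):
        disc = rng.integers(0, 3, size=(100, 4))
        cfg = MiningConfig(theta=0.05, max_len=None, n_bins=3)
        found = mine_frequent_patterns(disc, cfg)
        freq_sets = {p.items for p in found}
        for p in found:
            if len(p.items) > 1:
                for item in p.items:
                    assert (p.items - {item}) in freq_sets

    def test_canonical_ordering(self, rng):
        disc = rng.integers(0, 3, size=(60, 3))
        found = mine_frequent_patterns(disc, MiningConfig(theta=0.05, n_bins=3))
        keys = [p.canonical_key() for p in found]
        assert keys == sorted(keys)

    def test_max_len_caps_cardinality(self, rng):
        disc = np.tile([0, 1, 2, 0], (30, 1))
        found = mine_frequent_patterns(disc, MiningConfig(theta=0.5, max_len=2,
                                                          n_bins=3))
        assert max(len(p.items) for p in found) == 2


class TestPatternSupport:
    def test_empty_matrix_rejected(self):
        p = Pattern(items=frozenset({(0, 1)}))
        with pytest.raises(ValueError):
            pattern_support(p, np.empty((0, 2)))

    def test_half_support(self):
        disc = np.array([[1, 0], [1, 1], [0, 0], [1, 0]])
        p = Pattern(items=frozenset({(0, 1), (1, 0)}))
        assert pattern_support(p, disc) == 0.5

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_superset_support_never_exceeds_subset(self, seed):
        rng = np.random.default_rng(seed)
        disc = rng.integers(0, 3, size=(50, 4))
        metrics = rng.choice(4, size=3, replace=False)
        items = [(int(m), int(rng.integers(0, 3))) for m in metrics]
        sub = Pattern(items=frozenset(items[:2]))
        sup = Pattern(items=frozenset(items))
        assert pattern_support(sup, disc) <= pattern_support(sub, disc)


class TestPatternType:
    def test_duplicate_metric_rejected(self):
        with pytest.raises(ValueError, match="one item per metric"):
            Pattern(items=frozenset({(0, 1), (0, 2)}))

    def test_empty_items_rejected(self):
        with pytest.raises(ValueError):
            Pattern(items=frozenset())


class TestSubjectFrequencies:
    def test_pooled_fraction_per_subject(self):
        disc = np.array([[0], [0], [1], [0], [1], [1]])
        subj = np.array([0, 0, 0, 1, 1, 1])
        p = Pattern(items=frozenset({(0, 0)}))
        freqs = subject_pattern_frequencies([p], disc, subj, 2)
        np.testing.assert_allclose(freqs[:, 0], [2 / 3, 1 / 3])

    def test_invariant_to_pixel_ordering(self, rng):
        disc = rng.integers(0, 3, size=(90, 2))
        subj = rng.integers(0, 3, size=90)
        p = Pattern(items=frozenset({(0, 1), (1, 2)}))
        f1 = subject_pattern_frequencies([p], disc, subj, 3)
        perm = rng.permutation(90)
        f2 = subject_pattern_frequencies([p], disc[perm], subj[perm], 3)
        np.testing.assert_allclose(f1, f2)


class TestMannWhitneyVectorized:
    def test_matches_scipy_with_and_without_ties(self, rng):
        for trial in range(10):
            n1, n2 = int(rng.integers(5, 25)), int(rng.integers(5, 25))
            x = rng.choice([0.0, 0.1, 0.25, 0.7], size=(1, n1)) \
                if trial % 2 else rng.normal(size=(1, n1))
            y = rng.choice([0.0, 0.1, 0.25, 0.7], size=(1, n2)) \
                if trial % 2 else rng.normal(size=(1, n2))
            u, z = _mannwhitney_vectorized(x, y)
            ref = stats.mannwhitneyu(x[0], y[0], alternative="two-sided",
                                     method="asymptotic", use_continuity=False)
            assert u[0] == pytest.approx(ref.statistic)
            p = 2 * stats.norm.sf(abs(z[0]))
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestDiscriminativeSelection:
    def test_constant_frequencies_removed_at_stage1(self, rng):
        p = Pattern(items=frozenset({(0, 1)}), source_class="case")
        fc = np.full((1, 10), 0.3)
        fn = np.full((1, 12), 0.3)
        out = select_discriminative_patterns([p], fc, fn,
                                             DiscriminativeConfig(m=10))
        assert out == []

    def test_wrong_direction_removed_at_stage2(self, rng):
        # pattern tagged "case" but clearly higher in controls
        p = Pattern(items=frozenset({(0, 1)}), source_class="case")
        fc = rng.normal(0.1, 0.01, size=(1, 20))
        fn = rng.normal(0.5, 0.01, size=(1, 20))
        out = select_discriminative_patterns([p], fc, fn,
                                             DiscriminativeConfig(m=10))
        assert out == []

    def test_enriched_pattern_ranked_first(self, rng):
        strong = Pattern(items=frozenset({(0, 1)}), source_class="case")
        weak = Pattern(items=frozenset({(1, 2)}), source_class="case")
        noise = Pattern(items=frozenset({(2, 3)}), source_class="case")
        n = 30
        fc = np.vstack([rng.normal(0.30, 0.03, n), rng.normal(0.12, 0.03, n),
                        rng.normal(0.10, 0.03, n)])
        fn = np.vstack([rng.normal(0.05, 0.03, n), rng.normal(0.08, 0.03, n),
                        rng.normal(0.10, 0.03, n)])
        out = select_discriminative_patterns([strong, weak, noise], fc, fn,
                                             DiscriminativeConfig(m=2))
        assert out[0].pattern is strong
        assert len(out) <= 2

    def test_requires_two_subjects_per_class(self):
        p = Pattern(items=frozenset({(0, 1)}), source_class="case")
        with pytest.raises(ValueError):
            select_discriminative_patterns([p], np.zeros((1, 1)), np.zeros((1, 5)),
                                           DiscriminativeConfig())


class TestPatternFeatures:
    pats = [Pattern(items=frozenset({(0, 1)})), Pattern(items=frozenset({(0, 0), (1, 2)}))]

    def test_all_match_is_one(self):
        disc = np.tile([1, 0], (8, 1))
        fv = compute_pattern_features(disc, self.pats[:1])
        assert fv.values[0] == 1.0

    def test_no_match_is_zero(self):
        disc = np.tile([0, 0], (8, 1))
        fv = compute_pattern_features(disc, self.pats[:1])
        assert fv.values[0] == 0.0

    def test_partial_match_fraction(self):
        disc = np.array([[1, 0]] * 3 + [[0, 0]] * 7)
        fv = compute_pattern_features(disc, self.pats[:1])
        assert fv.values[0] == pytest.approx(0.3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compute_pattern_features(np.empty((0, 2)), self.pats)
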