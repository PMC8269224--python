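import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import adjusted_rand_score

from planoflux.omics_stats import (
    RankedGroup,
    anova_bh,
    compute_tpm,
    de_filter,
    detected_features,
    iga_pc,
    kmeans_trends,
    log_normalize,
)
from planoflux.synthetic_data import (
    ARCHETYPES,
    OmicsSimSpec,
    make_synthetic_counts,
)


def exact_iga_pc(membership) -> Fraction:
    """Brute-force oracle: exact rational minimum of the hypergeometric
    tail over ALL cutoffs (not only member-occupied ones)."""
    membership = np.asarray(membership, dtype=bool)
    N, K = membership.size, int(membership.sum())
    best = Fraction(1)
    x = 0
    for t in range(1, N + 1):
        x += bool(membership[t - 1])
        tail = sum(
            math.comb(K, k) * math.comb(N - K, t - k)
            for k in range(x, min(K, t) + 1)
        )
        best = min(best, Fraction(tail, math.comb(N, t)))
    return best


class TestTPM:
    def test_hand_computed_example(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 2000], index=["g1", "g2"])
        tpm = compute_tpm(counts, lengths)
        assert tpm.loc["g1", "s1"] == pytest.approx(666666.666, rel=1e-6)
        assert tpm.loc["g2", "s1"] == pytest.approx(333333.333, rel=1e-6)

    def test_equal_counts_equal_lengths_symmetry(self):
        g = 8
        counts = pd.DataFrame({"s1": [7] * g})
        lengths = pd.Series([500] * g)
        assert np.allclose(compute_tpm(counts, lengths), 1e6 / g)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 1000, size=(50, 6)))
        lengths = pd.Series(rng.integers(200, 5000, size=50))
        sums = compute_tpm(counts, lengths).sum(axis=0)
        assert np.allclose(sums, 1e6, atol=1e-6)

    def test_invariant_to_library_scaling(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 100, size=(20, 2)))
        lengths = pd.Series(rng.integers(300, 3000, size=20))
        a = compute_tpm(counts, lengths)
        b = compute_tpm(counts * 17, lengths)
        assert np.allclose(a, b)

    def test_all_zero_sample_stays_zero(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [5, 5]})
        lengths = pd.Series([100, 100])
        tpm = compute_tpm(counts, lengths)
        assert (tpm["s1"] == 0).all()
        assert tpm["s2"].sum() == pytest.approx(1e6)

    def test_detection_threshold_helper(self):
        tpm = pd.DataFrame(
            {"t1_r1": [10.0, 1.0], "t1_r2": [12.0, 2.0],
             "t2_r1": [0.0, 4.0], "t2_r2": [0.0, 6.0]},
            index=["hi", "lo"],
        )
        groups = pd.Series([1, 1, 2, 2], index=tpm.columns)
        det = detected_features(tpm, groups, threshold=5.0)
        assert bool(det["hi"]) is True
        assert bool(det["lo"]) is False


class TestAnovaBH:
    def _null_matrix(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        cols = [f"t{t}_r{r}" for t in range(5) for r in range(3)]
        mat = pd.DataFrame(rng.normal(5.0, 1.0, size=(n, 15)), columns=cols)
        groups = pd.Series([c.split("_")[0] for c in cols], index=cols)
        return mat, groups

    def test_null_false_positive_rate(self):
        mat, groups = self._null_matrix(n=1000, seed=4)
        res = anova_bh(mat, groups, alpha=0.05)
        # raw p-values are uniform under the null
        frac = (res["p"] < 0.05).mean()
        assert frac <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 1000)
        # BH-adjusted selections are rarer still
        assert res["significant"].mean() <= frac

    def test_constant_feature_gets_p_one(self):
        mat, groups = self._null_matrix(n=10)
        mat.iloc[0] = 3.14
        res = anova_bh(mat, groups)
        assert res["p"].iloc[0] == 1.0

    def test_bh_adjustment_monotone_in_rank(self):
        mat, groups = self._null_matrix(n=200, seed=1)
        res = anova_bh(mat, groups).sort_values("p")
        assert (np.diff(res["p_adj"]) >= -1e-12).all()

    def test_alpha_extremes(self):
        mat, groups = self._null_matrix(n=50, seed=2)
        everything = anova_bh(mat, groups, alpha=1.0)
        assert everything["significant"].all()
        nothing = anova_bh(mat, groups, alpha=0.0)
        assert not nothing["significant"].any()

    def test_strong_signal_detected(self):
        mat, groups = self._null_matrix(n=50, seed=3)
        mat.iloc[0, :3] += 30.0  # first time point shifted far away
        res = anova_bh(mat, groups)
        assert res["significant"].iloc[0]

    def test_single_group_rejected(self):
        mat, _ = self._null_matrix(n=5)
        groups = pd.Series("g", index=mat.columns)
        with pytest.raises(ValueError):
            anova_bh(mat, groups)


class TestDEFilter:
    def test_flat_profile_not_selected(self):
        p = pd.Series([0.01], index=["f"])
        prof = pd.DataFrame([[100.0] * 5], index=["f"])
        assert not de_filter(p, prof).iloc[0]

    def test_fold_change_gate(self):
        p = pd.Series([0.01], index=["f"])
        prof = pd.DataFrame([[100.0, 250.0]], index=["f"])
        assert de_filter(p, prof).iloc[0]  # log2(2.5) = 1.32 > 1

    def test_fdr_gate(self):
        p = pd.Series([0.2], index=["f"])
        prof = pd.DataFrame([[1.0, 1000.0]], index=["f"])
        assert not de_filter(p, prof).iloc[0]

    def test_zero_mean_uses_pseudocount(self):
        # pseudo-count = smallest positive value in the profile matrix (2.0)
        p = pd.Series([0.01, 0.5], index=["f", "g"])
        prof = pd.DataFrame([[0.0, 50.0], [2.0, 80.0]], index=["f", "g"])
        sel = de_filter(p, prof)
        assert sel["f"]  # log2(50/2) >> 1, no division blow-up
        assert not sel["g"]  # fails the FDR gate


class TestKMeansTrends:
    def _archetype_matrix(self, copies=50):
        profiles = np.repeat(ARCHETYPES, copies, axis=0)
        truth = np.repeat(np.arange(8), copies)
        cols = [f"t{t}" for t in range(5)]
        return pd.DataFrame(profiles, columns=cols), truth

    def test_noiseless_archetypes_recovered_exactly(self):
        mat, truth = self._archetype_matrix()
        result = kmeans_trends(mat, k=8, seed=0)
        assert adjusted_rand_score(truth, result.assignments) == 1.0

    def test_duplication_leaves_centroids_unchanged(self):
        mat, _ = self._archetype_matrix(copies=10)
        a = kmeans_trends(mat, k=8, seed=0)
        b = kmeans_trends(pd.concat([mat, mat]), k=8, seed=0)
        assert np.allclose(a.centroids.to_numpy(), b.centroids.to_numpy(),
                           atol=1e-8)

    def test_deterministic_under_seed(self):
        counts, _, groups, _ = make_synthetic_counts(
            OmicsSimSpec(n_features=100, seed=8)
        )
        logn = log_normalize(counts)
        a = kmeans_trends(logn, groups, seed=5)
        b = kmeans_trends(logn, groups, seed=5)
        assert a.assignments.equals(b.assignments)

    def test_labels_ordered_by_centroid_peak(self):
        mat, _ = self._archetype_matrix(copies=5)
        result = kmeans_trends(mat, k=8, seed=0)
        peaks = result.centroids.to_numpy().argmax(axis=1)
        assert (np.diff(peaks) >= 0).all()

    def test_too_many_clusters_rejected(self):
        mat, _ = self._archetype_matrix(copies=1)
        with pytest.raises(ValueError):
            kmeans_trends(mat.iloc[:5], k=8, seed=0)

    def test_inertia_exposed_nonnegative(self):
        mat, _ = self._archetype_matrix(copies=3)
        assert kmeans_trends(mat, k=8, seed=0).inertia >= 0.0


class TestIGA:
    def test_exhaustive_small_case(self):
        # members at ranks 1-3 of 10: P(X>=3 | n=3) = 1/C(10,3)
        mask = np.zeros(10, dtype=bool)
        mask[:3] = True
        assert iga_pc(RankedGroup(mask)) == pytest.approx(1.0 / 120.0)

    def test_whole_list_group_is_certain(self):
        assert iga_pc(RankedGroup(np.ones(25, dtype=bool))) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            RankedGroup(np.zeros(10, dtype=bool))

    def test_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 201))
            k = int(rng.integers(1, min(n, 20) + 1))
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=k, replace=False)] = True
            expected = float(exact_iga_pc(mask))
            assert iga_pc(RankedGroup(mask)) == pytest.approx(
                expected, rel=1e-9
            )

    @settings(derandomize=True, max_examples=60)
    @given(mask=arrays(bool, st.integers(2, 120)))
    def test_bounded_probability_on_any_mask(self, mask):
        """Property: PC is a probability for every nonempty membership."""
        if not mask.any():
            mask = mask.copy()
            mask[0] = True
        pc = iga_pc(RankedGroup(mask))
        assert 0.0 < pc <= 1.0

    def test_monotone_under_rank_improvement(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            mask = np.zeros(60, dtype=bool)
            mask[rng.choice(60, size=6, replace=False)] = True
            before = iga_pc(RankedGroup(mask.copy()))
            # move the worst-ranked member up to the best free slot
            worst = np.flatnonzero(mask)[-1]
            free = np.flatnonzero(~mask)[0]
            if free < worst:
                mask[worst] = False
                mask[free] = True
            assert iga_pc(RankedGroup(mask)) <= before + 1e-15
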