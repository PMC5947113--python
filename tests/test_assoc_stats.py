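"""Pearson matrices, correlation PCA and hierarchical clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rootmru.assoc_stats import (
    AssocError,
    hcluster,
    pca_correlation,
    pearson_matrix,
    significance_flags,
)


def _table(**cols):
    return pd.DataFrame(cols)


class TestPearsonMatrix:
    def test_exact_linearity(self):
        res = pearson_matrix(_table(x=[1, 2, 3], y=[2, 4, 6]))
        assert res.r.loc["x", "y"] == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        res = pearson_matrix(_table(x=[1, 2, 3], y=[6, 4, 2]))
        assert res.r.loc["x", "y"] == pytest.approx(-1.0)

    def test_four_point_example(self):
        # by the covariance/sd formula: cov* (n-1) = 4, sds give 5 -> r = 0.8
        res = pearson_matrix(_table(x=[1, 2, 3, 4], y=[1, 3, 2, 4]))
        assert res.r.loc["x", "y"] == pytest.approx(0.8, abs=1e-12)
        assert res.n.loc["x", "y"] == 4

    def test_pairwise_complete_counts(self):
        res = pearson_matrix(
            _table(x=[1, 2, 3, 4, np.nan], y=[2, 4, 5, np.nan, 9], z=[1, 1, 2, 3, 5])
        )
        assert res.n.loc["x", "y"] == 3
        assert res.n.loc["x", "z"] == 4

    def test_zero_variance_column_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pearson_matrix(_table(x=[1, 2, 3], c=[5, 5, 5]))
        assert math.isnan(res.r.loc["x", "c"])

    def test_too_few_pairs_undefined(self):
        with pytest.warns(UserWarning, match="complete pairs"):
            res = pearson_matrix(_table(x=[1, 2, np.nan], y=[1, np.nan, 3]))
        assert math.isnan(res.r.loc["x", "y"])

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = x + rng.normal(scale=0.5, size=20)
        base = pearson_matrix(_table(x=x, y=y)).r.loc["x", "y"]
        shifted = pearson_matrix(_table(x=3.0 * x + 7.0, y=0.2 * y - 1.0)).r.loc["x", "y"]
        flipped = pearson_matrix(_table(x=x, y=-y)).r.loc["x", "y"]
        assert shifted == pytest.approx(base, rel=1e-12)
        assert flipped == pytest.approx(-base, rel=1e-12)

    def test_p_matches_permutation_oracle(self):
        """The t-transform p-value agrees with a 10,000-permutation null
        within Monte-Carlo error on a small fixture."""
        x = np.array([2.1, 3.4, 1.2, 5.6, 4.4, 3.9, 2.8, 5.1, 1.9, 4.0])
        y = np.array([1.0, 2.9, 1.8, 4.2, 3.1, 4.4, 2.2, 3.6, 2.5, 3.0])
        res = pearson_matrix(_table(x=x, y=y))
        r_obs = abs(res.r.loc["x", "y"])
        rng = np.random.default_rng(12345)
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        n = len(x)
        hits = 0
        for _ in range(10_000):
            perm = rng.permutation(zy)
            hits += abs(float(zx @ perm) / (n - 1)) >= r_obs - 1e-12
        p_perm = hits / 10_000
        assert res.p.loc["x", "y"] == pytest.approx(p_perm, abs=5e-3)


class TestSignificanceFlags:
    def test_strong_correlation_double_starred(self):
        # r = 0.97 at n = 13: t = 0.97*sqrt(11)/sqrt(1-0.9409) ~ 13.2 on 11 df
        x = np.arange(13.0)
        rng = np.random.default_rng(5)
        for _ in range(100):
            y = x + rng.normal(scale=1.05, size=13)
            r = stats.pearsonr(x, y)[0]
            if abs(r - 0.97) < 0.005:
                break
        res = pearson_matrix(_table(x=x, y=y))
        flags = significance_flags(res)
        assert flags.loc["x", "y"] == "**"

    def test_zero_correlation_unflagged(self):
        res = pearson_matrix(_table(x=[1, 2, 3, 4], y=[1, 2, 2, 1]))
        flags = significance_flags(res)
        assert flags.loc["x", "y"] == ""

    def test_moderate_r_at_tiny_n_unflagged(self):
        # r = 0.5 on n = 4 -> t ~ 0.816 on 2 df, p > 0.4
        x = np.array([1.0, 2.0, 3.0, 4.0])
        xd = x - x.mean()
        ud = np.array([0.5, -1.5, 1.5, -0.5])  # orthogonal to xd, same norm
        y = 0.5 * xd + math.sqrt(0.75) * ud + 2.5
        res = pearson_matrix(_table(x=x, y=y))
        assert res.r.loc["x", "y"] == pytest.approx(0.5, abs=1e-12)
        assert res.p.loc["x", "y"] > 0.4
        assert significance_flags(res).loc["x", "y"] == ""

    def test_bh_adjustment_is_more_conservative(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(10, 6)), columns=list("abcdef"))
        res = pearson_matrix(df)
        raw = significance_flags(res)
        adj = significance_flags(res, adjust="bh")
        raw_hits = (raw.to_numpy() != "").sum()
        adj_hits = (adj.to_numpy() != "").sum()
        assert adj_hits <= raw_hits


class TestPcaCorrelation:
    def test_rank_one_table(self):
        x = np.arange(1.0, 7.0)
        res = pca_correlation(_table(x=x, y=2 * x))
        assert res.variance_fraction.tolist() == pytest.approx([1.0, 0.0], abs=1e-9)

    def test_two_variables_r08_gives_09_01(self):
        # eigenvalues of [[1, r], [r, 1]] are 1 +/- r
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])  # r = 0.8 with x
        res = pca_correlation(_table(x=x, y=y))
        assert res.variance_fraction.tolist() == pytest.approx([0.9, 0.1], abs=1e-9)

    def test_uncorrelated_pair_is_isotropic(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 1.0])  # r = 0 with x
        res = pca_correlation(_table(x=x, y=y))
        assert res.variance_fraction.tolist() == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_fractions_sum_to_one_and_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        res = pca_correlation(df)
        fr = res.variance_fraction.to_numpy()
        assert fr.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(fr) <= 1e-12).all()
        gram = res.loadings.to_numpy().T @ res.loadings.to_numpy()
        assert gram == pytest.approx(np.eye(5), abs=1e-9)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        res = pca_correlation(df)
        for comp in res.loadings.columns:
            col = res.loadings[comp].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_duplicating_a_variable_increases_pc1(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        base = pca_correlation(df).variance_fraction.iloc[0]
        dup = df.assign(a2=df["a"])
        boosted = pca_correlation(dup).variance_fraction.iloc[0]
        assert boosted > base

    def test_constant_column_named_in_error(self):
        df = _table(x=[1.0, 2.0, 3.0], flat=[4.0, 4.0, 4.0])
        with pytest.raises(AssocError, match="flat"):
            pca_correlation(df)


def _naive_average_linkage(dist: np.ndarray, labels: list[str]):
    """O(n^3) agglomeration oracle: merge the closest pair, with average
    linkage recomputed from the original distances of cluster members."""
    clusters = [frozenset([i]) for i in range(len(labels))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a] | clusters[b], d))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


class TestHcluster:
    def test_perfectly_correlated_pair_merges_at_zero(self):
        x = np.arange(1.0, 7.0)
        res = hcluster(_table(x=x, y=3 * x + 1))
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_identical_pair_merges_first(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=10)
        indep = rng.normal(size=10)
        res = hcluster(_table(a=x, b=2 * x, c=indep))
        first = {res.labels[int(res.linkage[0, 0])], res.labels[int(res.linkage[0, 1])]}
        assert first == {"a", "b"}

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(15, 6)), columns=list("abcdef"))
        res = hcluster(df)
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_matches_naive_agglomeration_oracle(self):
        """Merge heights and merge sets of a 5-variable table agree with a
        brute-force average-linkage agglomerator."""
        rng = np.random.default_rng(9)
        base = rng.normal(size=12)
        df = pd.DataFrame(
            {
                "a": base + rng.normal(scale=0.1, size=12),
                "b": base + rng.normal(scale=0.2, size=12),
                "c": rng.normal(size=12),
                "d": -base + rng.normal(scale=0.3, size=12),
                "e": rng.normal(size=12),
            }
        )
        r = pearson_matrix(df).r.to_numpy()
        dist = 1.0 - r
        np.fill_diagonal(dist, 0.0)
        oracle = _naive_average_linkage(dist, list(df.columns))

        res = hcluster(df)
        # reconstruct merge member-sets from the scipy linkage matrix
        members = {i: frozenset([i]) for i in range(5)}
        for step, row in enumerate(res.linkage):
            merged = members[int(row[0])] | members[int(row[1])]
            members[5 + step] = merged
            assert merged == oracle[step][0]
            assert row[2] == pytest.approx(oracle[step][1], rel=1e-9)

    def test_newick_contains_all_labels(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(10, 4)), columns=["w", "x", "y", "z"])
        res = hcluster(df)
        for label in "wxyz":
            assert label in res.newick
        assert res.newick.endswith(";")

    def test_single_variable_rejected(self):
        with pytest.raises(AssocError):
            hcluster(_table(x=[1.0, 2.0, 3.0]))
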