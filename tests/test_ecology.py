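"""Ecology layer: closed-form diversity values, the Bray-Curtis worked
example, classical-scaling properties of the PCoA, and PERMANOVA validity
against brute-force enumeration and an independent implementation."""

import numpy as np
import pandas as pd
import pytest

from helpers import permanova_f, permanova_p_enumerated
from virome import ecology


def ab(data, samples=None):
    df = pd.DataFrame(np.asarray(data, dtype=float))
    df.index = samples or [f"s{i}" for i in range(len(df))]
    return df


class TestAccumulationCurve:
    def test_full_subset_equals_union_richness_with_zero_sd(self, rng):
        x = (rng.random((6, 30)) > 0.5).astype(float)
        x[:, 0] = 1.0  # avoid empty rows
        a = ab(x / x.sum(axis=1, keepdims=True))
        groups = pd.Series(["g"] * 6, index=a.index)
        curve = ecology.accumulation_curve(a, groups, n_reps=10, seed=0)
        last = curve[curve["k"] == 6].iloc[0]
        union = (x > 0).any(axis=0).sum()
        assert last["mean_richness"] == union
        assert last["sd_richness"] == 0.0

    def test_identical_samples_give_flat_curve(self):
        row = [0.5, 0.5, 0.0]
        a = ab([row] * 5)
        groups = pd.Series(["g"] * 5, index=a.index)
        curve = ecology.accumulation_curve(a, groups, n_reps=5, seed=0)
        assert (curve["mean_richness"] == 2).all()

    def test_mean_curve_non_decreasing(self, rng):
        x = rng.dirichlet(np.ones(40), size=8) * (rng.random((8, 40)) > 0.3)
        x[:, 0] += 1e-3
        a = ab(x / x.sum(axis=1, keepdims=True))
        groups = pd.Series(["g"] * 8, index=a.index)
        curve = ecology.accumulation_curve(a, groups, n_reps=50, seed=1)
        assert (np.diff(curve["mean_richness"]) >= -1e-9).all()


class TestAlphaDiversity:
    def test_uniform_profile_closed_form(self):
        out = ecology.alpha_diversity(ab([[0.1] * 10]))
        assert out["shannon"].iloc[0] == pytest.approx(np.log(10), abs=1e-12)
        assert out["simpson"].iloc[0] == pytest.approx(0.9, abs=1e-12)
        assert out["observed_votus"].iloc[0] == 10

    def test_single_feature_zero_diversity(self):
        out = ecology.alpha_diversity(ab([[1.0, 0.0]]))
        assert out["shannon"].iloc[0] == 0.0
        assert out["simpson"].iloc[0] == 0.0

    def test_two_even_features(self):
        out = ecology.alpha_diversity(ab([[0.5, 0.5]]))
        assert out["shannon"].iloc[0] == pytest.approx(np.log(2))
        assert out["simpson"].iloc[0] == pytest.approx(0.5)

    def test_feature_order_invariant(self, rng):
        x = rng.dirichlet(np.ones(15), size=3)
        a = ecology.alpha_diversity(ab(x))
        b = ecology.alpha_diversity(ab(x[:, ::-1]))
        np.testing.assert_allclose(a["shannon"], b["shannon"])

    def test_negative_abundance_fails(self):
        with pytest.raises(ValueError):
            ecology.alpha_diversity(ab([[1.2, -0.2]]))


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = ecology.bray_curtis(ab([[0.5, 0.5], [0.5, 0.5]]))
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = ecology.bray_curtis(ab([[1.0, 0.0], [0.0, 1.0]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_worked_example(self):
        d = ecology.bray_curtis(ab([[0.7, 0.3, 0.0], [0.3, 0.3, 0.4]]))
        assert d.iloc[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_metric_axioms_on_simplex(self, rng):
        x = rng.dirichlet(np.ones(8), size=6)
        d = ecology.bray_curtis(ab(x)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 1 + 1e-12)).all()


class TestPCoA:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [2.0], [4.0], [7.0]])
        from scipy.spatial.distance import pdist, squareform
        d = pd.DataFrame(squareform(pdist(pts)))
        res = ecology.pcoa(d)
        assert res.variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
        axis = res.coordinates.iloc[:, 0].to_numpy()
        gaps = np.abs(np.diff(axis))
        assert np.allclose(gaps, [1, 1, 2, 3])

    def test_all_equal_points_zero_coordinates(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        res = ecology.pcoa(d)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_roundtrip(self, rng):
        from scipy.spatial.distance import pdist, squareform
        pts = rng.normal(size=(7, 3))
        d = pd.DataFrame(squareform(pdist(pts)))
        res = ecology.pcoa(d)
        d2 = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(d2 - d.to_numpy()).max() < 1e-8

    def test_matches_reference_implementation(self, rng):
        """Variance-explained ratios agree with scikit-bio's PCoA."""
        import skbio
        x = rng.dirichlet(np.ones(10), size=8)
        d = ecology.bray_curtis(ab(x))
        mine = ecology.pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)))
        pos = ref.eigvals[ref.eigvals > 1e-10].to_numpy()
        np.testing.assert_allclose(mine.eigenvalues, pos, atol=1e-8)

    def test_asymmetric_input_fails(self):
        d = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ecology.pcoa(d)


class TestPermanova:
    def test_pseudo_f_matches_group_decomposition(self, rng):
        """The hat-matrix trace form equals the classic within/between
        sum-of-squares pseudo-F for a categorical factor."""
        x = rng.dirichlet(np.ones(12), size=10)
        a = ab(x)
        labels = pd.Series(["u"] * 5 + ["v"] * 5, index=a.index, name="g")
        d = ecology.bray_curtis(a)
        res = ecology.permanova(d, labels, n_permutations=9, seed=0)
        f_oracle = permanova_f(d.to_numpy(), labels.to_numpy())
        assert res.f_stat == pytest.approx(f_oracle, rel=1e-10)

    def test_matches_reference_implementation(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova
        x = rng.dirichlet(np.ones(15), size=12)
        a = ab(x)
        labels = pd.Series(["u"] * 6 + ["v"] * 6, index=a.index, name="g")
        d = ecology.bray_curtis(a)
        mine = ecology.permanova(d, labels, n_permutations=999, seed=3)
        ref = sk_permanova(DistanceMatrix(d.to_numpy(), ids=list(d.index)),
                           labels.to_numpy(), permutations=999)
        assert mine.f_stat == pytest.approx(ref["test statistic"],
                                            rel=1e-10)
        assert mine.p == pytest.approx(ref["p-value"], abs=0.05)

    def test_small_design_matches_full_enumeration(self, rng):
        """n=6 with two groups of 3: the permutation p agrees with the
        exhaustive 20-assignment oracle within Monte-Carlo error."""
        x = rng.dirichlet(np.ones(8), size=6)
        a = ab(x)
        labels = pd.Series(["u"] * 3 + ["v"] * 3, index=a.index, name="g")
        d = ecology.bray_curtis(a)
        exact = permanova_p_enumerated(d.to_numpy(), labels.to_numpy())
        est = ecology.permanova(d, labels, n_permutations=1999, seed=1).p
        assert est == pytest.approx(exact, abs=0.05)

    def test_disjoint_groups_min_p_large_r2(self, rng):
        left = rng.dirichlet(np.ones(5), size=10)
        right = rng.dirichlet(np.ones(5), size=10)
        x = np.zeros((20, 10))
        x[:10, :5] = left
        x[10:, 5:] = right
        a = ab(x)
        labels = pd.Series(["u"] * 10 + ["v"] * 10, index=a.index, name="g")
        res = ecology.permanova(ecology.bray_curtis(a), labels,
                                n_permutations=1000, seed=0)
        # at the permutation floor, save for the rare permutation that
        # reproduces the observed grouping exactly and ties F_obs
        assert res.p <= 3 / 1001
        assert res.r2 > 0.5
        assert res.adjusted_r2 <= res.r2

    def test_constant_factor_fails(self, rng):
        x = rng.dirichlet(np.ones(5), size=4)
        a = ab(x)
        labels = pd.Series(["u"] * 4, index=a.index, name="g")
        with pytest.raises(ValueError, match="constant"):
            ecology.permanova(ecology.bray_curtis(a), labels)

    def test_p_respects_permutation_floor(self, rng):
        x = rng.dirichlet(np.ones(6), size=8)
        a = ab(x)
        labels = pd.Series(["u", "v"] * 4, index=a.index, name="g")
        res = ecology.permanova(ecology.bray_curtis(a), labels,
                                n_permutations=99, seed=0)
        assert res.p >= 1 / 100
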