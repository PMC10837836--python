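"""Diversity statistics checked against closed forms, brute-force permutation
oracles, and independent scikit-bio implementations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from spongefunc.diversity import (
    bray_curtis,
    dispersion_homogeneity,
    group_variability,
    log2_transform,
    pairwise_permanova,
    pcoa,
    permanova,
    shannon,
    variability_contrast,
)


def euclidean_dm(points: np.ndarray, ids=None) -> DistanceMatrix:
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestShannon:
    def test_uniform_gives_log_richness(self):
        assert shannon([1] * 8) == pytest.approx(math.log(8), abs=1e-12)

    def test_single_support_gives_zero(self):
        assert shannon([0, 7, 0]) == 0.0

    def test_direct_formula(self):
        p = np.array([1, 2, 3]) / 6
        expected = -(p * np.log(p)).sum()
        assert shannon([1, 2, 3]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.0114, abs=1e-4)

    def test_permutation_invariant_and_maximized_by_uniform(self):
        rng = np.random.default_rng(0)
        v = rng.integers(1, 50, 10)
        assert shannon(v) == pytest.approx(shannon(v[::-1]))
        assert shannon(v) <= math.log(10) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestBrayCurtis:
    def test_hand_value(self):
        m = pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=["x", "y"])
        assert bray_curtis(m)["x", "y"] == pytest.approx(0.5)

    def test_identical_rows_zero_disjoint_rows_one(self):
        m = pd.DataFrame(
            [[3, 1, 2, 0], [3, 1, 2, 0], [0, 0, 0, 5]], index=["a", "b", "c"]
        ).astype(float)
        dm = bray_curtis(m)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0

    def test_two_all_zero_samples_rejected(self):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 2]], index=["x", "y", "z"])
        with pytest.raises(ValueError, match="x"):
            bray_curtis(m)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_axioms_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.integers(0, 30, (4, 6)) + np.eye(4, 6))
        d = bray_curtis(m).data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert ((d >= 0) & (d <= 1)).all()


class TestPcoa:
    def test_two_samples_forced_geometry(self):
        dm = DistanceMatrix([[0, 0.6], [0.6, 0]], ids=["a", "b"])
        res = pcoa(dm)
        assert res.coordinates.shape == (2, 1)
        assert sorted(res.coordinates["PC1"].round(9)) == [-0.3, 0.3]

    def test_isometry_on_planted_points(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(4, 2))
        res = pcoa(euclidean_dm(points))
        recovered = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(recovered - squareform(pdist(points))).max() < 1e-9

    def test_eigenvalues_descending_and_proportions_sum_to_one(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.integers(1, 40, (5, 8)))
        res = pcoa(bray_curtis(log2_transform(m / m.to_numpy().sum(1, keepdims=True))))
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.integers(0, 40, (6, 10)) + 1)
        dm = bray_curtis(m)
        ours = pcoa(dm)
        theirs = skbio_pcoa(dm, number_of_dimensions=0)
        n_pos = ours.coordinates.shape[1]
        assert np.allclose(
            ours.eigenvalues[:n_pos], theirs.eigvals.to_numpy()[:n_pos], atol=1e-8
        )
        # embeddings agree up to axis sign
        theirs_coords = theirs.samples.to_numpy()[:, :n_pos]
        for k in range(n_pos):
            ok = np.allclose(ours.coordinates.iloc[:, k], theirs_coords[:, k], atol=1e-6)
            flipped = np.allclose(ours.coordinates.iloc[:, k], -theirs_coords[:, k], atol=1e-6)
            assert ok or flipped


def bruteforce_permanova_p(d: np.ndarray, labels: np.ndarray) -> float:
    """Independent oracle: pseudo-F over every relabeling, from first principles."""

    def pseudo_f(lab):
        n = len(lab)
        d2 = d ** 2
        ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for g in set(lab):
            idx = [i for i in range(n) if lab[i] == g]
            ss_within += sum(
                d2[i, j] for i in idx for j in idx if i < j
            ) / len(idx)
        a = len(set(lab))
        return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(labels)
    perms = sorted(set(itertools.permutations(labels)))
    count = sum(pseudo_f(np.array(p)) >= f_obs - 1e-10 * max(abs(f_obs), 1) for p in perms)
    return count / len(perms)


class TestPermanova:
    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        dm = euclidean_dm(rng.normal(size=(6, 3)))
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = permanova(dm, pd.Series(labels, index=dm.ids), method="exact")
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(bruteforce_permanova_p(dm.data, labels))

    def test_pseudo_f_matches_skbio(self):
        rng = np.random.default_rng(11)
        dm = euclidean_dm(rng.normal(size=(9, 4)))
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=dm.ids)
        ours = permanova(dm, groups, n_permutations=99, seed=0, method="sampled")
        theirs = skbio_permanova(dm, grouping=groups.to_numpy(), permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_sampled_p_floor(self):
        rng = np.random.default_rng(12)
        points = rng.normal(size=(8, 2))
        points[:4] += 50  # overwhelming separation
        dm = euclidean_dm(points)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=dm.ids)
        res = permanova(dm, groups, n_permutations=99, seed=1, method="sampled")
        assert res.p_value >= 1 / 100
        assert 0 <= res.r2 <= 1

    def test_degenerate_groupings_rejected(self):
        dm = euclidean_dm(np.arange(8).reshape(4, 2).astype(float))
        with pytest.raises(ValueError):
            permanova(dm, pd.Series(["a"] * 4, index=dm.ids))


class TestPairwisePermanova:
    def test_three_groups_give_three_pairs_with_bh(self):
        rng = np.random.default_rng(21)
        points = rng.normal(size=(12, 2))
        points[:4] += 10  # only group a strongly separated
        dm = euclidean_dm(points)
        groups = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4, index=dm.ids)
        out = pairwise_permanova(dm, groups, n_permutations=199, seed=2)
        assert len(out) == 3
        out = out.set_index(["group_a", "group_b"])
        assert out.loc[("a", "b"), "p_adjusted"] < 0.05
        assert out.loc[("a", "c"), "p_adjusted"] < 0.05
        assert out.loc[("b", "c"), "p_adjusted"] > 0.05
        order = out.sort_values("p_value")
        assert (order["p_adjusted"].to_numpy() >= order["p_value"].to_numpy() - 1e-12).all()
        assert order["p_adjusted"].is_monotonic_increasing


class TestDispersion:
    def test_congruent_groups_have_equal_dispersion(self):
        rng = np.random.default_rng(31)
        a = rng.normal(size=(5, 2))
        b = a + np.array([100.0, 0.0])  # congruent translate
        dm = euclidean_dm(np.vstack([a, b]))
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=dm.ids)
        dists, f_stat, p = dispersion_homogeneity(dm, groups)
        assert (dists >= 0).all()
        assert f_stat == pytest.approx(0.0, abs=1e-18)
        assert p > 0.99

    def test_singleton_group_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(32)
        points = rng.normal(size=(7, 2))
        dm = euclidean_dm(points)
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"], index=dm.ids)
        import logging

        with caplog.at_level(logging.WARNING):
            dists, _, _ = dispersion_homogeneity(dm, groups)
        assert len(dists) == 6
        assert any("c" in rec.message for rec in caplog.records)


class TestVariability:
    def test_identical_samples_zero_variability_and_order_invariance(self):
        points = np.array([[1.0, 1.0]] * 3 + [[0.0, 3.0], [2.0, 0.0], [4.0, 1.0]])
        dm = euclidean_dm(points)
        groups = pd.Series(["tight"] * 3 + ["loose"] * 3, index=dm.ids)
        v = group_variability(dm, groups)
        assert v["tight"] == 0.0
        shuffled = groups.sample(frac=1, random_state=0)
        assert group_variability(dm, shuffled).sort_index().equals(v.sort_index())

    def test_habitat_contrast_reports_both_classes(self):
        rng = np.random.default_rng(41)
        deep = rng.normal(scale=0.2, size=(6, 2))
        shallow = rng.normal(scale=3.0, size=(6, 2))
        dm = euclidean_dm(np.vstack([deep, shallow]))
        groups = pd.Series(
            ["d1"] * 3 + ["d2"] * 3 + ["s1"] * 3 + ["s2"] * 3, index=dm.ids
        )
        habitats = pd.Series(["deep"] * 6 + ["shallow"] * 6, index=dm.ids)
        arrays, f_stat, p = variability_contrast(dm, groups, habitats)
        assert set(arrays) == {"deep", "shallow"}
        assert arrays["deep"].mean() < arrays["shallow"].mean()
        assert p < 0.05
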