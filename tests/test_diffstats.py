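"""Enrichment testing, Bray-Curtis, ANOSIM and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest

from soilmep.diffstats import (
    anosim,
    bray_curtis,
    differential_enrichment,
    permanova,
)


def _labels(names, groups):
    return pd.Series(dict(zip(names, groups)))


def two_group_distance(n1, n2, within, between, rng=None, jitter=0.0):
    n = n1 + n2
    names = [f"s{i}" for i in range(n)]
    d = np.full((n, n), between, dtype=float)
    d[:n1, :n1] = within
    d[n1:, n1:] = within
    if jitter and rng is not None:
        noise = rng.random((n, n)) * jitter
        noise = (noise + noise.T) / 2
        d = d + noise
    np.fill_diagonal(d, 0.0)
    dm = pd.DataFrame(d, index=names, columns=names)
    labels = _labels(names, ["g1"] * n1 + ["g2"] * n2)
    return dm, labels


class TestEnrichment:
    def test_identical_groups_give_unit_fold_change(self):
        mat = pd.DataFrame(
            {"b1": [1.0], "b2": [1.0], "r1": [1.0], "r2": [1.0]}
        )
        labels = _labels(mat.columns, ["bulk", "bulk", "rhizosphere",
                                       "rhizosphere"])
        res = differential_enrichment(mat, labels)
        assert res["fold_change"].iloc[0] == pytest.approx(1.0)
        assert res["enriched_in"].iloc[0] == "none"

    def test_null_type_one_error_controlled(self, rng):
        # no real differences: the q < 0.05 rate stays near or below 5%
        rates = []
        for _ in range(30):
            mat = pd.DataFrame(
                rng.normal(10, 1, size=(500, 12)),
                columns=[f"s{j}" for j in range(12)],
            )
            labels = _labels(mat.columns, ["bulk"] * 6 + ["rhizosphere"] * 6)
            res = differential_enrichment(mat, labels)
            rates.append((res["q_value"] < 0.05).mean())
        mean_rate = np.mean(rates)
        se = np.std(rates) / np.sqrt(len(rates))
        assert mean_rate <= 0.05 + 2 * se

    def test_spiked_proteins_recovered(self, rng):
        # 100 of 1000 proteins spiked 4-fold, n=6 vs 6, sigma_log2 = 0.5
        n, n_spiked = 1000, 100
        base = rng.normal(20, 2, n)
        mat = {}
        for j in range(6):
            mat[f"b{j}"] = base + rng.normal(0, 0.5, n)
        spike = np.zeros(n)
        spike[:n_spiked] = 2.0  # log2(4)
        for j in range(6):
            mat[f"r{j}"] = base + spike + rng.normal(0, 0.5, n)
        mat = pd.DataFrame(mat)
        labels = _labels(mat.columns, ["bulk"] * 6 + ["rhizosphere"] * 6)
        res = differential_enrichment(mat, labels)
        called = res["enriched_in"].to_numpy() == "rhizosphere"
        recall = called[:n_spiked].mean()
        assert recall >= 0.8
        false_rate = called[n_spiked:].mean()
        assert false_rate < 0.02

    def test_low_observation_proteins_reported_not_tested(self):
        mat = pd.DataFrame(
            {"b1": [1.0], "b2": [np.nan], "r1": [2.0], "r2": [2.5]}
        )
        labels = _labels(mat.columns, ["bulk", "bulk", "rhizosphere",
                                       "rhizosphere"])
        res = differential_enrichment(mat, labels)
        assert res["enriched_in"].iloc[0] == "not_tested"

    def test_missing_compartment_rejected(self):
        mat = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError):
            differential_enrichment(mat, _labels(mat.columns, ["bulk", "bulk"]))


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        mat = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        d = bray_curtis(mat)
        assert d.loc["a", "b"] == 0.0

    def test_disjoint_supports_distance_one(self):
        mat = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 3.0]})
        assert bray_curtis(mat).loc["a", "b"] == 1.0

    def test_worked_example(self):
        mat = pd.DataFrame({"x": [2.0, 1.0], "y": [1.0, 1.0]})
        assert bray_curtis(mat).loc["x", "y"] == pytest.approx(0.2)

    def test_bounded_symmetric_zero_diagonal(self, rng):
        mat = pd.DataFrame(rng.random((20, 8)) + 0.01)
        d = bray_curtis(mat)
        arr = d.to_numpy()
        assert (arr >= 0).all() and (arr <= 1).all()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)

    def test_joint_rescaling_invariance(self, rng):
        mat = pd.DataFrame(rng.random((10, 4)) + 0.01)
        assert np.allclose(
            bray_curtis(mat).to_numpy(), bray_curtis(mat * 7.3).to_numpy()
        )

    def test_zero_sample_rejected(self):
        mat = pd.DataFrame({"a": [1.0], "b": [0.0]})
        with pytest.raises(ValueError):
            bray_curtis(mat)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self, rng):
        dm, labels = two_group_distance(4, 4, within=0.1, between=0.9,
                                        rng=rng, jitter=0.05)
        res = anosim(dm, labels, method="exact")
        assert res.R == pytest.approx(1.0)

    def test_matches_skbio_statistic(self, rng):
        import skbio

        arr = rng.random((8, 30))
        mat = pd.DataFrame(arr.T, columns=[f"s{i}" for i in range(8)])
        dm = bray_curtis(mat)
        labels = _labels(dm.index, ["g1"] * 4 + ["g2"] * 4)
        ours = anosim(dm, labels, method="exact")
        sk = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(dm.to_numpy(), ids=list(dm.index)),
            labels.to_numpy(), permutations=0,
        )
        assert ours.R == pytest.approx(sk["test statistic"], abs=1e-10)

    def test_exact_p_matches_sampled_estimate(self, rng):
        dm, labels = two_group_distance(3, 3, within=0.2, between=0.5,
                                        rng=rng, jitter=0.3)
        exact = anosim(dm, labels, method="exact")
        sampled = anosim(dm, labels, n_perm=2000, seed=0, method="permutation")
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 2000)
        assert abs(sampled.p_value - exact.p_value) < 3 * se + 1e-3

    def test_null_rejection_rate_calibrated(self, rng):
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            arr = rng.random((10, 25))
            mat = pd.DataFrame(arr.T, columns=[f"s{i}" for i in range(10)])
            dm = bray_curtis(mat)
            labels = _labels(dm.index, ["g1"] * 5 + ["g2"] * 5)
            res = anosim(dm, labels, n_perm=199, seed=rep, method="permutation")
            rejections += res.p_value <= 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 2 * se + 1e-9

    def test_rank_invariance_under_monotone_transform(self, rng):
        dm, labels = two_group_distance(4, 3, within=0.2, between=0.6,
                                        rng=rng, jitter=0.2)
        a = anosim(dm, labels, method="exact")
        b = anosim(dm**0.5, labels, method="exact")
        assert a.R == pytest.approx(b.R)
        assert a.p_value == pytest.approx(b.p_value)

    def test_singleton_group_rejected(self):
        dm, _ = two_group_distance(2, 2, 0.1, 0.9)
        labels = _labels(dm.index, ["g1", "g1", "g1", "g2"])
        with pytest.raises(ValueError):
            anosim(dm, labels)


class TestPermanova:
    def test_zero_within_distance_gives_r2_one(self):
        dm, labels = two_group_distance(3, 3, within=0.0, between=0.7)
        res = permanova(dm, labels, method="exact")
        assert res.R2 == pytest.approx(1.0)
        assert np.isinf(res.pseudo_F)

    def test_all_equal_distances_closed_form(self):
        # every pairwise distance c: SS_A = (a-1)c^2/2, so R^2 = (a-1)/(N-1)
        # and pseudo-F = 1; no permutation can beat the observed statistic
        dm, labels = two_group_distance(3, 3, within=0.4, between=0.4)
        res = permanova(dm, labels, method="exact")
        assert res.R2 == pytest.approx(1 / 5)
        assert res.pseudo_F == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_skbio_statistic(self, rng):
        import skbio

        arr = rng.random((9, 30))
        mat = pd.DataFrame(arr.T, columns=[f"s{i}" for i in range(9)])
        dm = bray_curtis(mat)
        labels = _labels(dm.index, ["g1"] * 4 + ["g2"] * 5)
        ours = permanova(dm, labels, method="exact")
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.to_numpy(), ids=list(dm.index)),
            labels.to_numpy(), permutations=0,
        )
        assert ours.pseudo_F == pytest.approx(sk["test statistic"], abs=1e-10)

    def test_exact_p_matches_sampled_estimate(self, rng):
        dm, labels = two_group_distance(3, 4, within=0.3, between=0.5,
                                        rng=rng, jitter=0.3)
        exact = permanova(dm, labels, method="exact")
        sampled = permanova(dm, labels, n_perm=2000, seed=1,
                            method="permutation")
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 2000)
        assert abs(sampled.p_value - exact.p_value) < 3 * se + 1e-3

    def test_p_bounded_below_by_permutation_count(self, rng):
        dm, labels = two_group_distance(4, 4, within=0.05, between=0.95,
                                        rng=rng, jitter=0.02)
        res = permanova(dm, labels, n_perm=99, seed=3, method="permutation")
        assert res.p_value >= 1 / 100

    def test_deterministic_under_seed(self, rng):
        dm, labels = two_group_distance(4, 4, within=0.3, between=0.5,
                                        rng=rng, jitter=0.3)
        a = permanova(dm, labels, n_perm=99, seed=5, method="permutation")
        b = permanova(dm, labels, n_perm=99, seed=5, method="permutation")
        assert a.p_value == b.p_value

    def test_single_group_rejected(self):
        dm, _ = two_group_distance(2, 2, 0.1, 0.9)
        labels = _labels(dm.index, ["g1"] * 4)
        with pytest.raises(ValueError):
            permanova(dm, labels)
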