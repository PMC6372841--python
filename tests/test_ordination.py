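import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from concord.data_model import FeatureTable
from concord.ordination import (DistanceMatrix, OrdinationError, bray_curtis,
                                friedman, mantel, pcoa, permanova, procrustes)

from conftest import random_table


def dm_from_points(points):
    n = len(points)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.linalg.norm(points[i] - points[j])
    return DistanceMatrix(tuple(f"s{i}" for i in range(n)), d)


class TestBrayCurtis:
    def test_forced_values(self):
        t = FeatureTable(pd.DataFrame({"a": [1.0, 1.0, 0.0],
                                       "b": [0.0, 1.0, 1.0],
                                       "c": [1.0, 1.0, 0.0],
                                       "d": [0.0, 0.0, 2.0]}), "gene")
        d = bray_curtis(t)
        assert d.data[0, 1] == pytest.approx(0.5)   # [1,1,0] vs [0,1,1]
        assert d.data[0, 2] == 0.0                  # identical samples
        assert d.data[0, 3] == 1.0                  # disjoint supports

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(31)
        t = random_table(rng, 30, 6, "gene")
        d = bray_curtis(t)
        X = t.values.to_numpy().T
        for i in range(6):
            for j in range(6):
                assert d.data[i, j] == pytest.approx(
                    scipy_braycurtis(X[i], X[j]) if i != j else 0.0,
                    abs=1e-12)

    def test_missing_cells_rejected(self):
        t = FeatureTable(pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}),
                         "protein")
        with pytest.raises(OrdinationError, match="missing"):
            bray_curtis(t)

    def test_joint_scale_invariance(self):
        rng = np.random.default_rng(32)
        t = random_table(rng, 20, 5, "gene")
        scaled = FeatureTable(t.values * 1234.5, "gene")
        np.testing.assert_allclose(bray_curtis(t).data,
                                   bray_curtis(scaled).data, atol=1e-12)

    def test_entries_within_unit_interval(self):
        rng = np.random.default_rng(33)
        d = bray_curtis(random_table(rng, 25, 7, "gene"))
        assert (d.data >= 0).all() and (d.data <= 1).all()


class TestPcoa:
    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(41)
        points = rng.normal(0, 1, (7, 3))
        dm = dm_from_points(points)
        res = pcoa(dm)
        recon = dm_from_points(res.coordinates)
        np.testing.assert_allclose(recon.data, dm.data, atol=1e-8)

    def test_collinear_points_have_single_axis(self):
        points = np.array([[0.0], [1.0], [2.0], [5.0]])
        res = pcoa(dm_from_points(points))
        assert res.coordinates.shape[1] == 1

    def test_all_zero_distances(self):
        dm = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        res = pcoa(dm)
        np.testing.assert_allclose(res.coordinates, 0.0)

    def test_matches_skbio_eigenvalues(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(42)
        t = random_table(rng, 40, 8, "gene")
        dm = bray_curtis(t)
        res = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.data, dm.ids))
        n_pos = res.coordinates.shape[1]
        np.testing.assert_allclose(res.eigenvalues[:n_pos],
                                   ref.eigvals.to_numpy()[:n_pos], atol=1e-9)

    def test_eigenvalues_sorted_descending(self):
        rng = np.random.default_rng(43)
        res = pcoa(bray_curtis(random_table(rng, 30, 8, "gene")))
        assert (np.diff(res.eigenvalues) <= 1e-12).all()


class TestProcrustes:
    def test_rotated_scaled_shifted_copy(self):
        rng = np.random.default_rng(51)
        X = rng.normal(0, 1, (8, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        Y = 3.1 * X @ R + np.array([5.0, -2.0])
        m2, _ = procrustes(X, Y)
        assert m2 <= 1e-10

    def test_self_comparison_zero(self):
        rng = np.random.default_rng(52)
        X = rng.normal(0, 1, (6, 3))
        assert procrustes(X, X)[0] <= 1e-12

    def test_matches_closed_form_oracle(self):
        # independent route: M2 = 1 - (sum of singular values)^2 of the
        # cross-product of unit-trace configurations
        rng = np.random.default_rng(53)
        for _ in range(5):
            X = rng.normal(0, 1, (9, 3))
            Y = rng.normal(0, 1, (9, 3))
            Xc = X - X.mean(0)
            Yc = Y - Y.mean(0)
            Xc /= np.linalg.norm(Xc)
            Yc /= np.linalg.norm(Yc)
            s = np.linalg.svd(Yc.T @ Xc, compute_uv=False)
            expected = 1.0 - s.sum() ** 2
            assert procrustes(X, Y)[0] == pytest.approx(expected, abs=1e-9)

    def test_matches_scipy_disparity(self):
        rng = np.random.default_rng(54)
        X = rng.normal(0, 1, (10, 2))
        Y = rng.normal(0, 1, (10, 2))
        _, _, disparity = scipy_procrustes(X, Y)
        assert procrustes(X, Y)[0] == pytest.approx(disparity, abs=1e-12)

    def test_invariant_to_prerotation(self):
        rng = np.random.default_rng(55)
        X = rng.normal(0, 1, (8, 2))
        Y = rng.normal(0, 1, (8, 2))
        q, _ = np.linalg.qr(rng.normal(0, 1, (2, 2)))
        assert procrustes(X @ q, Y)[0] == pytest.approx(procrustes(X, Y)[0],
                                                        abs=1e-12)

    def test_dimension_padding(self):
        rng = np.random.default_rng(56)
        X = rng.normal(0, 1, (6, 3))
        m2, aligned = procrustes(X, X[:, :2])
        assert aligned.shape == (6, 3)

    def test_degenerate_configuration_errors(self):
        with pytest.raises(OrdinationError):
            procrustes(np.zeros((5, 2)), np.ones((5, 2)))


class TestMantel:
    def test_identical_matrices(self):
        rng = np.random.default_rng(61)
        dm = bray_curtis(random_table(rng, 20, 8, "gene"))
        res = mantel(dm, dm, n_perm=99, seed=5)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(62)
        d1 = bray_curtis(random_table(rng, 20, 8, "gene"))
        d2 = bray_curtis(random_table(rng, 20, 8, "gene"))
        a = mantel(d1, d2, n_perm=199, seed=7)
        b = mantel(d1, d2, n_perm=199, seed=7)
        assert a.p_value == b.p_value and a.statistic == b.statistic

    def test_statistic_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as skbio_mantel
        rng = np.random.default_rng(63)
        d1 = bray_curtis(random_table(rng, 20, 7, "gene"))
        d2 = bray_curtis(random_table(rng, 20, 7, "gene"))
        r_ref, _, _ = skbio_mantel(skbio.DistanceMatrix(d1.data, d1.ids),
                                   skbio.DistanceMatrix(d2.data, d2.ids),
                                   permutations=0)
        assert mantel(d1, d2, n_perm=9, seed=0).statistic == pytest.approx(
            r_ref, abs=1e-12)

    def test_too_few_samples(self):
        dm = dm_from_points(np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(OrdinationError):
            mantel(dm, dm, n_perm=9, seed=0)


class TestPermanova:
    def _grouping(self, dm, split):
        return {s: ("g1" if i < split else "g2")
                for i, s in enumerate(dm.ids)}

    def test_separated_clusters_minimal_p(self):
        # maximal separation: only permutations recreating the exact
        # partition can tie the observed pseudo-F, so p sits at the floor
        pts = np.vstack([np.random.default_rng(1).normal(0, 0.01, (5, 2)),
                         np.random.default_rng(2).normal(50, 0.01, (7, 2))])
        dm = dm_from_points(pts)
        res = permanova(dm, self._grouping(dm, 5), n_perm=199, seed=3)
        assert res.statistic > 1e4
        assert res.p_value <= 3 / 200

    def test_statistic_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(71)
        dm = bray_curtis(random_table(rng, 25, 8, "gene"))
        grouping = self._grouping(dm, 4)
        ref = skbio_permanova(skbio.DistanceMatrix(dm.data, dm.ids),
                              [grouping[s] for s in dm.ids], permutations=0)
        res = permanova(dm, grouping, n_perm=9, seed=0)
        assert res.statistic == pytest.approx(ref["test statistic"],
                                              abs=1e-9)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(72)
        dm = bray_curtis(random_table(rng, 15, 6, "gene"))
        grouping = self._grouping(dm, 3)
        res = permanova(dm, grouping, n_perm=None)

        # independent oracle: enumerate all 20 balanced labelings directly
        def pseudo_f(labels):
            d2 = dm.data ** 2
            n = 6
            iu = np.triu_indices(n, k=1)
            ss_total = d2[iu].sum() / n
            ss_within = 0.0
            for g in ("g1", "g2"):
                idx = [i for i, l in enumerate(labels) if l == g]
                sub = d2[np.ix_(idx, idx)]
                ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
            return (ss_total - ss_within) / 1 / (ss_within / 4)

        obs = pseudo_f([grouping[s] for s in dm.ids])
        stats_all = []
        for combo in itertools.combinations(range(6), 3):
            labels = ["g1" if i in combo else "g2" for i in range(6)]
            stats_all.append(pseudo_f(labels))
        p_exact = np.mean([f >= obs - 1e-12 for f in stats_all])
        assert res.statistic == pytest.approx(obs, abs=1e-12)
        assert res.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_single_group_and_singleton_errors(self):
        dm = dm_from_points(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(OrdinationError):
            permanova(dm, {s: "g1" for s in dm.ids}, n_perm=9, seed=0)
        bad = {s: ("g1" if i else "g2") for i, s in enumerate(dm.ids)}
        with pytest.raises(OrdinationError, match="singleton"):
            permanova(dm, bad, n_perm=9, seed=0)


class TestFriedman:
    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(81)
        data = rng.normal(0, 1, (8, 5))
        res = friedman(data)
        ref_stat, ref_p = stats.friedmanchisquare(*data.T)
        assert res.statistic == pytest.approx(ref_stat, abs=1e-10)
        assert res.p_value == pytest.approx(ref_p, abs=1e-10)

    def test_tied_data_matches_scipy(self):
        rng = np.random.default_rng(82)
        data = rng.integers(0, 3, (10, 4)).astype(float)
        ref_stat, _ = stats.friedmanchisquare(*data.T)
        assert friedman(data).statistic == pytest.approx(ref_stat, abs=1e-10)

    def test_identical_ranking_gives_maximal_statistic(self):
        # every block ranks treatments identically: chi2 = n(k-1)
        n, k = 6, 4
        data = np.tile(np.arange(k, dtype=float), (n, 1))
        res = friedman(data)
        assert res.statistic == pytest.approx(n * (k - 1), abs=1e-12)

    def test_constant_blocks_warn_and_zero(self):
        with pytest.warns(UserWarning):
            res = friedman(np.ones((4, 3)))
        assert res.statistic == 0.0

    def test_missing_cells_rejected(self):
        data = np.ones((4, 3))
        data[0, 0] = np.nan
        with pytest.raises(OrdinationError):
            friedman(data)


class TestDistanceMatrixValidation:
    def test_asymmetry_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(OrdinationError):
            DistanceMatrix(("a", "b"), m)

    def test_nonzero_diagonal_rejected(self):
        m = np.array([[0.1, 1.0], [1.0, 0.0]])
        with pytest.raises(OrdinationError):
            DistanceMatrix(("a", "b"), m)

    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(91)
        dm = bray_curtis(random_table(rng, 10, 5, "gene"))
        path = tmp_path / "dm.tsv"
        dm.write_tsv(path)
        back = DistanceMatrix.read_tsv(path)
        assert back.ids == dm.ids
        np.testing.assert_allclose(back.data, dm.data, atol=1e-15)
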