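"""Permutation statistics: cluster extent, block tests, SD contrast, FC PCA."""

import numpy as np
import pytest

import boldlag as bl
from boldlag.groupstats import (
    block_mean_test,
    block_spearman_test,
    cluster_permutation_test,
    fc_difference_pca,
    lag_sd_contrast,
)
from boldlag.lagcore import TimeDelayMatrix
from boldlag.lattice import LatticeGeometry
from boldlag.partition import NetworkPartition

TR = 2.08


def _partition(n=70, m=7):
    return NetworkPartition(labels=np.arange(n) * m // n,
                            names=[f"N{i}" for i in range(m)])


def _rand_td(rng, n=70):
    u = np.triu(rng.standard_normal((n, n)), 1)
    return u - u.T


def _as_td(mat):
    return TimeDelayMatrix(td=mat, amp=np.zeros_like(mat),
                           validity=np.ones_like(mat, dtype=bool), tr=TR)


class TestBlockStructure:
    def test_unique_block_counts_for_seven_networks(self):
        part = _partition()
        assert len(part.block_pairs(include_diagonal=True)) == 28
        assert len(part.block_pairs(include_diagonal=False)) == 21

    def test_block_indices_unique_and_oriented(self):
        part = _partition(20, 4)
        rows, cols = part.block_indices(1, 1)
        assert np.all(rows < cols)
        rows, cols = part.block_indices(0, 2)
        assert set(part.labels[rows]) == {0} and set(part.labels[cols]) == {2}


class TestBlockSpearman:
    def test_identity_rho_one_everywhere(self):
        rng = np.random.default_rng(0)
        td = _as_td(_rand_td(rng))
        df = block_spearman_test(td, td, _partition(), n_perm=100, seed=1)
        assert len(df) == 28
        assert np.allclose(df.spearman_rho, 1.0)
        assert not df.significant.any()

    def test_independent_matrices_rho_near_zero(self):
        rng = np.random.default_rng(1)
        a, b = _as_td(_rand_td(rng, 140)), _as_td(_rand_td(rng, 140))
        df = block_spearman_test(a, b, _partition(140), n_perm=200, seed=2)
        bound = 3.0 / np.sqrt(df.n_pairs.to_numpy())
        assert (np.abs(df.spearman_rho.to_numpy()) <= bound).mean() > 0.9

    def test_reversed_block_significantly_low(self):
        """Negating one off-diagonal block in state B (reversed
        propagation) yields rho = -1 there, far below the
        entry-permutation null; preserved blocks stay at rho = 1."""
        rng = np.random.default_rng(3)
        part = _partition(105)
        base = _rand_td(rng, 105)
        reversed_b = base.copy()
        rows, cols = part.block_indices(1, 4)
        reversed_b[rows, cols] = -base[rows, cols]
        reversed_b[cols, rows] = -reversed_b[rows, cols]
        df = block_spearman_test(_as_td(base), _as_td(reversed_b), part,
                                 n_perm=300, seed=4)
        hit = df[(df.network_a == "N1") & (df.network_b == "N4")]
        assert np.allclose(hit.spearman_rho, -1.0)
        assert hit.significant.all()
        rest = df.drop(hit.index)
        assert np.allclose(rest.spearman_rho, 1.0)
        assert not rest.significant.any()

    def test_small_blocks_flagged_without_p(self):
        rng = np.random.default_rng(5)
        part = NetworkPartition(labels=np.array([0, 0, 1, 1, 1]),
                                names=["A", "B"])
        td = _as_td(_rand_td(rng, 5))
        df = block_spearman_test(td, td, part, n_perm=50, seed=6)
        assert df.p_corrected.isna().all()


class TestBlockMean:
    def test_diagonal_block_means_exactly_zero(self):
        rng = np.random.default_rng(7)
        tds = [_rand_td(rng) for _ in range(8)]
        df = block_mean_test(tds, [f"s{i}" for i in range(8)],
                             ["A"] * 4 + ["B"] * 4, _partition(),
                             n_perm=100, seed=8)
        diag = df[df.diagonal]
        assert len(diag) == 7
        assert (diag.filter(like="mean_lag_").to_numpy() == 0.0).all()
        assert len(df[~df.diagonal]) == 21

    def test_planted_early_network_detected(self):
        """Uniformly shifting one network's lag values early in state B
        makes its blocks significantly negative."""
        rng = np.random.default_rng(9)
        part = _partition()
        early = part.members(3)
        tds, subjects, states = [], [], []
        for i in range(12):
            mat = 0.2 * _rand_td(rng)
            state = "A" if i < 6 else "B"
            if state == "B":
                mat[early, :] -= 0.5
                mat[:, early] += 0.5
                mat[np.ix_(early, early)] = 0.2 * _rand_td(rng, early.size)
            tds.append(mat)
            subjects.append(f"s{i}")
            states.append(state)
        df = block_mean_test(tds, subjects, states, part, n_perm=300, seed=10)
        hit = df[(~df.diagonal)
                 & ((df.network_a == "N3") | (df.network_b == "N3"))]
        assert hit.significant.all()
        # sign: N3 early in B -> rows with N3 first have mean_lag_B < 0
        rows_first = hit[hit.network_a == "N3"]
        assert (rows_first.mean_lag_B < 0).all()
        others = df[(~df.diagonal)
                    & (df.network_a != "N3") & (df.network_b != "N3")]
        assert others.significant.mean() < 0.2


class TestLagSD:
    def test_scaled_state_detected(self):
        rng = np.random.default_rng(11)
        tds, subjects, states = [], [], []
        for i in range(10):
            base = 0.4 * _rand_td(rng, 40)
            scale = 2.0 if i >= 5 else 1.0
            tds.append(_as_td(scale * base))
            subjects.append(f"s{i}")
            states.append("A" if i < 5 else "B")
        res = lag_sd_contrast(tds, subjects, states, n_perm=500, seed=12)
        assert res.sd_by_state["B"] == pytest.approx(
            2.0 * res.sd_by_state["A"], rel=0.25
        )
        assert res.p_value < 0.05

    def test_single_subject_per_state_degenerate(self):
        rng = np.random.default_rng(13)
        res = lag_sd_contrast([_as_td(_rand_td(rng, 20)) for _ in range(2)],
                              ["s1", "s2"], ["A", "B"], n_perm=100, seed=14)
        assert res.p_value is None

    def test_null_not_rejected(self):
        rng = np.random.default_rng(15)
        tds = [_as_td(_rand_td(rng, 30)) for _ in range(10)]
        res = lag_sd_contrast(tds, [f"s{i}" for i in range(10)],
                              ["A"] * 5 + ["B"] * 5, n_perm=500, seed=16)
        assert res.p_value > 0.05


class TestClusterTest:
    def _null_maps(self, seed, n=12, geo=None):
        geo = geo or LatticeGeometry(shape=(6, 6, 2))
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n, geo.n_voxels)), geo

    def test_infinite_threshold_no_clusters(self):
        maps, geo = self._null_maps(0)
        res = cluster_permutation_test(
            maps, [f"s{i}" for i in range(12)], ["A"] * 6 + ["B"] * 6,
            geometry=geo, z_threshold=np.inf, n_perm=100, seed=1,
        )
        assert res.clusters == []

    def test_planted_blob_recovered(self):
        geo = LatticeGeometry(shape=(8, 8, 3))
        rng = np.random.default_rng(2)
        maps = 0.3 * rng.standard_normal((12, geo.n_voxels))
        blob = np.zeros(geo.shape)
        blob[2:5, 2:5, 1] = 1.0
        blob_idx = np.flatnonzero(geo.flatten(blob))
        maps[6:, blob_idx] += 2.0  # strong shift in state B
        res = cluster_permutation_test(
            maps, [f"s{i}" for i in range(12)], ["A"] * 6 + ["B"] * 6,
            geometry=geo, z_threshold=3.0, n_perm=200, seed=3,
        )
        sig = res.significant(0.05)
        assert sig
        vox = set(sig[0][0])
        jacc = len(vox & set(blob_idx)) / len(vox | set(blob_idx))
        assert jacc >= 0.5

    def test_no_adjacency_reduces_to_voxelwise(self):
        maps, geo = self._null_maps(4)
        res = cluster_permutation_test(
            maps, [f"s{i}" for i in range(12)], ["A"] * 6 + ["B"] * 6,
            geometry=None, adjacency=None, z_threshold=2.0,
            n_perm=100, seed=5,
        )
        assert all(extent == 1 for _, extent, _ in res.clusters)

    def test_reproducible_under_seed(self):
        maps, geo = self._null_maps(6)
        args = (maps, [f"s{i}" for i in range(12)], ["A"] * 6 + ["B"] * 6)
        r1 = cluster_permutation_test(*args, geometry=geo, z_threshold=2.0,
                                      n_perm=150, seed=7)
        r2 = cluster_permutation_test(*args, geometry=geo, z_threshold=2.0,
                                      n_perm=150, seed=7)
        assert np.array_equal(r1.null_max_extent, r2.null_max_extent)
        assert [c[2] for c in r1.clusters] == [c[2] for c in r2.clusters]


class TestFCDifferencePCA:
    def test_zero_difference_nothing_significant(self):
        rng = np.random.default_rng(8)
        mats = [rng.standard_normal((20, 20)) for _ in range(6)]
        mats = [0.5 * (m + m.T) for m in mats]
        fcs = mats + [m.copy() for m in mats]  # same matrices in both states
        subjects = [f"s{i}" for i in range(12)]
        states = ["A"] * 6 + ["B"] * 6
        res = fc_difference_pca(fcs, subjects, states, n_perm=100, seed=9)
        assert np.allclose(res.eigenvalues, 0.0)
        assert res.n_significant == 0

    def test_planted_network_fc_increase_detected(self):
        rng = np.random.default_rng(10)
        n = 30
        net = np.arange(10)
        fcs, subjects, states = [], [], []
        for i in range(12):
            m = 0.1 * rng.standard_normal((n, n))
            m = 0.5 * (m + m.T)
            if i >= 6:
                m[np.ix_(net, net)] += 0.8
            fcs.append(m)
            subjects.append(f"s{i}")
            states.append("A" if i < 6 else "B")
        res = fc_difference_pca(fcs, subjects, states, n_perm=200, seed=11)
        assert res.n_significant >= 1
        lead = np.abs(res.components[:, 0])
        assert lead[net].mean() > 1.5 * lead[10:].mean()
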