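"""Inferential machinery for state contrasts of lag structure.

All tests are permutation-based with the subject as the exchangeable
unit: state labels are flipped within subjects that contribute both
states and shuffled freely among the rest. Family-wise error over
blocks/ranks/clusters is controlled by the max-statistic method, and
every procedure takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from scipy.stats import rankdata

from .lagcore import FCMatrix, TimeDelayMatrix
from .lattice import LatticeGeometry, label_clusters
from .partition import NetworkPartition

__all__ = [
    "NetworkPartition",
    "ClusterResult",
    "LagSDContrast",
    "FCDifferencePCA",
    "cluster_permutation_test",
    "block_spearman_test",
    "block_mean_test",
    "lag_sd_contrast",
    "fc_difference_pca",
]


# ---------------------------------------------------------------------------
# label permutation


def _state_pair(states: list[str]) -> tuple[str, str]:
    uniq = sorted(set(states))
    if len(uniq) != 2:
        raise ValueError(f"exactly two states required, got {uniq}")
    return uniq[0], uniq[1]


def _permuted_states(
    subjects: list[str], states: list[str], rng: np.random.Generator
) -> np.ndarray:
    """One permutation of state labels, exchangeable at the subject level.

    Subjects present in both states have their labels flipped with
    probability 1/2; labels of the remaining maps are shuffled freely
    among themselves (preserving label counts).
    """
    subjects = np.asarray(subjects)
    states = np.asarray(states)
    out = states.copy()
    paired_mask = np.zeros(states.size, dtype=bool)
    for subj in np.unique(subjects):
        idx = np.flatnonzero(subjects == subj)
        if len(set(states[idx])) == 2:
            paired_mask[idx] = True
            if rng.random() < 0.5:
                a, b = _state_pair(list(states[idx]))
                swap = {a: b, b: a}
                out[idx] = [swap[s] for s in states[idx]]
    free = np.flatnonzero(~paired_mask)
    if free.size:
        out[free] = rng.permutation(out[free])
    return out


def _welch_z(maps: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Voxelwise z: difference of state means over pooled standard error."""
    a = maps[is_a]
    b = maps[~is_a]
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 subjects per state for the voxelwise z")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    se = np.sqrt(va / na + vb / nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (a.mean(axis=0) - b.mean(axis=0)) / se
    return np.where(np.isfinite(z), z, 0.0)


# ---------------------------------------------------------------------------
# cluster-extent permutation test


@dataclass
class ClusterResult:
    """Voxelwise z map plus supra-threshold clusters with corrected p."""

    voxelwise_z: np.ndarray
    clusters: list[tuple[np.ndarray, int, float]]
    threshold_z: float
    n_permutations: int
    null_max_extent: np.ndarray = field(default_factory=lambda: np.array([]))

    def significant(self, alpha: float = 0.05) -> list[tuple[np.ndarray, int, float]]:
        return [c for c in self.clusters if c[2] < alpha]


def _cluster_extents(
    supra: np.ndarray,
    geometry: LatticeGeometry | None,
    adjacency: sp.spmatrix | None,
) -> list[np.ndarray]:
    """Connected supra-threshold clusters as lists of voxel indices."""
    if not supra.any():
        return []
    if geometry is not None:
        labels, n = label_clusters(supra, geometry)
        return [np.flatnonzero(labels == i) for i in range(1, n + 1)]
    if adjacency is not None:
        idx = np.flatnonzero(supra)
        sub = adjacency[np.ix_(idx, idx)]
        n, comp = csgraph.connected_components(sub, directed=False)
        return [idx[comp == i] for i in range(n)]
    # no neighbor structure: every supra-threshold voxel is its own cluster
    return [np.array([i]) for i in np.flatnonzero(supra)]


def _max_extent(
    supra: np.ndarray,
    geometry: LatticeGeometry | None,
    adjacency: sp.spmatrix | None,
) -> int:
    if not supra.any():
        return 0
    if geometry is not None:
        labels, n = label_clusters(supra, geometry)
        if n == 0:
            return 0
        return int(np.bincount(labels[labels > 0]).max())
    if adjacency is not None:
        idx = np.flatnonzero(supra)
        sub = adjacency[np.ix_(idx, idx)]
        n, comp = csgraph.connected_components(sub, directed=False)
        return int(np.bincount(comp).max())
    return 1


def cluster_permutation_test(
    maps: np.ndarray,
    subjects: list[str],
    states: list[str],
    geometry: LatticeGeometry | None = None,
    adjacency: sp.spmatrix | None = None,
    z_threshold: float = 4.5,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-extent permutation test of a two-state map difference.

    ``maps`` is (n_maps, n_voxels), one subject-level map per row.
    Voxels with ``|z| > z_threshold`` are grouped into connected
    clusters (6-connectivity on ``geometry``, or a sparse ``adjacency``,
    or singletons when neither is given); the null distribution of the
    maximal cluster extent over ``n_perm`` state-label permutations
    yields corrected p-values.
    """
    maps = np.asarray(maps, dtype=float)
    states_arr = list(states)
    st_a, _ = _state_pair(states_arr)
    is_a = np.array([s == st_a for s in states_arr])
    if is_a.sum() < 2 or (~is_a).sum() < 2:
        raise ValueError("need >= 3 subjects per state for a meaningful test")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")

    z = _welch_z(maps, is_a)
    supra = np.abs(z) > z_threshold
    clusters = _cluster_extents(supra, geometry, adjacency)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    for r in range(n_perm):
        perm_states = _permuted_states(subjects, states_arr, rng)
        is_a_p = perm_states == st_a
        zp = _welch_z(maps, is_a_p)
        null_max[r] = _max_extent(np.abs(zp) > z_threshold, geometry, adjacency)

    out = []
    for vox in clusters:
        extent = int(vox.size)
        p = (1 + int((null_max >= extent).sum())) / (n_perm + 1)
        out.append((vox, extent, p))
    out.sort(key=lambda c: c[1], reverse=True)
    return ClusterResult(
        voxelwise_z=z, clusters=out, threshold_z=z_threshold,
        n_permutations=n_perm, null_max_extent=null_max,
    )


# ---------------------------------------------------------------------------
# block statistics


def _block_values(
    mat: np.ndarray, valid: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    vals = mat[rows, cols]
    ok = valid[rows, cols]
    return vals, ok


def block_spearman_test(
    td_state_a: TimeDelayMatrix,
    td_state_b: TimeDelayMatrix,
    partition: NetworkPartition,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Spearman rho between two states' lag values per RSN block.

    For each of the ``m (m + 1) / 2`` unique blocks, rho is computed
    over the block's valid voxel-pair lag entries. Significance of a
    *low* rho (lag structure not preserved) comes from permuting the
    entry correspondence within each block; family-wise correction uses
    the minimum null rho across blocks. Blocks with fewer than
    ``min_pairs`` valid pairs are flagged without a p-value.
    """
    if td_state_a.n != td_state_b.n:
        raise ValueError("TD matrices must share voxel ordering")
    rng = np.random.default_rng(seed)
    blocks = partition.block_pairs(include_diagonal=True)
    rows_list, ranks = [], []
    obs = []
    for a, b in blocks:
        rows, cols = partition.block_indices(a, b)
        va, oka = _block_values(td_state_a.td, td_state_a.validity, rows, cols)
        vb, okb = _block_values(td_state_b.td, td_state_b.validity, rows, cols)
        ok = oka & okb
        n_pairs = int(ok.sum())
        if n_pairs < min_pairs:
            rows_list.append((a, b, n_pairs, np.nan))
            ranks.append(None)
            continue
        ra = rankdata(va[ok])
        rb = rankdata(vb[ok])
        ra = ra - ra.mean()
        rb = rb - rb.mean()
        denom = np.sqrt((ra @ ra) * (rb @ rb))
        rho = float(ra @ rb / denom) if denom > 0 else np.nan
        rows_list.append((a, b, n_pairs, rho))
        ranks.append((ra, rb, denom))
        obs.append(rho)

    testable = [i for i, rk in enumerate(ranks) if rk is not None]
    null_min = np.full(n_perm, np.inf)
    for r in range(n_perm):
        best = np.inf
        for i in testable:
            ra, rb, denom = ranks[i]
            rb_p = rb[rng.permutation(rb.size)]
            rho_p = float(ra @ rb_p / denom)
            best = min(best, rho_p)
        null_min[r] = best

    records = []
    for i, (a, b, n_pairs, rho) in enumerate(rows_list):
        if ranks[i] is None or not np.isfinite(rho):
            p = np.nan
        else:
            p = (1 + int((null_min <= rho).sum())) / (n_perm + 1)
        records.append(
            {
                "network_a": partition.names[a],
                "network_b": partition.names[b],
                "diagonal": a == b,
                "n_pairs": n_pairs,
                "spearman_rho": rho,
                "p_corrected": p,
                "significant": bool(np.isfinite(p) and p < alpha),
            }
        )
    return pd.DataFrame.from_records(records)


def _block_means_for_matrix(
    td: np.ndarray, valid: np.ndarray, index_cache: list
) -> np.ndarray:
    out = np.empty(len(index_cache))
    for i, (rows, cols) in enumerate(index_cache):
        ok = valid[rows, cols]
        out[i] = td[rows, cols][ok].mean() if ok.any() else np.nan
    return out


def _as_td(item) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(item, TimeDelayMatrix):
        return item.td, item.validity
    arr = np.asarray(item, dtype=float)
    return arr, np.ones_like(arr, dtype=bool)


def diagonal_block_means(td, partition: NetworkPartition) -> dict[str, float]:
    """Mean lag over each full (intra-network) diagonal block.

    Evaluated pairwise as ``sum_{i<j} (td[i,j] + td[j,i])`` plus the zero
    diagonal: every addend cancels exactly in IEEE arithmetic for an
    anti-symmetric matrix, so the result is exactly 0.0 — the numerical
    counterpart of "anti-symmetry forces a zero mean in diagonal blocks".
    """
    mat, _ = _as_td(td)
    out = {}
    for a in range(partition.n_networks):
        rows, cols = partition.block_indices(a, a)
        m = partition.members(a).size
        paired = mat[rows, cols] + mat[cols, rows]
        out[partition.names[a]] = float(np.sum(paired) / (m * m))
    return out


def block_mean_test(
    tds: list,
    subjects: list[str],
    states: list[str],
    partition: NetworkPartition,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """State contrast of mean lag per off-diagonal RSN block.

    Per subject-level TD matrix the mean lag of every off-diagonal block
    is computed (positive = row network late relative to column
    network); the observed statistic is the difference of state group
    means, studentized by the permutation SD, with max-statistic
    correction over the off-diagonal blocks. Diagonal blocks are
    reported with mean 0: anti-symmetry forces the mean over a full
    diagonal block to vanish identically.
    """
    st_a, st_b = _state_pair(list(states))
    off_blocks = partition.block_pairs(include_diagonal=False)
    cache = [partition.block_indices(a, b) for a, b in off_blocks]
    bm = np.stack(
        [_block_means_for_matrix(*_as_td(item), cache) for item in tds]
    )  # (n_maps, n_off_blocks)
    states_arr = np.asarray(states)
    is_a = states_arr == st_a
    if is_a.sum() < 2 or (~is_a).sum() < 2:
        raise ValueError("need >= 3 subjects per state")

    def diff_of_means(mask_a: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(bm[mask_a], axis=0) - np.nanmean(bm[~mask_a], axis=0)

    obs = diff_of_means(is_a)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(off_blocks)))
    for r in range(n_perm):
        perm_states = _permuted_states(list(subjects), list(states), rng)
        null[r] = diff_of_means(perm_states == st_a)
    sd = null.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.nan)
    t_obs = obs / sd
    t_null = null / sd[None, :]
    max_null = np.nanmax(np.abs(t_null), axis=1)

    mean_a = np.nanmean(bm[is_a], axis=0)
    mean_b = np.nanmean(bm[~is_a], axis=0)
    records = []
    for i, (a, b) in enumerate(off_blocks):
        p = (
            (1 + int((max_null >= abs(t_obs[i])).sum())) / (n_perm + 1)
            if np.isfinite(t_obs[i])
            else np.nan
        )
        records.append(
            {
                "network_a": partition.names[a],
                "network_b": partition.names[b],
                "diagonal": False,
                f"mean_lag_{st_a}": mean_a[i],
                f"mean_lag_{st_b}": mean_b[i],
                "mean_lag_diff": obs[i],
                "p_corrected": p,
                "significant": bool(np.isfinite(p) and p < alpha),
            }
        )
    for a, _ in enumerate(partition.names):
        records.append(
            {
                "network_a": partition.names[a],
                "network_b": partition.names[a],
                "diagonal": True,
                f"mean_lag_{st_a}": 0.0,
                f"mean_lag_{st_b}": 0.0,
                "mean_lag_diff": 0.0,
                "p_corrected": np.nan,
                "significant": False,
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# lag-value SD contrast


@dataclass
class LagSDContrast:
    """Per-state mean lag SD, their difference, and the permutation p."""

    sd_by_state: dict[str, float]
    diff: float
    p_value: float | None
    n_permutations: int
    per_subject_sd: dict[str, np.ndarray] = field(default_factory=dict)


def _upper_sd(item) -> float:
    if isinstance(item, TimeDelayMatrix):
        vals = item.upper_values()
    else:
        arr = np.asarray(item, dtype=float)
        vals = arr[np.triu_indices(arr.shape[0], k=1)]
        vals = vals[np.isfinite(vals)]
    return float(vals.std()) if vals.size else np.nan


def lag_sd_contrast(
    tds: list,
    subjects: list[str],
    states: list[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> LagSDContrast:
    """Contrast the SD of unique (upper-triangle) lag values by state.

    The per-subject statistic is the SD over valid upper-triangle TD
    entries; the state difference of mean SD is tested by subject-level
    label permutation (two-sided). With one subject per state the
    permutation space is degenerate and the p-value is reported as None.
    """
    st_a, st_b = _state_pair(list(states))
    sds = np.array([_upper_sd(item) for item in tds])
    states_arr = np.asarray(states)
    is_a = states_arr == st_a
    mean_a = float(np.nanmean(sds[is_a]))
    mean_b = float(np.nanmean(sds[~is_a]))
    diff = mean_b - mean_a
    per_subject = {st_a: sds[is_a], st_b: sds[~is_a]}
    if is_a.sum() < 2 or (~is_a).sum() < 2:
        return LagSDContrast(
            sd_by_state={st_a: mean_a, st_b: mean_b}, diff=diff,
            p_value=None, n_permutations=0, per_subject_sd=per_subject,
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_states = _permuted_states(list(subjects), list(states), rng)
        pa = perm_states == st_a
        d = np.nanmean(sds[~pa]) - np.nanmean(sds[pa])
        if abs(d) >= abs(diff):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return LagSDContrast(
        sd_by_state={st_a: mean_a, st_b: mean_b}, diff=diff,
        p_value=p, n_permutations=n_perm, per_subject_sd=per_subject,
    )


# ---------------------------------------------------------------------------
# FC difference PCA


@dataclass
class FCDifferencePCA:
    """Eigenvalues/components of the state FC difference with null bands."""

    eigenvalues: np.ndarray
    components: np.ndarray
    null_quantile: np.ndarray
    n_significant: int
    significant: np.ndarray
    states_order: tuple[str, str]


def _diff_eigs(z_mats: np.ndarray, is_a: np.ndarray, k: int):
    D = z_mats[is_a].mean(axis=0) - z_mats[~is_a].mean(axis=0)
    Dc = D - D.mean(axis=0, keepdims=True)
    cov = (Dc @ Dc.T) / D.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    return np.clip(evals[order], 0, None), evecs[:, order]


def fc_difference_pca(
    fcs: list,
    subjects: list[str],
    states: list[str],
    n_perm: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    k_max: int = 10,
) -> FCDifferencePCA:
    """Spatial PCA of the between-state FC difference matrix.

    ``fcs`` holds subject-level Fisher-z FC matrices. The difference of
    state group means is column-centered and eigendecomposed; each
    rank's observed eigenvalue is compared against the ``1 - alpha``
    quantile of its permutation-null eigenvalues (state labels permuted
    at the subject level).
    """
    st_a, st_b = _state_pair(list(states))
    z_mats = np.stack(
        [item.z if isinstance(item, FCMatrix) else np.asarray(item, float)
         for item in fcs]
    )
    states_arr = np.asarray(states)
    is_a = states_arr == st_a
    k = min(k_max, z_mats.shape[1])
    evals, evecs = _diff_eigs(z_mats, is_a, k)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, k))
    for r in range(n_perm):
        perm_states = _permuted_states(list(subjects), list(states), rng)
        null[r], _ = _diff_eigs(z_mats, perm_states == st_a, k)
    q = np.quantile(null, 1.0 - alpha, axis=0)
    signif = evals > q
    return FCDifferencePCA(
        eigenvalues=evals, components=evecs, null_quantile=q,
        n_significant=int(signif.sum()), significant=signif,
        states_order=(st_a, st_b),
    )
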