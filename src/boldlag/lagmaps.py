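"""Map-level summaries of time-delay matrices.

A *lag projection* reduces the n x n TD matrix to a per-voxel vector:
the mean lag of each voxel versus the rest of the brain (negative =
early, positive = late under the package sign convention, i.e. row mean
of the TD matrix). A *seed-based lag map* instead measures each voxel's
lag against the mean time series of a seed region. Group-level results
are two-stage means: epochs are averaged within subject, subjects are
averaged with equal weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .epoch import TimeSeriesEpoch
from .lagcore import TimeDelayMatrix, estimate_pair_lag

__all__ = [
    "LagProjection",
    "SeedLagMap",
    "lag_projection",
    "seed_lag_map",
    "seed_lag_map_from_td",
    "group_average",
]


@dataclass
class LagProjection:
    """Per-voxel mean lag (seconds); coverage counts valid pairs used."""

    values: np.ndarray
    coverage: np.ndarray


@dataclass
class SeedLagMap:
    """Per-voxel lag (seconds) relative to a seed's mean time series."""

    values: np.ndarray
    seed_voxels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def lag_projection(td: TimeDelayMatrix) -> LagProjection:
    """Row-wise mean of the TD matrix over valid off-diagonal pairs.

    ``values[i] > 0`` means voxel *i* is late on average. When validity
    is complete the projection entries sum to ~0 (anti-symmetry). Voxels
    with no valid pairs get NaN and coverage 0.
    """
    n = td.n
    offdiag = ~np.eye(n, dtype=bool)
    use = td.validity & offdiag
    coverage = use.sum(axis=1)
    with np.errstate(invalid="ignore"):
        sums = np.where(use, td.td, 0.0).sum(axis=1)
        values = np.where(coverage > 0, sums / np.maximum(coverage, 1), np.nan)
    return LagProjection(values=values, coverage=coverage)


def seed_lag_map(
    epoch: TimeSeriesEpoch,
    seed_voxels,
    max_lag_frames: int = 4,
    normalize: bool = True,
) -> SeedLagMap:
    """Lag of every voxel against the seed's mean time series.

    Positive values mean the voxel is later than the seed reference.
    Voxels inside a multi-voxel seed may legitimately show non-zero lags
    against the seed mean. Invalid pair estimates (extremum at the
    window edge) yield NaN.
    """
    seed_voxels = np.atleast_1d(np.asarray(seed_voxels, dtype=int))
    if seed_voxels.size == 0:
        raise ValueError("seed must be non-empty")
    ref = epoch.data[seed_voxels].mean(axis=0)
    if ref[epoch.valid].var() == 0:
        raise ValueError("seed reference series has zero variance")
    values = np.full(epoch.n_voxels, np.nan)
    for v in range(epoch.n_voxels):
        est = estimate_pair_lag(
            epoch.data[v], ref, epoch.valid, tr=epoch.tr,
            max_lag_frames=max_lag_frames, normalize=normalize,
        )
        if est.valid:
            values[v] = est.tau
    return SeedLagMap(values=values, seed_voxels=seed_voxels)


def seed_lag_map_from_td(td: TimeDelayMatrix, seed_voxels) -> SeedLagMap:
    """Alternative seed map: average of TD columns over the seed voxels.

    This reading averages precomputed pairwise lags instead of
    re-estimating against the seed-mean time series; the two agree only
    approximately (lag estimation is nonlinear in the signals).
    """
    seed_voxels = np.atleast_1d(np.asarray(seed_voxels, dtype=int))
    if seed_voxels.size == 0:
        raise ValueError("seed must be non-empty")
    use = td.validity[:, seed_voxels]
    cnt = use.sum(axis=1)
    sums = np.where(use, td.td[:, seed_voxels], 0.0).sum(axis=1)
    values = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
    return SeedLagMap(values=values, seed_voxels=seed_voxels)


def group_average(
    values: list[np.ndarray],
    subjects: list[str],
    states: list[str],
) -> dict[str, np.ndarray]:
    """Two-stage, validity-aware group mean per state.

    ``values`` are equally shaped arrays (per-voxel maps or TD matrices)
    with NaN marking invalid entries. Entries are first averaged within
    subject across that subject's epochs, then across subjects with
    equal weight regardless of epoch counts; NaNs are skipped at both
    stages, so each entry is averaged over its contributors.
    """
    if not (len(values) == len(subjects) == len(states)):
        raise ValueError("values, subjects and states must align")
    out: dict[str, np.ndarray] = {}
    state_set = sorted(set(states))
    for st in state_set:
        subj_means = []
        for subj in sorted({s for s, x in zip(subjects, states) if x == st}):
            items = [
                np.asarray(v, dtype=float)
                for v, s, x in zip(values, subjects, states)
                if s == subj and x == st
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                subj_means.append(np.nanmean(np.stack(items), axis=0))
        if not subj_means:
            raise ValueError(f"state {st!r} has no contributing subjects")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[st] = np.nanmean(np.stack(subj_means), axis=0)
    return out
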