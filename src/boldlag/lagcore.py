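"""Pairwise temporal-lag estimation from lagged cross-covariance.

The lag between two infra-slow time series is defined as the abscissa of
the extremum of their lagged cross-covariance function

    C_{x1 x2}(tau) = (1/T) sum_t x1(t + tau) x2(t),

evaluated at integer frame offsets within a window of +-``max_lag_frames``
frames and refined to sub-sample resolution by fitting a parabola through
the extremum and its two neighbors. Because BOLD-like aperiodic signals
give rise to cross-covariance curves with a single well-defined extremum,
the extremum is located as the maximum of ``|C|``; the amplitude is
reported signed.

Sign convention: a positive lag ``tau_{ij}`` means series *i* is delayed
(late) relative to series *j*. Assembling all pairs yields the exactly
anti-symmetric time-delay (TD) matrix, ``td[i][j] = -td[j][i]`` with a
zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epoch import TimeSeriesEpoch

__all__ = [
    "CrossCovCurve",
    "LagEstimate",
    "TimeDelayMatrix",
    "FCMatrix",
    "lagged_crosscov",
    "lagged_crosscov_naive",
    "parabolic_vertex",
    "estimate_pair_lag",
    "build_td_matrix",
    "zero_lag_fc",
]

#: Minimum number of overlapping valid frame pairs per offset.
MIN_OVERLAP = 30


@dataclass
class CrossCovCurve:
    """Lagged cross-covariance (or cross-correlation) at integer offsets."""

    lags: np.ndarray        # integer frame offsets, -L..+L
    values: np.ndarray      # covariance/correlation per offset (NaN if unusable)
    n_valid: np.ndarray     # overlapping valid frame pairs per offset
    tr: float
    normalized: bool

    @property
    def usable(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class LagEstimate:
    """Sub-sample lag (seconds) and signed extremum amplitude for one pair."""

    tau: float
    amplitude: float
    valid: bool = True
    degenerate: bool = False


@dataclass
class TimeDelayMatrix:
    """Anti-symmetric n x n matrix of pairwise lags with paired amplitudes."""

    td: np.ndarray
    amp: np.ndarray
    validity: np.ndarray
    tr: float
    excluded: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n(self) -> int:
        return self.td.shape[0]

    def upper_values(self) -> np.ndarray:
        """Valid unique (upper-triangle) lag values in seconds."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.td[iu]
        ok = self.validity[iu]
        return vals[ok]


@dataclass
class FCMatrix:
    """Zero-lag Pearson correlation matrix with Fisher-z transform."""

    r: np.ndarray
    z: np.ndarray
    validity: np.ndarray
    excluded: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _windowed_product(
    a: np.ndarray,
    b: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    offset: int,
    normalize: bool,
) -> tuple[float, int]:
    """Demeaned product mean of a(t+offset) with b(t), offset >= 0."""
    n = a.size
    av = a[offset:]
    bv = b[: n - offset]
    m = mask_a[offset:] & mask_b[: n - offset]
    cnt = int(m.sum())
    if cnt == 0:
        return np.nan, 0
    av = av[m]
    bv = bv[m]
    av = av - av.mean()
    bv = bv - bv.mean()
    val = float(av @ bv) / cnt
    if normalize:
        sa = np.sqrt(float(av @ av) / cnt)
        sb = np.sqrt(float(bv @ bv) / cnt)
        denom = sa * sb
        val = val / denom if denom > 0 else np.nan
    return val, cnt


def lagged_crosscov(
    x1: np.ndarray,
    x2: np.ndarray,
    mask: np.ndarray | None = None,
    max_lag_frames: int = 4,
    normalize: bool = True,
    tr: float = 1.0,
    min_overlap: int = MIN_OVERLAP,
) -> CrossCovCurve:
    """Lagged cross-covariance of two equally long series over valid frames.

    For each integer offset ``tau_f`` in ``[-L, +L]`` the value is the
    mean over frames *t*, restricted to frames where both ``x1(t+tau_f)``
    and ``x2(t)`` are valid, of the demeaned product (demeaning per
    offset over the same frame set). With ``normalize=True`` the value is
    divided by the product of the standard deviations over those frames,
    yielding a correlation. A positive-offset extremum means ``x1`` is
    the delayed (later) series.

    Negative offsets are evaluated by the identity
    ``C_{x1 x2}(-a) = C_{x2 x1}(+a)`` through the same arithmetic, so the
    estimator is exactly symmetric under argument exchange.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be 1-D arrays of equal length")
    if mask is None:
        mask = np.ones(x1.size, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    L = int(max_lag_frames)
    if L < 1:
        raise ValueError("max_lag_frames must be >= 1")
    lags = np.arange(-L, L + 1)
    values = np.empty(lags.size)
    counts = np.empty(lags.size, dtype=int)
    for i, off in enumerate(lags):
        if off >= 0:
            v, c = _windowed_product(x1, x2, mask, mask, off, normalize)
        else:
            v, c = _windowed_product(x2, x1, mask, mask, -off, normalize)
        values[i], counts[i] = v, c
    i0 = L  # offset 0
    if counts[i0] < min_overlap:
        raise ValueError(
            f"insufficient overlap at lag 0: {counts[i0]} < {min_overlap} frames"
        )
    values[counts < min_overlap] = np.nan
    return CrossCovCurve(lags=lags, values=values, n_valid=counts, tr=tr,
                         normalized=normalize)


def lagged_crosscov_naive(
    x1: np.ndarray,
    x2: np.ndarray,
    mask: np.ndarray | None = None,
    max_lag_frames: int = 4,
    normalize: bool = True,
    tr: float = 1.0,
    min_overlap: int = MIN_OVERLAP,
) -> CrossCovCurve:
    """Brute-force double-loop reference implementation (testing oracle).

    Accumulates valid frame pairs one by one; numerically independent of
    the vectorized path.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = x1.size
    if mask is None:
        mask = np.ones(n, dtype=bool)
    L = int(max_lag_frames)
    lags = np.arange(-L, L + 1)
    values = np.full(lags.size, np.nan)
    counts = np.zeros(lags.size, dtype=int)
    for i, off in enumerate(lags):
        pairs = []
        for t in range(n):
            ts = t + off
            if 0 <= ts < n and mask[ts] and mask[t]:
                pairs.append((x1[ts], x2[t]))
        counts[i] = len(pairs)
        if not pairs:
            continue
        a = sum(p[0] for p in pairs) / len(pairs)
        b = sum(p[1] for p in pairs) / len(pairs)
        cov = sum((p[0] - a) * (p[1] - b) for p in pairs) / len(pairs)
        if normalize:
            va = sum((p[0] - a) ** 2 for p in pairs) / len(pairs)
            vb = sum((p[1] - b) ** 2 for p in pairs) / len(pairs)
            denom = (va ** 0.5) * (vb ** 0.5)
            cov = cov / denom if denom > 0 else np.nan
        values[i] = cov
    if counts[L] < min_overlap:
        raise ValueError("insufficient overlap at lag 0")
    values[counts < min_overlap] = np.nan
    return CrossCovCurve(lags=lags, values=values, n_valid=counts, tr=tr,
                         normalized=normalize)


def parabolic_vertex(
    y_prev: float, y_peak: float, y_next: float, peak_offset: int, tr: float
) -> LagEstimate:
    """Vertex of the parabola through three equally spaced curve samples.

    ``(y_prev, y_peak, y_next)`` are the signed cross-covariance values
    at offsets ``peak_offset - 1, peak_offset, peak_offset + 1``;
    ``y_peak`` must be the absolute-value extremum of the three. The
    fractional offset of the vertex is

        d = (y_prev - y_next) / (2 (y_prev - 2 y_peak + y_next)),

    and ``tau = (peak_offset + d) * tr`` seconds; the amplitude is the
    parabola's value at the vertex. Zero curvature returns the
    integer-offset estimate flagged as degenerate.
    """
    curvature = y_prev - 2.0 * y_peak + y_next
    if curvature == 0.0:
        return LagEstimate(tau=peak_offset * tr, amplitude=y_peak,
                           valid=True, degenerate=True)
    d = (y_prev - y_next) / (2.0 * curvature)
    amp = y_peak - (y_prev - y_next) ** 2 / (8.0 * curvature)
    return LagEstimate(tau=(peak_offset + d) * tr, amplitude=amp, valid=True)


def _estimate_from_curve(curve: CrossCovCurve) -> LagEstimate:
    vals = curve.values
    absvals = np.abs(vals)
    absvals = np.where(np.isfinite(absvals), absvals, -np.inf)
    if not np.isfinite(absvals).any() or absvals.max() == -np.inf:
        return LagEstimate(tau=np.nan, amplitude=np.nan, valid=False)
    k = int(np.argmax(absvals))
    if k == 0 or k == vals.size - 1:
        return LagEstimate(tau=np.nan, amplitude=np.nan, valid=False)
    if not (np.isfinite(vals[k - 1]) and np.isfinite(vals[k + 1])):
        return LagEstimate(tau=np.nan, amplitude=np.nan, valid=False)
    return parabolic_vertex(
        vals[k - 1], vals[k], vals[k + 1], int(curve.lags[k]), curve.tr
    )


def estimate_pair_lag(
    x1: np.ndarray,
    x2: np.ndarray,
    mask: np.ndarray | None = None,
    tr: float = 1.0,
    max_lag_frames: int = 4,
    normalize: bool = True,
    min_overlap: int = MIN_OVERLAP,
) -> LagEstimate:
    """Sub-sample lag of ``x1`` relative to ``x2`` (positive = x1 late).

    Locates the integer offset maximizing ``|C(tau)|`` and refines it by
    parabolic interpolation on the signed curve. Pairs whose extremum
    falls at the edge of the lag window are returned invalid (there is
    no neighboring sample to interpolate with) and should be excluded
    from downstream summaries.
    """
    curve = lagged_crosscov(
        x1, x2, mask, max_lag_frames=max_lag_frames, normalize=normalize,
        tr=tr, min_overlap=min_overlap,
    )
    return _estimate_from_curve(curve)


def _full_mask_curves(
    data: np.ndarray, L: int, normalize: bool
) -> np.ndarray:
    """All-pairs cross-covariance curves for fully valid epochs.

    Returns ``curves[L + a, i, j] = C_{x_i x_j}(+a)`` computed with the
    same per-offset demeaning as the pairwise path; the negative-offset
    plane is the transpose of the positive one, so anti-symmetry of the
    resulting lags is exact by construction.
    """
    n, T = data.shape
    curves = np.empty((2 * L + 1, n, n))
    for a in range(L + 1):
        A = data[:, a:]
        B = data[:, : T - a]
        Ac = A - A.mean(axis=1, keepdims=True)
        Bc = B - B.mean(axis=1, keepdims=True)
        cnt = T - a
        num = (Ac @ Bc.T) / cnt
        if normalize:
            sa = np.sqrt((Ac * Ac).sum(axis=1) / cnt)
            sb = np.sqrt((Bc * Bc).sum(axis=1) / cnt)
            denom = np.outer(sa, sb)
            with np.errstate(invalid="ignore", divide="ignore"):
                num = np.where(denom > 0, num / denom, np.nan)
        curves[L + a] = num
        if a > 0:
            curves[L - a] = num.T
    return curves


def build_td_matrix(
    epoch: TimeSeriesEpoch,
    max_lag_frames: int = 4,
    normalize: bool = True,
    min_overlap: int = MIN_OVERLAP,
) -> TimeDelayMatrix:
    """Assemble the anti-symmetric time-delay matrix for one epoch.

    The upper triangle is estimated pairwise; the lower triangle is its
    exact negation and the diagonal is zero, so ``td[i][j] = -td[j][i]``
    holds to the bit. Zero-variance voxels are excluded (their rows and
    columns are marked invalid) and reported in ``excluded``.
    """
    data = epoch.data
    mask = epoch.valid
    n, T = data.shape
    L = int(max_lag_frames)
    if int(mask.sum()) < min_overlap:
        raise ValueError("fewer than min_overlap valid frames in epoch")
    var = data[:, mask].var(axis=1)
    good = var > 0
    excluded = np.flatnonzero(~good)

    td = np.zeros((n, n))
    amp = np.zeros((n, n))
    validity = np.zeros((n, n), dtype=bool)

    if mask.all():
        curves = _full_mask_curves(data, L, normalize)
        absc = np.abs(curves)
        absc[~np.isfinite(absc)] = -np.inf
        kmax = absc.argmax(axis=0)
        interior = (kmax > 0) & (kmax < 2 * L)
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        y_peak = curves[kmax, ii, jj]
        km1 = np.clip(kmax - 1, 0, 2 * L)
        kp1 = np.clip(kmax + 1, 0, 2 * L)
        y_prev = curves[km1, ii, jj]
        y_next = curves[kp1, ii, jj]
        curvature = y_prev - 2.0 * y_peak + y_next
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(curvature != 0.0,
                         (y_prev - y_next) / (2.0 * curvature), 0.0)
            a_mat = np.where(
                curvature != 0.0,
                y_peak - (y_prev - y_next) ** 2 / (8.0 * curvature),
                y_peak,
            )
        tau = (kmax - L + d) * epoch.tr
        ok = (
            interior
            & np.isfinite(y_peak)
            & np.isfinite(y_prev)
            & np.isfinite(y_next)
            & np.outer(good, good)
        )
        iu = np.triu_indices(n, k=1)
        td[iu] = np.where(ok[iu], tau[iu], 0.0)
        amp[iu] = np.where(ok[iu], a_mat[iu], 0.0)
        validity[iu] = ok[iu]
    else:
        for i in range(n):
            if not good[i]:
                continue
            for j in range(i + 1, n):
                if not good[j]:
                    continue
                try:
                    est = estimate_pair_lag(
                        data[i], data[j], mask, tr=epoch.tr,
                        max_lag_frames=L, normalize=normalize,
                        min_overlap=min_overlap,
                    )
                except ValueError:
                    continue
                if est.valid and np.isfinite(est.tau):
                    td[i, j] = est.tau
                    amp[i, j] = est.amplitude
                    validity[i, j] = True

    td = td - td.T            # lower triangle = exact negation
    amp = amp + amp.T
    validity = validity | validity.T
    np.fill_diagonal(td, 0.0)
    np.fill_diagonal(amp, 0.0)
    np.fill_diagonal(validity, good)
    return TimeDelayMatrix(td=td, amp=amp, validity=validity, tr=epoch.tr,
                           excluded=excluded)


def zero_lag_fc(epoch: TimeSeriesEpoch, min_frames: int = 30) -> FCMatrix:
    """Zero-lag Pearson correlation over valid frames, with Fisher z.

    ``z = atanh(r)`` off the diagonal (clipped just inside +-1 for
    numerical safety); the diagonal of ``z`` is set to 0. Zero-variance
    voxels are excluded and reported.
    """
    data = epoch.data[:, epoch.valid]
    if data.shape[1] < min_frames:
        raise ValueError(f"need >= {min_frames} valid frames")
    var = data.var(axis=1)
    good = var > 0
    excluded = np.flatnonzero(~good)
    n = epoch.n_voxels
    r = np.zeros((n, n))
    if good.any():
        sub = np.corrcoef(data[good])
        r[np.ix_(good, good)] = sub
    np.fill_diagonal(r, np.where(good, 1.0, 0.0))
    z = np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    np.fill_diagonal(z, 0.0)
    validity = np.outer(good, good)
    return FCMatrix(r=r, z=z, validity=validity, excluded=excluded)
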