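"""Per-epoch time-series preparation before lag estimation.

Stages: per-voxel linear detrending, zero-phase low-pass filtering below
0.1 Hz (the infra-slow band), nuisance regression (including the global
mean signal), and frame censoring at a 0.5 % RMS frame-to-frame
intensity-change threshold with removal of surviving runs shorter than
10 contiguous frames.

Zero phase matters here: the measurand downstream is temporal lag, so
the filter must not introduce any group delay. The low-pass is a
second-order Butterworth applied forward and backward (effective fourth
order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .epoch import TimeSeriesEpoch

__all__ = [
    "NuisanceSet",
    "detrend_linear",
    "lowpass",
    "regress_nuisance",
    "censor_frames",
    "frame_displacement_rms",
    "preprocess_epoch",
]


@dataclass
class NuisanceSet:
    """Nuisance regressors (frames x q) with column labels."""

    regressors: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.shape[1] != len(self.labels):
            raise ValueError("one label per regressor column required")
        if not np.isfinite(self.regressors).all():
            raise ValueError("regressors must be finite")
        if (np.abs(self.regressors).max(axis=0) == 0).any():
            raise ValueError("constant-zero regressor column")


def detrend_linear(epoch: TimeSeriesEpoch) -> TimeSeriesEpoch:
    """Remove each voxel's least-squares line fitted over valid frames.

    The fitted line is evaluated and subtracted at *all* frames so that
    invalid frames stay aligned; residuals have zero mean over the valid
    frames.
    """
    if epoch.n_valid < 3:
        raise ValueError("need at least 3 valid frames to detrend")
    t = np.arange(epoch.n_frames, dtype=float)
    v = epoch.valid
    X = np.column_stack([np.ones(epoch.n_frames), t])
    coef, *_ = np.linalg.lstsq(X[v], epoch.data[:, v].T, rcond=None)
    return epoch.with_data(epoch.data - (X @ coef).T)


def lowpass(epoch: TimeSeriesEpoch, cutoff_hz: float = 0.1) -> TimeSeriesEpoch:
    """Zero-phase low-pass below ``cutoff_hz`` over the full frame axis.

    Gaps are not interpolated: filtering runs over all frames and the
    validity mask is carried through unchanged.
    """
    nyquist = 0.5 / epoch.tr
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:.4f}) Hz"
        )
    b, a = butter(2, cutoff_hz, btype="low", fs=1.0 / epoch.tr)
    filtered = filtfilt(b, a, epoch.data, axis=1)
    return epoch.with_data(filtered)


def regress_nuisance(
    epoch: TimeSeriesEpoch,
    nuis: NuisanceSet | None = None,
    include_global: bool = True,
) -> TimeSeriesEpoch:
    """Regress nuisance waveforms (and optionally the global mean) out.

    The design (intercept + regressors) is fitted over valid frames and
    its prediction subtracted at all frames; residuals are orthogonal to
    every regressor column over the valid frames. A rank-deficient
    design raises an error naming the collinear columns.
    """
    cols: list[np.ndarray] = [np.ones(epoch.n_frames)]
    labels = ["intercept"]
    if nuis is not None:
        if nuis.regressors.shape[0] != epoch.n_frames:
            raise ValueError("regressor rows must align with frames")
        for j, lab in enumerate(nuis.labels):
            cols.append(nuis.regressors[:, j])
            labels.append(lab)
    if include_global:
        cols.append(epoch.data.mean(axis=0))
        labels.append("global_mean")
    X = np.column_stack(cols)
    v = epoch.valid
    Xv = X[v]
    rank = np.linalg.matrix_rank(Xv)
    if rank < X.shape[1]:
        # pivoted QR localizes the dependent columns
        from scipy.linalg import qr

        _, R, piv = qr(Xv, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xv.shape) * np.finfo(float).eps
        bad = [labels[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(Xv, epoch.data[:, v].T, rcond=None)
    return epoch.with_data(epoch.data - (X @ coef).T)


def frame_displacement_rms(
    data: np.ndarray, reference_mean: float | None = None
) -> np.ndarray:
    """Normalized RMS frame-to-frame intensity change (DVARS-like), in %.

    ``out[t]`` (t >= 1) is the root mean square over voxels of the
    intensity change from frame ``t-1`` to ``t``, expressed as a
    percentage of the grand mean intensity (or of ``reference_mean`` if
    given — required when the data are already demeaned). ``out[0] = 0``
    by convention.
    """
    data = np.asarray(data, dtype=float)
    ref = float(np.mean(data)) if reference_mean is None else float(reference_mean)
    if ref <= 0:
        raise ValueError(
            "grand mean intensity is not positive; pass reference_mean "
            "(the data appear to be demeaned)"
        )
    diff = np.diff(data, axis=1)
    rms = np.sqrt((diff ** 2).mean(axis=0))
    out = np.zeros(data.shape[1])
    out[1:] = 100.0 * rms / ref
    return out


def _invalidate_short_runs(valid: np.ndarray, min_run: int) -> np.ndarray:
    """Zero out maximal valid runs shorter than ``min_run`` frames."""
    valid = valid.copy()
    n = valid.size
    t = 0
    while t < n:
        if valid[t]:
            start = t
            while t < n and valid[t]:
                t += 1
            if t - start < min_run:
                valid[start:t] = False
        else:
            t += 1
    return valid


def censor_frames(
    epoch: TimeSeriesEpoch,
    threshold_pct: float = 0.5,
    min_run: int = 10,
    reference_mean: float | None = None,
) -> TimeSeriesEpoch:
    """Censor frames by the RMS frame-to-frame intensity-change criterion.

    A frame is marked invalid when its normalized RMS change from the
    previous frame exceeds ``threshold_pct`` percent (the first frame of
    the epoch is kept by convention, having no predecessor). Afterwards,
    every maximal run of valid frames shorter than ``min_run`` is
    invalidated entirely. An epoch where nothing survives is returned
    with an all-false mask (check ``has_valid_frames``), not raised.
    """
    if epoch.n_frames < 2:
        raise ValueError("need at least 2 frames to censor")
    stat = frame_displacement_rms(epoch.data, reference_mean=reference_mean)
    new_valid = epoch.valid & (stat <= threshold_pct)
    new_valid[0] = epoch.valid[0]
    new_valid = _invalidate_short_runs(new_valid, min_run)
    return epoch.with_mask(new_valid)


def preprocess_epoch(
    epoch: TimeSeriesEpoch,
    nuisance: NuisanceSet | None = None,
    cutoff_hz: float = 0.1,
    include_global: bool = True,
    censor_threshold_pct: float = 0.5,
    min_run: int = 10,
    censor_on: str = "raw",
) -> TimeSeriesEpoch:
    """Full per-epoch pipeline: detrend, low-pass, nuisance, censor.

    With ``censor_on="raw"`` (default) the censoring statistic is
    computed from the input data — which still carries the mean
    intensity the percentage threshold is relative to — and the
    resulting mask is intersected at the end. ``censor_on="processed"``
    computes it from the processed data instead and then requires the
    caller to supply a meaningful reference via the raw grand mean.
    """
    if censor_on not in ("raw", "processed"):
        raise ValueError("censor_on must be 'raw' or 'processed'")
    raw_ref = float(np.mean(epoch.data))
    out = detrend_linear(epoch)
    out = lowpass(out, cutoff_hz=cutoff_hz)
    out = regress_nuisance(out, nuisance, include_global=include_global)
    if censor_on == "raw":
        censor_mask = censor_frames(
            epoch, threshold_pct=censor_threshold_pct, min_run=min_run
        ).valid
        combined = out.valid & censor_mask
        combined = _invalidate_short_runs(combined, min_run)
        out = out.with_mask(combined)
    else:
        out = censor_frames(
            out, threshold_pct=censor_threshold_pct, min_run=min_run,
            reference_mean=raw_ref,
        )
    return out
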