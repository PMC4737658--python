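"""Synthetic multi-subject two-state datasets with planted lag structure.

The study analyzed here concerns apparent propagation of infra-slow
(<0.1 Hz) BOLD activity, so every downstream stage needs input whose
true lag structure is known. The forward model is deliberately minimal:

* *k* latent aperiodic sources with 1/f^alpha power spectra (alpha = 1
  by default), generated on a fine time grid (default TR/32) so that
  fractional, sub-TR delays are representable;
* each voxel observes a weighted sum of the sources, each source shifted
  by a voxel-specific delay (cubic interpolation on the fine grid), plus
  white noise and a baseline intensity;
* multiple simultaneous sources with distinct delay fields play the role
  of multiple propagation "threads": the measured pairwise lag then
  depends nonlinearly on all delay fields, which is what gives the
  time-delay matrix a multi-dimensional structure.

Two brain states are emulated by giving each state its own
:class:`LagPlan` (e.g. reversed delays in a voxel subset, a uniformly
shifted "all-early" network, or a globally widened delay spread).
Everything is reproducible from integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .epoch import TimeSeriesEpoch
from .lattice import LatticeGeometry
from .partition import DEFAULT_NETWORK_NAMES, NetworkPartition

__all__ = [
    "SourceSet",
    "LagPlan",
    "StudyDesign",
    "generate_sources",
    "synthesize_epoch",
    "generate_study",
    "inject_artifacts",
    "planted_thread_td",
    "lattice_partition",
    "reorganized_two_state_design",
]

#: Study sampling defaults: TR in seconds and minimum epoch length in frames.
DEFAULT_TR = 2.08
DEFAULT_FRAMES = 150
#: Fine-grid resolution for representing fractional delays.
FINE_DIVISOR = 32
#: Baseline intensity added to every voxel (EPI-like), so that the 0.5 %
#: frame-censoring threshold corresponds to 5 intensity units.
DEFAULT_BASELINE = 1000.0
#: Infra-slow passband of the generated sources (Hz). Matching the band
#: the analysis targets keeps single-epoch lag estimates well-behaved:
#: power below ~1/epoch-length would act as an unresolvable trend.
DEFAULT_BAND = (0.01, 0.1)


@dataclass(frozen=True)
class SourceSet:
    """Latent aperiodic sources on a fine time grid."""

    signals: np.ndarray           # (k, m_fine), zero mean per row
    dt_fine: float                # seconds per fine sample
    spectral_exponent: float      # power ~ 1/f^alpha
    rng_seed: int

    @property
    def k(self) -> int:
        return self.signals.shape[0]

    @property
    def span(self) -> float:
        """Covered time span in seconds."""
        return (self.signals.shape[1] - 1) * self.dt_fine


@dataclass
class LagPlan:
    """Mixing weights and per-voxel fractional delays defining one state.

    ``delays[v, k]`` (seconds, not necessarily multiples of TR) shifts
    source *k* as seen by voxel *v*; for a single source the ground-truth
    pairwise lag is ``delays[i] - delays[j]``.
    """

    weights: np.ndarray           # (n_voxels, k)
    delays: np.ndarray            # (n_voxels, k) seconds
    noise_sd: float = 1.0
    tr: float = DEFAULT_TR
    n_frames: int = DEFAULT_FRAMES
    baseline: float = DEFAULT_BASELINE

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.delays = np.atleast_2d(np.asarray(self.delays, dtype=float))
        if self.weights.shape != self.delays.shape:
            raise ValueError("weights and delays must have the same shape")
        if not np.isfinite(self.delays).all():
            raise ValueError("delays must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    @property
    def k(self) -> int:
        return self.weights.shape[1]


@dataclass
class StudyDesign:
    """Two-state (or multi-state) multi-subject study layout."""

    n_subjects_per_state: int
    epochs_per_subject: int
    frames_per_epoch: int
    state_plans: dict[str, LagPlan]
    partition: NetworkPartition | None = None
    rng_seed: int = 0
    alpha: float = 1.0
    band: tuple[float, float] = DEFAULT_BAND
    dt_fine: float | None = None
    geometry: LatticeGeometry | None = None

    def __post_init__(self) -> None:
        if not self.state_plans:
            raise ValueError("state_plans must not be empty")
        if len(set(self.state_plans)) != len(self.state_plans):
            raise ValueError("state labels must be distinct")
        if self.frames_per_epoch < 1:
            raise ValueError("frames_per_epoch must be positive")


def generate_sources(
    k: int,
    m_fine: int,
    dt_fine: float,
    alpha: float = 1.0,
    seed: int = 0,
    band: tuple[float, float] = DEFAULT_BAND,
) -> SourceSet:
    """Generate *k* independent band-limited 1/f^alpha sources.

    White Gaussian noise is shaped in the frequency domain by
    ``f ** (-alpha / 2)`` inside the infra-slow passband ``band`` (zero
    outside, which also removes DC and enforces zero mean) and
    transformed back; each signal is standardized to unit variance. With
    ``alpha = 0`` the passband spectrum is flat.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if m_fine < 64:
        raise ValueError("m_fine must be >= 64")
    if dt_fine <= 0:
        raise ValueError("dt_fine must be positive")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((k, m_fine))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(m_fine, d=dt_fine)
    shape = np.zeros_like(freqs)
    in_band = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not in_band.any():
        raise ValueError("passband contains no resolvable frequencies")
    shape[in_band] = freqs[in_band] ** (-alpha / 2.0)
    signals = np.fft.irfft(spec * shape, n=m_fine, axis=1)
    signals -= signals.mean(axis=1, keepdims=True)
    sd = signals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    signals /= sd
    return SourceSet(signals=signals, dt_fine=dt_fine,
                     spectral_exponent=alpha, rng_seed=seed)


def synthesize_epoch(
    sources: SourceSet,
    plan: LagPlan,
    seed: int = 0,
    subject_id: str = "",
    state_label: str = "",
    epoch_id: str = "",
) -> TimeSeriesEpoch:
    """Sample one epoch from the forward model.

    Voxel *v* observes ``sum_k weights[v,k] * s_k(t - delays[v,k])``
    evaluated by cubic interpolation on the fine grid and sampled every
    TR, plus white noise of ``plan.noise_sd`` and the baseline. The
    sampling origin is placed so every delayed evaluation time falls
    inside the fine-grid span; delays too large for the span raise.
    """
    if plan.k != sources.k:
        raise ValueError("plan and sources disagree on the number of sources")
    d_max = float(plan.delays.max())
    d_min = float(plan.delays.min())
    t0 = max(0.0, d_max)
    t_frames = t0 + plan.tr * np.arange(plan.n_frames)
    t_last = t_frames[-1] - min(0.0, d_min)
    if t_last > sources.span + 1e-9:
        raise ValueError(
            f"required span {t_last:.2f}s exceeds fine-grid span "
            f"{sources.span:.2f}s; increase m_fine"
        )
    fine_t = sources.dt_fine * np.arange(sources.signals.shape[1])
    data = np.zeros((plan.n_voxels, plan.n_frames))
    for kk in range(sources.k):
        spline = CubicSpline(fine_t, sources.signals[kk])
        eval_t = t_frames[None, :] - plan.delays[:, kk][:, None]
        data += plan.weights[:, kk][:, None] * spline(eval_t)
    rng = np.random.default_rng(seed)
    if plan.noise_sd > 0:
        data += plan.noise_sd * rng.standard_normal(data.shape)
    data += plan.baseline
    return TimeSeriesEpoch(data=data, tr=plan.tr,
                           subject_id=subject_id, state_label=state_label,
                           epoch_id=epoch_id)


def _m_fine_for(plan: LagPlan, dt_fine: float) -> int:
    span_needed = (
        max(0.0, float(plan.delays.max()))
        + plan.tr * plan.n_frames
        - min(0.0, float(plan.delays.min()))
        + 4.0 * dt_fine
    )
    return max(64, int(np.ceil(span_needed / dt_fine)) + 1)


def generate_study(design: StudyDesign) -> list[TimeSeriesEpoch]:
    """Generate all subject epochs of a study design.

    Each subject-epoch gets an independent source realization; all
    epochs of a state share that state's :class:`LagPlan`. The output is
    deterministic given ``design.rng_seed``.
    """
    rng = np.random.default_rng(design.rng_seed)
    epochs: list[TimeSeriesEpoch] = []
    for state, plan in design.state_plans.items():
        plan = LagPlan(
            weights=plan.weights, delays=plan.delays, noise_sd=plan.noise_sd,
            tr=plan.tr, n_frames=design.frames_per_epoch,
            baseline=plan.baseline,
        )
        dt_fine = design.dt_fine or plan.tr / FINE_DIVISOR
        m_fine = _m_fine_for(plan, dt_fine)
        for s in range(design.n_subjects_per_state):
            for e in range(design.epochs_per_subject):
                src_seed = int(rng.integers(0, 2**31 - 1))
                noise_seed = int(rng.integers(0, 2**31 - 1))
                sources = generate_sources(
                    plan.k, m_fine, dt_fine, alpha=design.alpha,
                    seed=src_seed, band=design.band,
                )
                epochs.append(
                    synthesize_epoch(
                        sources, plan, seed=noise_seed,
                        subject_id=f"sub{s:02d}", state_label=state,
                        epoch_id=f"ep{e:02d}",
                    )
                )
    return epochs


def inject_artifacts(
    epoch: TimeSeriesEpoch, spike_frames, spike_amplitude: float
) -> TimeSeriesEpoch:
    """Add a global intensity deviation at the listed frames.

    The validity mask is left unchanged: flagging these frames is the
    job of the censoring stage.
    """
    spike_frames = np.atleast_1d(np.asarray(spike_frames, dtype=int))
    if spike_frames.size and (
        spike_frames.min() < 0 or spike_frames.max() >= epoch.n_frames
    ):
        raise ValueError("spike frame index out of range")
    out = epoch.copy()
    out.data[:, spike_frames] += spike_amplitude
    return out


def planted_thread_td(
    n_voxels: int,
    n_threads: int,
    seed: int = 0,
    snr: float = 5.0,
    scale: float = 0.5,
):
    """Anti-symmetric TD matrix with exactly ``n_threads`` planted threads.

    Thread topographies are orthonormal centered spatial patterns,
    combined into an anti-symmetric matrix whose column-centered column
    space has dimension exactly ``n_threads`` (pairs of threads form
    rotation-like terms ``v_a v_b' - v_b v_a'``; an odd leftover thread
    enters as a delay-difference term ``v 1' - 1 v'``). Anti-symmetric
    white noise is added at the given signal-to-noise ratio (ratio of
    the SD of the unique structural entries to the noise SD).

    Note that a forward time-series model with *k* simultaneous sources
    does **not** plant a rank-k structure: the measured pairwise lag is
    a weight-dependent mixture of per-source delay differences, which
    spans up to 2k-1 centered dimensions. Planting at the TD level is
    therefore the construction whose ground-truth dimensionality is
    unambiguous.
    """
    from .lagcore import TimeDelayMatrix

    if n_threads < 1 or n_voxels < n_threads + 2:
        raise ValueError("need n_voxels > n_threads + 1 and n_threads >= 1")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_voxels, n_threads + 1))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    v = q[:, :n_threads] * scale * np.sqrt(n_voxels)
    td = np.zeros((n_voxels, n_voxels))
    t = 0
    while t + 1 < n_threads:
        td += np.outer(v[:, t], v[:, t + 1]) - np.outer(v[:, t + 1], v[:, t])
        t += 2
    if t < n_threads:
        ones = np.ones(n_voxels)
        td += np.outer(v[:, t], ones) - np.outer(ones, v[:, t])
    if snr > 0:
        sig_sd = td[np.triu_indices(n_voxels, 1)].std()
        noise = rng.standard_normal((n_voxels, n_voxels)) * sig_sd / snr
        upper = np.triu(noise, 1)
        td = td + upper - upper.T
    return TimeDelayMatrix(
        td=td, amp=np.zeros_like(td),
        validity=np.ones_like(td, dtype=bool), tr=DEFAULT_TR,
    ), v


def lattice_partition(
    geometry: LatticeGeometry,
    n_networks: int = 7,
    names: list[str] | None = None,
    seed: int = 0,
) -> NetworkPartition:
    """Contiguous-ish partition of lattice voxels into named networks.

    Voxels are split into ``n_networks`` equal slabs along the flattened
    order, which keeps networks spatially compact on the lattice.
    """
    if names is None:
        names = (
            DEFAULT_NETWORK_NAMES[:n_networks]
            if n_networks <= len(DEFAULT_NETWORK_NAMES)
            else [f"NET{i}" for i in range(n_networks)]
        )
    n = geometry.n_voxels
    labels = np.minimum((np.arange(n) * n_networks) // n, n_networks - 1)
    return NetworkPartition(labels=labels, names=list(names))


def reorganized_two_state_design(
    geometry: LatticeGeometry | None = None,
    n_subjects_per_state: int = 6,
    epochs_per_subject: int = 1,
    frames_per_epoch: int = DEFAULT_FRAMES,
    noise_sd: float = 0.2,
    seed: int = 0,
    state_a: str = "wake",
    state_b: str = "sws",
) -> StudyDesign:
    """Two-state study emulating the three headline reorganization motifs.

    Relative to state A ("wake-like"), state B ("SWS-like") plants:

    * a *reversed* delay field in network 0 (a subcortex analog): voxels
      that lead in state A follow in state B;
    * an *all-early* network 3 (visual analog): its delays are uniformly
      shifted -0.5 s;
    * a *doubled delay spread* over the remaining cortex, so the SD of
      the unique lag values roughly doubles.

    Voxel weights on the single propagating source are 1; white noise at
    ``noise_sd`` (signal units; sources have unit variance).
    """
    if geometry is None:
        geometry = LatticeGeometry(shape=(6, 6, 3))
    n = geometry.n_voxels
    partition = lattice_partition(geometry, n_networks=7)
    rng = np.random.default_rng(seed)
    base = rng.uniform(-0.6, 0.6, size=n)        # wake delay field, seconds
    sub = partition.members(0)                    # subcortex analog
    vis = partition.members(3)                    # visual analog
    base[sub] = rng.uniform(-0.6, -0.2, size=sub.size)   # early in wake

    delays_b = 2.0 * base                         # doubled spread
    delays_b[sub] = -base[sub]                    # reversal: early -> late
    delays_b[vis] = 2.0 * base[vis] - 0.5         # uniformly early shift

    weights = np.ones((n, 1))
    plan_a = LagPlan(weights=weights, delays=base[:, None], noise_sd=noise_sd,
                     n_frames=frames_per_epoch)
    plan_b = LagPlan(weights=weights, delays=delays_b[:, None],
                     noise_sd=noise_sd, n_frames=frames_per_epoch)
    return StudyDesign(
        n_subjects_per_state=n_subjects_per_state,
        epochs_per_subject=epochs_per_subject,
        frames_per_epoch=frames_per_epoch,
        state_plans={state_a: plan_a, state_b: plan_b},
        partition=partition,
        rng_seed=seed,
        geometry=geometry,
    )
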