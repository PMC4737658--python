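"""Synthetic-data generator: spectra, planted delays, study bookkeeping."""

import numpy as np
import pytest
from scipy.signal import periodogram

import boldlag as bl
from boldlag.preprocess import frame_displacement_rms, censor_frames
from boldlag.synthdata import planted_thread_td, reorganized_two_state_design

TR = 2.08
DT = TR / 32


def _ensemble_slope(alpha: float, seed: int, k: int = 60) -> float:
    """Least-squares log-log periodogram slope inside the passband."""
    src = bl.generate_sources(k, 2 ** 14, DT, alpha=alpha, seed=seed)
    f, p = periodogram(src.signals, fs=1.0 / DT, axis=1)
    pm = p.mean(axis=0)
    m = (f >= 0.015) & (f <= 0.09) & (pm > 0)
    A = np.column_stack([np.ones(m.sum()), np.log(f[m])])
    coef, *_ = np.linalg.lstsq(A, np.log(pm[m]), rcond=None)
    return float(coef[1])


class TestGenerateSources:
    def test_white_spectrum_flat_in_passband(self):
        assert abs(_ensemble_slope(0.0, seed=0)) < 0.15

    def test_one_over_f_slope(self):
        assert abs(_ensemble_slope(1.0, seed=1) - (-1.0)) < 0.15

    def test_determinism_and_zero_mean(self):
        a = bl.generate_sources(3, 1024, DT, alpha=1.0, seed=5)
        b = bl.generate_sources(3, 1024, DT, alpha=1.0, seed=5)
        assert np.array_equal(a.signals, b.signals)
        assert np.allclose(a.signals.mean(axis=1), 0.0, atol=1e-12)
        assert np.isfinite(a.signals).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k=0, m_fine=1024, dt_fine=DT),
            dict(k=1, m_fine=32, dt_fine=DT),
            dict(k=1, m_fine=1024, dt_fine=-1.0),
            dict(k=1, m_fine=1024, dt_fine=DT, alpha=-0.5),
        ],
    )
    def test_argument_errors(self, kwargs):
        with pytest.raises(ValueError):
            bl.generate_sources(**kwargs)


class TestSynthesizeEpoch:
    def test_zero_delays_identical_rows(self):
        src = bl.generate_sources(1, 4096, DT, seed=2)
        plan = bl.LagPlan(weights=np.ones((4, 1)), delays=np.zeros((4, 1)),
                          noise_sd=0.0, n_frames=100)
        ep = bl.synthesize_epoch(src, plan, seed=0)
        assert np.allclose(ep.data, ep.data[0][None, :])
        assert ep.valid.all()

    def test_planted_one_second_delay_recovered(self):
        src = bl.generate_sources(1, 8192, DT, seed=7)
        plan = bl.LagPlan(weights=np.ones((2, 1)),
                          delays=np.array([[1.0], [0.0]]),
                          noise_sd=0.0, n_frames=150)
        ep = bl.synthesize_epoch(src, plan, seed=1)
        est = bl.estimate_pair_lag(ep.data[0], ep.data[1], tr=TR)
        assert est.valid
        assert abs(est.tau - 1.0) <= 0.05

    def test_pure_noise_unit_variance(self):
        src = bl.generate_sources(1, 2 ** 14, DT, seed=2)
        plan = bl.LagPlan(weights=np.zeros((6, 1)), delays=np.zeros((6, 1)),
                          noise_sd=1.0, n_frames=500, baseline=0.0)
        ep = bl.synthesize_epoch(src, plan, seed=9)
        assert np.allclose(ep.data.var(axis=1), 1.0, atol=0.2)

    def test_delay_beyond_span_raises(self):
        src = bl.generate_sources(1, 4096, DT, seed=2)
        plan = bl.LagPlan(weights=np.ones((2, 1)),
                          delays=np.array([[0.0], [-500.0]]),
                          noise_sd=0.0, n_frames=60)
        with pytest.raises(ValueError, match="span"):
            bl.synthesize_epoch(src, plan, seed=0)

    def test_superposition_scaling(self):
        src = bl.generate_sources(1, 8192, DT, seed=7)
        delays = np.array([[0.7], [0.0]])
        plan1 = bl.LagPlan(weights=np.ones((2, 1)), delays=delays,
                           noise_sd=0.0, n_frames=150, baseline=0.0)
        plan3 = bl.LagPlan(weights=3.0 * np.ones((2, 1)), delays=delays,
                           noise_sd=0.0, n_frames=150, baseline=0.0)
        e1 = bl.synthesize_epoch(src, plan1, seed=0)
        e3 = bl.synthesize_epoch(src, plan3, seed=0)
        cov1 = np.cov(e1.data)[0, 1]
        cov3 = np.cov(e3.data)[0, 1]
        assert np.isclose(cov3, 9.0 * cov1, rtol=1e-10)
        t1 = bl.estimate_pair_lag(e1.data[0], e1.data[1], tr=TR).tau
        t3 = bl.estimate_pair_lag(e3.data[0], e3.data[1], tr=TR).tau
        assert np.isclose(t1, t3, atol=1e-9)


class TestGenerateStudy:
    def _design(self, seed=0):
        n = 6
        plan = bl.LagPlan(weights=np.ones((n, 1)),
                          delays=np.linspace(-0.5, 0.5, n)[:, None],
                          noise_sd=0.1, n_frames=60)
        return bl.StudyDesign(
            n_subjects_per_state=5, epochs_per_subject=1, frames_per_epoch=60,
            state_plans={"wake": plan, "sws": plan}, rng_seed=seed,
        )

    def test_bookkeeping(self):
        epochs = bl.generate_study(self._design())
        assert len(epochs) == 10
        labels = {(e.state_label, e.subject_id, e.epoch_id) for e in epochs}
        assert len(labels) == 10
        assert {e.state_label for e in epochs} == {"wake", "sws"}

    def test_determinism(self):
        a = bl.generate_study(self._design(seed=3))
        b = bl.generate_study(self._design(seed=3))
        for x, y in zip(a, b):
            assert np.array_equal(x.data, y.data)

    def test_empty_state_plans_rejected(self):
        with pytest.raises(ValueError):
            bl.StudyDesign(n_subjects_per_state=1, epochs_per_subject=1,
                           frames_per_epoch=60, state_plans={})

    def test_planted_reversal_flips_subset_signs(self):
        """Negating a voxel subset's delays flips TD signs only in that
        subset's rows/columns (other voxels at zero delay)."""
        n = 8
        subset = np.array([0, 1, 2])
        delays_a = np.zeros((n, 1))
        delays_a[subset, 0] = [0.5, 0.8, 1.1]
        delays_b = -delays_a
        src = bl.generate_sources(1, 8192, DT, seed=11)
        tds = {}
        for key, d in (("a", delays_a), ("b", delays_b)):
            plan = bl.LagPlan(weights=np.ones((n, 1)), delays=d,
                              noise_sd=0.0, n_frames=150)
            tds[key] = bl.build_td_matrix(bl.synthesize_epoch(src, plan, seed=4))
        in_subset = np.zeros(n, dtype=bool)
        in_subset[subset] = True
        involves = in_subset[:, None] | in_subset[None, :]
        offdiag = ~np.eye(n, dtype=bool)
        flip = tds["a"].td + tds["b"].td           # ~0 where sign flipped
        same = tds["a"].td - tds["b"].td           # ~0 where unchanged
        assert np.abs(flip[involves & offdiag]).max() < 0.12
        assert np.abs(same[~involves & offdiag]).max() < 0.12


class TestInjectArtifacts:
    def test_empty_spikes_identity(self, ):
        rng = np.random.default_rng(0)
        ep = bl.TimeSeriesEpoch(1000 + rng.standard_normal((5, 40)), tr=TR)
        out = bl.inject_artifacts(ep, [], 10.0)
        assert np.array_equal(out.data, ep.data)
        assert np.array_equal(out.valid, ep.valid)

    def test_out_of_range_spike_rejected(self):
        ep = bl.TimeSeriesEpoch(np.ones((3, 20)) * 1000, tr=TR)
        with pytest.raises(ValueError):
            bl.inject_artifacts(ep, [25], 10.0)

    def test_spike_exceeds_censoring_threshold(self):
        """A 10x-noise-SD global spike pushes the normalized RMS change
        past the 0.5 % censoring threshold."""
        rng = np.random.default_rng(1)
        ep = bl.TimeSeriesEpoch(1000 + rng.standard_normal((20, 60)), tr=TR)
        out = bl.inject_artifacts(ep, [30], 10.0)
        stat = frame_displacement_rms(out.data)
        assert stat[30] > 0.5 and stat[31] > 0.5
        base = frame_displacement_rms(ep.data)
        assert base.max() < 0.5

    def test_spike_train_excludes_short_epoch(self):
        """Spikes at frames 3..12 of a 20-frame epoch fragment it into
        runs all shorter than 10 frames, so nothing survives."""
        rng = np.random.default_rng(2)
        ep = bl.TimeSeriesEpoch(1000 + 0.5 * rng.standard_normal((10, 20)), tr=TR)
        out = bl.inject_artifacts(ep, list(range(3, 13)), 25.0)
        censored = censor_frames(out, threshold_pct=0.5, min_run=10)
        assert not censored.has_valid_frames


class TestPlantedThreadTD:
    def test_antisymmetric_with_planted_rank(self):
        td, v = planted_thread_td(40, 2, seed=0, snr=0.0)
        assert np.allclose(td.td, -td.td.T)
        M = td.td - td.td.mean(axis=0, keepdims=True)
        assert np.linalg.matrix_rank(M, tol=1e-8) == 2

    def test_reorganized_design_shapes(self):
        design = reorganized_two_state_design(seed=1)
        assert set(design.state_plans) == {"wake", "sws"}
        pa = design.state_plans["wake"]
        pb = design.state_plans["sws"]
        assert pa.n_voxels == pb.n_voxels == design.geometry.n_voxels
        vis = design.partition.members(3)
        # visual-analog network is uniformly shifted early in state B
        shift = pb.delays[vis, 0] - 2.0 * pa.delays[vis, 0]
        assert np.allclose(shift, -0.5)
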