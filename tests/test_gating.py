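"""Trace-level gating analysis: filtering, amplitude histograms, normalized
open probability, Hill fits, relaxation fits, and dwell-time NPo."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from trpm2kit import gating, simulate as sim
from trpm2kit.gating import CurrentTrace, Epoch


def _one_channel_trace(po_target=0.5, duration=60.0, seed=0, noise_sd=0.3,
                       n_channels=1, voltage=-20.0):
    """Simulated patch at the cytosolic [Ca2+] that gives the target P_o."""
    params = sim.preset("WT", n_channels=n_channels, noise_sd=noise_sd)
    ca = brentq(lambda c: sim.equilibrium_po(params, c, voltage) - po_target,
                1e-3, 1e6)
    protocol = sim.SimProtocol(
        (Epoch(0.0, duration, adpr=100.0, ca_cyto_free=ca, voltage=voltage),),
        seed=seed)
    return sim.simulate_patch(params, protocol), params


class TestFilter:
    def test_dc_trace_unchanged(self):
        tr = CurrentTrace(np.full(5000, -3.0), 5000.0)
        out = gating.filter_trace(tr, 200.0)
        assert np.allclose(out.samples, -3.0, atol=1e-9)
        assert len(out.samples) == len(tr.samples)

    def test_sinusoid_at_10x_cutoff_strongly_attenuated(self):
        fs, fc = 20000.0, 200.0
        t = np.arange(0, 2.0, 1 / fs)
        tr = CurrentTrace(np.sin(2 * np.pi * 10 * fc * t), fs)
        out = gating.filter_trace(tr, fc)
        assert np.abs(out.samples[2000:-2000]).max() < 1.0 / 20.0

    def test_white_noise_variance_matches_enbw(self):
        """Gaussian filter ENBW: output/input variance = 1/(2 sqrt(pi) sigma)."""
        fs, fc = 10000.0, 200.0
        rng = np.random.default_rng(1)
        tr = CurrentTrace(rng.normal(0, 1.0, 200000), fs)
        out = gating.filter_trace(tr, fc)
        sigma = gating.gaussian_sigma_samples(fc, fs)
        expected = 1.0 / (2 * math.sqrt(math.pi) * sigma)
        ratio = out.samples.var() / tr.samples.var()
        assert ratio == pytest.approx(expected, rel=0.10)

    def test_cutoff_above_nyquist_rejected(self):
        tr = CurrentTrace(np.zeros(1000), 1000.0)
        with pytest.raises(ValueError):
            gating.filter_trace(tr, 600.0)


class TestAllPointsHistogram:
    def test_single_channel_unitary_current(self):
        res, params = _one_channel_trace(po_target=0.5, duration=30.0, seed=2)
        filtered = gating.filter_trace(res.trace, 200.0)
        fit = gating.fit_all_points_histogram(filtered.samples)
        assert fit.unitary_i == pytest.approx(-3.0, abs=0.1)
        assert fit.n_levels == 1
        assert sum(fit.level_weights) == pytest.approx(1.0, abs=1e-6)

    def test_all_closed_trace_flagged(self):
        rng = np.random.default_rng(3)
        fit = gating.fit_all_points_histogram(rng.normal(0, 0.3, 20000))
        assert fit.single_level
        assert math.isnan(fit.unitary_i)
        assert "single_level" in fit.flags

    def test_three_channels_equally_spaced_levels(self):
        res, _ = _one_channel_trace(po_target=0.5, duration=60.0, seed=4,
                                    n_channels=3)
        filtered = gating.filter_trace(res.trace, 200.0)
        fit = gating.fit_all_points_histogram(filtered.samples)
        assert fit.n_levels == 3
        spacings = np.diff(fit.level_means)
        assert np.allclose(spacings, -3.0, rtol=0.05)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            gating.fit_all_points_histogram(np.zeros(100))


class TestNormalizedPo:
    def test_identity_and_pure_block_cancel(self):
        assert gating.normalized_po(-100, -100, -3, -3).value == pytest.approx(1.0)
        # 50% pore block without any gating change
        assert gating.normalized_po(-50, -100, -1.5, -3).value == pytest.approx(1.0)

    def test_block_corrected_recovery_from_simulation(self):
        """40% unitary block with a true P_o ratio of ~0.3."""
        params = sim.preset("WT", n_channels=4, noise_sd=0.2)
        ca_ref = brentq(lambda c: sim.equilibrium_po(params, c, -20) - 0.55,
                        1e-3, 1e6)
        ca_test = brentq(lambda c: sim.equilibrium_po(params, c, -20) - 0.165,
                         1e-3, 1e6)
        # emulate a 40% block in the test condition via k_block override
        blocked = sim.preset("WT", n_channels=4, noise_sd=0.2,
                             k_block=ca_test * 1.5)  # -> i reduced to 60%
        prot_ref = sim.SimProtocol(
            (Epoch(0, 40.0, adpr=100, ca_cyto_free=ca_ref),), seed=7)
        prot_test = sim.SimProtocol(
            (Epoch(0, 40.0, adpr=100, ca_cyto_free=ca_test),), seed=8)
        res_ref = sim.simulate_patch(params, prot_ref)
        res_test = sim.simulate_patch(blocked, prot_test)
        I_ref = res_ref.trace.samples.mean()
        I = res_test.trace.samples.mean()
        i_ref = sim.unitary_current(params, -20, ca_ref)
        i = sim.unitary_current(blocked, -20, ca_test)
        po = gating.normalized_po(I, I_ref, i, i_ref)
        true_ratio = (res_test.true_po_per_epoch[0]
                      / res_ref.true_po_per_epoch[0])
        assert po.value == pytest.approx(true_ratio, rel=0.10)

    def test_zero_references_rejected(self):
        with pytest.raises(ValueError):
            gating.normalized_po(-50, 0, -3, -3)


class TestPip2Rescaling:
    def test_identity_and_20fold(self):
        po = gating.PoEstimate(1.0, "ca125")
        assert gating.rescale_to_pip2_reference(po, 1.0).value == 1.0
        assert gating.rescale_to_pip2_reference(po, 20.0).value == pytest.approx(0.05)

    def test_composition(self):
        po = gating.PoEstimate(0.7, "ca125")
        a_then_b = gating.rescale_to_pip2_reference(
            gating.rescale_to_pip2_reference(po, 4.0), 5.0)
        ab = gating.rescale_to_pip2_reference(po, 20.0)
        assert a_then_b.value == pytest.approx(ab.value, rel=1e-12)

    def test_low_po_fraction_arithmetic(self):
        assert gating.low_po_fraction(-2.0, 0.05, -100.0).value == pytest.approx(0.001)
        assert gating.low_po_fraction(-3.0, 2.0, -6.0).value == pytest.approx(1.0)

    def test_low_po_fraction_from_dwell_analysis(self):
        """Very-low-P_o channel: i*NPo/I_ref vs the true P_o fraction."""
        params = sim.preset("D921A", n_channels=3, noise_sd=0.2)
        prot = sim.SimProtocol(
            (Epoch(0, 60.0, adpr=100, ca_cyto_free=125.0),), seed=12)
        res = sim.simulate_patch(params, prot)
        i_unit = sim.unitary_current(params, -20, 125.0)
        rec = gating.idealize_and_npo(res.trace.samples, i_unit,
                                      sampling_rate=res.trace.sampling_rate)
        # reference: a hypothetical full-activity current of 20 channels
        I_ref = 20 * i_unit
        est = gating.low_po_fraction(i_unit, rec.n_po, I_ref)
        true = 3 * res.true_po_per_epoch[0] / 20
        assert est.value == pytest.approx(true, rel=0.25, abs=2e-4)


class TestHillFit:
    def _synth(self, k, n, seed, pmax=1.0, noise=0.05):
        rng = np.random.default_rng(seed)
        c = np.array([k / 8, k / 3, k, 2.5 * k, 8 * k, 60 * k])
        p = pmax * c ** n / (c ** n + k ** n)
        return c, p + rng.normal(0, noise * pmax, c.shape)

    @pytest.mark.parametrize("k_true,n_true", [(2.0, 1.5), (40.0, 1.5)])
    def test_parameter_recovery(self, k_true, n_true):
        """Median recovery error over replicate 5%-noise draws is within 15%
        (a single 6-point draw with free P_max and n_H is noise-limited)."""
        errors = []
        for seed in range(10):
            c, p = self._synth(k_true, n_true, seed=seed)
            fit = gating.fit_hill(c, p)
            errors.append(abs(fit.k_half - k_true) / k_true)
        assert np.median(errors) < 0.15

    def test_half_activation_on_fitted_curve(self):
        c, p = self._synth(2.0, 1.5, seed=9)
        fit = gating.fit_hill(c, p)
        assert fit(fit.k_half) == pytest.approx(fit.p_max / 2, rel=1e-12)

    def test_fix_pmax_constrains_saturation(self):
        c, p = self._synth(2.0, 1.2, seed=10)
        fit = gating.fit_hill(c, p, fix_pmax=True)
        assert fit.p_max == 1.0
        assert fit.k_half == pytest.approx(2.0, rel=0.2)

    def test_flat_data_raises(self):
        with pytest.raises(gating.FitFailure):
            gating.fit_hill([1, 2, 4], [0.5, 0.5, 0.5])


class TestDeactivation:
    def test_noise_free_exponential_exact(self):
        fs = 5000.0
        t = np.arange(0, 1.0, 1 / fs)
        tr = CurrentTrace(-8.0 * np.exp(-t / 0.1), fs)
        fit = gating.fit_deactivation(tr, t0=0.0, window=1.0)
        assert fit.tau == pytest.approx(100.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.0, abs=1e-9)

    def test_two_state_tau_is_inverse_k_close(self):
        params = sim.preset("WT", n_channels=500, noise_sd=0.05, z_gate=1e-9)
        res = sim.deactivation_protocol(params, [-20.0], ca_ext_mm=0.0,
                                        seed=21)[0]
        fit = gating.fit_deactivation(res.trace, t0=1.0, window=2.0)
        assert fit.tau == pytest.approx(1e3 / params.k_close0, rel=0.1)

    def test_feedback_plateau_flagged(self):
        params = sim.preset("WT", n_channels=300, noise_sd=0.05)
        res = sim.deactivation_protocol(params, [-80.0], ca_ext_mm=1.0,
                                        seed=5, t_decay_s=4.0)[0]
        fit = gating.fit_deactivation(res.trace, t0=1.0, window=4.0,
                                      require_closing_rate=True)
        assert fit.plateau_flagged
        assert abs(fit.offset) > 0.05 * abs(fit.amplitude)

    def test_window_too_short_rejected(self):
        tr = CurrentTrace(np.zeros(100), 100.0)
        with pytest.raises(ValueError):
            gating.fit_deactivation(tr, t0=0.0, window=0.05)


class TestIdealization:
    def test_fully_closed_npo_zero(self):
        rng = np.random.default_rng(30)
        rec = gating.idealize_and_npo(rng.normal(0, 0.2, 10000), -3.0,
                                      sampling_rate=5000.0)
        assert rec.n_po == 0.0

    def test_single_channel_po_recovery(self):
        res, _ = _one_channel_trace(po_target=0.25, duration=60.0, seed=31)
        rec = gating.idealize_and_npo(res.trace.samples, -3.0,
                                      sampling_rate=res.trace.sampling_rate)
        assert rec.n_po == pytest.approx(res.true_po_per_epoch[0], abs=0.03)
        assert rec.n_po == pytest.approx(0.25, abs=0.03)

    def test_two_channels_additive(self):
        res, _ = _one_channel_trace(po_target=0.25, duration=60.0, seed=32,
                                    n_channels=2)
        rec = gating.idealize_and_npo(res.trace.samples, -3.0,
                                      sampling_rate=res.trace.sampling_rate)
        assert rec.n_po == pytest.approx(0.5, abs=0.04)

    def test_dead_time_merges_short_events(self):
        fs = 1000.0
        samples = np.zeros(1000)
        samples[500:502] = -3.0  # 2 ms blip
        rec = gating.idealize_and_npo(samples, -3.0, sampling_rate=fs,
                                      dead_time=0.005)
        assert all(lvl == 0 or dur >= 0.005 for lvl, dur in rec.events)

    def test_event_durations_sum_to_segment(self):
        res, _ = _one_channel_trace(po_target=0.5, duration=10.0, seed=33)
        rec = gating.idealize_and_npo(res.trace.samples, -3.0,
                                      sampling_rate=res.trace.sampling_rate)
        assert rec.total_duration == pytest.approx(10.0, rel=1e-9)

    def test_zero_unitary_rejected(self):
        with pytest.raises(ValueError):
            gating.idealize_and_npo(np.zeros(100), 0.0)


def test_epoch_and_trace_validation():
    with pytest.raises(ValueError):
        Epoch(1.0, 0.5)
    with pytest.raises(ValueError):
        CurrentTrace(np.zeros(10), 1000.0,
                     (Epoch(0.0, 0.5), Epoch(0.4, 0.8)))  # overlap
    tr = CurrentTrace(np.arange(10, dtype=float), 10.0, (Epoch(0.0, 0.5),))
    assert len(tr.epoch_samples(tr.epochs[0])) == 5
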