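"""Whole-cell analyses: AP features, passive fits, firing statistics,
IPSC kinetics and GHK conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerephys import synth
from cerephys import intracellular as ic
from cerephys.core import SampledTrace, SpikeTrain, StimulusProtocol


# --------------------------------------------------------------------------
# action potentials
# --------------------------------------------------------------------------

class TestAPFeatures:
    def test_template_round_trip_grand_average(self):
        p = synth.APTemplateParams()
        trace, peaks = synth.synth_ap_trace(p, 10, 25.0, 10.0)
        g = ic.extract_ap_features(trace, peaks).grand_average
        dt_ms = 0.1
        assert abs(g.half_width - p.half_width) <= dt_ms + 1e-9
        assert abs(g.ahp_time - p.ahp_time) <= dt_ms + 1e-9
        assert abs(g.peak_voltage - p.peak_voltage) < 0.01 * abs(p.peak_voltage) + 0.1
        assert abs(g.ahp_min_voltage - p.ahp_min_voltage) < 0.1
        assert abs(g.threshold - p.threshold_voltage) < 0.01 * abs(p.threshold_voltage)
        # invariant relations between features
        assert np.isclose(g.amplitude, g.peak_voltage - g.threshold)
        assert np.isclose(g.ahp_amplitude, g.threshold - g.ahp_min_voltage)

    def test_slow_spiking_template_ahp(self):
        # ns-Golgi-like template: slower spike, later AHP
        p = synth.APTemplateParams(half_width=1.2, ahp_time=4.0, ahp_min_voltage=-51.5)
        trace, peaks = synth.synth_ap_trace(p, 6, 20.0, 10.0)
        g = ic.extract_ap_features(trace, peaks).grand_average
        assert abs(g.half_width - 1.2) <= 0.1 + 1e-9
        assert abs(g.ahp_time - 4.0) <= 0.1 + 1e-9

    def test_triangle_spike_analytic_half_width(self):
        # pure triangle: rise r, fall f; half-width = r/2 + f/2 exactly
        fs = 50_000.0
        r_ms, f_ms = 0.4, 1.0
        base, peak = -60.0, 20.0
        n_r, n_f = int(r_ms / 1000 * fs), int(f_ms / 1000 * fs)
        v = np.concatenate([np.full(400, base),
                            np.linspace(base, peak, n_r + 1),
                            np.linspace(peak, base, n_f + 1)[1:],
                            np.full(600, base)])
        pk = 400 + n_r
        feats = ic.extract_ap_features(SampledTrace(v, fs), [pk]).per_spike[0]
        assert abs(feats.half_width - (r_ms / 2 + f_ms / 2)) < 2 / fs * 1000

    def test_quantization_error_shrinks_with_sampling_rate(self):
        # half-width off the 10-kHz grid: finer sampling must not be worse
        p = synth.APTemplateParams(half_width=0.85)
        errs = {}
        for fs_khz in (10.0, 20.0):
            trace, peaks = synth.synth_ap_trace(p, 6, 25.0, fs_khz)
            g = ic.extract_ap_features(trace, peaks).grand_average
            errs[fs_khz] = abs(g.half_width - 0.85)
        assert errs[20.0] <= errs[10.0] + 1e-9
        assert errs[20.0] <= 1000.0 / 20_000.0

    def test_flat_trace_has_no_spikes(self):
        trace = SampledTrace(np.full(5000, -60.0), 10_000.0)
        with pytest.raises(ValueError, match="no spikes"):
            ic.extract_ap_features(trace, [])

    def test_spike_at_edge_rejected(self):
        trace, peaks = synth.synth_ap_trace(synth.APTemplateParams(), 3, 25.0, 10.0)
        with pytest.raises(ValueError, match="close to trace"):
            ic.extract_ap_features(trace, [5])


# --------------------------------------------------------------------------
# passive properties
# --------------------------------------------------------------------------

class TestPassive:
    def test_published_cell_round_trip(self):
        tr = synth.gen_membrane_step_response(185.5, 127.5, -20.0, 10.0)
        fit = ic.estimate_passive(tr, -20.0)
        assert abs(fit.cm_ - 127.5) / 127.5 < 0.01
        assert abs(fit.rm_ - 185.5) / 185.5 < 0.01
        assert np.isclose(fit.cm_, 1000.0 * fit.tau_ / fit.rm_)
        assert fit.ok_

    def test_zero_step_rejected(self):
        tr = synth.gen_membrane_step_response(185.5, 127.5, -20.0, 10.0)
        with pytest.raises(ValueError):
            ic.estimate_passive(tr, 0.0)

    def test_linear_regime_step_size_invariance(self):
        fits = [ic.estimate_passive(
            synth.gen_membrane_step_response(185.5, 127.5, i, 10.0), i)
            for i in (-10.0, -20.0)]
        assert np.isclose(fits[0].rm_, fits[1].rm_, rtol=1e-3)
        assert np.isclose(fits[0].cm_, fits[1].cm_, rtol=1e-3)

    def test_noisy_flag(self):
        tr = synth.gen_membrane_step_response(185.5, 127.5, -1.0, 10.0,
                                              noise_sd=2.0, seed=1)
        assert not ic.estimate_passive(tr, -1.0).ok_


# --------------------------------------------------------------------------
# I-F, accommodation, ISI prolongation, time locking
# --------------------------------------------------------------------------

def _regular_train(rate, duration=1.0):
    t = np.arange(1, int(rate * duration) + 1) / rate
    return SpikeTrain(t, duration)


class TestIFCurve:
    def test_linear_rate_law_recovered(self):
        # integer rates so sweep rate = i/cm exactly: slope 1 Hz per pA/pF
        cm = 100.0
        sweeps = [(i, _regular_train(i / cm)) for i in (100.0, 200.0, 300.0, 400.0)]
        fit = ic.compute_if_curve(sweeps, cm)
        assert fit.r2 > 0.999
        assert np.isclose(fit.poly_coeffs[0], 1.0, rtol=1e-6)

    def test_duplicated_sweeps_identical_fit(self):
        cm = 100.0
        sweeps = [(i, _regular_train(i / 10)) for i in (100.0, 200.0, 300.0)]
        f1 = ic.compute_if_curve(sweeps, cm)
        f2 = ic.compute_if_curve(sweeps, cm)
        assert np.array_equal(f1.poly_coeffs, f2.poly_coeffs)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            ic.compute_if_curve([(100.0, _regular_train(10))] * 2, 100.0)
        silent = [(i, SpikeTrain(np.array([]), 1.0)) for i in (1.0, 2.0, 3.0)]
        with pytest.raises(ValueError):
            ic.compute_if_curve(silent, 100.0)


class TestAccommodation:
    def test_constant_isi_gives_unity(self):
        res = ic.accommodation_index(_regular_train(25.0), (0.0, 1.0))
        assert np.isclose(res.steady_state_index, 1.0, atol=0.01)

    def test_linear_isi_doubling_gives_half(self):
        # constructed ISI sequence: ISIs grow linearly from d to 2d over 1 s
        isis = np.linspace(0.02, 0.04, 34)
        t = np.cumsum(isis)
        res = ic.accommodation_index(SpikeTrain(t, 1.2), (0.0, t[-1] + 0.001))
        assert abs(res.steady_state_index - 0.5) < 0.08

    def test_too_few_spikes(self):
        with pytest.raises(ValueError):
            ic.accommodation_index(SpikeTrain(np.array([0.1, 0.2]), 1.0), (0.0, 1.0))

    @given(st.floats(min_value=0.0, max_value=50.0))
    @settings(max_examples=20, deadline=None)
    def test_time_shift_invariance(self, dt):
        isis = np.linspace(0.02, 0.04, 34)
        t = np.cumsum(isis)
        a = ic.accommodation_index(SpikeTrain(t, 1.2), (0.0, 1.2))
        b = ic.accommodation_index(SpikeTrain(t + dt, 1.2 + dt), (dt, 1.2 + dt))
        assert np.isclose(a.steady_state_index, b.steady_state_index)


class TestISIProlongation:
    def test_forced_doubling_is_100_percent(self):
        t = np.arange(0.1, 2.0, 0.2)
        tr = SpikeTrain(t, 2.5)
        proto = StimulusProtocol(np.array([t[3] + 0.1]), 5.0)
        stretched = synth.prolong_isis(tr, proto, 2.0)
        res = ic.isi_prolongation(stretched, proto)
        assert np.isclose(res.normalized_increase, 1.0, atol=1e-6)
        assert np.isclose(res.control_isi, 200.0)

    def test_no_effect_is_zero(self):
        t = np.arange(0.1, 2.0, 0.2)
        proto = StimulusProtocol(np.array([t[3] + 0.1]), 5.0)
        res = ic.isi_prolongation(SpikeTrain(t, 2.5), proto)
        assert abs(res.normalized_increase) < 1e-9

    def test_stimulus_outside_all_isis(self):
        tr = SpikeTrain(np.array([0.1, 0.2]), 1.0)
        with pytest.raises(ValueError):
            ic.isi_prolongation(tr, StimulusProtocol(np.array([0.5]), 5.0))

    def test_uniform_time_shift_invariance(self):
        t = np.arange(0.1, 2.0, 0.2)
        proto = StimulusProtocol(np.array([0.75]), 5.0)
        a = ic.isi_prolongation(SpikeTrain(t, 2.5), proto)
        b = ic.isi_prolongation(SpikeTrain(t + 5.0, 7.5),
                                StimulusProtocol(np.array([5.75]), 5.0))
        assert np.isclose(a.normalized_increase, b.normalized_increase)


class TestTimeLocking:
    @staticmethod
    def _trials(rng, locked):
        fs, n = 10_000.0, 3000
        t = np.arange(n) / fs
        out = []
        common = np.sin(2 * np.pi * 30 * t)
        for _ in range(6):
            v = rng.normal(0, 1.0, n)
            if locked:
                post = t >= 0.1
                v[post] = common[post]
            out.append(SampledTrace(v, fs))
        return out

    def test_locked_trials_significant(self):
        trials = self._trials(np.random.default_rng(0), locked=True)
        res = ic.time_locking_zscore(trials, 0.1)
        assert res.significant and res.z_score > 3

    def test_null_false_positive_rate(self):
        # independent trials must stay below the 3-SD criterion in >= 95% of runs
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            trials = self._trials(np.random.default_rng(seed), locked=False)
            if ic.time_locking_zscore(trials, 0.1).significant:
                hits += 1
        assert hits / n_runs <= 0.05

    def test_mismatched_lengths_rejected(self):
        a = SampledTrace(np.zeros(100), 10_000.0)
        b = SampledTrace(np.zeros(101), 10_000.0)
        with pytest.raises(ValueError):
            ic.time_locking_zscore([a, a, b], 0.005)


# --------------------------------------------------------------------------
# IPSC kinetics & pharmacology
# --------------------------------------------------------------------------

class TestIPSCKinetics:
    def test_noiseless_identity(self):
        p = synth.IPSCParams()
        fit = ic.fit_ipsc(synth.synth_ipsc(p, 50.0))
        assert abs(fit.amplitude_ - 40.0) / 40.0 < 0.01
        assert abs(fit.rise_10_90_ - 2.5) / 2.5 < 0.01
        assert abs(fit.tau1_ - 8.2) / 8.2 < 0.01
        assert abs(fit.frac1_ - 0.523) / 0.523 < 0.01
        assert abs(fit.tau2_ - 34.8) / 34.8 < 0.01

    def test_single_exponential_degenerate(self):
        p = synth.IPSCParams(frac1=1.0, tau1=8.2, tau2=34.8)
        fit = ic.fit_ipsc(synth.synth_ipsc(p, 50.0))
        # either the fast fraction absorbs everything or the taus merge
        assert fit.frac1_ > 0.95 or abs(fit.tau2_ - fit.tau1_) / fit.tau1_ < 0.2 \
            or (1 - fit.frac1_) * fit.tau2_ < 0.05 * fit.tau1_

    def test_noisy_tau1_recovery(self):
        errs = []
        for seed in range(50):
            p = synth.IPSCParams(noise_sd=2.0)
            fit = ic.fit_ipsc(synth.synth_ipsc(p, 50.0, seed=seed))
            errs.append(abs(fit.tau1_ - 8.2) / 8.2)
        assert np.median(errs) < 0.15

    def test_recovery_bias_at_5pct_noise(self):
        t1, t2 = [], []
        for seed in range(60):
            p = synth.IPSCParams(noise_sd=2.0)  # 5% of the 40-pA amplitude
            fit = ic.fit_ipsc(synth.synth_ipsc(p, 50.0, seed=seed))
            t1.append(fit.tau1_)
            t2.append(fit.tau2_)
        assert abs(np.mean(t1) - 8.2) / 8.2 < 0.05
        assert abs(np.mean(t2) - 34.8) / 34.8 < 0.05

    def test_low_snr_flagged(self):
        p = synth.IPSCParams(amplitude=2.0, noise_sd=2.0)
        fit = ic.fit_ipsc(synth.synth_ipsc(p, 10.0, seed=3))
        assert fit.low_snr_


class TestBlock:
    def test_strychnine_worked_example(self):
        assert np.isclose(ic.block_percentage(40.0, 30.4).percent_block, 24.0)

    def test_limits(self):
        assert ic.block_percentage(40.0, 40.0).percent_block == 0.0
        assert ic.block_percentage(40.0, 0.0).percent_block == 100.0
        with pytest.raises(ValueError):
            ic.block_percentage(0.0, 10.0)


# --------------------------------------------------------------------------
# GHK
# --------------------------------------------------------------------------

class TestGHK:
    def test_symmetric_chloride_reverses_at_zero(self):
        ions = ic.IonConfig(cl_in=130.0, cl_out=130.0, p_ratio=0.0)
        assert abs(ic.ghk_reversal(ions)) < 1e-6

    def test_p_ratio_zero_reduces_to_nernst(self):
        ions = ic.IonConfig(p_ratio=0.0)
        nernst = ions.vt * np.log(ions.cl_in / ions.cl_out)
        assert np.isclose(ic.ghk_reversal(ions), nernst, atol=1e-6)

    def test_calibrated_solutions_give_minus_74(self):
        assert abs(ic.ghk_reversal(ic.IonConfig()) - (-74.0)) < 0.5

    def test_current_zero_at_reversal(self):
        ions = ic.IonConfig()
        e = ic.ghk_reversal(ions)
        assert abs(ic._total_flux(e, ions)) < 1e-6

    def test_matches_goldman_closed_form(self):
        # independent oracle: anion-only Goldman equation
        ions = ic.IonConfig()
        closed = ions.vt * np.log(
            (ions.cl_in + ions.p_ratio * ions.hco3_in)
            / (ions.cl_out + ions.p_ratio * ions.hco3_out))
        assert np.isclose(ic.ghk_reversal(ions), closed, atol=1e-6)

    def test_chord_conductance_worked_example(self):
        est = ic.conductances(40.0, -50.0)
        assert abs(est.g_chord - 40.0 / 24.0) < 0.02
        assert round(est.g_chord, 1) == 1.7

    def test_zero_amplitude_zero_conductances(self):
        est = ic.conductances(0.0, -50.0)
        assert est.g_chord == est.g_slope == est.g_sym_equiv == 0.0

    def test_symmetric_solution_limit_equalizes_conductances(self):
        # with both ions symmetric the GHK I-V is linear: chord = slope = sym
        ions = ic.IonConfig(cl_in=130.0, cl_out=130.0, hco3_in=25.0, hco3_out=25.0)
        est = ic.conductances(40.0, -50.0, ions)
        assert np.isclose(est.g_chord, est.g_slope, rtol=1e-9)
        sym_only = ions.cl_out / (ions.cl_out + ions.p_ratio * 25.0)
        assert np.isclose(est.g_sym_equiv, est.g_chord * sym_only, rtol=1e-9)

    def test_analytic_slope_matches_finite_difference(self):
        ions = ic.IonConfig()
        v = -50.0
        h = 1e-4
        fd = (ic._total_flux(v + h, ions) - ic._total_flux(v - h, ions)) / (2 * h)
        assert np.isclose(
            ic._ghk_anion_flux_dv(v, ions.cl_in, ions.cl_out, ions.vt)
            + ions.p_ratio * ic._ghk_anion_flux_dv(v, ions.hco3_in, ions.hco3_out, ions.vt),
            fd, rtol=1e-6)
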