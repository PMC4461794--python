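"""Whole-cell (in vitro) analyses.

Covers the intracellular measurement set: action-potential waveform
features (threshold from the second derivative, half-width, AHP), passive
membrane properties from current-step responses, current-to-frequency
curves normalized to capacitance, spike-frequency accommodation, ISI
prolongation by optogenetic stimulation, across-trial spike time locking,
IPSC kinetics (10–90% rise, bi-exponential decay) and pharmacological
block, and Goldman–Hodgkin–Katz conversion of IPSC amplitudes to reversal
potentials and conductances for the mixed Cl⁻/HCO₃⁻ receptor channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import brentq, curve_fit
from sklearn.base import BaseEstimator

from .core import SampledTrace, SpikeTrain, StimulusProtocol

R_GAS = 8.314462618       # J/(mol K)
FARADAY = 96485.33212     # C/mol


# --------------------------------------------------------------------------
# action-potential features
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class APFeatures:
    """Single-spike waveform features (voltages mV, times ms)."""

    threshold: float
    peak_voltage: float
    amplitude: float
    half_width: float
    ahp_min_voltage: float
    ahp_time: float
    ahp_amplitude: float


@dataclass(frozen=True)
class APAnalysis:
    per_spike: list
    grand_average: APFeatures
    mean_waveform: np.ndarray
    waveform_t_ms: np.ndarray


def _smoothed_second_derivative(v: np.ndarray, fs: float) -> np.ndarray:
    """Second derivative of the voltage: first derivative by centered
    differences, 1 kHz zero-phase low-pass, then another centered
    difference.  Zero-phase filtering keeps corner locations unbiased."""
    dv = np.gradient(v) * fs
    if fs > 2500.0:
        sos = signal.butter(2, 1000.0, btype="low", fs=fs, output="sos")
        dv = signal.sosfiltfilt(sos, dv)
    return np.gradient(dv) * fs


def _interp_crossing(t: np.ndarray, v: np.ndarray, level: float, i0: int, i1: int,
                     rising: bool) -> float:
    """Linearly interpolated time at which v crosses `level` between samples,
    searching i0..i1; for rising=True takes the last upward crossing, else
    the first downward crossing."""
    seg = v[i0:i1 + 1]
    above = seg >= level
    idx = np.flatnonzero(above[1:] != above[:-1])
    if idx.size == 0:
        raise ValueError("no level crossing in search window")
    j = idx[-1] if rising else idx[0]
    a, b = seg[j], seg[j + 1]
    frac = (level - a) / (b - a)
    return t[i0 + j] + frac * (t[i0 + j + 1] - t[i0 + j])


def _features_one_spike(v: np.ndarray, fs: float, peak: int, next_peak: int | None,
                        d2: np.ndarray) -> APFeatures:
    dt_ms = 1000.0 / fs
    w2 = int(round(0.002 * fs))  # threshold search: 2 ms before the peak
    lo = peak - w2
    if lo < 1:
        raise ValueError("spike too close to trace start for the analysis window")
    thr_idx = lo + int(np.argmax(d2[lo:peak]))
    thr_v = v[thr_idx]
    peak_v = v[peak]
    amp = peak_v - thr_v
    if amp <= 0:
        raise ValueError("non-positive spike amplitude")
    half_level = thr_v + amp / 2.0

    t_ms = np.arange(v.size) * dt_ms
    t_up = _interp_crossing(t_ms, v, half_level, thr_idx, peak, rising=True)
    # AHP window: 10 ms after the peak or until the next spike
    w_ahp = int(round(0.010 * fs))
    hi = peak + w_ahp
    if next_peak is not None:
        hi = min(hi, next_peak - 2)
    if hi >= v.size:
        raise ValueError("spike too close to trace end for the analysis window")
    t_down = _interp_crossing(t_ms, v, half_level, peak, hi, rising=False)
    ahp_idx = peak + int(np.argmin(v[peak:hi + 1]))
    ahp_v = v[ahp_idx]
    return APFeatures(
        threshold=float(thr_v),
        peak_voltage=float(peak_v),
        amplitude=float(amp),
        half_width=float(t_down - t_up),
        ahp_min_voltage=float(ahp_v),
        ahp_time=float((ahp_idx - thr_idx) * dt_ms),
        ahp_amplitude=float(thr_v - ahp_v),
    )


def extract_ap_features(trace: SampledTrace, spike_indices) -> APAnalysis:
    """Per-spike AP features plus the grand average.

    ``spike_indices`` are the sample indices of AP peaks.  The threshold is
    the voltage at the main (largest) peak of the second derivative within
    2 ms preceding the AP peak; the grand average is built by peak-aligned
    averaging of the spike waveforms and re-extracting features from the
    averaged waveform.
    """
    peaks = np.asarray(spike_indices, dtype=int)
    if peaks.size == 0:
        raise ValueError("no spikes")
    v = trace.data
    fs = trace.fs_hz
    d2 = _smoothed_second_derivative(v, fs)
    feats = []
    for i, pk in enumerate(peaks):
        nxt = int(peaks[i + 1]) if i + 1 < peaks.size else None
        feats.append(_features_one_spike(v, fs, int(pk), nxt, d2))

    # grand average by peak alignment (-3 ms .. +10 ms window)
    pre = int(round(0.003 * fs))
    post = int(round(0.010 * fs))
    segs = [v[pk - pre: pk + post + 1] for pk in peaks
            if pk - pre >= 0 and pk + post < v.size]
    mean_wave = np.mean(segs, axis=0)
    d2m = _smoothed_second_derivative(mean_wave, fs)
    grand = _features_one_spike(mean_wave, fs, pre, None, d2m)
    t_ms = (np.arange(mean_wave.size) - pre) * 1000.0 / fs
    return APAnalysis(feats, grand, mean_wave, t_ms)


# --------------------------------------------------------------------------
# passive membrane properties
# --------------------------------------------------------------------------

class PassiveMembraneFit(BaseEstimator):
    """Single-exponential fit of a small current-step voltage response.

    The step is assumed to start at t = 0 of the trace time base (samples
    with t < 0 are baseline).  Fitted attributes: ``rm_`` (MΩ), ``tau_``
    (ms), ``cm_`` (pF, = τ/Rm), ``fit_r2_``, and ``ok_`` (False when the
    exponential fit explains less than ``min_r2`` of the variance).
    """

    def __init__(self, min_r2: float = 0.9):
        self.min_r2 = min_r2

    def fit(self, trace: SampledTrace, i_step_pa: float):
        if i_step_pa == 0:
            raise ValueError("i_step must be nonzero")
        t = trace.times()
        v = trace.data
        pre = t < 0
        if not pre.any() or pre.all():
            raise ValueError("trace must contain both baseline and step samples")
        v0 = float(v[pre].mean())
        tm = t[~pre] * 1000.0  # ms from step onset
        vm = v[~pre]

        def model(x, dv, tau):
            return v0 + dv * (1.0 - np.exp(-x / tau))

        dv0 = vm[-len(vm) // 5:].mean() - v0
        p0 = [dv0 if dv0 != 0 else -1.0, max(tm[-1] / 5.0, 1e-3)]
        (dv, tau), _ = curve_fit(model, tm, vm, p0=p0, maxfev=20000,
                                 bounds=([-np.inf, 1e-6], [np.inf, np.inf]))
        resid = vm - model(tm, dv, tau)
        ss_tot = np.sum((vm - vm.mean()) ** 2)
        self.fit_r2_ = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
        self.rm_ = float(1000.0 * dv / i_step_pa)  # mV/pA → GΩ → ×1000 = MΩ
        self.tau_ = float(tau)
        self.cm_ = float(1000.0 * self.tau_ / self.rm_)  # ms/MΩ → nF → ×1000 = pF
        self.delta_v_ = float(dv)
        self.ok_ = bool(self.fit_r2_ >= self.min_r2)
        return self


def estimate_passive(trace: SampledTrace, i_step_pa: float) -> PassiveMembraneFit:
    """Rm, τ and Cm (= τ/Rm) from a small hyperpolarizing current step."""
    return PassiveMembraneFit().fit(trace, i_step_pa)


# --------------------------------------------------------------------------
# firing-rate analyses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IFCurveFit:
    points: np.ndarray      # (n, 2): current-per-capacitance pA/pF, rate Hz
    poly_coeffs: np.ndarray
    r2: float


def compute_if_curve(sweeps, cm_pf: float, degree: int = 1) -> IFCurveFit:
    """Current-to-frequency curve with current normalized to capacitance.

    ``sweeps`` is a list of (i_step_pA, SpikeTrain); the rate of each sweep
    is plotted against i_step/Cm and fitted with a single polynomial.
    """
    if len(sweeps) < 3:
        raise ValueError("need at least 3 sweeps")
    x = np.array([i / cm_pf for i, _ in sweeps])
    y = np.array([tr.rate() for _, tr in sweeps])
    if np.all(y == 0):
        raise ValueError("all sweeps have zero firing rate")
    coeffs = np.polyfit(x, y, degree)
    fitted = np.polyval(coeffs, x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(1.0 - np.sum((y - fitted) ** 2) / ss_tot) if ss_tot > 0 else 1.0
    return IFCurveFit(np.column_stack([x, y]), coeffs, r2)


@dataclass(frozen=True)
class AccommodationProfile:
    instantaneous_rates: np.ndarray  # Hz, one per ISI during the step
    steady_state_index: float        # late frequency / initial frequency


def accommodation_index(train: SpikeTrain, step_window: tuple,
                        late_s: float = 0.2) -> AccommodationProfile:
    """Spike-frequency accommodation over a depolarizing step.

    Initial frequency is the mean instantaneous rate of the first two ISIs;
    the steady state is the mean rate of ISIs ending within the last
    ``late_s`` seconds of the step.
    """
    lo, hi = step_window
    t = train.times[(train.times >= lo) & (train.times <= hi)]
    if t.size < 3:
        raise ValueError("need at least 3 spikes within the step window")
    isis = np.diff(t)
    rates = 1.0 / isis
    init = rates[:2].mean()
    late = rates[t[1:] >= hi - late_s]
    if late.size == 0:
        late = rates[-1:]
    return AccommodationProfile(rates, float(late.mean() / init))


@dataclass(frozen=True)
class ISIProlongation:
    control_isi: float       # ms
    stimulated_isi: float    # ms
    normalized_increase: float


def isi_prolongation(train: SpikeTrain, protocol: StimulusProtocol) -> ISIProlongation:
    """Prolongation of inter-spike intervals that contain a light pulse.

    The control ISI is the mean of ISIs with no stimulus; the stimulated
    ISI is the mean of ISIs during which at least one light onset fell.
    """
    t = train.times
    if t.size < 2:
        raise ValueError("need at least 2 spikes")
    isis = np.diff(t)
    onsets = protocol.onsets_s
    idx = np.searchsorted(t, onsets, side="right") - 1
    stim_mask = np.zeros(isis.size, dtype=bool)
    valid = (idx >= 0) & (idx < isis.size)
    stim_mask[np.unique(idx[valid])] = True
    if not stim_mask.any():
        raise ValueError("no stimulus fell inside an inter-spike interval")
    control = isis[~stim_mask].mean() * 1000.0
    stim = isis[stim_mask].mean() * 1000.0
    return ISIProlongation(float(control), float(stim),
                           float((stim - control) / control))


@dataclass(frozen=True)
class TimeLockResult:
    variability_timecourse: np.ndarray  # across-trial Vm SD / baseline mean SD
    z_score: float
    significant: bool


def time_locking_zscore(trials, stim_onset: float, post_s: float = 0.1,
                        smooth_ms: float = 5.0) -> TimeLockResult:
    """Across-trial membrane-voltage variability after a stimulus.

    The across-trial SD timecourse is smoothed (moving average,
    ``smooth_ms``), normalized to its pre-stimulus mean, and the
    post-stimulus decrease is expressed as a z-score against the baseline
    variability of the smoothed SD.  Significant when z ≥ 3.
    """
    if len(trials) < 3:
        raise ValueError("need at least 3 trials")
    lengths = {tr.n_samples for tr in trials}
    if len(lengths) != 1:
        raise ValueError("trials must share one time base")
    fs = trials[0].fs_hz
    vm = np.stack([tr.data for tr in trials])
    sd = vm.std(axis=0, ddof=1)
    w = max(1, int(round(smooth_ms / 1000.0 * fs)))
    sd_s = np.convolve(sd, np.ones(w) / w, mode="same")
    t = trials[0].times()
    base = t < stim_onset
    post = (t >= stim_onset) & (t < stim_onset + post_s)
    mu, sig = sd_s[base].mean(), sd_s[base].std(ddof=1)
    if sig == 0:
        raise ValueError("zero baseline variability")
    z_t = (mu - sd_s) / sig  # positive = variability decrease
    z = float(z_t[post].max())
    return TimeLockResult(sd_s / mu, z, bool(z >= 3.0))


# --------------------------------------------------------------------------
# IPSC kinetics & pharmacology
# --------------------------------------------------------------------------

class IPSCKineticsFit(BaseEstimator):
    """Kinetics of an averaged IPSC.

    Assumes the trace time base has t < 0 as baseline and the synaptic
    event starting at t ≥ 0.  Fitted attributes: ``amplitude_`` (pA,
    baseline to peak), ``rise_10_90_`` (ms, linear interpolation between
    the 10% and 90% crossings), ``tau1_``/``tau2_`` (ms, sorted fast/slow),
    ``frac1_`` (fast fraction), ``fit_r2_`` of the decay fit, and
    ``low_snr_`` (True when the amplitude is below ``snr_mult`` baseline
    SDs).
    """

    def __init__(self, snr_mult: float = 3.0):
        self.snr_mult = snr_mult

    def fit(self, trace: SampledTrace, y=None):
        t = trace.times()
        x = trace.data
        base = t < 0
        if not base.any():
            raise ValueError("trace must include a pre-event baseline window")
        baseline = float(x[base].mean())
        noise = float(x[base].std(ddof=1)) if base.sum() > 1 else 0.0
        y_ev = x - baseline
        ev = ~base
        pk_rel = int(np.argmax(np.abs(y_ev[ev])))
        pk = np.flatnonzero(ev)[0] + pk_rel
        sign = np.sign(y_ev[pk]) or 1.0
        y_pos = sign * y_ev  # peak-positive
        amp = float(y_pos[pk])
        self.amplitude_ = amp
        self.baseline_ = baseline
        # SNR check on a 0.5-ms-smoothed copy: the raw extremum of pure
        # noise already sits ~3 SD above baseline, a smoothed one does not
        w = max(1, int(round(0.0005 * trace.fs_hz)))
        y_smooth = np.convolve(y_pos, np.ones(w) / w, mode="same")
        self.low_snr_ = bool(noise > 0
                             and y_smooth[~base].max() < self.snr_mult * noise)

        t_ms = t * 1000.0
        on = np.flatnonzero(ev)[0]
        t10 = _interp_crossing(t_ms, y_pos, 0.1 * amp, on, pk, rising=True)
        t90 = _interp_crossing(t_ms, y_pos, 0.9 * amp, on, pk, rising=True)
        self.rise_10_90_ = float(t90 - t10)

        td = t_ms[pk:] - t_ms[pk]
        yd = y_pos[pk:]

        def biexp(tt, a, f, tau1, tau2):
            return a * (f * np.exp(-tt / tau1) + (1 - f) * np.exp(-tt / tau2))

        # initialize from the 1/e crossing of the decay
        below = np.flatnonzero(yd < amp / np.e)
        tau_e = td[below[0]] if below.size else td[-1] / 3.0
        p0 = [amp, 0.5, max(tau_e / 2.0, 1e-3), max(tau_e * 2.0, 2e-3)]
        bounds = ([0.0, 0.0, 1e-4, 1e-4], [np.inf, 1.0, np.inf, np.inf])
        try:
            popt, _ = curve_fit(biexp, td, yd, p0=p0, bounds=bounds, maxfev=40000)
        except RuntimeError as exc:
            raise RuntimeError(f"bi-exponential decay fit did not converge: {exc}") from exc
        a, f, tau1, tau2 = popt
        if tau1 > tau2:
            tau1, tau2, f = tau2, tau1, 1.0 - f
        self.tau1_, self.tau2_, self.frac1_ = float(tau1), float(tau2), float(f)
        fitted = biexp(td, *popt)
        ss_tot = np.sum((yd - yd.mean()) ** 2)
        self.fit_r2_ = float(1.0 - np.sum((yd - fitted) ** 2) / ss_tot) if ss_tot else 1.0
        self.sign_ = float(sign)
        return self


def fit_ipsc(trace: SampledTrace) -> IPSCKineticsFit:
    """Amplitude, 10–90% rise and bi-exponential decay of an averaged IPSC."""
    return IPSCKineticsFit().fit(trace)


@dataclass(frozen=True)
class BlockResult:
    control_amplitude: float
    drug_amplitude: float
    percent_block: float


def block_percentage(control_amplitude: float, drug_amplitude: float) -> BlockResult:
    """Percent reduction of the IPSC amplitude by a receptor antagonist."""
    if control_amplitude == 0:
        raise ValueError("control amplitude must be nonzero")
    pct = 100.0 * (1.0 - drug_amplitude / control_amplitude)
    return BlockResult(float(control_amplitude), float(drug_amplitude), float(pct))


# --------------------------------------------------------------------------
# Goldman–Hodgkin–Katz conversions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IonConfig:
    """Cl⁻/HCO₃⁻ concentrations (mM) on each side, relative permeability and
    temperature.

    Defaults are calibrated so that p_ratio = 0.2 reproduces the −74 mV
    IPSC reversal potential of the recording solutions; the exact solution
    composition is configurable because published tables underdetermine it.
    """

    cl_in: float = 5.2
    cl_out: float = 133.5
    hco3_in: float = 16.0
    hco3_out: float = 24.8
    p_ratio: float = 0.2    # P_HCO3 / P_Cl
    temp_c: float = 33.0

    @property
    def vt(self) -> float:
        """Thermal voltage RT/F in mV."""
        return R_GAS * (self.temp_c + 273.15) / FARADAY * 1000.0


def _ghk_anion_flux(v_mv: float, c_in: float, c_out: float, vt: float) -> float:
    """GHK current factor for a monovalent anion, outward-positive, per unit
    permeability (arbitrary common scale)."""
    u = v_mv / vt
    if abs(u) < 1e-9:
        return -(c_in - c_out) * vt  # limit V→0 of V(c_in − c_out e^u)/(1 − e^u)
    e = np.exp(u)
    return v_mv * (c_in - c_out * e) / (1.0 - e)


def _ghk_anion_flux_dv(v_mv: float, c_in: float, c_out: float, vt: float) -> float:
    """Analytic dI/dV of the factor above."""
    u = v_mv / vt
    if abs(u) < 1e-6:
        return (c_in + c_out) / 2.0  # Taylor limit at V = 0
    e = np.exp(u)
    n = c_in - c_out * e
    d = 1.0 - e
    dn = -c_out * e / vt
    dd = -e / vt
    return n / d + v_mv * (dn * d - n * dd) / d**2


def _total_flux(v_mv: float, ions: IonConfig) -> float:
    return (_ghk_anion_flux(v_mv, ions.cl_in, ions.cl_out, ions.vt)
            + ions.p_ratio * _ghk_anion_flux(v_mv, ions.hco3_in, ions.hco3_out, ions.vt))


def ghk_reversal(ions: IonConfig) -> float:
    """Reversal potential (mV) of the summed Cl⁻ + HCO₃⁻ GHK current,
    found as a numeric root in the physiological range."""
    for c in (ions.cl_in, ions.cl_out):
        if c <= 0:
            raise ValueError("chloride concentrations must be positive")
    lo, hi = -150.0, 50.0
    f_lo, f_hi = _total_flux(lo, ions), _total_flux(hi, ions)
    if f_lo * f_hi > 0:
        raise ValueError("no GHK reversal in the physiological range")
    return float(brentq(lambda v: _total_flux(v, ions), lo, hi, xtol=1e-9))


@dataclass(frozen=True)
class ConductanceEstimate:
    e_rev: float        # mV
    g_chord: float      # nS
    g_slope: float      # nS
    g_sym_equiv: float  # nS
    ions: IonConfig = field(default_factory=IonConfig)


def conductances(amplitude_pa: float, v_hold_mv: float,
                 ions: IonConfig | None = None) -> ConductanceEstimate:
    """Chord, slope and symmetric-chloride-equivalent conductances of a
    measured IPSC amplitude under the GHK current model.

    * chord: amplitude / (Vhold − Erev);
    * slope: analytic dI/dV of the GHK I–V at Vhold, with the permeability
      scaled so the model current at Vhold equals the measured amplitude;
    * symmetric equivalent: chord conductance the same permeability would
      yield with chloride symmetric at the external concentration
      (bicarbonate omitted, as in symmetric-chloride recordings).
    """
    ions = ions or IonConfig()
    e_rev = ghk_reversal(ions)
    if v_hold_mv == e_rev:
        raise ValueError("zero driving force at the holding potential")
    if amplitude_pa == 0:
        return ConductanceEstimate(e_rev, 0.0, 0.0, 0.0, ions)
    g_chord = abs(amplitude_pa / (v_hold_mv - e_rev))  # pA/mV = nS

    flux = _total_flux(v_hold_mv, ions)
    perm = amplitude_pa / flux  # permeability scale matching the measurement
    dflux = (_ghk_anion_flux_dv(v_hold_mv, ions.cl_in, ions.cl_out, ions.vt)
             + ions.p_ratio * _ghk_anion_flux_dv(v_hold_mv, ions.hco3_in,
                                                 ions.hco3_out, ions.vt))
    g_slope = abs(perm * dflux)

    sym_flux = _ghk_anion_flux(v_hold_mv, ions.cl_out, ions.cl_out, ions.vt)
    g_sym = abs(perm * sym_flux / v_hold_mv)  # Erev = 0 in symmetric chloride
    return ConductanceEstimate(float(e_rev), float(g_chord), float(g_slope),
                               float(g_sym), ions)
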