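"""Synthetic-data generators.

Every analysis stage in this package can be exercised without any recorded
data: this module generates soma-size samples, spontaneous and
stimulus-modulated spike trains, action-potential and IPSC waveforms,
passive membrane step responses, and two-channel immunofluorescence
intensity tables, each with the statistical structure of the corresponding
recordings.  Generators are phenomenological templates, not biophysical
simulations; a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import SampledTrace, SpikeTrain, StimulusProtocol

__all__ = [
    "MixtureSpec",
    "RateProfile",
    "APTemplateParams",
    "IPSCParams",
    "PopulationSpec",
    "IntensityPopSpec",
    "sample_soma_sizes",
    "gen_poisson_train",
    "gen_gamma_train",
    "synth_ap_trace",
    "synth_ipsc",
    "gen_membrane_step_response",
    "gen_intensity_table",
    "make_stim_protocol",
    "prolong_isis",
    "synth_extracellular_trace",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian mixture of soma sizes: list of (weight, mean µm, sd µm)."""

    components: tuple

    def __post_init__(self) -> None:
        comps = tuple((float(w), float(m), float(s)) for w, m, s in self.components)
        object.__setattr__(self, "components", comps)
        w = np.array([c[0] for c in comps])
        s = np.array([c[2] for c in comps])
        if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be positive and sum to 1")
        if np.any(s < 0):
            raise ValueError("sds must be non-negative")


@dataclass(frozen=True)
class RateProfile:
    """Firing-rate profile with a stimulus-locked inhibition window.

    Times are ms after light onset; rates in Hz.  Default values follow the
    in-vivo responsive-Golgi-cell statistics (baseline 10.9 Hz suppressed to
    1.58 Hz, onset 14.5 ms, duration 23.4 ms).
    """

    baseline_rate: float = 10.9
    inhibition_onset: float = 14.5
    inhibition_duration: float = 23.4
    inhibited_rate: float = 1.58

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.inhibited_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.inhibition_duration < 0:
            raise ValueError("inhibition duration must be non-negative")


@dataclass(frozen=True)
class APTemplateParams:
    """Action-potential template, parameterized by the extracted feature set.

    Defaults are the spontaneously-spiking Golgi cell population means
    (half-width 0.8 ms, AHP minimum -51.9 mV at 2.1 ms after threshold).
    """

    threshold_voltage: float = -38.9
    peak_voltage: float = 22.4
    half_width: float = 0.8
    ahp_min_voltage: float = -51.9
    ahp_time: float = 2.1
    resting_voltage: float = -60.0

    def __post_init__(self) -> None:
        if not (self.peak_voltage > self.threshold_voltage > self.ahp_min_voltage):
            raise ValueError("require peak > threshold > AHP minimum")
        if self.threshold_voltage <= self.resting_voltage + 1.0:
            raise ValueError("threshold must lie clearly above resting voltage")
        if self.half_width <= 0 or self.ahp_time <= 0:
            raise ValueError("half_width and ahp_time must be positive")


@dataclass(frozen=True)
class IPSCParams:
    """Averaged IPSC waveform parameters (population means as defaults)."""

    amplitude: float = 40.0       # pA, baseline-to-peak
    rise_10_90: float = 2.5       # ms
    tau1: float = 8.2             # ms, fast decay
    frac1: float = 0.523          # fraction of amplitude decaying with tau1
    tau2: float = 34.8            # ms, slow decay
    noise_sd: float = 0.0         # pA
    baseline: float = 0.0         # pA

    def __post_init__(self) -> None:
        if not (self.tau2 > self.tau1 > 0):
            raise ValueError("require tau2 > tau1 > 0")
        if not (0.0 <= self.frac1 <= 1.0):
            raise ValueError("frac1 must be in [0, 1]")
        if self.rise_10_90 <= 0:
            raise ValueError("rise time must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """One intensity population: bivariate-Gaussian (egfp, neurogranin) plus
    a zero-inflated apposition-count law (contact probability, mean count
    among contacted cells)."""

    egfp_mean: float
    egfp_sd: float
    ngn_mean: float
    ngn_sd: float
    p_contact: float
    mean_appositions: float  # mean among contacted cells, >= 1

    def __post_init__(self) -> None:
        if self.egfp_sd <= 0 or self.ngn_sd <= 0:
            raise ValueError("SDs must be positive")
        if not (0.0 <= self.p_contact <= 1.0):
            raise ValueError("p_contact must be a probability")
        if self.p_contact > 0 and self.mean_appositions < 1:
            raise ValueError("mean appositions among contacted cells must be >= 1")


@dataclass(frozen=True)
class IntensityPopSpec:
    """Two-population immunofluorescence table specification.

    Defaults emulate the 317-cell Golgi data set: 25% low-eGFP "GABAergic"
    cells (higher neurogranin, heavily contacted: 41% of cells, 7.65
    appositions each on average) vs 75% high-eGFP glycinergic cells (rarely
    contacted: ~3%, 1.88 appositions).  Population eGFP means are separated
    by ~5 within-population SDs.
    """

    n_cells: int = 317
    frac_low_egfp: float = 0.25
    low: PopulationSpec = field(default_factory=lambda: PopulationSpec(
        egfp_mean=0.25, egfp_sd=0.12, ngn_mean=1.5, ngn_sd=0.30,
        p_contact=32 / 79, mean_appositions=7.65))
    high: PopulationSpec = field(default_factory=lambda: PopulationSpec(
        egfp_mean=1.0, egfp_sd=0.15, ngn_mean=1.0, ngn_sd=0.30,
        p_contact=8 / 238, mean_appositions=1.88))

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_low_egfp <= 1.0):
            raise ValueError("frac_low_egfp must be in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")


# --------------------------------------------------------------------------
# samplers
# --------------------------------------------------------------------------

def sample_soma_sizes(spec: MixtureSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` soma sizes (µm) from a Gaussian mixture, truncated at 0."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    w = np.array([c[0] for c in spec.components])
    means = np.array([c[1] for c in spec.components])
    sds = np.array([c[2] for c in spec.components])
    comp = rng.choice(len(w), size=n, p=w)
    out = rng.normal(means[comp], sds[comp])
    # sizes are physical lengths: redraw the (negligible) negative mass
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
        bad = out <= 0
    return out


def gen_gamma_train(mean_isi: float, cv: float, duration: float, seed: int,
                    unit_id: str = "unit0") -> SpikeTrain:
    """Gamma-renewal spike train.

    Parameters
    ----------
    mean_isi : float
        Mean inter-spike interval in ms.
    cv : float
        Coefficient of variation of the ISI distribution (shape = 1/cv²).
    duration : float
        Recording duration in seconds.
    """
    if mean_isi <= 0:
        raise ValueError("mean_isi must be positive")
    if cv <= 0:
        raise ValueError("cv must be positive")
    rng = np.random.default_rng(seed)
    shape = 1.0 / cv**2
    scale_s = (mean_isi / 1000.0) * cv**2
    expected = duration / (mean_isi / 1000.0)
    times: list[np.ndarray] = []
    t = 0.0
    while t < duration:
        chunk = rng.gamma(shape, scale_s, size=max(64, int(1.5 * expected)))
        cum = t + np.cumsum(chunk)
        times.append(cum)
        t = cum[-1]
    all_t = np.concatenate(times)
    return SpikeTrain(all_t[all_t < duration], duration, unit_id)


def _inhibition_windows(profile: RateProfile, protocol: StimulusProtocol | None):
    if protocol is None or profile.inhibition_duration <= 0:
        return np.empty((0, 2))
    start = protocol.onsets_s + profile.inhibition_onset / 1000.0
    return np.column_stack([start, start + profile.inhibition_duration / 1000.0])


def gen_poisson_train(profile: RateProfile, protocol: StimulusProtocol | None,
                      duration: float, seed: int,
                      unit_id: str = "unit0") -> SpikeTrain:
    """Inhomogeneous-Poisson train with stimulus-locked inhibition windows.

    The rate is ``baseline_rate`` everywhere except within
    [onset, onset + duration] ms after each light pulse, where it is
    ``inhibited_rate``.  Implemented by thinning a homogeneous process at
    the maximum rate.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    rmax = max(profile.baseline_rate, profile.inhibited_rate)
    if rmax == 0:
        return SpikeTrain(np.empty(0), duration, unit_id)
    n = rng.poisson(rmax * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    windows = _inhibition_windows(profile, protocol)
    rate = np.full(t.size, profile.baseline_rate)
    for lo, hi in windows:
        rate[(t >= lo) & (t < hi)] = profile.inhibited_rate
    keep = rng.uniform(0.0, rmax, size=n) < rate
    t = np.unique(t[keep])
    return SpikeTrain(t, duration, unit_id)


# --------------------------------------------------------------------------
# action-potential trace
# --------------------------------------------------------------------------

def _solve_ap_decay(p: APTemplateParams, upstroke_ms: float):
    """Solve the repolarization exponential V = v_inf + (peak-v_inf)e^{-t/tau}
    so that it crosses half-amplitude at the requested half-width and reaches
    the AHP minimum at the requested AHP time (both measured from threshold).
    """
    amp = p.peak_voltage - p.threshold_voltage
    half_level = p.threshold_voltage + amp / 2.0
    h = p.half_width - upstroke_ms / 2.0          # ms from peak to half crossing
    d = p.ahp_time - upstroke_ms                  # ms from peak to AHP minimum
    if h <= 0 or d <= h:
        raise ValueError("half_width/ahp_time incompatible with upstroke duration")

    def resid(v_inf):
        a = (half_level - v_inf) / (p.peak_voltage - v_inf)
        b = (p.ahp_min_voltage - v_inf) / (p.peak_voltage - v_inf)
        return b - a ** (d / h)

    lo = p.ahp_min_voltage - 1e-9
    hi = p.ahp_min_voltage - 1e5
    if resid(lo) * resid(hi) > 0:
        raise ValueError("no repolarization solution for these AP parameters")
    v_inf = brentq(resid, hi, lo, xtol=1e-10)
    tau = h / np.log((p.peak_voltage - v_inf) / (half_level - v_inf))
    return v_inf, tau


def synth_ap_trace(params: APTemplateParams, n_spikes: int, rate: float,
                   fs_khz: float, seed: int = 0):
    """Voltage trace of a regularly firing cell built from an analytic AP
    template; returns ``(SampledTrace, peak_indices)``.

    The template is piecewise: a linear pre-threshold ramp, a linear
    upstroke (duration half the half-width), an exponential repolarization
    solved so that half-width and AHP time are met exactly, and a linear
    inter-spike recovery back to threshold.  Parameters that are integer
    multiples of the sample period are reproduced exactly by the matching
    feature extractor; otherwise within one sample period.
    """
    if fs_khz < 10:
        raise ValueError("sampling rate must be >= 10 kHz")
    del seed  # deterministic template; signature kept uniform with other generators
    fs = fs_khz * 1000.0
    dt_ms = 1000.0 / fs
    p = params
    upstroke = p.half_width / 2.0
    lead_s = 0.05

    if n_spikes == 0:
        n = int(round(2 * lead_s * fs))
        return SampledTrace(np.full(n, p.resting_voltage), fs, "mV"), np.empty(0, int)

    if rate <= 0:
        raise ValueError("rate must be positive")
    interval_ms = 1000.0 / rate
    # snap the upstroke to the sample grid so the AP peak falls exactly on
    # a sample; the decay solve absorbs the difference, keeping half-width
    # and AHP time exact
    upstroke = max(dt_ms, np.round(upstroke / dt_ms) * dt_ms)
    v_inf, tau = _solve_ap_decay(p, upstroke)
    if interval_ms <= p.ahp_time + 2 * dt_ms:
        raise ValueError("firing rate too high for this AP template")

    total_s = lead_s + n_spikes * interval_ms / 1000.0 + lead_s
    n = int(round(total_s * fs))
    t_ms = np.arange(n) * dt_ms
    v = np.full(n, p.resting_voltage)

    # threshold times snapped to the sample grid
    thr_ms = np.round((lead_s * 1000.0 + np.arange(n_spikes) * interval_ms) / dt_ms) * dt_ms
    ramp_ms = 2.0

    # initial ramp from rest to first threshold
    m = (t_ms >= thr_ms[0] - ramp_ms) & (t_ms < thr_ms[0])
    v[m] = p.resting_voltage + (p.threshold_voltage - p.resting_voltage) * (
        (t_ms[m] - (thr_ms[0] - ramp_ms)) / ramp_ms)

    peak_idx = np.empty(n_spikes, dtype=int)
    for k, t0 in enumerate(thr_ms):
        tp = t0 + upstroke
        ta = t0 + p.ahp_time
        m = (t_ms >= t0) & (t_ms < tp)
        v[m] = p.threshold_voltage + (p.peak_voltage - p.threshold_voltage) * (t_ms[m] - t0) / upstroke
        m = (t_ms >= tp) & (t_ms <= ta)
        v[m] = v_inf + (p.peak_voltage - v_inf) * np.exp(-(t_ms[m] - tp) / tau)
        peak_idx[k] = int(round(tp / dt_ms))
        # recovery ramp toward the next threshold (or toward rest after the last)
        if k + 1 < n_spikes:
            t_next, target = thr_ms[k + 1], p.threshold_voltage
        else:
            t_next, target = ta + 20.0, p.resting_voltage
        m = (t_ms > ta) & (t_ms < t_next)
        v[m] = p.ahp_min_voltage + (target - p.ahp_min_voltage) * (t_ms[m] - ta) / (t_next - ta)
    return SampledTrace(v, fs, "mV"), peak_idx


# --------------------------------------------------------------------------
# synaptic current / passive membrane traces
# --------------------------------------------------------------------------

def synth_ipsc(params: IPSCParams, fs_khz: float, seed: int = 0,
               pre_s: float = 0.05, post_s: float = 0.25) -> SampledTrace:
    """Averaged IPSC: baseline, a rise of exactly the requested 10–90% time,
    then an exactly bi-exponential decay from the peak, plus Gaussian noise.

    The rise is a sin² ramp scaled so its 10%→90% crossing time equals
    ``rise_10_90``; joining an analytic ramp to a clean bi-exponential keeps
    the decay segment uncontaminated, so noiseless round trips through the
    kinetics fitter are exact.
    """
    if fs_khz < 10:
        raise ValueError("sampling rate must be >= 10 kHz")
    p = params
    fs = fs_khz * 1000.0
    dt_ms = 1000.0 / fs
    n = int(round((pre_s + post_s) * fs))
    t_ms = np.arange(n) * dt_ms - pre_s * 1000.0
    i = np.full(n, p.baseline)
    if p.amplitude != 0:
        x10, x90 = np.arcsin(np.sqrt(0.1)), np.arcsin(np.sqrt(0.9))
        t_rise = p.rise_10_90 / ((x90 - x10) / (np.pi / 2.0))
        rising = (t_ms >= 0) & (t_ms < t_rise)
        i[rising] += p.amplitude * np.sin(np.pi * t_ms[rising] / (2 * t_rise)) ** 2
        decaying = t_ms >= t_rise
        td = t_ms[decaying] - t_rise
        i[decaying] += p.amplitude * (
            p.frac1 * np.exp(-td / p.tau1) + (1 - p.frac1) * np.exp(-td / p.tau2))
    if p.noise_sd > 0:
        i += np.random.default_rng(seed).normal(0.0, p.noise_sd, size=n)
    return SampledTrace(i, fs, "pA", t0_s=-pre_s)


def gen_membrane_step_response(rm: float, cm: float, i_step: float, fs_khz: float,
                               noise_sd: float = 0.0, seed: int = 0,
                               v0: float = -60.0, pre_s: float = 0.05,
                               step_s: float = 0.3) -> SampledTrace:
    """Voltage response to a current step: single-exponential charging with
    τ = R·C toward ΔV = I·R.

    rm in MΩ, cm in pF, i_step in pA (negative = hyperpolarizing); the step
    starts at t = 0 (``pre_s`` seconds of baseline precede it).
    """
    if rm <= 0 or cm <= 0:
        raise ValueError("rm and cm must be positive")
    fs = fs_khz * 1000.0
    tau_ms = rm * cm / 1000.0
    dv_mv = i_step * rm / 1e6 * 1e3  # pA·MΩ = µV; → mV
    n = int(round((pre_s + step_s) * fs))
    t_ms = np.arange(n) * 1000.0 / fs - pre_s * 1000.0
    v = np.full(n, v0)
    on = t_ms >= 0
    v[on] += dv_mv * (1.0 - np.exp(-t_ms[on] / tau_ms))
    if noise_sd > 0:
        v += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return SampledTrace(v, fs, "mV", t0_s=-pre_s)


# --------------------------------------------------------------------------
# intensity table / protocol / helpers
# --------------------------------------------------------------------------

def _sample_population(rng, pop: PopulationSpec, n: int, label: str) -> pd.DataFrame:
    egfp = rng.normal(pop.egfp_mean, pop.egfp_sd, n).clip(min=0.0)
    ngn = rng.normal(pop.ngn_mean, pop.ngn_sd, n).clip(min=0.0)
    contacted = rng.uniform(size=n) < pop.p_contact
    counts = np.zeros(n, dtype=int)
    if contacted.any():
        counts[contacted] = 1 + rng.poisson(max(pop.mean_appositions - 1.0, 0.0),
                                            contacted.sum())
    return pd.DataFrame({"egfp": egfp, "neurogranin": ngn,
                         "appositions": counts, "true_pop": label})


def gen_intensity_table(spec: IntensityPopSpec, seed: int) -> pd.DataFrame:
    """Per-cell intensity table: columns cell_id, egfp, neurogranin,
    appositions, true_pop ('low_egfp' | 'high_egfp')."""
    rng = np.random.default_rng(seed)
    n_low = int(round(spec.frac_low_egfp * spec.n_cells))
    parts = [_sample_population(rng, spec.low, n_low, "low_egfp"),
             _sample_population(rng, spec.high, spec.n_cells - n_low, "high_egfp")]
    df = pd.concat(parts, ignore_index=True)
    df = df.sample(frac=1.0, random_state=np.random.RandomState(seed)).reset_index(drop=True)
    df.insert(0, "cell_id", np.arange(len(df)))
    return df


def make_stim_protocol(pulse_ms: float = 25.0, rate: float = 4.0, bout_s: float = 3.0,
                       recovery_s: float = 7.0, total_s: float = 100.0) -> StimulusProtocol:
    """Light-pulse protocol: pulses at ``rate`` Hz within ``bout_s``-long
    bouts separated by ``recovery_s`` recovery periods, up to ``total_s``."""
    if min(pulse_ms, rate, bout_s, recovery_s, total_s) <= 0:
        raise ValueError("all protocol parameters must be positive")
    if rate * pulse_ms > 1000.0:
        raise ValueError("pulses overlap at this rate/duration")
    period = bout_s + recovery_s
    onsets = []
    bout_start = 0.0
    while bout_start < total_s:
        t = bout_start
        while t < min(bout_start + bout_s, total_s):
            if t + pulse_ms / 1000.0 <= total_s:
                onsets.append(t)
            t += 1.0 / rate
        bout_start += period
    return StimulusProtocol(np.array(onsets), pulse_ms)


def prolong_isis(train: SpikeTrain, protocol: StimulusProtocol, factor: float) -> SpikeTrain:
    """Stretch every inter-spike interval that contains a light onset by
    ``factor``, shifting all later spikes accordingly (used to emulate the
    ISI-prolongation effect with a known ground truth)."""
    if factor < 1.0:
        raise ValueError("factor must be >= 1")
    t = train.times.copy()
    shift = 0.0
    out = t.copy()
    for i in range(t.size - 1):
        out[i] = t[i] + shift
        isi = t[i + 1] - t[i]
        hits = np.any((protocol.onsets_s >= t[i]) & (protocol.onsets_s < t[i + 1]))
        if hits:
            shift += (factor - 1.0) * isi
    if t.size:
        out[-1] = t[-1] + shift
    dur = max(train.duration + shift, out[-1] + 1e-9 if out.size else 0.0)
    return SpikeTrain(out, dur, train.unit_id)


def synth_extracellular_trace(train: SpikeTrain, fs_khz: float, amplitude: float,
                              noise_sd: float, seed: int) -> SampledTrace:
    """Extracellular-like trace: a biphasic template (derivative of a
    Gaussian, ~1 ms wide) at each spike time plus white Gaussian noise."""
    fs = fs_khz * 1000.0
    n = int(round(train.duration * fs))
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, n)
    half = int(round(0.0015 * fs))
    tt = (np.arange(-half, half + 1)) / fs
    sig = 0.2e-3
    tmpl = -tt / sig * np.exp(0.5 - tt**2 / (2 * sig**2))
    tmpl *= amplitude / np.max(np.abs(tmpl))
    idx = np.round(train.times * fs).astype(int)
    for i in idx:
        lo, hi = i - half, i + half + 1
        if lo >= 0 and hi <= n:
            x[lo:hi] += tmpl
    return SampledTrace(x, fs, "uV")
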