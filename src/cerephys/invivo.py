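"""Extracellular (in vivo) analyses.

Spike extraction from high-pass-filtered traces, ISI-statistic unit
classification (MSF / LCV / ENT boundaries for cerebellar Golgi cells),
and peri-stimulus-time-histogram Z-score detection of optogenetic
responders: a unit counts as modulated when the absolute Z-score of a 3-ms
bin exceeds 2.5 in at least two bins of the 50-ms window after light
onset; onset latency is the first significant time point, peak latency the
maximal |Z|, and the summed significant time defines the inhibition
duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .core import SampledTrace, SpikeTrain, StimulusProtocol


@dataclass(frozen=True)
class UnitStats:
    msf: float   # Hz
    lcv: float
    ent: float   # bits
    n_spikes: int


@dataclass(frozen=True)
class ClassBoundaries:
    """Golgi-cell identification bounds on (MSF, ENT, LCV); all strict."""

    msf_max: float = 20.0
    ent_range: tuple = (0.5, 7.5)
    lcv_range: tuple = (0.02, 0.25)
    purkinje_msf_min: float = 40.0


@dataclass(frozen=True)
class PSTH:
    bin_edges: np.ndarray     # ms relative to light onset
    counts: np.ndarray        # pooled spike counts per bin
    n_trials: int
    baseline_window: tuple    # (ms, ms)

    @property
    def bin_ms(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class ResponseProfile:
    zscores: np.ndarray
    responsive: bool
    onset_latency: float      # ms from light onset
    peak_latency: float       # ms
    duration: float           # ms of significant time
    baseline_rate: float      # Hz
    inhibited_rate: float     # Hz over the significant bins


def filter_and_detect(trace: SampledTrace, threshold_sd: float = 5.0,
                      hp_hz: float = 1000.0, order: int = 4,
                      refractory_ms: float = 1.0) -> SpikeTrain:
    """High-pass filter (zero-phase Butterworth) and threshold spikes.

    The threshold is ``threshold_sd`` multiples of the noise SD (median
    absolute deviation estimate) applied to the absolute filtered signal;
    each crossing is assigned the time of the local extremum and a
    refractory lockout suppresses double counts.
    """
    if trace.fs_hz < 10000:
        raise ValueError("sampling rate must be >= 10 kHz")
    if threshold_sd < 2.0:
        raise ValueError("threshold below the noise floor")
    sos = signal.butter(order, hp_hz, btype="high", fs=trace.fs_hz, output="sos")
    x = signal.sosfiltfilt(sos, trace.data)
    noise = np.median(np.abs(x)) / 0.6745
    duration = trace.n_samples / trace.fs_hz
    if noise == 0:
        return SpikeTrain(np.empty(0), duration)
    thr = threshold_sd * noise
    above = np.abs(x) > thr
    if not above.any():
        return SpikeTrain(np.empty(0), duration)
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    lock = int(round(refractory_ms / 1000.0 * trace.fs_hz))
    times = []
    last = -np.inf
    for e in edges:
        if e - last < lock:
            continue
        seg_end = min(e + lock, trace.n_samples)
        pk = e + int(np.argmax(np.abs(x[e:seg_end])))
        times.append(pk / trace.fs_hz)
        last = pk
    t = np.unique(times)
    return SpikeTrain(t, max(duration, t[-1] + 1e-9), trace.units)


def unit_stats(train: SpikeTrain, min_isis: int = 50,
               ent_bins: int = 50, ent_range_ms: tuple = (1.0, 1e4)) -> UnitStats:
    """MSF, LCV and ISI entropy of an extracellular unit.

    MSF = spike count / duration; LCV = SD(ln ISI)/|mean(ln ISI)| with ISIs
    in ms; ENT = Shannon entropy (bits) of the ISI histogram over
    ``ent_bins`` log-spaced bins spanning ``ent_range_ms``.  The log-bin
    layout is a calibration constant: canonical Golgi-like gamma trains
    fall inside the classification bounds under it.
    """
    isis_ms = train.isis() * 1000.0
    if isis_ms.size < min_isis:
        raise ValueError(f"need at least {min_isis} ISIs")
    msf = train.n_spikes / train.duration
    log_isi = np.log(isis_ms)
    lcv = float(log_isi.std(ddof=1) / abs(log_isi.mean()))
    edges = np.logspace(np.log10(ent_range_ms[0]), np.log10(ent_range_ms[1]),
                        ent_bins + 1)
    counts, _ = np.histogram(np.clip(isis_ms, *ent_range_ms), bins=edges)
    p = counts / counts.sum()
    p = p[p > 0]
    ent = float(-(p * np.log2(p)).sum())
    return UnitStats(float(msf), lcv, ent, train.n_spikes)


def classify_unit(stats: UnitStats, b: ClassBoundaries = ClassBoundaries()) -> str:
    """'golgi' iff MSF < 20 Hz, 0.5 < ENT < 7.5 and 0.02 < LCV < 0.25 (all
    strict); 'purkinje' for fast-firing units (MSF ≥ 40 Hz, heuristic);
    otherwise 'other'."""
    if (stats.msf < b.msf_max
            and b.ent_range[0] < stats.ent < b.ent_range[1]
            and b.lcv_range[0] < stats.lcv < b.lcv_range[1]):
        return "golgi"
    if stats.msf >= b.purkinje_msf_min:
        return "purkinje"
    return "other"


def build_psth(train: SpikeTrain, protocol: StimulusProtocol, bin_ms: float = 3.0,
               window_ms: tuple = (-200.0, 100.0),
               baseline_ms: tuple = (-200.0, 0.0)) -> PSTH:
    """Spike counts per peri-stimulus bin, pooled over all light pulses."""
    if protocol.n_pulses == 0:
        raise ValueError("empty stimulus protocol")
    lo, hi = window_ms
    # bin edges anchored at light onset so latencies quantize cleanly
    n_lo = int(np.floor(-lo / bin_ms))
    n_hi = int(np.floor(hi / bin_ms))
    edges = np.arange(-n_lo, n_hi + 1) * bin_ms
    counts = np.zeros(edges.size - 1)
    lo = edges[0]
    for onset in protocol.onsets_s:
        rel = (train.times - onset) * 1000.0
        sel = rel[(rel >= lo) & (rel < edges[-1])]
        c, _ = np.histogram(sel, bins=edges)
        counts += c
    return PSTH(edges, counts, protocol.n_pulses, baseline_ms)


def detect_response(psth: PSTH, z_crit: float = 2.5, min_bins: int = 2,
                    response_ms: float = 50.0) -> ResponseProfile:
    """Z-score responder detection on a peri-stimulus histogram.

    Each bin count is normalized by the baseline bins' mean and SD; the
    unit is responsive when at least ``min_bins`` bins within
    ``response_ms`` after light onset have |Z| > ``z_crit``.  Latencies are
    measured from light onset: the onset latency is the start of the first
    significant bin and the peak latency the center of the maximal-|Z|
    bin.  The inhibited (modulated) rate is the pooled rate over the
    significant bins.
    """
    centers = psth.centers
    lo_b, hi_b = psth.baseline_window
    base = (centers >= lo_b) & (centers < hi_b)
    if base.sum() < 2:
        raise ValueError("baseline window too small")
    mu = psth.counts[base].mean()
    sd = psth.counts[base].std(ddof=1)
    if sd == 0:
        raise ValueError("zero baseline SD; PSTH baseline is flat")
    z = (psth.counts - mu) / sd
    # a bin counts as inside the response window only when fully contained
    resp = (psth.bin_edges[:-1] >= 0) & (psth.bin_edges[1:] <= response_ms)
    sig = resp & (np.abs(z) > z_crit)
    responsive = bool(sig.sum() >= min_bins)
    baseline_rate = mu / (psth.bin_ms / 1000.0) / psth.n_trials
    if responsive:
        # characterize the dominant modulation: keep significant bins whose
        # sign matches the net significant Z (an inhibition profile is not
        # contaminated by an isolated spuriously-high bin, and vice versa)
        dominant = np.sign(z[sig].sum())
        sig = sig & (np.sign(z) == dominant)
        starts = psth.bin_edges[:-1][sig]
        onset = float(starts.min())
        peak = float(centers[resp][np.argmax(np.abs(z[resp]))])
        duration = float(psth.bin_ms * sig.sum())
        inhibited = float(psth.counts[sig].sum()
                          / (sig.sum() * psth.bin_ms / 1000.0) / psth.n_trials)
    else:
        onset = peak = duration = np.nan
        inhibited = baseline_rate
    return ResponseProfile(z, responsive, onset, peak, duration,
                           float(baseline_rate), inhibited)


def smooth_psth(psth: PSTH, sigma_ms: float = 3.0) -> np.ndarray:
    """Gaussian-smoothed, rate-normalized PSTH curve (for 1-ms bins).

    The counts are convolved with a Gaussian kernel of SD ``sigma_ms`` and
    divided by the mean firing rate, so a flat histogram maps to 1.0.
    """
    if sigma_ms <= 0:
        raise ValueError("sigma must be positive")
    if psth.bin_ms > 1.0 + 1e-9:
        raise ValueError("smoothing expects 1-ms bins")
    # reflection padding conserves the total count exactly for the
    # symmetric kernel, so integrating the smoothed curve equals
    # integrating the raw histogram
    sm = gaussian_filter1d(psth.counts.astype(float), sigma_ms / psth.bin_ms,
                           mode="reflect")
    mean_count = psth.counts.mean()
    if mean_count == 0:
        return np.zeros_like(sm)
    return sm / mean_count
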