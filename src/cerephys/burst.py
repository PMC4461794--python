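"""Optogenetically evoked burst firing of nucleo-cortical neurons.

A burst is the maximal run of spikes following a light pulse whose
consecutive ISIs stay below a cutoff; its metrics are the spike count, the
duration (first to last spike) and the intra-burst frequency
(n−1)/duration.  Stimulus–response curves across light intensities or
durations are summarized per level and fitted with a saturating
(Hill-type) function to estimate the plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import SpikeTrain, StimulusProtocol


@dataclass(frozen=True)
class BurstMetrics:
    n_spikes: int
    duration: float               # ms, 0 for single-spike "bursts"
    mean_intraburst_freq: float   # Hz; NaN when n_spikes < 2
    stimulus: float               # the stimulus level (mW/mm² or ms)
    t_start: float                # s, first spike time


def detect_bursts(train: SpikeTrain, stim: StimulusProtocol, max_isi: float = 10.0,
                  start_within_ms: float = 20.0,
                  stimulus_level: float = np.nan) -> list:
    """Partition post-stimulus spikes into bursts.

    A burst starts with the first spike within ``start_within_ms`` of a
    light onset and extends while consecutive ISIs are ≤ ``max_isi`` ms.
    """
    if max_isi <= 0:
        raise ValueError("max_isi must be positive")
    t = train.times
    out = []
    used = np.zeros(t.size, dtype=bool)
    for onset in stim.onsets_s:
        cand = np.flatnonzero((t >= onset) & (t <= onset + start_within_ms / 1000.0)
                              & ~used)
        if cand.size == 0:
            continue
        i0 = i = cand[0]
        while i + 1 < t.size and (t[i + 1] - t[i]) * 1000.0 <= max_isi:
            i += 1
        used[i0:i + 1] = True
        n = i - i0 + 1
        dur_ms = (t[i] - t[i0]) * 1000.0
        freq = (n - 1) / (dur_ms / 1000.0) if n >= 2 and dur_ms > 0 else np.nan
        out.append(BurstMetrics(n, float(dur_ms), float(freq),
                                float(stimulus_level), float(t[i0])))
    return out


def _hill(x, plateau, half, n):
    return plateau * x**n / (x**n + half**n)


@dataclass(frozen=True)
class StimulusResponseCurve:
    levels: np.ndarray
    means: np.ndarray
    plateau: float
    half_level: float
    hill_coeff: float
    converged: bool


def stimulus_response_curve(bursts, metric: str = "mean_intraburst_freq") -> StimulusResponseCurve:
    """Per-stimulus-level means of a burst metric plus a saturating fit.

    ``bursts`` is a flat list of :class:`BurstMetrics` carrying their
    stimulus level; at least three distinct levels are required.  The fit is
    a 3-parameter Hill function; ``converged`` is False when the optimizer
    fails (constant data yields a zero-slope plateau fit).
    """
    vals = np.array([getattr(b, metric) for b in bursts], dtype=float)
    lv = np.array([b.stimulus for b in bursts], dtype=float)
    ok = ~np.isnan(vals)
    vals, lv = vals[ok], lv[ok]
    levels = np.unique(lv)
    if levels.size < 3:
        raise ValueError("need at least 3 stimulus levels")
    means = np.array([vals[lv == L].mean() for L in levels])
    if np.allclose(means, means[0]):
        return StimulusResponseCurve(levels, means, float(means[0]), 0.0, 1.0, True)
    p0 = [means.max(), np.median(levels), 1.5]
    try:
        popt, _ = curve_fit(_hill, levels, means, p0=p0,
                            bounds=([0, 1e-9, 0.1], [np.inf, np.inf, 10.0]),
                            maxfev=20000)
        return StimulusResponseCurve(levels, means, float(popt[0]), float(popt[1]),
                                     float(popt[2]), True)
    except RuntimeError:
        return StimulusResponseCurve(levels, means, float(means.max()), np.nan,
                                     np.nan, False)
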