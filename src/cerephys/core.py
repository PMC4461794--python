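"""Core in-memory containers shared by every analysis stage.

Time conventions: spike times and stimulus onsets are stored in seconds;
peri-stimulus quantities (latencies, bin widths, ISIs) are reported in
milliseconds at the analysis surface.  Sampled traces carry their sampling
rate in Hz and a unit string ("mV" or "pA").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one unit.

    Parameters
    ----------
    times : array of float
        Spike times in seconds, strictly increasing, within [0, duration].
    duration : float
        Recording duration in seconds.
    unit_id : str
        Free-form unit label.
    """

    times: np.ndarray
    duration: float
    unit_id: str = "unit0"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isis(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.times)

    def rate(self) -> float:
        """Mean firing rate in Hz over the full duration."""
        return self.n_spikes / self.duration

    def shifted(self, dt: float) -> "SpikeTrain":
        """Uniform time shift by ``dt`` seconds (duration stretched to fit)."""
        t = self.times + dt
        dur = max(self.duration + dt, t[-1] if t.size else 0.0) or self.duration
        return SpikeTrain(t, dur, self.unit_id)


@dataclass(frozen=True)
class SampledTrace:
    """Uniformly sampled voltage or current trace."""

    data: np.ndarray
    fs_hz: float
    units: str = "mV"
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.data.size)

    @property
    def dt(self) -> float:
        """Sample period in seconds."""
        return 1.0 / self.fs_hz

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz


@dataclass(frozen=True)
class StimulusProtocol:
    """Light-pulse onsets and durations.

    ``onsets_s`` are pulse-start times in seconds; ``pulse_ms`` is either a
    scalar (all pulses equal) or one duration per pulse, in milliseconds.
    """

    onsets_s: np.ndarray
    pulse_ms: np.ndarray | float = 25.0

    def __post_init__(self) -> None:
        on = np.asarray(self.onsets_s, dtype=float)
        object.__setattr__(self, "onsets_s", on)
        dur = np.broadcast_to(np.asarray(self.pulse_ms, dtype=float), on.shape).copy()
        object.__setattr__(self, "pulse_ms", dur)
        if on.size and np.any(np.diff(on) <= 0):
            raise ValueError("stimulus onsets must be strictly increasing")
        if np.any(dur <= 0):
            raise ValueError("pulse durations must be positive")
        # overlap check: next onset must not start before this pulse ends
        if on.size > 1 and np.any(on[1:] < on[:-1] + dur[:-1] / 1000.0):
            raise ValueError("overlapping light pulses")

    @property
    def n_pulses(self) -> int:
        return int(self.onsets_s.size)
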