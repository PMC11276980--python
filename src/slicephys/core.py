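"""Core data containers for slice electrophysiology.

All times are seconds relative to sweep/recording start, voltages are mV,
currents are pA.  Every container validates its invariants on construction
and refuses (rather than repairs) inconsistent data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_UNITS = ("mV", "pA", "a.u.")


class ValidationError(ValueError):
    """A container invariant was violated."""


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples : array-like
        Signal values (mV for voltage, pA for current, a.u. for
        uncalibrated field potentials).
    rate : float
        Sampling rate in Hz (> 0).
    t0 : float
        Time of the first sample in seconds (default 0).
    label : str
        Channel name.
    units : str
        One of ``mV``, ``pA``, ``a.u.``.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    label: str = ""
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("TimeSeries needs a 1-D signal of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("corrupt signal: non-finite samples")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise ValidationError("sampling rate must be a positive finite number")
        if self.units not in VALID_UNITS:
            raise ValidationError(f"units must be one of {VALID_UNITS}")
        self.rate = float(self.rate)
        self.t0 = float(self.t0)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording span in seconds (n / rate)."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.rate


@dataclass
class StepProtocol:
    """Rectangular current-step protocol.

    The laboratory convention emulated here is 1.5 s steps delivered every
    3.5 s with amplitudes spanning hyperpolarizing to strongly depolarizing
    currents on a 10-20 pA grid.
    """

    step_onset: float
    step_duration: float = 1.5
    amplitudes: np.ndarray = field(default_factory=lambda: np.arange(-100.0, 601.0, 20.0))
    inter_sweep_interval: float = 3.5

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.step_onset < 0:
            raise ValidationError("step_onset must be >= 0")
        if self.step_duration <= 0:
            raise ValidationError("step_duration must be > 0")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValidationError("step amplitudes must be finite")


@dataclass
class SweepFamily:
    """One voltage sweep per injected current amplitude."""

    protocol: StepProtocol
    sweeps: list[TimeSeries]

    def __post_init__(self) -> None:
        if len(self.sweeps) != self.protocol.amplitudes.size:
            raise ValidationError("need exactly one sweep per protocol amplitude")
        rates = {s.rate for s in self.sweeps}
        lengths = {s.n for s in self.sweeps}
        if len(rates) > 1 or len(lengths) > 1:
            raise ValidationError("all sweeps must share rate and length")

    @property
    def rate(self) -> float:
        return self.sweeps[0].rate

    def sweep_for(self, amplitude: float) -> TimeSeries:
        idx = int(np.argmin(np.abs(self.protocol.amplitudes - amplitude)))
        if abs(self.protocol.amplitudes[idx] - amplitude) > 1e-9:
            raise KeyError(f"no sweep at {amplitude} pA")
        return self.sweeps[idx]


@dataclass
class EventTrain:
    """Ordered onset times of unitary epileptiform events (uEEs).

    ``lockout`` records the refractory window used at detection time; when
    present, consecutive onsets must be separated by at least that much.
    """

    times: np.ndarray
    duration: float
    lockout: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValidationError("event times must be 1-D")
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.times.size:
            d = np.diff(self.times)
            if np.any(d <= 0):
                raise ValidationError("event times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValidationError("event times must lie in [0, duration]")
            if self.lockout is not None and d.size and d.min() < self.lockout - 1e-12:
                raise ValidationError("consecutive events closer than detection lockout")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def intervals(self) -> np.ndarray:
        """Inter-event intervals (IEIs) in seconds."""
        return np.diff(self.times)


@dataclass
class IctalDischarge:
    """A contiguous cluster of uEEs forming a seizure-like (ictal) event."""

    start: float
    end: float
    member_times: np.ndarray

    def __post_init__(self) -> None:
        self.member_times = np.asarray(self.member_times, dtype=float)
        if not self.end > self.start:
            raise ValidationError("ictal discharge must have end > start")
        if self.member_times.size < 2:
            raise ValidationError("ictal discharge needs >= 2 member events")
        if np.any(np.diff(self.member_times) <= 0):
            raise ValidationError("member times must be strictly increasing")
        if self.member_times[0] < self.start - 1e-9 or self.member_times[-1] > self.end + 1e-9:
            raise ValidationError("member times must lie within [start, end]")

    @property
    def n_uees(self) -> int:
        return self.member_times.size

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class StimMarkers:
    """Extracellular stimulation onset times with the stimulated pathway."""

    times: np.ndarray
    pathway: str = "other"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValidationError("need at least one stimulus time")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("stimulus times must be strictly increasing")
        if self.pathway not in ("schaffer", "temporoammonic", "other"):
            raise ValidationError("pathway must be schaffer, temporoammonic or other")
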