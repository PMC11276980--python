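"""Current-clamp measurements: passive properties, AP waveform, firing pattern.

Measurement definitions follow standard slice-physiology conventions:

* resting potential = pre-step voltage at zero injected current;
* input resistance = OLS slope of the steady-state I-V relation over
  spike-free sweeps (steady state = mean over the last 20% of the step);
* membrane tau = single-exponential fit to the onset of the largest
  hyperpolarizing response;
* spike onset = upward crossing of dV/dt through 5 mV/ms followed by a
  true AP (peak within 5 ms at least 20 mV above the onset voltage);
* AP amplitude, rise time (10-90%), half-width, fAHP (decay slowed below
  5 mV/ms), mAHP (post-peak minimum), time-to-mAHP (fAHP to mAHP) and ADP
  (peak between fAHP and mAHP relative to the fAHP voltage) are all
  measured relative to the detected threshold;
* rheobase = smallest step amplitude evoking at least one AP; adaptation
  ratios (second/first and last/first ISI) are taken at the next step
  above rheobase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .core import SweepFamily, TimeSeries, ValidationError


@dataclass
class PassiveProperties:
    rmp: float  # mV
    r_in: float  # MOhm
    tau_m: float  # ms

    def __post_init__(self) -> None:
        if self.r_in <= 0 or self.tau_m <= 0:
            raise ValidationError("r_in and tau_m must be > 0")


@dataclass
class APFeatures:
    """Per-spike waveform features (voltages mV, durations ms).

    AHP-related fields are ``None`` when the analysis window ends before a
    medium-AHP candidate (reported missing, never guessed).
    """

    threshold_v: float
    threshold_t: float  # s
    amplitude: float
    rise_10_90: float
    half_width: float
    fahp: float | None
    mahp: float | None
    time_to_mahp: float | None
    adp: float | None


@dataclass
class SpikeTrain:
    times: np.ndarray  # onset times, s
    current: float  # injected amplitude, pA

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size


@dataclass
class FiringPattern:
    rheobase: float  # pA
    time_of_first_spike: float  # ms from step onset
    fi_currents: np.ndarray
    fi_rates: np.ndarray  # Hz (count / step duration)
    max_rate: float
    current_at_max: float
    block_current: float | None
    max_fi_slope: float  # Hz/pA
    early_adaptation: float | None
    late_adaptation: float | None
    hump_amplitude: float | None = None


def _dvdt(v: np.ndarray, rate: float, smooth_hz: float | None) -> np.ndarray:
    """Centred-difference derivative in mV/ms, optionally on a lowpassed trace."""
    if smooth_hz is not None and smooth_hz < rate / 2:
        sos = sps.butter(4, smooth_hz, btype="low", fs=rate, output="sos")
        v = sps.sosfiltfilt(sos, v)
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) * rate / 2000.0
    d[0], d[-1] = d[1], d[-2]
    return d


def detect_spikes(
    sweep: TimeSeries,
    dvdt_threshold: float = 5.0,
    smooth_hz: float | None = None,
    current: float = np.nan,
) -> SpikeTrain:
    """Spike onsets from the dV/dt criterion.

    An onset is the first sample of an upward dV/dt crossing of
    ``dvdt_threshold`` (mV/ms) that is followed within 5 ms by a peak at
    least 20 mV above the onset voltage; onsets are separated by >= 1 ms.
    ``smooth_hz`` lowpasses the trace before differentiation (recommended
    ~2 kHz for noisy recordings; off by default).
    """
    v = sweep.samples
    d = _dvdt(v, sweep.rate, smooth_hz)
    crossings = np.flatnonzero((d[:-1] < dvdt_threshold) & (d[1:] >= dvdt_threshold)) + 1
    win = max(int(0.005 * sweep.rate), 1)
    sep = 0.001 * sweep.rate
    onsets: list[int] = []
    last = -np.inf
    for i in crossings:
        if i - last < sep:
            continue
        seg = v[i : i + win + 1]
        if seg.size and seg.max() >= v[i] + 20.0:
            onsets.append(i)
            last = i
    times = sweep.t0 + np.asarray(onsets, dtype=float) / sweep.rate
    return SpikeTrain(times=times, current=current)


def _interp_crossing(t: np.ndarray, v: np.ndarray, level: float, rising: bool) -> float | None:
    """First linear-interpolated crossing of ``level``."""
    if rising:
        idx = np.flatnonzero((v[:-1] < level) & (v[1:] >= level))
    else:
        idx = np.flatnonzero((v[:-1] >= level) & (v[1:] < level))
    if idx.size == 0:
        return None
    i = idx[0]
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return t[i] + frac * (t[i + 1] - t[i])


def ap_features(
    sweep: TimeSeries,
    onset: float,
    next_onset: float | None = None,
    dvdt_threshold: float = 5.0,
    smooth_hz: float | None = None,
    window: float = 0.150,
) -> APFeatures:
    """Measure one AP in the window [onset, next_onset or onset + 150 ms]."""
    rate = sweep.rate
    i_on = int(round((onset - sweep.t0) * rate))
    t_end = onset + window if next_onset is None else min(next_onset, onset + window)
    i_end = min(int(round((t_end - sweep.t0) * rate)), sweep.n)
    if i_end - i_on < 3:
        raise ValidationError("incomplete AHP window")
    v = sweep.samples[i_on:i_end]
    t = (np.arange(i_on, i_end) / rate + sweep.t0 - onset) * 1e3  # ms from onset

    threshold_v = float(v[0])
    i_peak_lim = min(int(0.005 * rate) + 1, v.size)
    i_peak = int(np.argmax(v[:i_peak_lim]))
    peak_v = float(v[i_peak])
    amplitude = peak_v - threshold_v
    if amplitude <= 0:
        raise ValidationError("no AP peak above threshold in window")
    if v.size - i_peak < max(3, int(0.0005 * rate)):
        raise ValidationError("incomplete AHP window")

    rise_seg_t, rise_seg_v = t[: i_peak + 1], v[: i_peak + 1]
    t10 = _interp_crossing(rise_seg_t, rise_seg_v, threshold_v + 0.1 * amplitude, True)
    t90 = _interp_crossing(rise_seg_t, rise_seg_v, threshold_v + 0.9 * amplitude, True)
    rise_10_90 = (t90 - t10) if (t10 is not None and t90 is not None) else np.nan

    half = threshold_v + amplitude / 2
    t_up = _interp_crossing(rise_seg_t, rise_seg_v, half, True)
    t_down = _interp_crossing(t[i_peak:], v[i_peak:], half, False)
    half_width = (t_down - t_up) if (t_up is not None and t_down is not None) else np.nan

    d = _dvdt(v, rate, smooth_hz)
    post = np.flatnonzero(np.abs(d[i_peak + 2 :]) < dvdt_threshold)
    if post.size == 0:
        return APFeatures(threshold_v, onset, amplitude, rise_10_90, half_width,
                          None, None, None, None)
    i_fahp = i_peak + 2 + int(post[0])
    # sub-sample refinement: interpolate the |dV/dt| crossing of the criterion
    if i_fahp > i_peak + 2 and abs(d[i_fahp - 1]) > abs(d[i_fahp]):
        frac = (abs(d[i_fahp - 1]) - dvdt_threshold) / (abs(d[i_fahp - 1]) - abs(d[i_fahp]))
        v_fahp = v[i_fahp - 1] + frac * (v[i_fahp] - v[i_fahp - 1])
    else:
        v_fahp = v[i_fahp]
    fahp = float(v_fahp) - threshold_v

    i_min = i_fahp + int(np.argmin(v[i_fahp:]))
    if i_min >= v.size - 1:
        # still falling at the window edge: no mAHP candidate
        return APFeatures(threshold_v, onset, amplitude, rise_10_90, half_width,
                          fahp, None, None, None)
    mahp = float(v[i_min]) - threshold_v
    time_to_mahp = float(t[i_min] - t[i_fahp])
    adp = float(v[i_fahp : i_min + 1].max() - v_fahp) if i_min > i_fahp else 0.0
    return APFeatures(threshold_v, onset, amplitude, rise_10_90, half_width,
                      fahp, mahp, time_to_mahp, adp)


def estimate_passive(
    family: SweepFamily,
    smooth_hz: float | None = None,
) -> PassiveProperties:
    """Passive membrane properties from a current-step family."""
    p = family.protocol
    rate = family.rate
    t_on, t_off = p.step_onset, p.step_onset + p.step_duration
    i_on, i_off = int(t_on * rate), int(t_off * rate)
    i_ss = i_off - max(int(0.2 * p.step_duration * rate), 1)  # last 20% of step

    spikefree, amps = [], []
    for amp, sw in zip(p.amplitudes, family.sweeps):
        if detect_spikes(sw, smooth_hz=smooth_hz).n == 0:
            spikefree.append(sw)
            amps.append(amp)
    amps = np.asarray(amps)
    if len(spikefree) < 3 or not np.any(amps < 0):
        raise ValidationError("insufficient subthreshold data")

    baselines = np.array([sw.samples[:i_on].mean() for sw in spikefree])
    zero = np.flatnonzero(amps == 0)
    rmp = float(baselines[zero[0]]) if zero.size else float(baselines.mean())

    deflections = np.array(
        [sw.samples[i_ss:i_off].mean() - b for sw, b in zip(spikefree, baselines)]
    )
    fit = linregress(amps, deflections)
    r_in = float(fit.slope * 1e3)  # mV/pA -> MOhm

    i_hyp = int(np.argmin(amps))
    sw = spikefree[i_hyp]
    v = sw.samples
    v_inf0 = v[i_ss:i_off].mean()
    v0 = baselines[i_hyp]
    t = np.arange(i_on, i_off) / rate - t_on
    y = v[i_on:i_off] - v_inf0
    sign = 1.0 if v0 > v_inf0 else -1.0
    yy = sign * y
    valid = np.flatnonzero(yy > 0.05 * max(sign * (v0 - v_inf0), 1e-9))
    if valid.size < 5:
        raise ValidationError("tau fit failed")
    k = valid[valid < valid[0] + max(valid.size // 2, 5)]
    slope = linregress(t[k], np.log(yy[k])).slope
    tau0 = -1.0 / slope if slope < 0 else 0.02
    i_fit = min(int((5 * tau0) * rate) + 1, i_off - i_on)
    try:
        popt, _ = curve_fit(
            lambda tt, vi, vz, tau: vi + (vz - vi) * np.exp(-tt / tau),
            t[:i_fit], v[i_on : i_on + i_fit],
            p0=(v_inf0, v0, tau0), maxfev=200,
        )
    except RuntimeError as exc:
        raise ValidationError("tau fit failed") from exc
    tau_m = float(popt[2] * 1e3)
    if tau_m <= 0:
        raise ValidationError("tau fit failed")
    return PassiveProperties(rmp=rmp, r_in=r_in, tau_m=tau_m)


def firing_pattern(
    family: SweepFamily,
    smooth_hz: float | None = None,
    block_rate_fraction: float = 0.5,
    block_voltage_margin: float = 5.0,
) -> FiringPattern:
    """Firing-pattern metrics across a current-step family.

    Depolarizing block is operationalized as the smallest amplitude above
    the maximal-rate current whose rate falls below
    ``block_rate_fraction`` of the maximum while the membrane holds a
    depolarized plateau (mean voltage over the last third of the step
    within ``block_voltage_margin`` mV of spike threshold).
    """
    p = family.protocol
    rate_hz = family.rate
    t_on, t_off = p.step_onset, p.step_onset + p.step_duration
    trains = [
        detect_spikes(sw, smooth_hz=smooth_hz, current=amp)
        for amp, sw in zip(p.amplitudes, family.sweeps)
    ]
    step_times = [tr.times[(tr.times >= t_on) & (tr.times < t_off)] for tr in trains]
    counts = np.array([st.size for st in step_times])
    rates = counts / p.step_duration
    spiking = np.flatnonzero(counts > 0)
    if spiking.size == 0:
        raise ValidationError("no rheobase (no sweep evoked a spike)")
    i_rheo = int(spiking[0])
    rheobase = float(p.amplitudes[i_rheo])
    time_of_first = float((step_times[i_rheo][0] - t_on) * 1e3)

    max_rate = float(rates.max())
    i_max = int(np.argmax(rates))  # argmax returns the first (smallest) amplitude
    current_at_max = float(p.amplitudes[i_max])

    thr_v = float(
        family.sweeps[i_rheo].samples[
            int(round((step_times[i_rheo][0] - family.sweeps[i_rheo].t0) * rate_hz))
        ]
    )
    block_current = None
    i_third = int(t_off * rate_hz) - max(int(p.step_duration / 3 * rate_hz), 1)
    for j in range(i_max + 1, p.amplitudes.size):
        plateau = family.sweeps[j].samples[i_third : int(t_off * rate_hz)].mean()
        if rates[j] < block_rate_fraction * max_rate and plateau > thr_v - block_voltage_margin:
            block_current = float(p.amplitudes[j])
            break

    rising = slice(0, i_max + 1)
    di = np.diff(p.amplitudes[rising])
    dr = np.diff(rates[rising])
    max_fi_slope = float((dr / di).max()) if di.size else 0.0

    early = late = None
    above = np.flatnonzero(p.amplitudes > rheobase)
    if above.size:
        st = step_times[int(above[0])]
        if st.size >= 3:
            # ISIs in integer sample counts: equal spacing gives ratios of
            # exactly 1, free of float round-off in the time axis
            isis = np.diff(np.rint(st * rate_hz))
            early = float(isis[1] / isis[0]) if isis.size >= 2 else None
            late = float(isis[-1] / isis[0])

    hump = None
    sub = np.flatnonzero((p.amplitudes > 0) & (counts == 0) & (p.amplitudes < rheobase))
    if sub.size:
        sw = family.sweeps[int(sub[-1])].samples
        i_on_s = int(t_on * rate_hz)
        i_100 = i_on_s + int(0.1 * rate_hz)
        i_ss = int(t_off * rate_hz) - max(int(0.2 * p.step_duration * rate_hz), 1)
        hump = float(sw[i_on_s:i_100].max() - sw[i_ss : int(t_off * rate_hz)].mean())

    return FiringPattern(
        rheobase=rheobase,
        time_of_first_spike=time_of_first,
        fi_currents=p.amplitudes.copy(),
        fi_rates=rates,
        max_rate=max_rate,
        current_at_max=current_at_max,
        block_current=block_current,
        max_fi_slope=max_fi_slope,
        early_adaptation=early,
        late_adaptation=late,
        hump_amplitude=hump,
    )
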