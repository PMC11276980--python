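"""Seedable generators with planted ground truth.

Three generators emulate the three recording modalities the analysis
modules consume:

* :func:`simulate_lfp` — 4-AP-like slice field potentials: interictal
  transients from a gamma renewal process, ictal clusters of closely
  spaced events, Gaussian (white or pink+white) background noise.
  Amplitudes are expressed relative to the noise SD because slice LFPs
  carry no absolute calibration.
* :func:`simulate_current_steps` — current-clamp sweep families from an
  RC membrane with an adaptive integrate-and-fire spiking rule and a
  stereotyped, closed-form action-potential template.
* :func:`simulate_epsc_trains` — evoked EPSC pairs/trains built from
  instantaneous-rise exponential-decay responses with configurable
  per-pulse gains.

Every generator returns the planted ground truth alongside the signal and
is bit-reproducible for a fixed config (the seed lives in the config).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    EventTrain,
    IctalDischarge,
    StepProtocol,
    StimMarkers,
    SweepFamily,
    TimeSeries,
    ValidationError,
)

# ---------------------------------------------------------------------------
# LFP generator
# ---------------------------------------------------------------------------


@dataclass
class LfpSimConfig:
    """Synthetic 4-AP-like LFP recording.

    ``interictal_amplitude`` is the sharp-lobe peak in units of ``noise_sd``
    (default 8, i.e. SNR 8).  Interictal onsets follow a gamma renewal
    process (``renewal_shape`` controls interval regularity) with mean
    interval ``1/interictal_rate`` and a 0.1 s floor.  Ictal clusters are
    runs of ``cluster_n_events`` events spaced ``intra_cluster_interval``
    apart with +/-20% uniform jitter, placed without overlap.
    """

    duration: float = 3600.0
    rate: float = 10_000.0
    interictal_rate: float = 1.5
    interictal_amplitude: float = 8.0
    interictal_width: float = 0.010
    ictal_cluster_count: int = 3
    intra_cluster_interval: float = 0.3
    cluster_n_events: int = 30
    cluster_jitter: float = 0.2
    renewal_shape: float = 8.0
    noise_sd: float = 1.0
    noise_spectrum: str = "white"
    polarity: str = "positive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.rate < 1000:
            raise ValidationError("rate must be >= 1000 Hz")
        if self.interictal_rate < 0:
            raise ValidationError("interictal_rate must be >= 0")
        if self.intra_cluster_interval <= 0.05:
            raise ValidationError("intra_cluster_interval must exceed the 50 ms lockout")
        if self.noise_spectrum not in ("white", "pink+white"):
            raise ValidationError("noise_spectrum must be 'white' or 'pink+white'")
        if self.polarity not in ("positive", "negative"):
            raise ValidationError("polarity must be 'positive' or 'negative'")


_MIN_INTERVAL = 0.1  # renewal floor, s
_CLUSTER_PAD = 5.0  # keep clusters away from edges and each other, s


def _renewal_times(rng: np.random.Generator, rate: float, shape: float, duration: float) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    mean = 1.0 / rate
    n_guess = int(duration * rate * 1.5) + 20
    times: list[float] = []
    t = 0.0
    while True:
        draws = np.maximum(rng.gamma(shape, mean / shape, size=n_guess), _MIN_INTERVAL)
        for d in draws:
            t += d
            if t >= duration:
                return np.asarray(times)
            times.append(t)


def _pink_white_noise(rng: np.random.Generator, n: int, rate: float, sd: float) -> np.ndarray:
    """Equal-power mix of 1/f-shaped and white Gaussian noise, total SD ``sd``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(np.maximum(f, 1.0))  # flat below 1 Hz, 1/f above
    pink = np.fft.irfft(spec, n=n)
    pink /= pink.std()
    return sd * (white + pink) / math.sqrt(2.0)


def _event_waveform(rate: float, width: float, amplitude: float) -> np.ndarray:
    """Biphasic transient: sharp depolarizing half-sine lobe of ``width``
    seconds followed by a slow, shallow opposite lobe (3x wider, one tenth
    the amplitude) that stays well below detection-threshold scale after
    lowpass filtering and ends inside the 50 ms detection lockout."""
    n_sharp = max(int(round(width * rate)), 2)
    n_slow = 3 * n_sharp
    sharp = amplitude * np.sin(np.pi * np.arange(n_sharp) / n_sharp)
    slow = -0.1 * amplitude * np.sin(np.pi * np.arange(n_slow) / n_slow)
    return np.concatenate([sharp, slow])


def simulate_lfp(
    cfg: LfpSimConfig,
) -> tuple[TimeSeries, EventTrain, list[IctalDischarge]]:
    """Generate an LFP recording with planted uEEs and ictal clusters.

    Returns the signal, the ground-truth event train (all planted onsets,
    sorted) and the ground-truth list of ictal discharges.
    """
    rng = np.random.default_rng(cfg.seed)

    # --- ictal clusters (placed first so the seed fixes their location) ---
    clusters: list[np.ndarray] = []
    spans: list[tuple[float, float]] = []
    for _ in range(cfg.ictal_cluster_count):
        jit = cfg.cluster_jitter * (2.0 * rng.random(cfg.cluster_n_events - 1) - 1.0)
        intervals = cfg.intra_cluster_interval * (1.0 + jit)
        span = float(intervals.sum())
        placed = False
        for _try in range(1000):
            lo, hi = _CLUSTER_PAD, cfg.duration - span - _CLUSTER_PAD
            if hi <= lo:
                break
            start = rng.uniform(lo, hi)
            end = start + span
            if all(start > e + 2 * _CLUSTER_PAD or end < s - 2 * _CLUSTER_PAD for s, e in spans):
                clusters.append(start + np.concatenate([[0.0], np.cumsum(intervals)]))
                spans.append((start, end))
                placed = True
                break
        if not placed:
            raise ValidationError("duration too short to place ictal clusters without overlap")
    clusters.sort(key=lambda c: c[0])

    # --- interictal background ---
    interictal = _renewal_times(rng, cfg.interictal_rate, cfg.renewal_shape, cfg.duration)

    all_times = np.sort(np.concatenate([interictal] + clusters)) if (
        interictal.size or clusters
    ) else np.empty(0)
    # enforce strictly increasing onsets (co-located draws are merged)
    if all_times.size:
        keep = np.concatenate([[True], np.diff(all_times) > 2e-3])
        all_times = all_times[keep]

    # --- render signal ---
    n = int(round(cfg.duration * cfg.rate))
    if cfg.noise_spectrum == "white":
        sig = rng.normal(0.0, cfg.noise_sd, n)
    else:
        sig = _pink_white_noise(rng, n, cfg.rate, cfg.noise_sd)
    wf = _event_waveform(cfg.rate, cfg.interictal_width, cfg.interictal_amplitude * cfg.noise_sd)
    if cfg.polarity == "negative":
        wf = -wf
    for t in all_times:
        i0 = int(round(t * cfg.rate))
        i1 = min(i0 + wf.size, n)
        if i0 < n:
            sig[i0:i1] += wf[: i1 - i0]

    ts = TimeSeries(samples=sig, rate=cfg.rate, units="a.u.", label="lfp-sim")
    train = EventTrain(times=all_times, duration=cfg.duration)
    discharges = [
        IctalDischarge(start=c[0], end=c[-1], member_times=c) for c in clusters
    ]
    return ts, train, discharges


# ---------------------------------------------------------------------------
# Current-clamp generator
# ---------------------------------------------------------------------------


@dataclass
class CellSimConfig:
    """Ground-truth twin of a CA1-like pyramidal cell.

    Defaults sit at the centre of the reported ranges for CA1 neurons
    (RMP about -63 mV, input resistance about 85 MOhm, membrane tau about
    20 ms, AP threshold about -44 mV, amplitude about 99 mV, fAHP -6 mV,
    mAHP -10 mV, ADP about 2 mV, rheobase on the order of 130 pA,
    depolarizing block near 590 pA).

    ``rheobase`` is authoritative: spiking starts at exactly that injected
    current.  ``adaptation_strength`` scales a spike-triggered adaptation
    current (5 pA increments per unit strength) that lengthens successive
    interspike intervals.
    """

    rmp: float = -63.0
    r_in: float = 85.0  # MOhm
    tau_m: float = 20.0  # ms
    spike_threshold: float = -44.0
    spike_amplitude: float = 99.0
    fahp_depth: float = 6.0  # mV below threshold
    mahp_depth: float = 9.9  # mV below threshold
    adp_amplitude: float = 2.0  # mV above the fAHP trough
    mahp_time: float = 65.0  # ms from the fAHP trough to the mAHP trough
    rise_ms: float = 0.58  # AP upstroke duration
    fall_ms: float = 3.2  # AP downstroke duration (peak to fAHP)
    rheobase: float = 130.0  # pA
    adaptation_strength: float = 2.0
    block_current: float = 590.0  # pA
    noise_sd: float = 0.2  # mV
    rate: float = 25_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.r_in <= 0:
            raise ValidationError("tau_m and r_in must be > 0")
        if self.block_current <= self.rheobase:
            raise ValidationError("block_current must exceed rheobase")
        if self.mahp_depth <= self.fahp_depth:
            raise ValidationError("mAHP must be deeper than fAHP")


_FOOT_SLOPE = 3.0  # mV/ms, sub-criterion approach to threshold
_ADP_RISE_MS = 5.0  # fAHP trough -> ADP peak
_RECOVERY_MS = 15.0  # mAHP trough -> hand-off to the RC recharge
_ADAPT_TAU = 1.0  # s, decay of the adaptation current
_BLOCK_ONSET = 0.2  # s after step onset, spiking ceases above block_current


@dataclass
class ApTemplateTruth:
    """Closed-form feature values of the stereotyped AP template.

    fAHP is recorded operationally — the voltage (relative to threshold) at
    the point where the downstroke slows below 5 mV/ms — because that is the
    definition the analysis applies; the geometric trough sits slightly
    deeper.  All times are ms, voltages mV.
    """

    threshold_v: float
    amplitude: float
    rise_10_90: float
    half_width: float
    fahp: float
    fahp_time: float
    mahp: float
    time_to_mahp: float
    adp: float


def _template_truth(cfg: CellSimConfig, theta_eff: float) -> ApTemplateTruth:
    theta = max(cfg.spike_threshold, theta_eff)
    A = cfg.spike_amplitude
    peak = theta + A
    v_fahp = theta - cfg.fahp_depth
    a_f = peak - v_fahp
    t_r, t_f = cfg.rise_ms, cfg.fall_ms
    rise = (t_r / math.pi) * (math.acos(-0.8) - math.acos(0.8))
    u_half = (2 * t_f / math.pi) * math.asin((A / 2) / a_f)
    half_width = t_r / 2 + u_half
    # downstroke slope: a_f * pi/(2 t_f) * cos(pi u / (2 t_f)); find |slope| = 5
    cos_phi = min(1.0, 5.0 * 2 * t_f / (a_f * math.pi))
    phi = math.acos(cos_phi)
    u_f5 = (2 * t_f / math.pi) * phi
    v_fahp_op = peak - a_f * math.sin(phi)
    v_mahp = theta - cfg.mahp_depth
    v_adp = v_fahp + cfg.adp_amplitude
    fahp_time = t_r + u_f5
    mahp_time_abs = t_r + t_f + cfg.mahp_time
    return ApTemplateTruth(
        threshold_v=theta,
        amplitude=A,
        rise_10_90=rise,
        half_width=half_width,
        fahp=v_fahp_op - theta,
        fahp_time=fahp_time,
        mahp=v_mahp - theta,
        time_to_mahp=mahp_time_abs - fahp_time,
        adp=v_adp - v_fahp_op,
    )


def _template_curve(u_ms: np.ndarray, cfg: CellSimConfig, theta_eff: float, v_end: float) -> np.ndarray:
    """Evaluate the AP template at times ``u_ms`` (ms) after the threshold
    crossing (start of the foot)."""
    theta = max(cfg.spike_threshold, theta_eff)
    t_foot = (theta - theta_eff) / _FOOT_SLOPE
    t_r, t_f = cfg.rise_ms, cfg.fall_ms
    A = cfg.spike_amplitude
    peak = theta + A
    v_fahp = theta - cfg.fahp_depth
    a_f = peak - v_fahp
    v_adp = v_fahp + cfg.adp_amplitude
    v_mahp = theta - cfg.mahp_depth
    t_adp_end = cfg.mahp_time - _ADP_RISE_MS  # ADP peak -> mAHP trough span

    b0 = t_foot
    b1 = b0 + t_r
    b2 = b1 + t_f
    b3 = b2 + _ADP_RISE_MS
    b4 = b2 + cfg.mahp_time
    b5 = b4 + _RECOVERY_MS

    u = u_ms
    conds = [
        u < b0,
        (u >= b0) & (u < b1),
        (u >= b1) & (u < b2),
        (u >= b2) & (u < b3),
        (u >= b3) & (u < b4),
        u >= b4,
    ]
    funcs = [
        theta_eff + _FOOT_SLOPE * u,
        theta + A * (1 - np.cos(np.pi * (u - b0) / t_r)) / 2,
        peak - a_f * np.sin(np.pi * (u - b1) / (2 * t_f)),
        v_fahp + (v_adp - v_fahp) * (1 - np.cos(np.pi * (u - b2) / _ADP_RISE_MS)) / 2,
        v_adp + (v_mahp - v_adp) * (1 - np.cos(np.pi * (u - b3) / t_adp_end)) / 2,
        v_mahp + (v_end - v_mahp) * (1 - np.cos(np.pi * np.minimum(u - b4, _RECOVERY_MS) / _RECOVERY_MS)) / 2,
    ]
    out = np.empty_like(u)
    for c, f in zip(conds, funcs):
        out[c] = np.broadcast_to(f, u.shape)[c] if np.ndim(f) else f
    return out


def _template_spans(cfg: CellSimConfig, theta_eff: float) -> tuple[float, float]:
    """(foot duration, total template duration) in seconds."""
    theta = max(cfg.spike_threshold, theta_eff)
    t_foot = (theta - theta_eff) / _FOOT_SLOPE
    total = t_foot + cfg.rise_ms + cfg.fall_ms + cfg.mahp_time + _RECOVERY_MS
    return t_foot * 1e-3, total * 1e-3


def simulate_current_steps(
    cfg: CellSimConfig, protocol: StepProtocol | None = None
) -> tuple[SweepFamily, dict]:
    """Render a current-step sweep family and its ground-truth record.

    The subthreshold response is an exact single-exponential RC charge
    toward ``rmp + I*r_in``; suprathreshold sweeps emit spikes from an
    adaptive integrate-and-fire rule and paste the stereotyped AP template
    at each threshold crossing.  Above ``block_current`` spiking ceases
    200 ms into the step and the membrane holds a depolarized plateau
    (phenomenological depolarizing block).

    The ground-truth dict carries, per sweep, the emitted spike-onset times
    and ISIs, plus family-level rheobase on the grid, the f-I table,
    adaptation ratios at the step above rheobase, and the closed-form AP
    template features.
    """
    if protocol is None:
        protocol = StepProtocol(step_onset=0.5)
    rng = np.random.default_rng(cfg.seed)

    r_mv = cfg.r_in * 1e-3  # mV per pA
    tau = cfg.tau_m * 1e-3  # s
    theta_eff = cfg.rmp + (cfg.rheobase - 1.0) * r_mv
    if theta_eff >= cfg.spike_threshold:
        warnings.warn(
            "rheobase-derived crossing voltage exceeds spike_threshold; "
            "the visible AP threshold will sit at the crossing voltage",
            stacklevel=2,
        )
    amps = protocol.amplitudes
    if cfg.rheobase > amps.max() or cfg.rheobase < amps.min():
        warnings.warn("rheobase lies outside the protocol amplitude range", stacklevel=2)

    truth_ap = _template_truth(cfg, theta_eff)
    t_foot_s, t_total_s = _template_spans(cfg, theta_eff)
    v_mahp = max(cfg.spike_threshold, theta_eff) - cfg.mahp_depth
    v_end = min(v_mahp + 1.5, theta_eff - 0.5)
    b_adapt = cfg.adaptation_strength * 5.0  # pA per spike

    t_on = protocol.step_onset
    t_off = t_on + protocol.step_duration
    sweep_len = protocol.inter_sweep_interval
    n = int(round(sweep_len * cfg.rate))
    t_axis = np.arange(n) / cfg.rate

    sweeps = []
    per_sweep = []
    for amp in amps:
        v = np.full(n, cfg.rmp, dtype=float)
        segments: list[tuple[float, float, float, float]] = []  # t0, t1, v_inf, v0
        spike_crossings: list[float] = []

        def _exp_to_rest(t_from: float, v_from: float) -> None:
            segments.append((t_from, sweep_len, cfg.rmp, v_from))

        def _exp_value(v_inf: float, v0: float, dt: float) -> float:
            return v_inf + (v0 - v_inf) * math.exp(-dt / tau)

        v_inf0 = cfg.rmp + amp * r_mv
        t_cross = (
            t_on + tau * math.log((v_inf0 - cfg.rmp) / (v_inf0 - theta_eff))
            if v_inf0 > theta_eff + 1e-9
            else math.inf
        )
        if t_cross + t_foot_s >= t_off:
            # never reaches threshold during the step: plain RC response
            segments.append((t_on, t_off, v_inf0, cfg.rmp))
            _exp_to_rest(t_off, _exp_value(v_inf0, cfg.rmp, t_off - t_on))
        else:
            segments.append((t_on, t_cross, v_inf0, cfg.rmp))
            w = 0.0
            truncated = False
            while True:
                spike_crossings.append(t_cross)
                w += b_adapt
                v_inf_w = cfg.rmp + (amp - w) * r_mv
                t_e = t_cross + t_total_s
                if t_e >= t_off:
                    truncated = True  # template spans the step end
                    break
                if v_inf_w <= theta_eff + 0.05:
                    # adaptation holds the cell below threshold for the rest of the step
                    segments.append((t_e, t_off, v_inf_w, v_end))
                    _exp_to_rest(t_off, _exp_value(v_inf_w, v_end, t_off - t_e))
                    break
                t_next = t_e + tau * math.log((v_inf_w - v_end) / (v_inf_w - theta_eff))
                if amp >= cfg.block_current and t_next - t_on > _BLOCK_ONSET:
                    # depolarizing block: hold a plateau just below threshold
                    v_plateau = max(cfg.spike_threshold, theta_eff) - 2.0
                    segments.append((t_e, t_off, v_plateau, v_end))
                    _exp_to_rest(t_off, _exp_value(v_plateau, v_end, t_off - t_e))
                    break
                if t_next + t_foot_s >= t_off:
                    segments.append((t_e, t_off, v_inf_w, v_end))
                    _exp_to_rest(t_off, _exp_value(v_inf_w, v_end, t_off - t_e))
                    break
                segments.append((t_e, t_next, v_inf_w, v_end))
                w *= math.exp(-(t_next - t_cross) / _ADAPT_TAU)
                t_cross = t_next

        for t0, t1, v_inf, v0 in segments:
            i0, i1 = int(round(t0 * cfg.rate)), int(round(t1 * cfg.rate))
            if i1 > i0:
                tt = t_axis[i0:i1] - t0
                v[i0:i1] = v_inf + (v0 - v_inf) * np.exp(-tt / tau)

        # paste AP templates (overwrite)
        for tc in spike_crossings:
            i0 = int(round(tc * cfg.rate))
            i1 = min(int(round((tc + t_total_s) * cfg.rate)), n)
            if i1 > i0:
                u_ms = (t_axis[i0:i1] - tc) * 1e3
                v[i0:i1] = _template_curve(u_ms, cfg, theta_eff, v_end)

        # a template truncated by the step end decays to rest from its last value
        if spike_crossings and spike_crossings[-1] + t_total_s >= t_off:
            i_e = min(int(round((spike_crossings[-1] + t_total_s) * cfg.rate)), n - 1)
            tt = t_axis[i_e:] - t_axis[i_e]
            v[i_e:] = cfg.rmp + (v[i_e] - cfg.rmp) * np.exp(-tt / tau)

        if cfg.noise_sd > 0:
            v = v + rng.normal(0.0, cfg.noise_sd, n)
        sweeps.append(TimeSeries(samples=v, rate=cfg.rate, units="mV", label=f"I={amp:g}pA"))
        onsets = np.asarray(spike_crossings) + t_foot_s
        per_sweep.append(
            {
                "amplitude": float(amp),
                "spike_onsets": onsets,
                "n_spikes": onsets.size,
                "isis": np.diff(onsets),
            }
        )

    family = SweepFamily(protocol=protocol, sweeps=sweeps)

    counts = np.array([s["n_spikes"] for s in per_sweep])
    rates = counts / protocol.step_duration
    spiking = np.flatnonzero(counts > 0)
    rheo_grid = float(amps[spiking[0]]) if spiking.size else math.nan
    truth: dict = {
        "rmp": cfg.rmp,
        "r_in": cfg.r_in,
        "tau_m": cfg.tau_m,
        "rheobase_grid": rheo_grid,
        "fi_currents": amps.copy(),
        "fi_rates": rates,
        "ap": truth_ap,
        "per_sweep": per_sweep,
        "theta_eff": theta_eff,
    }
    if spiking.size:
        truth["max_rate"] = float(rates.max())
        truth["current_at_max"] = float(amps[int(np.argmax(rates))])
        first = per_sweep[spiking[0]]["spike_onsets"]
        truth["time_of_first_spike"] = float((first[0] - t_on) * 1e3)  # ms
        # adaptation ratios at the next step above rheobase; missing if < 3 spikes
        above = [s for s in per_sweep if s["amplitude"] > rheo_grid]
        if above and above[0]["n_spikes"] >= 3:
            isis = above[0]["isis"]
            truth["adaptation_current"] = above[0]["amplitude"]
            truth["early_adaptation"] = float(isis[1] / isis[0])
            truth["late_adaptation"] = float(isis[-1] / isis[0])
    return family, truth


# ---------------------------------------------------------------------------
# Evoked-EPSC generator
# ---------------------------------------------------------------------------


@dataclass
class SynSimConfig:
    """Evoked EPSC pair/train generator.

    Responses are inward (negative) currents with instantaneous rise and
    exponential decay ``decay_tau``; pulse ``k`` has isolated peak
    ``a1 * per_pulse_ratio[k]`` superposed on the decaying tail of earlier
    responses.  For paired pulses the second gain is ``ppr``.
    """

    a1: float = 100.0  # pA
    ppr: float = 1.5
    per_pulse_ratio: tuple = (1.0, 1.4, 1.6, 1.7, 1.75)
    decay_tau: float = 20.0  # ms
    isi: float = 0.05  # s
    noise_sd: float = 2.0  # pA
    rate: float = 20_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a1 <= 0:
            raise ValidationError("a1 must be > 0")
        if abs(self.per_pulse_ratio[0] - 1.0) > 1e-12:
            raise ValidationError("per_pulse_ratio[0] must be 1")
        if self.isi <= 0:
            raise ValidationError("isi must be > 0")


def epsc_superposition(cfg: SynSimConfig, gains: np.ndarray, t: np.ndarray, stim_times: np.ndarray) -> np.ndarray:
    """Closed-form noiseless trace: sum of -a1*r_j*exp(-(t-t_j)/tau) for t >= t_j."""
    tau = cfg.decay_tau * 1e-3
    out = np.zeros_like(t)
    for tj, rj in zip(stim_times, gains):
        m = t >= tj
        out[m] += -cfg.a1 * rj * np.exp(-(t[m] - tj) / tau)
    return out


def simulate_epsc_trains(
    cfg: SynSimConfig, n_pulses: int = 5, pathway: str = "other"
) -> tuple[TimeSeries, StimMarkers, dict]:
    """Generate a voltage-clamp trace with 2 (paired-pulse) or 5 (train) EPSCs.

    Ground truth holds the isolated peak of each response and the value of
    the noiseless superposed trace at each stimulus time.
    """
    if n_pulses not in (2, 5):
        raise ValidationError("n_pulses must be 2 or 5")
    gains = (
        np.array([1.0, cfg.ppr])
        if n_pulses == 2
        else np.asarray(cfg.per_pulse_ratio, dtype=float)
    )
    rng = np.random.default_rng(cfg.seed)
    # stimuli snap to the sample grid (the stimulator runs off the DAQ clock)
    stim_times = np.round((0.2 + cfg.isi * np.arange(n_pulses)) * cfg.rate) / cfg.rate
    duration = stim_times[-1] + max(0.3, 10 * cfg.decay_tau * 1e-3)
    n = int(round(duration * cfg.rate))
    t = np.arange(n) / cfg.rate
    clean = epsc_superposition(cfg, gains, t, stim_times)
    tau = cfg.decay_tau * 1e-3
    superposed_at_stim = np.array(
        [
            sum(
                -cfg.a1 * rj * math.exp(-(tk - tj) / tau)
                for tj, rj in zip(stim_times, gains)
                if tj <= tk
            )
            for tk in stim_times
        ]
    )
    sig = clean + rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else clean
    ts = TimeSeries(samples=sig, rate=cfg.rate, units="pA", label="epsc-sim")
    markers = StimMarkers(times=stim_times, pathway=pathway)
    truth = {
        "isolated_peaks": cfg.a1 * gains,
        "gains": gains,
        "superposed_at_stim": superposed_at_stim,
        "decay_tau_ms": cfg.decay_tau,
    }
    return ts, markers, truth
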