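import numpy as np
import pytest

import slicephys as sp


def brute_force_uees(x: np.ndarray, rate: float, threshold: float, lockout: float):
    """Independent per-sample re-derivation of the threshold + lockout rule."""
    times = []
    last = -np.inf
    for i, xi in enumerate(x):
        if xi > threshold and (i - last) >= lockout * rate:
            times.append(i / rate)
            last = i
    return np.asarray(times)


def brute_force_spikes(v: np.ndarray, rate: float, thr: float = 5.0):
    """Naive re-derivation of the dV/dt spike-onset rule."""
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) * rate / 2000.0
    d[0], d[-1] = d[1], d[-2]
    win = max(int(0.005 * rate), 1)
    sep = 0.001 * rate
    onsets = []
    last = -np.inf
    for i in range(1, v.size):
        if d[i - 1] < thr <= d[i] and (i - last) >= sep:
            seg = v[i : i + win + 1]
            if seg.size and seg.max() >= v[i] + 20.0:
                onsets.append(i / rate)
                last = i
    return np.asarray(onsets)


@pytest.fixture(scope="session")
def noiseless_cell():
    """Exact RC cell on a 10 pA grid, no noise — analytic reference."""
    cfg = sp.CellSimConfig(rmp=-63.0, r_in=100.0, tau_m=20.0, noise_sd=0.0, rate=25_000.0)
    proto = sp.StepProtocol(step_onset=0.5, amplitudes=np.arange(-100.0, 601.0, 10.0))
    family, truth = sp.simulate_current_steps(cfg, proto)
    return cfg, family, truth


@pytest.fixture(scope="session")
def sparse_lfp():
    """600 s recording in the 2 s-IEI-mode regime with 3 planted clusters."""
    cfg = sp.LfpSimConfig(
        duration=600.0, rate=5000.0, interictal_rate=0.5, ictal_cluster_count=3, seed=11
    )
    ts, train, discharges = sp.simulate_lfp(cfg)
    return cfg, ts, train, discharges
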