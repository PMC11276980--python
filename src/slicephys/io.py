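"""Readers and writers for the package's neutral on-disk formats.

Two signal formats are supported:

* ``csv`` — two columns ``time_s,value`` preceded by a single ``#`` comment
  line carrying JSON metadata ``{"rate_hz": ..., "units": ..., "label": ...,
  "t0_s": ...}``.  Values are written with 12 significant digits.
* ``hdf5`` — a container with datasets ``/signal``, ``/rate``, ``/units``,
  ``/label``, ``/t0``; round-trips bit exactly.

Event annotations are CSV with columns ``kind,start_s,end_s,n_uees``
(``kind`` in ``{uee, ictal}``) plus a JSON comment header holding recording
duration and detection lockout.  Native acquisition formats (WinWCP,
PatchMaster) are not parsed here; export to one of the neutral formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    EventTrain,
    IctalDischarge,
    StepProtocol,
    SweepFamily,
    TimeSeries,
    ValidationError,
)

FORMATS = ("csv", "hdf5")


def _check_format(fmt: str) -> None:
    if fmt not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {fmt!r}")


def write_timeseries(ts: TimeSeries, path: str | Path, fmt: str = "csv") -> None:
    """Write a validated :class:`TimeSeries` to disk."""
    _check_format(fmt)
    path = Path(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=ts.samples)
            f.create_dataset("rate", data=ts.rate)
            f.create_dataset("t0", data=ts.t0)
            f.create_dataset("units", data=ts.units)
            f.create_dataset("label", data=ts.label)
        return
    meta = {"rate_hz": ts.rate, "units": ts.units, "label": ts.label, "t0_s": ts.t0}
    with open(path, "w") as f:
        f.write("# " + json.dumps(meta) + "\n")
        f.write("time_s,value\n")
        t = ts.times
        for ti, vi in zip(t, ts.samples):
            f.write(f"{ti:.12g},{vi:.12g}\n")


def read_timeseries(path: str | Path, fmt: str = "csv") -> TimeSeries:
    """Read a :class:`TimeSeries`; fails rather than guesses missing metadata."""
    _check_format(fmt)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "rate" not in f:
                raise ValidationError("unspecified sampling rate")
            return TimeSeries(
                samples=f["signal"][()],
                rate=float(f["rate"][()]),
                t0=float(f["t0"][()]) if "t0" in f else 0.0,
                units=f["units"][()].decode() if "units" in f else "a.u.",
                label=f["label"][()].decode() if "label" in f else "",
            )
    with open(path) as f:
        first = f.readline()
    if not first.startswith("#"):
        raise ValidationError("unspecified sampling rate (missing metadata header)")
    meta = json.loads(first.lstrip("#").strip())
    if "rate_hz" not in meta:
        raise ValidationError("unspecified sampling rate")
    df = pd.read_csv(path, comment="#")
    values = df["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("corrupt signal: non-finite samples")
    return TimeSeries(
        samples=values,
        rate=float(meta["rate_hz"]),
        t0=float(meta.get("t0_s", 0.0)),
        units=meta.get("units", "a.u."),
        label=meta.get("label", ""),
    )


def write_events(
    events: EventTrain,
    discharges: list[IctalDischarge],
    path: str | Path,
) -> None:
    """Write a uEE train plus its ictal discharges as a plain-text annotation.

    One ``uee`` row per event (onset in ``start_s``) and one ``ictal`` row per
    discharge.  Discharges must not overlap.
    """
    ds = sorted(discharges, key=lambda d: d.start)
    for a, b in zip(ds[:-1], ds[1:]):
        if b.start <= a.end:
            raise ValidationError("overlapping ictal discharges")
    meta = {"duration_s": events.duration, "lockout_s": events.lockout}
    with open(path, "w") as f:
        f.write("# " + json.dumps(meta) + "\n")
        f.write("kind,start_s,end_s,n_uees\n")
        for t in events.times:
            f.write(f"uee,{t:.12g},{t:.12g},1\n")
        for d in ds:
            f.write(f"ictal,{d.start:.12g},{d.end:.12g},{d.n_uees}\n")


def read_events(path: str | Path) -> tuple[EventTrain, list[IctalDischarge]]:
    """Read an annotation file back into (EventTrain, discharges)."""
    with open(path) as f:
        first = f.readline()
    if not first.startswith("#"):
        raise ValidationError("annotation file missing metadata header")
    meta = json.loads(first.lstrip("#").strip())
    df = pd.read_csv(path, comment="#")
    times = df.loc[df["kind"] == "uee", "start_s"].to_numpy(dtype=float)
    events = EventTrain(
        times=np.sort(times),
        duration=float(meta["duration_s"]),
        lockout=meta.get("lockout_s"),
    )
    discharges = []
    for _, row in df[df["kind"] == "ictal"].iterrows():
        members = events.times[
            (events.times >= row["start_s"] - 1e-9) & (events.times <= row["end_s"] + 1e-9)
        ]
        d = IctalDischarge(
            start=float(row["start_s"]), end=float(row["end_s"]), member_times=members
        )
        if d.n_uees != int(row["n_uees"]):
            raise ValidationError("annotation inconsistent: n_uees does not match members")
        discharges.append(d)
    return events, discharges


def event_classes(events: EventTrain, discharges: list[IctalDischarge]) -> np.ndarray:
    """Label each event ``ictal-member`` or ``interictal`` (exhaustive, exclusive)."""
    labels = np.full(events.n, "interictal", dtype=object)
    for d in discharges:
        labels[(events.times >= d.start - 1e-9) & (events.times <= d.end + 1e-9)] = "ictal-member"
    return labels


def write_sweepfamily(family: SweepFamily, path: str | Path) -> None:
    """Write a current-step sweep family to an HDF5 container."""
    p = family.protocol
    with h5py.File(path, "w") as f:
        f.create_dataset("sweeps", data=np.stack([s.samples for s in family.sweeps]))
        f.create_dataset("amplitudes", data=p.amplitudes)
        f.create_dataset("rate", data=family.rate)
        f.create_dataset("t0", data=family.sweeps[0].t0)
        f.create_dataset("units", data=family.sweeps[0].units)
        f.create_dataset("step_onset", data=p.step_onset)
        f.create_dataset("step_duration", data=p.step_duration)
        f.create_dataset("inter_sweep_interval", data=p.inter_sweep_interval)


def read_sweepfamily(path: str | Path) -> SweepFamily:
    with h5py.File(path, "r") as f:
        protocol = StepProtocol(
            step_onset=float(f["step_onset"][()]),
            step_duration=float(f["step_duration"][()]),
            amplitudes=f["amplitudes"][()],
            inter_sweep_interval=float(f["inter_sweep_interval"][()]),
        )
        rate = float(f["rate"][()])
        t0 = float(f["t0"][()])
        units = f["units"][()].decode()
        sweeps = [
            TimeSeries(samples=row, rate=rate, t0=t0, units=units, label=f"I={a:g}pA")
            for row, a in zip(f["sweeps"][()], protocol.amplitudes)
        ]
    return SweepFamily(protocol=protocol, sweeps=sweeps)
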