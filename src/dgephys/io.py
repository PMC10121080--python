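"""Reading and writing sweep containers.

Two interchange formats are supported:

* **container** — one HDF5 file per :class:`~dgephys.model.Experiment`.
  Layout: a group ``sweep_NNNN`` per sweep holding the ``samples`` dataset
  (float64, stored losslessly) with scalar attributes ``sampling_rate``,
  ``t0`` and ``channel_kind``; free-form sweep metadata is JSON-encoded in
  the ``metadata`` attribute, and protocols live in a ``protocol``
  subgroup.  The experiment design is JSON-encoded on the root group.
* **delimited** — a two-column text file ``time_s,value`` holding a single
  sweep, with an optional JSON sidecar (``<path>.meta.json``) for metadata.
  The sampling rate is inferred from the time column, which must be
  strictly increasing and uniformly spaced.

Container round-trips are bit-exact for samples and lossless for metadata.
An optional read-only adapter for Axon Binary Format files is provided in
:mod:`dgephys.abf` as an isolated plugin; nothing in the core requires it.
"""

from __future__ import annotations

import json
import os
from typing import Union

import h5py
import numpy as np

from .model import (
    Experiment,
    StepProtocol,
    StimEvent,
    Sweep,
    ValidationError,
)


class ParseError(ValueError):
    """Raised when a container or delimited file cannot be interpreted."""


# ---------------------------------------------------------------------------
# protocol (de)serialisation helpers

def _write_protocol(grp: h5py.Group, protocol) -> None:
    sub = grp.create_group("protocol")
    if isinstance(protocol, StepProtocol):
        sub.attrs["kind"] = "step"
        for name in ("start_pA", "stop_pA", "increment_pA", "step_duration_s",
                     "inter_step_s", "step_onset_s"):
            sub.attrs[name] = getattr(protocol, name)
    else:  # sequence of StimEvent
        sub.attrs["kind"] = "stim"
        events = list(protocol)
        sub.create_dataset("time_s", data=np.array([e.time_s for e in events]))
        sub.create_dataset(
            "intensity_uA", data=np.array([e.intensity_uA for e in events]))
        sub.create_dataset(
            "pulse_index_in_pair",
            data=np.array([e.pulse_index_in_pair or 0 for e in events], dtype=np.int8))
        sub.create_dataset(
            "interpulse_interval_ms",
            data=np.array([e.interpulse_interval_ms if e.interpulse_interval_ms
                           is not None else np.nan for e in events]))


def _read_protocol(grp: h5py.Group):
    if "protocol" not in grp:
        return None
    sub = grp["protocol"]
    kind = sub.attrs["kind"]
    if kind == "step":
        return StepProtocol(**{k: float(sub.attrs[k]) for k in
                               ("start_pA", "stop_pA", "increment_pA",
                                "step_duration_s", "inter_step_s", "step_onset_s")})
    if kind == "stim":
        times = sub["time_s"][()]
        intens = sub["intensity_uA"][()]
        idx = sub["pulse_index_in_pair"][()]
        ipi = sub["interpulse_interval_ms"][()]
        return [StimEvent(time_s=float(t), intensity_uA=float(a),
                          pulse_index_in_pair=int(i) if i else None,
                          interpulse_interval_ms=None if np.isnan(p) else float(p))
                for t, a, i, p in zip(times, intens, idx, ipi)]
    raise ParseError(f"unknown protocol kind {kind!r}")


# ---------------------------------------------------------------------------
# public API

def write_experiment(experiment: Experiment, path: Union[str, os.PathLike]) -> None:
    """Write an experiment to the native HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "dgephys-container-v1"
        f.attrs["design"] = json.dumps(experiment.design)
        for i, sw in enumerate(experiment.sweeps):
            grp = f.create_group(f"sweep_{i:04d}")
            grp.create_dataset("samples", data=sw.samples, dtype=np.float64)
            grp.attrs["sampling_rate"] = sw.sampling_rate
            grp.attrs["t0"] = sw.t0
            grp.attrs["channel_kind"] = sw.channel_kind
            grp.attrs["metadata"] = json.dumps(sw.metadata)
            if sw.protocol is not None:
                _write_protocol(grp, sw.protocol)


def _read_container(path) -> Experiment:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "dgephys-container-v1":
            raise ParseError(f"{path}: not a dgephys container (format attribute "
                             f"{f.attrs.get('format')!r})")
        design = json.loads(f.attrs.get("design", "{}"))
        sweeps = []
        for name in sorted(f.keys()):
            grp = f[name]
            if "sampling_rate" not in grp.attrs:
                raise ValidationError(f"{path}:{name}: missing sampling rate")
            sweeps.append(Sweep(
                samples=grp["samples"][()],
                sampling_rate=float(grp.attrs["sampling_rate"]),
                t0=float(grp.attrs["t0"]),
                channel_kind=str(grp.attrs["channel_kind"]),
                protocol=_read_protocol(grp),
                metadata=json.loads(grp.attrs.get("metadata", "{}")),
            ))
    return Experiment(sweeps=sweeps, design=design)


def write_delimited(sweep: Sweep, path: Union[str, os.PathLike]) -> None:
    """Write a single sweep as two-column text plus a JSON metadata sidecar."""
    t = sweep.times()
    with open(path, "w") as f:
        f.write("time_s,value\n")
        for ti, vi in zip(t, sweep.samples):
            f.write(f"{float(ti)!r},{float(vi)!r}\n")
    sidecar = {"sampling_rate": sweep.sampling_rate,
               "channel_kind": sweep.channel_kind,
               "t0": sweep.t0,
               "metadata": sweep.metadata}
    with open(str(path) + ".meta.json", "w") as f:
        json.dump(sidecar, f, indent=1)


def _read_delimited(path) -> Experiment:
    with open(path) as f:
        header = f.readline().strip()
        if header.replace(" ", "") != "time_s,value":
            raise ParseError(f"{path}: expected header 'time_s,value', "
                             f"got {header!r}")
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed numeric record ({exc})") from exc
    if data.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, got {data.shape[1]}")
    t, v = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2 if t.size >= 2 else 1
        raise ParseError(f"{path}: time column not strictly increasing "
                         f"(row {bad})")
    if not np.allclose(dt, dt.mean(), rtol=1e-6, atol=1e-12):
        raise ParseError(f"{path}: time column not uniformly spaced")
    sampling_rate = 1.0 / float(np.median(dt))
    meta_path = str(path) + ".meta.json"
    kwargs = {}
    metadata = {}
    if os.path.exists(meta_path):
        with open(meta_path) as f:
            sidecar = json.load(f)
        metadata = sidecar.get("metadata", {})
        kwargs["channel_kind"] = sidecar.get("channel_kind",
                                             "voltage_clamp_current")
    sweep = Sweep(samples=v, sampling_rate=sampling_rate, t0=float(t[0]),
                  metadata=metadata, **kwargs)
    return Experiment(sweeps=[sweep])


def read_experiment(path: Union[str, os.PathLike],
                    format: str = "container") -> Experiment:
    """Read an experiment from ``path``.

    Parameters
    ----------
    format : {'container', 'delimited'}
        ``'container'`` reads the native HDF5 layout; ``'delimited'`` reads
        a single two-column ``time_s,value`` text sweep (sampling rate
        inferred from the time spacing).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "container":
        return _read_container(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValidationError(f"unknown format {format!r}")
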