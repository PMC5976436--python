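"""File formats: delimited-text traces and i-V tables, a compact binary
trace container, profile tables, and JSON result records with provenance.

Text formats
------------
* i-V tables: 2-column CSV with header ``voltage_mV,current_pA``.
* traces: CSV with header ``time_s,current_pA`` plus an epoch sidecar CSV
  (``<name>.epochs.csv``) with header
  ``start_s,end_s,adpr_uM,ca_uM,pip2_uM,voltage_mV,label``.
* pore profiles: CSV with header ``s_A,center_x,center_y,center_z,radius_A,class``.

Binary trace container (``.trc``)
---------------------------------
For long recordings, byte layout (little endian):

====== ======= ==========================================================
offset size    content
====== ======= ==========================================================
0      8       magic ``b"TRPM2TRC"``
8      4       uint32, length H of the JSON header in bytes
12     H       UTF-8 JSON: {"sampling_rate": Hz, "n_samples": N,
               "epochs": [[start_s, end_s, adpr_uM, ca_uM, pip2_uM,
               voltage_mV, label], ...]}
12+H   4*N     float32 samples (pA)
====== ======= ==========================================================
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import struct
from pathlib import Path

import numpy as np

from .gating import CurrentTrace, Epoch
from .permeation import IVCurve

__all__ = [
    "read_iv_csv", "write_iv_csv",
    "read_trace_csv", "write_trace_csv",
    "read_trace_binary", "write_trace_binary",
    "write_profile_csv", "read_profile_csv",
    "result_record", "write_result_json",
]

TRACE_MAGIC = b"TRPM2TRC"


def write_iv_csv(path, iv: IVCurve) -> None:
    with open(path, "w") as fh:
        fh.write("voltage_mV,current_pA\n")
        for v, i in zip(iv.voltages_mv, iv.currents_pa):
            fh.write(f"{v:.10g},{i:.10g}\n")


def read_iv_csv(path, temperature: float | None = None,
                junction_potential_mv: float = 0.0) -> IVCurve:
    data = np.genfromtxt(path, delimiter=",", names=True)
    kwargs = {}
    if temperature is not None:
        kwargs["temperature"] = temperature
    return IVCurve(np.atleast_1d(data["voltage_mV"]),
                   np.atleast_1d(data["current_pA"]),
                   junction_potential_mv=junction_potential_mv, **kwargs)


def _epochs_to_rows(epochs):
    return [[ep.start, ep.end, ep.adpr, ep.ca_cyto_free, ep.pip2, ep.voltage,
             ep.label] for ep in epochs]


def _rows_to_epochs(rows):
    return tuple(Epoch(float(r[0]), float(r[1]), float(r[2]), float(r[3]),
                       float(r[4]), float(r[5]), str(r[6])) for r in rows)


def write_trace_csv(path, trace: CurrentTrace) -> None:
    path = Path(path)
    t = trace.times
    with open(path, "w") as fh:
        fh.write("time_s,current_pA\n")
        for ti, ii in zip(t, trace.samples):
            fh.write(f"{ti:.8f},{ii:.6g}\n")
    sidecar = path.with_suffix(".epochs.csv")
    with open(sidecar, "w") as fh:
        fh.write("start_s,end_s,adpr_uM,ca_uM,pip2_uM,voltage_mV,label\n")
        for row in _epochs_to_rows(trace.epochs):
            fh.write(",".join(str(x) for x in row) + "\n")


def read_trace_csv(path) -> CurrentTrace:
    path = Path(path)
    data = np.genfromtxt(path, delimiter=",", names=True)
    t = np.atleast_1d(data["time_s"])
    samples = np.atleast_1d(data["current_pA"])
    if len(t) < 2:
        raise ValueError("trace needs at least 2 samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    epochs = ()
    sidecar = path.with_suffix(".epochs.csv")
    if sidecar.exists():
        with open(sidecar) as fh:
            header = fh.readline()
            rows = [line.rstrip("\n").split(",") for line in fh if line.strip()]
        epochs = _rows_to_epochs(rows)
    return CurrentTrace(samples, rate, epochs)


def write_trace_binary(path, trace: CurrentTrace) -> None:
    header = {
        "sampling_rate": trace.sampling_rate,
        "n_samples": int(len(trace.samples)),
        "epochs": _epochs_to_rows(trace.epochs),
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(TRACE_MAGIC)
        fh.write(struct.pack("<I", len(blob)))
        fh.write(blob)
        fh.write(np.asarray(trace.samples, dtype="<f4").tobytes())


def read_trace_binary(path) -> CurrentTrace:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != TRACE_MAGIC:
            raise ValueError(f"bad magic {magic!r}: not a trace container")
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen).decode())
        samples = np.frombuffer(fh.read(4 * header["n_samples"]), dtype="<f4")
    return CurrentTrace(samples.astype(float), header["sampling_rate"],
                        _rows_to_epochs(header["epochs"]))


def write_profile_csv(path, profile) -> None:
    with open(path, "w") as fh:
        fh.write("s_A,center_x,center_y,center_z,radius_A,class\n")
        for s, c, r, cls in zip(profile.s, profile.centers, profile.radii,
                                profile.classes):
            fh.write(f"{s:.4f},{c[0]:.4f},{c[1]:.4f},{c[2]:.4f},{r:.4f},{cls}\n")


def read_profile_csv(path):
    from .pore import PoreProfile
    s, centers, radii, classes = [], [], [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.strip().split(",")
            if len(parts) < 6:
                continue
            s.append(float(parts[0]))
            centers.append([float(parts[1]), float(parts[2]), float(parts[3])])
            radii.append(float(parts[4]))
            classes.append(parts[5])
    return PoreProfile(np.array(s), np.array(centers), np.array(radii),
                       classes, np.zeros(len(s), dtype=bool))


# ---------------------------------------------------------------------------
# result provenance

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def result_record(payload: dict, seed: int | None = None,
                  config: dict | None = None) -> dict:
    """Wrap a result payload with provenance (package version, seed, config hash)."""
    from . import __version__

    record = {"package": "trpm2kit", "version": __version__,
              "result": _jsonable(payload)}
    if seed is not None:
        record["seed"] = int(seed)
    if config is not None:
        cfg = _jsonable(config)
        record["config"] = cfg
        record["config_sha256"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    return record


def write_result_json(path, payload: dict, seed: int | None = None,
                      config: dict | None = None) -> dict:
    record = result_record(payload, seed=seed, config=config)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return record
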