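"""Recording and model I/O.

Two interchange formats are supported: a packaged ``.npz`` array with a JSON
sidecar (lossless) and a minimal EDF reader/writer (16-bit quantized).
Models are serialized as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .core import ElectrodeLayout, Recording
from .microstates import MicrostateModel


# --------------------------------------------------------------------------
# packaged array + sidecar
# --------------------------------------------------------------------------

def write_recording(recording: Recording, path) -> None:
    """Write ``<path>.npz`` plus ``<path>.json`` sidecar."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
    np.savez_compressed(base.with_suffix(".npz"), data=recording.data)
    sidecar = {
        "rate": recording.rate,
        "labels": list(recording.layout.labels),
        "positions": recording.layout.positions.tolist(),
        "subject": recording.subject,
        "condition": recording.condition,
        "band": recording.band,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar))


def read_recording(path) -> Recording:
    path = Path(path)
    if path.suffix == ".edf":
        return read_edf(path)
    base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
    npz_path = base.with_suffix(".npz")
    sidecar_path = base.with_suffix(".json")
    if not npz_path.exists():
        raise FileNotFoundError(f"missing array file {npz_path}")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path} for {npz_path} (no silent defaults)")
    meta = json.loads(sidecar_path.read_text())
    with np.load(npz_path) as npz:
        data = npz["data"]
    layout = ElectrodeLayout(tuple(meta["labels"]),
                             np.asarray(meta["positions"], dtype=float))
    return Recording(data=data, rate=float(meta["rate"]), layout=layout,
                     subject=meta.get("subject", ""),
                     condition=meta.get("condition", ""),
                     band=meta.get("band"))


# --------------------------------------------------------------------------
# minimal EDF
# --------------------------------------------------------------------------

def _f(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    """Single-record EDF with symmetric physical range (16-bit quantized).

    Layout positions are stored in the per-signal transducer field so the
    round trip preserves geometry; intended for interchange with this
    package's own reader and standard EDF tools.
    """
    path = Path(path)
    data = recording.data
    C, T = data.shape
    phys_max = float(np.max(np.abs(data)))
    if phys_max == 0:
        phys_max = 1.0
    dig_max = 32767
    scaled = np.round(data / phys_max * dig_max).astype("<i2")
    duration = T / recording.rate
    header = b""
    header += _f("0", 8)
    header += _f(recording.subject or "X", 80)
    header += _f(f"cond={recording.condition or 'NA'} band={recording.band or 'NA'}", 80)
    header += _f("01.01.01", 8)
    header += _f("00.00.00", 8)
    header += _f(str(256 * (C + 1)), 8)
    header += _f("", 44)
    header += _f("1", 8)                       # one data record
    header += _f(f"{duration:.6g}", 8)
    header += _f(str(C), 4)
    for lab in recording.layout.labels:
        header += _f(lab, 16)
    for x, y in recording.layout.positions:
        header += _f(f"{x:.4f},{y:.4f}", 80)   # transducer field reused
    header += b"".join(_f("uV", 8) for _ in range(C))
    header += b"".join(_f(f"{-phys_max:.6g}"[:8], 8) for _ in range(C))
    header += b"".join(_f(f"{phys_max:.6g}"[:8], 8) for _ in range(C))
    header += b"".join(_f(str(-dig_max), 8) for _ in range(C))
    header += b"".join(_f(str(dig_max), 8) for _ in range(C))
    header += b"".join(_f("", 80) for _ in range(C))
    header += b"".join(_f(str(T), 8) for _ in range(C))
    header += b"".join(_f("", 32) for _ in range(C))
    path.write_bytes(header + scaled.tobytes())


def read_edf(path) -> Recording:
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"corrupt EDF header in {path}: file shorter than 256 bytes")
    try:
        n_records = int(raw[236:244].decode("ascii").strip())
        duration = float(raw[244:252].decode("ascii").strip())
        C = int(raw[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise ValueError(f"corrupt EDF header in {path} at offset 236-256") from exc
    off = 256
    labels = tuple(raw[off + 16 * i:off + 16 * (i + 1)].decode("ascii").strip()
                   for i in range(C))
    off += 16 * C
    positions = []
    for i in range(C):
        field = raw[off + 80 * i:off + 80 * (i + 1)].decode("ascii").strip()
        try:
            x, y = (float(v) for v in field.split(","))
        except ValueError:
            x, y = 0.0, 0.0
        positions.append((x, y))
    off += 80 * C
    off += 8 * C                               # physical dimension
    phys_min = np.array([float(raw[off + 8 * i:off + 8 * (i + 1)])
                         for i in range(C)])
    off += 8 * C
    phys_max = np.array([float(raw[off + 8 * i:off + 8 * (i + 1)])
                         for i in range(C)])
    off += 8 * C
    dig_min = np.array([int(raw[off + 8 * i:off + 8 * (i + 1)]) for i in range(C)])
    off += 8 * C
    dig_max = np.array([int(raw[off + 8 * i:off + 8 * (i + 1)]) for i in range(C)])
    off += 8 * C
    off += 80 * C                              # prefilter
    spr = [int(raw[off + 8 * i:off + 8 * (i + 1)]) for i in range(C)]
    off += 8 * C
    off += 32 * C
    if len(set(spr)) != 1:
        raise ValueError(f"unsupported EDF in {path}: per-signal rates differ")
    T = spr[0]
    subject = raw[8:88].decode("ascii").strip()
    rec_field = raw[88:168].decode("ascii").strip()
    condition, band = "", None
    for token in rec_field.split():
        if token.startswith("cond="):
            condition = token[5:]
        elif token.startswith("band="):
            band = token[5:]
    if condition == "NA":
        condition = ""
    if band == "NA":
        band = None
    rate = T * n_records / (duration * n_records)
    body = np.frombuffer(raw[off:], dtype="<i2")
    expected = C * T * n_records
    if body.size < expected:
        raise ValueError(f"corrupt EDF body in {path} at offset {off}: "
                         f"expected {expected} samples, found {body.size}")
    records = body[:expected].reshape(n_records, C, T)
    digital = np.concatenate([records[r] for r in range(n_records)], axis=1)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = phys_min[:, None] + (digital - dig_min[:, None]) * gain[:, None]
    layout = ElectrodeLayout(labels, np.asarray(positions, dtype=float))
    return Recording(data=data, rate=rate, layout=layout, subject=subject,
                     condition=condition, band=band)


# --------------------------------------------------------------------------
# model JSON
# --------------------------------------------------------------------------

def write_model(model: MicrostateModel, path) -> None:
    payload = {
        "K": model.K,
        "maps": model.maps.tolist(),
        "gev_total": None if np.isnan(model.gev_total) else model.gev_total,
        "ev_per_class": model.ev_per_class.tolist(),
        "cv_value": None if np.isnan(model.cv_value) else model.cv_value,
        "band": model.band,
        "level": model.level,
        "labels": list(model.labels),
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path) -> MicrostateModel:
    payload = json.loads(Path(path).read_text())
    return MicrostateModel(
        maps=np.asarray(payload["maps"], dtype=float),
        gev_total=(np.nan if payload["gev_total"] is None
                   else payload["gev_total"]),
        ev_per_class=np.asarray(payload["ev_per_class"], dtype=float),
        cv_value=(np.nan if payload["cv_value"] is None
                  else payload["cv_value"]),
        band=payload["band"], level=payload["level"],
        labels=tuple(payload["labels"]))
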