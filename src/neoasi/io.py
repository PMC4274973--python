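"""EDF reading and writing for neonatal EEG records.

Reading goes through :func:`mne.io.read_raw_edf`; channel labels are
normalized to canonical 10-20 form ("EEG Fp1-Cz" -> "Fp1", case and spacing
insensitive), EDF+ annotations are mapped to half-open ``[start, end)``
intervals, and a sidecar JSON (``<stem>.json``), if present, contributes
further annotations and metadata (ground-truth generator parameters, group
label).

Writing uses a small built-in EDF writer (plain EDF, 16-bit, one-second data
records) plus the sidecar JSON for annotations and metadata.  Round-tripping
a record reproduces the samples to within the 16-bit EDF quantization step.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np

from .errors import NeoasiError
from .records import Annotation, EEGRecord

__all__ = ["read_edf", "write_edf", "normalize_label"]

#: Canonical 10-20 (and common extension) electrode names.
_CANONICAL = {
    name.lower(): name
    for name in (
        "Fp1 Fp2 Fpz F3 F4 F7 F8 Fz C3 C4 Cz P3 P4 Pz O1 O2 Oz "
        "T3 T4 T5 T6 T7 T8 P7 P8 A1 A2 M1 M2"
    ).split()
}

_PREFIXES = ("eeg", "ref", "chan")


def normalize_label(raw: str) -> str:
    """Map a vendor channel label to canonical 10-20 form.

    Strips an "EEG" prefix and a "-Ref"/"-Cz" reference suffix, then matches
    case-insensitively against the canonical table.  Unknown labels pass
    through stripped but otherwise untouched (they only fail when a montage
    actually requests them).
    """
    s = raw.strip()
    low = s.lower()
    for p in _PREFIXES:
        if low.startswith(p + " ") or low.startswith(p + "_"):
            s = s[len(p) + 1:]
            break
    s = s.split("-")[0].strip()
    return _CANONICAL.get(s.lower(), s)


def read_edf(path: str | Path) -> EEGRecord:
    """Read an EDF/EDF+ file into an :class:`EEGRecord` (channels in uV).

    EDF+ annotations become half-open intervals; a sidecar ``<stem>.json``
    adds annotations (key ``"annotations"``: list of ``[start, end, tag]``)
    and metadata (key ``"meta"``).  Mismatched per-channel rates are
    resampled by mne to a common rate with a warning.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise NeoasiError(f"cannot parse EDF file {path}: {exc}") from exc
    data_uv = raw.get_data(units={"eeg": "uV"}) if len(raw.ch_names) else raw.get_data()
    labels = [normalize_label(ch) for ch in raw.ch_names]
    annotations = [
        Annotation(float(on), float(on) + float(du), str(desc))
        for on, du, desc in zip(raw.annotations.onset,
                                raw.annotations.duration,
                                raw.annotations.description)
    ]
    meta: dict = {"source": str(path)}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        blob = json.loads(sidecar.read_text())
        for start, end, tag in blob.get("annotations", []):
            annotations.append(Annotation(float(start), float(end), str(tag)))
        meta.update(blob.get("meta", {}))
    return EEGRecord(data=data_uv, fs=float(raw.info["sfreq"]), labels=labels,
                     annotations=annotations, meta=meta)


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(record: EEGRecord, path: str | Path,
              patient_id: str = "X", recording_id: str = "neoasi") -> Path:
    """Write an :class:`EEGRecord` as plain EDF plus a sidecar JSON.

    16-bit samples, one-second data records (the sampling rate must be a
    whole number of Hz); the signal is truncated to whole records.  The
    sidecar ``<stem>.json`` carries the annotations and ``record.meta`` so
    that :func:`read_edf` round-trips them.
    """
    path = Path(path)
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise NeoasiError(f"EDF writer needs an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1-s record
    n_records = record.n_samples // spr
    if n_records < 1:
        raise NeoasiError("record shorter than one EDF data record (1 s)")
    n_sig = len(record.labels)
    data = record.data[:, : n_records * spr]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-3)
    phys_max = np.ceil(phys_max)
    dig_min, dig_max = -32768, 32767

    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii(patient_id, 80)
    header += _ascii(recording_id, 80)
    now = _dt.datetime(2000, 1, 1)
    header += _ascii(now.strftime("%d.%m.%y"), 8)
    header += _ascii(now.strftime("%H.%M.%S"), 8)
    header += _ascii(256 * (n_sig + 1), 8)
    header += _ascii("", 44)
    header += _ascii(n_records, 8)
    header += _ascii(1, 8)
    header += _ascii(n_sig, 4)
    for lab in record.labels:
        header += _ascii(f"EEG {lab}", 16)
    header += b"".join(_ascii("", 80) for _ in range(n_sig))       # transducer
    header += b"".join(_ascii("uV", 8) for _ in range(n_sig))      # phys dim
    header += b"".join(_ascii(f"{-m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_ascii(f"{m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_ascii(dig_min, 8) for _ in range(n_sig))
    header += b"".join(_ascii(dig_max, 8) for _ in range(n_sig))
    header += b"".join(_ascii("", 80) for _ in range(n_sig))       # prefilter
    header += b"".join(_ascii(spr, 8) for _ in range(n_sig))
    header += b"".join(_ascii("", 32) for _ in range(n_sig))

    # digitize per channel against the header's (rounded-string) phys range
    pmax = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    scale = (dig_max - dig_min) / (2 * pmax)
    dig = np.clip(np.round((data + pmax[:, None]) * scale[:, None]) + dig_min,
                  dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            for ch in range(n_sig):
                fh.write(dig[ch, sl].tobytes())

    sidecar = {
        "annotations": [[a.start, a.end, a.tag] for a in record.annotations],
        "meta": _jsonable(record.meta),
        "fs": fs,
        "physical_dimension": "uV",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
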