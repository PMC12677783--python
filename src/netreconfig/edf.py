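"""Minimal EDF reader/writer.

Supports plain EDF (not EDF+ annotations): fixed 256-byte header, one
256-byte block per signal, 16-bit little-endian samples organised in data
records.  All channels must share one sampling rate.  Values are stored
with the standard physical/digital linear scaling, so a write/read
round-trip is exact up to 16-bit quantization of the physical range.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .signal_io import Recording

__all__ = ["read_edf", "write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start: start + length].decode("ascii", errors="replace").strip()


def read_edf(path: str | Path) -> Recording:
    """Read a plain EDF file into a :class:`Recording`."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"EDF file {path.name}: truncated header (<256 bytes)")
    try:
        n_records = int(_field(raw, 236, 8))
        record_dur = float(_field(raw, 244, 8))
        n_sig = int(_field(raw, 252, 4))
    except ValueError as exc:
        raise ValueError(f"EDF file {path.name}: malformed header field: {exc}") from exc
    if n_sig < 1:
        raise ValueError(f"EDF file {path.name}: header reports {n_sig} signals")
    header_bytes = 256 + 256 * n_sig
    if len(raw) < header_bytes:
        raise ValueError(f"EDF file {path.name}: truncated signal headers")
    sig = raw[256:header_bytes]

    def sig_fields(offset: int, width: int) -> list[str]:
        base = offset * n_sig
        return [
            sig[base + i * width: base + (i + 1) * width].decode(
                "ascii", errors="replace").strip()
            for i in range(n_sig)
        ]

    labels = sig_fields(0, 16)
    try:
        phys_min = np.array([float(v) for v in sig_fields(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in sig_fields(16 + 80 + 8 + 8, 8)])
        dig_min = np.array([float(v) for v in sig_fields(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in sig_fields(16 + 80 + 8 + 24, 8)])
        spr = np.array([int(v) for v in sig_fields(16 + 80 + 8 + 32 + 80, 8)])
    except ValueError as exc:
        raise ValueError(f"EDF file {path.name}: malformed signal header: {exc}") from exc
    if len(set(spr.tolist())) != 1:
        raise ValueError(
            f"EDF file {path.name}: channels have mixed samples-per-record; "
            "only uniform-rate EDF is supported"
        )
    n_per_rec = int(spr[0])
    fs = n_per_rec / record_dur

    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected = n_records * n_sig * n_per_rec
    if body.size < expected:
        raise ValueError(
            f"EDF file {path.name}: expected {expected} samples, found {body.size}"
        )
    body = body[:expected].reshape(n_records, n_sig, n_per_rec).astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset_phys = phys_min - gain * dig_min
    data = body * gain[None, :, None] + offset_phys[None, :, None]
    samples = data.transpose(1, 0, 2).reshape(n_sig, n_records * n_per_rec)
    return Recording(samples=samples, channel_labels=tuple(labels), fs=fs)


def write_edf(rec: Recording, path: str | Path,
              record_duration: float = 1.0) -> None:
    """Write a :class:`Recording` as plain EDF.

    The trailing part of the signal that does not fill a whole data record
    is dropped (EDF stores an integer number of records).
    """
    path = Path(path)
    n_per_rec = int(round(record_duration * rec.fs))
    if abs(n_per_rec - record_duration * rec.fs) > 1e-9 or n_per_rec < 1:
        raise ValueError("record_duration * fs must be a positive integer")
    n_records = rec.n_samples // n_per_rec
    if n_records < 1:
        raise ValueError("recording shorter than one data record")
    x = rec.samples[:, : n_records * n_per_rec]
    phys_min = x.min(axis=1)
    phys_max = x.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    def pad(value: str, width: int) -> bytes:
        s = value[:width]
        return (s + " " * (width - len(s))).encode("ascii")

    n_sig = rec.n_channels
    header = b"".join([
        pad("0", 8),
        pad(str(rec.subject_id or "X"), 80),
        pad("Startdate X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 + 256 * n_sig), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad(f"{record_duration:g}", 8),
        pad(str(n_sig), 4),
    ])

    def col(values: list[str], width: int) -> bytes:
        return b"".join(pad(v, width) for v in values)

    header += col(list(rec.channel_labels), 16)
    header += col([""] * n_sig, 80)          # transducer
    header += col(["uV"] * n_sig, 8)         # physical dimension
    header += col([f"{v:.6g}"[:8] for v in phys_min], 8)
    header += col([f"{v:.6g}"[:8] for v in phys_max], 8)
    header += col([str(_DIG_MIN)] * n_sig, 8)
    header += col([str(_DIG_MAX)] * n_sig, 8)
    header += col([""] * n_sig, 80)          # prefiltering
    header += col([str(n_per_rec)] * n_sig, 8)
    header += col([""] * n_sig, 32)          # reserved

    gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((x - phys_min[:, None]) / gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
    # (records, signals, samples-per-record) interleaving
    body = digital.reshape(n_sig, n_records, n_per_rec).transpose(1, 0, 2)
    path.write_bytes(header + body.tobytes())
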