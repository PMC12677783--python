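"""Recording I/O, preprocessing and band-limited windowing.

Recordings are multichannel time series (channels x samples). Two on-disk
formats are supported: standard EDF, and a plain delimited matrix (header
row of channel labels, one row per channel) with a JSON sidecar carrying
the sampling rate.

Preprocessing follows the conventional resting-state chain: power-line
notch, high-pass, then zero-phase Butterworth band decomposition into the
canonical delta/theta/alpha/beta/gamma bands, and segmentation into
non-overlapping fixed-length windows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "DEFAULT_BANDS",
    "CHANNELS_1020",
    "Recording",
    "BandWindowedSignals",
    "read_recording",
    "write_matrix",
    "preprocess",
    "band_window",
]

#: Canonical EEG frequency bands (Hz).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: 19-channel 10-20 montage, in the conventional site order.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

_FILTER_ORDER = 4   # Butterworth order for high-pass and band-pass
_NOTCH_Q = 30.0     # quality factor of the IIR notch


@dataclass
class Recording:
    """A multichannel recording with channel labels and sampling rate."""

    samples: np.ndarray
    channel_labels: tuple[str, ...]
    fs: float
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time matrix")
        if self.samples.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain NaN or Inf")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class BandWindowedSignals:
    """Band-decomposed signals segmented into equal non-overlapping windows.

    The full-length filtered signal per band is retained (``filtered``)
    alongside the window boundaries so downstream phase estimation can
    operate on the whole signal and slice afterwards.
    """

    bands: dict[str, tuple[float, float]]
    filtered: dict[str, np.ndarray]  # band -> (n_channels, n_samples)
    window_s: float
    fs: float
    window_starts: np.ndarray  # sample index of each window start
    channel_labels: tuple[str, ...]
    subject_id: str | None = None
    group: str | None = None

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.fs))

    def windows(self, band: str) -> np.ndarray:
        """Stacked windows for one band, shape (L, n_channels, window_samples)."""
        x = self.filtered[band]
        w = self.window_samples
        return np.stack([x[:, s: s + w] for s in self.window_starts])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, format: str | None = None,
                   fs: float | None = None) -> Recording:
    """Read a recording from EDF or a delimited matrix file.

    ``format`` is inferred from the suffix when not given.  For matrix
    input the sampling rate comes from a JSON sidecar ``<path>.json``
    (key ``fs``) or the ``fs`` argument.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        from .edf import read_edf

        return read_edf(path)
    if format == "matrix":
        return _read_matrix(path, fs=fs)
    raise ValueError(f"unknown recording format: {format!r}")


def _read_matrix(path: Path, fs: float | None = None) -> Recording:
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_name(path.name + ".json")
    labels = None
    subject_id = group = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs", fs)
        labels = meta.get("labels")
        subject_id = meta.get("subject_id")
        group = meta.get("group")
    if fs is None:
        raise ValueError(
            f"sampling rate not found for matrix recording {path.name}: "
            "provide fs or a JSON sidecar with an 'fs' key"
        )
    with open(path) as fh:
        header = fh.readline().strip()
        if not header:
            raise ValueError(f"matrix file {path.name} is empty")
        file_labels = header.replace(",", "\t").split("\t")
        try:
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"malformed matrix data in {path.name}: {exc}") from exc
    if data.shape[0] != len(file_labels):
        raise ValueError(
            f"matrix file {path.name}: header lists {len(file_labels)} channels "
            f"but {data.shape[0]} rows follow"
        )
    return Recording(
        samples=data,
        channel_labels=tuple(labels or file_labels),
        fs=float(fs),
        subject_id=subject_id,
        group=group,
    )


def write_matrix(rec: Recording, path: str | Path) -> None:
    """Write a recording as a tab-delimited matrix plus JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.samples, delimiter="\t", fmt="%.6g")
    meta = {
        "fs": rec.fs,
        "labels": list(rec.channel_labels),
        "subject_id": rec.subject_id,
        "group": rec.group,
    }
    path.with_name(path.name + ".json").write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(rec: Recording, notch_hz: float = 50.0,
               highpass_hz: float = 1.0) -> Recording:
    """Notch out power-line interference and high-pass filter.

    The notch is a second-order IIR notch (Q = 30) applied forward-backward;
    the high-pass is a zero-phase Butterworth of order 4.  Length and
    channel order are unchanged.
    """
    nyq = rec.fs / 2.0
    if not 0 < notch_hz < nyq:
        raise ValueError(f"notch frequency {notch_hz} Hz outside (0, {nyq}) Hz")
    if not 0 < highpass_hz < nyq:
        raise ValueError(f"high-pass edge {highpass_hz} Hz outside (0, {nyq}) Hz")
    b, a = sps.iirnotch(notch_hz, _NOTCH_Q, fs=rec.fs)
    x = sps.filtfilt(b, a, rec.samples, axis=-1)
    sos = sps.butter(_FILTER_ORDER, highpass_hz, btype="highpass",
                     fs=rec.fs, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=-1)
    return replace(rec, samples=x)


def band_window(rec: Recording,
                bands: dict[str, tuple[float, float]] | None = None,
                window_s: float = 2.0,
                edge_trim_s: float = 0.0) -> BandWindowedSignals:
    """Zero-phase Butterworth band decomposition plus windowing.

    Filters are applied to the full-length signal; windows are
    ``window_s``-second non-overlapping segments with identical boundaries
    across bands, the trailing partial window discarded.  ``edge_trim_s``
    optionally excludes that much signal at each end from windowing (to
    drop filter/analytic-transform edge artifacts); it defaults to 0 so a
    60 s recording yields exactly 30 two-second windows.
    """
    bands = dict(bands or DEFAULT_BANDS)
    nyq = rec.fs / 2.0
    for name, (lo, hi) in bands.items():
        if not 0 < lo < hi < nyq:
            raise ValueError(
                f"band {name!r} ({lo}-{hi} Hz) outside (0, {nyq}) Hz at "
                f"fs={rec.fs} Hz"
            )
    usable = rec.duration - 2.0 * edge_trim_s
    n_win = int(math.floor(usable / window_s + 1e-9))
    if n_win < 2:
        raise ValueError(
            f"recording of {rec.duration:.3g} s yields {n_win} windows of "
            f"{window_s} s; at least 2 are required"
        )
    w = int(round(window_s * rec.fs))
    offset = int(round(edge_trim_s * rec.fs))
    starts = offset + w * np.arange(n_win)
    filtered: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands.items():
        sos = sps.butter(_FILTER_ORDER, (lo, hi), btype="bandpass",
                         fs=rec.fs, output="sos")
        filtered[name] = sps.sosfiltfilt(sos, rec.samples, axis=-1)
    return BandWindowedSignals(
        bands=bands,
        filtered=filtered,
        window_s=window_s,
        fs=rec.fs,
        window_starts=starts,
        channel_labels=rec.channel_labels,
        subject_id=rec.subject_id,
        group=rec.group,
    )
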