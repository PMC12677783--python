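"""Phase-locking connectivity and multilayer network assembly.

Each 2-s window of each band yields one symmetric weighted adjacency
matrix of pairwise phase locking values (PLV); the ordered stack of
window matrices is the subject's multilayer network for that band.
Phases come from the analytic signal of the *full-length* band-filtered
channel, sliced into windows afterwards, which avoids per-window Gibbs
edge effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from .signal_io import BandWindowedSignals

__all__ = [
    "MultilayerNetwork",
    "instantaneous_phase",
    "plv",
    "plv_matrix",
    "build_multilayer",
]


@dataclass
class MultilayerNetwork:
    """Ordered stack of L symmetric weighted adjacency matrices.

    Inter-layer identity coupling is implicit in the shared node order;
    the coupling weight enters only in community detection.
    """

    layers: np.ndarray  # (L, N, N)
    node_labels: tuple[str, ...]
    band: str | None = None
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3 or self.layers.shape[1] != self.layers.shape[2]:
            raise ValueError("layers must have shape (L, N, N)")
        if self.layers.shape[0] < 2:
            raise ValueError("a multilayer network needs at least 2 layers")
        if not np.isfinite(self.layers).all():
            raise ValueError("layer weights contain NaN or Inf")
        if (self.layers < 0).any():
            raise ValueError("layer weights must be non-negative")
        if not np.allclose(self.layers, self.layers.transpose(0, 2, 1)):
            raise ValueError("every layer must be symmetric")
        diag = self.layers[:, np.arange(self.layers.shape[1]),
                           np.arange(self.layers.shape[1])]
        if not np.allclose(diag, 0.0):
            raise ValueError("layer diagonals must be zero")
        self.node_labels = tuple(str(c) for c in self.node_labels)
        if len(self.node_labels) != self.layers.shape[1]:
            raise ValueError("node_labels length must match layer size")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]

    def save(self, path: str | Path) -> None:
        """Write layers as a text container (one matrix block per layer)
        plus a JSON metadata sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            for t in range(self.n_layers):
                np.savetxt(fh, self.layers[t], delimiter="\t", fmt="%.8g")
                fh.write("\n")
        meta = {
            "node_labels": list(self.node_labels),
            "band": self.band,
            "subject_id": self.subject_id,
            "group": self.group,
            "n_layers": self.n_layers,
        }
        path.with_name(path.name + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "MultilayerNetwork":
        path = Path(path)
        meta = json.loads(path.with_name(path.name + ".json").read_text())
        blocks = [b for b in path.read_text().split("\n\n") if b.strip()]
        layers = np.stack([
            np.array([[float(v) for v in line.split("\t")]
                      for line in b.strip().splitlines()])
            for b in blocks
        ])
        return cls(layers=layers, node_labels=tuple(meta["node_labels"]),
                   band=meta.get("band"), subject_id=meta.get("subject_id"),
                   group=meta.get("group"))


def instantaneous_phase(segment: np.ndarray) -> np.ndarray:
    """Analytic-signal phase of each channel, wrapped to (-pi, pi].

    ``segment`` is a channels x samples array, assumed band-limited.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim == 1:
        segment = segment[None, :]
    power = np.abs(segment).max(axis=-1)
    if (power == 0).any():
        bad = int(np.argmax(power == 0))
        raise ValueError(f"channel {bad} is identically zero; phase undefined")
    return np.angle(hilbert(segment, axis=-1))


def plv(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase locking value: |mean unit phasor of the phase difference|."""
    phase_x = np.asarray(phase_x, dtype=float).ravel()
    phase_y = np.asarray(phase_y, dtype=float).ravel()
    if phase_x.shape != phase_y.shape:
        raise ValueError(
            f"phase series lengths differ: {phase_x.size} vs {phase_y.size}"
        )
    if phase_x.size < 2:
        raise ValueError("phase series must have length >= 2")
    return float(np.abs(np.mean(np.exp(1j * (phase_x - phase_y)))))


def plv_matrix(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLV of a channels x samples phase array (vectorized)."""
    z = np.exp(1j * np.asarray(phases, dtype=float))
    m = np.abs(z @ z.conj().T) / phases.shape[-1]
    m = np.clip((m + m.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(m, 0.0)
    return m


def build_multilayer(bws: BandWindowedSignals, band: str) -> MultilayerNetwork:
    """Assemble the PLV multilayer network for one band.

    Layer t is the pairwise PLV matrix of window t; node order equals
    channel order; weights stay fully weighted (no thresholding).
    """
    if band not in bws.filtered:
        raise KeyError(f"band {band!r} not present; have {sorted(bws.filtered)}")
    phases = instantaneous_phase(bws.filtered[band])
    w = bws.window_samples
    layers = np.stack([
        plv_matrix(phases[:, s: s + w]) for s in bws.window_starts
    ])
    return MultilayerNetwork(
        layers=layers,
        node_labels=bws.channel_labels,
        band=band,
        subject_id=bws.subject_id,
        group=bws.group,
    )
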