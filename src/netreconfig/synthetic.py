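"""Synthetic ground-truth generators.

Two levels of synthetic input:

* planted multilayer networks (stochastic block layers following a
  community schedule) with the matching ground-truth partition sequence;
* multichannel oscillatory recordings in which channels sharing a
  community carry a common band-limited carrier (common phase, slight
  per-channel amplitude jitter) plus independent Gaussian noise, with
  membership switching at scheduled, window-aligned times.

Cohorts of two or more groups get per-group effects: a coupling
multiplier scaling the common oscillation amplitude (lower coupling ->
noisier phase locking -> degraded coordinated switching downstream) and
a switching-rate multiplier thinning or densifying scheduled switches.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectivity import MultilayerNetwork
from .dynamic_communities import PartitionSequence, modularity
from .signal_io import CHANNELS_1020, DEFAULT_BANDS, Recording, write_matrix

__all__ = [
    "CommunitySchedule",
    "GroupEffect",
    "CohortSpec",
    "random_schedule",
    "generate_planted_multilayer",
    "generate_recording",
    "generate_cohort",
    "write_cohort",
]


@dataclass
class CommunitySchedule:
    """Scheduled community membership: epochs of constant partition.

    Epochs are ``(start_layer, end_layer, labels)`` with 1-based
    inclusive layer ranges that tile ``1..n_layers`` without gaps or
    overlap; labels are small integers >= 1, one per node.
    """

    n_nodes: int
    epochs: list[tuple[int, int, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule needs at least one epoch")
        self.epochs = [
            (int(s), int(e), np.asarray(lab, dtype=int))
            for s, e, lab in self.epochs
        ]
        expected_start = 1
        for s, e, lab in self.epochs:
            if s != expected_start or e < s:
                raise ValueError(
                    f"epochs must tile layers contiguously; got ({s}, {e}) "
                    f"where start {expected_start} was expected"
                )
            if lab.shape != (self.n_nodes,):
                raise ValueError("each epoch needs one label per node")
            if lab.min() < 1:
                raise ValueError("community labels must be >= 1")
            expected_start = e + 1

    @property
    def n_layers(self) -> int:
        return self.epochs[-1][1]

    def partition_at(self, layer: int) -> np.ndarray:
        """Planted partition of a 1-based layer index."""
        for s, e, lab in self.epochs:
            if s <= layer <= e:
                return lab
        raise IndexError(f"layer {layer} outside schedule 1..{self.n_layers}")

    def expand(self) -> np.ndarray:
        """Full N x L label matrix."""
        return np.column_stack([
            self.partition_at(t) for t in range(1, self.n_layers + 1)
        ])


@dataclass
class GroupEffect:
    """Per-group multipliers applied to the generative model."""

    coupling: float = 1.0        # scales the common-oscillation amplitude
    switching_rate: float = 1.0  # scales how many scheduled switches apply

    def __post_init__(self) -> None:
        if not 0 < self.coupling <= 1:
            raise ValueError("coupling multiplier must lie in (0, 1]")
        if self.switching_rate < 0:
            raise ValueError("switching-rate multiplier must be >= 0")


@dataclass
class CohortSpec:
    """Configuration of a synthetic two-or-more-group cohort."""

    n_subjects_per_group: int
    group_effects: dict[str, GroupEffect]
    sampling_rate: float = 500.0
    duration: float = 60.0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    # calibrated so a coupling-1.0 group sits above the community-detection
    # SNR threshold while coupling ~0.5 falls below it (planted deficit)
    noise_sd: float = 5.0
    window_s: float = 2.0
    amplitude: float = 1.0
    amp_jitter: float = 0.1
    phase_walk_sd: float = 0.02       # rad / sample, common per community
    freq_offset_frac: float = 0.5     # community carrier span, x bandwidth
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * sampling_rate must be an integer")
        edges = sorted(self.bands.values())
        for (lo, hi), (lo2, _hi2) in zip(edges, edges[1:]):
            if not lo < hi <= lo2:
                raise ValueError("bands must be ordered and non-overlapping")
        for lo, hi in self.bands.values():
            if not 0 < lo < hi < self.sampling_rate / 2:
                raise ValueError(
                    f"band ({lo}, {hi}) Hz outside (0, Nyquist) at "
                    f"fs={self.sampling_rate}"
                )


def random_schedule(n_nodes: int = 19, n_layers: int = 30,
                    n_epochs: int = 3, n_communities: int = 3,
                    seed: int | np.random.Generator | None = None,
                    ) -> CommunitySchedule:
    """Random epoch-tiled schedule with guaranteed changes between epochs.

    Epochs split ``1..n_layers`` evenly; the first partition is a balanced
    random split into ``n_communities``.  At each epoch boundary a
    coherent block (about half of one source community, at least 2 nodes)
    moves together into a single different community — a planted
    coordinated co-transition — so consecutive epochs always differ.
    """
    rng = np.random.default_rng(seed)
    if n_epochs > n_layers:
        raise ValueError("more epochs than layers")
    if n_communities < 2:
        raise ValueError("need at least 2 communities to schedule switches")
    bounds = np.linspace(0, n_layers, n_epochs + 1).astype(int)
    labels = 1 + (rng.permutation(n_nodes) % n_communities)
    epochs = []
    for e in range(n_epochs):
        if e > 0:
            labels = labels.copy()
            sizes = {c: int((labels == c).sum())
                     for c in range(1, n_communities + 1)}
            donors = [c for c, n in sizes.items() if n >= 3]
            src = int(rng.choice(donors if donors
                                 else [max(sizes, key=sizes.get)]))
            members = np.flatnonzero(labels == src)
            n_move = max(2, len(members) // 2)
            block = rng.choice(members, size=min(n_move, len(members)),
                               replace=False)
            dst = int(rng.choice([c for c in range(1, n_communities + 1)
                                  if c != src]))
            labels[block] = dst
        epochs.append((bounds[e] + 1, bounds[e + 1], labels))
    return CommunitySchedule(n_nodes=n_nodes, epochs=epochs)


# ---------------------------------------------------------------------------
# Planted multilayer networks
# ---------------------------------------------------------------------------

def generate_planted_multilayer(schedule: CommunitySchedule,
                                p_in: float, p_out: float,
                                weight_in: float, weight_out: float,
                                n_layers: int,
                                seed: int | np.random.Generator | None = None,
                                ) -> tuple[MultilayerNetwork, PartitionSequence]:
    """Stochastic-block multilayer network following a schedule.

    Within-community node pairs get an edge of weight ``weight_in`` with
    probability ``p_in``; between-community pairs ``weight_out`` with
    probability ``p_out``.  Weights live in [0, 1] so the result obeys
    the same invariants as a PLV network.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if not (0 <= weight_out < weight_in <= 1):
        raise ValueError("need 0 <= weight_out < weight_in <= 1")
    if schedule.n_layers != n_layers:
        raise ValueError(
            f"schedule covers {schedule.n_layers} layers, asked for {n_layers}"
        )
    rng = np.random.default_rng(seed)
    N = schedule.n_nodes
    iu = np.triu_indices(N, k=1)
    layers = np.zeros((n_layers, N, N))
    for t in range(n_layers):
        part = schedule.partition_at(t + 1)
        same = part[iu[0]] == part[iu[1]]
        p = np.where(same, p_in, p_out)
        w = np.where(same, weight_in, weight_out)
        vals = (rng.random(len(same)) < p) * w
        W = np.zeros((N, N))
        W[iu] = vals
        layers[t] = W + W.T
    truth = schedule.expand()
    quality = np.array([
        modularity(layers[t], truth[:, t]) if layers[t].sum() > 0 else 0.0
        for t in range(n_layers)
    ])
    net = MultilayerNetwork(
        layers=layers,
        node_labels=tuple(f"n{i}" for i in range(N)),
        band="synthetic",
    )
    seq = PartitionSequence(
        labels=truth,
        layer_valid=np.ones(n_layers, dtype=bool),
        quality=quality,
        params={"planted": True, "p_in": p_in, "p_out": p_out},
        aligned=True,
        node_labels=net.node_labels,
    )
    return net, seq


# ---------------------------------------------------------------------------
# Oscillatory recordings
# ---------------------------------------------------------------------------

def _subject_schedule(template: CommunitySchedule, rate: float,
                      rng: np.random.Generator) -> CommunitySchedule:
    """Apply a switching-rate multiplier to a template schedule.

    Each scheduled switch is kept independently with probability
    ``min(rate, 1)``; dropping a switch merges the epoch with its
    predecessor.  ``rate >= 1`` keeps every switch.
    """
    if rate >= 1.0 or len(template.epochs) == 1:
        return template
    epochs: list[tuple[int, int, np.ndarray]] = [template.epochs[0]]
    for s, e, lab in template.epochs[1:]:
        if rng.random() < rate:
            epochs.append((s, e, lab))
        else:
            ps, _pe, plab = epochs[-1]
            epochs[-1] = (ps, e, plab)
    return CommunitySchedule(n_nodes=template.n_nodes, epochs=epochs)


def generate_recording(schedule: CommunitySchedule, spec: CohortSpec,
                       subject_id: str, group: str,
                       rng: np.random.Generator | None = None) -> Recording:
    """One multichannel oscillatory recording realizing a schedule.

    Per band and epoch, each community gets a common carrier: frequency
    at the band's geometric mean plus a per-community offset (a fraction
    of the bandwidth, so distinct communities decohere within a window),
    a common slow phase random walk, and a random initial phase.  Every
    member channel plays that carrier with amplitude
    ``amplitude * (1 + jitter) * coupling``; independent white Gaussian
    noise of sd ``noise_sd`` is added per channel.
    """
    if group not in spec.group_effects:
        raise ValueError(f"group {group!r} not in spec.group_effects")
    rng = rng or np.random.default_rng(spec.seed)
    effect = spec.group_effects[group]
    N = schedule.n_nodes
    fs = spec.sampling_rate
    n_samples = int(round(spec.duration * fs))
    win = int(round(spec.window_s * fs))
    x = np.zeros((N, n_samples))
    t_idx = np.arange(n_samples) / fs

    ref_width = float(np.median([hi - lo for lo, hi in spec.bands.values()]))
    for lo, hi in spec.bands.values():
        f0 = math.sqrt(lo * hi)
        width = hi - lo
        # amplitude ~ sqrt(bandwidth) equalizes the in-band SNR across
        # bands (white noise power in a band grows linearly with width)
        amp = (spec.amplitude * math.sqrt(width / ref_width) * effect.coupling
               * (1.0 + spec.amp_jitter * rng.uniform(-1, 1, size=N)))
        for s, e, lab in schedule.epochs:
            i0 = (s - 1) * win
            i1 = min(e * win, n_samples)
            if i0 >= n_samples:
                break
            if e == schedule.n_layers:
                i1 = n_samples  # final epoch persists to the end
            seg = slice(i0, i1)
            length = i1 - i0
            comms = np.unique(lab)
            # evenly spaced community carriers (random assignment, small
            # jitter): distinct communities decohere within every window
            # instead of colliding by chance
            span = spec.freq_offset_frac * width
            if len(comms) > 1:
                grid = np.linspace(-span / 2, span / 2, len(comms))
            else:
                grid = np.zeros(1)
            grid = grid[rng.permutation(len(comms))]
            jitter_scale = (span / (4 * len(comms))) if len(comms) > 1 else 0.0
            for ci, c in enumerate(comms):
                members = np.flatnonzero(lab == c)
                off = grid[ci] + rng.uniform(-1, 1) * jitter_scale
                f = min(max(lo, f0 + off), hi)
                walk = np.cumsum(rng.normal(0.0, spec.phase_walk_sd, length))
                theta = 2 * np.pi * f * t_idx[seg] + rng.uniform(0, 2 * np.pi) + walk
                x[members, seg] += amp[members, None] * np.cos(theta)[None, :]
    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, size=x.shape)
    labels = (CHANNELS_1020 if N == len(CHANNELS_1020)
              else tuple(f"ch{i}" for i in range(N)))
    return Recording(samples=x, channel_labels=labels, fs=fs,
                     subject_id=subject_id, group=group)


def generate_cohort(spec: CohortSpec, schedule_template: CommunitySchedule,
                    ) -> list[tuple[Recording, str]]:
    """Independent per-subject recordings for every group in the spec."""
    if len(spec.group_effects) < 2:
        raise ValueError("a cohort needs at least 2 groups")
    if spec.n_subjects_per_group < 2:
        raise ValueError("a cohort needs at least 2 subjects per group")
    root = np.random.SeedSequence(spec.seed)
    out = []
    for g_idx, group in enumerate(spec.group_effects):
        effect = spec.group_effects[group]
        for s_idx in range(spec.n_subjects_per_group):
            child = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(g_idx, s_idx))
            rng = np.random.default_rng(child)
            sched = _subject_schedule(schedule_template,
                                      effect.switching_rate, rng)
            rec = generate_recording(
                sched, spec, subject_id=f"{group}{s_idx:03d}", group=group,
                rng=rng)
            out.append((rec, group))
    return out


def write_cohort(cohort: list[tuple[Recording, str]],
                 schedule: CommunitySchedule,
                 out_dir: str | Path,
                 fmt: str = "matrix",
                 seed: int | None = None) -> Path:
    """Write recordings, ground-truth partitions and a manifest CSV.

    Returns the manifest path.  ``fmt`` selects ``matrix`` (delimited
    text + JSON sidecar) or ``edf``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = schedule.expand()
    with open(out_dir / "ground_truth_partitions.tsv", "w") as fh:
        fh.write("node\t" + "\t".join(
            f"layer{t}" for t in range(truth.shape[1])) + "\n")
        for i in range(truth.shape[0]):
            fh.write(f"n{i}\t" + "\t".join(str(v) for v in truth[i]) + "\n")
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "path", "seed"])
        for rec, group in cohort:
            if fmt == "edf":
                from .edf import write_edf

                fname = f"{rec.subject_id}.edf"
                write_edf(rec, out_dir / fname)
            else:
                fname = f"{rec.subject_id}.tsv"
                write_matrix(rec, out_dir / fname)
            writer.writerow([rec.subject_id, group, fname,
                             "" if seed is None else seed])
    return manifest
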