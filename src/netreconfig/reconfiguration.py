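"""Network reconfiguration metrics from a partition sequence.

A node "moves" at a transition when its aligned community id changes
between two consecutive *valid* layers.  A move is *cohesive* when at
least one other node moves into the same target community at the same
transition, and *disjoint* (solo) otherwise, so per node

    flexibility  f_i = moves_i / T
    disjointedness d_i = solo moves_i / T
    cohesive fraction c_i = partnered moves_i / T        (f = c + d)

with T the number of used transitions (both endpoint layers valid).
The cohesion matrix counts pairwise simultaneous co-transitions into a
shared community; cohesion strength s_i is a node's count row-sum / T.
Community-level metrics are node-set means: community cohesion = mean s,
community disjointedness = mean d, community change = their sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamic_communities import PartitionSequence

__all__ = [
    "TransitionRecord",
    "NodeMetrics",
    "CohesionMatrix",
    "CommunityMetrics",
    "classify_transitions",
    "node_metrics",
    "cohesion",
    "community_metrics",
    "subject_metrics",
]


@dataclass
class TransitionRecord:
    """Per-node change record for one used transition (layers t -> t+1)."""

    t: int                       # transition index (from layer t to t+1)
    moved: np.ndarray            # (N,) bool
    target: np.ndarray           # (N,) community id in layer t+1
    partners: dict[int, frozenset[int]]  # node -> co-moving nodes, same target


@dataclass
class NodeMetrics:
    flexibility: np.ndarray
    disjointedness: np.ndarray
    cohesive_fraction: np.ndarray
    n_transitions_used: int


@dataclass
class CohesionMatrix:
    """Pairwise co-transition counts (symmetric, zero diagonal)."""

    counts: np.ndarray
    n_transitions_used: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any() or not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric and non-negative")
        if np.diagonal(self.counts).any():
            raise ValueError("counts diagonal must be zero")


@dataclass
class CommunityMetrics:
    cohesion: float
    disjointedness: float

    @property
    def change(self) -> float:
        return self.cohesion + self.disjointedness


def _used_transitions(P: PartitionSequence) -> list[int]:
    return [t for t in range(P.n_layers - 1)
            if P.layer_valid[t] and P.layer_valid[t + 1]]


def classify_transitions(P: PartitionSequence) -> list[TransitionRecord]:
    """Per-transition change records over the valid consecutive layers."""
    if not P.aligned:
        raise ValueError("labels must be aligned (run align_labels) first")
    used = _used_transitions(P)
    if not used:
        raise ValueError("no valid consecutive layer pair: metrics undefined")
    records = []
    for t in used:
        a, b = P.labels[:, t], P.labels[:, t + 1]
        moved = a != b
        partners: dict[int, frozenset[int]] = {}
        movers = np.flatnonzero(moved)
        for i in movers:
            same = movers[(P.labels[movers, t + 1] == b[i]) & (movers != i)]
            partners[int(i)] = frozenset(int(j) for j in same)
        records.append(TransitionRecord(t=t, moved=moved, target=b.copy(),
                                        partners=partners))
    return records


def node_metrics(P: PartitionSequence) -> NodeMetrics:
    """Flexibility, disjointedness and cohesive fraction per node."""
    records = classify_transitions(P)
    T = len(records)
    N = P.n_nodes
    moves = np.zeros(N)
    solo = np.zeros(N)
    for rec in records:
        for i in np.flatnonzero(rec.moved):
            moves[i] += 1
            if not rec.partners[int(i)]:
                solo[i] += 1
    return NodeMetrics(
        flexibility=moves / T,
        disjointedness=solo / T,
        cohesive_fraction=(moves - solo) / T,
        n_transitions_used=T,
    )


def cohesion(P: PartitionSequence) -> tuple[CohesionMatrix, np.ndarray]:
    """Cohesion matrix and per-node cohesion strength s_i = row sum / T."""
    records = classify_transitions(P)
    T = len(records)
    N = P.n_nodes
    counts = np.zeros((N, N), dtype=int)
    for rec in records:
        for i, mates in rec.partners.items():
            for j in mates:
                counts[i, j] += 1
    strength = counts.sum(axis=1) / T
    return CohesionMatrix(counts=counts, n_transitions_used=T), strength


def community_metrics(strength: np.ndarray,
                      disjointedness: np.ndarray) -> CommunityMetrics:
    """Node-set means: community cohesion, disjointedness (change = sum)."""
    return CommunityMetrics(
        cohesion=float(np.mean(strength)),
        disjointedness=float(np.mean(disjointedness)),
    )


def subject_metrics(P: PartitionSequence) -> dict:
    """All reconfiguration metrics of one partition sequence.

    Returns a dict with per-node arrays (``flexibility``,
    ``disjointedness``, ``cohesive_fraction``, ``cohesion_strength``,
    ``node_change``), the ``cohesion_matrix``, and scalar community-level
    values (``community_cohesion``, ``community_disjointedness``,
    ``community_change``).
    """
    nm = node_metrics(P)
    cm, strength = cohesion(P)
    comm = community_metrics(strength, nm.disjointedness)
    return {
        "flexibility": nm.flexibility,
        "disjointedness": nm.disjointedness,
        "cohesive_fraction": nm.cohesive_fraction,
        "cohesion_strength": strength,
        "node_change": strength + nm.disjointedness,
        "cohesion_matrix": cm,
        "n_transitions_used": nm.n_transitions_used,
        "community_cohesion": comm.cohesion,
        "community_disjointedness": comm.disjointedness,
        "community_change": comm.change,
    }
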