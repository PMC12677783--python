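"""Shared fixtures and independent oracles.

The expensive end-to-end synthetic cohort (2 x 20 subjects, 60 s @
500 Hz, patient coupling 0.5) is computed once per session and shared
by the synthetic-module tests and the acceptance suite.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from netreconfig.group_analysis import benchmark_classifiers
from netreconfig.pipeline import analyze_cohort, feature_matrix
from netreconfig.synthetic import (CohortSpec, GroupEffect, generate_cohort,
                                   random_schedule)

# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive; never call package internals)
# ---------------------------------------------------------------------------


def iter_set_partitions(items: list):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield []
        return
    codes = [0] * n
    while True:
        groups: dict[int, list] = {}
        for item, c in zip(items, codes):
            groups.setdefault(c, []).append(item)
        yield list(groups.values())
        # next restricted-growth string
        for i in range(n - 1, 0, -1):
            if codes[i] <= max(codes[:i]):
                codes[i] += 1
                for j in range(i + 1, n):
                    codes[j] = 0
                break
        else:
            return


def modularity_oracle(W: np.ndarray, labels: np.ndarray,
                      gamma: float = 1.0) -> float:
    """Literal double-sum weighted modularity (independent of the package)."""
    W = np.asarray(W, dtype=float)
    n = len(W)
    k = W.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += W[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def best_partition_oracle(W: np.ndarray, gamma: float = 1.0) -> float:
    """Exhaustive-search maximum modularity over all partitions (n <= 8)."""
    n = len(W)
    assert n <= 8, "exhaustive search limited to n <= 8"
    best = -np.inf
    for parts in iter_set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, group in enumerate(parts):
            labels[list(group)] = c
        best = max(best, modularity_oracle(W, labels, gamma))
    return best


def reconfig_oracle(labels: np.ndarray, layer_valid: np.ndarray):
    """Brute-force per-(node, transition) reconfiguration metrics.

    Independent enumeration: for every transition between two valid
    consecutive layers and every node, decide moved / solo / partnered
    and count pairwise co-transitions into a shared target.
    """
    N, L = labels.shape
    used = [t for t in range(L - 1) if layer_valid[t] and layer_valid[t + 1]]
    T = len(used)
    moves = np.zeros(N)
    solo = np.zeros(N)
    counts = np.zeros((N, N))
    for t in used:
        for i in range(N):
            if labels[i, t] == labels[i, t + 1]:
                continue
            moves[i] += 1
            partnered = False
            for j in range(N):
                if j == i:
                    continue
                if (labels[j, t] != labels[j, t + 1]
                        and labels[j, t + 1] == labels[i, t + 1]):
                    partnered = True
                    counts[i, j] += 1
            if not partnered:
                solo[i] += 1
    return {
        "T": T,
        "flexibility": moves / T,
        "disjointedness": solo / T,
        "cohesive_fraction": (moves - solo) / T,
        "counts": counts,
        "strength": counts.sum(axis=1) / T,
    }


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

#: scaled-down pipeline settings used by Monte-Carlo style tests
FAST_PIPELINE = dict(n_surrogates=20, n_init=3)


@pytest.fixture(scope="session")
def cohort_run():
    """Full end-to-end run on the reference synthetic cohort.

    2 groups x 20 subjects, 19 channels, 60 s @ 500 Hz, patient coupling
    0.5.  Community detection runs with 50 surrogates and 10 consensus
    initializations (down from the 100/100 defaults purely for runtime;
    the validation decision rule is unchanged).
    """
    spec = CohortSpec(
        n_subjects_per_group=20,
        group_effects={"control": GroupEffect(coupling=1.0),
                       "patient": GroupEffect(coupling=0.5)},
        duration=60.0,
        sampling_rate=500.0,
        seed=20,
    )
    schedule = random_schedule(n_nodes=19, n_layers=30, n_epochs=6,
                               n_communities=3, seed=21)
    cohort = generate_cohort(spec, schedule)
    table = analyze_cohort(cohort, seed=22, n_surrogates=50, n_init=10)
    return {"spec": spec, "schedule": schedule, "cohort": cohort,
            "table": table}


@pytest.fixture(scope="session")
def cohort_classification(cohort_run):
    """Six-classifier benchmark on the reference cohort (100 repetitions)."""
    X, groups, names = feature_matrix(cohort_run["table"],
                                      metric="cohesion_strength")
    report = benchmark_classifiers(X, groups, target_group="patient",
                                   n_repetitions=100, seed=23,
                                   feature_description=f"{len(names)} features")
    return report
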