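"""End-to-end orchestration: recordings -> tidy reconfiguration table.

Ties the stage modules together for cohorts of recordings and exposes
helpers to build classifier feature matrices from the tidy table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import build_multilayer
from .dynamic_communities import detect_communities
from .reconfiguration import subject_metrics
from .signal_io import DEFAULT_BANDS, Recording, band_window, preprocess, read_recording

__all__ = [
    "analyze_recording",
    "analyze_cohort",
    "load_cohort",
    "feature_matrix",
    "NODE_METRICS",
]

logger = logging.getLogger(__name__)

#: node-level metrics emitted into the tidy table, one row per site
NODE_METRICS = ("flexibility", "disjointedness", "cohesive_fraction",
                "cohesion_strength", "node_change")
#: community-level metrics, one row per subject x band (site = "global")
COMMUNITY_METRICS = ("community_cohesion", "community_disjointedness",
                     "community_change")


def analyze_recording(rec: Recording,
                      bands: dict[str, tuple[float, float]] | None = None,
                      window_s: float = 2.0,
                      notch_hz: float = 50.0,
                      highpass_hz: float = 1.0,
                      gamma: float = 1.0,
                      omega: float = 1.0,
                      n_surrogates: int = 100,
                      n_init: int = 100,
                      alpha: float = 0.05,
                      seed: int | np.random.Generator | None = None,
                      skip_preprocess: bool = False) -> pd.DataFrame:
    """Full single-subject pipeline; returns tidy metric rows.

    preprocess -> band_window -> per-band PLV multilayer ->
    validated consensus communities -> reconfiguration metrics.
    """
    bands = dict(bands or DEFAULT_BANDS)
    rng = np.random.default_rng(seed)
    if not skip_preprocess:
        rec = preprocess(rec, notch_hz=notch_hz, highpass_hz=highpass_hz)
    bws = band_window(rec, bands=bands, window_s=window_s)
    rows = []
    for band in bands:
        net = build_multilayer(bws, band)
        seq = detect_communities(net, gamma=gamma, omega=omega,
                                 n_surrogates=n_surrogates, n_init=n_init,
                                 alpha=alpha, seed=rng)
        try:
            m = subject_metrics(seq)
        except ValueError as exc:
            logger.warning("subject %s band %s: %s; skipping",
                           rec.subject_id, band, exc)
            continue
        for metric in NODE_METRICS:
            for i, site in enumerate(net.node_labels):
                rows.append({
                    "subject_id": rec.subject_id, "group": rec.group,
                    "band": band, "site": site, "metric": metric,
                    "value": float(m[metric][i]),
                })
        for metric in COMMUNITY_METRICS:
            rows.append({
                "subject_id": rec.subject_id, "group": rec.group,
                "band": band, "site": "global", "metric": metric,
                "value": float(m[metric]),
            })
    return pd.DataFrame(rows)


def analyze_cohort(cohort: list[tuple[Recording, str]],
                   seed: int | None = None,
                   **kwargs) -> pd.DataFrame:
    """Run :func:`analyze_recording` over a cohort (deterministic per seed)."""
    frames = []
    root = np.random.SeedSequence(seed)
    for idx, (rec, group) in enumerate(cohort):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(idx,)))
        logger.info("analyzing subject %s (%s), %d/%d",
                    rec.subject_id, group, idx + 1, len(cohort))
        df = analyze_recording(rec, seed=rng, **kwargs)
        if rec.group is None:
            df["group"] = group
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def load_cohort(manifest_path: str | Path) -> list[tuple[Recording, str]]:
    """Read a cohort from a manifest CSV (subject_id, group, path, seed)."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "path"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    out = []
    for _, row in table.iterrows():
        rec = read_recording(manifest_path.parent / row["path"])
        rec.subject_id = str(row["subject_id"])
        rec.group = str(row["group"])
        out.append((rec, str(row["group"])))
    return out


def feature_matrix(table: pd.DataFrame, metric: str = "cohesion_strength",
                   ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Subjects x (site x band) feature matrix for one node-level metric.

    Returns ``(X, group_labels, feature_names)``; with 19 sites and 5
    bands this is the 95-dimensional cohesion-strength feature vector.
    Subject x band cells absent from the table (no validated layer pair,
    hence no measurable reconfiguration) are imputed as 0.
    """
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} not in table")
    wide = sub.pivot_table(index=["subject_id", "group"],
                           columns=["band", "site"], values="value",
                           sort=False)
    n_missing = int(wide.isna().to_numpy().sum())
    if n_missing:
        logger.info("feature_matrix: imputing %d absent cells as 0",
                    n_missing)
        wide = wide.fillna(0.0)
    X = wide.to_numpy()
    groups = np.array([g for _s, g in wide.index])
    names = [f"{band}:{site}" for band, site in wide.columns]
    return X, groups, names
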