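"""Group-difference statistics and classifier benchmarking.

Kruskal-Wallis omnibus per metric x band x site, Dunn rank post-hoc
pairwise tests with Benjamini-Hochberg FDR correction (family = all
group pairs x sites within one metric x band), and a repeated matched
subsampling benchmark of six standard classifiers on per-subject
feature vectors (default: cohesion strength at every site x band).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupStatsResult",
    "ClassificationReport",
    "kruskal_wallis",
    "dunn_pairwise",
    "posthoc_fdr",
    "site_band_stats",
    "significance_matrix",
    "benchmark_classifiers",
    "DEFAULT_CLASSIFIERS",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupStatsResult:
    """Tidy omnibus + post-hoc results.

    ``omnibus``: metric, band, site, H, p.
    ``pairwise``: metric, band, site, group_a, group_b, p, q, significant.
    """

    omnibus: pd.DataFrame
    pairwise: pd.DataFrame
    alpha: float = 0.05


@dataclass
class ClassificationReport:
    """Mean +/- sd scores per classifier over repeated subsampling."""

    scores: pd.DataFrame  # classifier, score, mean, sd
    target_group: str
    n_repetitions: int
    feature_description: str = ""
    seed: int | None = None

    def best(self, score: str = "accuracy") -> tuple[str, float]:
        df = self.scores[self.scores["score"] == score]
        row = df.loc[df["mean"].idxmax()]
        return str(row["classifier"]), float(row["mean"])


def kruskal_wallis(samples: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p.

    Degenerate input (all values identical) returns (0, 1) instead of
    raising, matching the no-evidence reading.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(len(s) < 1 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(s) for s in samples) < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def dunn_pairwise(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based z-tests for all group pairs (two-sided, raw p)."""
    names = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], float) for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    mean_ranks = {}
    start = 0
    for g in names:
        n_g = len(samples[g])
        mean_ranks[g] = ranks[start: start + n_g].mean()
        start += n_g
    rows = []
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    for a, b in itertools.combinations(names, 2):
        na, nb = len(samples[a]), len(samples[b])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    return pd.DataFrame(rows)


def posthoc_fdr(values: np.ndarray, groups: np.ndarray,
                alpha: float = 0.05) -> GroupStatsResult:
    """Omnibus + BH-corrected Dunn post-hoc for a single value family."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = {g: values[groups == g] for g in pd.unique(groups)}
    h, p = kruskal_wallis(list(samples.values()))
    omnibus = pd.DataFrame([{"metric": "value", "band": "", "site": "",
                             "H": h, "p": p}])
    pw = dunn_pairwise(samples)
    reject, q, _, _ = multipletests(pw["p"].to_numpy(), alpha=alpha,
                                    method="fdr_bh")
    pw = pw.assign(metric="value", band="", site="", q=q, significant=reject)
    return GroupStatsResult(omnibus=omnibus, pairwise=pw, alpha=alpha)


def site_band_stats(table: pd.DataFrame, metric: str,
                    alpha: float = 0.05) -> GroupStatsResult:
    """Per-site omnibus and post-hoc tests for one metric, all bands.

    ``table`` is tidy: subject_id, group, band, site, metric, value.
    The BH family is all group pairs x sites within each metric x band.
    """
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} not present in table")
    omni_rows = []
    pair_frames = []
    for band, band_df in sub.groupby("band", sort=False):
        band_pairs = []
        for site, site_df in band_df.groupby("site", sort=False):
            samples = {
                g: site_df.loc[site_df["group"] == g, "value"].to_numpy()
                for g in pd.unique(site_df["group"])
            }
            h, p = kruskal_wallis(list(samples.values()))
            omni_rows.append({"metric": metric, "band": band, "site": site,
                              "H": h, "p": p})
            pw = dunn_pairwise(samples)
            pw = pw.assign(metric=metric, band=band, site=site)
            band_pairs.append(pw)
        band_pw = pd.concat(band_pairs, ignore_index=True)
        reject, q, _, _ = multipletests(band_pw["p"].to_numpy(), alpha=alpha,
                                        method="fdr_bh")
        band_pw = band_pw.assign(q=q, significant=reject)
        pair_frames.append(band_pw)
    return GroupStatsResult(
        omnibus=pd.DataFrame(omni_rows),
        pairwise=pd.concat(pair_frames, ignore_index=True),
        alpha=alpha,
    )


def significance_matrix(result: GroupStatsResult, group_a: str,
                        group_b: str) -> pd.DataFrame:
    """0/1 site x band matrix of significant pairwise differences."""
    pw = result.pairwise
    sel = pw[((pw["group_a"] == group_a) & (pw["group_b"] == group_b))
             | ((pw["group_a"] == group_b) & (pw["group_b"] == group_a))]
    if sel.empty:
        raise ValueError(f"no pairwise results for {group_a} vs {group_b}")
    return (sel.assign(sig=sel["significant"].astype(int))
               .pivot_table(index="site", columns="band", values="sig",
                            aggfunc="max", sort=False))


# ---------------------------------------------------------------------------
# Classifier benchmarking
# ---------------------------------------------------------------------------

def DEFAULT_CLASSIFIERS(seed: int) -> dict:
    """The six benchmark classifiers (library defaults, seeded)."""
    return {
        "SVM (Gaussian)": SVC(kernel="rbf", random_state=seed),
        "Random Forest": RandomForestClassifier(random_state=seed),
        "Gradient Boosting": GradientBoostingClassifier(random_state=seed),
        "Multilayer Perceptron": MLPClassifier(random_state=seed,
                                               max_iter=500),
        "KNN": KNeighborsClassifier(),
        "Naive Bayes": GaussianNB(),
    }


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """z-score both sets using *training* statistics only."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def benchmark_classifiers(features: np.ndarray, labels: np.ndarray,
                          target_group: str,
                          n_repetitions: int = 1000,
                          test_fraction: float = 0.2,
                          classifiers: dict | None = None,
                          seed: int | None = None,
                          feature_description: str = "",
                          ) -> ClassificationReport:
    """Repeated matched-subsampling one-vs-rest benchmark.

    Per repetition: the test set is ``test_fraction`` of the target
    subjects plus an equal-sized random sample of non-target subjects;
    the training set is the remaining target subjects plus an
    equal-sized non-target sample disjoint from the test set.  Features
    are standardized with training statistics only.  Scores (accuracy,
    precision, recall, F1 for the target class) are averaged over
    repetitions.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    tgt = np.flatnonzero(y == target_group)
    rest = np.flatnonzero(y != target_group)
    if len(tgt) < 5:
        raise ValueError("target group needs >= 5 subjects")
    n_test_t = max(1, int(round(test_fraction * len(tgt))))
    if len(rest) < 2 * n_test_t:
        raise ValueError("non-target pool too small for matched sampling")
    rng = np.random.default_rng(seed)
    names = list((classifiers or DEFAULT_CLASSIFIERS(seed or 0)))
    records: dict[str, dict[str, list[float]]] = {
        name: {"accuracy": [], "precision": [], "recall": [], "f1": []}
        for name in names
    }
    rep = 0
    guard = 0
    while rep < n_repetitions:
        guard += 1
        if guard > 10 * n_repetitions:
            raise RuntimeError("too many degenerate repetitions")
        clf_map = classifiers or DEFAULT_CLASSIFIERS(int(rng.integers(2**31)))
        test_t = rng.choice(tgt, size=n_test_t, replace=False)
        test_r = rng.choice(rest, size=n_test_t, replace=False)
        train_t = np.setdiff1d(tgt, test_t)
        rest_pool = np.setdiff1d(rest, test_r)
        n_train_r = min(len(train_t), len(rest_pool))
        if n_train_r < 1 or len(train_t) < 1:
            logger.info("degenerate split resampled at repetition %d", rep)
            continue
        train_r = rng.choice(rest_pool, size=n_train_r, replace=False)
        tr = np.concatenate([train_t, train_r])
        te = np.concatenate([test_t, test_r])
        y_tr = (y[tr] == target_group).astype(int)
        y_te = (y[te] == target_group).astype(int)
        if len(np.unique(y_tr)) < 2:
            logger.info("single-class training set resampled at rep %d", rep)
            continue
        X_tr, X_te = _standardize(X[tr], X[te])
        for name in names:
            clf = clf_map[name]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X_tr, y_tr)
            pred = clf.predict(X_te)
            records[name]["accuracy"].append(accuracy_score(y_te, pred))
            records[name]["precision"].append(
                precision_score(y_te, pred, zero_division=0))
            records[name]["recall"].append(
                recall_score(y_te, pred, zero_division=0))
            records[name]["f1"].append(f1_score(y_te, pred, zero_division=0))
        rep += 1
    rows = []
    for name in names:
        for score, vals in records[name].items():
            rows.append({"classifier": name, "score": score,
                         "mean": float(np.mean(vals)),
                         "sd": float(np.std(vals))})
    return ClassificationReport(
        scores=pd.DataFrame(rows),
        target_group=target_group,
        n_repetitions=n_repetitions,
        feature_description=feature_description,
        seed=seed,
    )
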