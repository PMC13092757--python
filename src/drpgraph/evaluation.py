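"""Cross-validation splits, classification metrics and significance tests.

Two split protocols: ``random_pair`` (stratified k-fold over labeled
pairs) and ``disjoint_entity`` (cold start: cells and drugs are each
partitioned into folds; a fold's test pairs use only its own entities, so
no test cell line or drug is ever seen in training — pairs straddling
partitions are dropped and reported).

AUC comparisons use the DeLong placement-value test for paired correlated
AUCs and a paired bootstrap for AUPR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (average_precision_score, f1_score,
                             precision_score, recall_score, roc_auc_score)
from sklearn.model_selection import StratifiedKFold

from .datasets import SENSITIVE, RESISTANT, ResponseRecord

RANDOM_PAIR = "random_pair"
DISJOINT_ENTITY = "disjoint_entity"


@dataclass
class SplitPlan:
    mode: str
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx) into pairs
    dropped: np.ndarray                          # straddling pairs (disjoint mode)
    seed: int


@dataclass
class FoldReport:
    fold: int
    scores: np.ndarray
    labels: np.ndarray
    metrics: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def binary_labels(records: list[ResponseRecord]) -> np.ndarray:
    """sensitive -> 1, resistant -> 0; anything else is a caller error."""
    out = np.empty(len(records), dtype=np.int64)
    for i, r in enumerate(records):
        if r.label == SENSITIVE:
            out[i] = 1
        elif r.label == RESISTANT:
            out[i] = 0
        else:
            raise ValueError(f"pair ({r.cell_id}, {r.drug_id}) has label {r.label!r}; "
                             "only sensitive/resistant pairs enter the classifier")
    return out


def make_splits(pairs: list[ResponseRecord], mode: str = RANDOM_PAIR,
                n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Fold assignment over labeled pairs; see module docstring for modes."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    y = binary_labels(pairs)
    n = len(pairs)
    if mode == RANDOM_PAIR:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(n), y)]
        return SplitPlan(mode=mode, folds=folds, dropped=np.array([], dtype=int), seed=seed)
    if mode != DISJOINT_ENTITY:
        raise ValueError(f"unknown split mode {mode!r}")

    cells = sorted({p.cell_id for p in pairs})
    drugs = sorted({p.drug_id for p in pairs})
    if len(cells) < n_folds or len(drugs) < n_folds:
        raise ValueError(f"disjoint_entity needs >= {n_folds} cells and drugs "
                         f"(have {len(cells)}, {len(drugs)})")
    rng = np.random.default_rng(seed)
    cell_fold = dict(zip(rng.permutation(cells).tolist(),
                         np.arange(len(cells)) % n_folds))
    drug_fold = dict(zip(rng.permutation(drugs).tolist(),
                         np.arange(len(drugs)) % n_folds))
    folds = []
    dropped_mask = np.ones(n, dtype=bool)
    for f in range(n_folds):
        test = np.array([i for i, p in enumerate(pairs)
                         if cell_fold[p.cell_id] == f and drug_fold[p.drug_id] == f],
                        dtype=int)
        train = np.array([i for i, p in enumerate(pairs)
                          if cell_fold[p.cell_id] != f and drug_fold[p.drug_id] != f],
                         dtype=int)
        dropped_mask[test] = False
        dropped_mask[train] = False
        folds.append((train, test))
    # a pair is "dropped" for fold f if it straddles; report pairs in no test fold
    in_test = np.zeros(n, dtype=bool)
    for _, te in folds:
        in_test[te] = True
    return SplitPlan(mode=mode, folds=folds, dropped=np.where(~in_test)[0], seed=seed)


def make_holdout(pairs: list[ResponseRecord], mode: str = RANDOM_PAIR,
                 test_fraction: float = 0.10, seed: int = 0,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """A single train/test split with the same entity-disjointness guarantees."""
    n_folds = max(2, int(round(1.0 / test_fraction)))
    plan = make_splits(pairs, mode=mode, n_folds=n_folds, seed=seed)
    return plan.folds[0]


# ---------------------------------------------------------------------------
# metrics


def evaluate(scores: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> dict[str, float]:
    """AUC, AUPR, accuracy, precision, recall and F1 at the given threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to evaluate")
    pred = (scores >= threshold).astype(int)
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "accuracy": float((pred == labels).mean()),
        "precision": float(precision_score(labels, pred, zero_division=0)),
        "recall": float(recall_score(labels, pred, zero_division=0)),
        "f1": float(f1_score(labels, pred, zero_division=0)),
    }


def aggregate_folds(reports: list[dict[str, float]]) -> dict[str, dict[str, float]]:
    """Per-metric mean, standard deviation and standard error across folds."""
    keys = reports[0].keys()
    out = {}
    for k in keys:
        vals = np.array([r[k] for r in reports], dtype=float)
        out[k] = {"mean": float(vals.mean()),
                  "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                  "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0}
    return out


# ---------------------------------------------------------------------------
# significance


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Mid-rank placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    v10 = np.empty(m)
    for i, s in enumerate(pos):
        v10[i] = (np.sum(s > neg) + 0.5 * np.sum(s == neg)) / n
    v01 = np.empty(n)
    for j, s in enumerate(neg):
        v01[j] = (np.sum(s < pos) + 0.5 * np.sum(s == pos)) / m
    return v10, v01, float(v10.mean())


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float, float]:
    """Paired DeLong comparison of two correlated AUCs on the same labels.

    Returns (auc_a, auc_b, two-sided p). Zero variance of the difference
    (e.g. identical scorers) yields p = 1 with a warning.
    """
    import warnings

    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    v10a, v01a, auc_a = _placements(scores_a, labels)
    v10b, v01b, auc_b = _placements(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        warnings.warn("zero variance of the AUC difference; p set to 1")
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z)))
    return auc_a, auc_b, min(p, 1.0)


def bootstrap_pvalue(scores_a: np.ndarray, scores_b: np.ndarray,
                     labels: np.ndarray, metric: str = "aupr",
                     n_boot: int = 1000, seed: int = 0) -> float:
    """One-sided paired bootstrap p: fraction of resamples with metric_b >= metric_a.

    Single-class resamples are redrawn (bounded retries) and counted.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if metric == "auc":
        fn = roc_auc_score
    elif metric == "aupr":
        fn = average_precision_score
    else:
        raise ValueError(f"unknown metric {metric!r}")
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    rng = np.random.default_rng(seed)
    n = len(labels)
    count = 0
    redraws = 0
    done = 0
    while done < n_boot and redraws < 10 * n_boot:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(labels[idx])) < 2:
            redraws += 1
            continue
        if fn(labels[idx], scores_b[idx]) >= fn(labels[idx], scores_a[idx]):
            count += 1
        done += 1
    if done == 0:
        raise ValueError("all bootstrap resamples degenerate")
    return count / done


def logistic_baseline(train_x: np.ndarray, train_y: np.ndarray,
                      test_x: np.ndarray, seed: int = 0) -> np.ndarray:
    """Logistic regression on raw concatenated pair features (reference scorer)."""
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(train_x, train_y)
    return clf.predict_proba(test_x)[:, 1]
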