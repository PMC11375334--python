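"""Subtype-stratified disease-identification models.

Three binary tasks — CRC vs NC, AA vs NC, and CRC+AA vs NC — are fitted
overall and inside each gut-microbial subtype with gradient-boosted trees.
Features are the relative abundances of genera passing a Kruskal-Wallis
screen refit on the training split only (leakage-free by default; a
``screen_on_all`` switch mirrors designs that screen before splitting).
Discovery-set metrics are training resubstitution; the test block is
omitted for strata below a minimum size, matching the study's handling of
its 57-sample subtype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from xgboost import XGBClassifier

from .tables import AbundanceTable, normalize_tss

TASKS = {
    "CRC": ("CRC",),        # CRC vs NC
    "AA": ("AA",),          # AA vs NC
    "CRC+AA": ("CRC", "AA"),  # any disease vs NC
}

DEFAULT_PARAMS = {"n_estimators": 200, "max_depth": 6, "learning_rate": 0.1}


def stratified_split(
    labels: Sequence,
    train_frac: float = 0.8,
    seed: int = 0,
    min_test_total: int = 60,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-class random split; returns (train_idx, test_idx, has_test).

    Class proportions are preserved to rounding.  If the stratum is smaller
    than ``min_test_total`` or any class would contribute zero test
    samples, everything goes to training and ``has_test`` is False.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    labels = np.asarray(labels)
    n = labels.size
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    ok = n >= min_test_total
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size)
        if idx.size - n_train == 0:
            ok = False
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    if not ok:
        return np.sort(np.arange(n)), np.array([], dtype=int), False
    return (
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(test_parts)),
        True,
    )


def train_model(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    params: dict | None = None,
) -> XGBClassifier:
    """Fit the gradient-boosted tree classifier (deterministic given seed)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set has a single class")
    merged = dict(DEFAULT_PARAMS)
    if params:
        merged.update(params)
    model = XGBClassifier(
        **merged,
        random_state=int(seed) % (2**31 - 1),
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(np.asarray(features, dtype=float), labels.astype(int))
    return model


@dataclass
class BlockReport:
    """Metrics for one (task, stratum, split) block."""

    task: str
    stratum: str
    split: str  # discovery | test
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.tp + self.fp + self.tn + self.fn

        def pct(num: int, den: int) -> float:
            return round(100.0 * num / den, 2) if den else float("nan")

        self.accuracy = pct(self.tp + self.tn, total)
        self.sensitivity = pct(self.tp, self.tp + self.fn)
        self.specificity = pct(self.tn, self.tn + self.fp)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def evaluate(
    model: XGBClassifier,
    features: np.ndarray,
    truth: np.ndarray,
    task: str,
    stratum: str,
    split: str,
) -> BlockReport:
    """Confusion counts and percentage metrics; positive class = diseased."""
    truth = np.asarray(truth).astype(int)
    if truth.size == 0:
        raise ValueError("empty evaluation set")
    pred = model.predict(np.asarray(features, dtype=float)).astype(int)
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    return BlockReport(task=task, stratum=stratum, split=split, tp=tp, fp=fp, tn=tn, fn=fn)


def _screen_taxa(
    X: np.ndarray, y: np.ndarray, columns: Sequence[str], alpha: float
) -> list[int]:
    """Indices of features whose KW p (2 groups) clears alpha; all if none."""
    keep = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            continue
        _, p = stats.kruskal(col[y == 1], col[y == 0])
        if p < alpha:
            keep.append(j)
    return keep if keep else list(range(X.shape[1]))


def stratified_comparison(
    table: AbundanceTable,
    diseases: Sequence[str],
    subtype_labels: Sequence[str] | None,
    train_frac: float = 0.8,
    min_test_total: int = 60,
    alpha: float = 0.05,
    seed: int = 0,
    params: dict | None = None,
    screen_on_all: bool = False,
    tasks: Sequence[str] = ("CRC", "AA", "CRC+AA"),
) -> pd.DataFrame:
    """Fit every (task x stratum) disease model and report metric blocks.

    Strata are 'overall' plus each subtype.  Returns a tidy frame with one
    row per block (task, stratum, split, confusion counts, accuracy,
    sensitivity, specificity, n, note).  Tasks whose stratum lacks a class
    are skipped with a note row.
    """
    rel = table if table.is_relative else normalize_tss(table)
    X_all = rel.values()
    diseases = np.asarray(list(diseases))
    strata: dict[str, np.ndarray] = {"overall": np.arange(len(diseases))}
    if subtype_labels is not None:
        sub = np.asarray(list(subtype_labels))
        for s in sorted(np.unique(sub)):
            strata[str(s)] = np.flatnonzero(sub == s)

    # one child seed per task, shared across strata: a stratum holding the
    # whole cohort then reproduces the overall block exactly
    task_seeds = {
        t: int(s % (2**31 - 1))
        for t, s in zip(tasks, np.random.SeedSequence(seed).generate_state(len(tasks)))
    }
    rows = []
    for stratum, stratum_idx in strata.items():
        for task in tasks:
            child_seed = task_seeds[task]
            positive = TASKS[task]
            mask = np.isin(diseases[stratum_idx], positive + ("NC",))
            idx = stratum_idx[mask]
            y = np.isin(diseases[idx], positive).astype(int)
            if len(np.unique(y)) < 2:
                rows.append({"task": task, "stratum": stratum, "split": "skipped",
                             "note": "missing class", "n": int(idx.size)})
                continue
            tr, te, has_test = stratified_split(
                y, train_frac=train_frac, seed=child_seed,
                min_test_total=min_test_total,
            )
            X, note = X_all[idx], ""
            screen_X, screen_y = (X, y) if screen_on_all else (X[tr], y[tr])
            feats = _screen_taxa(screen_X, screen_y, rel.taxon_ids, alpha)
            model = train_model(X[tr][:, feats], y[tr], seed=child_seed, params=params)
            disc = evaluate(model, X[tr][:, feats], y[tr], task, stratum, "discovery")
            blocks = [disc]
            if has_test:
                blocks.append(evaluate(model, X[te][:, feats], y[te], task, stratum, "test"))
            else:
                note = "no test set (stratum below minimum size)"
            for b in blocks:
                rows.append({
                    "task": b.task, "stratum": b.stratum, "split": b.split,
                    "tp": b.tp, "fp": b.fp, "tn": b.tn, "fn": b.fn,
                    "accuracy": b.accuracy, "sensitivity": b.sensitivity,
                    "specificity": b.specificity, "n": b.n,
                    "n_features": len(feats), "note": note,
                })
    return pd.DataFrame(rows)
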