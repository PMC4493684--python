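"""Component-level cross-validation and (imbalance-corrected) metrics.

Standard pair-level cross-validation leaks information: the same protein
can appear in training and test pairs, so a classifier can score well by
memorising single-protein reactivity. The component-level k-fold scheme
used here removes that leak. Pairs are stratified into k folds; for each
fold F the test set A contains every pair whose *both* proteins occur in
F, and the training set B every pair whose *neither* protein occurs in F.
Predictions over all A-sets are pooled (a pair may be scored in more than
one fold) before computing metrics.

Because benchmark datasets are artificially balanced while in reality
non-interacting pairs outnumber interacting ones by roughly three orders
of magnitude, precision/accuracy/specificity can be corrected by
multiplying the negative-example terms (TN, FP) of the confusion matrix by
the expected negatives:positives ratio d. Recall and AUC are unaffected by
class imbalance.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from .fragment_dataset import FragmentPairDataset

logger = logging.getLogger("mlppi")

#: default imbalance correction constant: the estimated negatives:positives
#: ratio in the yeast proteome (~26,000 hetero interactions, ~6,300 proteins)
DEFAULT_D = 762.0


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


# ---------------------------------------------------------------------------
# Component-level cross-validation

def stratified_folds(pairs: list[tuple[str, str, int]], k: int,
                     seed: int) -> list[list[tuple[str, str, int]]]:
    """Deal pairs into k folds, each holding ~1/k of either class."""
    if k < 2:
        raise ValueError("k must be >= 2")
    pos = [p for p in pairs if p[2] == 1]
    neg = [p for p in pairs if p[2] == 0]
    if not pos or not neg:
        raise ValueError("both classes must be present")
    if k > min(len(pos), len(neg)):
        raise ValueError(
            f"k={k} exceeds the minority-class pair count "
            f"{min(len(pos), len(neg))}")
    rng = random.Random(seed)
    rng.shuffle(pos)
    rng.shuffle(neg)
    folds: list[list] = [[] for _ in range(k)]
    for i, p in enumerate(pos):
        folds[i % k].append(p)
    for i, p in enumerate(neg):
        folds[i % k].append(p)
    return folds


def component_folds(pairs: list[tuple[str, str, int]], k: int = 30,
                    seed: int = 0):
    """Stratified component-level folds as (train B, test A) pair lists.

    Pairs are dealt into k stratified folds. For each fold, P is the set
    of proteins occurring in it; A = pairs with both members in P;
    B = pairs with neither member in P.
    """
    folds = stratified_folds(pairs, k, seed)
    splits = []
    for fold in folds:
        P = {x for a, b, _ in fold for x in (a, b)}
        A = [(a, b, y) for a, b, y in pairs if a in P and b in P]
        B = [(a, b, y) for a, b, y in pairs if a not in P and b not in P]
        splits.append((B, A))
    return splits


def run_cv(pairs, fit_fn, predict_fn, k: int = 30, seed: int = 0,
           dedupe: str = "pool") -> dict:
    """Component-level CV: train on each B, score its A, pool predictions.

    ``fit_fn(train_pairs)`` returns a fitted model; ``predict_fn(model,
    test_pairs)`` returns one score per pair. ``dedupe="pool"`` keeps
    duplicate predictions of pairs appearing in several A-sets;
    ``dedupe="mean"`` averages them per pair first. Folds with an empty
    training set are skipped with a warning.
    """
    scores, labels, keys = [], [], []
    for fold_no, (B, A) in enumerate(component_folds(pairs, k, seed)):
        if not B:
            logger.warning("fold %d has an empty training set; skipped", fold_no)
            continue
        if not A:
            continue
        try:
            model = fit_fn(B)
        except ValueError as exc:
            logger.warning("fold %d skipped: %s", fold_no, exc)
            continue
        preds = predict_fn(model, A)
        scores.extend(float(s) for s in preds)
        labels.extend(y for _, _, y in A)
        keys.extend((a, b) for a, b, _ in A)
    if not scores:
        raise ValueError("cross-validation produced no predictions")
    scores = np.array(scores)
    labels = np.array(labels)
    if dedupe == "mean":
        df = pd.DataFrame({"key": keys, "score": scores, "label": labels})
        agg = df.groupby("key", sort=False).agg(
            score=("score", "mean"), label=("label", "first"))
        scores, labels = agg["score"].to_numpy(), agg["label"].to_numpy()
    result = metrics(scores, labels)
    result["n_predictions"] = int(len(scores))
    result["scores"] = scores
    result["labels"] = labels
    return result


# ---------------------------------------------------------------------------
# Metrics

def metrics(scores, labels, threshold: float = 0.5) -> dict:
    """Accuracy, precision, recall and ROC AUC at a fixed 0.5 threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    acc = (tp + tn) / len(labels) if len(labels) else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    rec = tp / (tp + fn) if tp + fn else float("nan")
    if len(np.unique(labels)) == 2:
        auc = float(roc_auc_score(labels, scores))
    else:
        auc = float("nan")
    return {"accuracy": acc, "precision": prec, "recall": rec, "auc": auc,
            "confusion": ConfusionCounts(tp, tn, fp, fn)}


def rank_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney rank statistic with midrank ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if not n_pos or not n_neg:
        return float("nan")
    ranks = rankdata(scores)
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def corrected_metrics(c: ConfusionCounts, d: float = DEFAULT_D) -> dict:
    """Imbalance-corrected accuracy/precision plus (unchanged) recall and
    specificity, obtained by weighting TN and FP by d."""
    if d <= 0:
        raise ValueError("d must be positive")
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    accuracy = (c.TP + d * c.TN) / (c.TP + d * c.TN + d * c.FP + c.FN)
    precision = c.TP / (c.TP + d * c.FP) if c.TP + d * c.FP else float("nan")
    recall = c.TP / (c.TP + c.FN) if c.TP + c.FN else float("nan")
    specificity = c.TN / (c.TN + c.FP) if c.TN + c.FP else float("nan")
    return {"accuracy": accuracy, "precision": precision,
            "recall": recall, "specificity": specificity}


def negatives_positives_ratio(n_proteins: int, n_interactions: int) -> float:
    """(C(n, 2) - I) / I: expected non-interacting per interacting pair."""
    if n_interactions <= 0:
        raise ValueError("n_interactions must be positive")
    return (n_proteins * (n_proteins - 1) / 2 - n_interactions) / n_interactions


def blind_precision(d: float = DEFAULT_D) -> float:
    """Expected corrected precision when labelling every pair positive."""
    return 1.0 / (1.0 + d)


# ---------------------------------------------------------------------------
# Secondary-structure pattern table

SS_PAIRS = ("EE", "EH", "EC", "HH", "HC", "CC")


def ss_pattern_frequencies(ds: FragmentPairDataset) -> pd.DataFrame:
    """Unordered ss3 symbol-pair frequencies at the first, central and last
    window positions, separately for interacting and non-interacting
    fragment pairs. Frequencies sum to 1 per position per class."""
    w = ds.window
    positions = {"first": 0, "center": w // 2, "last": w - 1}
    counts: dict[tuple[str, int, str], int] = {}
    for ss_a, ss_b, label in zip(ds.ss_a, ds.ss_b, ds.labels):
        for pname, p in positions.items():
            pair = "".join(sorted(ss_a[p] + ss_b[p], key="EHC".index))
            key = (pname, label, pair)
            counts[key] = counts.get(key, 0) + 1
    rows = []
    for pname in positions:
        for label, cls in ((1, "interacting"), (0, "non_interacting")):
            total = sum(counts.get((pname, label, pp), 0) for pp in SS_PAIRS)
            for pp in SS_PAIRS:
                freq = counts.get((pname, label, pp), 0) / total if total else 0.0
                rows.append({"position": pname, "class": cls,
                             "pattern": f"{pp[0]}-{pp[1]}", "frequency": freq})
    return pd.DataFrame(rows)
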