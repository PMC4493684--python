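"""Two-level interaction predictor.

Level I is a probabilistic classifier over fragment pairs. Applying it to
all full-window fragment-centre pairs of two chains yields a score matrix
of shape (n_a - w + 1) x (n_b - w + 1), cell (r, c) holding the interaction
likelihood of the fragments centred at residues (r + w//2, c + w//2).

Level II aggregates that matrix into a fixed 46-value feature vector —
moments, best rows/columns/diagonals, their intersection, a score
histogram, and connected-component fractions of the thresholded, trimmed
bipartite contact graph — and classifies the protein pair from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import networkx as nx
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import encoders
from .fragment_dataset import FragmentPairDataset
from .structure_io import ProteinChain

MODEL_FORMAT_VERSION = 1

N_PAIR_FEATURES = 46  # 2 + 10 + 10 + 5 + 5 + 1 + 10 + 3
DEFAULT_EDGE_THRESHOLD = 0.5
DEFAULT_K_EDGES = 3


@dataclass
class ModelConfig:
    """Classifier choice and hyperparameters for one level.

    Defaults follow the tuned settings: level-I random forest with 300
    trees / depth 15 (SVM RBF: C=2, gamma=0.048); level-II random forest
    with 300 trees / depth 7 (SVM RBF: C=1, gamma=2).
    """

    classifier: str = "random_forest"
    level: int = 1
    trees: int = 300
    max_depth: int | None = None
    C: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.classifier not in ("random_forest", "svm_rbf"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.level not in (1, 2):
            raise ValueError("level must be 1 or 2")
        if self.max_depth is None:
            self.max_depth = 15 if self.level == 1 else 7
        if self.C is None:
            self.C = 2.0 if self.level == 1 else 1.0
        if self.gamma is None:
            self.gamma = 0.048 if self.level == 1 else 2.0

    def build(self, seed: int):
        if self.classifier == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.trees, max_depth=self.max_depth,
                random_state=seed, n_jobs=1)
        return SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                   probability=True, random_state=seed)


@dataclass
class ScoreMatrix:
    """All-vs-all level-I likelihoods for fragment centres of two chains."""

    values: np.ndarray
    window: int

    @property
    def offset(self) -> int:
        return self.window // 2

    def centers(self, r: int, c: int) -> tuple[int, int]:
        return r + self.offset, c + self.offset


@dataclass
class Level1Model:
    clf: object
    scheme: str
    window: int
    symmetrized: bool = True


@dataclass
class Level2Model:
    clf: object
    level1: Level1Model
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD
    k_edges: int = DEFAULT_K_EDGES


# ---------------------------------------------------------------------------
# Level I

def train_level1(dataset: FragmentPairDataset, scheme: str = "ss3",
                 cfg: ModelConfig | None = None, seed: int = 0,
                 symmetrize: bool = True) -> Level1Model:
    """Fit the fragment-pair classifier.

    ``symmetrize`` duplicates every example with the fragments swapped, and
    marks the model so that scoring averages both fragment orders — the
    fragment-interaction relation is unordered, so the score should not
    depend on which chain is called "a".
    """
    if len(dataset) == 0:
        raise ValueError("empty fragment dataset")
    cfg = cfg or ModelConfig(level=1)
    X, y = encoders.encode_dataset(dataset, scheme)
    if symmetrize:
        half = X.shape[1] // 2
        X = np.vstack([X, np.hstack([X[:, half:], X[:, :half]])])
        y = np.concatenate([y, y])
    if len(np.unique(y)) < 2:
        raise ValueError("level-I training needs both classes present")
    clf = cfg.build(seed)
    clf.fit(X, y)
    return Level1Model(clf, scheme, dataset.window, symmetrized=symmetrize)


def score_matrix(model: Level1Model, a: ProteinChain,
                 b: ProteinChain) -> ScoreMatrix:
    """Level-I likelihoods for every full-window fragment-centre pair."""
    w = model.window
    if len(a) < w or len(b) < w:
        raise ValueError(f"chains must be at least {w} residues long")
    feats_a = _window_features(a, w, model.scheme)
    feats_b = _window_features(b, w, model.scheme)
    na, nb = feats_a.shape[0], feats_b.shape[0]
    X = np.hstack([np.repeat(feats_a, nb, axis=0),
                   np.tile(feats_b, (na, 1))])
    pos_col = list(model.clf.classes_).index(1)
    scores = model.clf.predict_proba(X)[:, pos_col]
    if model.symmetrized:
        half = X.shape[1] // 2
        swapped = np.hstack([X[:, half:], X[:, :half]])
        scores = (scores + model.clf.predict_proba(swapped)[:, pos_col]) / 2.0
    return ScoreMatrix(scores.reshape(na, nb), w)


def _window_features(chain: ProteinChain, w: int, scheme: str) -> np.ndarray:
    table = encoders.load_hqi8() if scheme in ("hqi8", "ss3+hqi8") else None
    rows = []
    for c in range(w // 2, len(chain) - w // 2):
        lo, hi = c - w // 2, c + w // 2 + 1
        rows.append(encoders.encode_fragment(
            chain.sequence[lo:hi], chain.ss3[lo:hi], scheme, table))
    return np.array(rows)


# ---------------------------------------------------------------------------
# Score-matrix aggregation (level-II features)

def matrix_features(S: ScoreMatrix | np.ndarray,
                    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
                    k_edges: int = DEFAULT_K_EDGES,
                    bins: int = 10) -> np.ndarray:
    """Aggregate a score matrix into the fixed 46-value feature vector.

    Order: mean, variance | 10 best row sums | 10 best column sums |
    5 best diagonal sums of S (non-negative offsets) | 5 best diagonal sums
    of S transposed | intersection sum of the 10 best rows x 10 best
    columns | 10-bin score histogram (frequencies) | fractions of nodes in
    the 3 largest connected components of the trimmed contact graph.
    Short matrices are zero-padded so the length is always 46.
    """
    M = S.values if isinstance(S, ScoreMatrix) else np.asarray(S, dtype=float)
    if M.size == 0:
        raise ValueError("empty score matrix")
    n_rows, n_cols = M.shape

    mean = M.mean()
    var = M.var()

    row_sums = M.sum(axis=1)
    col_sums = M.sum(axis=0)
    top_rows = _top_padded(row_sums, 10)
    top_cols = _top_padded(col_sums, 10)

    diag_s = np.array([np.diagonal(M, off).sum() for off in range(n_cols)])
    diag_t = np.array([np.diagonal(M.T, off).sum() for off in range(n_rows)])
    top_diag_s = _top_padded(diag_s, 5)
    top_diag_t = _top_padded(diag_t, 5)

    row_idx = np.argsort(-row_sums, kind="stable")[:10]
    col_idx = np.argsort(-col_sums, kind="stable")[:10]
    intersection = M[np.ix_(row_idx, col_idx)].sum()

    hist, _ = np.histogram(M, bins=np.linspace(0.0, 1.0, bins + 1))
    hist = hist / M.size

    comps = graph_fractions(M, edge_threshold, k_edges)

    out = np.concatenate([
        [mean, var], top_rows, top_cols, top_diag_s, top_diag_t,
        [intersection], hist, comps,
    ])
    assert out.shape[0] == N_PAIR_FEATURES
    return out


def _top_padded(values: np.ndarray, k: int) -> np.ndarray:
    top = np.sort(values)[::-1][:k]
    if len(top) < k:
        top = np.concatenate([top, np.zeros(k - len(top))])
    return top


def graph_fractions(S: ScoreMatrix | np.ndarray,
                    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
                    k_edges: int = DEFAULT_K_EDGES) -> np.ndarray:
    """Fractions of nodes in the 3 largest components of the contact graph.

    The bipartite graph has one node per row and per column; a candidate
    edge (r, c) exists when the score reaches ``edge_threshold``. Each node
    keeps only its ``k_edges`` strongest candidates (ties broken towards
    smaller column, then row index) and an edge survives when either
    endpoint keeps it. Isolated nodes form no components; fractions are
    over all row+column nodes, descending, zero-padded to 3.
    """
    M = S.values if isinstance(S, ScoreMatrix) else np.asarray(S, dtype=float)
    n_rows, n_cols = M.shape
    rr, cc = np.nonzero(M >= edge_threshold)
    # rank candidates per node: strongest first, ties by (col, row)
    incident: dict[tuple[str, int], list[tuple[float, int, int]]] = {}
    for r, c in zip(rr.tolist(), cc.tolist()):
        item = (-M[r, c], c, r)
        incident.setdefault(("r", r), []).append(item)
        incident.setdefault(("c", c), []).append(item)
    kept: set[tuple[int, int]] = set()
    for items in incident.values():
        items.sort()
        for _, c, r in items[:k_edges]:
            kept.add((r, c))

    g = nx.Graph()
    g.add_edges_from((("r", r), ("c", c)) for r, c in kept)
    total = n_rows + n_cols
    sizes = sorted((len(comp) for comp in nx.connected_components(g)),
                   reverse=True)[:3]
    fracs = np.zeros(3)
    for k, size in enumerate(sizes):
        fracs[k] = size / total
    return fracs


# ---------------------------------------------------------------------------
# Level II

def pair_features(level1: Level1Model, a: ProteinChain, b: ProteinChain,
                  edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
                  k_edges: int = DEFAULT_K_EDGES) -> np.ndarray:
    return matrix_features(score_matrix(level1, a, b), edge_threshold, k_edges)


def train_level2(pairs: list[tuple[ProteinChain, ProteinChain, int]],
                 level1: Level1Model, cfg: ModelConfig | None = None,
                 seed: int = 0,
                 edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
                 k_edges: int = DEFAULT_K_EDGES,
                 feature_cache: dict | None = None) -> Level2Model:
    """Fit the protein-pair classifier on aggregated score-matrix features.

    Pairs whose chains are shorter than the extraction window are skipped
    with a warning. ``feature_cache`` (keyed by (id_a, id_b)) avoids
    recomputing score matrices across folds.
    """
    cfg = cfg or ModelConfig(level=2)
    X, y = [], []
    for a, b, label in pairs:
        feats = _cached_features(level1, a, b, edge_threshold, k_edges,
                                 feature_cache)
        if feats is None:
            continue
        X.append(feats)
        y.append(label)
    if not X:
        raise ValueError("no usable pairs for level-II training")
    if len(np.unique(y)) < 2:
        raise ValueError("level-II training needs both classes present")
    clf = cfg.build(seed)
    clf.fit(np.array(X), np.array(y))
    return Level2Model(clf, level1, edge_threshold, k_edges)


def predict_pair(model: Level2Model, a: ProteinChain, b: ProteinChain,
                 feature_cache: dict | None = None) -> float:
    """Positive-class likelihood for one protein pair."""
    feats = _cached_features(model.level1, a, b, model.edge_threshold,
                             model.k_edges, feature_cache)
    if feats is None:
        raise ValueError("chains shorter than the extraction window")
    pos_col = list(model.clf.classes_).index(1)
    return float(model.clf.predict_proba(feats.reshape(1, -1))[0, pos_col])


def _cached_features(level1, a, b, edge_threshold, k_edges, cache):
    import logging

    w = level1.window
    if len(a) < w or len(b) < w:
        logging.getLogger("mlppi").warning(
            "pair (%s, %s) skipped: chain shorter than window %d",
            a.chain_id, b.chain_id, w)
        return None
    key = (a.chain_id, b.chain_id, edge_threshold, k_edges)
    if cache is not None and key in cache:
        return cache[key]
    feats = pair_features(level1, a, b, edge_threshold, k_edges)
    if cache is not None:
        cache[key] = feats
    return feats


# ---------------------------------------------------------------------------
# Serialization

def save_model(model, path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path):
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    return payload["model"]
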