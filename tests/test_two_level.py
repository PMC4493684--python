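import random

import numpy as np
import pytest

from mlppi.fragment_dataset import FragmentPairDataset
from mlppi.structure_io import ProteinChain
from mlppi.two_level_predictor import (
    ModelConfig,
    ScoreMatrix,
    graph_fractions,
    load_model,
    matrix_features,
    save_model,
    score_matrix,
    train_level1,
)


# --- independent oracle: explicit loops and full sorts --------------------

def oracle_matrix_features(M, edge_threshold=0.5, k_edges=3):
    n_rows, n_cols = M.shape
    cells = [M[r, c] for r in range(n_rows) for c in range(n_cols)]
    mean = sum(cells) / len(cells)
    var = sum((x - mean) ** 2 for x in cells) / len(cells)

    row_sums = sorted((sum(M[r, :]) for r in range(n_rows)), reverse=True)
    col_sums = sorted((sum(M[:, c]) for c in range(n_cols)), reverse=True)
    top_rows = (row_sums + [0.0] * 10)[:10]
    top_cols = (col_sums + [0.0] * 10)[:10]

    diag_s = []
    for off in range(n_cols):
        diag_s.append(sum(M[k, k + off] for k in range(n_rows)
                          if 0 <= k + off < n_cols))
    diag_t = []
    T = M.T
    for off in range(n_rows):
        diag_t.append(sum(T[k, k + off] for k in range(n_cols)
                          if 0 <= k + off < n_rows))
    top_diag_s = (sorted(diag_s, reverse=True) + [0.0] * 5)[:5]
    top_diag_t = (sorted(diag_t, reverse=True) + [0.0] * 5)[:5]

    by_row = sorted(range(n_rows), key=lambda r: (-sum(M[r, :]), r))[:10]
    by_col = sorted(range(n_cols), key=lambda c: (-sum(M[:, c]), c))[:10]
    intersection = sum(M[r, c] for r in by_row for c in by_col)

    hist = [0] * 10
    for x in cells:
        b = min(int(x * 10), 9)
        hist[b] += 1
    hist = [h / len(cells) for h in hist]

    comps = oracle_graph_fractions(M, edge_threshold, k_edges)
    return np.array([mean, var] + top_rows + top_cols + top_diag_s
                    + top_diag_t + [intersection] + hist + comps)


def oracle_graph_fractions(M, edge_threshold, k_edges):
    n_rows, n_cols = M.shape
    candidates = [(r, c) for r in range(n_rows) for c in range(n_cols)
                  if M[r, c] >= edge_threshold]
    kept = set()
    for node_kind, n in (("r", n_rows), ("c", n_cols)):
        for node in range(n):
            inc = [(r, c) for r, c in candidates
                   if (r if node_kind == "r" else c) == node]
            inc.sort(key=lambda rc: (-M[rc], rc[1], rc[0]))
            kept.update(inc[:k_edges])
    # union-find over surviving edges
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for r, c in kept:
        ra, rb = find(("r", r)), find(("c", c))
        parent[ra] = rb
    sizes = {}
    for node in {n for rc in kept for n in (("r", rc[0]), ("c", rc[1]))}:
        root = find(node)
        sizes[root] = sizes.get(root, 0) + 1
    top = sorted(sizes.values(), reverse=True)[:3]
    top += [0] * (3 - len(top))
    return [s / (n_rows + n_cols) for s in top]


class TestMatrixFeatures:
    def test_hand_computed_2x2(self):
        f = matrix_features(np.array([[1.0, 2.0], [3.0, 4.0]]),
                            edge_threshold=5.0)  # no graph edges
        assert f[0] == pytest.approx(2.5)       # mean
        assert f[2] == pytest.approx(7.0)       # best row sum
        assert f[12] == pytest.approx(6.0)      # best column sum
        assert f[22] == pytest.approx(5.0)      # best diagonal of S
        assert f[27] == pytest.approx(5.0)      # best diagonal of S^T
        assert f[32] == pytest.approx(10.0)     # intersection (all cells)

    def test_all_zero_matrix(self):
        f = matrix_features(np.zeros((4, 5)))
        hist = f[33:43]
        assert hist[0] == 1.0 and hist[1:].sum() == 0
        assert f[0] == f[1] == 0.0
        np.testing.assert_allclose(f[43:], 0.0)

    def test_length_is_always_46(self):
        rng = np.random.default_rng(0)
        for shape in [(1, 1), (2, 3), (7, 2), (15, 40), (3, 3)]:
            f = matrix_features(rng.random(shape))
            assert f.shape == (46,)

    def test_histogram_normalized_variance_nonneg(self):
        rng = np.random.default_rng(1)
        M = rng.random((12, 9))
        f = matrix_features(M)
        assert f[33:43].sum() == pytest.approx(1.0)
        assert f[1] >= 0

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            shape = (rng.integers(1, 41), rng.integers(1, 41))
            M = rng.random(shape)
            got = matrix_features(M)
            want = oracle_matrix_features(M)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_removing_weakest_cell_never_raises_top_row_sums(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            M = rng.random((8, 8))
            weakest = np.unravel_index(np.argmin(M), M.shape)
            M2 = M.copy()
            M2[weakest] = 0.0
            before = matrix_features(M)[2:12]
            after = matrix_features(M2)[2:12]
            assert np.all(after <= before + 1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            matrix_features(np.empty((0, 0)))


class TestGraphFractions:
    def test_all_below_threshold(self):
        np.testing.assert_allclose(
            graph_fractions(np.full((3, 4), 0.2), 0.5, 3), [0, 0, 0])

    def test_full_2x2_block_single_component(self):
        np.testing.assert_allclose(
            graph_fractions(np.ones((2, 2)), 0.5, 3), [1.0, 0, 0])

    def test_two_disjoint_blocks(self):
        M = np.zeros((3, 3))
        M[:2, :2] = 1.0
        M[2, 2] = 1.0
        np.testing.assert_allclose(graph_fractions(M, 0.5, 3),
                                   [4 / 6, 2 / 6, 0])

    def test_trimming_caps_node_degree_from_one_side(self):
        # one row connected to 5 columns: row keeps only 3 edges, and the
        # orphaned columns keep theirs, so the component holds all 6 nodes
        M = np.zeros((1, 5))
        M[0, :] = [0.9, 0.8, 0.7, 0.6, 0.55]
        fracs = graph_fractions(M, 0.5, 3)
        assert fracs[0] == pytest.approx(1.0)

    def test_fractions_descending(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            f = graph_fractions(rng.random((10, 10)), 0.7, 3)
            assert f[0] >= f[1] >= f[2] >= 0


def make_separable_dataset(n=40, w=5):
    ds = FragmentPairDataset(w)
    rng = random.Random(0)
    for k in range(n):
        label = k % 2
        ss = "H" * w if label else "C" * w
        ds.seq_a.append("".join(rng.choice("ACDE") for _ in range(w)))
        ds.ss_a.append(ss)
        ds.seq_b.append("".join(rng.choice("ACDE") for _ in range(w)))
        ds.ss_b.append(ss)
        ds.labels.append(label)
    return ds


class TestLevel1:
    def test_separable_dataset_perfectly_fit(self):
        from sklearn.metrics import roc_auc_score

        from mlppi.encoders import encode_dataset

        ds = make_separable_dataset()
        model = train_level1(ds, "ss3", seed=0)
        X, y = encode_dataset(ds, "ss3")
        pos = list(model.clf.classes_).index(1)
        scores = model.clf.predict_proba(X)[:, pos]
        assert roc_auc_score(y, scores) == 1.0

    def test_shuffled_labels_near_chance(self):
        from sklearn.metrics import roc_auc_score
        from sklearn.model_selection import cross_val_predict

        from mlppi.encoders import encode_dataset

        rng = random.Random(1)
        ds = make_separable_dataset(60)
        rng.shuffle(ds.labels)
        X, y = encode_dataset(ds, "ss3")
        cfg = ModelConfig(level=1, trees=50)
        proba = cross_val_predict(cfg.build(0), X, y, cv=5,
                                  method="predict_proba")[:, 1]
        assert 0.2 < roc_auc_score(y, proba) < 0.8

    def test_single_class_rejected(self):
        ds = make_separable_dataset(10)
        ds.labels = [1] * len(ds.labels)
        with pytest.raises(ValueError):
            train_level1(ds, "ss3")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            train_level1(FragmentPairDataset(5), "ss3")


class TestScoreMatrix:
    def _model(self, w=5):
        return train_level1(make_separable_dataset(w=w), "ss3", seed=0)

    def test_minimal_chains_give_1x1(self):
        model = self._model()
        a = ProteinChain("a", "AAAAA", "HHHHH")
        b = ProteinChain("b", "CCCCC", "HHHHH")
        S = score_matrix(model, a, b)
        assert S.values.shape == (1, 1)
        assert S.centers(0, 0) == (2, 2)

    def test_entries_are_likelihoods(self):
        model = self._model()
        a = ProteinChain("a", "A" * 12, "HHHCCCHHHCCC")
        b = ProteinChain("b", "C" * 10, "CCHHHHHCCC")
        S = score_matrix(model, a, b)
        assert S.values.shape == (8, 6)
        assert np.all((S.values >= 0) & (S.values <= 1))

    def test_symmetrized_model_gives_transposed_matrix(self):
        model = self._model()
        a = ProteinChain("a", "A" * 9, "HHHHCCCHH")
        b = ProteinChain("b", "C" * 8, "CCHHHHCC")
        S_ab = score_matrix(model, a, b).values
        S_ba = score_matrix(model, b, a).values
        np.testing.assert_allclose(S_ab, S_ba.T, atol=1e-9)

    def test_short_chain_rejected(self):
        model = self._model()
        with pytest.raises(ValueError):
            score_matrix(model, ProteinChain("a", "AAA", "HHH"),
                         ProteinChain("b", "A" * 6, "H" * 6))


class TestModelConfig:
    def test_level_defaults(self):
        l1 = ModelConfig(level=1)
        l2 = ModelConfig(level=2)
        assert (l1.trees, l1.max_depth) == (300, 15)
        assert (l2.trees, l2.max_depth) == (300, 7)
        s1 = ModelConfig(classifier="svm_rbf", level=1)
        s2 = ModelConfig(classifier="svm_rbf", level=2)
        assert (s1.C, s1.gamma) == (2.0, 0.048)
        assert (s2.C, s2.gamma) == (1.0, 2.0)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(classifier="mlp")


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        model = train_level1(make_separable_dataset(), "ss3", seed=0)
        path = tmp_path / "m.joblib"
        save_model(model, path)
        back = load_model(path)
        assert back.scheme == "ss3" and back.window == model.window
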