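"""Numeric encodings of fragments and whole sequences.

Fragment-level schemes feed the level-I classifier:

* ``raw_sequence`` — integer code per residue;
* ``hqi8`` — eight physicochemical index values per residue;
* ``ss3`` — one-hot 3-state secondary structure per residue;
* ``ss3+raw`` / ``ss3+hqi8`` — concatenations.

Whole-sequence encoders are the classical aggregation baselines used to
benchmark pair predictors: amino-acid composition (AAC), 2-gram
frequencies, pseudo amino-acid composition (PseAAC), quasi-residue couples
(QRC) and Liu-style sequence "deviation" autocorrelations. A protein pair
is represented by concatenating the two per-protein vectors.

Unknown residues ('X') are excluded from composition counts; index-table
lookups map 'X' to the column-wise mean over the 20 standard amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .structure_io import AMINO_ACIDS

SS_ALPHABET = "EHC"

_AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
_SS_INDEX = {s: k for k, s in enumerate(SS_ALPHABET)}

SCHEMES = ("raw_sequence", "hqi8", "ss3", "ss3+raw", "ss3+hqi8")


@dataclass
class AminoAcidIndexTable:
    """Per-amino-acid vectors of physicochemical index values."""

    name: str
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.values.values()}
        if len(lengths) != 1:
            raise ValueError("index vectors must share one length")
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"table {self.name} missing amino acids "
                             f"{sorted(missing)}")
        self.n_indices = lengths.pop()
        if "X" not in self.values:
            self.values["X"] = np.mean(
                [self.values[aa] for aa in AMINO_ACIDS], axis=0)

    def row(self, aa: str) -> np.ndarray:
        return self.values.get(aa, self.values["X"])

    def matrix(self, seq: str) -> np.ndarray:
        """(len(seq), n_indices) matrix of index values."""
        return np.array([self.row(aa) for aa in seq])

    def standardized(self) -> "AminoAcidIndexTable":
        """Columns rescaled to zero mean / unit variance over the 20 residues."""
        base = np.array([self.values[aa] for aa in AMINO_ACIDS])
        mu = base.mean(axis=0)
        sd = base.std(axis=0)
        sd[sd == 0] = 1.0
        vals = {aa: (self.values[aa] - mu) / sd for aa in self.values
                if aa != "X"}
        return AminoAcidIndexTable(self.name + "_std", vals)


def _load_table(filename: str, name: str) -> AminoAcidIndexTable:
    values: dict[str, np.ndarray] = {}
    data = resources.files("mlppi.data").joinpath(filename).read_text()
    for line in data.splitlines():
        if not line or line.startswith("#") or line.startswith("aa\t"):
            continue
        parts = line.split("\t")
        values[parts[0]] = np.array([float(x) for x in parts[1:]])
    return AminoAcidIndexTable(name, values)


def load_hqi8() -> AminoAcidIndexTable:
    """Bundled 8-index table (synthetic stand-in built from classical
    published physicochemical properties; see the data file header)."""
    return _load_table("hqi8_synthetic.tsv", "hqi8")


def load_liu7() -> AminoAcidIndexTable:
    """Bundled 7-index table (synthetic stand-in; see the data file header)."""
    return _load_table("liu7_synthetic.tsv", "liu7")


# ---------------------------------------------------------------------------
# Fragment encodings (level-I)

def _encode_raw(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(aa, 20) for aa in seq], dtype=float)


def _encode_hqi8(seq: str, table: AminoAcidIndexTable) -> np.ndarray:
    return table.matrix(seq).ravel()


def _encode_ss3(ss: str) -> np.ndarray:
    out = np.zeros((len(ss), 3))
    for k, s in enumerate(ss):
        out[k, _SS_INDEX[s]] = 1.0
    return out.ravel()


def encode_fragment(seq: str, ss: str, scheme: str,
                    table: AminoAcidIndexTable | None = None) -> np.ndarray:
    if scheme == "raw_sequence":
        return _encode_raw(seq)
    if scheme == "hqi8":
        return _encode_hqi8(seq, table or load_hqi8())
    if scheme == "ss3":
        return _encode_ss3(ss)
    if scheme == "ss3+raw":
        return np.concatenate([_encode_ss3(ss), _encode_raw(seq)])
    if scheme == "ss3+hqi8":
        return np.concatenate([_encode_ss3(ss),
                               _encode_hqi8(seq, table or load_hqi8())])
    raise ValueError(f"unknown encoding scheme {scheme!r}")


def encode_fragment_pair(frag_a: tuple[str, str], frag_b: tuple[str, str],
                         scheme: str,
                         table: AminoAcidIndexTable | None = None) -> np.ndarray:
    """Encode an ordered pair of (sequence, ss3) fragments as one vector."""
    if len(frag_a[0]) != len(frag_b[0]):
        raise ValueError("fragments must share the window length")
    if table is None and scheme in ("hqi8", "ss3+hqi8"):
        table = load_hqi8()
    return np.concatenate([encode_fragment(*frag_a, scheme, table),
                           encode_fragment(*frag_b, scheme, table)])


def encode_dataset(ds, scheme: str,
                   table: AminoAcidIndexTable | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Encode a FragmentPairDataset into (X, y) arrays."""
    if table is None and scheme in ("hqi8", "ss3+hqi8"):
        table = load_hqi8()
    rows = [
        encode_fragment_pair((sa, ta), (sb, tb), scheme, table)
        for sa, ta, sb, tb in zip(ds.seq_a, ds.ss_a, ds.seq_b, ds.ss_b)
    ]
    return np.array(rows), np.array(ds.labels)


# ---------------------------------------------------------------------------
# Whole-sequence baselines (level-II comparison encoders)

def aac(seq: str) -> np.ndarray:
    """Amino-acid composition: 20 frequencies summing to 1 ('X' ignored)."""
    counts = np.zeros(20)
    for ch in seq:
        k = _AA_INDEX.get(ch)
        if k is not None:
            counts[k] += 1
    total = counts.sum()
    return counts / total if total else counts


def two_grams(seq: str) -> np.ndarray:
    """Frequencies of the 400 ordered adjacent amino-acid pairs."""
    counts = np.zeros((20, 20))
    for u, v in zip(seq, seq[1:]):
        ku, kv = _AA_INDEX.get(u), _AA_INDEX.get(v)
        if ku is not None and kv is not None:
            counts[ku, kv] += 1
    denom = max(len(seq) - 1, 1)
    return counts.ravel() / denom


def pse_aac(seq: str, lam: int = 4, weight: float = 0.05,
            table: AminoAcidIndexTable | None = None) -> np.ndarray:
    """Pseudo amino-acid composition with lam correlation tiers.

    The k-th tier factor is the mean over positions of the mean squared
    difference of the (column-standardized) index values of residues k
    apart. Entries follow Chou's normalization: the first 20 are
    composition-derived, the last lam are ``weight * theta_k``, all divided
    by ``sum(f) + weight * sum(theta)``.
    """
    n = len(seq)
    if lam >= n:
        raise ValueError(f"lam={lam} must be smaller than sequence length {n}")
    table = (table or load_hqi8()).standardized()
    mat = table.matrix(seq)
    thetas = np.zeros(lam)
    for k in range(1, lam + 1):
        diffs = mat[:-k] - mat[k:]
        thetas[k - 1] = np.mean(np.mean(diffs ** 2, axis=1))
    comp = aac(seq)
    denom = comp.sum() + weight * thetas.sum()
    if denom == 0:
        denom = 1.0
    return np.concatenate([comp, weight * thetas]) / denom


def qrc(seq: str, table: AminoAcidIndexTable | None = None,
        m: int = 3) -> np.ndarray:
    """Quasi-residue couples: per index and gap, summed couple values.

    For index d and gap g in {0..m-1}, the entry for the ordered pair
    (u, v) accumulates ``x_u,d + x_v,d`` over every occurrence of u at
    position p and v at position p+g+1. Output is index-major, then gap,
    then the 400 ordered pairs, giving ``n_indices * m * 400`` values.
    """
    table = table or load_hqi8()
    n = len(seq)
    out = np.zeros((table.n_indices, m, 20, 20))
    for g in range(m):
        step = g + 1
        for p in range(n - step):
            u, v = seq[p], seq[p + step]
            ku, kv = _AA_INDEX.get(u), _AA_INDEX.get(v)
            if ku is None or kv is None:
                continue
            out[:, g, ku, kv] += table.row(u) + table.row(v)
    return out.ravel()


def liu_deviation(seq: str, table: AminoAcidIndexTable | None = None,
                  L: int = 9) -> np.ndarray:
    """Sequence 'deviation' autocorrelations gamma_{d,j}.

    gamma_{d,j} = (1/(n-d)) * sum_i x_{i,j} * x_{i+d,j} for each index j
    and lag d = 1..L, returned in row-major (j, d) order.
    """
    n = len(seq)
    if L >= n:
        raise ValueError(f"L={L} must be smaller than sequence length {n}")
    table = table or load_liu7()
    mat = table.matrix(seq)  # (n, n_indices)
    out = np.empty((table.n_indices, L))
    for d in range(1, L + 1):
        out[:, d - 1] = np.sum(mat[:-d] * mat[d:], axis=0) / (n - d)
    return out.ravel()


BASELINE_SCHEMAS = ("aac", "pseaac", "2grams", "qrc", "liu_hqi8", "liu_original")


def sequence_features(seq: str, schema: str) -> np.ndarray:
    """Apply one named baseline aggregation schema to a sequence."""
    if schema == "aac":
        return aac(seq)
    if schema == "pseaac":
        return pse_aac(seq)
    if schema == "2grams":
        return two_grams(seq)
    if schema == "qrc":
        return qrc(seq)
    if schema == "liu_hqi8":
        return liu_deviation(seq, load_hqi8())
    if schema == "liu_original":
        return liu_deviation(seq, load_liu7())
    raise ValueError(f"unknown baseline schema {schema!r}")


def pair_baseline_features(seq_a: str, seq_b: str, schema: str) -> np.ndarray:
    """Pair representation: concatenation [f(a), f(b)] of per-protein vectors."""
    return np.concatenate([sequence_features(seq_a, schema),
                           sequence_features(seq_b, schema)])
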