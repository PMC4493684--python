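"""Sliding-window fragment pairs and their residue-level labels.

A fragment is an odd-length window of ``w`` residues centred on a residue
that admits a full window. A fragment pair from two interacting chains is

* **positive** when the central residues are in contact and at least ``t``
  further contact pairs fall inside the +-D residue box around the centres
  (the interaction threshold filters out weak, possibly spurious contacts);
* **negative** when at least one of the two fragments touches no interface
  at all (no residue of the window in contact with any residue of the
  partner chain) — negatives are drawn only from interacting chain pairs;
* discarded otherwise (both fragments touch the interface but the centres
  are not a strong contact), which keeps ambiguous pairs out of training.

Negatives vastly outnumber positives, so the assembled dataset keeps all
positives and samples negatives at a 3:1 ratio.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .structure_io import ContactMap, ProteinChain

DEFAULT_WINDOW = 21
THRESHOLD_GRID = (0, 5, 10, 15, 20)


@dataclass(frozen=True)
class FragmentPair:
    """One labelled pair of window centres on two chains."""

    center_a: int
    center_b: int
    window: int
    label: int | None = None  # 1 positive, 0 negative, None unlabeled

    def __post_init__(self) -> None:
        w = self.window
        if w % 2 == 0 or not 3 <= w <= 31:
            raise ValueError(f"window must be odd and in [3, 31], got {w}")


@dataclass
class LabelingParams:
    """Residue-level labelling parameters.

    t: interaction threshold (neighbour contact pairs required beyond the
    central one); D: maximal neighbour interaction distance in residues;
    neg_ratio: negatives sampled per positive; seed: sampling seed.
    """

    t: int = 15
    D: int = 10
    neg_ratio: int = 3
    seed: int = 0
    count_mode: str = "pairs"  # "pairs" | "residues"

    def __post_init__(self) -> None:
        if self.t < 0 or self.D < 0 or self.neg_ratio < 0:
            raise ValueError("t, D and neg_ratio must be non-negative")
        if self.count_mode not in ("pairs", "residues"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")


@dataclass
class FragmentPairDataset:
    """Materialised fragment-pair examples ready for encoding.

    Each example stores the two window substrings of sequence and secondary
    structure plus the binary label, so encoders need no chain look-ups.
    """

    window: int
    seq_a: list[str] = field(default_factory=list)
    ss_a: list[str] = field(default_factory=list)
    seq_b: list[str] = field(default_factory=list)
    ss_b: list[str] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)

    def add(self, chain_a: ProteinChain, chain_b: ProteinChain,
            pair: FragmentPair) -> None:
        h = pair.window // 2
        ia, ib = pair.center_a, pair.center_b
        self.seq_a.append(chain_a.sequence[ia - h:ia + h + 1])
        self.ss_a.append(chain_a.ss3[ia - h:ia + h + 1])
        self.seq_b.append(chain_b.sequence[ib - h:ib + h + 1])
        self.ss_b.append(chain_b.ss3[ib - h:ib + h + 1])
        self.labels.append(int(pair.label))

    def extend(self, other: "FragmentPairDataset") -> None:
        if other.window != self.window:
            raise ValueError("window mismatch")
        for name in ("seq_a", "ss_a", "seq_b", "ss_b", "labels"):
            getattr(self, name).extend(getattr(other, name))

    def __len__(self) -> int:
        return len(self.labels)


def _valid_centers(n: int, w: int) -> range:
    h = w // 2
    return range(h, n - h)


def neighbour_contact_count(cmap: ContactMap, i: int, j: int, D: int,
                            mode: str = "pairs") -> int:
    """Neighbouring interaction count inside the +-D box around (i, j).

    ``mode="pairs"`` (default) counts contact *pairs* in the box, which is
    symmetric in the two chains; ``mode="residues"`` counts distinct
    residues of either chain involved in a box contact. The central pair
    (resp. the two central residues) is excluded.
    """
    box = [(ii, jj) for ii, jj in cmap.contacts
           if abs(ii - i) <= D and abs(jj - j) <= D]
    if mode == "pairs":
        return len(box) - (1 if (i, j) in cmap.contacts else 0)
    if mode == "residues":
        res = {("a", ii) for ii, _ in box} | {("b", jj) for _, jj in box}
        res.discard(("a", i))
        res.discard(("b", j))
        return len(res)
    raise ValueError(f"unknown count mode {mode!r}")


def label_positives(cmap: ContactMap, params: LabelingParams,
                    window: int = DEFAULT_WINDOW) -> list[FragmentPair]:
    """Fragment pairs whose centres are a contact with >= t neighbours."""
    ca = _valid_centers(cmap.n_a, window)
    cb = _valid_centers(cmap.n_b, window)
    out = []
    for i, j in sorted(cmap.contacts):
        if i in ca and j in cb and \
                neighbour_contact_count(cmap, i, j, params.D,
                                        params.count_mode) >= params.t:
            out.append(FragmentPair(i, j, window, 1))
    return out


def _active_centers(contact_flags: np.ndarray, w: int) -> np.ndarray:
    """Boolean per-centre flag: some window residue touches the interface."""
    n = len(contact_flags)
    h = w // 2
    cum = np.concatenate([[0], np.cumsum(contact_flags)])
    active = np.zeros(n, dtype=bool)
    for c in range(h, n - h):
        active[c] = cum[c + h + 1] - cum[c - h] > 0
    return active


def label_negatives(cmap: ContactMap, params: LabelingParams,
                    window: int = DEFAULT_WINDOW) -> list[FragmentPair]:
    """Fragment pairs where at least one fragment touches no interface.

    Raises if the contact map is empty: negatives come only from
    interacting chain pairs.
    """
    if not cmap.contacts:
        raise ValueError("negatives are drawn only from interacting pairs; "
                         "contact map is empty")
    in_contact_a = np.zeros(cmap.n_a, dtype=bool)
    in_contact_b = np.zeros(cmap.n_b, dtype=bool)
    for i, j in cmap.contacts:
        in_contact_a[i] = True
        in_contact_b[j] = True
    active_a = _active_centers(in_contact_a, window)
    active_b = _active_centers(in_contact_b, window)

    h = window // 2
    out = []
    for i in range(h, cmap.n_a - h):
        for j in range(h, cmap.n_b - h):
            if not (active_a[i] and active_b[j]):
                out.append(FragmentPair(i, j, window, 0))
    return out


def sample_dataset(
    chain_a: ProteinChain,
    chain_b: ProteinChain,
    positives: list[FragmentPair],
    negatives: list[FragmentPair],
    params: LabelingParams,
) -> FragmentPairDataset:
    """All positives plus min(neg_ratio * n_pos, n_neg) sampled negatives."""
    if not positives:
        raise ValueError("no positive fragment pairs to build a dataset from")
    window = positives[0].window
    rng = random.Random(params.seed)
    n_neg = min(params.neg_ratio * len(positives), len(negatives))
    chosen = rng.sample(negatives, n_neg)
    combined = list(positives) + chosen
    rng.shuffle(combined)

    ds = FragmentPairDataset(window)
    for pair in combined:
        ds.add(chain_a, chain_b, pair)
    return ds


def build_corpus_dataset(
    complexes: list[tuple[ProteinChain, ProteinChain, ContactMap]],
    params: LabelingParams,
    window: int = DEFAULT_WINDOW,
) -> FragmentPairDataset:
    """Label every complex and sample negatives at the corpus level 3:1."""
    all_pos: list[tuple[int, FragmentPair]] = []
    all_neg: list[tuple[int, FragmentPair]] = []
    for k, (_, _, cmap) in enumerate(complexes):
        for p in label_positives(cmap, params, window):
            all_pos.append((k, p))
        if cmap.contacts:
            for p in label_negatives(cmap, params, window):
                all_neg.append((k, p))
    if not all_pos:
        raise ValueError("corpus yielded no positive fragment pairs")
    rng = random.Random(params.seed)
    n_neg = min(params.neg_ratio * len(all_pos), len(all_neg))
    chosen = rng.sample(all_neg, n_neg)
    combined = all_pos + chosen
    rng.shuffle(combined)

    ds = FragmentPairDataset(window)
    for k, pair in combined:
        a, b, _ = complexes[k]
        ds.add(a, b, pair)
    return ds
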