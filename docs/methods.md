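# Methods

## Problem and model

`mlppi` predicts whether two proteins form a (hetero)dimeric complex using
only their amino-acid sequences and 3-state secondary structure (E/H/C).
Three-dimensional structures are needed only at training time, to define
residue-level ground truth.

The predictor has two levels.

**Level I — fragment pairs.** Residue-level ground truth comes from
inter-chain contacts: residues *i* of chain A and *j* of chain B are in
contact when any pair of their heavy atoms is within 4 Å (inclusive; the
atom set is configurable because interface-contact conventions vary —
any-heavy-atom at 4 Å is the common reading). Sliding windows of odd width
*w* (default 21, allowed range 3–31) centred on each residue define
fragments. A fragment pair is

* *positive* when the central residues are in contact and at least *t*
  further contact pairs fall within the ±D residue box around the centres
  (*D* = 10 by default; *t* ∈ {0, 5, 10, 15, 20}, default 15). The
  threshold focuses training on strong interface patches rather than
  incidental crystal contacts. The neighbour count is over contact *pairs*
  in the box (symmetric in the two chains, and stricter than counting
  residues); `count_mode="residues"` switches to distinct-residue counting.
* *negative* when at least one fragment has no residue in contact with any
  residue of the partner chain. Negatives are drawn only from chain pairs
  that do interact, so "fragment far from the interface" is well defined.
* neither (both fragments touch the interface but the centres are not a
  qualifying contact): discarded, to keep ambiguous pairs out of training.

Negatives are sampled (per corpus, uniformly, seeded) to a 3:1
negative:positive ratio. Fragments are encoded as raw integer codes,
8-value physicochemical index vectors, one-hot 3-state structure, or
concatenations; the default classifier is a random forest with 300 trees
and depth 15 (SVM-RBF alternative: C = 2, γ = 0.048). Training examples
are duplicated in both fragment orders and scoring averages both orders,
so the learned score is exactly symmetric under swapping the chains.

**Level II — protein pairs.** Applying the level-I model to all
full-window fragment-centre pairs of two chains yields a score matrix of
shape (n_a − w + 1) × (n_b − w + 1); cell (r, c) maps to residue centres
(r + w//2, c + w//2). Only full windows are scored because the level-I
model is defined only for complete fragments. The matrix is aggregated
into exactly 46 features:

| block | count |
|---|---|
| mean and (population) variance of all cells | 2 |
| sums of the 10 best rows / 10 best columns (raw sums, zero-padded) | 20 |
| sums of the 5 best diagonals of S and of Sᵀ | 10 |
| sum of cells on the intersections of the 10 best rows × columns | 1 |
| 10-bin histogram of scores, normalised to frequencies | 10 |
| fractions of nodes in the 3 largest connected components | 3 |

Diagonal bookkeeping: the "diagonals of S" are those with non-negative
offset, and the "diagonals of Sᵀ" the non-negative offsets of the
transpose; together they cover every diagonal, with the main diagonal
eligible on both sides — the only reading under which the two blocks
differ. The histogram is normalised so the features are length-invariant.

The graph features treat cells with score ≥ 0.5 (`edge_threshold`,
configurable; 0 disables thresholding) as candidate contacts in a
bipartite graph over the window-centre nodes of the two chains. Each node
keeps only its 3 strongest incident edges (`k_edges`; interacting residues
typically touch 2–3 partners), an edge surviving if either endpoint keeps
it, ties broken towards the smaller column then row index. Isolated nodes
form no components; fractions are over all row+column nodes.

The level-II classifier is a random forest with 300 trees and depth 7
(SVM-RBF alternative: C = 1, γ = 2).

## Negative protein pairs

Pairing random proteins produces negatives whose degree distribution
differs from the positives', letting a classifier cheat by scoring overall
reactivity. The generator instead walks the positive graph greedily:
repeatedly take the vertex v with the largest remaining working degree and
pair it with a non-adjacent u maximising remaining degree first and graph
distance second (disconnected = infinite, preferred — remote pairs are the
least likely false negatives); both working degrees are decremented; if no
admissible u exists, v's degree is zeroed. Degrees are re-evaluated every
iteration. Ties are broken lexicographically for reproducibility, and
candidates must have remaining degree > 0 — otherwise a vertex could
collect more negatives than it has positive interactions, defeating the
degree-matching purpose. On graphs whose complement admits a perfect
matching (e.g. a set of disjoint positive edges), every vertex ends with
exactly equal positive and negative degree.

## Component-level cross-validation

Standard pair-level k-fold CV leaks: a protein in a test pair may also sit
in training pairs. The component-level variant deals pairs into k
stratified folds; for each fold F with protein set P, the test set A is
*every* pair with both members in P and the training set B every pair with
neither member in P. Predictions over all A-sets are pooled as-is
(duplicates retained; `dedupe="mean"` averages per pair). The fold count
must not exceed the minority-class pair count. Accuracy/precision/recall
use a fixed 0.5 threshold; AUC uses midrank tie handling.

## Imbalance-corrected metrics

Benchmarks are balanced, reality is not: with ~26,000 hetero-interactions
among ~6,300 yeast proteins, (C(6300, 2) − 26000)/26000 ≈ 762.1481
non-interacting pairs per interacting one. Corrected metrics multiply the
negative-based confusion terms by d (default 762, the rounded ratio):

    Accuracy  = (TP + d·TN) / (TP + d·TN + d·FP + FN)
    Precision = TP / (TP + d·FP)

Recall and specificity (hence AUC) are unchanged by d. The blind-labelling
baseline precision is 1/(1 + d) ≈ 0.0013.

## Synthetic benchmark

The generator builds two-chain complexes with planted interfaces so the
whole pipeline can be exercised without structure downloads. Defaults
(chosen once as the study conditions): 40 complexes, chain lengths 60–90,
interface length 12–20 placed at least 10 residues from the chain ends,
contact density 1.0, interface secondary-structure bias 0.9 over a
background of H/E/C = 0.3/0.2/0.5.

Contacts form an anti-diagonal band of width 3 across the two interface
segments (matching the 2–3 partners of a typical interacting residue).
Each complex draws an interface *type* (helix or sheet) shared by both
chains, and interface positions emit that symbol with the bias
probability. Type matching is the planted *compatibility* signal: in a
generated negative pair both proteins still own interfaces (as in real
interactomes), but their types agree only by chance, so a predictor that
merely detects "has an interface" gains nothing — exactly the failure mode
the degree-matched negatives are designed to expose. With bias 0 the
structure carries no information about contacts and the pipeline must
score at chance; this is the built-in negative control.

In `coords` geometry mode, single-heavy-atom residues are laid out so the
4 Å relation recovers the planted band exactly: interface rows face each
other 2 Å apart with 2 Å spacing (one step off-diagonal 2.83 Å — contact;
two steps 4.47 Å — no contact) and all other residues are parked ≥ 46 Å
away. What the generator does *not* emulate: realistic fold geometry,
sequence–structure coupling, homologous redundancy, multi-domain or
multi-interface proteins, and noisy/predicted secondary structure. Passing
the synthetic end-to-end test therefore demonstrates that the machinery
propagates a planted local compatibility signal to the pair level, not
field performance on real proteomes.

## Evaluation experiment

`pipeline.run_synthetic_experiment` mirrors the full protocol: complexes
are split at the protein level (half for level-I training — every chain
appears on exactly one side, so the split discards nothing), the level-I
model is trained on fragment pairs labelled at t = 0, negatives are
generated on the held-out half's interaction graph, and the pair
classifier is evaluated by 10-fold component-level CV (10 rather than 30
folds because the held-out half contains 40 pairs). Score matrices are
cached per pair across folds; only the 46-dimensional level-II fit is
repeated. On these defaults the biased benchmark reaches a 5-seed mean
pooled AUC around 0.68 and the bias-0 control around 0.54.

## Numerical choices and edge cases

* Matrices shorter than 10 rows/columns or 5 diagonals are zero-padded so
  the feature vector length is always 46.
* Histogram bins are [0, 0.1), …, [0.9, 1.0] with the last bin closed.
* `'X'` residues are excluded from composition numerators and
  denominators; index-table lookups map `'X'` to the column-wise mean.
* PseAAC standardizes index columns to zero mean/unit variance before
  computing correlation tiers (the conventional recipe); tier weight 0.05
  and λ = 4 by default. QRC and the deviation encoder use raw table
  values; deviation lag L defaults to 9, QRC gap depth m to 3.
* The bundled 8- and 7-value amino-acid index tables are synthetic
  stand-ins assembled from classical published physicochemical properties
  (see the data-file headers); any user table of the same shape is
  accepted, and all code paths are table-agnostic.
* DSSP reduction: H/G/I → H, E/B → E, everything else (including gaps)
  → C; the mapping is overridable.
* PDB reading keeps the first altloc, drops hydrogens and non-standard
  residues, and maps unknown standard-record residue names to 'X'.

## Known limitations

* The score-matrix pass is O(n_a · n_b) classifier evaluations per pair;
  long chains are quadratically expensive.
* The negative generator is deterministic; sampling variability in
  negatives is not modelled.
* Probability calibration of the forests is not attempted; the 0.5
  decision threshold is a convention.
* Homodimers are out of scope throughout (self-pairs are dropped).
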