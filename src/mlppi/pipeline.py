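"""End-to-end experiment glue: benchmark -> level I -> level II -> CV.

The synthetic experiment mirrors the evaluation protocol used on real
complexes: complexes are split at the protein level, the fragment-pair
classifier is trained on one half, and the pair classifier is evaluated by
component-level cross-validation on the other half (positives plus
degree-matched generated negatives). Only sequence and secondary structure
reach the predictors at evaluation time; 3D information is used solely to
label training fragments.
"""

from __future__ import annotations

import dataclasses
import random

from . import two_level_predictor as tlp
from .evaluation import run_cv
from .fragment_dataset import LabelingParams, build_corpus_dataset
from .pair_builder import build_positive_graph, generate_negatives
from .synthetic_fixtures import Benchmark, SyntheticConfig, generate_benchmark


def run_synthetic_experiment(
    cfg: SyntheticConfig,
    seed: int,
    t: int = 0,
    window: int = 21,
    k_folds: int = 10,
    scheme: str = "ss3",
    train_fraction: float = 0.5,
    level1_cfg: tlp.ModelConfig | None = None,
    level2_cfg: tlp.ModelConfig | None = None,
) -> dict:
    """Generate a benchmark and score the full two-level pipeline.

    Returns the pooled component-level CV metrics plus bookkeeping counts.
    """
    cfg = dataclasses.replace(cfg, seed=seed)
    bench = generate_benchmark(cfg)
    rng = random.Random(seed + 1)

    order = list(range(len(bench.complexes)))
    rng.shuffle(order)
    n_train = round(len(order) * train_fraction)
    train_cx = [bench.complexes[i] for i in order[:n_train]]
    eval_cx = [bench.complexes[i] for i in order[n_train:]]

    params = LabelingParams(t=t, seed=rng.randrange(2 ** 31))
    dataset = build_corpus_dataset(train_cx, params, window)
    level1 = tlp.train_level1(dataset, scheme, level1_cfg,
                              seed=rng.randrange(2 ** 31))

    eval_graph = build_positive_graph([cm for _, _, cm in eval_cx])
    positives = [(a.chain_id, b.chain_id, 1) for a, b, _ in eval_cx]
    negatives = [(a, b, 0) for a, b in sorted(generate_negatives(eval_graph))]
    pairs = positives + negatives

    cache: dict = {}
    model_seed = rng.randrange(2 ** 31)

    def fit_fn(train_pairs):
        triples = [(bench.chains[a], bench.chains[b], y)
                   for a, b, y in train_pairs]
        return tlp.train_level2(triples, level1, level2_cfg, seed=model_seed,
                                feature_cache=cache)

    def predict_fn(model, test_pairs):
        return [tlp.predict_pair(model, bench.chains[a], bench.chains[b],
                                 feature_cache=cache)
                for a, b, _ in test_pairs]

    result = run_cv(pairs, fit_fn, predict_fn, k=k_folds,
                    seed=rng.randrange(2 ** 31))
    result["n_level1_examples"] = len(dataset)
    result["n_eval_pairs"] = len(pairs)
    result["n_eval_positives"] = len(positives)
    result["n_eval_negatives"] = len(negatives)
    return result
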