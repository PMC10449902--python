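"""End-to-end orchestration: simulate -> profiles -> score -> FDR -> network.

The full chain is deterministic under its seeds: two runs with the same
configuration produce byte-identical network files.
"""

from __future__ import annotations

import os
from dataclasses import replace

import numpy as np
import pandas as pd

from . import fdr as fdrmod
from . import io as iomod
from .classifier import ClassifierSpec, CoelutionClassifier, build_classifier
from .features import candidate_pairs, featurize_pairs
from .profiles import ProfileSet, infer_protein_profiles
from .simulate import GroundTruth, SimulationConfig, planted_pair_labels, simulate_dataset


def training_data(config: SimulationConfig, r2_threshold: float = 0.3,
                  sg_window: int = 5, sg_order: int = 2,
                  n_random_negatives: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Labeled feature matrix from one simulated experiment (control condition).

    Positives are planted co-complex pairs among the co-elution candidates;
    negatives are the remaining candidates plus an equal number of random
    non-candidate pairs (the analogue of randomly selected negative training
    pairs), so the classifier sees both hard and easy negatives.
    """
    records, _, truth = simulate_dataset(config)
    pset = infer_protein_profiles(records, config.n_fractions)
    condition = config.conditions[0]
    mat = pset.processed_matrix(condition, sg_window, sg_order)
    cands = candidate_pairs(mat, threshold=r2_threshold)
    feats = featurize_pairs(mat, cands)
    labels = planted_pair_labels(truth, zip(cands["protein_a"], cands["protein_b"]))

    n_rand = len(cands) if n_random_negatives is None else n_random_negatives
    if n_rand:
        rand = fdrmod.generate_decoys(cands, mat.index, n=n_rand,
                                      seed=config.seed + 77)
        rand_feats = featurize_pairs(mat, rand)
        feats = np.vstack([feats, rand_feats])
        labels = np.concatenate([labels, np.zeros(len(rand), dtype=int)])
    return feats, labels


def train_default_classifier(train_seeds: tuple[int, ...] = tuple(range(101, 117)),
                             base_config: SimulationConfig = SimulationConfig(),
                             spec: ClassifierSpec | None = None) -> CoelutionClassifier:
    """One classifier trained on held-out simulations, reused for evaluation
    datasets — mirroring the use of a single pretrained co-elution model."""
    feats_all, labels_all = [], []
    for s in train_seeds:
        f, l = training_data(replace(base_config, seed=int(s)))
        feats_all.append(f)
        labels_all.append(l)
    X = np.vstack(feats_all)
    y = np.concatenate(labels_all)
    if spec is None:
        spec = ClassifierSpec(layer_sizes=(X.shape[1], 100, 72), seed=int(train_seeds[0]))
    model = build_classifier(spec)
    model.fit(X, y)
    return model


def score_condition(profile_set: ProfileSet, condition: str,
                    model: CoelutionClassifier, decoy_seed: int,
                    r2_threshold: float = 0.3,
                    sg_window: int = 5, sg_order: int = 2) -> pd.DataFrame:
    """Candidate selection, featurization, classification and decoy scoring
    for one condition; returns the audit table of targets and decoys."""
    mat = profile_set.processed_matrix(condition, sg_window, sg_order)
    cands = candidate_pairs(mat, condition, threshold=r2_threshold)
    if not len(cands):
        raise ValueError(f"no candidate pairs in condition {condition}")
    t_probs = model.predict_probability(featurize_pairs(mat, cands))
    decoys = fdrmod.generate_decoys(cands, mat.index, seed=decoy_seed)
    decoys.insert(2, "condition", condition)
    d_probs = model.predict_probability(featurize_pairs(mat, decoys))
    return fdrmod.score_table(cands, t_probs, decoys, d_probs)


def run_pipeline(config: SimulationConfig, model: CoelutionClassifier,
                 out_dir: str | None = None, condition: str | None = None,
                 fdr: float = 0.05, min_probability: float = 0.75) -> dict:
    """Simulate one experiment and produce its filtered interaction network.

    Returns a dict with the scored audit table, the retained interaction
    set, and the ground truth; optionally writes ``network.tsv`` and
    ``scored_pairs.tsv`` under ``out_dir``.
    """
    records, standards, truth = simulate_dataset(config)
    pset = infer_protein_profiles(records, config.n_fractions)
    condition = condition or config.conditions[0]
    scored = score_condition(pset, condition, model, decoy_seed=config.seed + 13)
    retained = fdrmod.filter_interactions(scored, fdr=fdr,
                                          min_probability=min_probability,
                                          organism=truth.organism)
    result = {
        "records": records, "standards": standards, "truth": truth,
        "profiles": pset, "scored": scored, "retained": retained,
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        edges = retained.rename(columns={"protein_a": "node_a", "protein_b": "node_b"})
        iomod.write_network(edges, os.path.join(out_dir, "network.tsv"))
        scored.to_csv(os.path.join(out_dir, "scored_pairs.tsv"), sep="\t",
                      index=False, float_format="%.10g")
    return result


def empirical_fdr(model: CoelutionClassifier, base_config: SimulationConfig,
                  seeds: tuple[int, ...], fdr: float = 0.05,
                  min_probability: float = 0.75) -> pd.DataFrame:
    """Fraction of retained interactions not planted, over replicate simulations.

    For each seed, one experiment is simulated, scored on its control
    condition with the shared pretrained classifier, and filtered at
    q <= ``fdr`` and probability >= ``min_probability``; the false-discovery
    fraction is measured against the planted co-complex pair set.
    """
    rows = []
    for s in seeds:
        cfg = replace(base_config, seed=int(s))
        res = run_pipeline(cfg, model, fdr=fdr, min_probability=min_probability)
        truth: GroundTruth = res["truth"]
        ret = res["retained"]
        n_ret = len(ret)
        n_false = sum(
            0 if truth.is_true_pair(a, b) else 1
            for a, b in zip(ret["protein_a"], ret["protein_b"])
        )
        n_true_total = len(truth.true_pairs)
        recall = (n_ret - n_false) / n_true_total if n_true_total else np.nan
        rows.append({
            "seed": int(s),
            "n_retained": n_ret,
            "n_false": n_false,
            "empirical_fdr": (n_false / n_ret) if n_ret else 0.0,
            "recall": recall,
        })
    return pd.DataFrame(rows)
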