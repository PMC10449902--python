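"""Target-decoy FDR control for predicted interactions.

Decoy pairs are sampled uniformly from the unordered protein pairs that did
NOT pass the co-elution screen — the null of random co-elution — and scored
by the same trained classifier on their real profiles.  The FDR at a
probability threshold t is #(decoys >= t) / max(1, #(targets >= t)); each
target's q-value is the minimum FDR over thresholds at or below its score
(monotone step-down), with ties sharing the worse q.  The final interaction
set keeps targets with q <= 0.05 and probability >= 0.75.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class DecoyPoolError(ValueError):
    pass


def generate_decoys(candidates: pd.DataFrame, proteins: Sequence[str],
                    n: int | None = None, seed: int = 0) -> pd.DataFrame:
    """n distinct decoy pairs from the non-candidate pool, without replacement.

    ``candidates`` must have protein_a/protein_b columns (a < b); ``n``
    defaults to the candidate count.  Deterministic under ``seed``.
    Raises :class:`DecoyPoolError` when the pool is smaller than n.
    """
    proteins = sorted(set(proteins))
    cand = set(zip(candidates["protein_a"], candidates["protein_b"]))
    n_total = len(proteins) * (len(proteins) - 1) // 2
    pool_size = n_total - len(cand)
    if n is None:
        n = len(cand)
    if n > pool_size:
        raise DecoyPoolError(f"decoy pool has only {pool_size} pairs, {n} requested")

    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    # rejection sampling is cheap while n << pool; fall back to enumeration
    if n <= pool_size // 4:
        arr = np.array(proteins)
        while len(chosen) < n:
            i, j = rng.integers(0, len(arr), 2)
            if i == j:
                continue
            pair = (arr[min(i, j)], arr[max(i, j)])
            if pair in cand or pair in chosen:
                continue
            chosen.add(pair)
        pairs = sorted(chosen)
    else:
        pool = [p for p in combinations(proteins, 2) if p not in cand]
        idx = rng.choice(len(pool), size=n, replace=False)
        pairs = sorted(pool[i] for i in idx)
    return pd.DataFrame(pairs, columns=["protein_a", "protein_b"])


def target_decoy_qvalues(target_scores: np.ndarray, decoy_scores: np.ndarray) -> np.ndarray:
    """q-value per target score, in the input order of ``target_scores``."""
    t = np.asarray(target_scores, float)
    d = np.asarray(decoy_scores, float)
    if len(t) == 0 or len(d) == 0:
        raise ValueError("both target and decoy score sets must be non-empty")
    order = np.argsort(-t, kind="mergesort")
    ts = t[order]
    n_targets_ge = np.arange(1, len(ts) + 1, dtype=float)
    # decoys >= each target score
    d_sorted = np.sort(d)
    n_decoys_ge = len(d) - np.searchsorted(d_sorted, ts, side="left")
    fdr = n_decoys_ge / np.maximum(1.0, n_targets_ge)
    # step-down: q at rank i = min FDR over ranks >= i (lower thresholds)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    # ties share the worse q: propagate the max q within equal scores
    for i in range(len(ts) - 2, -1, -1):
        if ts[i] == ts[i + 1]:
            q_sorted[i] = q_sorted[i + 1]
    q = np.empty_like(q_sorted)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def score_table(targets: pd.DataFrame, target_probs: np.ndarray,
                decoys: pd.DataFrame, decoy_probs: np.ndarray) -> pd.DataFrame:
    """Audit table of all targets and decoys with probabilities and q-values."""
    q = target_decoy_qvalues(target_probs, decoy_probs)
    t = targets.copy()
    t["probability"] = target_probs
    t["q_value"] = q
    t["is_decoy"] = False
    d = decoys.copy()
    d["probability"] = decoy_probs
    d["q_value"] = np.nan
    d["is_decoy"] = True
    return pd.concat([t, d], ignore_index=True)


def filter_interactions(scored: pd.DataFrame, fdr: float = 0.05,
                        min_probability: float = 0.75,
                        organism: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Final interaction set: targets with q <= fdr and probability >= min_probability.

    Decoys never pass.  When an organism map ({protein: host|phage}) is
    given, each edge is annotated host-host / host-phage / phage-phage.
    """
    out = scored[
        (~scored.get("is_decoy", pd.Series(False, index=scored.index)))
        & (scored["q_value"] <= fdr)
        & (scored["probability"] >= min_probability)
    ].copy()
    if organism is not None:
        out["interaction_type"] = [
            interaction_type(a, b, organism)
            for a, b in zip(out["protein_a"], out["protein_b"])
        ]
    return out.reset_index(drop=True)


def interaction_type(a: str, b: str, organism: Mapping[str, str]) -> str:
    kinds = sorted((organism[a], organism[b]))
    return f"{kinds[0]}-{kinds[1]}"
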