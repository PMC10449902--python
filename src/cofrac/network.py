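"""Interactome graph construction and topology / enrichment statistics.

The retained interaction set becomes a simple undirected networkx graph
whose nodes carry organism tags (host / phage) and whose edges carry the
classifier probability and q-value.  On top of it: a log-log least-squares
power-law fit of the degree distribution (the scale-free check), genomic
distances of phage-phage pairs (the synteny check), ROC-based threshold
selection for virion-enrichment data, and neighborhood queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


class DegenerateDegreeError(ValueError):
    pass


def build_network(edges: pd.DataFrame, organism: Mapping[str, str]) -> nx.Graph:
    """Simple undirected graph from a retained-interaction table.

    Self-loops are forbidden; duplicate edges collapse to the higher
    probability.
    """
    g = nx.Graph()
    for _, row in edges.iterrows():
        a, b = row["protein_a"], row["protein_b"]
        if a == b:
            raise ValueError(f"self-loop on {a}")
        prob = float(row["probability"])
        if g.has_edge(a, b) and g[a][b]["probability"] >= prob:
            continue
        g.add_edge(a, b, probability=prob,
                   q_value=float(row.get("q_value", np.nan)),
                   interaction_type=row.get("interaction_type", ""))
    for node in g.nodes:
        g.nodes[node]["organism"] = organism.get(node, "host")
    return g


def edge_type_counts(g: nx.Graph) -> dict[str, int]:
    """Edge counts by interaction class; they partition the edge set."""
    counts = {"host-host": 0, "host-phage": 0, "phage-phage": 0}
    for a, b in g.edges:
        kinds = sorted((g.nodes[a]["organism"], g.nodes[b]["organism"]))
        counts[f"{kinds[0]}-{kinds[1]}"] += 1
    return counts


def degree_powerlaw_fit(g: nx.Graph) -> tuple[float, float]:
    """Least-squares line of log10(frequency) on log10(degree).

    Fitted over degrees >= 1 with frequency > 0; returns (exponent, r²)
    where exponent = -slope.  A single distinct degree is degenerate; two
    distinct degrees fit with a small-support warning.
    """
    degrees = np.array([d for _, d in g.degree() if d >= 1])
    if degrees.size == 0:
        raise DegenerateDegreeError("graph has no edges")
    values, freqs = np.unique(degrees, return_counts=True)
    if len(values) < 2:
        raise DegenerateDegreeError("degenerate degree distribution (single degree value)")
    if len(values) < 3:
        warnings.warn("power-law fit on fewer than 3 distinct degrees")
    res = stats.linregress(np.log10(values), np.log10(freqs))
    return float(-res.slope), float(res.rvalue ** 2)


def simulate_scalefree_graph(gamma: float, n_base: int = 600, k_max: int = 12,
                             seed: int = 0) -> nx.Graph:
    """Random simple graph whose degree frequencies follow k^(-gamma).

    Plants ``round(n_base * k**-gamma)`` nodes of degree k for k = 1..k_max
    and pairs stubs with the configuration model (self-loops and multi-edges
    collapsed).  This is the generative standard for exponent-recovery
    checks of :func:`degree_powerlaw_fit`: the log-log frequency line is
    planted directly, which is the quantity the least-squares fit estimates.
    (On a preferential-attachment realization the raw histogram's one-count
    tail biases the least-squares slope well below the asymptotic exponent —
    a property of the fitting method, not of the generator.)
    """
    ks = np.arange(1, k_max + 1)
    counts = np.maximum(1, np.round(n_base * ks.astype(float) ** -gamma)).astype(int)
    degs = np.repeat(ks, counts)
    if degs.sum() % 2:
        degs = np.append(degs, 1)
    g = nx.configuration_model(degs.tolist(), seed=seed)
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def genomic_distance(pairs: pd.DataFrame, annotation: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Start-to-start genomic distance in kb for each pair on a linear genome.

    Pairs with an unannotated gene or with genes on different genomes are
    skipped (counted in the second return value).
    """
    ann = annotation.set_index("gene_id")
    rows = []
    skipped = 0
    for _, row in pairs.iterrows():
        a, b = row["protein_a"], row["protein_b"]
        if a not in ann.index or b not in ann.index:
            skipped += 1
            continue
        if ann.loc[a, "genome_id"] != ann.loc[b, "genome_id"]:
            skipped += 1
            continue
        dist_kb = abs(int(ann.loc[a, "start"]) - int(ann.loc[b, "start"])) / 1000.0
        rows.append((a, b, dist_kb))
    if skipped:
        warnings.warn(f"skipped {skipped} pair(s) without comparable annotation")
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "distance_kb"]), skipped


@dataclass(frozen=True)
class RocResult:
    """ROC sweep over observed score values.

    ``selected_threshold`` is the Youden point (max tpr - fpr, ties broken
    toward the higher threshold) — maximum sensitivity at the lowest
    false-positive rate.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    selected_threshold: float


def roc_threshold(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Full ROC over observed score values, AUC by trapezoid, Youden threshold."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    thresholds = np.unique(s)[::-1]  # descending; classify positive at score >= t
    tpr = np.array([np.sum((s >= t) & (y == 1)) / n_pos for t in thresholds])
    fpr = np.array([np.sum((s >= t) & (y == 0)) / n_neg for t in thresholds])
    # close the curve at (0,0) and (1,1)
    f = np.concatenate([[0.0], fpr, [1.0]])
    t = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(t, f))
    youden = tpr - fpr
    best = int(np.argmax(youden))  # first index = highest threshold wins ties
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                     selected_threshold=float(thresholds[best]))


def roc_table(result: RocResult) -> pd.DataFrame:
    return pd.DataFrame({"threshold": result.thresholds, "tpr": result.tpr,
                         "fpr": result.fpr})


def enrichment_log2fc(enriched: pd.Series, reference: pd.Series) -> pd.Series:
    """log2((enriched + c) / (reference + c)) over the shared protein universe.

    The pseudocount c is half the smallest nonzero intensity across both
    samples, keeping proteins absent from one sample finite.
    """
    idx = enriched.index.intersection(reference.index)
    e = enriched.loc[idx].astype(float)
    r = reference.loc[idx].astype(float)
    pooled = np.concatenate([e.to_numpy(), r.to_numpy()])
    nonzero = pooled[pooled > 0]
    c = nonzero.min() / 2.0 if nonzero.size else 1.0
    return np.log2((e + c) / (r + c)).rename("log2fc")


def neighborhood_query(g: nx.Graph, protein_id: str,
                       min_probability: float = 0.0) -> nx.Graph:
    """Induced star of the protein and its direct interactors at or above a
    probability cutoff; unknown proteins give an empty graph with a warning."""
    if protein_id not in g:
        warnings.warn(f"protein {protein_id} not in network")
        return nx.Graph()
    star = nx.Graph()
    star.add_node(protein_id, **g.nodes[protein_id])
    for nb in g.neighbors(protein_id):
        if g[protein_id][nb]["probability"] >= min_probability:
            star.add_node(nb, **g.nodes[nb])
            star.add_edge(protein_id, nb, **g[protein_id][nb])
    return star
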