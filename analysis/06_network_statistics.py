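"""Interactome topology, synteny and virion-enrichment statistics.

Builds the graph from the retained interactions, counts edges by
host/phage class, fits the log-log degree power law, measures genomic
distances of phage-phage pairs (the no-synteny signature), and selects the
virion-enrichment intensity threshold from the ROC against known virion
proteins.
"""

import os

import pandas as pd

from cofrac import io
from cofrac.network import (build_network, degree_powerlaw_fit, edge_type_counts,
                            enrichment_log2fc, genomic_distance, roc_table,
                            roc_threshold, simulate_scalefree_graph)
from cofrac.simulate import SimulationConfig, simulate_dataset

DATA = os.path.join(os.path.dirname(__file__), "..", "results", "data")
OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 3


def main() -> None:
    edges = io.read_network(os.path.join(OUT, "network.tsv")).rename(
        columns={"node_a": "protein_a", "node_b": "protein_b"})
    _, _, truth = simulate_dataset(SimulationConfig(seed=SEED))

    g = build_network(edges, dict(truth.organism))
    counts = edge_type_counts(g)
    print(f"network: {g.number_of_nodes()} proteins, {g.number_of_edges()} "
          f"interactions {counts}")
    try:
        exponent, r2 = degree_powerlaw_fit(g)
        print(f"degree power law on this network: exponent {exponent:.2f} "
              f"(r2 = {r2:.2f}) — a small union of planted cliques is not "
              f"scale-free, so a poor fit here is expected")
    except ValueError as err:
        print(f"degree power law not fit: {err}")
    sf = simulate_scalefree_graph(gamma=2.2, seed=SEED)
    exp_sf, r2_sf = degree_powerlaw_fit(sf)
    print(f"estimator check on a planted scale-free graph (gamma = 2.2): "
          f"exponent {exp_sf:.2f} (r2 = {r2_sf:.2f})")

    ann = io.read_annotation(os.path.join(DATA, "gene_annotation.tsv"))
    pp = edges[edges["interaction_type"] == "phage-phage"]
    dist, skipped = genomic_distance(pp, ann)
    if len(dist):
        print(f"phage-phage genomic distance: median "
              f"{dist['distance_kb'].median():.1f} kb, max "
              f"{dist['distance_kb'].max():.1f} kb over {len(dist)} pairs "
              f"({skipped} skipped)")

    vir = pd.read_csv(os.path.join(DATA, "virion_enrichment.tsv"), sep="\t")
    scores = vir["enriched_intensity"] / vir["reference_intensity"]
    roc = roc_threshold(scores, vir["is_virion"])
    roc_table(roc).to_csv(os.path.join(OUT, "virion_roc.tsv"), sep="\t",
                          index=False, float_format="%.6g")
    lfc = enrichment_log2fc(vir.set_index("protein_id")["enriched_intensity"],
                            vir.set_index("protein_id")["reference_intensity"])
    called = scores >= roc.selected_threshold
    print(f"virion ROC: AUC {roc.auc:.2f}, threshold {roc.selected_threshold:.2f} "
          f"-> {int(called.sum())} proteins called virion "
          f"(mean log2 enrichment of known virion proteins: "
          f"{lfc[vir.set_index('protein_id')['is_virion'] == 1].mean():.2f})")


if __name__ == "__main__":
    main()
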