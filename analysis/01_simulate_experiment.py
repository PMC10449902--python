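"""Simulate the co-fractionation study and write its raw tables.

A 72-fraction, two-replicate SEC-MS experiment of a control and an infected
condition, with 15 planted complexes (3-5 subunits) and 15 monomers, plus
the auxiliary measurements: calibration standards, a whole-proteome
abundance companion experiment, a virion-enrichment experiment and gene
coordinates on two linear genomes.  Outputs land under results/data/.
"""

import os

from cofrac import io
from cofrac.simulate import (SimulationConfig, simulate_dataset,
                             simulate_gene_annotation, simulate_virion_experiment,
                             simulate_whole_proteome)

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "data")
SEED = 3


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    records, standards, truth = simulate_dataset(config)

    io.write_peptide_table(records, os.path.join(OUT, "peptides.tsv"))
    io.write_calibration_standards(standards, os.path.join(OUT, "standards.csv"))
    io.write_config(config.as_dict(), os.path.join(OUT, "simulation.cfg"))
    simulate_whole_proteome(truth).to_csv(
        os.path.join(OUT, "whole_proteome.tsv"), sep="\t", index=False)
    simulate_virion_experiment(truth).to_csv(
        os.path.join(OUT, "virion_enrichment.tsv"), sep="\t", index=False)
    io.write_annotation(simulate_gene_annotation(truth),
                        os.path.join(OUT, "gene_annotation.tsv"))

    n_phage = sum(1 for o in truth.organism.values() if o == "phage")
    print(f"simulated {len(truth.monomer_mw)} proteins "
          f"({n_phage} phage, {len(truth.monomer_mw) - n_phage} host), "
          f"{len(truth.complexes)} complexes, {len(truth.true_pairs)} planted pairs")
    print(f"{len(records)} peptide records written to {os.path.normpath(OUT)}")


if __name__ == "__main__":
    main()
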