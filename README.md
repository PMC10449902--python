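# cofrac

Co-fractionation mass spectrometry interaction mapping for host–pathogen
studies. When a native lysate is separated by size-exclusion chromatography
(SEC) and every fraction is quantified by MS, each protein leaves an
intensity trace across fractions; proteins that belong to the same complex
co-elute, so matching peak shapes and positions are evidence of physical
association. `cofrac` implements the full analysis chain for such an
experiment — built for infection studies (e.g. a jumbophage infecting
*Pseudomonas aeruginosa*) where thousands of host–pathogen interactions are
mapped in one run — and ships a synthetic-data generator with planted
ground truth so every stage can be validated end to end.

## The method

Given peptide-level intensities over `F = 72` fractions, two biological
replicates and two conditions (control and infected):

1. **Protein inference (sibling peptides).** For each protein the two
   peptides whose traces (concatenated across all samples) show the highest
   mutual Pearson correlation are averaged, so the same peptides quantify
   the protein everywhere. Profiles are Savitzky–Golay smoothed and min–max
   rescaled to [0, 1]; replicates are averaged.
2. **Candidate selection.** All protein pairs with squared Pearson
   correlation r² ≥ 0.3 enter prediction.
3. **Co-elution scoring.** Each pair is described by 147 features —
   per-fraction sliding-window (q = 6) correlation (72), per-fraction
   intensity difference (72), peak shift, Euclidean distance, and the
   contrast angle arccos(⟨x,y⟩/‖x‖‖y‖) — and scored by a fully connected
   network (147 → 100 → dropout 0.2 → 72 → sigmoid; Adam, lr 10⁻³, binary
   cross-entropy, ≤100 epochs, early stopping patience 20).
4. **FDR control.** An equal number of decoy pairs is sampled from the
   pairs that failed the co-elution screen and scored by the same model;
   target–decoy competition yields q-values
   (FDR(t) = #decoys ≥ t / #targets ≥ t, step-down), and the final network
   keeps targets with q ≤ 0.05 **and** probability ≥ 0.75.
5. **MW calibration.** log₁₀(MW) is regressed on apex fraction over a
   standards mixture (anchored at the high-MW end by a ribosome-scale
   particle); a peak at ≥ 2× the protein's monomeric mass is "assembled".
6. **Differential SEC.** Per protein, the posterior probability (equal
   priors) that control and infected profiles come from independent latent
   profiles rather than noisy copies of a shared one — sensitive to both
   peak shifts (assembly state) and amplitude changes (stoichiometry).
   Combined with whole-proteome abundance statistics (|log₂FC| ≥ 2,
   BH q ≤ 0.01) and the SEC score ≥ 0.5 rule into regulation classes.
7. **Network statistics.** Edge accounting by host/phage class, log–log
   least-squares power-law fit of the degree distribution, genomic
   distances of phage–phage pairs, and ROC-based (Youden) threshold
   selection for virion-enrichment experiments.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
experiment (seed 3; outputs under `results/`):

```sh
python analysis/01_simulate_experiment.py
python analysis/02_profiles_and_qc.py
python analysis/04_score_interactions.py
```

which prints:

```
simulated 73 proteins (25 phage, 48 host), 15 complexes, 87 planted pairs
26896 peptide records written to results/data

control: 73 proteins | mean replicate r = 0.949 | global replicate r2 = 0.924 | 70% single-peak proteins
infected: 73 proteins | mean replicate r = 0.941 | global replicate r2 = 0.923 | 71% single-peak proteins

classifier trained: 22145 parameters, 67 epochs, validation loss 0.0000
238 candidate pairs scored against 238 decoys; 87 interactions retained
empirical FDR vs planted complexes: 0.0% | recall of planted pairs: 100.0%
network written to results/network.tsv
```

Reading: replicate agreement around r ≈ 0.95 says fractionation is
reproducible; 238 pairs pass the r² ≥ 0.3 screen, of which 87 survive
target–decoy q ≤ 0.05 plus probability ≥ 0.75 — here exactly the planted
co-complex pairs, with zero false discoveries on this run.
`03_mw_calibration.py`, `05_differential_sec.py` and
`06_network_statistics.py` continue with assembly-state calls, regulation
classes and network/ROC statistics.

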