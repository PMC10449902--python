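# Methods

## Signal model

The atomic observation is a protein's elution profile: its MS intensity
across F = 72 SEC fractions for one condition and replicate, inferred from
peptide-level quantities. The governing assumption is chromatographic:
members of one complex migrate together, so they share an elution peak
whose position reflects the assembly's hydrodynamic size, mapped to
molecular weight through a log-linear calibration (the SEC convention:
log₁₀ MW is linear in elution volume over the resolving range of the
column).

## Profile construction

**Sibling-peptide inference.** Peptide traces are collapsed per protein by
the top-2 rule: among a protein's peptides, the unordered pair with the
highest Pearson correlation of traces concatenated across *all* conditions
and replicates is averaged. Computing the selection globally guarantees the
same peptides quantify the protein in every sample, so between-sample
differences reflect biology rather than peptide choice. One peptide passes
through; two are averaged directly; ties between equally correlated pairs
break by lexicographic peptide order for determinism. Proteins with zero
total intensity are dropped with a warning.

**Smoothing and rescaling.** Profiles are Savitzky–Golay smoothed and
min–max rescaled to [0, 1]. Window 5 and polynomial order 2 are the
defaults: the smallest quadratic-preserving window suppresses fraction
noise without distorting peaks 1–2.5 fractions wide at 72-fraction
resolution. Negative filter output is clipped to zero before rescaling;
all-zero (or constant) profiles map to zero. Each replicate is processed
separately, replicates are averaged per condition, and the average is
rescaled once more; smoothing before averaging was chosen because replicate
apexes can sit a fraction apart and averaging raw traces first would
broaden peaks before the filter sees them. The alternative order (average,
then smooth) differs only at the second decimal of downstream scores.

**Peak detection.** Local maxima of the processed profile with prominence
≥ 0.1 and width ≥ 2 fractions (scipy's peak machinery). The peaks-per-
protein count is the resolution proxy: one peak per assembly the protein
participates in. The primary peak is the most prominent one, ties broken
toward the earlier (larger-assembly) apex.

## Pair scoring

Candidates are all pairs with squared Pearson correlation ≥ 0.3 on
processed profiles. Each candidate gets a 2F + 3 = 147-value descriptor:

- positions 1–72: Pearson correlation in a width-6 window centred on each
  fraction, truncated at the edges (truncation is what yields exactly one
  value per fraction); windows that are constant in either trace give 0;
- positions 73–144: per-fraction absolute intensity difference;
- positions 145–147: primary-apex peak shift (0 if either profile has no
  peak), Euclidean distance, and the contrast angle
  arccos(⟨x,y⟩/‖x‖‖y‖) in radians (π/2 for a zero-norm profile).

The windowed correlations are computed with local mean-centred sums, so
batch results match a window-by-window computation at float precision even
in profile tails spanning many orders of magnitude.

**Classifier.** A fully connected network: 147 inputs → 100 ReLU units →
dropout 0.2 → 72 ReLU units → 1 sigmoid output (22,145 trainable
parameters), trained with Adam (learning rate 10⁻³, batch 64) on binary
cross-entropy for at most 100 epochs with early stopping (patience 20) on a
20% validation split, best weights restored. The network is implemented
directly on numpy — forward/backward passes, inverted dropout and Adam —
which keeps training bit-reproducible under a seed, a property the
pipeline's determinism contract depends on. Inputs are z-scored with
statistics frozen at fit time (stored with the model, not parameters).
Dropout rate 0.2 is the conventional reading of the architecture's dropout
layer; a literal 0.2% would make the layer inert.

**Training corpus.** The reference workflow pretrains on millions of
labeled pairs from external co-fractionation corpora. Here the analogue is
planted labels pooled from 16 simulated layouts (seeds disjoint from any
evaluation data): positives are co-complex candidate pairs, negatives are
the remaining candidates plus an equal number of random non-candidate
pairs, so the model sees both hard negatives (neighbouring species that
pass the co-elution screen) and easy ones. Few-layout training
demonstrably overfits layout quirks and mis-ranks neighbour-complex pairs;
the corpus size is the lever that fixes it, not any threshold.

## FDR control

Decoys represent the null of random co-elution: an equal number of pairs
sampled uniformly without replacement from the pairs that *failed* the
candidate screen, scored by the same model on their real profiles (not
permuted ones). FDR at threshold t is #(decoys ≥ t)/max(1, #targets ≥ t);
q-values are the running minimum over lower thresholds (step-down), ties
sharing the worse value. The final set keeps q ≤ 0.05 and probability
≥ 0.75; the two filters are complementary (decoys control random
co-elution, the probability floor controls classifier confidence). The
cited posterior-probability competition of the original toolkit lives in
prior work; the standard count-ratio estimator stands in for it here, with
the same contract. FDR is controlled per condition.

## Molecular-weight calibration

Least-squares regression of log₁₀(MW) on apex fraction over the standards
(including a ribosome-scale high-MW anchor, regressed with the mixture
rather than anchored separately). Queries outside the standards' fraction
span return a value flagged as extrapolated — estimates for very large
assemblies carry extra error for exactly this reason. Monomeric masses are
sums of average residue masses (derived from elemental weights C 12.0107,
H 1.00794, N 14.0067, O 15.9994, S 32.065) plus one water (18.01528 Da).
A peak is "assembled" iff its apparent MW is ≥ 2× the monomeric mass,
boundary inclusive.

## Differential SEC score

For one protein with processed profiles a, b under two conditions, two
hypotheses are compared fraction-wise with Gaussian noise of scale s:
H0 — both are noisy copies of one shared latent profile m_i ~ N(μ₀, τ²);
H1 — independent latent profiles. Both marginal likelihoods are Gaussian in
closed form (H0 factorises through the sum/difference rotation:
(a−b)/√2 ~ N(0, s²)), and the score is the posterior of H1 under equal
priors. Identical profiles can never score above 0.5 (the H0 marginal
dominates on the diagonal); apex shifts and amplitude changes both inflate
|a−b| relative to s and drive the score toward 1. The score is unsigned; a
signed centre-of-mass diagnostic reports the shift direction.

Plug-ins: μ₀ and τ are the pooled mean and standard deviation of the two
profiles (τ floored at 0.1); s is the median absolute fraction-wise
difference between processed replicate profiles, taken over fractions where
either replicate exceeds 0.05 — elution profiles are mostly baseline zeros,
which would otherwise drive the estimate to zero regardless of peak-level
noise — and floored at 0.01.

Abundance regulation is assessed on the whole-proteome companion
measurement: log₂ fold change of condition means, two-sided t-test on log
intensities, Benjamini–Hochberg adjustment. A plain t-test is used because
no moderated statistic is specified for this axis. Classes combine
SEC score ≥ 0.5 and (|log₂FC| ≥ 2 and q ≤ 0.01) into
none / assembly_only / abundance_only / both.

## Network statistics

The retained set forms a simple undirected graph with host/phage node tags;
edge counts partition exactly into host-host, host-phage and phage-phage.
The degree power-law fit is the least-squares line of log₁₀ frequency on
log₁₀ degree over degrees with positive frequency — deliberately the
figure-style fit rather than a maximum-likelihood estimator, for fidelity
to the published method. A known consequence: on a preferential-attachment
realization the raw histogram's one-count tail biases this slope far below
the asymptotic exponent (measured ≈1.8–2.0 against a nominal 3), so
exponent-recovery checks use a configuration-model graph whose degree
frequencies are planted on the log–log line the fit estimates
(`simulate_scalefree_graph`); there the exponent is recovered within ~0.15.
Genomic distances are start-to-start on a linear genome, in kb; pairs on
different genomes are skipped with a warning. ROC threshold selection
sweeps observed score values, computes AUC by trapezoid, and takes the
Youden point (max TPR − FPR, ties toward the higher threshold) —
operationalising "maximum sensitivity at the lowest false-positive rate".

## Synthetic data

The generator emulates the study design: 72 fractions, 2 replicates,
control + infected conditions, 15 complexes of 3–5 subunits and 15
monomers (≈75 proteins, ≈90 planted pairs) — a deliberately desk-scale
proteome that keeps 20-replicate evaluations cheap while exercising every
code path. Elution peaks are Gaussians in fraction space (the simplest
generative match to smooth unimodal SEC peaks); complex members share one
apex whose position is consistent, through the calibration map, with the
sum of their monomeric masses; each member optionally (p = 0.5) carries a
secondary monomeric peak at 0.3 relative height; monomers elute at their
monomeric mass. Peak widths are drawn from 1.0–2.5 fractions — an
engineering default, not a claim about real peak-width distributions.
Replicates jitter each species' apex by N(0, 0.5 fractions), matching
replicate peaks overlapping within 1–2 fractions; peptide intensities are
the protein profile × a log-uniform [0.2, 1] response factor (so top-2
selection is non-trivial) × unit-mean log-normal noise (CV 0.2); values
under a detection limit are omitted, as a DIA report would. In the infected
condition, 20% of proteins are perturbed (shift ±10 fractions, abundance
×2², or both, in rotation). Calibration standards are noiseless by default
with a noise toggle.

Species apexes are planted with a minimum mutual separation of 2 fractions
inside their MW regions. This is an identifiability choice made at design
time: two species co-eluting at the same position are indistinguishable
from co-elution data in principle, so without separation an
empirical-FDR-against-planted-truth measurement would measure
identifiability, not the method. Real lysates *do* contain coincidentally
co-eluting unrelated species; passing tests on this generator therefore
demonstrates correct behaviour of the pipeline where co-elution signal is
decodable, and says nothing about the share of real pairs that are
inherently confounded. Other features of real data not emulated: retention
drift between runs, chimeric/shared peptides, missing fractions, baseline
contamination, heavy-tailed intensity noise.

Auxiliary experiments: a triplicate whole-proteome measurement (CV 0.1), a
virion-enrichment experiment (known virion proteins enriched by
2^N(4, 2)), and gene coordinates scattered uniformly on a 280-kb phage /
6.3-Mb host genome (no synteny by construction).

## Numerical choices and degenerate inputs

Pearson correlation over zero-variance traces is defined as 0 (no evidence
of co-movement). Min–max rescaling of a constant profile gives zeros.
Tied classifier scores share the worse q-value. The decoy sampler rejects
requests larger than the non-candidate pool, reporting its size. The
power-law fit refuses a single-degree graph and warns below three distinct
degrees. Pseudocounts for enrichment log-ratios are half the smallest
nonzero intensity. All stochastic components run on seeded generators;
identical seeds give byte-identical outputs end to end.

## Problem sizes

Default evaluations use the desk-scale design above: ≈75 proteins per
experiment, ≈240 candidate pairs, classifier training on ≈9,000 labeled
pairs from 16 layouts, and 20 replicate experiments for FDR measurement.
These sizes were chosen so the whole evaluation chain is a sub-minute
computation on one CPU while every statistic of interest (FDR, recall,
AUROC, MW error) is estimated from dozens-to-hundreds of events.

## Known limitations

- The SEC differential score is a documented stand-in for the cited
  Bayesian module of prior work; it preserves the score's contract
  ([0, 1], 0.5 boundary, sensitivity to shift and stoichiometry) but not
  that module's exact internals.
- The t-test/BH abundance axis is underpowered at two replicates; the
  simulated companion experiment uses three.
- The log–log least-squares power-law fit is biased on heavy-tailed
  realizations (see above); it is kept because it is the published method.
- Training labels come from the simulator, not an external interaction
  corpus; transfer to real data would require retraining on curated
  positives/negatives, for which the trainer accepts any labeled pair
  table.
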