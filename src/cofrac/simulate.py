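"""Synthetic co-fractionation datasets with planted ground truth.

The generator emulates a size-exclusion chromatography / MS experiment of
the kind used for interactome mapping: a lysate separated into F fractions
(72 by default), measured in biological duplicate under a control and an
infected condition.  Planted protein complexes give all their members one
shared Gaussian elution peak whose position is consistent, through the
log-linear fraction-to-MW calibration, with the sum of the members'
monomeric masses; monomers elute at their monomeric mass.  Peptide-level
intensities are the protein profile times a peptide response factor times
multiplicative log-normal noise, and replicate runs jitter each species'
apex by a fraction of a fraction index.

Complex and monomer apexes are planted with a minimum mutual separation
(``min_apex_separation``): two distinct species co-eluting at exactly the
same position are indistinguishable from co-elution data in principle, so
separable apexes are what makes the planted pair labels a meaningful
evaluation standard.  Real lysates do contain coincidentally co-eluting
species; see the methods note for what that means for interpreting results.

Everything is deterministic under ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Experimental design of one synthetic co-fractionation study.

    Defaults describe a 72-fraction, two-replicate, control-vs-infected
    experiment with 15 planted complexes of 3-5 subunits and 15 monomers;
    replicate apex jitter of 0.5 fractions keeps replicate peaks overlapping
    within 1-2 fractions, and 20% multiplicative noise is typical of
    label-free MS intensities.
    """

    n_fractions: int = 72
    n_replicates: int = 2
    conditions: tuple[str, ...] = ("control", "infected")
    n_complexes: int = 15
    complex_size_range: tuple[int, int] = (3, 5)
    n_monomers: int = 15
    peptides_per_protein_range: tuple[int, int] = (3, 6)
    peak_sigma_range: tuple[float, float] = (1.0, 2.5)
    apex_jitter_sd: float = 0.5
    noise_cv: float = 0.2
    perturbed_fraction: float = 0.2
    shift_magnitude: float = 10.0
    abundance_log2fc: float = 2.0
    seed: int = 0

    # engineering knobs (documented in docs/methods.md)
    min_apex_separation: float = 2.0
    monomer_peak_prob: float = 0.5
    monomer_peak_height: float = 0.3
    phage_fraction: float = 0.3
    calibration_slope: float = -0.045   # log10 Da per fraction
    calibration_intercept: float = 7.2  # log10 Da at fraction 0
    n_standards: int = 8
    standards_noise_sd: float = 0.0     # fractions; 0 = noiseless standards
    detection_limit: float = 1.0        # intensities below this are not reported
    abundance_log10_range: tuple[float, float] = (5.0, 7.0)

    def __post_init__(self) -> None:
        for name in ("n_fractions", "n_replicates", "n_complexes", "n_monomers"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.complex_size_range[0] < 2:
            raise ConfigError("complexes need at least 2 members")
        if not (0.0 <= self.perturbed_fraction <= 1.0):
            raise ConfigError("perturbed_fraction must be in [0, 1]")
        if len(self.conditions) < 1:
            raise ConfigError("at least one condition required")

    def fraction_to_mw(self, fraction: float | np.ndarray) -> float | np.ndarray:
        return 10.0 ** (self.calibration_slope * np.asarray(fraction, float)
                        + self.calibration_intercept)

    def mw_to_fraction(self, mw_da: float | np.ndarray) -> float | np.ndarray:
        return (np.log10(np.asarray(mw_da, float)) - self.calibration_intercept) \
            / self.calibration_slope

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PlantedComplex:
    complex_id: str
    members: tuple[str, ...]
    apex_by_condition: Mapping[str, float]
    mw_da: float
    sigma: float


@dataclass(frozen=True)
class GroundTruth:
    """Planted labels for every downstream evaluation."""

    complexes: tuple[PlantedComplex, ...]
    true_pairs: frozenset[tuple[str, str]]
    differential_proteins: Mapping[str, str]   # protein -> {shift, abundance, both}
    virion_proteins: frozenset[str]
    monomer_mw: Mapping[str, float]
    organism: Mapping[str, str]                # protein -> {host, phage}
    abundance: Mapping[str, float]
    config: SimulationConfig

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(sorted(self.monomer_mw))

    def is_true_pair(self, a: str, b: str) -> bool:
        return (min(a, b), max(a, b)) in self.true_pairs


def _spaced_positions(rng: np.random.Generator, n: int, lo: float, hi: float,
                      min_sep: float) -> np.ndarray:
    """n positions in [lo, hi], pairwise separated by >= min_sep, in random order."""
    span = hi - lo
    needed = (n - 1) * min_sep
    if needed > span:
        raise ConfigError(
            f"cannot place {n} apexes with separation {min_sep} in [{lo:.1f}, {hi:.1f}]"
        )
    slack = span - needed
    gaps = rng.dirichlet(np.ones(n + 1)) * slack
    pos = lo + np.cumsum(gaps[:-1]) + np.arange(n) * min_sep
    return pos[rng.permutation(n)]


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), length))


def _gaussian(fractions: np.ndarray, apex: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((fractions - apex) / sigma) ** 2)


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one complete synthetic experiment.

    Returns
    -------
    records
        Long-format peptide table (see :mod:`cofrac.io`), with intensities
        below the detection limit omitted, as a DIA report would.
    standards
        Calibration-standards table (name, mw_da, apex_fraction) spanning
        the fraction range, including a large ribosome-like particle.
    truth
        :class:`GroundTruth` with planted complexes, pair labels,
        differential and virion labels, and per-protein monomeric masses.
    """
    rng = np.random.default_rng(config.seed)
    F = config.n_fractions
    fractions = np.arange(1, F + 1, dtype=float)

    # --- plant species apexes ------------------------------------------------
    # complexes elute early (high MW), monomers late (low MW)
    cx_lo, cx_hi = 0.07 * F, 0.486 * F
    mono_lo, mono_hi = 0.528 * F, 0.972 * F
    cx_apex = _spaced_positions(rng, config.n_complexes, cx_lo, cx_hi,
                                config.min_apex_separation)
    mono_apex = _spaced_positions(rng, config.n_monomers, mono_lo, mono_hi,
                                  config.min_apex_separation)

    sizes = rng.integers(config.complex_size_range[0], config.complex_size_range[1] + 1,
                         config.n_complexes)
    n_members = int(sizes.sum())
    n_proteins = n_members + config.n_monomers
    if config.complex_size_range[1] > n_proteins:
        raise ConfigError("complex size exceeds total protein count")

    proteins: list[str] = []
    monomer_mw: dict[str, float] = {}
    complexes: list[PlantedComplex] = []
    # protein -> list of (apex, sigma, relative height); the complex peak is the
    # reference height 1, the optional monomeric peak is smaller
    peaks: dict[str, list[tuple[float, float, float]]] = {}
    species_of: dict[str, str] = {}  # protein -> species id whose jitter it follows

    idx = 0
    for c, (apex, size) in enumerate(zip(cx_apex, sizes)):
        mw_total = float(config.fraction_to_mw(apex))
        shares = rng.dirichlet(np.full(size, 5.0))
        sigma = float(rng.uniform(*config.peak_sigma_range))
        members = []
        for s in shares:
            pid = f"P{idx:04d}"
            idx += 1
            members.append(pid)
            mw = float(s * mw_total)
            monomer_mw[pid] = mw
            peaks[pid] = [(float(apex), sigma, 1.0)]
            species_of[pid] = f"CPX{c:03d}"
            if rng.random() < config.monomer_peak_prob:
                mono_f = float(np.clip(config.mw_to_fraction(mw), 2.0, F - 1.0))
                mono_sigma = float(rng.uniform(*config.peak_sigma_range))
                peaks[pid].append((mono_f, mono_sigma, config.monomer_peak_height))
        proteins.extend(members)
        complexes.append(PlantedComplex(
            complex_id=f"CPX{c:03d}",
            members=tuple(members),
            apex_by_condition={cond: float(apex) for cond in config.conditions},
            mw_da=mw_total,
            sigma=sigma,
        ))

    for m, apex in enumerate(mono_apex):
        pid = f"P{idx:04d}"
        idx += 1
        proteins.append(pid)
        monomer_mw[pid] = float(config.fraction_to_mw(apex))
        sigma = float(rng.uniform(*config.peak_sigma_range))
        peaks[pid] = [(float(apex), sigma, 1.0)]
        species_of[pid] = f"MONO{m:03d}"

    true_pairs = frozenset(
        (min(a, b), max(a, b))
        for cx in complexes for a, b in combinations(cx.members, 2)
    )

    # --- organism tags and virion labels ------------------------------------
    organism: dict[str, str] = {}
    for cx in complexes:
        u = rng.random()
        if u < 0.25:
            kinds = ["phage"] * len(cx.members)
        elif u < 0.50:  # mixed complex: a host-phage interface
            kinds = ["phage" if rng.random() < 0.5 else "host" for _ in cx.members]
            if "phage" not in kinds:
                kinds[0] = "phage"
            if "host" not in kinds:
                kinds[-1] = "host"
        else:
            kinds = ["host"] * len(cx.members)
        organism.update(dict(zip(cx.members, kinds)))
    for pid in proteins[n_members:]:
        organism[pid] = "phage" if rng.random() < config.phage_fraction else "host"
    phage_proteins = sorted(p for p in proteins if organism[p] == "phage")
    n_virion = max(1, len(phage_proteins) // 2) if phage_proteins else 0
    virion = frozenset(
        rng.choice(phage_proteins, size=n_virion, replace=False).tolist()
    ) if n_virion else frozenset()

    # --- differential labels -------------------------------------------------
    n_pert = int(round(config.perturbed_fraction * n_proteins))
    pert_ids = rng.choice(np.array(proteins), size=n_pert, replace=False).tolist()
    types = ["shift", "abundance", "both"]
    differential = {pid: types[i % 3] for i, pid in enumerate(pert_ids)}
    shift_sign = {pid: (1.0 if rng.random() < 0.5 else -1.0) for pid in pert_ids}

    abundance = {pid: float(10.0 ** rng.uniform(*config.abundance_log10_range))
                 for pid in proteins}

    truth = GroundTruth(
        complexes=tuple(complexes),
        true_pairs=true_pairs,
        differential_proteins=differential,
        virion_proteins=virion,
        monomer_mw=monomer_mw,
        organism=organism,
        abundance=abundance,
        config=config,
    )

    # --- replicate-level apex jitter (shared within a species) ---------------
    jitter: dict[tuple[str, str, int], float] = {}
    for sp in sorted(set(species_of.values())):
        for cond in config.conditions:
            for rep in range(1, config.n_replicates + 1):
                jitter[(sp, cond, rep)] = (
                    float(rng.normal(0.0, config.apex_jitter_sd))
                    if config.apex_jitter_sd > 0 else 0.0
                )

    # --- peptide-level records ------------------------------------------------
    s = float(np.sqrt(np.log1p(config.noise_cv ** 2)))  # log-normal with unit mean
    control = config.conditions[0]
    rows_protein, rows_peptide, rows_cond, rows_rep = [], [], [], []
    blocks = []
    for pid in proteins:
        n_pep = int(rng.integers(config.peptides_per_protein_range[0],
                                 config.peptides_per_protein_range[1] + 1))
        pep_seqs = sorted({_random_peptide(rng, int(rng.integers(8, 16)))
                           for _ in range(n_pep)})
        responses = 10.0 ** rng.uniform(np.log10(0.2), 0.0, len(pep_seqs))
        ptype = differential.get(pid)
        for cond in config.conditions:
            shift = 0.0
            scale = 1.0
            if cond != control and ptype in ("shift", "both"):
                shift = shift_sign[pid] * config.shift_magnitude
            if cond != control and ptype in ("abundance", "both"):
                scale = 2.0 ** config.abundance_log2fc
            for rep in range(1, config.n_replicates + 1):
                jit = jitter[(species_of[pid], cond, rep)]
                profile = np.zeros(F)
                for apex, sigma, height in peaks[pid]:
                    a = float(np.clip(apex + shift + jit, 1.0, F))
                    profile += height * _gaussian(fractions, a, sigma)
                profile *= abundance[pid] * scale
                for pep, resp in zip(pep_seqs, responses):
                    noise = (np.exp(rng.normal(-0.5 * s * s, s, F))
                             if s > 0 else np.ones(F))
                    inten = profile * resp * noise
                    blocks.append(inten)
                    rows_protein.append(pid)
                    rows_peptide.append(pep)
                    rows_cond.append(cond)
                    rows_rep.append(rep)

    inten = np.concatenate(blocks)
    n_traces = len(rows_protein)
    records = pd.DataFrame({
        "protein_id": np.repeat(rows_protein, F),
        "peptide": np.repeat(rows_peptide, F),
        "condition": np.repeat(rows_cond, F),
        "replicate": np.repeat(np.array(rows_rep, dtype=int), F),
        "fraction": np.tile(np.arange(1, F + 1), n_traces),
        "intensity": inten,
    })
    records = records[records["intensity"] >= config.detection_limit].reset_index(drop=True)

    standards = make_standards(config, rng)
    return records, standards, truth


def make_standards(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Calibration standards spanning the fraction range, noiseless by default.

    Includes a ribosome-like 2.2 MDa particle, mirroring the practice of
    anchoring the high-MW end of an SEC calibration with a purified ribosome.
    """
    F = config.n_fractions
    apexes = np.linspace(0.08 * F, 0.95 * F, config.n_standards)
    names = [f"STD{i + 1:02d}" for i in range(config.n_standards)]
    mws = config.fraction_to_mw(apexes)
    ribo_mw = 2.2e6
    ribo_apex = float(config.mw_to_fraction(ribo_mw))
    names.append("RIBOSOME_70S")
    apexes = np.append(apexes, ribo_apex)
    mws = np.append(mws, ribo_mw)
    if config.standards_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed + 1)
        apexes = apexes + rng.normal(0.0, config.standards_noise_sd, len(apexes))
    return pd.DataFrame({"name": names, "mw_da": mws, "apex_fraction": apexes})


def planted_pair_labels(truth: GroundTruth, pairs: Iterable[tuple[str, str]]) -> np.ndarray:
    """0/1 labels for candidate pairs: 1 iff the unordered pair is co-complex."""
    known = set(truth.monomer_mw)
    labels = []
    for a, b in pairs:
        if a not in known:
            raise KeyError(f"unknown protein {a}")
        if b not in known:
            raise KeyError(f"unknown protein {b}")
        labels.append(1 if truth.is_true_pair(a, b) else 0)
    return np.asarray(labels, dtype=int)


def simulate_whole_proteome(truth: GroundTruth, noise_cv: float = 0.1,
                            n_replicates: int = 3,
                            seed: int | None = None) -> pd.DataFrame:
    """Independent whole-lysate abundance measurement of the same proteins.

    Mirrors the paired global-proteome experiment used to separate
    abundance-level from assembly-level regulation: abundance-perturbed
    proteins change by ``2**abundance_log2fc`` in non-control conditions,
    shift-only proteins do not change at all.  Defaults to triplicate
    measurement, the usual design of a global-abundance companion
    experiment (it is independent of the fractionation replicates).
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    s = float(np.sqrt(np.log1p(noise_cv ** 2)))
    control = config.conditions[0]
    rows = []
    for pid in sorted(truth.monomer_mw):
        ptype = truth.differential_proteins.get(pid)
        for cond in config.conditions:
            scale = 1.0
            if cond != control and ptype in ("abundance", "both"):
                scale = 2.0 ** config.abundance_log2fc
            for rep in range(1, n_replicates + 1):
                noise = np.exp(rng.normal(-0.5 * s * s, s)) if s > 0 else 1.0
                rows.append((pid, cond, rep, truth.abundance[pid] * scale * noise))
    return pd.DataFrame(rows, columns=["protein_id", "condition", "replicate", "intensity"])


def simulate_virion_experiment(truth: GroundTruth, enrichment_log2fc: float = 4.0,
                               noise_sd: float = 2.0,
                               seed: int | None = None) -> pd.DataFrame:
    """Virion-enrichment intensities for phage proteins.

    Virion proteins are enriched by ``enrichment_log2fc`` (in log2 units, sd
    ``noise_sd``) over their whole-proteome reference; non-virion phage
    proteins scatter around zero enrichment.  Used for ROC threshold
    selection against the known-virion label set.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    rows = []
    for pid in sorted(truth.monomer_mw):
        if truth.organism[pid] != "phage":
            continue
        base = truth.abundance[pid]
        lfc = rng.normal(enrichment_log2fc if pid in truth.virion_proteins else 0.0,
                         noise_sd)
        rows.append((pid, base * 2.0 ** lfc, base, int(pid in truth.virion_proteins)))
    return pd.DataFrame(rows, columns=["protein_id", "enriched_intensity",
                                       "reference_intensity", "is_virion"])


def simulate_gene_annotation(truth: GroundTruth, phage_genome_length: int = 280_000,
                             host_genome_length: int = 6_300_000,
                             seed: int | None = None) -> pd.DataFrame:
    """Gene coordinates for every simulated protein on two linear genomes.

    Phage genes scatter uniformly over a jumbophage-sized genome (no
    synteny), host genes over a bacterial chromosome.  Gene length is drawn
    from the protein's monomeric mass (~110 Da per residue, 3 bp per codon).
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 15485863 if seed is None else seed)
    rows = []
    for pid in sorted(truth.monomer_mw):
        org = truth.organism[pid]
        glen = phage_genome_length if org == "phage" else host_genome_length
        length = max(150, int(truth.monomer_mw[pid] / 110.0) * 3)
        length = min(length, glen // 2)
        start = int(rng.integers(1, glen - length))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((pid, start, start + length - 1, strand,
                     f"{org}_genome", glen))
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand",
                                       "genome_id", "genome_length"])
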