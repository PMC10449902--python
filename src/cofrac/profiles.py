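"""From peptide records to protein elution profiles.

Protein quantities are inferred with the sibling-peptide-correlation
strategy: among a protein's peptides, the unordered pair whose traces
(concatenated across every condition and replicate, so the same peptides
serve every sample) correlate best is averaged; a single peptide passes
through, two peptides are averaged directly.  Profiles are then smoothed
with a Savitzky-Golay filter and min-max rescaled to [0, 1]; replicates are
averaged per condition after processing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter


class ProfileConfigError(ValueError):
    pass


@dataclass
class FractionProfile:
    """One protein's intensity trace across F fractions for a condition."""

    protein_id: str
    condition: str
    intensities: np.ndarray
    processed: bool = False
    selected_peptides: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.processed:
            lo, hi = self.intensities.min(initial=0.0), self.intensities.max(initial=0.0)
            if lo < -1e-9 or hi > 1.0 + 1e-9:
                raise ValueError("processed profile must lie in [0, 1]")


@dataclass(frozen=True)
class ElutionPeak:
    """A local maximum of a processed ([0,1]) elution profile.

    ``apex_fraction`` and the boundaries are 1-based fraction indices;
    ``apparent_mw_da`` is filled in by the calibration module.
    """

    apex_fraction: int
    prominence: float
    left_fraction: int
    right_fraction: int
    apparent_mw_da: float | None = None
    extrapolated: bool = False


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, defined as 0 when either trace has zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ProfileSet:
    """Raw protein-level traces for every condition and replicate.

    ``replicate_profiles[(condition, replicate)]`` is a proteins x F frame;
    ``condition_profiles[condition]`` averages replicates.  Processing
    (smooth + rescale per replicate, average, rescale) happens in
    :meth:`processed_matrix`.
    """

    n_fractions: int
    conditions: tuple[str, ...]
    replicates: tuple[int, ...]
    replicate_profiles: dict[tuple[str, int], pd.DataFrame]
    selected_peptides: dict[str, tuple[str, ...]]
    dropped_proteins: tuple[str, ...] = ()
    _processed_cache: dict = field(default_factory=dict, repr=False)

    @property
    def proteins(self) -> list[str]:
        first = next(iter(self.replicate_profiles.values()))
        return list(first.index)

    def condition_matrix(self, condition: str) -> pd.DataFrame:
        """Raw replicate-averaged profiles for one condition."""
        mats = [self.replicate_profiles[(condition, r)] for r in self.replicates]
        return sum(mats) / len(mats)

    def condition_profiles(self, condition: str) -> list[FractionProfile]:
        mat = self.condition_matrix(condition)
        return [
            FractionProfile(pid, condition, mat.loc[pid].to_numpy(),
                            selected_peptides=self.selected_peptides[pid])
            for pid in mat.index
        ]

    def processed_matrix(self, condition: str, sg_window: int = 5,
                         sg_order: int = 2) -> pd.DataFrame:
        """Processed ([0,1]) profiles: per-replicate SG smoothing and
        rescaling, replicate averaging, then a final rescale."""
        key = (condition, sg_window, sg_order)
        if key not in self._processed_cache:
            mats = []
            for r in self.replicates:
                raw = self.replicate_profiles[(condition, r)].to_numpy()
                mats.append(np.vstack([
                    smooth_and_rescale(row, sg_window, sg_order) for row in raw
                ]))
            mean = np.mean(mats, axis=0)
            mean = np.vstack([_rescale(row) for row in mean])
            self._processed_cache[key] = pd.DataFrame(
                mean, index=self.proteins,
                columns=np.arange(1, self.n_fractions + 1))
        return self._processed_cache[key]


def infer_protein_profiles(records: pd.DataFrame,
                           n_fractions: int | None = None) -> ProfileSet:
    """Collapse peptide records to protein traces (top-2 sibling peptides).

    For proteins with three or more peptides, all peptide pairs are scored
    by Pearson correlation of their traces concatenated across every
    condition and replicate, and the best pair (ties broken by lexicographic
    peptide order) is averaged — so the same two peptides quantify the
    protein in every sample.  Proteins with zero total intensity are dropped
    with a warning.
    """
    F = int(n_fractions if n_fractions is not None else records["fraction"].max())
    conditions = tuple(pd.unique(records["condition"]))
    replicates = tuple(sorted(records["replicate"].unique()))

    # dense peptide x (condition, replicate, fraction) matrix, missing = 0
    pivot = records.pivot_table(
        index=["protein_id", "peptide"],
        columns=["condition", "replicate", "fraction"],
        values="intensity", aggfunc="sum", fill_value=0.0,
    )
    full_cols = pd.MultiIndex.from_product(
        [conditions, replicates, range(1, F + 1)],
        names=["condition", "replicate", "fraction"])
    pivot = pivot.reindex(columns=full_cols, fill_value=0.0)

    selected: dict[str, tuple[str, ...]] = {}
    protein_rows: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for pid, block in pivot.groupby(level=0, sort=True):
        traces = block.droplevel(0)
        mat = traces.to_numpy()
        if mat.sum() == 0.0:
            dropped.append(str(pid))
            continue
        peptides = list(traces.index)
        if len(peptides) <= 2:
            chosen = list(range(len(peptides)))
        else:
            best = None
            for i, j in combinations(range(len(peptides)), 2):
                r = pearson(mat[i], mat[j])
                cand = (-r, peptides[i], peptides[j], (i, j))
                if best is None or cand < best:
                    best = cand
            chosen = list(best[3])
        selected[str(pid)] = tuple(peptides[i] for i in chosen)
        protein_rows[str(pid)] = mat[chosen].mean(axis=0)

    if dropped:
        warnings.warn(f"dropped {len(dropped)} protein(s) with zero total intensity: "
                      + ", ".join(dropped[:5]))

    proteins = sorted(protein_rows)
    stacked = np.vstack([protein_rows[p] for p in proteins]) if proteins else \
        np.zeros((0, len(full_cols)))
    replicate_profiles: dict[tuple[str, int], pd.DataFrame] = {}
    for ci, cond in enumerate(conditions):
        for ri, rep in enumerate(replicates):
            start = (ci * len(replicates) + ri) * F
            replicate_profiles[(cond, rep)] = pd.DataFrame(
                stacked[:, start:start + F], index=proteins,
                columns=np.arange(1, F + 1))
    return ProfileSet(
        n_fractions=F, conditions=conditions, replicates=replicates,
        replicate_profiles=replicate_profiles, selected_peptides=selected,
        dropped_proteins=tuple(dropped),
    )


def _rescale(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def smooth_and_rescale(profile: np.ndarray | FractionProfile, window: int = 5,
                       order: int = 2):
    """Savitzky-Golay smoothing followed by min-max rescaling to [0, 1].

    Negative filter output is clipped to zero before rescaling; an all-zero
    (or constant) profile maps to all zeros.  ``window`` must be odd and no
    larger than the profile length.
    """
    if isinstance(profile, FractionProfile):
        out = smooth_and_rescale(profile.intensities, window, order)
        return FractionProfile(profile.protein_id, profile.condition, out,
                               processed=True,
                               selected_peptides=profile.selected_peptides)
    x = np.asarray(profile, dtype=float)
    if window > len(x):
        raise ProfileConfigError(f"SG window {window} exceeds profile length {len(x)}")
    if window % 2 == 0:
        raise ProfileConfigError("SG window must be odd")
    if order >= window:
        raise ProfileConfigError("SG order must be smaller than the window")
    if not np.any(x):
        return np.zeros_like(x)
    sm = np.clip(savgol_filter(x, window, order), 0.0, None)
    return _rescale(sm)


def detect_peaks(profile: np.ndarray | FractionProfile, min_prominence: float = 0.1,
                 min_width: int = 2) -> list[ElutionPeak]:
    """Local maxima of a processed profile, by prominence and width.

    The number of peaks per protein is a direct proxy for how many distinct
    assemblies the protein participates in.  Returned sorted by apex
    fraction (1-based).
    """
    x = profile.intensities if isinstance(profile, FractionProfile) else \
        np.asarray(profile, float)
    idx, props = find_peaks(x, prominence=min_prominence, width=min_width)
    peaks = [
        ElutionPeak(
            apex_fraction=int(i) + 1,
            prominence=float(p),
            left_fraction=int(lb) + 1,
            right_fraction=int(rb) + 1,
        )
        for i, p, lb, rb in zip(idx, props["prominences"],
                                props["left_bases"], props["right_bases"])
    ]
    return sorted(peaks, key=lambda pk: pk.apex_fraction)


def primary_peak(peaks: list[ElutionPeak]) -> ElutionPeak | None:
    """Highest-prominence peak; ties broken toward the earlier apex."""
    if not peaks:
        return None
    return max(peaks, key=lambda pk: (pk.prominence, -pk.apex_fraction))


def replicate_correlation(mat_a: pd.DataFrame, mat_b: pd.DataFrame) -> tuple[pd.Series, float, int]:
    """Replicate agreement on raw profiles.

    Returns per-protein Pearson r over the shared protein set, the global r²
    of all paired intensities pooled, and the count of proteins present in
    only one replicate (excluded).
    """
    shared = mat_a.index.intersection(mat_b.index)
    excluded = (len(mat_a.index) - len(shared)) + (len(mat_b.index) - len(shared))
    a = mat_a.loc[shared].to_numpy()
    b = mat_b.loc[shared].to_numpy()
    per_protein = pd.Series(
        [pearson(a[i], b[i]) for i in range(len(shared))], index=shared, name="replicate_r")
    global_r = pearson(a.ravel(), b.ravel())
    return per_protein, float(global_r ** 2), int(excluded)


def peak_count_table(profile_set: ProfileSet, condition: str,
                     min_prominence: float = 0.1, min_width: int = 2,
                     sg_window: int = 5, sg_order: int = 2) -> pd.Series:
    """Peaks per protein on processed profiles for one condition."""
    mat = profile_set.processed_matrix(condition, sg_window, sg_order)
    return pd.Series(
        {pid: len(detect_peaks(mat.loc[pid].to_numpy(), min_prominence, min_width))
         for pid in mat.index},
        name="n_peaks",
    )


def qc_report(profile_set: ProfileSet, condition: str) -> pd.DataFrame:
    """Per-protein QC: peptide count, replicate correlation, peak count."""
    reps = profile_set.replicates
    per_protein, global_r2, _ = replicate_correlation(
        profile_set.replicate_profiles[(condition, reps[0])],
        profile_set.replicate_profiles[(condition, reps[-1])],
    )
    n_peaks = peak_count_table(profile_set, condition)
    out = pd.DataFrame({
        "protein_id": per_protein.index,
        "n_peptides": [len(profile_set.selected_peptides[p]) for p in per_protein.index],
        "replicate_r": per_protein.values,
        "n_peaks": n_peaks.loc[per_protein.index].values,
    })
    out.attrs["global_r2"] = global_r2
    return out
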