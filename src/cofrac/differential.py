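"""Differential SEC analysis between two conditions.

A protein's SEC differential score is the posterior probability, under
equal priors, of the hypothesis that its two condition profiles come from
independent latent elution profiles (H1) rather than noisy copies of one
shared latent profile (H0).  Fraction-wise noise is Gaussian with scale
``noise_sd`` (plug-in: the median absolute fraction-wise difference between
replicate profiles), and the latent profile prior is Gaussian with
empirical-Bayes mean and scale taken from the two profiles.  The score
lives in [0, 1] with 0.5 as the decision boundary and responds to both peak
position (assembly state) and amplitude (stoichiometry) changes.

Abundance-level regulation is assessed separately on whole-proteome summed
intensities (two-sided t-test on log intensities, Benjamini-Hochberg
adjusted), and the two axes combine into regulation classes using the
thresholds |log2FC| >= 2, q <= 0.01 and SEC score >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import ProfileSet

_LOG_HALF = float(np.log(0.5))


@dataclass(frozen=True)
class DifferentialResult:
    protein_id: str
    sec_score: float
    log2fc: float
    abundance_q: float
    regulation: str  # none | assembly_only | abundance_only | both


def estimate_noise_sd(profile_set: ProfileSet, condition: str,
                      sg_window: int = 5, sg_order: int = 2,
                      floor: float = 0.01, signal_level: float = 0.05) -> float:
    """Median absolute fraction-wise difference between processed replicate
    profiles — the data-driven plug-in for the Gaussian noise scale.

    The median is taken over fractions where either replicate carries signal
    (> ``signal_level``): elution profiles are mostly baseline zeros, which
    would otherwise drive the plug-in to zero regardless of peak-level noise.
    """
    from .profiles import smooth_and_rescale

    reps = profile_set.replicates
    if len(reps) < 2:
        return floor
    mats = []
    for r in reps[:2]:
        raw = profile_set.replicate_profiles[(condition, r)].to_numpy()
        mats.append(np.vstack([smooth_and_rescale(row, sg_window, sg_order)
                               for row in raw]))
    diff = np.abs(mats[0] - mats[1])
    mask = np.maximum(mats[0], mats[1]) > signal_level
    if not mask.any():
        return floor
    return float(max(np.median(diff[mask]), floor))


def sec_differential_score(profile_a: np.ndarray, profile_b: np.ndarray,
                           noise_sd: float) -> float:
    """Posterior probability of 'different' in the two-model comparison.

    H0: a_i, b_i ~ N(m_i, s²) with a shared latent m_i ~ N(mu0, tau²);
    H1: independent latents for a and b.  Marginals are Gaussian in closed
    form; equal model priors.  Symmetric in its arguments, <= 0.5 for
    identical profiles.
    """
    a = np.asarray(profile_a, float)
    b = np.asarray(profile_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("profiles must be non-empty")
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    s2 = float(noise_sd) ** 2
    pooled = np.concatenate([a, b])
    mu0 = float(pooled.mean())
    tau2 = max(float(pooled.var()), 0.01)

    # H1: each observation ~ N(mu0, s² + tau²), independent
    var1 = s2 + tau2
    ll1 = float(np.sum(stats.norm.logpdf(a, mu0, np.sqrt(var1))
                       + stats.norm.logpdf(b, mu0, np.sqrt(var1))))
    # H0: (a_i, b_i) bivariate normal, cov = [[s²+tau², tau²], [tau², s²+tau²]]
    # factorised via the sum/difference rotation:
    #   (a+b)/sqrt(2) ~ N(sqrt(2) mu0, s² + 2 tau²), (a-b)/sqrt(2) ~ N(0, s²)
    u = (a + b) / np.sqrt(2.0)
    w = (a - b) / np.sqrt(2.0)
    ll0 = float(np.sum(stats.norm.logpdf(u, np.sqrt(2.0) * mu0, np.sqrt(s2 + 2 * tau2))
                       + stats.norm.logpdf(w, 0.0, np.sqrt(s2))))
    # posterior of H1 under equal priors, in log space for stability
    m = max(ll0, ll1)
    p1 = np.exp(ll1 - m) / (np.exp(ll0 - m) + np.exp(ll1 - m))
    return float(p1)


def apex_shift_sign(profile_a: np.ndarray, profile_b: np.ndarray) -> int:
    """Signed diagnostic: +1 if B's centre of mass elutes later (smaller
    assembly), -1 if earlier, 0 for no material change."""
    a = np.asarray(profile_a, float)
    b = np.asarray(profile_b, float)
    f = np.arange(1, len(a) + 1)
    ca = float((f * a).sum() / a.sum()) if a.sum() > 0 else 0.0
    cb = float((f * b).sum() / b.sum()) if b.sum() > 0 else 0.0
    d = cb - ca
    return 0 if abs(d) < 0.5 else (1 if d > 0 else -1)


def differential_scores(profile_set: ProfileSet, condition_a: str, condition_b: str,
                        noise_sd: float | None = None,
                        sg_window: int = 5, sg_order: int = 2) -> pd.DataFrame:
    """SEC differential score per protein between two conditions."""
    if noise_sd is None:
        noise_sd = estimate_noise_sd(profile_set, condition_a, sg_window, sg_order)
    A = profile_set.processed_matrix(condition_a, sg_window, sg_order)
    B = profile_set.processed_matrix(condition_b, sg_window, sg_order)
    rows = []
    for pid in A.index:
        a = A.loc[pid].to_numpy()
        b = B.loc[pid].to_numpy()
        rows.append({
            "protein_id": pid,
            "sec_score": sec_differential_score(a, b, noise_sd),
            "shift_sign": apex_shift_sign(a, b),
        })
    return pd.DataFrame(rows)


def abundance_differential(whole_proteome: pd.DataFrame, condition_a: str,
                           condition_b: str) -> pd.DataFrame:
    """log2 fold change (B over A) and BH-adjusted q per protein.

    ``whole_proteome`` is long-format (protein_id, condition, replicate,
    intensity) with >= 2 replicates per condition.  Proteins absent (all
    zero) in one condition get an infinite fold change flag and no q.
    """
    piv = whole_proteome.pivot_table(index="protein_id", columns=["condition", "replicate"],
                                     values="intensity", aggfunc="sum", fill_value=0.0)
    a = piv[condition_a]
    b = piv[condition_b]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(mean_b / mean_a)

    finite = np.isfinite(log2fc) & (mean_a > 0) & (mean_b > 0)
    pvals = pd.Series(np.nan, index=piv.index)
    for pid in piv.index[finite]:
        la = np.log10(np.maximum(a.loc[pid].to_numpy(), 1e-12))
        lb = np.log10(np.maximum(b.loc[pid].to_numpy(), 1e-12))
        if la.std() == 0 and lb.std() == 0 and np.isclose(la.mean(), lb.mean()):
            pvals[pid] = 1.0
        else:
            pvals[pid] = stats.ttest_ind(lb, la).pvalue
    qvals = pd.Series(np.nan, index=piv.index)
    mask = pvals.notna()
    if mask.any():
        qvals[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    return pd.DataFrame({
        "protein_id": piv.index,
        "log2fc": log2fc.values,
        "p_value": pvals.values,
        "abundance_q": qvals.values,
        "infinite_fc": ~finite.values,
    }).reset_index(drop=True)


def classify_regulation(sec_score: float, log2fc: float, abundance_q: float,
                        sec_threshold: float = 0.5, fc_threshold: float = 2.0,
                        q_threshold: float = 0.01) -> str:
    """Combine the two regulation axes into a class label."""
    assembly = sec_score >= sec_threshold
    abundance = (np.isfinite(log2fc) and abs(log2fc) >= fc_threshold
                 and np.isfinite(abundance_q) and abundance_q <= q_threshold)
    if assembly and abundance:
        return "both"
    if assembly:
        return "assembly_only"
    if abundance:
        return "abundance_only"
    return "none"


def differential_report(profile_set: ProfileSet, whole_proteome: pd.DataFrame,
                        condition_a: str, condition_b: str,
                        noise_sd: float | None = None,
                        sec_threshold: float = 0.5, fc_threshold: float = 2.0,
                        q_threshold: float = 0.01) -> pd.DataFrame:
    """Full per-protein differential table (SEC score, log2FC, q, class)."""
    sec = differential_scores(profile_set, condition_a, condition_b, noise_sd)
    ab = abundance_differential(whole_proteome, condition_a, condition_b)
    out = sec.merge(ab, on="protein_id", how="left")
    out["regulation"] = [
        classify_regulation(s, f, q, sec_threshold, fc_threshold, q_threshold)
        for s, f, q in zip(out["sec_score"],
                           out["log2fc"].fillna(np.nan),
                           out["abundance_q"].fillna(np.nan))
    ]
    return out
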