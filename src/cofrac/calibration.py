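"""SEC molecular-weight calibration and assembly-state classification.

The calibration is the SEC convention: a least-squares line of log10(MW) on
apex fraction, fitted to a standards mixture (optionally anchored at the
high-MW end by a purified ribosome).  A detected peak's apparent MW is the
curve evaluated at its apex; a peak at >= 2x the protein's sequence-derived
monomeric mass is called assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import ElutionPeak

# Average residue masses from elemental weights
# C=12.0107, H=1.00794, N=14.0067, O=15.9994, S=32.065.
_C, _H, _N, _O, _S = 12.0107, 1.00794, 14.0067, 15.9994, 32.065
WATER_MASS = 2 * _H + _O  # 18.01528 Da


def _residue(c: int, h: int, n: int, o: int, s: int = 0) -> float:
    return c * _C + h * _H + n * _N + o * _O + s * _S


RESIDUE_MASSES: dict[str, float] = {
    "G": _residue(2, 3, 1, 1),
    "A": _residue(3, 5, 1, 1),
    "S": _residue(3, 5, 1, 2),
    "P": _residue(5, 7, 1, 1),
    "V": _residue(5, 9, 1, 1),
    "T": _residue(4, 7, 1, 2),
    "C": _residue(3, 5, 1, 1, 1),
    "L": _residue(6, 11, 1, 1),
    "I": _residue(6, 11, 1, 1),
    "N": _residue(4, 6, 2, 2),
    "D": _residue(4, 5, 1, 3),
    "Q": _residue(5, 8, 2, 2),
    "K": _residue(6, 12, 2, 1),
    "E": _residue(5, 7, 1, 3),
    "M": _residue(5, 9, 1, 1, 1),
    "H": _residue(6, 7, 3, 1),
    "F": _residue(9, 9, 1, 1),
    "R": _residue(6, 12, 4, 1),
    "Y": _residue(9, 9, 1, 2),
    "W": _residue(11, 10, 2, 1),
}


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationCurve:
    """log10(MW in Da) = slope * fraction + intercept.

    ``slope`` is negative: earlier fractions hold larger species.  Queries
    outside ``valid_fraction_range`` (the span of the standards) are allowed
    but flagged as extrapolated — MW estimates for assemblies beyond the
    calibration range carry extra error.
    """

    slope: float
    intercept: float
    valid_fraction_range: tuple[float, float]
    fit_r2: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CalibrationError("calibration slope must be negative "
                                   "(larger species elute earlier)")


def fit_calibration(standards: pd.DataFrame) -> CalibrationCurve:
    """Least-squares line of log10(mw_da) on apex_fraction.

    Needs at least two standards at distinct fractions.  ``fit_r2`` is the
    squared correlation of the regression; for two points it is exactly 1.
    """
    frac = np.asarray(standards["apex_fraction"], dtype=float)
    mw = np.asarray(standards["mw_da"], dtype=float)
    if len(frac) < 2:
        raise CalibrationError("need at least 2 calibration standards")
    if np.ptp(frac) == 0:
        raise CalibrationError("calibration standards at coincident fractions")
    res = stats.linregress(frac, np.log10(mw))
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        valid_fraction_range=(float(frac.min()), float(frac.max())),
        fit_r2=float(res.rvalue ** 2),
    )


def apparent_mw(peak: ElutionPeak | float, curve: CalibrationCurve) -> tuple[float, bool]:
    """Apparent MW in Da at a peak's apex, plus an extrapolation flag."""
    frac = peak.apex_fraction if isinstance(peak, ElutionPeak) else float(peak)
    mw = 10.0 ** (curve.slope * frac + curve.intercept)
    lo, hi = curve.valid_fraction_range
    return float(mw), not (lo <= frac <= hi)


def annotate_peaks(peaks: list[ElutionPeak], curve: CalibrationCurve) -> list[ElutionPeak]:
    out = []
    for pk in peaks:
        mw, extra = apparent_mw(pk, curve)
        out.append(replace(pk, apparent_mw_da=mw, extrapolated=extra))
    return out


def monomeric_mass(sequence: str) -> float:
    """Average monomeric mass of a protein sequence (residues + one water)."""
    total = WATER_MASS
    for i, aa in enumerate(sequence):
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}") from None
    return total


def assembly_state(peaks: list[ElutionPeak], monomer_mw: float,
                   curve: CalibrationCurve) -> tuple[list[str], str]:
    """Classify each peak as monomeric or assembled.

    A peak is assembled iff its apparent MW is at least twice the monomeric
    mass (boundary inclusive); the protein summary is 'assembled' if any
    peak is.
    """
    states = []
    for pk in peaks:
        mw = pk.apparent_mw_da
        if mw is None:
            mw, _ = apparent_mw(pk, curve)
        states.append("assembled" if mw >= 2.0 * monomer_mw else "monomeric")
    summary = "assembled" if "assembled" in states else "monomeric"
    return states, summary


def assembly_report(peak_map: dict[str, list[ElutionPeak]],
                    monomer_mw: dict[str, float],
                    curve: CalibrationCurve) -> pd.DataFrame:
    """Per-protein assembly summary across detected peaks."""
    rows = []
    for pid in sorted(peak_map):
        peaks = annotate_peaks(peak_map[pid], curve)
        if pid not in monomer_mw:
            continue
        states, summary = assembly_state(peaks, monomer_mw[pid], curve)
        rows.append({
            "protein_id": pid,
            "n_peaks": len(peaks),
            "monomer_mw_da": monomer_mw[pid],
            "max_apparent_mw_da": max((p.apparent_mw_da for p in peaks), default=np.nan),
            "assembly_state": summary,
        })
    return pd.DataFrame(rows)
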