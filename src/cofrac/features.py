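"""Candidate-pair selection and the 147-value co-elution descriptor.

Five feature families describe how similarly two proteins elute:

(i)   sliding-window (q = 6) Pearson correlation, one value per fraction;
(ii)  per-fraction absolute intensity difference on [0,1] profiles;
(iii) peak shift between the primary (highest-prominence) apexes;
(iv)  Euclidean distance between the profiles;
(v)   contrast angle, arccos of the normalized dot product.

With F = 72 fractions the per-fraction families expand to 72 values each,
so the vector is 72 + 72 + 3 = 147; for other F it is 2F + 3.  Sliding
windows are centered on each fraction and truncated at the edges, which is
what yields exactly one value per fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import detect_peaks, primary_peak


class FeatureConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CandidatePair:
    """Unordered protein pair (a < b) retained by the co-elution screen."""

    protein_a: str
    protein_b: str
    condition: str
    r_squared: float

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError("self-pairs are not allowed")
        if self.protein_a > self.protein_b:
            raise ValueError("pair must be lexicographically ordered")


def candidate_pairs(profiles: pd.DataFrame, condition: str = "",
                    threshold: float = 0.3) -> pd.DataFrame:
    """All unordered pairs with squared Pearson correlation >= threshold.

    ``profiles`` is a proteins x F matrix of processed profiles.  Pairs
    where either profile has zero variance are given r = 0.  Returns a frame
    with columns protein_a, protein_b, r_squared (a < b).
    """
    X = profiles.to_numpy(dtype=float)
    names = np.asarray(profiles.index)
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[sd == 0.0, :] = 0.0
    corr[:, sd == 0.0] = 0.0
    r2 = corr ** 2
    ia, ib = np.triu_indices(len(names), k=1)
    keep = r2[ia, ib] >= threshold
    a, b = names[ia[keep]], names[ib[keep]]
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    out = pd.DataFrame({
        "protein_a": a2, "protein_b": b2,
        "r_squared": r2[ia[keep], ib[keep]],
    })
    if condition:
        out.insert(2, "condition", condition)
    return out.sort_values(["protein_a", "protein_b"], kind="mergesort").reset_index(drop=True)


def _window_bounds(F: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Half-open [start, end) per fraction for a centered width-q window,
    truncated at the profile edges."""
    i = np.arange(F)
    start = np.maximum(0, i - q // 2)
    end = np.minimum(F, i + (q + 1) // 2)
    return start, end


def sliding_window_correlation(x: np.ndarray, y: np.ndarray, q: int = 6) -> np.ndarray:
    """Pearson correlation of x and y over a width-q window centered at each
    fraction (edge-truncated).  Windows with zero variance in either trace
    contribute 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    F = len(x)
    if q > F:
        raise FeatureConfigError(f"window q={q} exceeds profile length {F}")
    return _batch_swc(x[None, :], y[None, :], q)[0]


def _batch_swc(X: np.ndarray, Y: np.ndarray, q: int) -> np.ndarray:
    """Vectorized sliding-window correlation for P aligned profile pairs.

    Uses local two-pass (mean-centred) sums over strided windows, so the
    result matches a window-by-window Pearson computation to float
    precision even where profile values span many orders of magnitude.
    """
    P, F = X.shape
    pad_left, pad_right = q // 2, (q + 1) // 2 - 1

    def windows(Z: np.ndarray) -> np.ndarray:
        pad = np.full((P, 1), np.nan)
        Zp = np.concatenate([np.repeat(pad, pad_left, axis=1), Z,
                             np.repeat(pad, pad_right, axis=1)], axis=1)
        return np.lib.stride_tricks.sliding_window_view(Zp, q, axis=1)

    Wx, Wy = windows(X), windows(Y)
    mask = np.isfinite(Wx)
    n = mask.sum(axis=2)
    Wx0 = np.where(mask, Wx, 0.0)
    Wy0 = np.where(mask, Wy, 0.0)
    mx = Wx0.sum(axis=2) / n
    my = Wy0.sum(axis=2) / n
    dx = np.where(mask, Wx0 - mx[:, :, None], 0.0)
    dy = np.where(mask, Wy0 - my[:, :, None], 0.0)
    vx = (dx * dx).sum(axis=2)
    vy = (dy * dy).sum(axis=2)
    cov = (dx * dy).sum(axis=2)
    bad = (vx == 0.0) | (vy == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    return np.where(bad, 0.0, np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0))


def intensity_difference(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Element-wise |x - y| on processed profiles."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    return np.abs(x - y)


def pair_scalars(x: np.ndarray, y: np.ndarray,
                 peaks_x: list | None = None,
                 peaks_y: list | None = None) -> tuple[float, float, float]:
    """(peak shift, Euclidean distance, contrast angle) for one pair.

    The peak shift compares primary (highest-prominence) apexes and is 0
    when either profile has no detected peak; the contrast angle is the
    arccos of the normalized dot product in radians, with pi/2 for a
    zero-norm input.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    px = primary_peak(peaks_x if peaks_x is not None else detect_peaks(x))
    py = primary_peak(peaks_y if peaks_y is not None else detect_peaks(y))
    shift = float(abs(px.apex_fraction - py.apex_fraction)) if px and py else 0.0
    eucl = float(np.linalg.norm(x - y))
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        angle = np.pi / 2
    else:
        angle = float(np.arccos(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0)))
    return shift, eucl, angle


def featurize(x: np.ndarray, y: np.ndarray, q: int = 6,
              peaks_x: list | None = None, peaks_y: list | None = None) -> np.ndarray:
    """Assemble the co-elution descriptor for one pair (length 2F + 3).

    Layout: positions 0..F-1 sliding-window correlation; F..2F-1 intensity
    difference; then peak shift, Euclidean distance, contrast angle.
    """
    swc = sliding_window_correlation(x, y, q)
    diff = intensity_difference(x, y)
    scalars = pair_scalars(x, y, peaks_x, peaks_y)
    return np.concatenate([swc, diff, scalars])


def featurize_pairs(profiles: pd.DataFrame, pairs: pd.DataFrame, q: int = 6,
                    peak_min_prominence: float = 0.1,
                    peak_min_width: int = 2) -> np.ndarray:
    """Feature matrix (n_pairs x (2F+3)) for many pairs over one profile set.

    Peaks are detected once per protein and reused across pairs.
    """
    F = profiles.shape[1]
    X = profiles.to_numpy(dtype=float)
    index = {p: i for i, p in enumerate(profiles.index)}
    missing = [p for p in pd.unique(pairs[["protein_a", "protein_b"]].values.ravel())
               if p not in index]
    if missing:
        raise KeyError(f"missing profile for protein {missing[0]}")
    ia = pairs["protein_a"].map(index).to_numpy()
    ib = pairs["protein_b"].map(index).to_numpy()

    swc = _batch_swc(X[ia], X[ib], q)
    diff = np.abs(X[ia] - X[ib])

    apex = np.full(len(index), np.nan)
    for p, i in index.items():
        pk = primary_peak(detect_peaks(X[i], peak_min_prominence, peak_min_width))
        if pk is not None:
            apex[i] = pk.apex_fraction
    shift = np.abs(apex[ia] - apex[ib])
    shift = np.nan_to_num(shift, nan=0.0)

    eucl = np.linalg.norm(X[ia] - X[ib], axis=1)
    norms = np.linalg.norm(X, axis=1)
    dots = np.einsum("ij,ij->i", X[ia], X[ib])
    denom = norms[ia] * norms[ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(dots / denom, -1.0, 1.0)
    angle = np.where(denom == 0.0, np.pi / 2, np.arccos(np.nan_to_num(cosang, nan=1.0)))

    return np.hstack([swc, diff, shift[:, None], eucl[:, None], angle[:, None]])
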