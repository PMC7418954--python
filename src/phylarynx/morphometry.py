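"""Landmark-based laryngeal morphometrics and the "larynx size" axis.

Each larynx is summarized by 14 labeled 3-D landmarks (mm) placed on the
cricoid, thyroid, and arytenoid cartilages and the hyoid bone.  Ten
interlandmark Euclidean distances characterize gross laryngeal shape; a
principal component analysis of their log10 values (on the correlation
matrix) yields a single dominant size factor used as the working "larynx
size" variable in all allometric analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MEASUREMENT_DEFINITIONS",
    "MEASUREMENT_NAMES",
    "measurements_from_landmarks",
    "coefficient_of_variation",
    "size_axis",
    "SizeAxis",
]

#: measurement name -> landmark index pairs whose Euclidean distances are
#: averaged.  Landmarks are numbered 1-14: 1-4 midsagittal cricoid extents
#: (ventral basal/apical, dorsal basal/apical), 5-6 lateral cricoid base,
#: 7-9 midsagittal thyroid (ventral basal, ventral apical, midpoint),
#: 10-11 dorsal thyroid lateral extents, 12-13 right/left arytenoid vocal
#: processes, 14 hyoid apex.  Vocal fold length is the mean of the
#: midpoint-to-right and midpoint-to-left vocal-process distances.
MEASUREMENT_DEFINITIONS: dict[str, tuple[tuple[int, int], ...]] = {
    "ventral cricoid height": ((1, 2),),
    "larynx height": ((1, 14),),
    "ventral thyroid height": ((7, 8),),
    "vocal fold length": ((9, 12), (9, 13)),
    "crico-thyroid distance": ((4, 9),),
    "dorsal cricoid height": ((3, 4),),
    "apical cricoid depth": ((2, 4),),
    "basal cricoid depth": ((1, 3),),
    "basal cricoid width": ((5, 6),),
    "dorsal thyroid width": ((10, 11),),
}

MEASUREMENT_NAMES: tuple[str, ...] = tuple(MEASUREMENT_DEFINITIONS)

N_LANDMARKS = 14


def measurements_from_landmarks(
    landmarks: np.ndarray | dict[int, np.ndarray],
    coincidence_tol: float = 1e-9,
) -> pd.Series:
    """Compute the 10 named distances (mm) from a 14 x 3 landmark array.

    ``landmarks`` may be a (14, 3) array (row *i* = landmark *i*+1) or a
    mapping from landmark number (1-14) to a length-3 coordinate.  Distances
    defined by several landmark pairs (vocal fold length) are the mean of
    the pairwise distances.
    """
    if isinstance(landmarks, dict):
        missing = [k for k in range(1, N_LANDMARKS + 1) if k not in landmarks]
        if missing:
            raise ValueError(f"missing landmarks: {missing}")
        lm = np.asarray([landmarks[k] for k in range(1, N_LANDMARKS + 1)], dtype=float)
    else:
        lm = np.asarray(landmarks, dtype=float)
    if lm.shape != (N_LANDMARKS, 3):
        raise ValueError(f"expected 14 x 3 landmark coordinates, got {lm.shape}")
    if not np.all(np.isfinite(lm)):
        bad = sorted(set(np.where(~np.isfinite(lm))[0] + 1))
        raise ValueError(f"non-finite coordinates at landmarks {bad}")
    d = np.linalg.norm(lm[:, None, :] - lm[None, :, :], axis=-1)
    off = d.copy()
    np.fill_diagonal(off, np.inf)
    if off.min() <= coincidence_tol:
        i, j = np.unravel_index(np.argmin(off), off.shape)
        warnings.warn(
            f"landmarks {i + 1} and {j + 1} coincide within {coincidence_tol:g} mm",
            stacklevel=2,
        )
    out = {
        name: float(np.mean([d[a - 1, b - 1] for a, b in pairs]))
        for name, pairs in MEASUREMENT_DEFINITIONS.items()
    }
    return pd.Series(out, name="distance_mm")


def coefficient_of_variation(values) -> float:
    """Sample CV: SD (n-1 denominator) over mean, computed on raw values."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least 2 values")
    m = x.mean()
    if m <= 0:
        raise ValueError("CV requires a positive mean")
    return float(x.std(ddof=1) / m)


@dataclass
class SizeAxis:
    """Leading principal component of the log10 measurement table.

    ``scores`` are standardized (unit variance) per-species values;
    ``loadings`` are correlation-scale loadings (eigenvector times the
    square root of the eigenvalue), sign-oriented so their mean is
    positive; ``variance_explained`` is the leading eigenvalue over the
    number of measurements; ``correlations`` are Pearson r between the
    scores and each log10 measurement column.
    """

    scores: pd.Series
    loadings: pd.Series
    variance_explained: float
    correlations: pd.Series
    standardized: bool = True

    def to_dict(self) -> dict:
        return {
            "variance_explained": self.variance_explained,
            "loadings": self.loadings.round(6).to_dict(),
            "correlations": self.correlations.round(6).to_dict(),
        }


def size_axis(log_measurements: pd.DataFrame, standardize_scores: bool = True) -> SizeAxis:
    """PCA size axis from a species x measurements table of log10 values.

    The PCA runs on the correlation matrix (all columns standardized), so
    the axis is invariant to the units of any raw measurement column.  With
    one retained component a varimax rotation is the identity, so loadings
    are reported directly on the correlation scale.  Set
    ``standardize_scores=False`` to keep scores in eigenvector scale
    (variance = eigenvalue) instead of unit variance.
    """
    X = log_measurements.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("size axis needs at least 3 species")
    if np.isnan(X).any():
        raise ValueError("missing cells in measurement table")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = list(log_measurements.columns[sd == 0])
        raise ValueError(f"constant measurement columns (correlation undefined): {const}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    lead = np.argmax(evals)
    ev, vec = float(evals[lead]), evecs[:, lead]
    if vec.mean() < 0:
        vec = -vec
    raw_scores = Z @ vec  # variance = eigenvalue (for the n-1 convention)
    loadings = vec * np.sqrt(ev)
    scores = raw_scores / raw_scores.std(ddof=1) if standardize_scores else raw_scores
    corr = np.array([np.corrcoef(scores, X[:, j])[0, 1] for j in range(p)])
    cols = list(log_measurements.columns)
    return SizeAxis(
        scores=pd.Series(scores, index=log_measurements.index, name="larynx_size"),
        loadings=pd.Series(loadings, index=cols, name="pc1_loading"),
        variance_explained=ev / p,
        correlations=pd.Series(corr, index=cols, name="r_with_size"),
        standardized=standardize_scores,
    )
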