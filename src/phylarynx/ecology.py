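"""Acoustic allometry and social-group-size comparisons.

F0 (fundamental frequency, Hz) scales negatively with larynx size on a
log-linear axis; the phylogenetic regressions here mirror that analysis,
while the group-size tests (Mann-Whitney U, Spearman rank correlation,
dispersion summaries) are deliberately non-phylogenetic, matching the
descriptive comparisons they reproduce.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .comparative import GLSFit, design_with_intercept, pgls_lambda
from .phylo import Phylogeny

__all__ = [
    "f0_allometry",
    "ols_r2",
    "mann_whitney",
    "spearman",
    "group_dispersion",
    "assemble_group_size",
]

logger = logging.getLogger(__name__)


def f0_allometry(
    f0: pd.Series,
    size: pd.Series,
    tree: Phylogeny,
    species: list[str] | None = None,
) -> GLSFit:
    """pGLS of log10 mean F0 on larynx size within a species set.

    ``f0`` (Hz) and ``size`` are indexed by species label; rows with
    missing F0 are excluded and logged by name (species with too few
    usable calls).  ``species`` restricts the fit to a clade; the tree is
    pruned to the analyzed set.
    """
    keep = [s for s in (species or list(f0.index)) if s in f0.index]
    usable = [s for s in keep if np.isfinite(f0.get(s, np.nan)) and f0[s] > 0]
    excluded = sorted(set(keep) - set(usable))
    if excluded:
        logger.info("excluded species with missing F0: %s", excluded)
    if len(usable) < 10:
        raise ValueError(f"need >= 10 species with F0, have {len(usable)}")
    sub = tree.prune_to(usable)
    order = sub.tip_labels
    y = np.log10(f0.loc[order].to_numpy(dtype=float))
    x = size.loc[order].to_numpy(dtype=float)
    X, names = design_with_intercept(x)
    names[1] = "size"
    return pgls_lambda(y, X, sub, names=names)


def ols_r2(y, x) -> float:
    """Coefficient of determination of an ordinary (non-phylogenetic)
    simple linear regression of y on x."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U for the first sample, with two-sided P.

    Exact enumeration when both samples have n <= 20 and no ties;
    tie-corrected normal approximation otherwise.  The conservation
    identity U_a + U_b = n_a * n_b is asserted on every call.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u_b = len(a) * len(b) - u_a
    assert abs(u_a + u_b - len(a) * len(b)) < 1e-9
    return u_a, float(res.pvalue)


def spearman(a, b) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), P by the
    t-approximation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 4:
        raise ValueError("need at least 4 pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant vector has no rank correlation")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def group_dispersion(values) -> dict:
    """Location and dispersion of group sizes, both MAD variants.

    Returns the median, the (unscaled) median absolute deviation about the
    median, and the mean absolute deviation about the mean.  Both
    dispersion variants are reported because "MAD" is used ambiguously in
    the comparative literature.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    med = float(np.median(x))
    return {
        "median": med,
        "mad_median": float(np.median(np.abs(x - med))),
        "mad_mean": float(np.mean(np.abs(x - x.mean()))),
    }


def assemble_group_size(
    solitary: bool = False,
    breeding_pair: bool = False,
    mean: float | None = None,
    minimum: float | None = None,
    maximum: float | None = None,
) -> float:
    """Mean social group size from heterogeneous literature records.

    Rules: an explicitly stated mean wins; solitary species count as 1 and
    breeding-pair species as 2; otherwise the midpoint of a reported
    min-max range is used.
    """
    if mean is not None:
        return float(mean)
    if solitary:
        return 1.0
    if breeding_pair:
        return 2.0
    if minimum is not None and maximum is not None:
        return (float(minimum) + float(maximum)) / 2.0
    raise ValueError("no usable group-size information in record")
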