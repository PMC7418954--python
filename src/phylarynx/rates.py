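"""Brownian-motion rate estimation and clade rate comparisons.

The BM rate sigma^2 is the trait variance accumulated per My.  It is
estimated from phylogenetically independent contrasts: under BM the n - 1
standardized contrasts are i.i.d. N(0, sigma^2), so their mean square is
the ML rate estimate.  Clade rate ratios are tested by permuting squared
contrasts between clades (contrasts are exchangeable under a common-rate
null); posteriors use the scaled-inverse-chi-square conjugate form under a
Jeffreys prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phylo import Phylogeny

__all__ = [
    "pic",
    "clade_rate",
    "rate_ratio_test",
    "rate_posterior",
    "trait_vs_body_rate",
    "ancestral_states",
    "RateResult",
    "AncestralStates",
]


def pic(tree: Phylogeny, y) -> np.ndarray:
    """Standardized phylogenetically independent contrasts.

    Felsenstein pruning with branch-length extension; polytomies are folded
    pairwise through zero-length connectors (with a warning), giving the
    usual n - 1 contrasts.  Each contrast is N(0, sigma^2) i.i.d. under BM.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != tree.n_tips:
        raise ValueError(f"trait has {len(y)} values, tree has {tree.n_tips} tips")
    val = np.zeros(tree.n_nodes)
    ext = np.zeros(tree.n_nodes)  # extended branch length below each node
    tippos = {int(t): k for k, t in enumerate(tree.tip_ids)}
    contrasts: list[float] = []
    warned = False
    for v in tree.postorder:
        if tree.is_tip[v]:
            val[v] = y[tippos[v]]
            ext[v] = 0.0
            continue
        kids = tree.children[v]
        if len(kids) > 2 and not warned:
            warnings.warn(
                "polytomy resolved with zero-length internal edges", stacklevel=2
            )
            warned = True
        x1 = val[kids[0]]
        v1 = ext[kids[0]] + tree.blen[kids[0]]
        for c in kids[1:]:
            x2 = val[c]
            v2 = ext[c] + tree.blen[c]
            denom = v1 + v2
            if denom <= 0:
                raise ValueError(
                    "zero-length terminal pair with a contrast to standardize"
                )
            contrasts.append((x1 - x2) / np.sqrt(denom))
            x1 = (x1 * v2 + x2 * v1) / denom
            v1 = v1 * v2 / denom
        val[v] = x1
        ext[v] = v1
    return np.asarray(contrasts)


def _clade_subtree(tree: Phylogeny, clade_tips) -> Phylogeny:
    labels = [l if isinstance(l, str) else tree.tip_labels[l] for l in clade_tips]
    positions = [tree.tip_index(l) for l in labels]
    if len(positions) < 3:
        raise ValueError("clade rate needs at least 3 tips")
    if not tree.is_monophyletic(positions):
        raise ValueError("clade tip set is not monophyletic in the tree")
    return tree.prune_to(labels)


def _clade_contrasts(y, tree: Phylogeny, clade_tips) -> np.ndarray:
    sub = _clade_subtree(tree, clade_tips)
    yv = np.asarray(y, dtype=float)
    ysub = np.array([yv[tree.tip_index(l)] for l in sub.tip_labels])
    return pic(sub, ysub)


def clade_rate(y, tree: Phylogeny, clade_tips) -> float:
    """ML BM rate of a monophyletic clade: mean squared contrast within
    the clade subtree (trait units^2 / My)."""
    c = _clade_contrasts(y, tree, clade_tips)
    return float(np.mean(c**2))


@dataclass
class RateResult:
    sigma2_a: float
    sigma2_b: float
    ratio: float
    P: float
    n_perm: int
    seed: int | None
    posterior_a: np.ndarray | None = field(default=None, repr=False)
    posterior_b: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "sigma2_a": self.sigma2_a,
            "sigma2_b": self.sigma2_b,
            "ratio": self.ratio,
            "P": self.P,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def rate_ratio_test(
    y,
    tree: Phylogeny,
    clade_a,
    clade_b,
    n_perm: int = 10_000,
    seed: int | None = None,
    n_draws: int = 0,
) -> RateResult:
    """One-tailed permutation test of the clade-A / clade-B BM rate ratio.

    The null pools the two clades' squared standardized contrasts and
    reassigns them to clades at the observed counts; P is the +1-corrected
    fraction of permuted ratios at least as large as the observed one
    (alternative: ratio > 1).  Optionally attaches ``n_draws`` posterior
    rate draws per clade for density plots.
    """
    if n_perm < 999:
        warnings.warn(f"n_perm={n_perm} < 999 gives a coarse P value", stacklevel=2)
    ca = _clade_contrasts(y, tree, clade_a) ** 2
    cb = _clade_contrasts(y, tree, clade_b) ** 2
    sa, sb = float(ca.mean()), float(cb.mean())
    obs = sa / sb
    pooled = np.concatenate([ca, cb])
    m, N = len(ca), len(ca) + len(cb)
    rng = np.random.default_rng(seed)
    # batched permutations: argsort of uniform keys row-wise
    order = np.argsort(rng.random((n_perm, N)), axis=1)
    shuffled = pooled[order]
    r = shuffled[:, :m].mean(axis=1) / shuffled[:, m:].mean(axis=1)
    hits = int(np.sum(r >= obs))
    P = (hits + 1) / (n_perm + 1)
    post_a = post_b = None
    if n_draws:
        post_a = rate_posterior(y, tree, clade_a, n_draws, seed=rng.integers(2**31))
        post_b = rate_posterior(y, tree, clade_b, n_draws, seed=rng.integers(2**31))
    return RateResult(
        sigma2_a=sa, sigma2_b=sb, ratio=float(obs), P=float(P),
        n_perm=n_perm, seed=seed, posterior_a=post_a, posterior_b=post_b,
    )


def rate_posterior(
    y, tree: Phylogeny, clade_tips, n_draws: int = 10_000, seed: int | None = None
) -> np.ndarray:
    """Posterior draws of a clade's BM rate.

    Under the i.i.d.-contrast likelihood with Jeffreys prior 1/sigma^2 the
    posterior is scaled-inverse-chi-square(m, s^2) for m contrasts with
    mean square s^2; draws are sampled directly as m s^2 / chi2(m).
    """
    c = _clade_contrasts(y, tree, clade_tips)
    m = len(c)
    s2 = float(np.mean(c**2))
    rng = np.random.default_rng(seed)
    return m * s2 / rng.chisquare(m, size=n_draws)


def trait_vs_body_rate(
    trait_a,
    trait_b,
    tree: Phylogeny,
    clade_tips=None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Rate ratio of two traits measured on the same tips (paired test).

    Both traits must be on comparable scales (e.g., both log10 mm); the
    ratio is clade_rate(trait_a) / clade_rate(trait_b) on the same
    (sub)tree, and the one-tailed P comes from a permutation that swaps the
    two traits' squared contrasts within each contrast pair, respecting the
    pairing by node.
    """
    sub = tree if clade_tips is None else _clade_subtree(tree, clade_tips)
    ya = np.asarray(trait_a, dtype=float)
    yb = np.asarray(trait_b, dtype=float)
    if clade_tips is not None:
        ya = np.array([ya[tree.tip_index(l)] for l in sub.tip_labels])
        yb = np.array([yb[tree.tip_index(l)] for l in sub.tip_labels])
    scale = np.std(ya) / max(np.std(yb), np.finfo(float).tiny)
    if scale > 1e3 or scale < 1e-3:
        warnings.warn(
            f"traits differ in scale by {scale:.3g}x; is the unit comparable?",
            stacklevel=2,
        )
    a2 = pic(sub, ya) ** 2
    b2 = pic(sub, yb) ** 2
    obs = float(a2.mean() / b2.mean())
    rng = np.random.default_rng(seed)
    m = len(a2)
    swap = rng.random((n_perm, m)) < 0.5
    pa = np.where(swap, b2, a2)
    pb = np.where(swap, a2, b2)
    hits = int(np.sum(pa.mean(axis=1) / pb.mean(axis=1) >= obs))
    P = (hits + 1) / (n_perm + 1)
    return obs, float(P)


@dataclass
class AncestralStates:
    """Reconstructed node values for the ancestral phenogram.

    ``heights``/``values`` are indexed by node id (root = 0); ``segments``
    lists (parent_height, parent_value, child_height, child_value) for
    every edge, ready for phenogram rendering.  ``branch_rates`` records
    the per-edge sigma^2 used for the (possibly rate-heterogeneous)
    reconstruction.
    """

    heights: np.ndarray
    values: np.ndarray
    branch_rates: dict[int, float]
    tree: Phylogeny = field(repr=False)

    @property
    def segments(self) -> list[tuple[float, float, float, float]]:
        t = self.tree
        return [
            (
                float(self.heights[t.parent[v]]),
                float(self.values[t.parent[v]]),
                float(self.heights[v]),
                float(self.values[v]),
            )
            for v in range(1, t.n_nodes)
        ]

    @property
    def root_value(self) -> float:
        return float(self.values[0])


def ancestral_states(
    y, tree: Phylogeny, regime_rates: dict[int, float] | None = None
) -> AncestralStates:
    """ML ancestral state reconstruction under (rate-scaled) BM.

    Each branch length is first multiplied by its rate (default 1
    everywhere), which turns a branch-heterogeneous-rate BM into standard
    BM on a rescaled tree; node estimates are then the exact conditional
    means given the tips (flat root prior), computed by two-pass Gaussian
    message passing in linear time.  Tip values equal the observations.
    """
    y = np.asarray(y, dtype=float)
    n = tree.n_nodes
    rates = np.ones(n)
    for e, r in (regime_rates or {}).items():
        if r <= 0:
            raise ValueError(f"rate on edge {e} must be positive, got {r}")
        rates[e] = r
    b = tree.blen * rates  # rate-rescaled branch lengths

    tippos = {int(t): k for k, t in enumerate(tree.tip_ids)}
    up_mu = np.zeros(n)
    up_v = np.zeros(n)
    # upward (pruning) pass: conditional mean/variance of tips below a node
    for v in tree.postorder:
        if tree.is_tip[v]:
            up_mu[v] = y[tippos[v]]
            up_v[v] = 0.0
        else:
            prec = 0.0
            mean = 0.0
            for c in tree.children[v]:
                p = 1.0 / (up_v[c] + b[c])
                prec += p
                mean += p * up_mu[c]
            up_mu[v] = mean / prec
            up_v[v] = 1.0 / prec

    # downward pass: message from the rest of the tree, then combine
    down_mu = np.zeros(n)
    down_v = np.full(n, np.inf)
    values = np.zeros(n)
    for v in tree.preorder:
        if tree.is_tip[v]:
            values[v] = y[tippos[v]]
        elif np.isinf(down_v[v]):
            values[v] = up_mu[v]
        else:
            pu = 1.0 / up_v[v] if up_v[v] > 0 else np.inf
            pd_ = 1.0 / down_v[v]
            values[v] = (up_mu[v] * pu + down_mu[v] * pd_) / (pu + pd_)
        for c in tree.children[v]:
            prec = 0.0
            mean = 0.0
            if not np.isinf(down_v[v]):
                p = 1.0 / down_v[v]
                prec += p
                mean += p * down_mu[v]
            for s in tree.children[v]:
                if s == c:
                    continue
                p = 1.0 / (up_v[s] + b[s])
                prec += p
                mean += p * up_mu[s]
            down_mu[c] = mean / prec
            down_v[c] = 1.0 / prec + b[c]
    return AncestralStates(
        heights=tree.heights.copy(),
        values=values,
        branch_rates={int(e): float(rates[e]) for e in range(1, n)},
        tree=tree,
    )
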