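"""Trees, trait tables, and phylogenetic covariance structures.

The :class:`Phylogeny` wraps a rooted, fully branch-lengthed dendropy tree
and exposes the array views (parents, branch lengths, node heights, tip
order) that the comparative machinery consumes.  Branch lengths are treated
as absolute time (My) throughout; nothing here rescales a tree to unit
depth.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "read_tree",
    "graft_trees",
    "vcv_bm",
    "apply_lambda",
    "match_taxa",
    "normalize_label",
]

#: default relative tolerance (fraction of tree depth) for the
#: ultrametricity check; violations warn, they never raise
ULTRAMETRIC_RTOL = 1e-6


def normalize_label(label: str) -> str:
    """Canonical form of a taxon label: spaces become underscores,
    surrounding whitespace is stripped, case is preserved."""
    return label.strip().replace(" ", "_")


class Phylogeny:
    """A rooted tree with strictly positive branch lengths.

    Node ids are assigned in preorder (root = 0).  ``parent[i]`` is the id
    of node *i*'s parent (-1 for the root), ``blen[i]`` the length of the
    edge above node *i* (0 for the root), and ``heights[i]`` the distance
    from the root (root = 0, increasing toward the tips).  ``tip_ids`` and
    ``tip_labels`` give the tips in dendropy leaf-iteration order, which is
    the canonical trait-vector order for every downstream routine.
    """

    def __init__(self, tree: dendropy.Tree, check_ultrametric: bool = True):
        self._dtree = tree
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ValueError(
                        f"edge above node {nd.taxon.label if nd.taxon else i!r} "
                        "has no branch length"
                    )
                if not np.isfinite(nd.edge.length) or nd.edge.length <= 0:
                    raise ValueError(
                        f"branch length {nd.edge.length!r} above node "
                        f"{nd.taxon.label if nd.taxon else i!r} is not finite and > 0"
                    )
                blen[i] = float(nd.edge.length)
        heights = np.zeros(n)
        for i in range(1, n):  # preorder: parent precedes child
            heights[i] = heights[parent[i]] + blen[i]
        tip_nodes = [nd for nd in tree.leaf_node_iter()]
        tip_ids = np.array([index[id(nd)] for nd in tip_nodes], dtype=int)
        tip_labels = [normalize_label(nd.taxon.label) for nd in tip_nodes]
        if len(set(tip_labels)) != len(tip_labels):
            dupes = {t for t in tip_labels if tip_labels.count(t) > 1}
            raise ValueError(f"duplicate tip labels after normalization: {sorted(dupes)}")

        self.parent = parent
        self.blen = blen
        self.heights = heights
        self.tip_ids = tip_ids
        self.tip_labels = tip_labels
        self.n_tips = len(tip_labels)
        self.n_nodes = n
        # children lists and traversal orders
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            children[parent[i]].append(i)
        self.children = children
        self.preorder = np.arange(n)
        self.postorder = np.array(list(reversed(range(n))), dtype=int)
        self.is_tip = np.zeros(n, dtype=bool)
        self.is_tip[tip_ids] = True
        if check_ultrametric:
            self._warn_if_not_ultrametric()

    # -- basic properties ------------------------------------------------

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length (My)."""
        return float(self.heights[self.tip_ids].max())

    @property
    def tip_heights(self) -> np.ndarray:
        return self.heights[self.tip_ids]

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        h = self.tip_heights
        return bool(np.ptp(h) <= rtol * max(h.max(), np.finfo(float).tiny))

    def _warn_if_not_ultrametric(self) -> None:
        if not self.is_ultrametric():
            warnings.warn(
                f"tree is not ultrametric within rtol={ULTRAMETRIC_RTOL:g} "
                f"(tip height spread {np.ptp(self.tip_heights):.6g}); "
                "analyses proceed anyway",
                stacklevel=3,
            )

    # -- structure queries -----------------------------------------------

    def tip_index(self, label: str) -> int:
        """Position of a tip label in the canonical trait-vector order."""
        return self.tip_labels.index(normalize_label(label))

    def path_to_root(self, node: int) -> list[int]:
        """Node ids from ``node`` up to (and including) the root."""
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(self.parent[path[-1]])
        return path

    def tips_below(self, node: int) -> list[int]:
        """Tip-order positions (not node ids) of tips descending from node."""
        stack, out = [node], []
        tippos = {int(t): k for k, t in enumerate(self.tip_ids)}
        while stack:
            v = stack.pop()
            if self.is_tip[v]:
                out.append(tippos[v])
            stack.extend(self.children[v])
        return sorted(out)

    def mrca_nodes(self) -> np.ndarray:
        """Tip × tip matrix of MRCA node ids (diagonal: the tip's own node)."""
        n = self.n_tips
        M = np.zeros((n, n), dtype=int)
        below: dict[int, list[int]] = {}
        tippos = {int(t): k for k, t in enumerate(self.tip_ids)}
        for v in self.postorder:
            if self.is_tip[v]:
                below[v] = [tippos[v]]
                M[tippos[v], tippos[v]] = v
            else:
                kids = self.children[v]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        ia = below[kids[a]]
                        ib = below[kids[b]]
                        M[np.ix_(ia, ib)] = v
                        M[np.ix_(ib, ia)] = v
                below[v] = [t for k in kids for t in below[k]]
        return M

    def mrca_heights(self) -> np.ndarray:
        """Tip × tip matrix of MRCA heights (shared root-to-MRCA path)."""
        return self.heights[self.mrca_nodes()]

    def edge_list(self) -> list[tuple[int, int, float]]:
        """(parent, child, length) triples for every edge."""
        return [
            (int(self.parent[i]), i, float(self.blen[i]))
            for i in range(1, self.n_nodes)
            if self.parent[i] >= 0
        ]

    def is_monophyletic(self, tip_positions: Iterable[int]) -> bool:
        """Whether a set of tips (canonical positions) forms a clade."""
        want = sorted(set(int(i) for i in tip_positions))
        node = self.mrca_node(want)
        return self.tips_below(node) == want

    def mrca_node(self, tip_positions: Sequence[int]) -> int:
        paths = [set(self.path_to_root(int(self.tip_ids[i]))) for i in tip_positions]
        common = set.intersection(*paths)
        # deepest common ancestor = max height
        return max(common, key=lambda v: self.heights[v])

    # -- manipulation ----------------------------------------------------

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Subtree induced by the given tip labels (normalized).

        Unifurcations created by pruning are suppressed; the root stays at
        the original root so node heights keep their time calibration.
        """
        keep = {normalize_label(l) for l in labels}
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        t = self._dtree.clone(depth=1)
        t.retain_taxa_with_labels([l for l in keep])
        # dendropy suppresses internal unifurcations; if the root is left
        # with a single child, reroot at the MRCA of the retained tips
        # (standard drop-tip behavior: the stem edge is discarded).
        while t.seed_node.num_child_nodes() == 1:
            child = t.seed_node.child_nodes()[0]
            child.parent_node = None
            child.edge.length = None
            t.seed_node = child
        return Phylogeny(t, check_ultrametric=False)

    def newick(self) -> str:
        s = self._dtree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Phylogeny {self.n_tips} tips, depth {self.depth:.4g}>"


def read_tree(text: str, schema: str | None = None) -> Phylogeny:
    """Parse a Newick or Nexus string (or file contents) into a Phylogeny.

    Tip labels are normalized (spaces to underscores).  Every non-root edge
    must carry a finite positive branch length.
    """
    stripped = text.lstrip()
    if schema is None:
        schema = "nexus" if stripped.upper().startswith("#NEXUS") else "newick"
    try:
        t = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy error messages carry the position
        raise ValueError(f"could not parse {schema} tree: {exc}") from exc
    t.is_rooted = True
    for leaf in t.leaf_node_iter():
        leaf.taxon.label = normalize_label(leaf.taxon.label)
    return Phylogeny(t)


def read_tree_file(path: str) -> Phylogeny:
    with open(path) as fh:
        return read_tree(fh.read())


def graft_trees(t1: Phylogeny, t2: Phylogeny, root_age: float) -> Phylogeny:
    """Join two clade trees under a new root of age ``root_age`` (My).

    Each input tree's root is attached by a stem of length
    ``root_age - depth(tree)``, so if both inputs are ultrametric the graft
    is ultrametric with total depth ``root_age``.
    """
    d1, d2 = t1.depth, t2.depth
    if root_age < max(d1, d2):
        raise ValueError(
            f"root_age {root_age} is younger than the deeper input tree "
            f"(depths {d1:.6g}, {d2:.6g})"
        )
    n1 = t1.newick().rstrip().rstrip(";")
    n2 = t2.newick().rstrip().rstrip(";")
    s1 = root_age - d1
    s2 = root_age - d2
    merged = f"({n1}:{s1!r},{n2}:{s2!r});"
    return read_tree(merged)


def vcv_bm(tree: Phylogeny) -> np.ndarray:
    """Brownian-motion covariance structure of the tips.

    ``V[i, j]`` is the height of the MRCA of tips *i* and *j* (shared
    root-to-MRCA path length); the diagonal holds root-to-tip path lengths.
    The trait-scale rate sigma^2 multiplies this matrix downstream.
    """
    return tree.mrca_heights()


def apply_lambda(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonal entries scaled by ``lam``.

    ``lam`` = 1 leaves V unchanged (pure Brownian motion); ``lam`` = 0
    yields a star phylogeny (diagonal matrix).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    W = V * lam
    np.fill_diagonal(W, np.diag(V))
    return W


def match_taxa(
    tree: Phylogeny,
    table: pd.DataFrame,
    species_col: str = "species",
    synonyms: Mapping[str, str] | None = None,
) -> tuple[Phylogeny, pd.DataFrame, dict]:
    """Align a trait table with a tree.

    Labels are normalized on both sides, an optional synonym map is applied
    to the table's species names, the tree is pruned to the intersection,
    and the table rows are reordered to the pruned tree's tip order.

    Returns ``(pruned_tree, reordered_table, report)`` where the report
    lists the names dropped on each side.
    """
    syn = {normalize_label(k): normalize_label(v) for k, v in (synonyms or {}).items()}
    names = [syn.get(normalize_label(s), normalize_label(s)) for s in table[species_col]]
    tbl = table.copy()
    tbl[species_col] = names
    if len(set(names)) != len(names):
        dupes = {s for s in names if names.count(s) > 1}
        raise ValueError(f"duplicate species in table after normalization: {sorted(dupes)}")
    tree_set = set(tree.tip_labels)
    tbl_set = set(names)
    common = tree_set & tbl_set
    if not common:
        sugg = _nearest_suggestions(tbl_set, tree_set)
        raise ValueError(
            "no overlap between tree tips and table species; nearest-name "
            f"suggestions: {sugg}"
        )
    pruned = tree.prune_to(common)
    order = pruned.tip_labels
    tbl = tbl.set_index(species_col).loc[order].reset_index()
    report = {
        "n_matched": len(common),
        "dropped_from_tree": sorted(tree_set - common),
        "dropped_from_table": sorted(tbl_set - common),
    }
    return pruned, tbl, report


def _nearest_suggestions(queries: set[str], pool: set[str], k: int = 3) -> dict:
    import difflib

    return {
        q: difflib.get_close_matches(q, pool, n=k, cutoff=0.6)
        for q in sorted(queries)[:10]
    }
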