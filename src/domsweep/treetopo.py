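"""Genotype-posterior distances, neighbor joining, and topology classes.

Distances are expected per-site allelic differences between individuals,
averaged over co-covered SNP sites: D(g1, g2) = |g1 - g2| / 2 under the
genotype posteriors of both samples. Trees come from classic Saitou-Nei
neighbor joining (deterministic tie-breaking, negative branch lengths
clamped to zero). Classification roots each tree on the OrII outgroup and
asks whether the domesticated samples are one clade (the
introgressed-single-domestication signature) or whether each domesticated
subpopulation instead sits with its own wild progenitor (the genome-wide,
multiple-origin pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .simpop import DOM_SUBPOPS, DEFAULT_PROGENITORS

__all__ = [
    "Leaf",
    "Node",
    "DistanceMatrix",
    "pair_diff_stats",
    "pairwise_distance",
    "neighbor_joining",
    "parse_newick",
    "classify_topology",
    "region_tree",
    "concatenation_experiment",
    "bipartitions",
]

#: expected allelic difference between diploid genotypes (dosage scale / 2)
DIFF_MATRIX = np.array([[0.0, 0.5, 1.0], [0.5, 0.0, 0.5], [1.0, 0.5, 0.0]])


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class Node:
    name: Optional[str] = None
    length: float = 0.0
    children: List["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        stack = [self]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.append(nd)
            else:
                stack.extend(reversed(nd.children))
        return out

    def leaf_names(self) -> List[str]:
        return [l.name for l in self.leaves()]

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_inner() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.10g}"


def parse_newick(text: str) -> Node:
    """Minimal Newick parser (names, branch lengths, no quoting)."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse() -> Node:
        nonlocal pos
        node = Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in ",();":
            pos += 1
        label = text[start:pos]
        if ":" in label:
            name, _, ln = label.partition(":")
            node.name = name or None
            node.length = float(ln)
        elif label:
            node.name = label
        return node

    return parse()


def subpop_of_leaf(name: str) -> str:
    """Leaf ids are '<subpop>_<k>'; recover the subpopulation label."""
    return name.rsplit("_", 1)[0]


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Pairwise expected allelic differences with co-coverage counts."""

    d: np.ndarray  # (n, n) float
    n_overlap: np.ndarray  # (n, n) int
    ids: List[str]
    min_overlap: int = 20

    @property
    def reliable(self) -> np.ndarray:
        off = ~np.eye(len(self.ids), dtype=bool)
        return (self.n_overlap >= self.min_overlap) | ~off

    def reliable_taxa(self) -> np.ndarray:
        """Indices of taxa whose every pairwise entry meets the overlap
        minimum (others are dropped from tree building)."""
        ok = self.reliable
        return np.flatnonzero(ok.all(axis=1))


def pair_diff_stats(
    post: np.ndarray, covered: np.ndarray, site_mask: np.ndarray | None = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Summed expected differences and co-coverage counts over sites.

    ``post``: (n, S, 3) genotype posteriors per individual; ``covered``:
    (n, S) bool. Returns ``(sums, counts)`` both (n, n); the distance matrix
    is ``sums / counts``. Restricting to a site subset via ``site_mask``
    lets callers assemble region trees and concatenations cheaply.
    """
    if site_mask is not None:
        post = post[:, site_mask]
        covered = covered[:, site_mask]
    P = np.where(covered[:, :, None], post, 0.0)
    M = P @ DIFF_MATRIX
    sums = np.einsum("asg,bsg->ab", P, M)
    cov = covered.astype(np.float64)
    counts = cov @ cov.T
    return sums, counts.astype(np.int64)


def pairwise_distance(
    post: np.ndarray,
    covered: np.ndarray,
    ids: Sequence[str],
    site_mask: np.ndarray | None = None,
    min_overlap: int = 20,
) -> DistanceMatrix:
    """Expected per-site allelic difference between all pairs of samples."""
    sums, counts = pair_diff_stats(post, covered, site_mask)
    if np.any((counts == 0) & ~np.eye(len(ids), dtype=bool)):
        raise ValueError("sample pair with zero co-covered SNPs")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, counts, list(ids), min_overlap)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dist, ids: Sequence[str] | None = None) -> Node:
    """Classic Saitou-Nei neighbor joining.

    ``dist`` may be a DistanceMatrix (unreliable taxa dropped first) or a
    square array. Ties in the Q criterion break to the smallest (row, col).
    Negative branch lengths are clamped to zero. Returns an unrooted tree
    represented with a trifurcating (or, for 3 taxa, star) root.
    """
    if isinstance(dist, DistanceMatrix):
        keep = dist.reliable_taxa()
        D = dist.d[np.ix_(keep, keep)].astype(float).copy()
        names = [dist.ids[i] for i in keep]
    else:
        D = np.asarray(dist, dtype=float).copy()
        names = list(ids) if ids is not None else [f"t{i}" for i in range(D.shape[0])]
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 reliable taxa")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    nodes: List[Node] = [Node(name=nm) for nm in names]
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (R[i_loc] - R[j_loc]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        # new distances to the joined node reuse slot i
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = parent
        active.remove(j)
    # resolve the final three with the three-point formulas
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    return root


# ---------------------------------------------------------------------------
# rooting and classification


def _adjacency(root: Node):
    """Undirected adjacency of the tree; nodes are object ids."""
    adj: Dict[int, List[Tuple[Node, float]]] = {}
    index: Dict[int, Node] = {}

    def walk(nd: Node):
        index[id(nd)] = nd
        adj.setdefault(id(nd), [])
        for ch in nd.children:
            index[id(ch)] = ch
            adj.setdefault(id(ch), [])
            adj[id(nd)].append((ch, ch.length))
            adj[id(ch)].append((nd, ch.length))
            walk(ch)

    walk(root)
    return adj, index


def _build_rooted(adj, start: Node, parent_id: int | None, length: float) -> Node:
    nd = Node(name=start.name, length=length)
    for nbr, ln in adj[id(start)]:
        if parent_id is not None and id(nbr) == parent_id:
            continue
        nd.children.append(_build_rooted(adj, nbr, id(start), ln))
    return nd


def root_on_edge(tree: Node, child: Node) -> Node:
    """Reroot the (unrooted) tree on the edge above ``child``.

    The new root is bifurcating: one side is ``child``'s subtree, the other
    the remainder of the tree; the old edge length is split evenly.
    """
    adj, _ = _adjacency(tree)
    nbrs = [(nbr, ln) for nbr, ln in adj[id(child)]]
    parent = None
    length = 0.0
    # the neighbor "above" child in the original orientation is whichever is
    # not one of its own children
    child_ids = {id(c) for c in child.children}
    for nbr, ln in nbrs:
        if id(nbr) not in child_ids:
            parent, length = nbr, ln
            break
    if parent is None:
        raise ValueError("cannot root on the edge above the current root")
    left = _build_rooted(adj, child, id(parent), length / 2.0)
    right = _build_rooted(adj, parent, id(child), length / 2.0)
    return Node(children=[left, right])


def _find_clade_node(tree: Node, target: frozenset) -> Optional[Tuple[Node, Node]]:
    """Locate a node whose leaf set equals ``target``; return (node, parent)."""
    stack = [(tree, None)]
    while stack:
        nd, parent = stack.pop()
        names = frozenset(nd.leaf_names())
        if names == target:
            return nd, parent
        if target < names:
            for ch in nd.children:
                stack.append((ch, nd))
    return None


def bipartitions(tree: Node) -> set:
    """Non-trivial bipartitions as frozensets of one side's leaf names."""
    all_leaves = frozenset(tree.leaf_names())
    out = set()

    def walk(nd: Node):
        names = frozenset(nd.leaf_names())
        if 1 < len(names) < len(all_leaves) - 1:
            out.add(min(names, frozenset(all_leaves - names), key=sorted))
        for ch in nd.children:
            walk(ch)

    for ch in tree.children:
        walk(ch)
    return out


def root_on_outgroup(tree: Node, outgroup: str = "OrII") -> Node:
    """Root on the edge separating the outgroup, with a defined fallback.

    If the outgroup is monophyletic in the unrooted tree, root on its stem
    edge; otherwise root on the terminal edge of the first outgroup leaf in
    leaf order (low-coverage trees occasionally scramble the outgroup).
    """
    leaves = tree.leaves()
    out_leaves = [l for l in leaves if subpop_of_leaf(l.name) == outgroup]
    if not out_leaves:
        raise ValueError(f"tree has no {outgroup} leaf to root on")
    target = frozenset(l.name for l in out_leaves)
    if len(out_leaves) == 1:
        return root_on_edge(tree, out_leaves[0])
    found = _find_clade_node(tree, target)
    if found is not None and found[1] is not None:
        return root_on_edge(tree, found[0])
    # outgroup clade may be "wrapped around" the arbitrary root: then the
    # complement forms a node
    comp = frozenset(l.name for l in leaves) - target
    found = _find_clade_node(tree, comp)
    if found is not None and found[1] is not None:
        return root_on_edge(tree, found[0])
    return root_on_edge(tree, out_leaves[0])


def classify_topology(
    tree: Node,
    progenitors: Mapping[str, str] | None = None,
    outgroup: str = "OrII",
) -> str:
    """Classify a labeled tree against the two domestication signatures.

    Returns ``"domesticate_monophyletic"`` if, after rooting on the
    outgroup, all domesticated leaves form a single clade;
    ``"subpop_concordant"`` if instead every domesticated subpopulation is a
    clade whose sister region holds its designated wild progenitor's leaves
    and no other domesticated subpopulation; ``"other"`` otherwise.
    """
    if progenitors is None:
        progenitors = DEFAULT_PROGENITORS
    rooted = root_on_outgroup(tree, outgroup)
    names = rooted.leaf_names()
    by_subpop: Dict[str, set] = {}
    for nm in names:
        by_subpop.setdefault(subpop_of_leaf(nm), set()).add(nm)
    dom_present = [d for d in DOM_SUBPOPS if d in by_subpop]
    if len(dom_present) < 2:
        raise ValueError("need at least two domesticated subpopulations")
    dom_leaves = frozenset().union(*(by_subpop[d] for d in dom_present))
    if _find_clade_node(rooted, frozenset(dom_leaves)) is not None:
        return "domesticate_monophyletic"
    for d in dom_present:
        found = _find_clade_node(rooted, frozenset(by_subpop[d]))
        if found is None or found[1] is None:
            return "other"
        node, parent = found
        sister = set(parent.leaf_names()) - set(node.leaf_names())
        prog = progenitors[d]
        if not sister & by_subpop.get(prog, set()):
            return "other"
        for other_dom in dom_present:
            if other_dom != d and sister & by_subpop[other_dom]:
                return "other"
    return "subpop_concordant"


# ---------------------------------------------------------------------------
# region trees and concatenation


def region_tree(
    post: np.ndarray,
    covered: np.ndarray,
    positions: np.ndarray,
    ids: Sequence[str],
    interval: Tuple[int, int],
    min_snps: int = 20,
    min_overlap: int = 20,
    progenitors: Mapping[str, str] | None = None,
):
    """NJ tree and classification from SNPs within ``interval``.

    ``positions`` are the coordinates of the SNP sites underlying ``post``.
    Raises if fewer than ``min_snps`` SNPs fall in the interval.
    Returns ``(tree, classification, n_snps)``.
    """
    start, end = interval
    mask = (positions >= start) & (positions < end)
    n_snps = int(mask.sum())
    if n_snps < min_snps:
        raise ValueError(f"only {n_snps} SNPs in region (minimum {min_snps})")
    dm = pairwise_distance(post, covered, ids, site_mask=mask, min_overlap=min_overlap)
    tree = neighbor_joining(dm)
    return tree, classify_topology(tree, progenitors), n_snps


def concatenation_experiment(
    region_stats: Sequence[Tuple[np.ndarray, np.ndarray]],
    ids: Sequence[str],
    min_overlap: int = 20,
    progenitors: Mapping[str, str] | None = None,
):
    """Classification as progressively more neutral regions are concatenated.

    ``region_stats[0]`` holds the (sums, counts) pair-statistics of the
    sweep region; subsequent entries are neutral regions. For each k the
    distances over the union of the first k+1 regions are classified.
    Returns ``(classes, flip_k)`` where ``flip_k`` is the smallest number of
    concatenated neutral regions at which the classification leaves
    ``domesticate_monophyletic`` (None if it never does).
    """
    sums = np.zeros_like(region_stats[0][0])
    counts = np.zeros_like(region_stats[0][1])
    classes = []
    flip_k = None
    for k, (s, c) in enumerate(region_stats):
        sums = sums + s
        counts = counts + c
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, counts, list(ids), min_overlap)
        tree = neighbor_joining(dm)
        cls = classify_topology(tree, progenitors)
        classes.append(cls)
        if flip_k is None and k > 0 and cls != "domesticate_monophyletic":
            flip_k = k
    return classes, flip_k
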