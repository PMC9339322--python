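"""Phylogeny container, Newick/TSV I/O, de-replication, and contrasts.

The :class:`Phylogeny` used throughout gcjump is a flat, array-backed rooted
tree: nodes are indexed ``0..n_nodes-1`` in preorder (root first, children in
input order), each non-root node stores the length of the branch above it in
substitutions per site, and a *branch* is identified by the index of the node
below it.  This layout keeps the numerical core (pruning likelihoods, MCMC
over per-branch jump counts) simple and fast while dendropy handles Newick
parsing.

Polytomies are accepted on input.  Operations that need a unique sister
branch or Felsenstein contrasts reject non-binary nodes with
:class:`~gcjump.errors.PolytomyError` rather than resolving them silently;
use :func:`resolve_polytomies` (zero-length branches) when that is the
behaviour you want.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    GCJumpError,
    NewickFormatError,
    PolytomyError,
    TraitTableError,
)

__all__ = [
    "Phylogeny",
    "ContrastSet",
    "read_newick",
    "newick_from_string",
    "write_newick",
    "read_trait_table",
    "write_trait_table",
    "validate_traits",
    "subsample_tree",
    "node_depths",
    "shared_path_matrix",
    "resolve_polytomies",
    "pic_contrasts",
    "excess_kurtosis",
]

_UNQUOTED_LABEL = re.compile(r"^[A-Za-z0-9_.\-]+$")


class Phylogeny:
    """Rooted phylogeny with branch lengths in substitutions per site.

    Parameters
    ----------
    parent
        Integer array of length ``n_nodes``; ``parent[0] == -1`` (root) and
        ``parent[i] < i`` for every other node (preorder).
    blen
        Branch length above each node (``blen[0]`` is ignored and stored as
        0).  All lengths must be finite and >= 0.
    labels
        One label per node; tips must be labelled and tip labels unique.
        Internal labels may be ``None``.
    """

    __slots__ = ("parent", "blen", "labels", "children", "is_tip")

    def __init__(self, parent, blen, labels):
        parent = np.asarray(parent, dtype=np.int64)
        blen = np.asarray(blen, dtype=np.float64).copy()
        if parent.ndim != 1 or parent.shape != blen.shape or len(labels) != parent.size:
            raise GCJumpError("parent, blen and labels must have equal length")
        if parent.size == 0 or parent[0] != -1:
            raise GCJumpError("node 0 must be the root (parent -1)")
        if np.any(parent[1:] < 0) or np.any(parent[1:] >= np.arange(1, parent.size)):
            raise GCJumpError("nodes must be in preorder with a single root")
        blen[0] = 0.0
        if not np.all(np.isfinite(blen)) or np.any(blen < 0):
            raise GCJumpError("branch lengths must be finite and >= 0")
        self.parent = parent
        self.blen = blen
        self.labels = list(labels)
        children: list[list[int]] = [[] for _ in range(parent.size)]
        for i in range(1, parent.size):
            children[parent[i]].append(i)
        self.children = children
        self.is_tip = np.array([len(c) == 0 for c in children], dtype=bool)
        tips = [self.labels[i] for i in np.flatnonzero(self.is_tip)]
        if any(t is None for t in tips):
            raise GCJumpError("every tip must be labelled")
        if len(set(tips)) != len(tips):
            raise GCJumpError("tip labels must be unique")

    # ------------------------------------------------------------------ #
    # basic structure
    # ------------------------------------------------------------------ #
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def root(self) -> int:
        return 0

    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices()]

    def branches(self) -> np.ndarray:
        """All branch ids (= indices of non-root nodes)."""
        return np.arange(1, self.n_nodes)

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def preorder(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def postorder(self) -> np.ndarray:
        # parents precede children in index order, so reversed indices are
        # a valid postorder
        return np.arange(self.n_nodes - 1, -1, -1)

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def sister(self, node: int) -> int:
        """The other child of ``node``'s parent; parent must be binary."""
        if node == 0:
            raise GCJumpError("the root has no sister branch")
        sibs = self.children[self.parent[node]]
        if len(sibs) != 2:
            raise PolytomyError(
                f"parent of node {node} has {len(sibs)} children; a unique "
                "sister requires a binary parent (resolve_polytomies first)"
            )
        return sibs[0] if sibs[1] == node else sibs[1]

    def subtree_tips(self, node: int) -> np.ndarray:
        """Indices of tips descending from (and including) ``node``."""
        if self.is_tip[node]:
            return np.array([node], dtype=np.int64)
        stack = [node]
        out = []
        while stack:
            v = stack.pop()
            if self.is_tip[v]:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return np.array(sorted(out), dtype=np.int64)

    def total_branch_length(self) -> float:
        return float(self.blen[1:].sum())

    def clade_heights(self) -> np.ndarray:
        """Max node-to-descendant-tip path length, per node (tips: 0)."""
        h = np.zeros(self.n_nodes)
        for v in self.postorder():
            if not self.is_tip[v]:
                h[v] = max(h[c] + self.blen[c] for c in self.children[v])
        return h

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.blen.copy(), list(self.labels))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes>"


@dataclass
class ContrastSet:
    """Scaled phylogenetically independent contrasts (GC% units)."""

    contrasts: np.ndarray
    node_ids: np.ndarray

    def __len__(self) -> int:
        return self.contrasts.size


# ---------------------------------------------------------------------- #
# Newick I/O
# ---------------------------------------------------------------------- #
def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    nodes = list(dtree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = np.empty(len(nodes), dtype=np.int64)
    blen = np.zeros(len(nodes))
    labels: list[str | None] = []
    for i, n in enumerate(nodes):
        parent[i] = -1 if n.parent_node is None else index[id(n.parent_node)]
        if n.parent_node is not None:
            if n.edge.length is None:
                who = n.taxon.label if n.taxon else (n.label or f"node {i}")
                raise NewickFormatError(
                    f"missing branch length above '{who}'; branch lengths are "
                    "mandatory on read"
                )
            blen[i] = float(n.edge.length)
        labels.append(n.taxon.label if n.taxon is not None else n.label)
    return Phylogeny(parent, blen, labels)


def newick_from_string(text: str) -> Phylogeny:
    """Parse one Newick tree from a string.

    Raises :class:`NewickFormatError` naming the byte offset of the failure
    for malformed input, and for any branch without a length (lengths are
    never silently defaulted).
    """
    if not text.strip():
        raise NewickFormatError("empty Newick input", offset=0)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        offset = None
        col = getattr(exc, "col_num", None)
        line = getattr(exc, "line_num", None)
        if col is not None:
            offset = int(col) - 1
            if line and line > 1:
                lines = text.splitlines(keepends=True)[: line - 1]
                offset += sum(len(s.encode()) for s in lines)
        raise NewickFormatError(f"Newick parse failure: {exc}", offset=offset) from exc
    return _from_dendropy(dtree)


def read_newick(path) -> Phylogeny:
    """Read a rooted Newick tree (branch lengths mandatory) from ``path``."""
    with open(path, "r", encoding="utf-8") as fh:
        return newick_from_string(fh.read())


def _fmt_label(label: str) -> str:
    if _UNQUOTED_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _fmt_len(x: float) -> str:
    return format(float(x), ".12g")


def write_newick(tree: Phylogeny, branch_annotations=None, path=None) -> str:
    """Serialize a tree to Newick, optionally with branch comments.

    ``branch_annotations`` maps branch id (non-root node index) to a value
    emitted as a ``[&pp=<value>]`` comment after the branch length, e.g.
    ``A:0.5[&pp=0.97]``.  This is the dialect used for posterior-annotated
    trees; readers that ignore square-bracket comments still recover the
    topology and lengths.
    """
    ann = {}
    if branch_annotations:
        for k, v in branch_annotations.items():
            k = int(k)
            if k <= 0 or k >= tree.n_nodes:
                raise GCJumpError(f"annotation key {k} is not a branch of the tree")
            ann[k] = v

    buf = io.StringIO()

    def emit(v: int) -> None:
        if not tree.is_tip[v]:
            buf.write("(")
            for j, c in enumerate(tree.children[v]):
                if j:
                    buf.write(",")
                emit(c)
            buf.write(")")
        if tree.labels[v] is not None:
            buf.write(_fmt_label(tree.labels[v]))
        if v != 0:
            buf.write(":" + _fmt_len(tree.blen[v]))
            if v in ann:
                buf.write(f"[&pp={format(float(ann[v]), '.6g')}]")

    emit(0)
    buf.write(";")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


# ---------------------------------------------------------------------- #
# Trait table I/O
# ---------------------------------------------------------------------- #
_TRAIT_COLUMNS = ("tip_label", "gc_percent")


def read_trait_table(path) -> dict[str, float]:
    """Read a tip -> GC% table from TSV with header ``tip_label  gc_percent``."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if tuple(df.columns[:2]) != _TRAIT_COLUMNS:
        raise TraitTableError(
            f"trait TSV must start with columns {_TRAIT_COLUMNS}, got "
            f"{tuple(df.columns)}"
        )
    if df["tip_label"].duplicated().any():
        dup = df.loc[df["tip_label"].duplicated(), "tip_label"].iloc[0]
        raise TraitTableError(f"duplicate tip label in trait table: '{dup}'")
    values = pd.to_numeric(df["gc_percent"], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna(), "tip_label"].iloc[0]
        raise TraitTableError(f"non-numeric gc_percent for tip '{bad}'")
    if ((values < 0) | (values > 100)).any():
        bad = df.loc[(values < 0) | (values > 100), "tip_label"].iloc[0]
        raise TraitTableError(f"gc_percent outside [0, 100] for tip '{bad}'")
    return dict(zip(df["tip_label"], values.astype(float)))


def write_trait_table(traits: dict[str, float], path) -> None:
    df = pd.DataFrame(
        {"tip_label": list(traits.keys()), "gc_percent": list(traits.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def validate_traits(tree: Phylogeny, traits: dict[str, float]) -> np.ndarray:
    """Check ``traits`` covers exactly the tips of ``tree``; return tip values
    ordered by tip index."""
    tips = tree.tip_labels()
    missing = [t for t in tips if t not in traits]
    if missing:
        raise TraitTableError(f"missing trait value for tip '{missing[0]}'")
    extra = set(traits) - set(tips)
    if extra:
        raise TraitTableError(
            f"trait table has {len(extra)} entries that are not tips of the "
            f"tree (e.g. '{sorted(extra)[0]}')"
        )
    return np.array([traits[t] for t in tips], dtype=np.float64)


# ---------------------------------------------------------------------- #
# depths, subsampling, polytomy resolution
# ---------------------------------------------------------------------- #
def node_depths(tree: Phylogeny) -> np.ndarray:
    """Root-to-node path length for every node (``depth[root] == 0``)."""
    d = np.zeros(tree.n_nodes)
    for v in range(1, tree.n_nodes):
        d[v] = d[tree.parent[v]] + tree.blen[v]
    return d


def _extract_subtree(tree: Phylogeny, keep_tips: set[int]) -> Phylogeny:
    """Induced subtree on ``keep_tips`` with unary nodes suppressed (branch
    lengths summed through them).  The original root is retained; if it ends
    up with a single child the root stays unary."""
    n_below = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in tree.postorder():
        if tree.is_tip[v]:
            n_below[v] = 1 if v in keep_tips else 0
        else:
            n_below[v] = sum(n_below[c] for c in tree.children[v])
    if n_below[0] == 0:
        raise GCJumpError("no tips retained")

    parent_out: list[int] = []
    blen_out: list[float] = []
    labels_out: list[str | None] = []

    def add(parent_idx: int, blen: float, label) -> int:
        parent_out.append(parent_idx)
        blen_out.append(blen)
        labels_out.append(label)
        return len(parent_out) - 1

    def build(v: int, parent_idx: int, acc: float) -> None:
        # skip through unary chains, accumulating branch length
        while True:
            if tree.is_tip[v]:
                add(parent_idx, acc, tree.labels[v])
                return
            kids = [c for c in tree.children[v] if n_below[c] > 0]
            if len(kids) == 1:
                c = kids[0]
                acc += tree.blen[c]
                v = c
            else:
                me = add(parent_idx, acc, tree.labels[v])
                for c in kids:
                    build(c, me, tree.blen[c])
                return

    # root: never skipped, even if unary
    root_kids = [c for c in tree.children[0] if n_below[c] > 0]
    if tree.is_tip[0]:
        raise GCJumpError("cannot extract from a single-node tree")
    me = add(-1, 0.0, tree.labels[0])
    for c in root_kids:
        build(c, me, tree.blen[c])
    return Phylogeny(np.array(parent_out), np.array(blen_out), labels_out)


def subsample_tree(tree: Phylogeny, age_threshold: float) -> Phylogeny:
    """De-replicate: collapse every clade younger than ``age_threshold`` to a
    single representative tip.

    Clade "age" is the maximum node-to-descendant-tip path length within the
    clade, so a clade is collapsed only when *all* its tips lie within the
    threshold.  The retained representative is the lexicographically smallest
    tip label (deterministic, no random state).  Collapsing is iterated to a
    fixed point: pruning can shorten a surviving node's height below the
    threshold, in which case that node is collapsed on the next pass.  The
    result is idempotent and contains no internal node of height below the
    threshold with more than one retained tip.
    """
    if not age_threshold > 0:
        raise GCJumpError("age_threshold must be > 0")
    current = tree
    while True:
        heights = current.clade_heights()
        # maximal internal nodes with height < threshold
        targets = []
        for v in range(current.n_nodes):
            if current.is_tip[v] or heights[v] >= age_threshold:
                continue
            p = current.parent[v]
            if p == -1 or heights[p] >= age_threshold:
                targets.append(v)
        if not targets:
            return current
        keep = set(current.tip_indices().tolist())
        for v in targets:
            tips = current.subtree_tips(v)
            rep = min(tips, key=lambda i: current.labels[i])
            for t in tips:
                if t != rep:
                    keep.discard(int(t))
        current = _extract_subtree(current, keep)


def shared_path_matrix(tree: Phylogeny, weights=None) -> np.ndarray:
    """Dense tip-by-tip matrix of summed edge weights along shared
    root-to-MRCA paths (weights default to branch lengths, giving the
    Brownian covariance structure; diagonal = weighted tip depth).

    Rows/columns follow ``tree.tip_indices()`` order.
    """
    w = tree.blen if weights is None else np.asarray(weights, dtype=np.float64)
    if w.shape != (tree.n_nodes,):
        raise GCJumpError("weights must have one entry per node")
    depth = np.zeros(tree.n_nodes)
    for v in range(1, tree.n_nodes):
        depth[v] = depth[tree.parent[v]] + w[v]
    tips = tree.tip_indices()
    pos = {int(t): k for k, t in enumerate(tips)}
    n = tips.size
    C = np.zeros((n, n))
    for i, t in enumerate(tips):
        C[i, i] = depth[t]
    below: dict[int, list[int]] = {}
    for v in tree.postorder():
        if tree.is_tip[v]:
            below[v] = [pos[v]]
            continue
        kids = tree.children[v]
        for ai in range(len(kids)):
            for bi in range(ai + 1, len(kids)):
                for i in below[kids[ai]]:
                    for j in below[kids[bi]]:
                        C[i, j] = C[j, i] = depth[v]
        below[v] = [i for c in kids for i in below[c]]
    return C


def resolve_polytomies(tree: Phylogeny) -> Phylogeny:
    """Resolve every polytomy into an arbitrary caterpillar of zero-length
    branches (deterministic: children folded left-to-right in input order).

    The resulting tree is binary and defines the same tip covariance under
    Brownian-type models.  Note that zero-length internal branches make the
    resolved nodes unusable as contrast denominators.
    """
    parent_out: list[int] = []
    blen_out: list[float] = []
    labels_out: list[str | None] = []

    def add(parent_idx, blen, label):
        parent_out.append(parent_idx)
        blen_out.append(blen)
        labels_out.append(label)
        return len(parent_out) - 1

    def build(v, parent_idx, blen):
        me = add(parent_idx, blen, tree.labels[v])
        kids = tree.children[v]
        if len(kids) <= 2:
            for c in kids:
                build(c, me, tree.blen[c])
            return
        # fold: first child attaches to me, rest hang off a zero-length chain
        host = me
        for j, c in enumerate(kids[:-2]):
            build(c, host, tree.blen[c])
            host = add(host, 0.0, None)
        build(kids[-2], host, tree.blen[kids[-2]])
        build(kids[-1], host, tree.blen[kids[-1]])

    build(0, -1, 0.0)
    return Phylogeny(np.array(parent_out), np.array(blen_out), labels_out)


# ---------------------------------------------------------------------- #
# contrasts and the fat-tail diagnostic
# ---------------------------------------------------------------------- #
def pic_contrasts(tree: Phylogeny, traits: dict[str, float]) -> ContrastSet:
    """Felsenstein's scaled phylogenetically independent contrasts.

    At each internal node the contrast is ``(x_L - x_R) / sqrt(t'_L + t'_R)``
    with the usual rootward branch-length inflation
    ``t' = t + t_L t_R / (t_L + t_R)``.  A binary tree with ``N`` tips yields
    exactly ``N - 1`` contrasts.  Polytomies raise
    :class:`~gcjump.errors.PolytomyError` (resolve explicitly with
    :func:`resolve_polytomies` if zero-length resolution is acceptable); a
    zero combined branch length at a contrast node raises
    :class:`~gcjump.errors.GCJumpError`.
    """
    x = validate_traits(tree, traits)
    xs = np.zeros(tree.n_nodes)
    ts = np.zeros(tree.n_nodes)
    xs[tree.tip_indices()] = x
    contrasts = []
    node_ids = []
    for v in tree.postorder():
        if tree.is_tip[v]:
            ts[v] = tree.blen[v]
            continue
        kids = tree.children[v]
        if len(kids) != 2:
            raise PolytomyError(
                f"node {v} has {len(kids)} children; contrasts require a "
                "binary tree (pre-resolve polytomies with zero-length "
                "branches via resolve_polytomies if appropriate)"
            )
        a, b = kids
        denom = ts[a] + ts[b]
        if denom <= 0:
            raise GCJumpError(
                f"zero combined branch length at contrast node {v}; cannot "
                "scale the contrast"
            )
        contrasts.append((xs[a] - xs[b]) / np.sqrt(denom))
        node_ids.append(v)
        xs[v] = (xs[a] * ts[b] + xs[b] * ts[a]) / denom
        ts[v] = tree.blen[v] + ts[a] * ts[b] / denom
    return ContrastSet(np.array(contrasts), np.array(node_ids, dtype=np.int64))


def excess_kurtosis(values) -> float:
    """Sample excess kurtosis ``m4 / m2**2 - 3`` from central sample moments.

    No small-sample bias correction is applied.  Values near 0 are consistent
    with Gaussian (Brownian) contrasts; strongly positive values indicate
    fat tails, the signature of jump-like evolution.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 4:
        raise GCJumpError("excess kurtosis requires at least 4 values")
    c = v - v.mean()
    m2 = np.mean(c**2)
    if m2 <= 0:
        raise GCJumpError("excess kurtosis undefined for zero variance")
    return float(np.mean(c**4) / m2**2 - 3.0)
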