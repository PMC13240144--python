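"""Phylogeny input/output and tree-sample utilities.

Wraps :mod:`dendropy` for parsing and serialisation (Newick and Nexus), and
provides the tree-level plumbing the comparative analysis needs:

* :class:`Phylogeny` -- a rooted tree with branch lengths and unique tip
  labels, flattened into index arrays for fast post-order computation;
* :class:`TreeSample` -- an ordered collection of trees over a common label
  set (e.g. a posterior sample of bird phylogenies, tagged by backbone);
* :func:`mcc_tree` -- the maximum clade credibility tree of a sample;
* :func:`phylo_correlation` -- the species-by-species correlation matrix
  implied by shared ancestry, used as the covariance structure of the
  phylogenetic random effect in the mixed models.

Tip labels are matched after normalising underscores to spaces; comparisons
are case-insensitive (survey spreadsheets and supertree labels disagree on
both routinely).
"""

from __future__ import annotations

import logging
import math
import random
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Relative spread of root-to-tip depths tolerated before a tree is treated
#: as non-ultrametric (published supertrees carry rounding noise).
ULTRAMETRIC_RTOL = 1e-3

#: Seed used when arbitrarily resolving polytomies into zero-length branches.
POLYTOMY_SEED = 20_260_924


class TreeError(ValueError):
    """Structural problem with a phylogeny or tree sample."""


class NewickParseError(TreeError):
    """Malformed tree string; carries position information when available."""


def normalize_label(label: str) -> str:
    """Canonical form used for matching taxon names to dataset species."""
    return " ".join(label.replace("_", " ").strip().lower().split())


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """Rooted binary phylogeny flattened to index arrays.

    Nodes are indexed ``0 .. n_nodes-1`` with tips first (``0 .. n_tips-1``,
    in the order of :attr:`tip_labels`).  ``parent[root] == -1``.  ``blen[i]``
    is the length of the edge above node ``i`` (0 for the root).  Internal
    nodes carry ``left``/``right`` child indices; :attr:`postorder` lists the
    internal nodes in a valid post-order.
    """

    tip_labels: list[str]
    parent: np.ndarray
    blen: np.ndarray
    left: np.ndarray
    right: np.ndarray
    postorder: np.ndarray
    root: int

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, *,
                      resolve_polytomies: bool = True,
                      seed: int = POLYTOMY_SEED) -> "Phylogeny":
        tree = tree.clone(depth=1)
        if any(len(nd.child_nodes()) > 2 for nd in tree.preorder_node_iter()):
            if not resolve_polytomies:
                raise TreeError("tree contains polytomies")
            log.warning("resolving polytomies arbitrarily (seed=%d)", seed)
            tree.resolve_polytomies(rng=random.Random(seed))
        tree.suppress_unifurcations()

        leaves = list(tree.leaf_node_iter())
        labels = [lf.taxon.label if lf.taxon else "" for lf in leaves]
        if any(not lb for lb in labels):
            raise TreeError("unlabeled tip encountered")
        if len(set(labels)) != len(labels):
            dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")

        n_tips = len(leaves)
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        n_nodes = n_tips + len(internals)
        index: dict[int, int] = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        for j, nd in enumerate(internals):
            index[id(nd)] = n_tips + j

        parent = np.full(n_nodes, -1, dtype=np.int64)
        blen = np.zeros(n_nodes)
        left = np.full(n_nodes, -1, dtype=np.int64)
        right = np.full(n_nodes, -1, dtype=np.int64)
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                el = nd.edge.length
                blen[i] = 0.0 if el is None else float(el)
                if blen[i] < 0:
                    raise TreeError(f"negative branch length above node {i}")
            kids = nd.child_nodes()
            if kids:
                if len(kids) != 2:
                    raise TreeError("non-binary node after polytomy resolution")
                left[i] = index[id(kids[0])]
                right[i] = index[id(kids[1])]
        postorder = np.array([index[id(nd)] for nd in internals], dtype=np.int64)
        return cls(labels, parent, blen, left, right, postorder,
                   root=index[id(tree.seed_node)])

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None
                    ) -> dendropy.Tree:
        ns = taxon_namespace or dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=ns)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, lb in enumerate(self.tip_labels):
            nodes[i].taxon = ns.require_taxon(label=lb)
        for i in range(self.n_nodes):
            if self.left[i] >= 0:
                nodes[i].add_child(nodes[self.left[i]])
                nodes[i].add_child(nodes[self.right[i]])
            if i != self.root:
                nodes[i].edge.length = float(self.blen[i])
        tree.seed_node = nodes[self.root]
        tree.is_rooted = True
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True).strip()

    # -- geometry ----------------------------------------------------------

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths, indexed like nodes."""
        d = np.zeros(self.n_nodes)
        stack = [self.root]
        while stack:
            i = stack.pop()
            if i != self.root:
                d[i] = d[self.parent[i]] + self.blen[i]
            if self.left[i] >= 0:
                stack.append(self.left[i])
                stack.append(self.right[i])
        return d

    def tip_depths(self) -> np.ndarray:
        return self.depths()[: self.n_tips]

    def max_depth(self) -> float:
        return float(self.tip_depths().max())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        td = self.tip_depths()
        mx = td.max()
        if mx <= 0:
            return True
        return float((td.max() - td.min()) / mx) <= rtol

    def scaled(self, factor: float) -> "Phylogeny":
        """Uniformly rescale all branch lengths."""
        out = Phylogeny(list(self.tip_labels), self.parent.copy(),
                        self.blen * factor, self.left.copy(),
                        self.right.copy(), self.postorder.copy(), self.root)
        return out

    def subtree_tipsets(self) -> dict[int, frozenset[str]]:
        """Tip-label set below each node."""
        sets: dict[int, frozenset[str]] = {}
        for i in range(self.n_tips):
            sets[i] = frozenset([self.tip_labels[i]])
        for i in self.postorder:
            sets[i] = sets[self.left[i]] | sets[self.right[i]]
        return sets

    def prune_to(self, keep: Iterable[str]) -> "Phylogeny":
        """Restrict the tree to the given tip labels (normalised matching)."""
        wanted = {normalize_label(k) for k in keep}
        have = {normalize_label(lb) for lb in self.tip_labels}
        missing = wanted - have
        if missing:
            raise TreeError(f"species not in tree: {sorted(missing)}")
        dt = self.to_dendropy()
        taxa = [t for t in dt.taxon_namespace
                if normalize_label(t.label) in wanted]
        dt.retain_taxa(taxa)
        return Phylogeny.from_dendropy(dt)

    def label_index(self) -> dict[str, int]:
        """Normalised tip label -> tip index."""
        return {normalize_label(lb): i for i, lb in enumerate(self.tip_labels)}


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick string into a :class:`Phylogeny`.

    Raises :class:`NewickParseError` (with the underlying position message)
    on malformed input and :class:`TreeError` on duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return Phylogeny.from_dendropy(tree)


# ---------------------------------------------------------------------------
# Tree samples and the MCC tree
# ---------------------------------------------------------------------------

@dataclass
class TreeSample:
    """Ordered sample of phylogenies over an identical tip label set."""

    trees: list[Phylogeny]
    backbone_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("empty tree sample")
        ref = frozenset(normalize_label(lb) for lb in self.trees[0].tip_labels)
        for k, t in enumerate(self.trees):
            s = frozenset(normalize_label(lb) for lb in t.tip_labels)
            if s != ref:
                raise TreeError(f"tree {k} has a different tip label set")
        if not self.backbone_tags:
            self.backbone_tags = [""] * len(self.trees)
        if len(self.backbone_tags) != len(self.trees):
            raise TreeError("backbone_tags length mismatch")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    @classmethod
    def read(cls, path_or_buffer, schema: str = "newick",
             backbone_tag: str = "") -> "TreeSample":
        """Read a multi-tree Newick file or a Nexus TREES block."""
        if hasattr(path_or_buffer, "read"):
            tl = dendropy.TreeList.get(file=path_or_buffer, schema=schema)
        else:
            tl = dendropy.TreeList.get(path=str(path_or_buffer), schema=schema)
        trees = [Phylogeny.from_dendropy(t) for t in tl]
        return cls(trees, [backbone_tag] * len(trees))

    def write(self, path, schema: str = "newick") -> None:
        with open(path, "w") as fh:
            if schema == "nexus":
                fh.write("#NEXUS\nBEGIN TREES;\n")
                for k, t in enumerate(self.trees):
                    fh.write(f"  TREE tree_{k} = {t.to_newick()}\n")
                fh.write("END;\n")
            else:
                for t in self.trees:
                    fh.write(t.to_newick() + "\n")

    def prune_to(self, keep: Iterable[str]) -> "TreeSample":
        keep = list(keep)
        return TreeSample([t.prune_to(keep) for t in self.trees],
                          list(self.backbone_tags))


def clade_table(sample: TreeSample) -> dict[frozenset[str], float]:
    """Bipartition (tip subset below an edge) -> frequency in the sample.

    Trivial clades (single tips, the full tip set) come out at frequency 1 on
    any sample, matching the invariant expected of a clade table.
    """
    counts: dict[frozenset[str], int] = {}
    n = len(sample)
    for t in sample:
        for s in t.subtree_tipsets().values():
            key = frozenset(normalize_label(x) for x in s)
            counts[key] = counts.get(key, 0) + 1
    return {k: v / n for k, v in counts.items()}


def mcc_score(tree: Phylogeny, table: Mapping[frozenset[str], float]) -> float:
    """Sum of log clade frequencies of the tree's clades under ``table``."""
    score = 0.0
    for s in tree.subtree_tipsets().values():
        key = frozenset(normalize_label(x) for x in s)
        f = table.get(key, 0.0)
        if f <= 0:
            return -math.inf
        score += math.log(f)
    return score


def mcc_tree(sample: TreeSample) -> Phylogeny:
    """Maximum clade credibility tree of a sample.

    Restricted to members of the sample (the standard practice, and the only
    way to guarantee a valid, dated tree): returns the member maximising the
    sum of log clade frequencies.  Ties break to the earliest tree in input
    order, so the result is deterministic.
    """
    table = clade_table(sample)
    best, best_score = 0, -math.inf
    for k, t in enumerate(sample):
        s = mcc_score(t, table)
        if s > best_score:
            best, best_score = k, s
    return sample.trees[best]


# ---------------------------------------------------------------------------
# Phylogenetic correlation structure
# ---------------------------------------------------------------------------

def phylo_correlation(tree: Phylogeny, *, rtol: float = ULTRAMETRIC_RTOL
                      ) -> pd.DataFrame:
    """Species-by-species correlation implied by shared ancestry.

    Entry (i, j) is the root-to-MRCA path length shared by tips i and j,
    scaled so the diagonal is 1.  For an ultrametric tree this is the shared
    depth divided by total depth; trees whose tip depths spread beyond
    ``rtol`` trigger a warning and per-tip normalisation
    ``d(mrca) / sqrt(d_i d_j)`` instead.

    The result is symmetric positive semi-definite and invariant to uniform
    rescaling of all branch lengths.
    """
    n = tree.n_tips
    d = tree.depths()
    td = d[:n]
    ultra = tree.is_ultrametric(rtol)
    if not ultra:
        warnings.warn("tree is not ultrametric within tolerance; "
                      "normalising by per-tip depths", stacklevel=2)

    shared = np.zeros((n, n))
    # accumulate MRCA depths: post-order, pairs split across the two children
    tipsets: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    for v in tree.postorder:
        a = tipsets[tree.left[v]]
        b = tipsets[tree.right[v]]
        shared[np.ix_(a, b)] = d[v]
        shared[np.ix_(b, a)] = d[v]
        tipsets[v] = np.concatenate([a, b])
    if ultra:
        mx = td.max()
        corr = shared / (mx if mx > 0 else 1.0)
    else:
        corr = shared / np.sqrt(np.outer(td, td))
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=tree.tip_labels, columns=tree.tip_labels)
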