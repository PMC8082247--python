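"""Neighbor-joining, rooting, bipartitions, monophyly and Newick I/O.

The tree container wraps :class:`dendropy.Tree`; node supports (integers
0–100 from the jackknife) live on ``node.support`` and are serialised as
internal node labels in Newick.  Neighbor joining is implemented here with an
explicit determinism contract: ties in the selection criterion break toward
the smallest (row, column) index pair in current label order, and negative
branch-length estimates are clamped to zero.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

from .afdist import DistanceMatrix


class NewickParseError(ValueError):
    """Malformed Newick input (message carries the source position)."""


class PhyloTree:
    """Phylogenetic tree with branch lengths and optional node supports."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        for node in tree:
            if not hasattr(node, "support"):
                node.support = None

    # -- construction / serialisation ------------------------------------

    @classmethod
    def read_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises schema-specific subclasses
            raise NewickParseError(str(exc)) from exc
        out = cls(tree)
        for node in tree.preorder_node_iter():
            if node.taxon is None and node.label and node.label.isdigit():
                node.support = int(node.label)
        return out

    def write_newick(self, show_supports: bool = True, support_floor: int = 0) -> str:
        """Newick text; supports become internal node labels.

        ``support_floor`` suppresses the display of supports below the floor
        (the underlying tree data are untouched).
        """
        tree = self._tree.clone(depth=1)
        for node in tree.preorder_node_iter():
            if node.taxon is not None:
                continue
            sup = getattr(node, "support", None)
            if show_supports and sup is not None and sup >= support_floor:
                node.label = str(int(sup))
            else:
                node.label = None
        text = tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".6g",
        )
        return text.strip()

    def ascii(self) -> str:
        return self._tree.as_ascii_plot()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- queries ----------------------------------------------------------

    @property
    def tip_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self._tree.leaf_node_iter()}

    def _leafsets(self) -> Iterable[tuple[dendropy.Node, frozenset[str]]]:
        memo: dict[int, frozenset[str]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                ls = frozenset([node.taxon.label])
            else:
                ls = frozenset().union(*(memo[id(c)] for c in node.child_nodes()))
            memo[id(node)] = ls
            yield node, ls

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each stored as the block not containing the
        lexicographically smallest tip (the anchor)."""
        tips = self.tip_labels
        if len(tips) < 4:
            return set()
        anchor = min(tips)
        splits: set[frozenset[str]] = set()
        for node, ls in self._leafsets():
            if node.parent_node is None:
                continue
            if 2 <= len(ls) <= len(tips) - 2:
                splits.add(ls if anchor not in ls else frozenset(tips - ls))
        return splits

    def node_supports(self) -> dict[frozenset[str], int | None]:
        """Map canonical bipartition → support for internal edges."""
        tips = self.tip_labels
        anchor = min(tips)
        out: dict[frozenset[str], int | None] = {}
        for node, ls in self._leafsets():
            if node.parent_node is None or not (2 <= len(ls) <= len(tips) - 2):
                continue
            key = ls if anchor not in ls else frozenset(tips - ls)
            out[key] = getattr(node, "support", None)
        return out

    # -- rooting / monophyly ----------------------------------------------

    def root_with_outgroup(self, outgroup: Iterable[str]) -> "PhyloTree":
        """Root on the edge subtending ``outgroup``, splitting it equally."""
        og = frozenset(outgroup)
        tips = self.tip_labels
        unknown = og - tips
        if unknown:
            raise ValueError(f"unknown outgroup tips: {sorted(unknown)}")
        if not og or og == tips:
            raise ValueError("outgroup must be a proper nonempty subset of tips")
        clone = self.copy()
        target = None
        for node, ls in clone._leafsets():
            if node.parent_node is None:
                continue
            if ls == og or (tips - ls) == og:
                target = node.edge
                break
        if target is None:
            raise ValueError(
                f"outgroup {sorted(og)} does not form a clade in the unrooted tree"
            )
        length = target.length if target.length is not None else 0.0
        clone._tree.reroot_at_edge(target, length1=length / 2.0, length2=length / 2.0)
        clone._tree.is_rooted = True
        return clone

    def is_monophyletic(self, taxa: Iterable[str], outgroup: Iterable[str]) -> bool:
        """True iff ``taxa`` form a clade once the tree is rooted by ``outgroup``."""
        taxa = frozenset(taxa)
        unknown = taxa - self.tip_labels
        if unknown:
            raise ValueError(f"unknown tip labels: {sorted(unknown)}")
        if len(taxa) <= 1:
            return True
        rooted = self.root_with_outgroup(outgroup)
        return any(ls == taxa for _, ls in rooted._leafsets())


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classic neighbor joining on a valid distance matrix.

    Exact on additive matrices.  Joins the pair minimising the rate-corrected
    criterion Q_ij = (n−2)·d_ij − r_i − r_j; branch lengths come from the
    standard two-point formulas and are clamped at zero.
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("non-finite distances")

    taxon_ns = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(label))
        nodes.append(node)
    d = dm.values.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = np.full((m, m), np.inf)
        flat[iu] = q[iu]
        i, j = np.unravel_index(int(np.argmin(flat)), flat.shape)  # row-major ⇒
        # first minimum in (row, column) order: the tie-break contract
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        ci, cj = nodes[i], nodes[j]
        ci.edge.length = max(li, 0.0)
        cj.edge.length = max(lj, 0.0)
        parent.add_child(ci)
        parent.add_child(cj)
        dnew = (d[i, :] + d[j, :] - d[i, j]) / 2.0
        keep = [x for x in range(m) if x != j]
        d = d[np.ix_(keep, keep)]
        dnew = dnew[keep]
        pos = keep.index(i)
        d[pos, :] = dnew
        d[:, pos] = dnew
        d[pos, pos] = 0.0
        nodes = [parent if x == i else nodes[x] for x in keep]

    # final trifurcation: three-point formulas
    l0 = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    l1 = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    l2 = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    root = dendropy.Node()
    for node, length in zip(nodes, (l0, l1, l2)):
        node.edge.length = max(length, 0.0)
        root.add_child(node)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)


def bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    return tree.bipartitions()


def root_with_outgroup(tree: PhyloTree, outgroup: Iterable[str]) -> PhyloTree:
    return tree.root_with_outgroup(outgroup)


def is_monophyletic(
    tree: PhyloTree, taxa: Iterable[str], outgroup: Iterable[str]
) -> bool:
    return tree.is_monophyletic(taxa, outgroup)


def read_newick(text: str) -> PhyloTree:
    return PhyloTree.read_newick(text)


def write_newick(tree: PhyloTree, **kwargs) -> str:
    return tree.write_newick(**kwargs)
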