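"""Rooted-tree data model and utilities.

Every downstream analysis (gene-tree duplication mapping, birth-death
simulation, synteny truth tracking) is conditioned on a rooted, bifurcating
species tree with a deterministic "ladder" node ordering, so that internal
nodes can be reported as a stable index sequence N1..Nk from the root toward
the tips.  Gene trees carry a taxon and a gene identifier per leaf; any
multifurcation in an input gene tree is resolved deterministically
(lexicographically by smallest descendant leaf label) so reconciliation is
well defined.

Newick parsing is delegated to dendropy; serialization and the tree
algorithms are implemented here on a lightweight node model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "TreeError",
    "ParseError",
    "Node",
    "Tree",
    "SpeciesTree",
    "GeneTree",
    "parse_newick",
    "ladderize",
    "lca_map",
    "restrict",
    "root_with_outgroup",
]


class TreeError(ValueError):
    """Invalid tree structure or labels."""


class ParseError(TreeError):
    """Malformed Newick input; carries the character position when known."""

    def __init__(self, message: str, offset: Optional[int] = None):
        super().__init__(message if offset is None else f"{message} (near character {offset})")
        self.offset = offset


@dataclass
class Node:
    label: Optional[str] = None
    length: Optional[float] = None  # branch length to parent; None for an unlengthed edge
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None
    index: Optional[int] = None  # ladder index (internal nodes of a ladderized tree)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"

    # dataclass __eq__ would recurse through parents; identity semantics are correct here
    __hash__ = object.__hash__
    __eq__ = object.__eq__

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> frozenset:
        return frozenset(n.label for n in self.leaves())


class Tree:
    """A rooted tree owning its node structure."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> frozenset:
        return self.root.leaf_labels()

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def node_depths(self) -> dict[Node, int]:
        depth: dict[Node, int] = {self.root: 0}
        for node in self.preorder():
            for child in node.children:
                depth[child] = depth[node] + 1
        return depth

    # -- serialization -----------------------------------------------------
    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = _quote(node.label or "")
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    s += _quote(node.label)
            if lengths and node.length is not None:
                s += f":{node.length:.12g}"
            return s

        return fmt(self.root) + ";"

    def copy(self) -> "Tree":
        return type(self)(_clone(self.root))

    # -- validation --------------------------------------------------------
    def validate_bifurcating(self) -> None:
        for node in self.preorder():
            if node.children and len(node.children) != 2:
                raise TreeError(
                    f"internal node with {len(node.children)} children; expected bifurcating"
                )

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, each as the smaller-side label set.

        Used as the brute-force Robinson-Foulds primitive in tests.
        """
        all_leaves = self.leaf_labels()
        out = set()
        for node in self.preorder():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_labels()
            other = all_leaves - side
            if len(side) < 2 and len(other) < 2:
                continue
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out


class SpeciesTree(Tree):
    """Rooted bifurcating species tree; leaf labels are unique taxon names."""

    def __init__(self, root: Node):
        super().__init__(root)
        labels = [n.label for n in self.leaves()]
        if any(not lab for lab in labels):
            raise TreeError("species tree has an unlabeled leaf")
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels in species tree")

    @property
    def taxa(self) -> frozenset:
        return self.leaf_labels()

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = []
        for leaf in self.leaves():
            d, node = 0.0, leaf
            while node.parent is not None:
                d += node.length or 0.0
                node = node.parent
            depths.append(d)
        return max(depths) - min(depths) <= tol


class GeneTree(Tree):
    """Rooted gene tree; each leaf carries a taxon and a unique gene identifier.

    Leaf labels of the form ``taxon<sep>rest`` (default separator ``@``) are
    split into taxon and gene id; a bare label is both its own taxon and id.
    """

    def __init__(self, root: Node, taxon_sep: str = "@"):
        super().__init__(root)
        self.taxon_sep = taxon_sep
        ids = [self.gene_id(n) for n in self.leaves()]
        if len(ids) != len(set(ids)):
            raise TreeError("duplicate gene identifiers in gene tree")

    def taxon(self, leaf: Node) -> str:
        label = leaf.label or ""
        return label.split(self.taxon_sep, 1)[0] if self.taxon_sep in label else label

    def gene_id(self, leaf: Node) -> str:
        return leaf.label or ""

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.taxon(n) for n in self.leaves())


# ---------------------------------------------------------------------------
# Newick I/O


def _quote(label: str) -> str:
    if any(c in label for c in "()[]{}/\\,;:=*'\"`+<> \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _clone(node: Node) -> Node:
    new = Node(label=node.label, length=node.length, index=node.index)
    for child in node.children:
        new.add_child(_clone(child))
    return new


def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label is not None:
        label = dnode.label
    node = Node(label=label, length=dnode.edge.length)
    for dchild in dnode.child_nodes():
        node.add_child(_from_dendropy(dchild))
    return node


def parse_newick(
    text: str,
    kind: str = "species",
    resolve_multifurcations: bool = True,
) -> Tree:
    """Parse one Newick string into a SpeciesTree or GeneTree.

    ``kind`` is ``"species"`` (strictly bifurcating, unique taxon labels) or
    ``"gene"`` (multifurcations resolved deterministically when requested).
    """
    if kind not in ("species", "gene"):
        raise ValueError(f"unknown tree kind {kind!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        offset = getattr(exc, "column", None)
        raise ParseError(f"malformed Newick: {exc}", offset=offset) from None
    root = _from_dendropy(dtree.seed_node)
    if root.is_leaf and root.label is None:
        raise ParseError("empty Newick string")
    if kind == "species":
        tree = SpeciesTree(root)
        tree.validate_bifurcating()
        for node in tree.preorder():
            if node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length {node.length}")
        return tree
    n_resolved = 0
    if resolve_multifurcations:
        n_resolved = _resolve_multifurcations(root)
    tree = GeneTree(root)
    tree.resolved_multifurcations = n_resolved
    return tree


def _resolve_multifurcations(root: Node) -> int:
    """Binarize in place, lexicographically by smallest descendant label."""
    count = 0
    for node in list(root.preorder()):
        while len(node.children) > 2:
            count += 1
            kids = sorted(node.children, key=lambda c: min(c.leaf_labels()))
            a, b = kids[0], kids[1]
            joined = Node(length=0.0)
            node.children = [c for c in node.children if c is not a and c is not b]
            joined.add_child(a)
            joined.add_child(b)
            node.add_child(joined)
    return count


# ---------------------------------------------------------------------------
# Tree utilities


def ladderize(tree: SpeciesTree) -> SpeciesTree:
    """Return a copy with canonical child order and root-to-tip node indices.

    Children are ordered larger clade first (descendant-leaf count), ties
    broken by the lexicographically smallest descendant leaf label.  Internal
    nodes are then indexed 1..k in preorder, giving the N1..Nk ladder used to
    report per-node duplication percentages.
    """
    out = tree.copy()
    size: dict[Node, int] = {}
    min_label: dict[Node, str] = {}
    for node in out.postorder():
        if node.is_leaf:
            size[node] = 1
            min_label[node] = node.label or ""
        else:
            size[node] = sum(size[c] for c in node.children)
            min_label[node] = min(min_label[c] for c in node.children)
    for node in out.preorder():
        node.children.sort(key=lambda c: (-size[c], min_label[c]))
    idx = 0
    for node in out.preorder():
        if not node.is_leaf:
            idx += 1
            node.index = idx
    return out


def lca_map(gene_tree: GeneTree, species_tree: SpeciesTree) -> dict[Node, Node]:
    """Map each gene-tree node to its species-tree LCA.

    A leaf maps to its taxon's leaf; an internal node maps to the most recent
    common ancestor, in the species tree, of the taxa beneath it.  A gene-tree
    node mapping to the same species node as one of its children marks a gene
    duplication at that species node.
    """
    taxon_node = {leaf.label: leaf for leaf in species_tree.leaves()}
    depth = species_tree.node_depths()

    def lca(a: Node, b: Node) -> Node:
        while a is not b:
            if depth[a] < depth[b]:
                b = b.parent
            elif depth[a] > depth[b]:
                a = a.parent
            else:
                a, b = a.parent, b.parent
        return a

    mapping: dict[Node, Node] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            taxon = gene_tree.taxon(node)
            if taxon not in taxon_node:
                raise TreeError(f"gene-tree taxon {taxon!r} not in species tree")
            mapping[node] = taxon_node[taxon]
        else:
            m = mapping[node.children[0]]
            for child in node.children[1:]:
                m = lca(m, mapping[child])
            mapping[node] = m
    return mapping


def restrict(species_tree: SpeciesTree, taxa: Iterable[str]) -> SpeciesTree:
    """Induced subtree on ``taxa``: degree-2 nodes suppressed, lengths summed."""
    keep = frozenset(taxa)
    missing = keep - species_tree.taxa
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeError("restriction needs at least 2 taxa")

    def build(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.label in keep:
                return Node(label=node.label, length=node.length)
            return None
        kept = [build(c) for c in node.children]
        kept = [k for k in kept if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if child.length is not None and node.length is not None:
                child.length += node.length
            elif node.length is not None:
                child.length = node.length
            return child
        new = Node(label=node.label, length=node.length)
        for k in kept:
            new.add_child(k)
        return new

    root = build(species_tree.root)
    assert root is not None
    root.length = None  # the root edge has no meaning in the induced tree
    return SpeciesTree(root)


def root_with_outgroup(tree: GeneTree, outgroup_taxa: Iterable[str]) -> GeneTree:
    """Re-root a gene tree on the edge above the smallest clade holding all
    ``outgroup_taxa`` leaves.  Rooting is the caller's responsibility for
    reconciliation; this helper covers the common outgroup convention.
    """
    wanted = frozenset(outgroup_taxa)
    leaves = [n for n in tree.leaves() if tree.taxon(n) in wanted]
    if not leaves:
        raise TreeError("no outgroup leaves present")
    # smallest node whose leaf set covers all outgroup leaves
    cover = leaves[0]
    target = frozenset(n.label for n in leaves)
    while not target <= cover.leaf_labels():
        cover = cover.parent
    if cover.parent is None:
        return GeneTree(_clone(tree.root), taxon_sep=tree.taxon_sep)
    # walk from cover to the old root, reversing parent links
    new_root = Node()
    old_len = cover.length
    new_root.add_child(_clone_subtree_only(cover))
    flipped = _reverse_path(cover.parent, cover)
    flipped.length = old_len
    new_root.children[0].length = (old_len or 0.0) / 2 if old_len else old_len
    flipped.length = (old_len or 0.0) / 2 if old_len else old_len
    new_root.add_child(flipped)
    return GeneTree(new_root, taxon_sep=tree.taxon_sep)


def _clone_subtree_only(node: Node) -> Node:
    return _clone(node)


def _reverse_path(node: Node, coming_from: Node) -> Node:
    """Rebuild ``node`` as seen from ``coming_from``, recursing rootward."""
    new = Node(label=node.label)
    for child in node.children:
        if child is coming_from:
            continue
        new.add_child(_clone(child))
    if node.parent is not None:
        up = _reverse_path(node.parent, node)
        up.length = node.length
        new.add_child(up)
    # suppress a degree-1 pass-through at the old root
    if len(new.children) == 1:
        only = new.children[0]
        if new.length is not None and only.length is not None:
            only.length += new.length
        only.parent = None
        return only
    return new
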