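"""Rooted trees with edge-attached supports, rooting and LCA utilities.

Gene trees carry a gene id and a species id on every leaf and an optional
bootstrap support (integer percent, 0-100) on every internal node; species
trees carry species ids on leaves and ancestor names (``LCA_A`` ...) on
internal nodes.  Newick text is parsed through dendropy; the in-memory
representation is a small mutable node structure so that rerooting can move
supports with their bipartitions and the downstream algorithms (lineage
delineation, reconciliation) can walk the tree cheaply.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import dendropy


class TreeError(ValueError):
    """Invalid tree input or operation."""


class NewickParseError(TreeError):
    """Malformed newick; message carries the reader's line/column offset."""


class DuplicateLeafError(TreeError):
    """Two or more leaves share a label."""


@dataclass
class Node:
    name: str | None = None
    support: int | None = None
    length: float | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    # -- structure ---------------------------------------------------------
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
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.leaves())

    def ancestors(self, include_self: bool = False) -> Iterator["Node"]:
        node = self if include_self else self.parent
        while node is not None:
            yield node
            node = node.parent

    def copy(self) -> "Node":
        clone = Node(name=self.name, support=self.support, length=self.length)
        for child in self.children:
            clone.add_child(child.copy())
        return clone


class Tree:
    """A rooted (possibly multifurcating) tree over a root :class:`Node`."""

    def __init__(self, root: Node):
        self.root = root
        self._index: dict[str, Node] | None = None

    # -- iteration ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def copy(self):
        return type(self)(self.root.copy())

    # -- lookup ------------------------------------------------------------
    def _build_index(self) -> dict[str, Node]:
        index: dict[str, Node] = {}
        for node in self.preorder():
            if node.name is not None:
                index.setdefault(node.name, node)
        return index

    def find(self, name: str) -> Node:
        if self._index is None:
            self._index = self._build_index()
        try:
            return self._index[name]
        except KeyError:
            raise TreeError(f"no node named {name!r} in tree") from None

    def invalidate(self) -> None:
        self._index = None

    # -- lca ---------------------------------------------------------------
    def lca(self, nodes: Iterable[Node | str]) -> Node:
        """Lowest common ancestor of a non-empty set of nodes (or names)."""
        resolved = [self.find(n) if isinstance(n, str) else n for n in nodes]
        if not resolved:
            raise TreeError("lca of an empty node set is undefined")
        depths = {}
        for node in resolved:
            d = sum(1 for _ in node.ancestors())
            depths[id(node)] = d
        current = resolved[0]
        depth = depths[id(current)]
        for other in resolved[1:]:
            od = sum(1 for _ in other.ancestors())
            while depth > od:
                current = current.parent
                depth -= 1
            while od > depth:
                other = other.parent
                od -= 1
            while current is not other:
                current = current.parent
                other = other.parent
                depth -= 1
        return current

    # -- splits ------------------------------------------------------------
    def unrooted_splits(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial bipartitions of the leaf label set, unrooted sense."""
        all_leaves = self.leaf_names()
        splits = set()
        for node in self.preorder():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            other = all_leaves - side
            if side and other:
                splits.add(frozenset((side, other)))
        return splits

    def split_supports(self) -> dict[frozenset[frozenset[str]], int | None]:
        all_leaves = self.leaf_names()
        out: dict[frozenset[frozenset[str]], int | None] = {}
        for node in self.preorder():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            split = frozenset((side, all_leaves - side))
            prev = out.get(split)
            out[split] = node.support if prev is None else prev
        return out


class GeneTree(Tree):
    """Gene family tree; each leaf name is a gene id mapped to a species."""

    def __init__(self, root: Node, species_map: dict[str, str]):
        super().__init__(root)
        self.species_map = species_map

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy(), dict(self.species_map))

    def species_of(self, leaf: Node | str) -> str:
        name = leaf if isinstance(leaf, str) else leaf.name
        try:
            return self.species_map[name]
        except KeyError:
            raise TreeError(f"gene {name!r} has no species assignment") from None


class SpeciesTree(Tree):
    """Species tree; internal node names are ancestor labels (``LCA_*``)."""

    def ancestor(self, name: str) -> Node:
        node = self.find(name)
        return node


# ---------------------------------------------------------------------------
# newick in / out
# ---------------------------------------------------------------------------

_NUMERIC = re.compile(r"^\d+(\.\d+)?$")


def _dendropy_parse(newick_text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise DuplicateLeafError(f"duplicate leaf labels in newick input: {exc}") from exc
    except Exception as exc:  # dendropy raises several reader error types
        raise NewickParseError(f"malformed newick: {exc}") from exc


def _convert(dnode, interpret_support: bool, support_scale: str) -> Node:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = Node(length=dnode.edge.length)
    if dnode.is_leaf():
        node.name = label
    elif label is not None:
        if interpret_support and _NUMERIC.match(label):
            node.support = _parse_support(label, support_scale)
        else:
            node.name = label
    for child in dnode.child_nodes():
        node.add_child(_convert(child, interpret_support, support_scale))
    return node


def _parse_support(label: str, support_scale: str) -> int:
    value = float(label)
    if support_scale == "fraction" or (support_scale == "auto" and value <= 1.0 and "." in label):
        value *= 100.0
    support = int(round(value))
    if not 0 <= support <= 100:
        raise TreeError(f"support {label!r} outside [0, 100] after scaling")
    return support


def split_gene_label(label: str, sep: str = "_") -> tuple[str, str]:
    """Split ``g12_B.rapa`` into (gene id, species id); gene id keeps the label."""
    if sep not in label:
        raise TreeError(f"gene label {label!r} has no {sep!r} separator to derive a species")
    _, species = label.split(sep, 1)
    return label, species


def read_gene_tree(
    newick_text: str,
    species_map: dict[str, str] | None = None,
    label_sep: str = "_",
    support_scale: str = "auto",
) -> GeneTree:
    """Parse a gene-family newick string.

    Numeric internal labels are bootstrap supports; ``support_scale`` may be
    ``"percent"``, ``"fraction"`` (multiplied by 100 on ingest) or ``"auto"``
    (values <= 1 written with a decimal point are fractions).  When no
    explicit ``species_map`` is given, species ids are derived from leaf
    labels of the form ``<gene>_<species>``.
    """
    dtree = _dendropy_parse(newick_text)
    root = _convert(dtree.seed_node, interpret_support=True, support_scale=support_scale)
    leaves = [n.name for n in root.leaves()]
    dupes = sorted({name for name in leaves if leaves.count(name) > 1})
    if dupes:
        raise DuplicateLeafError(f"duplicate leaf labels: {', '.join(dupes)}")
    if species_map is None:
        species_map = dict(split_gene_label(name, label_sep) for name in leaves)
    missing = [name for name in leaves if name not in species_map]
    if missing:
        raise TreeError(f"species map lacks entries for: {', '.join(sorted(missing))}")
    return GeneTree(root, species_map)


def read_species_tree(newick_text: str) -> SpeciesTree:
    """Parse a species tree; internal labels are ancestor names, not supports."""
    dtree = _dendropy_parse(newick_text)
    root = _convert(dtree.seed_node, interpret_support=False, support_scale="percent")
    return SpeciesTree(root)


def _fmt_length(length: float | None) -> str:
    if length is None:
        return ""
    return f":{length:g}"


def _node_newick(node: Node, label_of: Callable[[Node], str]) -> str:
    if node.is_leaf:
        return f"{node.name}{_fmt_length(node.length)}"
    inner = ",".join(_node_newick(c, label_of) for c in node.children)
    return f"({inner}){label_of(node)}{_fmt_length(node.length)}"


def write_gene_tree(tree: GeneTree) -> str:
    label = lambda n: "" if n.support is None else str(n.support)
    return _node_newick(tree.root, label) + ";"


def write_species_tree(tree: SpeciesTree) -> str:
    label = lambda n: n.name or ""
    return _node_newick(tree.root, label) + ";"


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------


def root_by_outgroup(tree: GeneTree, outgroup_leaves: Iterable[str]) -> GeneTree:
    """Root on the edge separating ``outgroup_leaves`` from the rest.

    The outgroup must form one side of a split of the unrooted topology;
    otherwise a :class:`TreeError` lists the intruding leaves.  A tree whose
    root already induces that split is returned unchanged (as a copy).
    """
    outgroup = frozenset(outgroup_leaves)
    all_leaves = tree.leaf_names()
    if not outgroup:
        raise TreeError("empty outgroup")
    unknown = outgroup - all_leaves
    if unknown:
        raise TreeError(f"outgroup leaves absent from tree: {', '.join(sorted(unknown))}")
    if outgroup == all_leaves:
        raise TreeError("outgroup cannot contain every leaf")

    work = tree.copy()
    if len(work.root.children) == 2:
        for child in work.root.children:
            if child.leaf_names() == outgroup:
                return work  # already rooted on the outgroup edge

    target = None
    for node in work.preorder():
        if node is work.root:
            continue
        side = node.leaf_names()
        if side == outgroup or side == all_leaves - outgroup:
            target = node
            break
    if target is None:
        mrca = work.lca([leaf for leaf in outgroup])
        intruders = sorted(mrca.leaf_names() - outgroup)
        raise TreeError(
            "outgroup is not monophyletic in the unrooted tree; intruding leaves: "
            + ", ".join(intruders)
        )
    root = _reroot_above(work.root, target)
    rooted = GeneTree(root, dict(work.species_map))
    return rooted


def _reroot_above(old_root: Node, target: Node) -> Node:
    """Re-hang the tree so the edge above ``target`` carries the new root."""
    path = list(target.ancestors())  # target.parent ... old_root
    # detach target
    parent = target.parent
    parent.children.remove(target)
    target.parent = None

    # edge attributes to push down the reversed path: edge(path[i] above) was
    # stored on path[i]; after reversal it describes path[i+1] as seen from
    # path[i].
    saved = [(n.length, n.support) for n in path]

    new_root = Node()
    # split the old (parent -> target) edge between the two root children
    if target.length is not None:
        half = target.length / 2.0
        target.length = half
        parent_edge_length = half
    else:
        parent_edge_length = None
    parent_edge_support = target.support

    new_root.add_child(target)
    new_root.add_child(parent)
    for i, node in enumerate(path):
        upper = path[i + 1] if i + 1 < len(path) else None
        if upper is not None:
            upper.children.remove(node)
            node.add_child(upper)
            upper.length, upper.support = saved[i]
    parent.parent = new_root
    parent.length = parent_edge_length
    parent.support = parent_edge_support

    # suppress a unifurcation left at the old root position
    _suppress_unifurcations(new_root)
    return new_root


def _suppress_unifurcations(root: Node) -> None:
    for node in list(root.preorder()):
        while len(node.children) == 1 and node is not root:
            child = node.children[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            if child.support is None:
                child.support = node.support
            grand = node.parent
            grand.children[grand.children.index(node)] = child
            child.parent = grand
            node = child
    while len(root.children) == 1:
        only = root.children[0]
        only.parent = None
        only.length = None
        root.children = []
        root = only  # caller keeps original reference; avoided by construction
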