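"""Partition a gene tree into ancestral homolog lineages.

A lineage is a well-supported clade hypothesized to descend from a single
gene copy in the last common ancestor of the ingroup clades (A/B/D).  A
clade qualifies when it either (1) contains genes from clade D together
with genes from clade A and/or B, or (2) is the sister of a clade
satisfying (1); lineages are the *minimal* such clades: a qualifying clade
that contains two or more disjoint deeper qualifying clades is divided
further.  Outgroup-clade genes (clade F by default) form one extra lineage,
numbered last.  Ingroup leaves that end up under no qualifying clade are
absorbed into an existing lineage by a configurable, logged policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import CladeMap
from .trees import GeneTree, Node, TreeError

INGROUP_CLADES = ("A", "B")
REQUIRED_CLADE = "D"


def clade_content(tree: GeneTree, node: Node, clade_map: CladeMap) -> frozenset[str]:
    """Set of clade labels of the species of all leaves under ``node``."""
    return frozenset(clade_map[tree.species_of(leaf)] for leaf in node.leaves())


def satisfies_criterion1(tree: GeneTree, node: Node, clade_map: CladeMap) -> bool:
    """Genes from clade D present, together with genes from clade A and/or B."""
    content = clade_content(tree, node, clade_map)
    return REQUIRED_CLADE in content and bool(content & set(INGROUP_CLADES))


def satisfies_criterion2(tree: GeneTree, node: Node, clade_map: CladeMap) -> bool:
    """Sister of a clade satisfying criterion 1 (root: no sister, False)."""
    if node.parent is None:
        return False
    return any(
        satisfies_criterion1(tree, sib, clade_map)
        for sib in node.parent.children
        if sib is not node
    )


@dataclass
class Lineage:
    lineage_id: str
    anchor: Node
    members: frozenset[str]
    clade_content: frozenset[str]
    species: frozenset[str]
    anchor_support: int | None
    is_outgroup: bool = False


@dataclass
class LineagePartition:
    lineages: list[Lineage]
    support_min: int
    outgroup_clade: str
    support_absent: str
    unassigned_policy: str
    warnings: list[str] = field(default_factory=list)

    @property
    def ingroup_lineages(self) -> list[Lineage]:
        return [l for l in self.lineages if not l.is_outgroup]

    def lineage_of(self) -> dict[str, str]:
        """gene id -> lineage id."""
        return {g: l.lineage_id for l in self.lineages for g in l.members}

    def to_frame(self, tree: GeneTree, clade_map: CladeMap):
        import pandas as pd

        rows = []
        for lin in self.lineages:
            for gene in sorted(lin.members):
                sp = tree.species_of(gene)
                rows.append(
                    (gene, sp, clade_map[sp], lin.lineage_id, lin.anchor_support)
                )
        return pd.DataFrame(
            rows, columns=["gene_id", "species_id", "clade", "lineage_id", "anchor_support"]
        )


def delineate_lineages(
    tree: GeneTree,
    clade_map: CladeMap,
    support_min: int = 60,
    outgroup_clade: str = "F",
    support_absent: str = "fail",
    unassigned_policy: str = "nearest-anchor",
) -> LineagePartition:
    """Partition all gene-tree leaves into lineages.

    ``support_absent`` controls internal nodes without a support value:
    ``"fail"`` (default) treats them as unsupported, ``"pass"`` as supported.
    The tree must already be rooted so the outgroup-clade genes form one side
    of the root (see :func:`linfam.trees.root_by_outgroup`).
    """
    if support_absent not in ("fail", "pass"):
        raise ValueError("support_absent must be 'fail' or 'pass'")
    warnings: list[str] = []

    outgroup_leaves = frozenset(
        leaf.name
        for leaf in tree.leaves()
        if clade_map[tree.species_of(leaf)] == outgroup_clade
    )
    if any(node.support is not None for node in tree.preorder() if not node.is_leaf):
        pass
    elif support_absent == "fail" and len(tree.leaves()) > 2:
        raise TreeError(
            "tree carries no support values; set support_absent='pass' to delineate anyway"
        )

    ingroup_root = _ingroup_root(tree, outgroup_leaves)

    def support_ok(node: Node) -> bool:
        if node is ingroup_root:
            return True
        if node.support is None:
            return support_absent == "pass"
        return node.support >= support_min

    def is_candidate(node: Node) -> bool:
        if node.is_leaf and node.parent is not None:
            # a single leaf can qualify only through criterion 2
            return satisfies_criterion2(tree, node, clade_map)
        return support_ok(node) and (
            satisfies_criterion1(tree, node, clade_map)
            or satisfies_criterion2(tree, node, clade_map)
        )

    def maximal_candidates_below(node: Node) -> list[Node]:
        found: list[Node] = []
        stack = list(node.children)
        while stack:
            child = stack.pop()
            if is_candidate(child):
                found.append(child)
            else:
                stack.extend(child.children)
        return found

    def refine(node: Node) -> list[Node]:
        # a clade divides when >= 2 disjoint qualifying clades lie strictly
        # below it; a single maximal candidate is followed down, since any
        # division of its subtree also divides this node (leftover leaves
        # are absorbed by the unassigned-leaf policy)
        below = maximal_candidates_below(node)
        if len(below) >= 2:
            anchors: list[Node] = []
            for cand in below:
                anchors.extend(refine(cand))
            return anchors
        if len(below) == 1:
            deeper = refine(below[0])
            if len(deeper) >= 2 or deeper[0] is not below[0]:
                return deeper
            return [node]
        return [node]

    if is_candidate(ingroup_root) or (
        satisfies_criterion1(tree, ingroup_root, clade_map)
        or satisfies_criterion2(tree, ingroup_root, clade_map)
    ):
        anchors = refine(ingroup_root)
    else:
        warnings.append(
            "no clade satisfies either lineage criterion; whole ingroup kept as one lineage"
        )
        anchors = [ingroup_root]

    # membership: leaves under each anchor, then absorb leftovers
    anchor_set = set(id(a) for a in anchors)
    members: dict[int, set[str]] = {id(a): set(a.leaf_names()) for a in anchors}
    assigned = set().union(*members.values()) if members else set()
    ingroup_leaf_names = ingroup_root.leaf_names()
    unassigned = sorted(ingroup_leaf_names - assigned)
    if unassigned:
        warnings.append(
            f"{len(unassigned)} leaves outside any qualifying clade absorbed by policy "
            f"{unassigned_policy!r}"
        )
        _absorb(tree, unassigned, anchors, members, anchor_set, unassigned_policy)

    # number by preorder traversal of anchors
    order = {id(n): i for i, n in enumerate(tree.preorder())}
    anchors.sort(key=lambda a: order[id(a)])
    lineages = []
    for i, anchor in enumerate(anchors, start=1):
        genes = frozenset(members[id(anchor)])
        species = frozenset(tree.species_of(g) for g in genes)
        lineages.append(
            Lineage(
                lineage_id=f"L{i}",
                anchor=anchor,
                members=genes,
                clade_content=frozenset(clade_map[s] for s in species),
                species=species,
                anchor_support=anchor.support,
            )
        )
    if outgroup_leaves:
        species = frozenset(tree.species_of(g) for g in outgroup_leaves)
        og_anchor = next(
            child
            for child in tree.root.children
            if child.leaf_names() == outgroup_leaves
        )
        lineages.append(
            Lineage(
                lineage_id=f"L{len(anchors) + 1}",
                anchor=og_anchor,
                members=outgroup_leaves,
                clade_content=frozenset({outgroup_clade}),
                species=species,
                anchor_support=og_anchor.support,
                is_outgroup=True,
            )
        )
    return LineagePartition(
        lineages=lineages,
        support_min=support_min,
        outgroup_clade=outgroup_clade,
        support_absent=support_absent,
        unassigned_policy=unassigned_policy,
        warnings=warnings,
    )


def _ingroup_root(tree: GeneTree, outgroup_leaves: frozenset[str]) -> Node:
    if not outgroup_leaves:
        return tree.root
    if len(tree.root.children) != 2:
        raise TreeError(
            "tree root is not binary; root on the outgroup edge first (root_by_outgroup)"
        )
    for child in tree.root.children:
        if child.leaf_names() == outgroup_leaves:
            other = next(c for c in tree.root.children if c is not child)
            return other
    raise TreeError(
        "outgroup-clade genes do not form one side of the root; "
        "root the tree on the outgroup edge first"
    )


def _absorb(
    tree: GeneTree,
    unassigned: list[str],
    anchors: list[Node],
    members: dict[int, set[str]],
    anchor_set: set[int],
    policy: str,
) -> None:
    if policy != "nearest-anchor":
        raise ValueError(f"unknown unassigned-leaf policy {policy!r}")
    depth = {id(tree.root): 0}
    for node in tree.preorder():
        for child in node.children:
            depth[id(child)] = depth[id(node)] + 1
    anchor_min_gene = {id(a): min(a.leaf_names()) for a in anchors}
    for leaf_name in unassigned:
        leaf = tree.find(leaf_name)
        # nearest ancestor that is itself an anchor
        target = None
        for anc in leaf.ancestors():
            if id(anc) in anchor_set:
                target = anc
                break
        if target is None:
            # deepest shared ancestor with any lineage anchor; ties broken by
            # the lineage's smallest member gene id (child-order invariant)
            best = None
            for anchor in anchors:
                d = depth[id(tree.lca([leaf, anchor]))]
                key = (-d, anchor_min_gene[id(anchor)])
                if best is None or key < best[0]:
                    best = (key, anchor)
            target = best[1]
        members[id(target)].add(leaf_name)
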