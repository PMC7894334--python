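"""Gene-tree / species-tree reconciliation and gain/loss accounting.

Standard LCA reconciliation: every gene-tree node maps to the species-tree
LCA of its descendant species; a node is a duplication when its mapping
coincides with a child's mapping.  Copy numbers at a named ancestor are
counted from survival evidence (Dollo-minimal): a gene copy is present at
ancestor S when some gene-tree edge crosses S, i.e. its lower endpoint maps
inside S's subtree while its upper endpoint maps strictly above (or is a
duplication at S).  Losses are scored as clade-stem absences: one loss per
(lineage, clade) pair where the lineage retains no gene from that clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import CladeMap
from .lineages import Lineage, LineagePartition
from .trees import GeneTree, Node, SpeciesTree, Tree, TreeError

SPECIATION = "speciation"
DUPLICATION = "duplication"


@dataclass
class NodeReconciliation:
    gene_tree: GeneTree
    species_tree: SpeciesTree
    mapping: dict[int, Node]  # id(gene node) -> species node
    event: dict[int, str]  # id(gene node) -> speciation | duplication | leaf

    def species_node(self, gene_node: Node) -> Node:
        return self.mapping[id(gene_node)]


def _species_ancestor_sets(species_tree: Tree) -> dict[int, frozenset[int]]:
    ancsets: dict[int, frozenset[int]] = {}
    for node in species_tree.preorder():
        parent_set = ancsets.get(id(node.parent), frozenset()) if node.parent else frozenset()
        ancsets[id(node)] = parent_set | {id(node)}
    return ancsets


def lca_reconcile(gene_tree: GeneTree, species_tree: SpeciesTree) -> NodeReconciliation:
    """LCA mapping plus speciation/duplication labels for every gene node."""
    species_leaf = {leaf.name: leaf for leaf in species_tree.leaves()}
    missing = sorted(
        {gene_tree.species_of(l) for l in gene_tree.leaves()} - set(species_leaf)
    )
    if missing:
        raise TreeError(f"species absent from species tree: {', '.join(missing)}")

    mapping: dict[int, Node] = {}
    event: dict[int, str] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            mapping[id(node)] = species_leaf[gene_tree.species_of(node)]
            event[id(node)] = "leaf"
        else:
            child_maps = [mapping[id(c)] for c in node.children]
            m = species_tree.lca(child_maps)
            mapping[id(node)] = m
            dup = any(mapping[id(c)] is m for c in node.children)
            event[id(node)] = DUPLICATION if dup else SPECIATION
    return NodeReconciliation(gene_tree, species_tree, mapping, event)


# ---------------------------------------------------------------------------
# per-lineage induced reconciliation and copy counting
# ---------------------------------------------------------------------------


def induced_subtree(tree: GeneTree, leaf_names: frozenset[str]) -> GeneTree:
    """Copy of the subtree spanned by ``leaf_names``, unifurcations suppressed."""
    keep = set(leaf_names)

    def build(node: Node) -> Node | None:
        if node.is_leaf:
            if node.name in keep:
                return Node(name=node.name, length=node.length)
            return None
        built = [b for b in (build(c) for c in node.children) if b is not None]
        if not built:
            return None
        if len(built) == 1:
            child = built[0]
            if child.length is not None or node.length is not None:
                child.length = (child.length or 0.0) + (node.length or 0.0)
            return child
        clone = Node(support=node.support, length=node.length)
        for b in built:
            clone.add_child(b)
        return clone

    root = build(tree.root)
    if root is None:
        raise TreeError("no requested leaves found in tree")
    root.parent = None
    species = {name: tree.species_of(name) for name in keep}
    return GeneTree(root, species)


@dataclass
class _LineageRecon:
    lineage: Lineage
    recon: NodeReconciliation

    def copies_at(self, ancestor: Node, ancsets: dict[int, frozenset[int]]) -> int:
        """Gene copies surviving to species-tree node ``ancestor``.

        Counts gene-tree edges crossing the ancestor's crown.  A node is
        at-or-below the crown when it maps inside the ancestor's subtree,
        except duplications mapping exactly to the ancestor: those occur on
        the branch above the crown, so their incoming edge does not cross
        it while their child edges may.
        """
        target = id(ancestor)
        mapping, event = self.recon.mapping, self.recon.event

        def below_crown(node: Node) -> bool:
            m = mapping[id(node)]
            if target not in ancsets[id(m)]:
                return False
            return not (m is ancestor and event[id(node)] == DUPLICATION)

        count = 0
        for node in self.recon.gene_tree.preorder():
            if not below_crown(node):
                continue
            if node.parent is None or not below_crown(node.parent):
                count += 1  # edge from the stem or from above the crown
        return count

    def duplications(self) -> list[Node]:
        return [
            n
            for n in self.recon.gene_tree.preorder()
            if self.recon.event.get(id(n)) == DUPLICATION
        ]


def _lineage_recons(
    gene_tree: GeneTree, species_tree: SpeciesTree, partition: LineagePartition
) -> dict[str, _LineageRecon]:
    if set().union(*(l.members for l in partition.lineages)) != gene_tree.leaf_names():
        raise TreeError("lineage partition does not match the gene tree's leaf set")
    out = {}
    for lin in partition.lineages:
        sub = induced_subtree(gene_tree, lin.members)
        out[lin.lineage_id] = _LineageRecon(lin, lca_reconcile(sub, species_tree))
    return out


def copy_number_at(
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    partition: LineagePartition,
    ancestor_name: str,
    include_outgroup: bool = False,
) -> tuple[dict[str, int], int]:
    """Per-lineage and total copy numbers surviving to a named ancestor."""
    ancestor = species_tree.ancestor(ancestor_name)
    ancsets = _species_ancestor_sets(species_tree)
    recons = _lineage_recons(gene_tree, species_tree, partition)
    per_lineage: dict[str, int] = {}
    for lin in partition.lineages:
        if lin.is_outgroup and not include_outgroup:
            continue
        per_lineage[lin.lineage_id] = recons[lin.lineage_id].copies_at(ancestor, ancsets)
    return per_lineage, sum(per_lineage.values())


@dataclass
class GainLossSummary:
    ingroup_ancestor: str
    clade_ancestors: dict[str, str]  # clade label -> ancestor node name
    copies: dict[str, dict[str, int]]  # lineage -> ancestor name -> copies
    stem_gains: int
    clade_gains: dict[str, int]  # per-clade extra-copy gains
    gains_per_clade_total: int
    gains_pooled: int
    losses: int
    loss_pairs: list[tuple[str, str]]  # (lineage, clade) absences
    gain_lineages: dict[str, list[str]] = field(default_factory=dict)

    @property
    def gains(self) -> int:
        """Headline gain tally (per-clade counting)."""
        return self.gains_per_clade_total


def tally_gains_losses(
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    partition: LineagePartition,
    clade_map: CladeMap,
    ingroup_ancestor: str = "LCA_ABD",
    clade_ancestors: dict[str, str] | None = None,
) -> GainLossSummary:
    """Count copy-number gains and losses from the family origin to the clade LCAs.

    Gains: the expansion from one ancestral copy to the per-lineage copies at
    the ingroup ancestor (stem gains), plus per-clade extra copies acquired
    between the ingroup ancestor and each clade LCA.  A pooled tally that
    counts each duplication node once regardless of how many clades it
    predates is reported alongside.  Losses: clade-stem absences (Dollo).
    """
    if clade_ancestors is None:
        clade_ancestors = {"A": "LCA_A", "B": "LCA_B", "D": "LCA_D"}
    ancsets = _species_ancestor_sets(species_tree)
    abd = species_tree.ancestor(ingroup_ancestor)
    clade_nodes = {c: species_tree.ancestor(n) for c, n in clade_ancestors.items()}
    recons = _lineage_recons(gene_tree, species_tree, partition)

    copies: dict[str, dict[str, int]] = {}
    clade_gains = {c: 0 for c in clade_ancestors}
    gain_lineages: dict[str, list[str]] = {c: [] for c in clade_ancestors}
    loss_pairs: list[tuple[str, str]] = []
    total_abd = 0
    pooled_dups = 0

    ingroup = partition.ingroup_lineages
    for lin in ingroup:
        lr = recons[lin.lineage_id]
        c_abd = lr.copies_at(abd, ancsets)
        row = {ingroup_ancestor: c_abd}
        total_abd += c_abd
        for clade, node in clade_nodes.items():
            c_x = lr.copies_at(node, ancsets)
            row[clade_ancestors[clade]] = c_x
            extra = max(0, c_x - max(c_abd, 1))
            if extra:
                clade_gains[clade] += extra
                gain_lineages[clade].append(lin.lineage_id)
            if clade not in lin.clade_content:
                loss_pairs.append((lin.lineage_id, clade))
        copies[lin.lineage_id] = row
        # pooled: duplication nodes predating at least one clade LCA
        for dup in lr.duplications():
            m = lr.recon.mapping[id(dup)]
            if any(id(m) in ancsets[id(node)] for node in clade_nodes.values()):
                pooled_dups += 1

    stem_gains = max(0, total_abd - 1)
    per_clade_total = stem_gains + sum(clade_gains.values())
    pooled = max(0, len(ingroup) - 1) + pooled_dups
    return GainLossSummary(
        ingroup_ancestor=ingroup_ancestor,
        clade_ancestors=clade_ancestors,
        copies=copies,
        stem_gains=stem_gains,
        clade_gains=clade_gains,
        gains_per_clade_total=per_clade_total,
        gains_pooled=pooled,
        losses=len(loss_pairs),
        loss_pairs=loss_pairs,
        gain_lineages=gain_lineages,
    )
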