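"""Birth–death gene-family simulator with full ground-truth event logs.

One ancestral gene copy is placed in the root of a clade-structured species
tree and evolves down it under a Gillespie birth–death process: each copy
duplicates at rate ``dup_rate`` and is lost at rate ``loss_rate`` per unit
branch length.  Duplicates are placed in tandem (immediately after the
parent gene in the genome's gene order) with probability ``p_tandem``,
otherwise at a uniform random chromosome position.  Genomes carry inert
background genes whose cross-species orthology provides the collinear
signal the synteny stage chains; speciation copies the genome, so regions
stay collinear except where dispersed duplicates land.  CDS sequences are
evolved along the resulting gene tree under a simple codon scheme with a
configurable nonsynonymous/synonymous acceptance ratio omega, and
bootstrap-like supports are drawn from a two-component model.

Every stochastic choice that shapes the gene tree and the gene order is
written to the event log, so :func:`replay_events` reconstructs the exact
tree and locus table from the log alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import exp
from typing import Any

import numpy as np
import pandas as pd

from .io import CladeMap, assign_ranks
from .trees import GeneTree, Node, SpeciesTree, read_species_tree

DEFAULT_SPECIES_NEWICK = (
    "(((((Athaliana:0.30,Alyrata:0.30)N1:0.10,Csativa:0.40)LCA_A:0.25,"
    "(Brapa:0.35,Boleracea:0.35)LCA_B:0.30)LCA_AB:0.15,"
    "(Aalpina:0.55,Amontbretiana:0.55)LCA_D:0.25)LCA_ABD:0.20,"
    "Aarabicum:1.00)LCA_Brassicaceae;"
)

DEFAULT_CLADE_MAP = {
    "Athaliana": "A",
    "Alyrata": "A",
    "Csativa": "A",
    "Brapa": "B",
    "Boleracea": "B",
    "Aalpina": "D",
    "Amontbretiana": "D",
    "Aarabicum": "F",
}


@dataclass
class SimConfig:
    """Study conditions for one simulated gene family.

    Defaults emulate the regime of a Brassicaceae-specific family that
    expanded from a single ancestral copy to tens-to-a-hundred copies per
    species across eight representative genomes, partly through tandem
    duplication, with strongly diverged (40-72% identical) conserved
    regions and purifying selection (Ka/Ks well below 1).
    """

    species_newick: str = DEFAULT_SPECIES_NEWICK
    clade_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CLADE_MAP))
    dup_rate: float = 3.6  # duplications / gene / unit time
    loss_rate: float = 0.4  # losses / gene / unit time
    p_tandem: float = 0.35
    n_chromosomes: int = 3
    n_background: int = 80  # background genes per chromosome
    rearrangement_rate: float = 4.0  # segment moves / genome / unit time
    seg_len_min: int = 8
    seg_len_max: int = 40
    n_codons: int = 300
    substitution_rate: float = 0.55  # attempted changes / site / unit time
    omega: float = 0.7  # nonsynonymous acceptance ratio
    q_support: float = 0.9  # P(support = 100) for a true bipartition
    support_low: int = 30  # otherwise uniform on [support_low, 100)
    seed: int = 0
    max_expected_family: float = 1e4
    require_ingroup: bool = True  # condition on survival outside the outgroup clade
    outgroup_clade: str = "F"

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.p_tandem <= 1.0:
            raise ValueError("p_tandem must lie in [0, 1]")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)


@dataclass
class SimulatedFamily:
    gene_tree: GeneTree
    species_tree: SpeciesTree
    clade_map: CladeMap
    loci: pd.DataFrame  # family + background genes, ranks assigned
    pairs: pd.DataFrame  # homolog/ortholog anchor pairs, BLAST-like
    cds: dict[str, str]
    proteins: dict[str, str]
    events: list[dict[str, Any]]
    founder_of: dict[str, str]  # leaf gene id -> founder label
    region_of: dict[str, int]  # leaf gene id -> ancestral-locus region id
    config: SimConfig
    n_resampled: int = 0

    @property
    def founder_count(self) -> int:
        """Distinct ingroup founders (copies alive at the ingroup crown)."""
        return len(
            {f for f in self.founder_of.values() if f != "outgroup"}
        )

    def events_json(self) -> str:
        return json.dumps(self.events, indent=1)


# ---------------------------------------------------------------------------
# event simulation
# ---------------------------------------------------------------------------


class _Copy:
    __slots__ = ("cid", "node", "start", "founder", "region")

    def __init__(self, cid: int, node: Node, start: float, founder: str | None, region: int):
        self.cid = cid
        self.node = node
        self.start = start
        self.founder = founder
        self.region = region


def _expected_family_size(config: SimConfig, species_tree: SpeciesTree) -> float:
    depth: dict[int, float] = {id(species_tree.root): 0.0}
    total = 0.0
    for node in species_tree.preorder():
        for child in node.children:
            depth[id(child)] = depth[id(node)] + (child.length or 0.0)
        if node.is_leaf:
            total += exp((config.dup_rate - config.loss_rate) * depth[id(node)])
    return total


def simulate_events(config: SimConfig, rng: np.random.Generator):
    """Run the birth–death process once; returns raw (possibly extinct) state."""
    species_tree = read_species_tree(config.species_newick)
    branch_name = _branch_names(species_tree)
    lam, mu = config.dup_rate, config.loss_rate
    counter = {"next": 1, "region": 1}
    events: list[dict[str, Any]] = []

    # root genome: background genes, then the founding copy inserted
    genome = [
        [f"bg{c:02d}g{i:03d}" for i in range(config.n_background)]
        for c in range(config.n_chromosomes)
    ]
    chrom0 = int(rng.integers(config.n_chromosomes))
    slot0 = int(rng.integers(len(genome[chrom0]) + 1))
    genome[chrom0].insert(slot0, 0)
    events.append(
        {"type": "origin", "copy": 0, "chrom": chrom0, "slot": slot0}
    )

    leaf_records: list[dict[str, Any]] = []
    root_gene = Node()
    root_copy = _Copy(0, root_gene, 0.0, None, 0)

    def recurse(species_node: Node, copies: list[_Copy], genome, t0: float) -> None:
        if species_node.name == "LCA_ABD":
            for c in copies:
                c.founder = f"F{c.cid}"
        if species_node.is_leaf:
            for c in copies:
                c.node.name = f"g{c.cid}_{species_node.name}"
                c.node.length = round(t0 - c.start, 12)
            leaf_records.append(
                {
                    "species": species_node.name,
                    "genome": [list(ch) for ch in genome],
                    "copies": {
                        c.cid: (c.founder or "outgroup", c.region) for c in copies
                    },
                }
            )
            return
        for child in species_node.children:
            child_genome = [list(ch) for ch in genome]
            child_copies = []
            for c in copies:
                node = Node()
                c.node.add_child(node)
                child_copies.append(_Copy(c.cid, node, t0, c.founder, c.region))
            _branch(child, child_copies, child_genome, t0)

    def _branch(species_child: Node, copies: list[_Copy], genome, t0: float) -> None:
        t_end = t0 + (species_child.length or 0.0)
        t = t0
        bname = branch_name[id(species_child)]
        rho = config.rearrangement_rate
        while True:
            rate = len(copies) * (lam + mu) + rho
            if rate <= 0:
                break
            t_next = t + rng.exponential(1.0 / rate)
            if t_next >= t_end:
                break
            t = t_next
            if rng.random() < rho / rate:  # genome rearrangement
                ev = _rearrange(genome, config, rng)
                if ev is not None:
                    ev.update({"time": round(t, 12), "branch": bname})
                    events.append(ev)
                continue
            idx = int(rng.integers(len(copies)))
            copy = copies[idx]
            if rng.random() < lam / (lam + mu):  # duplication
                new_id = counter["next"]
                counter["next"] += 1
                copy.node.length = round(t - copy.start, 12)
                left, right = Node(), Node()
                copy.node.add_child(left)
                copy.node.add_child(right)
                new_region = copy.region
                if rng.random() < config.p_tandem:
                    placement = "tandem"
                    ci, pos = _find_gene(genome, copy.cid)
                    genome[ci].insert(pos + 1, new_id)
                    chrom, slot = ci, pos + 1
                else:
                    placement = "dispersed"
                    chrom = int(rng.integers(len(genome)))
                    slot = int(rng.integers(len(genome[chrom]) + 1))
                    genome[chrom].insert(slot, new_id)
                    new_region = counter["region"]
                    counter["region"] += 1
                events.append(
                    {
                        "type": "duplication",
                        "time": round(t, 12),
                        "branch": bname,
                        "parent": copy.cid,
                        "child": new_id,
                        "placement": placement,
                        "chrom": chrom,
                        "slot": slot,
                    }
                )
                copies[idx] = _Copy(copy.cid, left, t, copy.founder, copy.region)
                copies.append(_Copy(new_id, right, t, copy.founder, new_region))
            else:  # loss
                events.append(
                    {
                        "type": "loss",
                        "time": round(t, 12),
                        "branch": bname,
                        "copy": copy.cid,
                    }
                )
                ci, pos = _find_gene(genome, copy.cid)
                del genome[ci][pos]
                copy.node.name = None  # dead tip, pruned later
                copy.node.length = round(t - copy.start, 12)
                copies.pop(idx)
        recurse(species_child, copies, genome, t_end)

    recurse(species_tree.root, [root_copy], genome, 0.0)
    return species_tree, root_gene, events, leaf_records


def _rearrange(genome, config: SimConfig, rng: np.random.Generator) -> dict | None:
    """Excise a random gene segment and reinsert it elsewhere; returns the log entry."""
    src = int(rng.integers(len(genome)))
    if len(genome[src]) < 2:
        return None
    start = int(rng.integers(len(genome[src])))
    length = int(rng.integers(config.seg_len_min, config.seg_len_max + 1))
    length = min(length, len(genome[src]) - start)
    dst = int(rng.integers(len(genome)))
    ev = {"type": "rearrangement", "src": src, "start": start, "length": length, "dst": dst}
    _apply_rearrangement(genome, ev, rng_slot=int(rng.integers(10**9)))
    ev["slot"] = ev.pop("_slot")
    return ev


def _apply_rearrangement(genome, ev: dict, rng_slot: int | None = None) -> None:
    """Apply one segment move; chooses the insertion slot when not in the log."""
    src, start, length, dst = ev["src"], ev["start"], ev["length"], ev["dst"]
    segment = genome[src][start : start + length]
    del genome[src][start : start + length]
    if "slot" in ev:
        slot = ev["slot"]
    else:
        slot = rng_slot % (len(genome[dst]) + 1)
        ev["_slot"] = slot
    genome[dst][slot:slot] = segment


def _branch_names(species_tree: SpeciesTree) -> dict[int, str]:
    names = {}
    for i, node in enumerate(species_tree.preorder()):
        names[id(node)] = node.name if node.name else f"node{i}"
    return names


def _find_gene(genome, gene) -> tuple[int, int]:
    for ci, chrom in enumerate(genome):
        try:
            return ci, chrom.index(gene)
        except ValueError:
            continue
    raise KeyError(gene)


def _prune_dead(root: Node) -> Node | None:
    """Drop dead tips, suppress unifurcations; keep leaf branch lengths."""

    def build(node: Node) -> Node | None:
        if not node.children:
            if node.name is None:
                return None
            return Node(name=node.name, length=node.length)
        built = [b for b in (build(c) for c in node.children) if b is not None]
        if not built:
            return None
        if len(built) == 1:
            child = built[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            return child
        clone = Node(length=node.length)
        for b in built:
            clone.add_child(b)
        return clone

    pruned = build(root)
    if pruned is not None:
        pruned.length = None
        pruned.parent = None
    return pruned


# ---------------------------------------------------------------------------
# replay: event log -> gene tree topology + genomes
# ---------------------------------------------------------------------------


def replay_events(
    species_newick: str,
    events: list[dict[str, Any]],
    n_chromosomes: int,
    n_background: int,
) -> tuple[Node, dict[str, list[list]]]:
    """Reconstruct the (unpruned) gene tree and leaf genomes from the log.

    The log records every duplication/loss with its branch and genome
    placement in application order, so the reconstruction is exact.
    """
    species_tree = read_species_tree(species_newick)
    branch_name = _branch_names(species_tree)
    by_branch: dict[str, list[dict]] = {}
    origin = None
    for ev in events:
        if ev["type"] == "origin":
            origin = ev
        else:
            by_branch.setdefault(ev["branch"], []).append(ev)

    genome = [
        [f"bg{c:02d}g{i:03d}" for i in range(n_background)] for c in range(n_chromosomes)
    ]
    genome[origin["chrom"]].insert(origin["slot"], 0)
    root_gene = Node()
    genomes_out: dict[str, list[list]] = {}

    def recurse(species_node: Node, copies: dict[int, tuple[Node, float]], genome, t0):
        if species_node.is_leaf:
            for cid, (node, start) in copies.items():
                node.name = f"g{cid}_{species_node.name}"
                node.length = round(t0 - start, 12)
            genomes_out[species_node.name] = [list(ch) for ch in genome]
            return
        for child in species_node.children:
            child_genome = [list(ch) for ch in genome]
            child_copies = {}
            for cid, (node, _) in copies.items():
                sub = Node()
                node.add_child(sub)
                child_copies[cid] = (sub, t0)
            t_end = t0 + (child.length or 0.0)
            for ev in by_branch.get(branch_name[id(child)], []):
                if ev["type"] == "duplication":
                    node, start = child_copies.pop(ev["parent"])
                    node.length = round(ev["time"] - start, 12)
                    left, right = Node(), Node()
                    node.add_child(left)
                    node.add_child(right)
                    child_copies[ev["parent"]] = (left, ev["time"])
                    child_copies[ev["child"]] = (right, ev["time"])
                    child_genome[ev["chrom"]].insert(ev["slot"], ev["child"])
                elif ev["type"] == "rearrangement":
                    _apply_rearrangement(child_genome, ev)
                else:
                    node, start = child_copies.pop(ev["copy"])
                    node.length = round(ev["time"] - start, 12)
                    ci, pos = _find_gene(child_genome, ev["copy"])
                    del child_genome[ci][pos]
            recurse(child, child_copies, child_genome, t_end)

    recurse(species_tree.root, {0: (root_gene, 0.0)}, genome, 0.0)
    return root_gene, genomes_out


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

from .seqstats import _CODON_TABLE, STOP  # standard code shared with the estimator

_NON_STOP = sorted(c for c, aa in _CODON_TABLE.items() if aa != STOP)
_BASE_LIST = ["A", "C", "G", "T"]


def evolve_sequences(
    tree: GeneTree,
    n_codons: int,
    substitution_rate: float,
    omega: float,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, str]]:
    """Evolve a CDS along the tree; returns (cds by leaf, protein by leaf).

    Attempted point mutations arrive at ``substitution_rate`` per site;
    changes creating stop codons are rejected, synonymous changes are always
    accepted and nonsynonymous ones with probability ``min(1, omega)``.
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    root_seq = list("".join(rng.choice(_NON_STOP, size=n_codons)))
    out_cds: dict[str, str] = {}

    def mutate(seq: list[str], t: float) -> list[str]:
        seq = list(seq)
        n_attempts = rng.poisson(substitution_rate * len(seq) * max(t, 0.0))
        for _ in range(n_attempts):
            pos = int(rng.integers(len(seq)))
            base = _BASE_LIST[int(rng.integers(4))]
            if base == seq[pos]:
                continue
            ci = pos - pos % 3
            old_codon = "".join(seq[ci : ci + 3])
            new_codon = old_codon[: pos - ci] + base + old_codon[pos - ci + 1 :]
            if _CODON_TABLE[new_codon] == STOP:
                continue
            if _CODON_TABLE[new_codon] != _CODON_TABLE[old_codon] and rng.random() > min(
                1.0, omega
            ):
                continue
            seq[pos] = base
        return seq

    def walk(node: Node, seq: list[str]) -> None:
        seq = mutate(seq, node.length or 0.0)
        if node.is_leaf:
            out_cds[node.name] = "".join(seq)
            return
        for child in node.children:
            walk(child, seq)

    root = tree.root
    seq0 = mutate(root_seq, 0.0)
    for child in root.children:
        walk(child, seq0)
    if root.is_leaf:
        out_cds[root.name] = "".join(seq0)
    proteins = {
        name: "".join(_CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))
        for name, cds in out_cds.items()
    }
    return out_cds, proteins


def simulate_supports(
    tree: GeneTree, q: float, low: int, rng: np.random.Generator
) -> None:
    """Assign supports in place: 100 with probability q, else uniform [low, 100)."""
    for node in tree.preorder():
        if node.is_leaf or node is tree.root:
            continue
        if rng.random() < q:
            node.support = 100
        else:
            node.support = int(rng.integers(low, 100))


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------


def simulate_family(config: SimConfig) -> SimulatedFamily:
    """Simulate one gene family; resamples families extinct in all species."""
    rng = np.random.default_rng(config.seed)
    species_probe = read_species_tree(config.species_newick)
    expected = _expected_family_size(config, species_probe)
    if expected > config.max_expected_family:
        raise ValueError(
            f"expected family size {expected:.0f} exceeds "
            f"{config.max_expected_family:.0f}; lower dup_rate or raise loss_rate"
        )

    ingroup_species = {
        s for s, c in config.clade_map.items() if c != config.outgroup_clade
    }
    n_resampled = 0
    while True:
        species_tree, raw_root, events, leaf_records = simulate_events(config, rng)
        pruned = _prune_dead(raw_root)
        survived = pruned is not None
        if survived and config.require_ingroup:
            survived = any(
                rec["copies"] and rec["species"] in ingroup_species
                for rec in leaf_records
            )
        if survived:
            break
        n_resampled += 1
        if n_resampled > 1000:
            raise RuntimeError("family extinct in 1000 consecutive simulations")

    clade_map = CladeMap(config.clade_map)
    founder_of: dict[str, str] = {}
    region_of: dict[str, int] = {}
    loci_rows = []
    for rec in leaf_records:
        species = rec["species"]
        for ci, chrom in enumerate(rec["genome"]):
            for pos, entry in enumerate(chrom):
                if isinstance(entry, int):
                    gene = f"g{entry}_{species}"
                    founder, region = rec["copies"][entry]
                    founder_of[gene] = founder
                    region_of[gene] = region
                else:
                    gene = f"{entry}_{species}"
                loci_rows.append(
                    (gene, species, f"chr{ci + 1}", pos * 1000, pos * 1000 + 600, "+")
                )
    loci = pd.DataFrame(
        loci_rows, columns=["gene_id", "species", "chrom", "start", "end", "strand"]
    )
    loci = assign_ranks(loci)

    species_map = {name: name.rsplit("_", 1)[1] for name in pruned.leaf_names()}
    gene_tree = GeneTree(pruned, species_map)
    simulate_supports(gene_tree, config.q_support, config.support_low, rng)
    cds, proteins = evolve_sequences(
        gene_tree, config.n_codons, config.substitution_rate, config.omega, rng
    )
    pairs = _make_pairs(founder_of, loci)
    return SimulatedFamily(
        gene_tree=gene_tree,
        species_tree=species_tree,
        clade_map=clade_map,
        loci=loci,
        pairs=pairs,
        cds=cds,
        proteins=proteins,
        events=events,
        founder_of=founder_of,
        region_of=region_of,
        config=config,
        n_resampled=n_resampled,
    )


def _make_pairs(founder_of: dict[str, str], loci: pd.DataFrame) -> pd.DataFrame:
    """Homolog pair table: family pairs within founder lineages plus all
    intra-species family pairs (for tandem detection), plus background
    ortholog pairs that serve as collinearity anchors."""
    rows = []
    genes = sorted(founder_of)
    species_of = dict(zip(loci["gene_id"], loci["species"]))
    by_founder: dict[str, list[str]] = {}
    for g in genes:
        by_founder.setdefault(founder_of[g], []).append(g)
    for members in by_founder.values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                rows.append((a, b, 1e-50))
    # intra-species pairs across founders (same family, detectable by BLAST)
    by_species: dict[str, list[str]] = {}
    for g in genes:
        by_species.setdefault(species_of[g], []).append(g)
    seen = {(a, b) for a, b, _ in rows}
    for members in by_species.values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if (a, b) not in seen and (b, a) not in seen:
                    rows.append((a, b, 1e-45))
    # background ortholog anchors
    bg = loci[~loci["gene_id"].isin(founder_of)].copy()
    bg["ancestor"] = bg["gene_id"].str.rsplit("_", n=1).str[0]
    for _, group in bg.groupby("ancestor"):
        members = sorted(group["gene_id"])
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                rows.append((a, b, 1e-60))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "evalue"])


# ---------------------------------------------------------------------------
# ground truth tallies for recovery tests
# ---------------------------------------------------------------------------


def true_event_tallies(family: SimulatedFamily) -> dict[str, Any]:
    """Duplication/loss event counts by species-tree position.

    ``stem``: duplications on the path from the family origin to the
    ingroup crown (branch into LCA_ABD); ``per_clade``: duplications
    predating each clade LCA counted once per clade they predate;
    ``pooled``: the same duplications counted once each; ``losses``: all
    loss events on ingroup branches.
    """
    species_tree = family.species_tree
    branch_name = _branch_names(species_tree)
    # path branches from root to a named node (branch labelled by child name)
    def path_to(name: str) -> list[str]:
        node = species_tree.find(name)
        names = []
        while node.parent is not None:
            names.append(branch_name[id(node)])
            node = node.parent
        return names

    abd_path = set(path_to("LCA_ABD"))
    clade_paths = {c: set(path_to(f"LCA_{c}")) - abd_path for c in ("A", "B", "D")}
    ingroup_branches = {
        branch_name[id(n)]
        for n in species_tree.find("LCA_ABD").preorder()
    }
    stem = pooled = 0
    per_clade = {c: 0 for c in clade_paths}
    losses = 0
    for ev in family.events:
        if ev["type"] == "duplication":
            if ev["branch"] in abd_path:
                stem += 1
            hit = [c for c, p in clade_paths.items() if ev["branch"] in p]
            if hit:
                pooled += 1
                for c in hit:
                    per_clade[c] += 1
        elif ev["type"] == "loss" and ev["branch"] in ingroup_branches | abd_path:
            losses += 1
    return {
        "stem": stem,
        "per_clade": per_clade,
        "per_clade_total": stem + sum(per_clade.values()),
        "pooled": stem + pooled,
        "losses": losses,
    }
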