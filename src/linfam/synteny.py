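"""Tandem-array detection and collinear-block chaining.

Anchors (homologous gene pairs admitted by E-value) are chained into
collinear blocks by dynamic programming over gene ranks, MCScanX-style:
a chain is strictly monotone in both genomes (same or inverted
orientation), consecutive anchors may be separated by at most ``max_gaps``
intervening ranks, each anchor scores ``match_score`` and every skipped
rank costs ``gap_penalty``; chains shorter than ``match_size`` anchors are
discarded.  Tandem arrays are transitive groups of same-chromosome
homologs whose consecutive members lie within a small rank distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainParams:
    match_score: int = 50
    match_size: int = 10
    gap_penalty: int = -1
    overlap_window: int = 5
    e_value_max: float = 1e-10
    max_gaps: int = 25

    def __post_init__(self):
        if self.match_size < 2:
            raise ValueError("match_size must be >= 2")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")
        if self.gap_penalty > 0:
            raise ValueError("gap_penalty must be <= 0")


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int


@dataclass
class TandemArray:
    species: str
    chrom: str
    genes: list[str]  # ordered by rank
    ranks: list[int]

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def n_duplications(self) -> int:
        return len(self.genes) - 1


@dataclass
class SyntenyBlock:
    chrom_a: tuple[str, str]  # (species, chromosome)
    chrom_b: tuple[str, str]
    orientation: str  # "same" | "inverted"
    anchors: list[Anchor]
    score: int

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)

    def validate(self, params: ChainParams) -> None:
        """Re-check the block's own invariants; raises AssertionError."""
        assert self.n_anchors >= params.match_size
        sign = 1 if self.orientation == "same" else -1
        gaps = 0
        for prev, cur in zip(self.anchors, self.anchors[1:]):
            da = cur.rank_a - prev.rank_a
            db = sign * (cur.rank_b - prev.rank_b)
            assert 1 <= da <= params.max_gaps + 1, "rank gap violation on genome a"
            assert 1 <= db <= params.max_gaps + 1, "rank gap violation on genome b"
            gaps += (da - 1) + (db - 1)
        expected = params.match_score * self.n_anchors + params.gap_penalty * gaps
        assert self.score == expected, "score inconsistent with anchors and gaps"


# ---------------------------------------------------------------------------
# tandem arrays
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def detect_tandem_arrays(
    loci: pd.DataFrame,
    pairs: pd.DataFrame,
    max_intervening: int = 5,
    e_value_max: float = 1e-10,
) -> list[TandemArray]:
    """Group same-chromosome homologs into tandem arrays.

    Homology is the transitive closure of the admitted pair list; within a
    homology group and chromosome, genes whose consecutive rank distance is
    at most ``max_intervening`` belong to one array.  Arrays have >= 2
    members; the number of implied tandem duplication events is
    ``sum(size - 1)`` over arrays.
    """
    info = loci.set_index("gene_id")[["species", "chrom", "rank"]]
    admitted = pairs[pairs["evalue"] <= e_value_max]
    uf = _UnionFind()
    for gene_a, gene_b in admitted[["gene_a", "gene_b"]].itertuples(index=False):
        if gene_a not in info.index or gene_b not in info.index:
            log.warning("homolog pair gene without locus skipped: %s / %s", gene_a, gene_b)
            continue
        uf.union(gene_a, gene_b)

    groups: dict[tuple[str, str, str], list[tuple[int, str]]] = {}
    for gene in uf.parent:
        root = uf.find(gene)
        species, chrom, rank = info.loc[gene]
        groups.setdefault((root, species, chrom), []).append((int(rank), gene))

    arrays: list[TandemArray] = []
    for (_, species, chrom), members in sorted(groups.items()):
        members.sort()
        run: list[tuple[int, str]] = []
        for rank, gene in members:
            if run and rank - run[-1][0] > max_intervening:
                if len(run) >= 2:
                    arrays.append(_make_array(species, chrom, run))
                run = []
            run.append((rank, gene))
        if len(run) >= 2:
            arrays.append(_make_array(species, chrom, run))
    return arrays


def _make_array(species: str, chrom: str, run: list[tuple[int, str]]) -> TandemArray:
    return TandemArray(
        species=species,
        chrom=chrom,
        genes=[g for _, g in run],
        ranks=[r for r, _ in run],
    )


def tandem_duplication_count(arrays: list[TandemArray]) -> int:
    return sum(a.n_duplications for a in arrays)


# ---------------------------------------------------------------------------
# anchor chaining
# ---------------------------------------------------------------------------


def _best_chain(
    anchors: list[Anchor], params: ChainParams, sign: int
) -> tuple[int, list[Anchor]]:
    """Highest-scoring monotone chain for one orientation (sign = +1/-1)."""
    if not anchors:
        return 0, []
    order = sorted(anchors, key=lambda a: (a.rank_a, sign * a.rank_b))
    n = len(order)
    score = [params.match_score] * n
    prev = [-1] * n
    limit = params.max_gaps + 1
    for i in range(n):
        ai = order[i]
        for j in range(i):
            aj = order[j]
            da = ai.rank_a - aj.rank_a
            db = sign * (ai.rank_b - aj.rank_b)
            if not (1 <= da <= limit and 1 <= db <= limit):
                continue
            gap = (da - 1) + (db - 1)
            cand = score[j] + params.match_score + params.gap_penalty * gap
            if cand > score[i]:
                score[i] = cand
                prev[i] = j
    best = max(range(n), key=lambda i: score[i])
    chain = []
    i = best
    while i != -1:
        chain.append(order[i])
        i = prev[i]
    chain.reverse()
    return score[best], chain


def chain_anchors(
    anchors: list[Anchor],
    params: ChainParams,
    chrom_a: tuple[str, str] = ("", ""),
    chrom_b: tuple[str, str] = ("", ""),
) -> list[SyntenyBlock]:
    """All collinear blocks on one chromosome pair.

    Blocks are extracted greedily best-first; after each extraction, anchors
    within ``overlap_window`` ranks of the block's anchors (on either
    genome) are suppressed before re-chaining.
    """
    active = list(anchors)
    blocks: list[SyntenyBlock] = []
    while active:
        best = None
        for orientation, sign in (("same", 1), ("inverted", -1)):
            sc, chain = _best_chain(active, params, sign)
            if chain and (best is None or sc > best[0]):
                best = (sc, chain, orientation)
        if best is None or len(best[1]) < params.match_size:
            break
        sc, chain, orientation = best
        blocks.append(
            SyntenyBlock(
                chrom_a=chrom_a, chrom_b=chrom_b, orientation=orientation,
                anchors=chain, score=sc,
            )
        )
        used_a = {a.rank_a for a in chain}
        used_b = {a.rank_b for a in chain}
        w = params.overlap_window

        def clear(anchor: Anchor) -> bool:
            near_a = any(abs(anchor.rank_a - r) <= w for r in used_a)
            near_b = any(abs(anchor.rank_b - r) <= w for r in used_b)
            return not (near_a or near_b)

        active = [a for a in active if clear(a)]
    return blocks


def find_synteny_blocks(
    loci: pd.DataFrame, pairs: pd.DataFrame, params: ChainParams | None = None
) -> list[SyntenyBlock]:
    """Chain all admitted anchors, grouped by (species, chromosome) pair."""
    if params is None:
        params = ChainParams()
    info = loci.set_index("gene_id")[["species", "chrom", "rank"]]
    admitted = pairs[pairs["evalue"] <= params.e_value_max]
    grouped: dict[tuple[tuple[str, str], tuple[str, str]], list[Anchor]] = {}
    for gene_a, gene_b in admitted[["gene_a", "gene_b"]].itertuples(index=False):
        if gene_a not in info.index or gene_b not in info.index:
            log.warning("anchor gene without locus skipped: %s / %s", gene_a, gene_b)
            continue
        sa, ca, ra = info.loc[gene_a]
        sb, cb, rb = info.loc[gene_b]
        key_a, key_b = (str(sa), str(ca)), (str(sb), str(cb))
        if key_a == key_b and gene_a == gene_b:
            continue
        if (key_b, int(rb)) < (key_a, int(ra)):
            key_a, key_b = key_b, key_a
            gene_a, gene_b = gene_b, gene_a
            ra, rb = rb, ra
        grouped.setdefault((key_a, key_b), []).append(
            Anchor(gene_a, gene_b, int(ra), int(rb))
        )
    blocks: list[SyntenyBlock] = []
    for (key_a, key_b), group in sorted(grouped.items()):
        blocks.extend(chain_anchors(group, params, key_a, key_b))
    return blocks


# ---------------------------------------------------------------------------
# pair classification (Fig-2-style matrix)
# ---------------------------------------------------------------------------


@dataclass
class SyntenyMatrix:
    species: list[str]
    tandem_counts: dict[str, int]  # diagonal: tandem duplication events
    pair_counts: dict[tuple[str, str], dict[str, int]]  # off-diagonal cells
    syntenic_pairs: list[tuple[str, str]]
    nonsyntenic_pairs: list[tuple[str, str]]
    syntenic_pairs_strict: list[tuple[str, str]] = field(default_factory=list)
    lineages_with_synteny: set[str] = field(default_factory=set)

    @property
    def n_syntenic(self) -> int:
        return len(self.syntenic_pairs)

    @property
    def n_nonsyntenic(self) -> int:
        return len(self.nonsyntenic_pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp in self.species:
            rows.append((sp, sp, "tandem", self.tandem_counts.get(sp, 0)))
        for (sa, sb), cell in sorted(self.pair_counts.items()):
            rows.append((sa, sb, "syntenic", cell["syntenic"]))
            rows.append((sa, sb, "nonsyntenic", cell["nonsyntenic"]))
        return pd.DataFrame(rows, columns=["species_a", "species_b", "kind", "count"])


def classify_pairs(
    partition,
    pairs: pd.DataFrame,
    blocks: list[SyntenyBlock],
    arrays: list[TandemArray],
    loci: pd.DataFrame,
    e_value_max: float = 1e-10,
    span_membership: bool = True,
    window: int = 5,
) -> SyntenyMatrix:
    """Label each interspecific family-homolog pair syntenic or not.

    A pair is syntenic when both genes fall inside one shared collinear
    block: as chained anchors, or (with ``span_membership``, the default)
    at positionally consistent places in the block — within ``window``
    ranks of one of its anchors on both genomes.  Mere co-occurrence
    anywhere inside the block's extent does not qualify: a gene that
    transposed into a collinear segment far from its partner's homologous
    position is not syntenic with it.  The stricter anchors-only labelling
    is reported alongside.
    """
    family = set().union(*(l.members for l in partition.lineages))
    lineage_of = partition.lineage_of()
    info = loci.set_index("gene_id")[["species", "chrom", "rank"]]
    admitted = pairs[pairs["evalue"] <= e_value_max]

    anchor_pairs = {
        frozenset((a.gene_a, a.gene_b)) for b in blocks for a in b.anchors
    }

    def near_block_anchor(
        block: SyntenyBlock, ka: tuple[str, str], ra: int, kb: tuple[str, str], rb: int
    ) -> bool:
        """Both genes within ``window`` ranks of one anchor, consistently."""
        if {block.chrom_a, block.chrom_b} != {ka, kb}:
            return False
        sign = 1 if block.orientation == "same" else -1
        for anchor in block.anchors:
            sides = []
            if ka == block.chrom_a and kb == block.chrom_b:
                sides.append((ra - anchor.rank_a, rb - anchor.rank_b))
            if ka == block.chrom_b and kb == block.chrom_a:
                sides.append((ra - anchor.rank_b, rb - anchor.rank_a))
            for da, db in sides:
                # close to the anchor on both genomes, with displacements
                # that agree under the block's orientation
                if (
                    abs(da) <= window
                    and abs(db) <= window
                    and abs(da - sign * db) <= 2
                ):
                    return True
        return False

    syntenic, nonsyntenic, strict = [], [], []
    lineages_hit: set[str] = set()
    pair_counts: dict[tuple[str, str], dict[str, int]] = {}
    seen: set[frozenset[str]] = set()
    for gene_a, gene_b in admitted[["gene_a", "gene_b"]].itertuples(index=False):
        if gene_a not in family or gene_b not in family:
            continue
        if gene_a not in info.index or gene_b not in info.index:
            log.warning("family pair gene without locus excluded: %s / %s", gene_a, gene_b)
            continue
        key = frozenset((gene_a, gene_b))
        if key in seen:
            continue
        seen.add(key)
        sa, ca, ra = info.loc[gene_a]
        sb, cb, rb = info.loc[gene_b]
        if sa == sb:
            continue  # interspecific pairs only; within-species handled as tandem
        cell_key = tuple(sorted((str(sa), str(sb))))
        cell = pair_counts.setdefault(cell_key, {"syntenic": 0, "nonsyntenic": 0})
        is_anchor = key in anchor_pairs
        is_span = is_anchor
        if not is_span and span_membership:
            ka, kb = (str(sa), str(ca)), (str(sb), str(cb))
            for block in blocks:
                if near_block_anchor(block, ka, int(ra), kb, int(rb)):
                    is_span = True
                    break
        pair = (min(gene_a, gene_b), max(gene_a, gene_b))
        if is_anchor:
            strict.append(pair)
        if is_span:
            syntenic.append(pair)
            cell["syntenic"] += 1
            for g in pair:
                if g in lineage_of:
                    lineages_hit.add(lineage_of[g])
        else:
            nonsyntenic.append(pair)
            cell["nonsyntenic"] += 1

    species = sorted({str(s) for s in info["species"].dropna().unique()})
    tandem_counts: dict[str, int] = {}
    for arr in arrays:
        if set(arr.genes) & family:
            tandem_counts[arr.species] = tandem_counts.get(arr.species, 0) + arr.n_duplications
    return SyntenyMatrix(
        species=species,
        tandem_counts=tandem_counts,
        pair_counts=pair_counts,
        syntenic_pairs=sorted(syntenic),
        nonsyntenic_pairs=sorted(nonsyntenic),
        syntenic_pairs_strict=sorted(strict),
        lineages_with_synteny=lineages_hit,
    )
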