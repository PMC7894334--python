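"""Alignment trimming, conserved-region similarity, protein lengths, Ka/Ks.

Ka/Ks uses Nei–Gojobori (1986) counting: per-codon synonymous site
fractions, pathway-averaged substitution counts for multi-hit codons
(pathways through stop codons excluded when any stop-free pathway exists),
and the Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).
Mutations that would create a stop codon are counted as nonsynonymous in
the site totals, as in the original method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np

GAP_CHARS = frozenset("-.")

_BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}
for _a in _BASES:
    for _b in _BASES:
        for _c in _BASES:
            _CODON_TABLE[_a + _b + _c] = ""
# standard genetic code
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _codon in enumerate(_CODON_TABLE):
    _CODON_TABLE[_codon] = _AA[_i]

STOP = "*"


class SeqStatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# alignment trimming
# ---------------------------------------------------------------------------


@dataclass
class AlignmentBlock:
    ids: list[str]
    rows: list[str]
    column_index: list[int]  # retained column -> original column

    @property
    def n_columns(self) -> int:
        return len(self.column_index)


def trim_columns(alignment: Mapping[str, str], gap_threshold: float = 0.3) -> AlignmentBlock:
    """Keep exactly the columns whose non-gap fraction is >= ``gap_threshold``."""
    if not alignment:
        raise SeqStatsError("empty alignment")
    ids = list(alignment)
    rows = [alignment[i] for i in ids]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise SeqStatsError("alignment rows differ in length")
    arr = np.array([list(r) for r in rows])
    non_gap = ~np.isin(arr, list(GAP_CHARS))
    # boundary semantics: a column with k residues of n rows is kept iff
    # k/n >= threshold; the epsilon guards float rounding at exact ratios
    n = len(rows)
    counts = non_gap.sum(axis=0)
    keep = counts >= gap_threshold * n - 1e-9
    kept_idx = [int(i) for i in np.nonzero(keep)[0]]
    trimmed = ["".join(arr[r, kept_idx]) for r in range(n)]
    return AlignmentBlock(ids=ids, rows=trimmed, column_index=kept_idx)


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


def pairwise_similarity(row_a: str, row_b: str) -> float | None:
    """Percent identity over columns where neither row is gapped.

    Returns ``None`` when no mutually ungapped column exists.
    """
    if len(row_a) != len(row_b):
        raise SeqStatsError("rows differ in length")
    both = [
        (a, b)
        for a, b in zip(row_a, row_b)
        if a not in GAP_CHARS and b not in GAP_CHARS
    ]
    if not both:
        return None
    matches = sum(1 for a, b in both if a == b)
    return 100.0 * matches / len(both)


def lineage_conservation_stats(
    partition,
    alignments: Mapping[str, Mapping[str, str]],
    gap_threshold: float = 0.3,
):
    """Per-lineage conserved-region length and median pairwise similarity.

    ``alignments`` maps lineage id -> (sequence id -> aligned row).  The
    conserved length is the trimmed column count; similarity is the median
    over all unordered member pairs (None for single-member lineages).
    """
    import pandas as pd

    rows = []
    for lin in partition.lineages:
        aln = alignments.get(lin.lineage_id)
        if aln is None:
            continue
        block = trim_columns(aln, gap_threshold)
        sims = [
            s
            for a, b in combinations(range(len(block.rows)), 2)
            if (s := pairwise_similarity(block.rows[a], block.rows[b])) is not None
        ]
        median_sim = float(np.median(sims)) if sims else None
        rows.append((lin.lineage_id, len(block.rows), block.n_columns, median_sim))
    return pd.DataFrame(
        rows, columns=["lineage_id", "n", "conserved_len", "median_similarity"]
    )


# ---------------------------------------------------------------------------
# Ka/Ks (NG86)
# ---------------------------------------------------------------------------


@dataclass
class KaKsResult:
    ka: float | None
    ks: float | None
    ratio: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    flags: list[str] = field(default_factory=list)


def _codons(cds: str, name: str) -> list[str]:
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise SeqStatsError(f"{name}: CDS length {len(seq)} not divisible by 3")
    if any(ch in GAP_CHARS for ch in seq):
        raise SeqStatsError(f"{name}: gapped CDS not allowed")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for idx, codon in enumerate(codons):
        if codon not in _CODON_TABLE:
            raise SeqStatsError(f"{name}: invalid codon {codon!r} at codon index {idx}")
        if _CODON_TABLE[codon] == STOP and idx != len(codons) - 1:
            raise SeqStatsError(f"{name}: internal stop codon at codon index {idx}")
    # a trailing stop codon carries no site information
    if codons and _CODON_TABLE[codons[-1]] == STOP:
        codons = codons[:-1]
    return codons


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon."""
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE[mutant] == _CODON_TABLE[codon] and _CODON_TABLE[mutant] != STOP:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    stop_free = []
    for order in permutations(diff_pos):
        current = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if _CODON_TABLE[nxt] == STOP:
                through_stop = True
            if _CODON_TABLE[nxt] == _CODON_TABLE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        results.append((syn, nonsyn))
        if not through_stop:
            stop_free.append((syn, nonsyn))
    use = stop_free if stop_free else results
    syn = sum(s for s, _ in use) / len(use)
    nonsyn = sum(n for _, n in use) / len(use)
    return syn, nonsyn


def _jukes_cantor(p: float) -> float | None:
    if p < 0:
        return None
    if p >= 0.75:
        return None
    return -0.75 * float(np.log(1.0 - 4.0 * p / 3.0))


def ka_ks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei–Gojobori Ka/Ks for one in-frame, gap-free CDS pair."""
    codons_a = _codons(cds_a, "cds_a")
    codons_b = _codons(cds_b, "cds_b")
    if len(codons_a) != len(codons_b):
        raise SeqStatsError(
            f"CDS lengths differ after frame check: {len(codons_a)} vs {len(codons_b)} codons"
        )
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    flags: list[str] = []
    if S <= 0 or N <= 0:
        return KaKsResult(None, None, None, S, N, Sd, Nd, ["no_sites"])
    ps, pn = Sd / S, Nd / N
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    if ks is None and ps >= 0.75:
        flags.append("ks_saturated")
    if ka is None and pn >= 0.75:
        flags.append("ka_saturated")
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    elif ks is not None and ks == 0:
        flags.append("ks_zero")
    return KaKsResult(ka, ks, ratio, S, N, Sd, Nd, flags)


# ---------------------------------------------------------------------------
# protein length summary
# ---------------------------------------------------------------------------


@dataclass
class LengthSummary:
    n: int
    min: int
    max: int
    median: float
    n_short: int
    short_threshold: int


def length_summary(
    sequences: Mapping[str, str] | Sequence[int], short_threshold: int = 100
) -> LengthSummary:
    """Summarize protein lengths (aa); accepts a FASTA dict or raw lengths.

    Median for even n is the mean of the central pair.
    """
    if isinstance(sequences, Mapping):
        lengths = [len(s.replace("-", "").replace(".", "")) for s in sequences.values()]
    else:
        lengths = [int(x) for x in sequences]
    if not lengths:
        raise SeqStatsError("no sequences to summarize")
    arr = np.array(lengths)
    return LengthSummary(
        n=len(lengths),
        min=int(arr.min()),
        max=int(arr.max()),
        median=float(np.median(arr)),
        n_short=int((arr < short_threshold).sum()),
        short_threshold=short_threshold,
    )
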