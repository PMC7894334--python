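"""Tabular and sequence IO: clade maps, gene loci, homolog pairs, FASTA.

Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at the boundary.  Gene order ("rank") is the 0-based
position of a gene along its chromosome after sorting by start coordinate.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class InputError(ValueError):
    """Malformed tabular/sequence input."""


# ---------------------------------------------------------------------------
# clade map
# ---------------------------------------------------------------------------

DEFAULT_CLADES = ("A", "B", "D", "F")


class CladeMap:
    """Total mapping species id -> clade label over a declared alphabet."""

    def __init__(self, mapping: Mapping[str, str], alphabet: Iterable[str] = DEFAULT_CLADES):
        self.alphabet = tuple(alphabet)
        bad = {s: c for s, c in mapping.items() if c not in self.alphabet}
        if bad:
            raise InputError(f"clade labels outside alphabet {self.alphabet}: {bad}")
        self.mapping = dict(mapping)

    def __getitem__(self, species: str) -> str:
        try:
            return self.mapping[species]
        except KeyError:
            raise InputError(f"species {species!r} missing from clade map") from None

    def __contains__(self, species: str) -> bool:
        return species in self.mapping

    def species_in(self, clade: str) -> list[str]:
        return sorted(s for s, c in self.mapping.items() if c == clade)

    @classmethod
    def from_tsv(cls, path: str | Path, alphabet: Iterable[str] = DEFAULT_CLADES) -> "CladeMap":
        df = pd.read_csv(path, sep="\t")
        if not {"species", "clade"}.issubset(df.columns):
            raise InputError("clade map TSV needs 'species' and 'clade' columns")
        return cls(dict(zip(df["species"], df["clade"])), alphabet)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.mapping.items()), columns=["species", "clade"]
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene loci
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"
    species: str | None = None
    rank: int | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise InputError(f"{self.gene_id}: start {self.start} >= end {self.end}")


LOCUS_COLUMNS = ["gene_id", "species", "chrom", "start", "end", "strand", "rank"]


def loci_frame(loci: Iterable[GeneLocus]) -> pd.DataFrame:
    """Locus table as a DataFrame with per-chromosome ranks assigned."""
    df = pd.DataFrame(
        [(l.gene_id, l.species, l.chrom, l.start, l.end, l.strand, l.rank) for l in loci],
        columns=LOCUS_COLUMNS,
    )
    return assign_ranks(df)


def assign_ranks(df: pd.DataFrame) -> pd.DataFrame:
    """(Re)assign gene order per (species, chromosome) by start coordinate."""
    df = df.sort_values(["species", "chrom", "start", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )
    df["rank"] = df.groupby(["species", "chrom"], dropna=False).cumcount()
    return df


def read_bed(path: str | Path, species: str | None = None) -> pd.DataFrame:
    """BED6 (chrom, start, end, name, score, strand); 0-based half-open."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "gene_id": str},
    )
    out = df[["gene_id", "chrom", "start", "end", "strand"]].copy()
    out["species"] = species
    return assign_ranks(out)


def read_gff3(path: str | Path, species: str | None = None, feature: str = "gene") -> pd.DataFrame:
    """Minimal GFF3 gene reader; converts 1-based inclusive to half-open."""
    rows = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            attrs = dict(
                item.split("=", 1) for item in parts[8].split(";") if "=" in item
            )
            gene_id = attrs.get("ID") or attrs.get("Name")
            if gene_id is None:
                raise InputError(f"GFF3 {feature} record without ID attribute: {line!r}")
            rows.append((gene_id, parts[0], int(parts[3]) - 1, int(parts[4]), parts[6]))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    df["species"] = species
    return assign_ranks(df)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["score"] = 0
    out[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# homolog pairs (BLAST tabular, outfmt 6)
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ["gene_a", "gene_b", "evalue"]


def read_blast_pairs(path: str | Path) -> pd.DataFrame:
    """BLAST outfmt-6 table; only query/subject ids and the E-value are kept."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise InputError("homolog pair table needs at least 3 columns")
    evalue_col = 10 if df.shape[1] >= 11 else df.shape[1] - 1
    out = df[[0, 1, evalue_col]].copy()
    out.columns = PAIR_COLUMNS
    out["evalue"] = out["evalue"].astype(float)
    if (out["evalue"] < 0).any():
        raise InputError("negative E-values in homolog pair table")
    return out


def write_pairs(df: pd.DataFrame, path: str | Path) -> None:
    df[PAIR_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def filter_pairs(pairs: pd.DataFrame, e_value_max: float) -> pd.DataFrame:
    """Admit pairs at the E-value cutoff and drop self hits / duplicates.

    Pairs are unordered: (a, b) and (b, a) collapse to one row.
    """
    kept = pairs[(pairs["evalue"] <= e_value_max) & (pairs["gene_a"] != pairs["gene_b"])].copy()
    lo = kept[["gene_a", "gene_b"]].min(axis=1)
    hi = kept[["gene_a", "gene_b"]].max(axis=1)
    kept["gene_a"], kept["gene_b"] = lo, hi
    kept = kept.sort_values("evalue", kind="mergesort").drop_duplicates(["gene_a", "gene_b"])
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InputError(f"no sequences in FASTA {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def fasta_text(sequences: Mapping[str, str]) -> str:
    buf = _io.StringIO()
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()
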