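"""End-to-end orchestration: delineate -> reconcile -> synteny -> seqstats.

A single config (dict or YAML) names either real inputs (tree, clade map,
loci, pairs, FASTA) or a ``simulation`` block; every under-specified
constant of the analysis (support threshold, tandem adjacency bound,
support-absent policy, gap threshold, Ka/Ks species pair) surfaces in the
config and is echoed into the report so runs are auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .io import CladeMap, read_bed, read_blast_pairs, read_fasta
from .lineages import delineate_lineages
from .reconcile import tally_gains_losses
from .seqstats import ka_ks, length_summary, lineage_conservation_stats, trim_columns
from .simulate import SimConfig, simulate_family
from .synteny import (
    ChainParams,
    classify_pairs,
    detect_tandem_arrays,
    find_synteny_blocks,
    tandem_duplication_count,
)
from .trees import read_gene_tree, read_species_tree


@dataclass
class RunReport:
    version: str
    config_hash: str
    seed: int | None
    constants: dict[str, Any]
    lineage_count: int | None = None
    ingroup_lineage_count: int | None = None
    gains: int | None = None
    gains_pooled: int | None = None
    losses: int | None = None
    tandem_arrays: int | None = None
    tandem_duplications: int | None = None
    syntenic_pairs: int | None = None
    nonsyntenic_pairs: int | None = None
    lineages_with_synteny: int | None = None
    length_summary: dict[str, Any] | None = None
    conserved_length_range: list[int] | None = None
    median_similarity_range: list[float] | None = None
    median_kaks: float | None = None
    n_kaks_pairs: int | None = None
    failed_stage: str | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        from dataclasses import asdict

        return json.dumps(asdict(self), indent=1, default=str)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_inputs(config: dict) -> dict[str, Any]:
    """Materialize stage inputs from a simulation block or from files."""
    if "simulation" in config:
        sim_kwargs = dict(config["simulation"] or {})
        if "seed" in config and "seed" not in sim_kwargs:
            sim_kwargs["seed"] = config["seed"]
        family = simulate_family(SimConfig(**sim_kwargs))
        return {
            "gene_tree": family.gene_tree,
            "species_tree": family.species_tree,
            "clade_map": family.clade_map,
            "loci": family.loci,
            "pairs": family.pairs,
            "proteins": family.proteins,
            "cds": family.cds,
            "family": family,
        }
    inputs = config.get("inputs")
    if not inputs:
        raise ValueError("config needs either a 'simulation' or an 'inputs' block")
    for key in ("gene_tree", "species_tree", "clades"):
        if key not in inputs:
            raise FileNotFoundError(f"config inputs missing required entry {key!r}")
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(f"input file not found: {inputs[key]}")
    out: dict[str, Any] = {
        "gene_tree": read_gene_tree(Path(inputs["gene_tree"]).read_text()),
        "species_tree": read_species_tree(Path(inputs["species_tree"]).read_text()),
        "clade_map": CladeMap.from_tsv(inputs["clades"]),
    }
    if "loci" in inputs:
        out["loci"] = read_bed(inputs["loci"])
    if "pairs" in inputs:
        out["pairs"] = read_blast_pairs(inputs["pairs"])
    if "proteins" in inputs:
        out["proteins"] = read_fasta(inputs["proteins"])
    if "cds" in inputs:
        out["cds"] = read_fasta(inputs["cds"])
    return out


def run_all(config: dict, out_dir: str | Path | None = None) -> RunReport:
    """Execute all stages; identical config and seed give identical reports."""
    constants = {
        "support_min": config.get("delineate", {}).get("support_min", 60),
        "outgroup_clade": config.get("delineate", {}).get("outgroup_clade", "F"),
        "support_absent": config.get("delineate", {}).get("support_absent", "fail"),
        "unassigned_policy": config.get("delineate", {}).get(
            "unassigned_policy", "nearest-anchor"
        ),
        "ingroup_ancestor": config.get("reconcile", {}).get("ingroup_ancestor", "LCA_ABD"),
        "max_intervening": config.get("synteny", {}).get("max_intervening", 5),
        "chain_params": config.get("synteny", {}).get("params", {}),
        "gap_threshold": config.get("seqstats", {}).get("gap_threshold", 0.3),
        "short_threshold": config.get("seqstats", {}).get("short_threshold", 100),
        "kaks_species": config.get("seqstats", {}).get("kaks_species"),
        "median_convention": "mean of central pair for even n",
    }
    report = RunReport(
        version=__version__,
        config_hash=_config_hash(config),
        seed=config.get("seed"),
        constants=constants,
    )
    try:
        data = load_inputs(config)
    except Exception as exc:
        report.failed_stage = "inputs"
        report.warnings.append(str(exc))
        return report

    partition = None
    try:
        partition = delineate_lineages(
            data["gene_tree"],
            data["clade_map"],
            support_min=constants["support_min"],
            outgroup_clade=constants["outgroup_clade"],
            support_absent=constants["support_absent"],
            unassigned_policy=constants["unassigned_policy"],
        )
        report.lineage_count = len(partition.lineages)
        report.ingroup_lineage_count = len(partition.ingroup_lineages)
        report.warnings.extend(partition.warnings)
    except Exception as exc:
        report.failed_stage = "delineate"
        report.warnings.append(str(exc))
        return report

    try:
        summary = tally_gains_losses(
            data["gene_tree"],
            data["species_tree"],
            partition,
            data["clade_map"],
            ingroup_ancestor=constants["ingroup_ancestor"],
            clade_ancestors=config.get("reconcile", {}).get("clade_ancestors"),
        )
        report.gains = summary.gains
        report.gains_pooled = summary.gains_pooled
        report.losses = summary.losses
    except Exception as exc:
        report.failed_stage = "reconcile"
        report.warnings.append(str(exc))
        return report

    if "loci" in data and "pairs" in data:
        try:
            params = ChainParams(**constants["chain_params"])
            arrays = detect_tandem_arrays(
                data["loci"],
                data["pairs"],
                max_intervening=constants["max_intervening"],
                e_value_max=params.e_value_max,
            )
            blocks = find_synteny_blocks(data["loci"], data["pairs"], params)
            matrix = classify_pairs(
                partition, data["pairs"], blocks, arrays, data["loci"],
                e_value_max=params.e_value_max,
            )
            family_genes = set().union(*(l.members for l in partition.lineages))
            fam_arrays = [a for a in arrays if set(a.genes) & family_genes]
            report.tandem_arrays = len(fam_arrays)
            report.tandem_duplications = tandem_duplication_count(fam_arrays)
            report.syntenic_pairs = matrix.n_syntenic
            report.nonsyntenic_pairs = matrix.n_nonsyntenic
            report.lineages_with_synteny = len(matrix.lineages_with_synteny)
            if out_dir is not None:
                matrix.to_frame().to_csv(
                    Path(out_dir) / "synteny_matrix.tsv", sep="\t", index=False
                )
        except Exception as exc:
            report.failed_stage = "synteny"
            report.warnings.append(str(exc))
            return report

    if "proteins" in data:
        try:
            summary_len = length_summary(
                data["proteins"], short_threshold=constants["short_threshold"]
            )
            report.length_summary = {
                "n": summary_len.n,
                "min": summary_len.min,
                "max": summary_len.max,
                "median": summary_len.median,
                "n_short": summary_len.n_short,
            }
            alignments = {
                lin.lineage_id: {
                    g: data["proteins"][g] for g in sorted(lin.members) if g in data["proteins"]
                }
                for lin in partition.lineages
            }
            alignments = {k: v for k, v in alignments.items() if v}
            stats = lineage_conservation_stats(
                partition, alignments, gap_threshold=constants["gap_threshold"]
            )
            if len(stats):
                report.conserved_length_range = [
                    int(stats["conserved_len"].min()),
                    int(stats["conserved_len"].max()),
                ]
                sims = stats["median_similarity"].dropna()
                if len(sims):
                    report.median_similarity_range = [
                        round(float(sims.min()), 2),
                        round(float(sims.max()), 2),
                    ]
            if "cds" in data:
                ratios = kaks_species_pairs(
                    partition, data["cds"], data["gene_tree"], constants["kaks_species"]
                )
                if ratios:
                    report.median_kaks = round(float(np.median(ratios)), 4)
                    report.n_kaks_pairs = len(ratios)
            if out_dir is not None:
                stats.to_csv(Path(out_dir) / "lineage_stats.tsv", sep="\t", index=False)
        except Exception as exc:
            report.failed_stage = "seqstats"
            report.warnings.append(str(exc))
            return report

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        partition.to_frame(data["gene_tree"], data["clade_map"]).to_csv(
            out / "lineages.tsv", sep="\t", index=False
        )
    return report


def kaks_species_pairs(partition, cds, gene_tree, species_pair=None) -> list[float]:
    """Ka/Ks ratios for within-lineage interspecific CDS pairs.

    ``species_pair`` restricts to one species pair (the classic congeneric
    comparison); when None, all interspecific within-lineage pairs are used.
    """
    ratios: list[float] = []
    for lin in partition.lineages:
        members = sorted(g for g in lin.members if g in cds)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                sa, sb = gene_tree.species_of(a), gene_tree.species_of(b)
                if sa == sb:
                    continue
                if species_pair is not None and {sa, sb} != set(species_pair):
                    continue
                if len(cds[a]) != len(cds[b]):
                    continue  # unaligned pair; Ka/Ks needs codon alignment
                result = ka_ks(cds[a], cds[b])
                if result.ratio is not None:
                    ratios.append(result.ratio)
    return ratios
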