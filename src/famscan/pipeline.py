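"""Sequential composition of the analysis stages with one reproducible config.

Stage order mirrors how a family survey is run: domain scan -> architecture
calls -> chromosomal mapping and clusters -> duplication inference -> protein
physicochemistry -> expression normalization -> (optional) subgroup
classification and curated-table statistics. Every report carries provenance
(tool version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .classify import assign_subgroup, read_panel
from .domain_scan import call_architecture, default_profiles, scan_sequence
from .duplication import (
    default_candidate_pairs,
    detect_segmental,
    detect_tandem,
    pairwise_similarity,
)
from .expression import expression_summary, fpkm_to_tpm, read_matrix
from .family_table import load_family_table, summary_report
from .genome_map import chromosome_distribution, find_clusters, parse_gff3
from .protparam import PKA_SETS, isoelectric_point, molecular_weight

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Inputs and stage parameters for one pipeline run."""

    gff3: str | Path | None = None
    fasta: str | Path | None = None
    fpkm: str | Path | None = None
    table: str | Path | None = None
    panel: str | Path | None = None
    evalue: float = 1e-3
    dup_window: int = 20
    dup_threshold: int = 5
    min_anchor_score: float = 60.0
    max_intervening: int = 0
    pka_set: str = "bjellqvist"
    calibration_shuffles: int = 1000
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0 < self.evalue <= 1:
            raise PipelineError("evalue must be in (0, 1]")
        if self.dup_threshold < 0 or self.dup_window < self.dup_threshold:
            raise PipelineError("need 0 <= dup_threshold <= dup_window")
        if self.pka_set not in PKA_SETS:
            raise PipelineError(f"unknown pKa set {self.pka_set!r}")

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the config provides inputs for; returns the JSON report."""
    for label in ("gff3", "fasta", "fpkm", "table", "panel"):
        p = getattr(config, label)
        if p is not None and not Path(p).exists():
            raise PipelineError(f"input {label} not found: {p}")

    report: dict = {
        "provenance": {
            "tool": "famscan",
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
        }
    }

    proteins = _read_fasta(Path(config.fasta)) if config.fasta else None
    models = parse_gff3(config.gff3) if config.gff3 else None
    exon_counts = {g.gene_id: g.exon_count for g in models} if models else {}

    family_ids: list[str] = []
    if proteins is not None:
        profiles = default_profiles(
            n_shuffles=config.calibration_shuffles, seed=config.seed
        )
        n_db = len(proteins)
        calls = {}
        hits_per_protein = {}
        for pid in sorted(proteins):
            hits = []
            for prof in profiles.values():
                hits.extend(
                    scan_sequence(
                        prof,
                        proteins[pid],
                        protein_id=pid,
                        evalue=config.evalue,
                        database_size=n_db,
                    )
                )
            hits_per_protein[pid] = hits
            calls[pid] = call_architecture(
                hits, exon_counts.get(pid, 1), protein_id=pid
            )
        family_ids = sorted(
            pid for pid, c in calls.items() if c.type_call in ("TypeI", "TypeII")
        )
        report["scan"] = {
            "n_proteins": n_db,
            "n_family": len(family_ids),
            "n_typeI": sum(1 for c in calls.values() if c.type_call == "TypeI"),
            "n_typeII": sum(1 for c in calls.values() if c.type_call == "TypeII"),
            "n_reannotation_flags": sum(
                1 for c in calls.values() if c.reannotation_flag
            ),
        }

    if models is not None and family_ids:
        dist = chromosome_distribution(models, family_ids)
        clusters = find_clusters(models, family_ids, config.max_intervening)
        report["map"] = {
            "chromosome_distribution": dist,
            "n_clusters": len(clusters),
            "cluster_sizes": sorted(len(c.member_ids) for c in clusters),
        }

    if models is not None and proteins is not None and len(family_ids) >= 2:
        sim = pairwise_similarity(proteins)
        tandem = detect_tandem(models, family_ids, sim)
        candidates = default_candidate_pairs(family_ids, sim)
        segmental = detect_segmental(
            models,
            candidates,
            sim,
            window=config.dup_window,
            threshold=config.dup_threshold,
            min_anchor_score=config.min_anchor_score,
        )
        report["duplication"] = {
            "n_tandem_pairs": len(tandem),
            "n_segmental": len(segmental),
            "n_segmental_intra": sum(1 for e in segmental if e.locality == "intra"),
            "n_segmental_inter": sum(1 for e in segmental if e.locality == "inter"),
            "anchor_supports": sorted(e.anchor_support for e in segmental),
        }

    if proteins is not None and family_ids:
        pka = PKA_SETS[config.pka_set]
        props = {
            pid: {
                "length": len(proteins[pid]),
                "mw_da": molecular_weight(proteins[pid]),
                "pI": isoelectric_point(proteins[pid], pka),
            }
            for pid in family_ids
        }
        report["protparam"] = {
            "mean_pI": sum(p["pI"] for p in props.values()) / len(props),
            "mean_mw_da": sum(p["mw_da"] for p in props.values()) / len(props),
            "n": len(props),
        }

    if config.fpkm:
        tpm = fpkm_to_tpm(read_matrix(config.fpkm, unit="FPKM"))
        report["expression"] = {
            "samples": tpm.samples,
            "column_sums": [float(s) for s in tpm.values.sum(axis=0)],
        }
        if family_ids:
            in_matrix = [g for g in family_ids if g in tpm.genes]
            if in_matrix:
                summ = expression_summary(tpm, {"family": in_matrix})
                report["expression"]["top_gene"] = summ["top_gene"]

    if config.panel and proteins is not None and family_ids:
        panel = read_panel(config.panel)
        assignments = assign_subgroup(
            {pid: proteins[pid] for pid in family_ids}, panel
        )
        report["classify"] = {
            "labels": {a.query_id: a.label for a in assignments},
        }

    if config.table:
        report["table_stats"] = summary_report(load_family_table(config.table))

    return report
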