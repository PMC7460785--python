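"""End-to-end orchestration: scan -> confirm -> classify -> annotate ->
genome context -> physchem -> expression, with a JSON-able run manifest.

Stages whose inputs are absent are skipped and noted in the manifest.
Everything is deterministic for fixed inputs and configuration; the
manifest carries the thresholds, counts and seed so two runs on the same
inputs are comparable field by field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from zfpkit._version import __version__
from zfpkit.seq_io import read_proteome, read_gene_order, write_annotations, ProteinRecord
from zfpkit.motif_scan import scan_c2h2, scan_ear, attach_confirmation
from zfpkit.motif_classify import ClassifierRules, classify_all, default_rules, load_rules
from zfpkit.family_annotate import classify_architecture, family_summary
from zfpkit.genome_context import (
    chromosome_distribution,
    find_local_duplications,
    load_wgd_pairs,
)
from zfpkit.physchem import physchem_table
from zfpkit.expression import (
    abundance_tiers,
    collapse_probesets,
    log2_matrix,
    read_expression_tsv,
    read_gene_map,
    tissue_induction,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    proteome: Path
    out_dir: Path
    gene_order: Optional[Path] = None
    expression: Optional[Path] = None
    gene_map: Optional[Path] = None
    rules: Optional[Path] = None
    keep_drop: Optional[Path] = None
    wgd_pairs: Optional[Path] = None
    append_records: list[Path] = field(default_factory=list)
    scan_mode: str = "published"
    variant_policy: str = "longest_per_gene"
    tandem_max_linker: int = 11
    duplication_window: int = 100
    induction_fold: float = 2.0
    induction_tissues: list[str] = field(default_factory=lambda: ["nodule"])
    tiers_k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tandem_max_linker", "duplication_window", "induction_fold", "tiers_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _read_keep_drop(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            out[parts[0]] = parts[1] if len(parts) > 1 else "keep"
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage and return (and write) the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rules: ClassifierRules = load_rules(config.rules) if config.rules else default_rules()

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "scan_mode": config.scan_mode,
        "thresholds": {
            "tandem_max_linker": config.tandem_max_linker,
            "duplication_window": config.duplication_window,
            "induction_fold": config.induction_fold,
            "tiers_k": config.tiers_k,
        },
        "stages": {},
    }

    # --- scan ---
    records = read_proteome(config.proteome, variant_policy=config.variant_policy)
    by_id = {r.id: r for r in records}
    calls = {}
    for rec in records:
        motifs = scan_c2h2(rec, mode=config.scan_mode)
        if motifs:
            calls[rec.id] = motifs
    manifest["stages"]["scan"] = {
        "proteins_scanned": len(records),
        "candidates": len(calls),
        "candidate_motifs": int(sum(len(m) for m in calls.values())),
    }

    # --- confirmation filter ---
    keep_drop = _read_keep_drop(config.keep_drop) if config.keep_drop else None
    confirmed, n_dropped = attach_confirmation(calls, keep_drop)
    manifest["stages"]["confirm"] = {
        "dropped": n_dropped,
        "confirmed": len(confirmed),
    }

    # --- appended records (family members recovered outside the proteome) ---
    for extra_path in config.append_records:
        for rec in read_proteome(extra_path, variant_policy="all"):
            motifs = scan_c2h2(rec, mode=config.scan_mode)
            if motifs:
                confirmed[rec.id] = motifs
                by_id[rec.id] = rec
    manifest["stages"]["family"] = {
        "zfps": len(confirmed),
        "motifs": int(sum(len(m) for m in confirmed.values())),
    }

    # --- classify ---
    all_motifs = [m for ms in confirmed.values() for m in ms]
    gene_of = {pid: by_id[pid].gene_id for pid in confirmed}
    typed, summary = classify_all(all_motifs, rules, gene_of=gene_of)
    typed_by_protein: dict[str, list] = {}
    for m in typed:
        typed_by_protein.setdefault(m.protein_id, []).append(m)
    manifest["stages"]["classify"] = {
        "type_counts": summary.type_counts,
        "subgroup_counts": summary.subgroup_counts,
        "gene_counts": summary.gene_counts,
        "total_motifs": summary.total,
    }
    pd.DataFrame(
        summary.to_rows(), columns=["mtype", "subgroup", "motifs", "genes"]
    ).to_csv(out_dir / "classification.tsv", sep="\t", index=False)

    # --- annotate ---
    annotations = []
    for pid in sorted(typed_by_protein):
        rec = by_id[pid]
        annotations.append(
            classify_architecture(
                pid,
                len(rec),
                typed_by_protein[pid],
                scan_ear(rec),
                tandem_threshold=config.tandem_max_linker,
            )
        )
    fam = family_summary(annotations)
    write_annotations(annotations, out_dir)
    manifest["stages"]["annotate"] = {
        "count_classes": fam.count_class_counts,
        "single_ear_classes": fam.single_ear_counts,
        "single_arrangements": fam.single_arrangements,
        "multi_tandem": fam.multi_tandem,
        "multi_no_tandem": fam.multi_no_tandem,
        "fraction_single": round(fam.fraction_single, 4),
    }

    family_ids = sorted(confirmed)
    ann_by_id = {a.protein_id: a for a in annotations}

    # --- genome context ---
    if config.gene_order is not None:
        index, _ = read_gene_order(config.gene_order)
        present = [g for g in family_ids if g in index]
        dist = chromosome_distribution(index, present)
        dist.to_csv(out_dir / "chromosome_distribution.tsv", sep="\t")
        clusters = find_local_duplications(index, present, window=config.duplication_window)
        with open(out_dir / "local_duplications.tsv", "w") as fh:
            fh.write("chromosome\tsize\tmembers\n")
            for c in clusters:
                fh.write(f"{c.chromosome}\t{c.size}\t{','.join(c.members)}\n")
        stage = {
            "genes_placed": len(present),
            "per_chromosome": {c: int(n) for c, n in dist["count"].items()},
            "local_duplication_clusters": len(clusters),
            "cluster_sizes": sorted((c.size for c in clusters), reverse=True),
        }
        if config.wgd_pairs is not None:
            pairs = load_wgd_pairs(config.wgd_pairs, family_ids, ann_by_id)
            stage["wgd_pairs"] = len(pairs)
            stage["wgd_concordant"] = sum(1 for p in pairs if p.concordant)
        manifest["stages"]["genome"] = stage
    else:
        manifest["stages"]["genome"] = "skipped (no gene order input)"

    # --- physchem ---
    fam_records = [by_id[pid] for pid in family_ids]
    table = physchem_table(fam_records)
    table.to_csv(out_dir / "physchem.tsv", sep="\t", index=False)
    manifest["stages"]["physchem"] = {
        "proteins": len(table),
        "mw_kda_range": [float(table["mw_kda"].min()), float(table["mw_kda"].max())],
        "pi_range": [float(table["pi"].min()), float(table["pi"].max())],
    }

    # --- expression ---
    if config.expression is not None and config.gene_map is not None:
        matrix = read_expression_tsv(config.expression)
        gene_map = read_gene_map(config.gene_map)
        fam_map = {p: g for p, g in gene_map.items() if g in set(family_ids)}
        gene_matrix = collapse_probesets(matrix, fam_map)
        tiers, cuts = abundance_tiers(log2_matrix(gene_matrix), k=config.tiers_k)
        induction = tissue_induction(
            gene_matrix, config.induction_tissues, fold=config.induction_fold
        )
        tiers.to_frame().join(induction).to_csv(out_dir / "expression_tiers.tsv", sep="\t")
        manifest["stages"]["expression"] = {
            "mapped_genes": len(gene_matrix),
            "tier_counts": tiers.value_counts().to_dict(),
            "tier_cuts": [round(c, 3) for c in cuts],
            "induced": int(induction["flagged"].sum()),
        }
    else:
        manifest["stages"]["expression"] = "skipped (no expression input)"

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
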