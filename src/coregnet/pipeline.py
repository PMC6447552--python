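"""End-to-end pipeline: filter targets → find motifs → test significance
→ build network → select hubs, with a machine-readable run report.

Each stage writes its outputs under ``out_dir`` so a run can be resumed
or inspected stage by stage; the report records counts, thresholds and
the seed, making results self-describing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .curation import TargetList, evidence_summary, intersect_with_upregulated
from .motifs import MotifClass, find_fbls, find_ffls
from .network import build_coregulatory_network, select_hubs
from .regdata import (
    RegulationTable,
    RegulatorClass,
    RegulatoryInteraction,
    export_fanmod_edgelist,
    export_graph,
    read_regulation_table,
)
from .significance import FFL_TRIAD, NullModelConfig, test_motif_enrichment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    table_path: str | Path = ""
    upregulated_path: str | Path | None = None
    out_dir: str | Path = "coregnet-out"
    null_model: NullModelConfig = field(default_factory=NullModelConfig)
    run_significance: bool = True
    include_tf_ffls: bool = False
    include_composite_ffls: bool = False
    per_class_mean: bool = False
    hub_in_degree: int = 10
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        nm = raw.pop("null_model", {})
        cfg = cls(**raw)
        if isinstance(nm, dict):
            cfg.null_model = NullModelConfig(**nm)
        return cfg


def _filter_table(table: RegulationTable, upregulated: set[str]) -> RegulationTable:
    """Drop miRNA→gene interactions whose gene is not up-regulated.

    miRNA→TF, TF→miRNA and TF→gene edges pass through: the expression
    filter applies to the miRNA target-gene list, not to the TF layer.
    """
    from .regdata import TargetClass

    kept: list[RegulatoryInteraction] = []
    for ix in table.interactions:
        if (
            ix.regulator_class is RegulatorClass.MIRNA
            and ix.target_class is TargetClass.GENE
            and ix.target_id not in upregulated
        ):
            continue
        kept.append(ix)
    return RegulationTable(kept, dedupe=True)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and return (and write) the run report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "version": __version__, "stages": {}}

    table = read_regulation_table(cfg.table_path)
    report["stages"]["input"] = {
        "n_interactions": len(table),
        "n_duplicates_dropped": table.n_duplicates_dropped,
    }

    # --- stage 1: expression filter
    if cfg.upregulated_path is not None:
        upregulated = {
            line.strip()
            for line in Path(cfg.upregulated_path).read_text().splitlines()
            if line.strip()
        }
        targets = TargetList.from_regulation_table(table)
        kept = intersect_with_upregulated(targets, upregulated)
        table = _filter_table(table, upregulated | kept.target_ids)
        stage = {
            "n_upregulated": len(upregulated),
            "n_targets_kept": len(kept),
            "n_interactions_after": len(table),
        }
        if kept.target_ids:
            stage["evidence"] = evidence_summary(kept)
        report["stages"]["filter_targets"] = stage

    # --- stage 2: motifs
    ffls = find_ffls(table)
    fbls = find_fbls(table)
    report["stages"]["find_motifs"] = {
        **ffls.counts,
        "FBL": fbls.counts["FBL"],
        "FBL_pure": fbls.n_fbl_pure,
        "FFL_total": ffls.n_ffl_total,
    }

    # --- stage 3: network (miRNA-FFLs + FBLs by default)
    sets = [MotifClass.MIRNA_FFL]
    if cfg.include_tf_ffls:
        sets.append(MotifClass.TF_FFL)
    if cfg.include_composite_ffls:
        sets.append(MotifClass.COMPOSITE_FFL)
    chosen = [i for i in ffls if i.motif_class in sets]
    network = build_coregulatory_network(chosen, list(fbls))
    report["stages"]["build_network"] = {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "merged_classes": [c.value for c in sets] + ["FBL"],
    }
    if network.n_edges:
        export_graph(network, "GraphML", out / "network.graphml")
        export_graph(network, "SIF", out / "network.sif")
        export_fanmod_edgelist(network, out / "network_fanmod.txt")

    # --- stage 4: significance
    if cfg.run_significance and network.n_edges >= 2:
        res = test_motif_enrichment(network, FFL_TRIAD, cfg.null_model)
        report["stages"]["significance"] = res.to_dict()

    # --- stage 5: hubs
    if network.n_nodes:
        hubs = select_hubs(
            network,
            per_class_mean=cfg.per_class_mean,
            in_degree_threshold=cfg.hub_in_degree,
        )
        report["stages"]["find_hubs"] = {
            "hub_mirnas": hubs.hub_mirnas,
            "hub_tfs": hubs.hub_tfs,
            "hub_genes": hubs.hub_genes,
            "regulator_mean_degree": hubs.regulator_mean_degree,
            "in_degree_threshold": cfg.hub_in_degree,
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
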