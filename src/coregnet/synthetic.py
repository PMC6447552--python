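"""Synthetic regulation tables with known ground truth.

Emulates a curated miRNA/TF/gene regulatory universe at the scale of a
typical cancer-stem-cell study — a few dozen regulators, one to two
hundred target genes — with sparse directed background edges of the four
regulation types (miRNA→TF, miRNA→gene, TF→miRNA, TF→gene) and,
optionally, planted motif instances whose counts are known exactly.

With ``disjoint_planting`` each planted feed-forward loop consumes three
fresh nodes (miRNA, TF, gene) and each feedback loop two, and background
edges are drawn only among non-planted nodes, so no accidental motif
touches a planted node and the planted counts are exact.  Without it,
planted counts are lower bounds.

Edge effects follow the regulatory convention: miRNA edges are emitted as
repression, TF edges as unspecified.  Evidence labels are Bernoulli
draws; the default fraction of validated interactions (0.16) matches the
validated/predicted split typical of merged prediction+curation target
lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import MotifClass, MotifInstance
from .regdata import (
    Effect,
    Evidence,
    RegulationTable,
    RegulatorClass,
    RegulatoryInteraction,
    TargetClass,
)

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "generate_expression_labels"]

DEFAULT_EDGE_PROB = {
    "miRNA->TF": 0.05,
    "miRNA->gene": 0.04,
    "TF->miRNA": 0.03,
    "TF->gene": 0.03,
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic regulatory universe.

    Defaults mirror the curated input scale of a hepatic cancer-stem-cell
    study: 15 miRNAs, 32 TFs and 157 target genes.
    """

    n_mirna: int = 15
    n_tf: int = 32
    n_gene: int = 157
    edge_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_PROB)
    )
    planted: dict[str, int] = field(default_factory=dict)
    disjoint_planting: bool = True
    frac_validated: float = 0.16
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirna, self.n_tf, self.n_gene) < 0:
            raise ValueError("node counts must be non-negative")
        for k, p in self.edge_prob.items():
            if k not in DEFAULT_EDGE_PROB:
                raise ValueError(f"unknown edge type {k!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge_prob[{k!r}]={p} outside [0,1]")
        if not 0.0 <= self.frac_validated <= 1.0:
            raise ValueError("frac_validated outside [0,1]")
        for k, c in self.planted.items():
            MotifClass(k)  # raises on unknown class
            if c < 0:
                raise ValueError("planted counts must be non-negative")
        if self.disjoint_planting:
            need = self.planted_node_budget()
            have = {"miRNA": self.n_mirna, "TF": self.n_tf, "gene": self.n_gene}
            for role, cnt in need.items():
                if cnt > have[role]:
                    raise ValueError(
                        f"disjoint planting needs {cnt} {role} nodes, "
                        f"spec provides {have[role]}"
                    )

    def planted_node_budget(self) -> dict[str, int]:
        ffl_classes = (
            MotifClass.MIRNA_FFL.value,
            MotifClass.TF_FFL.value,
            MotifClass.COMPOSITE_FFL.value,
        )
        n_ffl = sum(self.planted.get(c, 0) for c in ffl_classes)
        n_fbl = self.planted.get(MotifClass.FBL.value, 0)
        return {"miRNA": n_ffl + n_fbl, "TF": n_ffl + n_fbl, "gene": n_ffl}


@dataclass
class GroundTruth:
    planted_instances: list[MotifInstance] = field(default_factory=list)
    upregulated_genes: set[str] = field(default_factory=set)
    decoy_genes: set[str] = field(default_factory=set)


def _mk_interaction(src: str, tgt: str, src_cls: RegulatorClass,
                    tgt_cls: TargetClass, validated: bool) -> RegulatoryInteraction:
    return RegulatoryInteraction(
        regulator_id=src,
        regulator_class=src_cls,
        target_id=tgt,
        target_class=tgt_cls,
        effect=Effect.REPRESSION
        if src_cls is RegulatorClass.MIRNA
        else Effect.UNSPECIFIED,
        evidence=Evidence.VALIDATED if validated else Evidence.PREDICTED,
        source="synthetic",
    )


def generate(spec: SyntheticSpec) -> tuple[RegulationTable, GroundTruth]:
    """Draw one regulation table (deterministic for a fixed seed)."""
    rng = np.random.default_rng(spec.seed)
    mirnas = [f"miR-{i:03d}" for i in range(1, spec.n_mirna + 1)]
    tfs = [f"TF-{i:03d}" for i in range(1, spec.n_tf + 1)]
    genes = [f"G-{i:04d}" for i in range(1, spec.n_gene + 1)]

    interactions: list[RegulatoryInteraction] = []
    truth = GroundTruth()

    def val() -> bool:
        return bool(rng.random() < spec.frac_validated)

    # --- planting: consume fresh nodes from the front of each pool
    next_m = next_t = next_g = 0
    planted_nodes: set[str] = set()

    def take(pool: list[str], cursor: int, role: str) -> tuple[str, int]:
        if cursor >= len(pool):
            raise ValueError(f"planting exhausted the {role} node pool")
        node = pool[cursor]
        planted_nodes.add(node)
        return node, cursor + 1

    plant_order = (
        MotifClass.MIRNA_FFL,
        MotifClass.TF_FFL,
        MotifClass.COMPOSITE_FFL,
        MotifClass.FBL,
    )
    for cls in plant_order:
        for _ in range(spec.planted.get(cls.value, 0)):
            m, next_m = take(mirnas, next_m, "miRNA")
            t, next_t = take(tfs, next_t, "TF")
            edges: list[RegulatoryInteraction] = []
            if cls is MotifClass.FBL:
                g = None
            else:
                g, next_g = take(genes, next_g, "gene")
                edges.append(
                    _mk_interaction(m, g, RegulatorClass.MIRNA, TargetClass.GENE, val())
                )
                edges.append(
                    _mk_interaction(t, g, RegulatorClass.TF, TargetClass.GENE, val())
                )
            if cls in (MotifClass.MIRNA_FFL, MotifClass.COMPOSITE_FFL, MotifClass.FBL):
                edges.append(
                    _mk_interaction(m, t, RegulatorClass.MIRNA, TargetClass.TF, val())
                )
            if cls in (MotifClass.TF_FFL, MotifClass.COMPOSITE_FFL, MotifClass.FBL):
                edges.append(
                    _mk_interaction(t, m, RegulatorClass.TF, TargetClass.MIRNA, val())
                )
            interactions.extend(edges)
            truth.planted_instances.append(
                MotifInstance(
                    motif_class=cls,
                    mirna_id=m,
                    tf_id=t,
                    target_id=g,
                    edges=tuple(
                        (e.regulator_id, e.target_id, e.regulator_class)
                        for e in edges
                    ),
                    target_roles=frozenset({"gene"}) if g else frozenset(),
                    composite_overlap=False,
                )
            )

    # --- background edges (Bernoulli per ordered pair, per layer)
    if spec.disjoint_planting:
        bg_m = [v for v in mirnas if v not in planted_nodes]
        bg_t = [v for v in tfs if v not in planted_nodes]
        bg_g = [v for v in genes if v not in planted_nodes]
    else:
        bg_m, bg_t, bg_g = mirnas, tfs, genes

    existing = {(ix.regulator_id, ix.target_id) for ix in interactions}
    layers = (
        ("miRNA->TF", bg_m, bg_t, RegulatorClass.MIRNA, TargetClass.TF),
        ("miRNA->gene", bg_m, bg_g, RegulatorClass.MIRNA, TargetClass.GENE),
        ("TF->miRNA", bg_t, bg_m, RegulatorClass.TF, TargetClass.MIRNA),
        ("TF->gene", bg_t, bg_g, RegulatorClass.TF, TargetClass.GENE),
    )
    for key, srcs, tgts, scls, tcls in layers:
        p = spec.edge_prob.get(key, 0.0)
        if p <= 0.0 or not srcs or not tgts:
            continue
        draws = rng.random((len(srcs), len(tgts))) < p
        for i, src in enumerate(srcs):
            for j in np.nonzero(draws[i])[0]:
                tgt = tgts[j]
                if src == tgt or (src, tgt) in existing:
                    continue
                existing.add((src, tgt))
                interactions.append(_mk_interaction(src, tgt, scls, tcls, val()))

    return RegulationTable(interactions, dedupe=True), truth


def generate_expression_labels(
    table: RegulationTable, frac_upregulated: float, seed: int
) -> GroundTruth:
    """Assign each gene-role node an up-regulated or decoy label.

    miRNAs are down-regulated by convention (the study condition the
    curation filter emulates); only gene-role nodes are labelled.
    """
    if not 0.0 <= frac_upregulated <= 1.0:
        raise ValueError("frac_upregulated outside [0,1]")
    if len(table) == 0:
        raise ValueError("cannot label an empty table")
    rng = np.random.default_rng(seed)
    up: set[str] = set()
    decoy: set[str] = set()
    for g in sorted(table.nodes_with_role("gene")):
        (up if rng.random() < frac_upregulated else decoy).add(g)
    return GroundTruth(upregulated_genes=up, decoy_genes=decoy)
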