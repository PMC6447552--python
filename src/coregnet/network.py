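"""Co-regulatory network assembly, degree statistics, hubs and subnetworks.

The co-regulatory network is the union of the supporting edges of a set
of motif instances — by convention the miRNA-headed feed-forward loops
merged with the feedback loops — with duplicate nodes and edges removed.
Hubs are selected by two degree rules:

1. **Regulator hubs** (miRNA and TF nodes): total degree (in + out)
   strictly greater than the arithmetic mean total degree over the
   pooled miRNA+TF node set.
2. **Target-gene hubs**: in-degree of at least 10 *and* the node is a
   common target, i.e. it receives at least one miRNA edge and at least
   one TF edge.

Subnetworks come in two flavours: the induced subgraph on a node set,
and the motif closure of a seed — the union of every motif instance that
touches at least one seed node (the natural shape of a single-regulator
subnetwork).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .motifs import MotifClass, MotifInstance, MotifSet
from .regdata import CoregNetwork, RegulatorClass

__all__ = [
    "DegreeRecord",
    "HubReport",
    "build_coregulatory_network",
    "degree_table",
    "select_hubs",
    "extract_subnetwork",
    "coregulation_in_edges",
]


@dataclass(frozen=True)
class DegreeRecord:
    node_id: str
    roles: frozenset[str]
    in_degree: int
    out_degree: int

    @property
    def total(self) -> int:
        return self.in_degree + self.out_degree


@dataclass
class HubReport:
    hub_mirnas: list[str]
    hub_tfs: list[str]
    hub_genes: list[str]
    regulator_mean_degree: float
    records: dict[str, DegreeRecord] = field(default_factory=dict)

    @property
    def n_regulator_hubs(self) -> int:
        return len(self.hub_mirnas) + len(self.hub_tfs)


def build_coregulatory_network(*motif_sets: MotifSet | Sequence[MotifInstance]
                               ) -> CoregNetwork:
    """Merge motif instances into one deduplicated directed network.

    Typically called with (miRNA-FFLs, FBLs).  The merge is idempotent
    and order-independent up to edge insertion order: supplying the same
    instance twice changes nothing, and node/edge *sets* do not depend on
    argument order.
    """
    net = CoregNetwork()
    for mset in motif_sets:
        for inst in mset:
            net.add_node(inst.mirna_id, {"miRNA"})
            net.add_node(inst.tf_id, {"TF"})
            if inst.target_id is not None:
                net.add_node(inst.target_id,
                             inst.target_roles or {"gene"})
            for s, t, c in inst.edges:
                net.add_edge(s, t, c, provenance=inst)
            if inst not in net.instances:
                net.instances.append(inst)
    return net


def degree_table(network: CoregNetwork) -> list[DegreeRecord]:
    """One degree record per node, over distinct directed edges."""
    indeg = {v: 0 for v in network.nodes}
    outdeg = {v: 0 for v in network.nodes}
    for s, t in network.edge_pairs():
        outdeg[s] += 1
        indeg[t] += 1
    return [
        DegreeRecord(v, network.nodes[v], indeg[v], outdeg[v])
        for v in network.nodes
    ]


def select_hubs(
    network: CoregNetwork,
    *,
    per_class_mean: bool = False,
    in_degree_threshold: int = 10,
) -> HubReport:
    """Apply the two hub rules to a merged co-regulatory network.

    Rule 1 pools miRNA- and TF-role nodes and uses their mean total
    degree as the cut (strict >).  With ``per_class_mean`` each regulator
    class is compared against its own class mean instead.  Rule 2 scans
    gene-role nodes for in-degree >= ``in_degree_threshold`` with at
    least one incoming miRNA edge and one incoming TF edge.
    """
    records = {r.node_id: r for r in degree_table(network)}
    mirna_nodes = sorted(
        v for v, roles in network.nodes.items() if "miRNA" in roles
    )
    tf_nodes = sorted(
        v for v, roles in network.nodes.items() if "TF" in roles
    )
    regulators = sorted(set(mirna_nodes) | set(tf_nodes))
    if not regulators:
        raise ValueError("network has no regulator (miRNA/TF) nodes")

    def mean_of(nodes: Iterable[str]) -> float:
        nodes = list(nodes)
        return sum(records[v].total for v in nodes) / len(nodes)

    pooled_mean = mean_of(regulators)
    if per_class_mean:
        cut = {"miRNA": mean_of(mirna_nodes) if mirna_nodes else 0.0,
               "TF": mean_of(tf_nodes) if tf_nodes else 0.0}
        hub_mirnas = [v for v in mirna_nodes if records[v].total > cut["miRNA"]]
        hub_tfs = [v for v in tf_nodes if records[v].total > cut["TF"]]
    else:
        hub_mirnas = [v for v in mirna_nodes if records[v].total > pooled_mean]
        hub_tfs = [v for v in tf_nodes if records[v].total > pooled_mean]

    in_classes: dict[str, set[RegulatorClass]] = {}
    for s, t, c in network.edges:
        in_classes.setdefault(t, set()).add(c)
    hub_genes = sorted(
        v
        for v, roles in network.nodes.items()
        if "gene" in roles
        and records[v].in_degree >= in_degree_threshold
        and RegulatorClass.MIRNA in in_classes.get(v, ())
        and RegulatorClass.TF in in_classes.get(v, ())
    )
    return HubReport(
        hub_mirnas=hub_mirnas,
        hub_tfs=hub_tfs,
        hub_genes=hub_genes,
        regulator_mean_degree=pooled_mean,
        records=records,
    )


def extract_subnetwork(
    network: CoregNetwork, keep: set[str], mode: str = "induced"
) -> CoregNetwork:
    """Subnetwork on a node set.

    ``induced`` keeps edges with both endpoints in ``keep``;
    ``motif-closure`` rebuilds the union of every motif instance that
    contains at least one node of ``keep`` (seed subnetworks).  Unknown
    ids are dropped.
    """
    known = {v for v in keep if v in network.nodes}
    if mode == "induced":
        sub = CoregNetwork()
        for v in known:
            sub.add_node(v, network.nodes[v])
        for s, t, c in network.edges:
            if s in known and t in known:
                sub.add_edge(s, t, c)
        return sub
    if mode == "motif-closure":
        hit = [
            inst for inst in network.instances
            if known.intersection(inst.node_ids)
        ]
        return build_coregulatory_network(hit)
    raise ValueError(f"unknown mode {mode!r} (use 'induced' or 'motif-closure')")


def coregulation_in_edges(
    network: CoregNetwork, motifs: MotifSet
) -> list[tuple[str, int]]:
    """Rank joint targets by how many FFL instances they close.

    A target's score is the number of FFL instances (any class) in which
    it is the joint target — the count of its incoming miRNA–TF common
    edge pairs.  Descending score, ties broken by id.
    """
    scores: dict[str, int] = {}
    for inst in motifs:
        if inst.motif_class is MotifClass.FBL or inst.target_id is None:
            continue
        scores[inst.target_id] = scores.get(inst.target_id, 0) + 1
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
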