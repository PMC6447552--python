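"""Domain types and I/O for typed regulatory-interaction tables and networks.

The pipeline's primary input is a flat table of directed regulatory
interactions: a miRNA or transcription factor (TF) regulator, a target
(gene, TF, or miRNA), the direction of the effect, and an evidence label
(experimentally validated vs computationally predicted).  A node may hold
several roles at once — e.g. a TF that is itself a miRNA target — and is
always represented as a single node carrying a role set.

Exports cover the formats downstream viewers and motif tools consume:
SIF and GraphML for Cytoscape-style viewers, plain TSV edge lists, and
the integer edge list ("1<TAB>2" per line) that FANMOD-style motif
detectors read, with a sidecar file mapping integers back to node ids.
"""

from __future__ import annotations

import csv
import enum
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatorClass",
    "TargetClass",
    "Effect",
    "Evidence",
    "RegulatoryInteraction",
    "RegulationTable",
    "CoregNetwork",
    "TableFormatError",
    "read_regulation_table",
    "write_regulation_table",
    "export_fanmod_edgelist",
    "export_graph",
]

COLUMNS = (
    "regulator_id",
    "regulator_class",
    "target_id",
    "target_class",
    "effect",
    "evidence",
    "source",
)


class RegulatorClass(str, enum.Enum):
    MIRNA = "miRNA"
    TF = "TF"


class TargetClass(str, enum.Enum):
    MIRNA = "miRNA"
    TF = "TF"
    GENE = "gene"


class Effect(str, enum.Enum):
    REPRESSION = "repression"
    ACTIVATION = "activation"
    UNSPECIFIED = "unspecified"


class Evidence(str, enum.Enum):
    VALIDATED = "validated"
    PREDICTED = "predicted"


class TableFormatError(ValueError):
    """A regulation table violates the expected format or its invariants."""


@dataclass(frozen=True, order=True)
class RegulatoryInteraction:
    """One directed, typed regulatory edge.

    Identifiers are whitespace-trimmed but otherwise preserved verbatim:
    curated miRNA/gene symbols must never be silently renamed.
    """

    regulator_id: str
    regulator_class: RegulatorClass
    target_id: str
    target_class: TargetClass
    effect: Effect = Effect.UNSPECIFIED
    evidence: Evidence = Evidence.PREDICTED
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "regulator_id", self.regulator_id.strip())
        object.__setattr__(self, "target_id", self.target_id.strip())
        object.__setattr__(self, "source", self.source.strip())
        if not self.regulator_id or not self.target_id:
            raise TableFormatError("empty regulator or target identifier")
        if self.regulator_id == self.target_id:
            raise TableFormatError(
                f"self-regulation not allowed: {self.regulator_id!r}"
            )
        if (
            self.regulator_class is RegulatorClass.MIRNA
            and self.target_class is TargetClass.MIRNA
        ):
            raise TableFormatError(
                f"a miRNA cannot regulate another miRNA: "
                f"{self.regulator_id!r} -> {self.target_id!r}"
            )

    @property
    def dedup_key(self) -> tuple:
        return (
            self.regulator_id,
            self.target_id,
            self.effect,
            self.evidence,
            self.source,
        )


class RegulationTable:
    """An ordered, duplicate-free collection of regulatory interactions.

    ``node_roles`` maps each node id to the set of roles implied by the
    interactions it takes part in; dual-role nodes (e.g. a miRNA that is
    also a TF target gene) hold one entry with a multi-element role set.
    """

    def __init__(
        self,
        interactions: Iterable[RegulatoryInteraction],
        *,
        dedupe: bool = False,
    ) -> None:
        seen: OrderedDict[tuple, RegulatoryInteraction] = OrderedDict()
        dropped = 0
        for ix in interactions:
            if ix.dedup_key in seen:
                dropped += 1
                if not dedupe:
                    raise TableFormatError(
                        f"duplicate interaction: {ix.regulator_id} -> {ix.target_id}"
                    )
            else:
                seen[ix.dedup_key] = ix
        self.interactions: tuple[RegulatoryInteraction, ...] = tuple(seen.values())
        self.n_duplicates_dropped = dropped
        if dropped:
            logger.info("dropped %d duplicate interaction rows", dropped)

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self):
        return iter(self.interactions)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulationTable):
            return NotImplemented
        return self.interactions == other.interactions

    @property
    def node_roles(self) -> dict[str, frozenset[str]]:
        roles: dict[str, set[str]] = {}
        for ix in self.interactions:
            roles.setdefault(ix.regulator_id, set()).add(ix.regulator_class.value)
            roles.setdefault(ix.target_id, set()).add(ix.target_class.value)
        return {n: frozenset(r) for n, r in roles.items()}

    def edges_by_class(self, cls: RegulatorClass) -> set[tuple[str, str]]:
        """Directed (regulator, target) pairs of edges acted in class ``cls``."""
        return {
            (ix.regulator_id, ix.target_id)
            for ix in self.interactions
            if ix.regulator_class is cls
        }

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, r in self.node_roles.items() if role in r}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (
                ix.regulator_id,
                ix.regulator_class.value,
                ix.target_id,
                ix.target_class.value,
                ix.effect.value,
                ix.evidence.value,
                ix.source,
            )
            for ix in self.interactions
        ]
        return pd.DataFrame(rows, columns=list(COLUMNS))


@dataclass
class CoregNetwork:
    """A merged, deduplicated regulatory network.

    ``edges`` are directed (source, target, regulator_class) triples kept
    in first-insertion order; ``provenance`` records, per edge, the motif
    instances that contributed it, and ``instances`` keeps the motif
    instances themselves so seed subnetworks can be rebuilt later.
    """

    nodes: dict[str, frozenset[str]] = field(default_factory=dict)
    edges: "OrderedDict[tuple[str, str, RegulatorClass], None]" = field(
        default_factory=OrderedDict
    )
    provenance: dict[tuple[str, str, RegulatorClass], list] = field(
        default_factory=dict
    )
    instances: list = field(default_factory=list)

    def add_node(self, node: str, roles: Iterable[str]) -> None:
        self.nodes[node] = frozenset(self.nodes.get(node, frozenset()) | set(roles))

    def add_edge(
        self,
        source: str,
        target: str,
        regulator_class: RegulatorClass,
        provenance=None,
    ) -> None:
        key = (source, target, regulator_class)
        self.edges.setdefault(key, None)
        if provenance is not None:
            self.provenance.setdefault(key, []).append(provenance)
        for endpoint in (source, target):
            self.nodes.setdefault(endpoint, frozenset())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Distinct directed (source, target) pairs, classes collapsed."""
        return len(self.edge_pairs())

    def edge_pairs(self) -> "OrderedDict[tuple[str, str], None]":
        pairs: OrderedDict[tuple[str, str], None] = OrderedDict()
        for s, t, _ in self.edges:
            pairs.setdefault((s, t), None)
        return pairs

    def edge_classes(self) -> dict[tuple[str, str], set[RegulatorClass]]:
        out: dict[tuple[str, str], set[RegulatorClass]] = {}
        for s, t, c in self.edges:
            out.setdefault((s, t), set()).add(c)
        return out

    def to_digraph(self) -> nx.DiGraph:
        """Topology-only view: node roles as attributes, classes collapsed."""
        G = nx.DiGraph()
        for node, roles in self.nodes.items():
            G.add_node(node, roles=",".join(sorted(roles)))
        for (s, t), classes in self.edge_classes().items():
            G.add_edge(s, t, regulator_class=",".join(sorted(c.value for c in classes)))
        return G


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_enum(cls, raw: str, row_no: int, column: str):
    try:
        return cls(raw.strip())
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise TableFormatError(
            f"line {row_no}: invalid {column} {raw!r} (allowed: {allowed})"
        ) from None


def read_regulation_table(
    path: str | Path,
    dialect: str = "tab",
    column_map: Mapping[str, str] | None = None,
    sheet: str | int | None = None,
) -> RegulationTable:
    """Read a regulation table from TSV/CSV (or an XLSX sheet).

    Parameters
    ----------
    path : file path
        Delimited text with a header row, or an ``.xlsx`` workbook.
    dialect : {"tab", "comma"}
        Field delimiter for text files; ignored for XLSX.
    column_map : mapping, optional
        Maps canonical column names (``regulator_id`` ...) to the header
        names actually present in the file, absorbing whatever layout a
        supplementary spreadsheet uses.
    sheet : sheet name or index, optional
        Which worksheet to read from an XLSX workbook.

    Duplicate rows are dropped with a logged count (the resulting table's
    ``n_duplicates_dropped`` records how many).
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        df = pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
    else:
        sep = {"tab": "\t", "comma": ","}.get(dialect)
        if sep is None:
            raise ValueError(f"unknown dialect {dialect!r} (use 'tab' or 'comma')")
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"missing mandatory column(s): {', '.join(missing)}"
        )

    interactions = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rec = dict(zip(df.columns, row))
        interactions.append(
            RegulatoryInteraction(
                regulator_id=str(rec["regulator_id"]),
                regulator_class=_parse_enum(
                    RegulatorClass, str(rec["regulator_class"]), i, "regulator_class"
                ),
                target_id=str(rec["target_id"]),
                target_class=_parse_enum(
                    TargetClass, str(rec["target_class"]), i, "target_class"
                ),
                effect=_parse_enum(Effect, str(rec["effect"]), i, "effect"),
                evidence=_parse_enum(Evidence, str(rec["evidence"]), i, "evidence"),
                source=str(rec["source"]),
            )
        )
    return RegulationTable(interactions, dedupe=True)


def write_regulation_table(
    table: RegulationTable, path: str | Path, dialect: str = "tab"
) -> None:
    """Write a table so that reading it back reproduces it exactly."""
    sep = {"tab": "\t", "comma": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r} (use 'tab' or 'comma')")
    table.to_dataframe().to_csv(path, sep=sep, index=False)


def export_fanmod_edgelist(
    network: CoregNetwork, path: str | Path
) -> dict[str, int]:
    """Write the integer edge list a FANMOD-style motif tool reads.

    One directed edge per line as ``<int><TAB><int>``; integers are
    assigned by first appearance in the network's edge order, starting at
    1 (so the first edge of a 3-node loop becomes ``1<TAB>2``).  The
    id-to-integer mapping is returned and also written to a sidecar TSV
    at ``<path>.map.tsv``.
    """
    pairs = network.edge_pairs()
    if not pairs:
        raise ValueError("cannot export an empty network")
    mapping: dict[str, int] = {}
    lines = []
    for s, t in pairs:
        for node in (s, t):
            if node not in mapping:
                mapping[node] = len(mapping) + 1
        lines.append(f"{mapping[s]}\t{mapping[t]}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    with open(str(path) + ".map.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["node_id", "integer"])
        for node, idx in mapping.items():
            writer.writerow([node, idx])
    return mapping


def _sif_interaction(cls: RegulatorClass) -> str:
    return "miRNA-repression" if cls is RegulatorClass.MIRNA else "TF-regulation"


def export_graph(network: CoregNetwork, format: str, path: str | Path) -> None:
    """Export a network as SIF, GraphML, or a TSV edge list.

    GraphML carries node role sets and edge regulator classes as
    attributes; SIF encodes the regulator class in the interaction-type
    column ("miRNA-repression" / "TF-regulation").
    """
    path = Path(path)
    if format == "SIF":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            for s, t, c in network.edges:
                writer.writerow([s, _sif_interaction(c), t])
    elif format == "GraphML":
        nx.write_graphml(network.to_digraph(), path)
    elif format == "edgelist-TSV":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["source", "target", "regulator_class"])
            for s, t, c in network.edges:
                writer.writerow([s, t, c.value])
    else:
        raise ValueError(
            f"unknown format {format!r} (supported: SIF, GraphML, edgelist-TSV)"
        )
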