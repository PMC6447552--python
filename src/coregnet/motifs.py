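"""Enumeration and classification of miRNA–TF feed-forward and feedback loops.

A feed-forward loop (FFL) is an ordered triple (m, t, g): a miRNA *m*, a
TF *t* and a joint target *g* distinct from both, such that both m→g and
t→g are present.  The class is decided by which regulatory edges link the
miRNA–TF pair:

* **composite-FFL** — both m→t and t→m exist (mutual regulation);
* **miRNA-FFL** — only m→t exists (the miRNA is the master regulator);
* **TF-FFL** — only t→m exists (the TF is the master regulator);
* neither edge → the triple is not a motif.

The three FFL classes therefore partition the set of qualifying triples.
A feedback loop (FBL) is a reciprocal miRNA–TF pair (m→t and t→m) with no
joint-target requirement; each FBL carries a flag marking whether the
pair also heads at least one composite-FFL, since composite loops contain
a reciprocal pair by construction.

Only edge direction and regulator class decide membership — the annotated
effect (repression vs activation) does not, because curated regulation
tables mix annotation vocabularies.  A strict mode requiring miRNA edges
to be repressive is available via ``require_mirna_repression``.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field

from .regdata import Effect, RegulationTable, RegulatorClass

__all__ = ["MotifClass", "MotifInstance", "MotifSet", "find_ffls", "find_fbls",
           "count_seed_motifs"]


class MotifClass(str, enum.Enum):
    MIRNA_FFL = "miRNA-FFL"
    TF_FFL = "TF-FFL"
    COMPOSITE_FFL = "composite-FFL"
    FBL = "FBL"


@dataclass(frozen=True, order=True)
class MotifInstance:
    """One motif occurrence.

    ``edges`` are the supporting (source, target, regulator_class)
    triples: 3 for a plain FFL, 4 for a composite-FFL, 2 for an FBL.
    ``target_id`` is None for FBLs; ``composite_overlap`` is meaningful
    for FBLs only and marks reciprocal pairs that also head at least one
    composite-FFL.
    """

    motif_class: MotifClass
    mirna_id: str
    tf_id: str
    target_id: str | None = None
    edges: tuple = ()
    target_roles: frozenset = frozenset()
    composite_overlap: bool = False

    @property
    def node_ids(self) -> tuple[str, ...]:
        if self.target_id is None:
            return (self.mirna_id, self.tf_id)
        return (self.mirna_id, self.tf_id, self.target_id)


@dataclass
class MotifSet:
    """Motif instances grouped by class, with per-class counts."""

    instances: tuple[MotifInstance, ...] = ()

    def by_class(self, cls: MotifClass) -> tuple[MotifInstance, ...]:
        return tuple(i for i in self.instances if i.motif_class is cls)

    @property
    def counts(self) -> dict[str, int]:
        out = {c.value: 0 for c in MotifClass}
        for i in self.instances:
            out[i.motif_class.value] += 1
        return out

    @property
    def n_ffl_total(self) -> int:
        return sum(
            1 for i in self.instances if i.motif_class is not MotifClass.FBL
        )

    @property
    def n_fbl_pure(self) -> int:
        """FBLs whose miRNA–TF pair heads no composite-FFL."""
        return sum(
            1
            for i in self.instances
            if i.motif_class is MotifClass.FBL and not i.composite_overlap
        )

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)


def _edge_maps(table: RegulationTable, require_mirna_repression: bool):
    mi_targets: dict[str, set[str]] = defaultdict(set)
    tf_targets: dict[str, set[str]] = defaultdict(set)
    for ix in table.interactions:
        if ix.regulator_class is RegulatorClass.MIRNA:
            if require_mirna_repression and ix.effect is not Effect.REPRESSION:
                continue
            mi_targets[ix.regulator_id].add(ix.target_id)
        else:
            tf_targets[ix.regulator_id].add(ix.target_id)
    return mi_targets, tf_targets


def find_ffls(
    table: RegulationTable, *, require_mirna_repression: bool = False
) -> MotifSet:
    """Enumerate every FFL triple, classified exclusively.

    Output is deterministic: instances are sorted by
    (class, miRNA, TF, target).
    """
    mi_targets, tf_targets = _edge_maps(table, require_mirna_repression)
    roles = table.node_roles
    instances: list[MotifInstance] = []
    for m in sorted(mi_targets):
        for t in sorted(tf_targets):
            if m == t:
                continue
            joints = (mi_targets[m] & tf_targets[t]) - {m, t}
            if not joints:
                continue
            m_to_t = t in mi_targets[m]
            t_to_m = m in tf_targets[t]
            if m_to_t and t_to_m:
                cls = MotifClass.COMPOSITE_FFL
                pair_edges = (
                    (m, t, RegulatorClass.MIRNA),
                    (t, m, RegulatorClass.TF),
                )
            elif m_to_t:
                cls = MotifClass.MIRNA_FFL
                pair_edges = ((m, t, RegulatorClass.MIRNA),)
            elif t_to_m:
                cls = MotifClass.TF_FFL
                pair_edges = ((t, m, RegulatorClass.TF),)
            else:
                continue
            for g in sorted(joints):
                instances.append(
                    MotifInstance(
                        motif_class=cls,
                        mirna_id=m,
                        tf_id=t,
                        target_id=g,
                        edges=pair_edges
                        + ((m, g, RegulatorClass.MIRNA), (t, g, RegulatorClass.TF)),
                        target_roles=roles.get(g, frozenset()),
                    )
                )
    instances.sort(key=lambda i: (i.motif_class.value, i.mirna_id, i.tf_id,
                                  i.target_id or ""))
    return MotifSet(tuple(instances))


def find_fbls(
    table: RegulationTable, *, require_mirna_repression: bool = False
) -> MotifSet:
    """Enumerate reciprocal miRNA–TF pairs (feedback loops).

    Each pair is reported once, flagged if it also participates in at
    least one composite-FFL (i.e. the pair co-regulates a joint target).
    """
    mi_targets, tf_targets = _edge_maps(table, require_mirna_repression)
    instances = []
    for m in sorted(mi_targets):
        for t in sorted(mi_targets[m]):
            if m in tf_targets.get(t, ()):  # m->t and t->m both present
                has_joint = bool((mi_targets[m] & tf_targets[t]) - {m, t})
                instances.append(
                    MotifInstance(
                        motif_class=MotifClass.FBL,
                        mirna_id=m,
                        tf_id=t,
                        edges=(
                            (m, t, RegulatorClass.MIRNA),
                            (t, m, RegulatorClass.TF),
                        ),
                        composite_overlap=has_joint,
                    )
                )
    return MotifSet(tuple(instances))


def count_seed_motifs(motifs: MotifSet, seed_a: str, seed_b: str) -> int:
    """Number of miRNA-FFLs headed by the pair (miRNA ``seed_a``, TF ``seed_b``).

    Used to size seed subnetworks, e.g. how many joint targets a single
    miRNA–TF pair co-regulates.
    """
    return sum(
        1
        for i in motifs.instances
        if i.motif_class is MotifClass.MIRNA_FFL
        and i.mirna_id == seed_a
        and i.tf_id == seed_b
    )
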