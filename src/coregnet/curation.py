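"""Curation of miRNA target lists against condition-specific expression.

The curation step keeps, from a merged list of predicted and validated
miRNA targets, only those targets that are up-regulated in the condition
of interest — the rationale being that a down-regulated miRNA releases
its repression, so its genuine targets should rise.  The module also
summarizes the evidence composition (validated vs predicted) of a target
list and identifies the targets that are themselves transcription
factors, which seed the downstream co-regulation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .regdata import Evidence, RegulationTable, RegulatorClass, TargetClass

__all__ = [
    "TargetEntry",
    "TargetList",
    "intersect_with_upregulated",
    "evidence_summary",
    "count_tfs_in_targets",
]


@dataclass(frozen=True, order=True)
class TargetEntry:
    target_id: str
    evidence: Evidence
    source: str = ""


@dataclass
class TargetList:
    """Per-miRNA target collections plus their deduplicated union.

    When the same (miRNA, target) pair carries conflicting evidence
    across sources, the merged view resolves it to the stronger label —
    validated wins by default (``predicted_wins`` inverts this).
    """

    per_mirna: dict[str, list[TargetEntry]] = field(default_factory=dict)
    predicted_wins: bool = False

    @classmethod
    def from_regulation_table(cls, table: RegulationTable) -> "TargetList":
        per: dict[str, list[TargetEntry]] = {}
        for ix in table.interactions:
            if ix.regulator_class is RegulatorClass.MIRNA and ix.target_class in (
                TargetClass.GENE,
                TargetClass.TF,
            ):
                per.setdefault(ix.regulator_id, []).append(
                    TargetEntry(ix.target_id, ix.evidence, ix.source)
                )
        return cls(per_mirna=per)

    @property
    def merged(self) -> dict[str, Evidence]:
        """Deduplicated union of all targets with conflict-resolved evidence."""
        strong = Evidence.PREDICTED if self.predicted_wins else Evidence.VALIDATED
        out: dict[str, Evidence] = {}
        for entries in self.per_mirna.values():
            for e in entries:
                prev = out.get(e.target_id)
                if prev is None:
                    out[e.target_id] = e.evidence
                elif prev is not e.evidence:
                    out[e.target_id] = strong
        return out

    @property
    def target_ids(self) -> set[str]:
        return {e.target_id for v in self.per_mirna.values() for e in v}

    def __len__(self) -> int:
        return len(self.target_ids)


def intersect_with_upregulated(
    targets: TargetList, upregulated: set[str]
) -> TargetList:
    """Keep only targets whose id is in the up-regulated set.

    The per-miRNA structure is preserved; miRNAs left with no surviving
    target are dropped.  Matching is exact string identity on trimmed
    ids.  Idempotent and monotone in ``upregulated``.
    """
    up = {g.strip() for g in upregulated}
    per = {
        m: kept
        for m, entries in targets.per_mirna.items()
        if (kept := [e for e in entries if e.target_id in up])
    }
    return TargetList(per_mirna=per, predicted_wins=targets.predicted_wins)


def evidence_summary(targets: TargetList) -> dict:
    """Fractions and counts of validated vs predicted targets.

    Computed on the merged, deduplicated target list (so a target backed
    by both labels counts once, under the resolved label).
    """
    merged = targets.merged
    if not merged:
        raise ValueError("evidence fractions are undefined for an empty target list")
    n = len(merged)
    n_val = sum(1 for ev in merged.values() if ev is Evidence.VALIDATED)
    return {
        "n_targets": n,
        "n_validated": n_val,
        "n_predicted": n - n_val,
        "frac_validated": n_val / n,
        "frac_predicted": (n - n_val) / n,
    }


def count_tfs_in_targets(
    targets: TargetList, tf_roster: set[str]
) -> tuple[int, list[str]]:
    """How many distinct targets are themselves TFs, and which."""
    hits = sorted(targets.target_ids & set(tf_roster))
    return len(hits), hits
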