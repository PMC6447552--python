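"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own edge-map helpers: they
scan raw interaction rows / node triples so that agreement with the
implementation is a genuine cross-check.
"""

from __future__ import annotations

from itertools import combinations, permutations

import networkx as nx
import pytest

from coregnet.regdata import (
    Effect,
    Evidence,
    RegulationTable,
    RegulatorClass,
    RegulatoryInteraction,
    TargetClass,
)


def make_ix(reg, reg_cls, tgt, tgt_cls, effect="unspecified",
            evidence="predicted", source="test"):
    return RegulatoryInteraction(
        regulator_id=reg,
        regulator_class=RegulatorClass(reg_cls),
        target_id=tgt,
        target_class=TargetClass(tgt_cls),
        effect=Effect(effect),
        evidence=Evidence(evidence),
        source=source,
    )


@pytest.fixture
def toy_table() -> RegulationTable:
    """The minimal miRNA-FFL: miR-148a-3p represses E2F1 and CCDC6, and
    E2F1 regulates CCDC6."""
    return RegulationTable([
        make_ix("hsa-miR-148a-3p", "miRNA", "E2F1", "TF", "repression"),
        make_ix("hsa-miR-148a-3p", "miRNA", "CCDC6", "gene", "repression"),
        make_ix("E2F1", "TF", "CCDC6", "gene"),
    ])


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_force_ffls(table: RegulationTable) -> dict[str, set[tuple]]:
    """O(n^3) scan over all ordered (miRNA, TF, target) node triples."""
    mi_edges = set()
    tf_edges = set()
    for ix in table.interactions:
        if ix.regulator_class is RegulatorClass.MIRNA:
            mi_edges.add((ix.regulator_id, ix.target_id))
        else:
            tf_edges.add((ix.regulator_id, ix.target_id))
    mirnas = {s for s, _ in mi_edges}
    tfs = {s for s, _ in tf_edges}
    all_nodes = {n for e in mi_edges | tf_edges for n in e}
    out = {"miRNA-FFL": set(), "TF-FFL": set(), "composite-FFL": set()}
    for m in mirnas:
        for t in tfs:
            if m == t:
                continue
            for g in all_nodes:
                if g in (m, t):
                    continue
                if (m, g) not in mi_edges or (t, g) not in tf_edges:
                    continue
                m_to_t = (m, t) in mi_edges
                t_to_m = (t, m) in tf_edges
                if m_to_t and t_to_m:
                    out["composite-FFL"].add((m, t, g))
                elif m_to_t:
                    out["miRNA-FFL"].add((m, t, g))
                elif t_to_m:
                    out["TF-FFL"].add((m, t, g))
    return out


def brute_force_fbls(table: RegulationTable) -> set[tuple]:
    mi_edges = set()
    tf_edges = set()
    for ix in table.interactions:
        (mi_edges if ix.regulator_class is RegulatorClass.MIRNA
         else tf_edges).add((ix.regulator_id, ix.target_id))
    return {(m, t) for m, t in mi_edges if (t, m) in tf_edges}


_ORACLE_PAIRS = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))
_oracle_names: dict[int, str | None] = {}


def _canonical_code(code: int) -> int:
    best = 64
    for perm in permutations(range(3)):
        c = 0
        for bit, (s, t) in enumerate(_ORACLE_PAIRS):
            if code >> bit & 1:
                ps, pt = perm[s], perm[t]
                c |= 1 << _ORACLE_PAIRS.index((ps, pt))
        best = min(best, c)
    return best


def _oracle_name(code: int) -> str | None:
    """Triad class of an edge code, or None if not weakly connected.

    Canonicalizes by exhaustive permutation, then names the canonical
    form via networkx on a 3-node graph — a path fully disjoint from the
    package's precomputed lookup."""
    canon = _canonical_code(code)
    if canon not in _oracle_names:
        sub = nx.DiGraph()
        sub.add_nodes_from(range(3))
        for bit, (s, t) in enumerate(_ORACLE_PAIRS):
            if canon >> bit & 1:
                sub.add_edge(s, t)
        if sub.number_of_edges() == 0 or not nx.is_weakly_connected(sub):
            _oracle_names[canon] = None
        else:
            _oracle_names[canon] = nx.triads.triad_type(sub)
    return _oracle_names[canon]


def brute_force_triad_census(G: nx.DiGraph) -> dict[str, int]:
    """Exhaustive enumeration over all node triples with canonical
    isomorphism labeling."""
    counts: dict[str, int] = {}
    memo: dict[int, str | None] = {}
    nodes = list(G.nodes())
    adj = {u: set(G.successors(u)) for u in nodes}
    for a, b, c in combinations(nodes, 3):
        code = (
            (b in adj[a])
            | (a in adj[b]) << 1
            | (c in adj[a]) << 2
            | (a in adj[c]) << 3
            | (c in adj[b]) << 4
            | (b in adj[c]) << 5
        )
        if code not in memo:
            memo[code] = _oracle_name(code)
        label = memo[code]
        if label is not None:
            counts[label] = counts.get(label, 0) + 1
    return counts
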