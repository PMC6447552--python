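"""Network merge, degree statistics, hub rules and subnetworks."""

from __future__ import annotations

import pytest

from conftest import make_ix
from coregnet.motifs import MotifClass, find_fbls, find_ffls
from coregnet.network import (
    build_coregulatory_network,
    coregulation_in_edges,
    degree_table,
    extract_subnetwork,
    select_hubs,
)
from coregnet.regdata import RegulationTable
from coregnet.synthetic import SyntheticSpec, generate


def single_ffl_network():
    table = RegulationTable([
        make_ix("m", "miRNA", "t", "TF"),
        make_ix("m", "miRNA", "g", "gene"),
        make_ix("t", "TF", "g", "gene"),
    ])
    return build_coregulatory_network(find_ffls(table))


def merged_synthetic():
    table, _ = generate(SyntheticSpec(
        n_mirna=12, n_tf=15, n_gene=60,
        edge_prob={"miRNA->TF": 0.12, "miRNA->gene": 0.08,
                   "TF->miRNA": 0.08, "TF->gene": 0.08},
        seed=14))
    ffls = find_ffls(table)
    fbls = find_fbls(table)
    net = build_coregulatory_network(
        list(ffls.by_class(MotifClass.MIRNA_FFL)), list(fbls))
    return table, ffls, fbls, net


class TestMerge:
    def test_single_ffl_three_nodes_three_edges(self):
        net = single_ffl_network()
        assert (net.n_nodes, net.n_edges) == (3, 3)

    def test_idempotent_on_duplicate_instances(self):
        table = RegulationTable([
            make_ix("m", "miRNA", "t", "TF"),
            make_ix("m", "miRNA", "g", "gene"),
            make_ix("t", "TF", "g", "gene"),
        ])
        ffls = find_ffls(table)
        once = build_coregulatory_network(ffls)
        twice = build_coregulatory_network(ffls, ffls)
        assert once.nodes == twice.nodes
        assert list(once.edges) == list(twice.edges)

    def test_order_independent_node_and_edge_sets(self):
        _, ffls, fbls, _ = merged_synthetic()
        mirna = list(ffls.by_class(MotifClass.MIRNA_FFL))
        a = build_coregulatory_network(mirna, list(fbls))
        b = build_coregulatory_network(list(fbls), mirna)
        assert a.nodes == b.nodes
        assert set(a.edges) == set(b.edges)

    def test_node_set_is_union_of_instance_nodes(self):
        _, ffls, fbls, net = merged_synthetic()
        expected = set()
        for inst in list(ffls.by_class(MotifClass.MIRNA_FFL)) + list(fbls):
            expected.update(inst.node_ids)
        assert set(net.nodes) == expected

    def test_empty_inputs_give_empty_network(self):
        net = build_coregulatory_network()
        assert net.n_nodes == 0 and net.n_edges == 0


class TestDegrees:
    def test_single_ffl_degrees(self):
        net = single_ffl_network()
        rec = {r.node_id: r for r in degree_table(net)}
        assert (rec["m"].in_degree, rec["m"].out_degree) == (0, 2)
        assert (rec["t"].in_degree, rec["t"].out_degree) == (1, 1)
        assert (rec["g"].in_degree, rec["g"].out_degree) == (2, 0)
        assert rec["g"].total == 2

    def test_empty_network_empty_table(self):
        from coregnet.regdata import CoregNetwork
        assert degree_table(CoregNetwork()) == []

    def test_degree_conservation(self):
        _, _, _, net = merged_synthetic()
        recs = degree_table(net)
        assert sum(r.in_degree for r in recs) == net.n_edges
        assert sum(r.out_degree for r in recs) == net.n_edges


def star_network(n_mirna_in: int, n_tf_in: int, gene: str = "hub"):
    """A gene receiving edges from the given numbers of miRNAs and TFs."""
    rows = []
    for i in range(n_mirna_in):
        rows.append(make_ix(f"m{i}", "miRNA", gene, "gene"))
    for i in range(n_tf_in):
        rows.append(make_ix(f"t{i}", "TF", gene, "gene"))
    table = RegulationTable(rows)
    from coregnet.regdata import CoregNetwork
    net = CoregNetwork()
    for ix in table:
        net.add_node(ix.regulator_id, {ix.regulator_class.value})
        net.add_node(ix.target_id, {"gene"})
        net.add_edge(ix.regulator_id, ix.target_id, ix.regulator_class)
    return net


class TestHubRules:
    def test_regular_network_has_no_regulator_hubs(self):
        # all regulators at identical total degree: strict > mean fails
        net = star_network(3, 3)
        report = select_hubs(net)
        assert report.hub_mirnas == [] and report.hub_tfs == []

    def test_in_degree_exactly_ten_passes(self):
        net = star_network(5, 5)
        report = select_hubs(net)
        assert report.hub_genes == ["hub"]

    def test_in_degree_nine_fails(self):
        net = star_network(5, 4)
        assert select_hubs(net).hub_genes == []

    def test_all_mirna_sources_fail_common_target_clause(self):
        net = star_network(10, 0)
        assert select_hubs(net).hub_genes == []

    def test_regulator_above_mean_is_hub(self):
        rows = [make_ix("m1", "miRNA", f"g{i}", "gene") for i in range(6)]
        rows += [make_ix("m2", "miRNA", "g0", "gene"),
                 make_ix("t1", "TF", "g0", "gene")]
        table = RegulationTable(rows)
        from coregnet.regdata import CoregNetwork
        net = CoregNetwork()
        for ix in table:
            net.add_node(ix.regulator_id, {ix.regulator_class.value})
            net.add_node(ix.target_id, {"gene"})
            net.add_edge(ix.regulator_id, ix.target_id, ix.regulator_class)
        report = select_hubs(net)
        # degrees: m1=6, m2=1, t1=1 -> mean 8/3; only m1 above
        assert report.hub_mirnas == ["m1"]
        assert report.regulator_mean_degree == pytest.approx(8 / 3)

    def test_no_regulators_errors(self):
        from coregnet.regdata import CoregNetwork
        net = CoregNetwork()
        net.add_node("g1", {"gene"})
        with pytest.raises(ValueError, match="regulator"):
            select_hubs(net)

    def test_relabeling_permutes_but_preserves_hub_set(self):
        _, _, _, net = merged_synthetic()
        report = select_hubs(net)
        from coregnet.regdata import CoregNetwork
        relabel = {v: f"X{idx}" for idx, v in enumerate(sorted(net.nodes))}
        renamed = CoregNetwork()
        for v, roles in net.nodes.items():
            renamed.add_node(relabel[v], roles)
        for s, t, c in net.edges:
            renamed.add_edge(relabel[s], relabel[t], c)
        report2 = select_hubs(renamed)
        assert sorted(relabel[v] for v in report.hub_mirnas) == \
            sorted(report2.hub_mirnas)
        assert sorted(relabel[v] for v in report.hub_genes) == \
            sorted(report2.hub_genes)


class TestSubnetworks:
    def test_keep_all_induced_is_identity(self):
        _, _, _, net = merged_synthetic()
        sub = extract_subnetwork(net, set(net.nodes), mode="induced")
        assert set(sub.nodes) == set(net.nodes)
        assert set(sub.edge_pairs()) == set(net.edge_pairs())

    def test_motif_closure_of_single_seed_returns_full_ffl(self):
        net = single_ffl_network()
        sub = extract_subnetwork(net, {"m"}, mode="motif-closure")
        assert set(sub.nodes) == {"m", "t", "g"}
        assert sub.n_edges == 3

    def test_induced_matches_edge_filter_oracle(self):
        _, _, _, net = merged_synthetic()
        keep = set(list(net.nodes)[::2])
        sub = extract_subnetwork(net, keep, mode="induced")
        expected = {(s, t) for s, t in net.edge_pairs()
                    if s in keep and t in keep}
        assert set(sub.edge_pairs()) == expected

    def test_unknown_ids_dropped_and_empty_keep_empty_net(self):
        net = single_ffl_network()
        sub = extract_subnetwork(net, {"nope"}, mode="induced")
        assert sub.n_nodes == 0
        assert extract_subnetwork(net, set(), mode="induced").n_nodes == 0

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError, match="unknown mode"):
            extract_subnetwork(single_ffl_network(), {"m"}, mode="fuzzy")


class TestCoregulationRanking:
    def test_rank_by_ffl_membership(self):
        rows = [make_ix("m", "miRNA", "t", "TF")]
        rows += [make_ix("m", "miRNA", "gA", "gene"),
                 make_ix("t", "TF", "gA", "gene"),
                 make_ix("m2", "miRNA", "t", "TF"),
                 make_ix("m2", "miRNA", "gA", "gene"),
                 make_ix("m", "miRNA", "gB", "gene"),
                 make_ix("t", "TF", "gB", "gene")]
        table = RegulationTable(rows)
        motifs = find_ffls(table)
        net = build_coregulatory_network(motifs)
        ranking = coregulation_in_edges(net, motifs)
        assert ranking[0][0] == "gA"
        assert ranking[0][1] > ranking[-1][1]

    def test_no_ffls_empty_ranking(self):
        from coregnet.motifs import MotifSet
        assert coregulation_in_edges(single_ffl_network(), MotifSet()) == []

    def test_scores_match_counting_oracle(self):
        _, ffls, _, net = merged_synthetic()
        ranking = dict(coregulation_in_edges(net, ffls))
        oracle: dict[str, int] = {}
        for inst in ffls:
            if inst.target_id is not None:
                oracle[inst.target_id] = oracle.get(inst.target_id, 0) + 1
        assert ranking == oracle
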