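"""Bipartite/ternary network assembly, degrees and export round trips."""

import random

import networkx as nx
import pytest

from pgnet import (AssociationRecord, build_bipartite, build_ternary,
                   degree_distribution, export_network, load_ternary_fixture)
from pgnet.io import TernaryTriple, ValidationError
from pgnet.network import read_edge_tsv


def rec(mirna, disease, biomarker=False):
    return AssociationRecord(ncrna_id=mirna, ncrna_class="miRNA",
                             disease=disease, biomarker=biomarker)


@pytest.fixture
def small_records():
    return [rec("m1", "Heart failure"), rec("m2", "Heart failure"),
            rec("m3", "Stroke"), rec("m4", "Stroke"),
            rec("m1", "Stroke")]


class TestBuildBipartite:
    def test_counts(self, small_records):
        net = build_bipartite(small_records)
        assert len(net.phenotype_nodes) == 2
        assert len(net.genotype_nodes) == 4
        assert len(net.edges) == 5

    def test_hub_degree_counts_distinct_diseases(self, catalog):
        records = [rec("miR-146a-5p", d) for d in catalog.labels[:12]]
        net = build_bipartite(records)
        assert net.degree_of("miR-146a-5p") == 12

    def test_duplicate_records_one_edge(self):
        net = build_bipartite([rec("m1", "Stroke")] * 3)
        assert len(net.edges) == 1

    def test_biomarker_flag_or_merged(self):
        net = build_bipartite([rec("m1", "Stroke", False),
                               rec("m1", "Heart failure", True)])
        assert net.node_attrs["m1"]["biomarker"] is True

    def test_empty_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            net = build_bipartite([])
        assert net.is_empty()

    def test_record_order_invariance(self, small_records):
        shuffled = small_records[:]
        random.Random(3).shuffle(shuffled)
        a, b = build_bipartite(small_records), build_bipartite(shuffled)
        assert a.edges == b.edges and a.node_attrs == b.node_attrs


class TestDegreeDistribution:
    def test_direct_normalization(self):
        records = ([rec("m1", "Stroke"), rec("m2", "Stroke"),
                    rec("m3", "Stroke")]
                   + [rec("m4", d) for d in
                      ("Stroke", "Heart failure", "Hypertension")])
        dist = degree_distribution(build_bipartite(records), "genotype")
        assert dist.pk == {1: 0.75, 3: 0.25}

    def test_star_network(self):
        net = build_bipartite([rec(f"m{i}", "Stroke") for i in range(7)])
        gen = degree_distribution(net, "genotype")
        phe = degree_distribution(net, "phenotype")
        assert set(gen.degrees.values()) == {1}
        assert phe.degrees == {"Stroke": 7}

    def test_handshake(self, small_records):
        net = build_bipartite(small_records)
        gen = degree_distribution(net, "genotype")
        phe = degree_distribution(net, "phenotype")
        assert sum(gen.degrees.values()) == sum(phe.degrees.values()) \
            == len(net.edges)

    def test_pk_sums_to_one(self, synthetic_default):
        net = build_bipartite(synthetic_default.associations)
        dist = degree_distribution(net)
        assert abs(sum(dist.pk.values()) - 1) < 1e-12
        assert min(dist.histogram) >= 1

    def test_empty_network_rejected(self):
        with pytest.warns(UserWarning):
            net = build_bipartite([])
        with pytest.raises(ValidationError):
            degree_distribution(net)


class TestBuildTernary:
    def test_fixture_pair_counts(self):
        net = build_ternary(load_ternary_fixture())
        assert net.pair_counts() == {"lncRNA": 14, "circRNA": 3}

    def test_na_emits_no_mrna_edge(self):
        t = TernaryTriple(sponge_id="APPAT", sponge_class="lncRNA",
                          mirna_id="miR-647")
        net = build_ternary([t])
        assert net.edges == {("APPAT", "miR-647", "sponge")}

    def test_novlnc6_sponge_degree(self):
        net = build_ternary(load_ternary_fixture())
        assert net.sponge_degree("novlnc6") == 3

    def test_edge_count_invariant(self):
        triples = load_ternary_fixture()
        net = build_ternary(triples)
        n_sponge_edges = len({(t.sponge_id, t.mirna_id) for t in triples})
        n_mrna_edges = len({(t.mirna_id, g) for t in triples
                            for g in t.mrna_genes})
        assert len(net.edges) == n_sponge_edges + n_mrna_edges

    def test_node_types(self):
        net = build_ternary(load_ternary_fixture())
        assert set(net.nodes.values()) == {"sponge", "miRNA", "mRNA"}


class TestExport:
    def test_sif_one_line_per_edge(self, small_records, tmp_path):
        net = build_bipartite(small_records)
        out = tmp_path / "net.sif"
        export_network(net, out, "sif")
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 5
        assert all("\tassoc\t" in ln for ln in lines)

    def test_graphml_three_node_types(self, tmp_path):
        net = build_ternary(load_ternary_fixture())
        out = tmp_path / "net.graphml"
        export_network(net, out, "graphml")
        g = nx.read_graphml(out)
        kinds = {d["kind"] for _, d in g.nodes(data=True)}
        assert kinds == {"sponge", "miRNA", "mRNA"}
        assert g.number_of_edges() == len(net.edges)

    def test_edge_tsv_round_trip(self, small_records, tmp_path):
        net = build_bipartite(small_records)
        out = tmp_path / "edges.tsv"
        export_network(net, out, "edge_tsv")
        assert {(s, t) for s, t, _ in read_edge_tsv(out)} == net.edges

    def test_unknown_format_rejected(self, small_records, tmp_path):
        with pytest.raises(ValidationError):
            export_network(build_bipartite(small_records),
                           tmp_path / "x", "dot")
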