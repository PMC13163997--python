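"""Triplet assembly sign rule, network construction, exports."""

import xml.etree.ElementTree as ET

import networkx as nx
import numpy as np
import pytest

from cernax import (assemble_triplets, build_network, export_network,
                    extract_subnetwork, read_network_edge_tsv)
from cernax.interactions import LNC_MIR, MIR_MRNA, InteractionEdge

from oracles import triplets_reference


def _lm(l, m, clip=3):
    return InteractionEdge(source=l, target=m, edge_type=LNC_MIR, clip_count=clip)


def _mg(m, g):
    return InteractionEdge(source=m, target=g, edge_type=MIR_MRNA)


class TestAssembleTriplets:
    def test_down_lnc_up_mir_down_mrna_kept(self):
        out = assemble_triplets([_lm("L", "m")], [_mg("m", "G")],
                                {"L": "down", "m": "up", "G": "down"})
        assert [(t.lncrna, t.mirna, t.mrna) for t in out] == [("L", "m", "G")]

    def test_up_lnc_up_mir_down_mrna_rejected(self):
        out = assemble_triplets([_lm("L", "m")], [_mg("m", "G")],
                                {"L": "up", "m": "up", "G": "down"})
        assert out == []

    def test_mirror_orientation_also_kept(self):
        # upregulated lncRNA + downregulated miRNA + upregulated mRNA
        out = assemble_triplets([_lm("L", "m")], [_mg("m", "G")],
                                {"L": "up", "m": "down", "G": "up"})
        assert len(out) == 1

    def test_missing_direction_named_in_error(self):
        with pytest.raises(ValueError, match="'G'"):
            assemble_triplets([_lm("L", "m")], [_mg("m", "G")],
                              {"L": "down", "m": "up"})

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_l, n_m, n_g = rng.integers(1, 8, size=3)
        lncs = [f"L{i}" for i in range(n_l)]
        mirs = [f"m{i}" for i in range(n_m)]
        genes = [f"G{i}" for i in range(n_g)]
        dirs = {x: rng.choice(["up", "down"]) for x in lncs + mirs + genes}
        lm_pairs = {(l, m) for l in lncs for m in mirs if rng.random() < 0.4}
        mg_pairs = {(m, g) for m in mirs for g in genes if rng.random() < 0.4}
        got = assemble_triplets([_lm(l, m) for l, m in lm_pairs],
                                [_mg(m, g) for m, g in mg_pairs], dirs)
        got_keys = {(t.lncrna, t.mirna, t.mrna) for t in got}
        assert got_keys == triplets_reference(lm_pairs, mg_pairs, dirs)

    def test_output_order_is_lexicographic_and_stable(self):
        dirs = {"L1": "down", "L0": "down", "m": "up", "G": "down"}
        out = assemble_triplets([_lm("L1", "m"), _lm("L0", "m")],
                                [_mg("m", "G")], dirs)
        assert [t.lncrna for t in out] == ["L0", "L1"]


class TestBuildNetwork:
    def test_single_triplet_three_nodes_two_edges(self):
        (t,) = assemble_triplets([_lm("L", "m")], [_mg("m", "G")],
                                 {"L": "down", "m": "up", "G": "down"})
        net = build_network([t])
        assert net.graph.number_of_nodes() == 3
        assert net.graph.number_of_edges() == 2

    def test_shared_mirna_five_nodes_four_edges(self):
        dirs = {"L1": "down", "L2": "down", "m": "up", "G1": "down", "G2": "down"}
        trips = assemble_triplets([_lm("L1", "m"), _lm("L2", "m")],
                                  [_mg("m", "G1"), _mg("m", "G2")], dirs)
        net = build_network(trips)
        assert net.graph.number_of_nodes() == 5
        assert net.graph.number_of_edges() == 4

    def test_fixture_with_published_network_shape(self):
        """A constructed fixture reproducing the canonical 12-lncRNA (8 up,
        4 down), 22-miRNA (20 up, 2 down), 8-mRNA network shape."""
        up_lncs = [f"UL{i}" for i in range(8)]
        dn_lncs = [f"DL{i}" for i in range(4)]
        up_mirs = [f"um{i}" for i in range(20)]
        dn_mirs = [f"dm{i}" for i in range(2)]
        dn_genes = [f"DG{i}" for i in range(6)]
        up_genes = [f"UG{i}" for i in range(2)]
        dirs = {**{x: "up" for x in up_lncs + up_mirs + up_genes},
                **{x: "down" for x in dn_lncs + dn_mirs + dn_genes}}
        lm = [_lm(l, m) for l in dn_lncs for m in up_mirs] + \
             [_lm(l, m) for l in up_lncs for m in dn_mirs]
        mg = [_mg(m, dn_genes[i % 6]) for i, m in enumerate(up_mirs)] + \
             [_mg(m, g) for m in dn_mirs for g in up_genes]
        net = build_network(assemble_triplets(lm, mg, dirs))
        counts = net.counts_by_type()
        assert counts["lncRNA"] == {"up": 8, "down": 4}
        assert counts["miRNA"] == {"up": 20, "down": 2}
        assert counts["mRNA"]["up"] + counts["mRNA"]["down"] == 8

    def test_empty_triplets_give_empty_network(self):
        net = build_network([])
        assert net.graph.number_of_nodes() == 0

    def test_sign_rule_holds_for_every_retained_triplet(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            nodes = {f"L{i}" for i in range(4)} | {f"m{i}" for i in range(4)} \
                | {f"G{i}" for i in range(4)}
            dirs = {x: rng.choice(["up", "down"]) for x in nodes}
            lm = [_lm(f"L{i}", f"m{j}") for i in range(4) for j in range(4)
                  if rng.random() < 0.5]
            mg = [_mg(f"m{j}", f"G{k}") for j in range(4) for k in range(4)
                  if rng.random() < 0.5]
            for t in assemble_triplets(lm, mg, dirs):
                assert dirs[t.lncrna] == dirs[t.mrna] != dirs[t.mirna]


@pytest.fixture
def axis_network():
    dirs = {"XIST-LIKE": "down", "ZNF662-LIKE": "down",
            **{f"m{i}": "up" for i in range(6)}, "L2": "down", "G2": "down"}
    lm = [_lm("XIST-LIKE", f"m{i}") for i in range(6)] + [_lm("L2", "m0")]
    mg = [_mg(f"m{i}", "ZNF662-LIKE") for i in range(6)] + [_mg("m0", "G2")]
    return build_network(assemble_triplets(lm, mg, dirs))


class TestExtractSubnetwork:
    def test_radius_zero_single_node_no_edges(self, axis_network):
        sub = extract_subnetwork(axis_network, "ZNF662-LIKE", radius=0)
        assert set(sub.graph.nodes) == {"ZNF662-LIKE"}
        assert sub.graph.number_of_edges() == 0

    def test_radius_two_around_mrna_recovers_clean_axis(self):
        dirs = {"XIST-LIKE": "down", "ZNF662-LIKE": "down",
                **{f"m{i}": "up" for i in range(6)}}
        lm = [_lm("XIST-LIKE", f"m{i}") for i in range(6)]
        mg = [_mg(f"m{i}", "ZNF662-LIKE") for i in range(6)]
        net = build_network(assemble_triplets(lm, mg, dirs))
        sub = extract_subnetwork(net, "ZNF662-LIKE", radius=2)
        assert set(sub.graph.nodes) == {"ZNF662-LIKE", "XIST-LIKE"} | \
            {f"m{i}" for i in range(6)}

    def test_radius_two_reaches_second_order_neighbors(self, axis_network):
        sub = extract_subnetwork(axis_network, "ZNF662-LIKE", radius=2)
        expected = {"ZNF662-LIKE", "XIST-LIKE", "L2", "G2"} | \
            {f"m{i}" for i in range(6)}
        assert set(sub.graph.nodes) == expected

    def test_radius_beyond_diameter_gives_whole_component(self, axis_network):
        sub = extract_subnetwork(axis_network, "XIST-LIKE", radius=10)
        assert set(sub.graph.nodes) == set(axis_network.graph.nodes)

    def test_unknown_center_rejected(self, axis_network):
        with pytest.raises(ValueError, match="NOPE"):
            extract_subnetwork(axis_network, "NOPE")


class TestExports:
    def test_single_triplet_sif_has_two_lines(self, tmp_path):
        (t,) = assemble_triplets([_lm("L", "m")], [_mg("m", "G")],
                                 {"L": "down", "m": "up", "G": "down"})
        net = build_network([t])
        path = tmp_path / "n.sif"
        export_network(net, path, "sif")
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 2
        assert all(len(l.split("\t")) == 3 for l in lines)

    def test_edge_tsv_round_trip_is_lossless(self, axis_network, tmp_path):
        path = tmp_path / "edges.tsv"
        export_network(axis_network, path, "edge_tsv")
        back = read_network_edge_tsv(path)
        assert back.edges == axis_network.edges
        assert back.nodes == axis_network.nodes

    def test_graphml_is_well_formed_and_reloads(self, axis_network, tmp_path):
        path = tmp_path / "n.graphml"
        export_network(axis_network, path, "graphml")
        root = ET.parse(path).getroot()
        assert root.tag.endswith("graphml")
        g = nx.read_graphml(path)
        assert set(g.nodes) == set(axis_network.graph.nodes)
        assert g.nodes["XIST-LIKE"]["node_type"] == "lncRNA"

    def test_unknown_format_rejected(self, axis_network, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(axis_network, tmp_path / "x", "dot")
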