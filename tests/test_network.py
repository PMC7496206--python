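"""Inverse-expression pairing, sub-network splitting, TF layer, export."""

import warnings

import pandas as pd
import pytest
from lxml import etree

from glunet.mti import MTIEvidence, PredictionHit
from glunet.network import (
    NetworkEdge,
    build_tf_layer,
    edges_to_frame,
    export_network,
    hub_mirnas,
    network_summary,
    pair_inverse,
    read_edge_tsv,
    split_networks,
    to_graph,
)
from glunet.profiles import PROFILE_VERDICTS, ProfileType, inverse_type


def strong(m, g):
    return ((m, g), MTIEvidence(m, g, experimental_strong=True))


class TestPairInverse:
    def test_hd_mirna_hi_gene_joins_high_dn_network(self):
        hits = {
            t: PredictionHit(t, 160.0 if t == "miranda" else 90.0, -14.0)
            for t in ("miranda", "pita", "rnahybrid")
        }
        evidence = {("m1", "g1"): MTIEvidence("m1", "g1", hits=hits)}
        edges = pair_inverse(
            {"m1": ProfileType.HD}, {"g1": ProfileType.HI}, evidence, "high"
        )
        assert len(edges) == 1
        e = edges[0]
        assert (e.level, e.mirna_direction, e.condition) == (3, "down", "high")
        # HD miRNA is unchanged under low glucose: no low-condition edge
        assert pair_inverse({"m1": ProfileType.HD}, {"g1": ProfileType.HI}, evidence, "low") == []

    def test_non_inverse_profiles_yield_no_edge(self):
        evidence = dict([strong("m1", "g1")])
        assert (
            pair_inverse({"m1": ProfileType.HD}, {"g1": ProfileType.HD}, evidence, "high") == []
        )

    def test_flat_entities_excluded(self):
        evidence = dict([strong("m1", "g1")])
        assert pair_inverse({"m1": ProfileType.FLAT}, {"g1": ProfileType.I}, evidence, "high") == []

    def test_unknown_ids_warn_and_skip(self):
        evidence = dict([strong("m1", "g1"), strong("mX", "g1")])
        with pytest.warns(UserWarning, match="absent"):
            edges = pair_inverse({"m1": ProfileType.I}, {"g1": ProfileType.D}, evidence, "high")
        assert [e.source for e in edges] == ["m1"]

    def test_inverse_invariant_holds_on_all_outputs(self, noiseless_dataset):
        from glunet.diffexpr import GENE_THRESHOLDS, MIRNA_THRESHOLDS, call_differential
        from glunet.mti import merge_evidence
        from glunet.profiles import classify_entities

        ds = noiseless_dataset
        gp = classify_entities(
            call_differential(ds.gene_expr, GENE_THRESHOLDS, "low_vs_mod"),
            call_differential(ds.gene_expr, GENE_THRESHOLDS, "high_vs_mod"),
        )
        mp = classify_entities(
            call_differential(ds.mirna_expr, MIRNA_THRESHOLDS, "low_vs_mod"),
            call_differential(ds.mirna_expr, MIRNA_THRESHOLDS, "high_vs_mod"),
        )
        evidence = merge_evidence(ds.evidence)
        for cond in ("low", "high"):
            for e in pair_inverse(mp, gp, evidence, cond):
                assert e.target_profile is inverse_type(e.source_profile)
                assert PROFILE_VERDICTS[e.source_profile][0 if cond == "low" else 1] == e.mirna_direction


def edge(m, g, condition="high", direction="down", level=3):
    mt = {"down": ProfileType.HD, "up": ProfileType.HI}[direction]
    return NetworkEdge(
        source=m,
        target=g,
        edge_kind="mti",
        condition=condition,
        mirna_direction=direction,
        level=level,
        source_profile=mt,
        target_profile=inverse_type(mt),
    )


class TestSplitAndSummary:
    def test_partition(self):
        edges = [
            edge("m1", "g1", "high", "down"),
            edge("m2", "g2", "high", "up"),
            edge("m3", "g3", "low", "down"),
            edge("m4", "g4", "low", "up"),
        ]
        subnets = split_networks(edges)
        assert {k: len(v) for k, v in subnets.items()} == {
            "high_dn": 1,
            "high_up": 1,
            "low_dn": 1,
            "low_up": 1,
        }
        # union is the full set, pairwise disjoint
        all_back = [e for es in subnets.values() for e in es]
        assert sorted((e.source, e.target) for e in all_back) == sorted(
            (e.source, e.target) for e in edges
        )

    def test_summary_counts(self):
        edges = [edge("m1", "g1"), edge("m1", "g2"), edge("m2", "g3")]
        assert network_summary(edges) == {"n_mirnas": 2, "n_genes": 3, "n_edges": 3}


class TestHubMirnas:
    def test_star_fixture_boundary(self):
        edges = [edge("m1", f"g{i}") for i in range(11)]  # 11 targets
        assert hub_mirnas(edges, min_targets=10) == [("m1", 11)]
        assert hub_mirnas(edges, min_targets=11) == []  # strict >

    def test_matches_brute_force_degrees(self):
        import numpy as np

        rng = np.random.default_rng(7)
        edges = [
            edge(f"m{rng.integers(5)}", f"g{rng.integers(40)}") for _ in range(150)
        ]
        got = hub_mirnas(edges, min_targets=3)
        degrees = {}
        for e in edges:
            degrees.setdefault(e.source, set()).add(e.target)
        expected = sorted(
            ((m, len(gs)) for m, gs in degrees.items() if len(gs) > 3),
            key=lambda t: (-t[1], t[0]),
        )
        assert got == expected


class TestTfLayer:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["tf_gene", "mirna", "sign"])

    def test_de_tf_de_mirna_edge_retained(self):
        table = self.make_table([("tf1", "m1", "repress")])
        edges = build_tf_layer(table, {"m1": ProfileType.HD}, {"tf1": ProfileType.HI})
        assert len(edges) == 1
        assert (edges[0].sign, edges[0].edge_kind) == ("repress", "tf_mirna")

    def test_flat_tf_yields_no_edges(self):
        table = self.make_table([("tf1", "m1", "activate")])
        assert build_tf_layer(table, {"m1": ProfileType.HD}, {"tf1": ProfileType.FLAT}) == []

    def test_missing_tf_warns(self):
        table = self.make_table([("ghost", "m1", "activate")])
        with pytest.warns(UserWarning, match="absent"):
            assert build_tf_layer(table, {"m1": ProfileType.HD}, {}) == []

    def test_planted_hub_out_degree_recovered(self, noiseless_dataset):
        """A planted TF linked to many DE miRNAs keeps its full out-degree."""
        from glunet.diffexpr import GENE_THRESHOLDS, MIRNA_THRESHOLDS, call_differential
        from glunet.profiles import classify_entities

        ds = noiseless_dataset
        gp = classify_entities(
            call_differential(ds.gene_expr, GENE_THRESHOLDS, "low_vs_mod"),
            call_differential(ds.gene_expr, GENE_THRESHOLDS, "high_vs_mod"),
        )
        mp = classify_entities(
            call_differential(ds.mirna_expr, MIRNA_THRESHOLDS, "low_vs_mod"),
            call_differential(ds.mirna_expr, MIRNA_THRESHOLDS, "high_vs_mod"),
        )
        edges = build_tf_layer(ds.tf_table, mp, gp)
        got = {(e.source, e.target, e.sign) for e in edges}
        assert got == ds.truth.tf_links


class TestExport:
    def test_edge_tsv_round_trip(self, tmp_path):
        edges = [edge(f"m{i % 17}", f"g{i % 31}", level=1 + i % 4) for i in range(500)]
        p = export_network(edges, tmp_path / "e.tsv", "edge-tsv")
        back = read_edge_tsv(p)
        assert {(e.source, e.target, e.level) for e in back} == {
            (e.source, e.target, e.level) for e in edges
        }

    def test_empty_outputs_are_valid(self, tmp_path):
        p = export_network([], tmp_path / "e.tsv", "edge-tsv")
        assert read_edge_tsv(p) == []
        sif = export_network([], tmp_path / "e.sif", "sif")
        assert sif.read_text() == ""

    def test_sif_labels(self, tmp_path):
        edges = [
            edge("m1", "g1", level=4),
            NetworkEdge("tf1", "m1", "tf_mirna", sign="activate"),
        ]
        p = export_network(edges, tmp_path / "n.sif", "sif")
        lines = p.read_text().splitlines()
        assert "m1\tmti_L4\tg1" in lines
        assert "tf1\ttf_mirna\tm1" in lines

    def test_graphml_is_well_formed_with_declared_keys(self, tmp_path):
        edges = [edge("m1", "g1"), edge("m2", "g2", "low", "up", 1)]
        p = export_network(edges, tmp_path / "n.graphml", "graphml")
        doc = etree.parse(str(p))
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        declared = {k.get("attr.name") for k in doc.findall(".//g:key", ns)}
        assert {"interaction", "condition", "level", "kind", "profile"} <= declared
        assert len(doc.findall(".//g:edge", ns)) == 2

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown export format"):
            export_network([], tmp_path / "x", "xgmml")
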