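"""Unit and property tests for the bipartite DEG container."""

import numpy as np
import pytest

from degraph.deg_core import (
    ADVERSE,
    DEG,
    DEGEdge,
    PSEUDO_NON_ADVERSE,
    load_sider,
    merge_degs,
    neighborhood,
    read_deg,
    sample_pseudo_negatives,
    write_deg,
)

from conftest import make_deg, oracle_gamma, random_bipartite_deg


class TestLoadSider:
    def test_empty_table(self):
        deg = load_sider([])
        assert deg.n_drugs() == deg.n_effects() == deg.n_edges() == 0

    def test_duplicate_rows_collapse(self):
        rows = [
            ("d1", "DrugOne", "c1", "EffectOne"),
            ("d1", "DrugOne", "c1", "EffectOne"),
            ("d1", "DrugOne", "c2", "EffectTwo"),
        ]
        deg = load_sider(rows)
        assert deg.n_edges() == 2
        assert all(e.label == ADVERSE for e in deg.edges.values())

    def test_empty_id_rejected_with_row_number(self):
        rows = [("d1", "x", "c1", "y"), ("", "x", "c2", "y")]
        with pytest.raises(ValueError, match="row 2"):
            load_sider(rows)

    def test_nodes_deduplicated(self):
        rows = [("d1", "A", "c1", "X"), ("d1", "A", "c2", "Y"), ("d2", "B", "c1", "X")]
        deg = load_sider(rows)
        assert deg.n_drugs() == 2 and deg.n_effects() == 2 and deg.n_edges() == 3


class TestNeighborhood:
    def test_isolated_node(self):
        deg = make_deg(["d1"], ["e1"], [])
        assert neighborhood(deg, "d1") == set()

    def test_single_edge(self):
        deg = make_deg(["d1"], ["e1"], [("d1", "e1")])
        assert neighborhood(deg, "d1") == {("effect", "e1")}
        assert neighborhood(deg, "e1") == {("drug", "d1")}

    def test_toy_t1_mixed_classes(self, toy_t1):
        assert neighborhood(toy_t1, "d1") == {
            ("effect", "e1"),
            ("effect", "e2"),
            ("drug", "d2"),
        }

    def test_unknown_node_names_id(self, toy_t1):
        with pytest.raises(KeyError, match="nope"):
            neighborhood(toy_t1, "nope")

    def test_agrees_with_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            deg = random_bipartite_deg(rng)
            for d in deg.drugs:
                assert neighborhood(deg, d, "drug") == oracle_gamma(deg, ("drug", d))
            for e in deg.effects:
                assert neighborhood(deg, e, "effect") == oracle_gamma(
                    deg, ("effect", e)
                )


class TestBipartiteness:
    def test_edge_endpoints_must_exist(self):
        deg = make_deg(["d1"], ["e1"], [])
        with pytest.raises(KeyError):
            deg.add_edge(DEGEdge("d1", "missing"))
        with pytest.raises(KeyError):
            deg.add_edge(DEGEdge("missing", "e1"))

    def test_one_edge_per_pair(self, toy_t1):
        n = toy_t1.n_edges()
        toy_t1.add_edge(DEGEdge("d1", "e1", label=PSEUDO_NON_ADVERSE))
        assert toy_t1.n_edges() == n  # replaced, not duplicated

    def test_edge_weight_validation(self):
        with pytest.raises(ValueError):
            DEGEdge("d", "e", temporal_weight=-1.0)
        with pytest.raises(ValueError):
            DEGEdge("d", "e", frequency_weight=0)
        with pytest.raises(ValueError):
            DEGEdge("d", "e", temporal_weight=float("nan"))


class TestPseudoNegatives:
    def test_zero_draw(self, toy_t1):
        assert sample_pseudo_negatives(toy_t1, 0, seed=1) == set()

    def test_exhaustive_small_case(self):
        # 2x2 grid, 3 adverse edges -> the unique remaining pair
        deg = make_deg(
            ["d1", "d2"], ["e1", "e2"], [("d1", "e1"), ("d1", "e2"), ("d2", "e1")]
        )
        assert sample_pseudo_negatives(deg, 1, seed=7) == {("d2", "e2")}

    def test_full_complement(self, toy_t1):
        total = toy_t1.n_drugs() * toy_t1.n_effects()
        available = total - toy_t1.n_edges()
        got = sample_pseudo_negatives(toy_t1, available, seed=3)
        assert got == {
            (d, e)
            for d in toy_t1.drugs
            for e in toy_t1.effects
            if not toy_t1.has_edge(d, e)
        }

    def test_seed_reproducible_and_disjoint_from_adverse(self):
        rng = np.random.default_rng(5)
        deg = random_bipartite_deg(rng)
        n = min(5, deg.n_drugs() * deg.n_effects() - deg.n_edges())
        a = sample_pseudo_negatives(deg, n, seed=11)
        b = sample_pseudo_negatives(deg, n, seed=11)
        assert a == b
        assert not (a & deg.adverse_pairs())

    def test_overdraw_reports_both_counts(self, toy_t1):
        available = toy_t1.n_drugs() * toy_t1.n_effects() - toy_t1.n_edges()
        with pytest.raises(ValueError, match=f"{available}"):
            sample_pseudo_negatives(toy_t1, available + 1, seed=0)


class TestMerge:
    def _user_deg(self, pairs_weights):
        deg = DEG()
        for (d, e), w in pairs_weights.items():
            deg.add_drug(d)
            deg.add_effect(e)
            deg.add_edge(DEGEdge(d, e, temporal_weight=w))
        return deg

    def test_single_member_identity(self):
        g = self._user_deg({("d1", "e1"): 2.0, ("d1", "e2"): 5.0})
        merged = merge_degs([g])
        assert merged.n_edges() == 2
        assert all(e.frequency_weight == 1 for e in merged.edges.values())

    def test_mean_and_count(self):
        g1 = self._user_deg({("d", "e"): 2.0})
        g2 = self._user_deg({("d", "e"): 4.0})
        merged = merge_degs([g1, g2])
        edge = merged.edges[("d", "e")]
        assert edge.temporal_weight == pytest.approx(3.0, abs=1e-9)
        assert edge.frequency_weight == 2

    def test_empty_list(self):
        merged = merge_degs([])
        assert merged.n_edges() == 0 and merged.n_drugs() == 0

    def test_frequency_counts_members_random(self):
        rng = np.random.default_rng(8)
        members = []
        for _ in range(6):
            pw = {
                (f"d{rng.integers(3)}", f"e{rng.integers(3)}"): float(rng.integers(10))
                for _ in range(4)
            }
            members.append(self._user_deg(pw))
        merged = merge_degs(members)
        for pair, edge in merged.edges.items():
            containing = [g for g in members if pair in g.edges]
            assert edge.frequency_weight == len(containing)
            expected = np.mean([g.edges[pair].temporal_weight for g in containing])
            assert edge.temporal_weight == pytest.approx(expected, abs=1e-9)


class TestSerialization:
    def test_empty_roundtrip(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_deg(DEG(), path)
        assert read_deg(path) == DEG()

    def test_toy_roundtrip(self, toy_t1, tmp_path):
        path = tmp_path / "t1.tsv"
        write_deg(toy_t1, path)
        assert read_deg(path) == toy_t1

    def test_weights_roundtrip_full_precision(self, tmp_path):
        deg = DEG()
        deg.add_drug("d", "Drug Name")
        deg.add_effect("e", "Effect Name")
        deg.add_edge(DEGEdge("d", "e", temporal_weight=2.0 / 3.0, frequency_weight=1))
        path = tmp_path / "w.tsv"
        write_deg(deg, path)
        back = read_deg(path)
        assert back == deg
        assert back.edges[("d", "e")].temporal_weight == 2.0 / 3.0

    def test_isolated_nodes_survive(self, tmp_path):
        deg = make_deg(["d1", "d2"], ["e1"], [("d1", "e1")])
        path = tmp_path / "iso.tsv"
        write_deg(deg, path)
        assert "d2" in read_deg(path).drugs

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "drug_id\teffect_id\tlabel\ttemporal_weight\tfrequency_weight\n"
            "a\tb\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            read_deg(path)
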