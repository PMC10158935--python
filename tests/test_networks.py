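import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernet import (
    InteractionCatalog,
    RegulatoryNetwork,
    build_cerna_network,
    build_negative_network,
    candidate_cerna_pairs,
    check_mediator_integrity,
    pearson_correlation,
    seed_match_scan,
    stack_expression,
)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 4.0])
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)
        assert pearson_correlation(x, 2 * x + 3) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        assert pearson_correlation([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_correlation([1, 2], [2, 1])


def _expr_from_rows(rows: dict, n=60, seed=0):
    rng = np.random.default_rng(seed)
    data = {}
    for fid, spec in rows.items():
        if isinstance(spec, np.ndarray):
            data[fid] = spec
        else:
            data[fid] = rng.normal(size=n)
    return pd.DataFrame(data).T


@pytest.fixture
def toy_negative_setup():
    """miR-a strongly anti-correlated with g1 and l1; decoys independent."""
    rng = np.random.default_rng(4)
    n = 80
    m = rng.normal(size=n)
    expr = _expr_from_rows(
        {
            "miR-a": m,
            "g1": -3 * m + rng.normal(size=n),
            "l1": -3 * m + rng.normal(size=n),
            "g2": rng.normal(size=n),
            "l2": rng.normal(size=n),
            "miR-b": rng.normal(size=n),
        },
        n=n,
    )
    catalog = InteractionCatalog.from_pairs(
        [("miR-a", "g1"), ("miR-a", "l1"), ("miR-a", "g2"), ("miR-b", "g1"), ("miR-b", "l2")]
    )
    return expr, catalog


class TestNegativeNetwork:
    def test_empty_catalog_empty_network(self, toy_negative_setup):
        expr, _ = toy_negative_setup
        cat = InteractionCatalog(pd.DataFrame(columns=["regulator", "target", "source"]))
        net = build_negative_network({"miR-a"}, {"g1"}, cat, expr)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_planted_pair_kept_decoy_and_noncatalog_dropped(self, toy_negative_setup):
        expr, cat = toy_negative_setup
        net = build_negative_network(
            {"miR-a", "miR-b"}, {"g1", "g2"}, cat, expr, target_class="mRNA"
        )
        assert net.graph.has_edge("miR-a", "g1")
        assert net.graph.edges["miR-a", "g1"]["pcc"] < -0.7
        assert not net.graph.has_edge("miR-a", "g2")  # decoy: no correlation
        assert not net.graph.has_edge("miR-b", "g2")  # not in catalog
        # nodes restricted to edge endpoints
        assert set(net.graph.nodes) == {"miR-a", "g1"}

    def test_non_de_features_excluded(self, toy_negative_setup):
        expr, cat = toy_negative_setup
        net = build_negative_network(set(), {"g1"}, cat, expr)
        assert net.n_edges == 0

    def test_output_is_bipartite_and_negative(self, toy_negative_setup):
        expr, cat = toy_negative_setup
        net = build_negative_network(
            {"miR-a"}, {"g1", "l1"}, cat, expr, target_class="mRNA"
        )
        net.validate()
        assert nx.is_bipartite(net.graph)

    def test_threshold_monotonicity(self, toy_negative_setup):
        """Relaxing the PCC cutoff can only add edges."""
        expr, cat = toy_negative_setup
        regs, tgts = {"miR-a", "miR-b"}, {"g1", "g2", "l1", "l2"}
        strict = build_negative_network(regs, tgts, cat, expr, pcc_max=-0.7)
        loose = build_negative_network(regs, tgts, cat, expr, pcc_max=-0.1)
        assert set(strict.graph.edges) <= set(loose.graph.edges)


def _negative_net(edges, target_cls="mRNA"):
    g = nx.Graph()
    for m, t in edges:
        g.add_node(m, cls="miRNA")
        g.add_node(t, cls=target_cls)
        g.add_edge(m, t, pcc=-0.9)
    return RegulatoryNetwork(g, "negative")


class TestCandidatePairs:
    def test_disjoint_mirnas_give_nothing(self):
        net1 = _negative_net([("miR-1", "g1")])
        net2 = _negative_net([("miR-2", "l1")], "lncRNA")
        assert candidate_cerna_pairs(net1, net2) == []

    def test_minimal_shared_mirna(self):
        net1 = _negative_net([("miR-1", "g1")])
        net2 = _negative_net([("miR-1", "l1")], "lncRNA")
        assert candidate_cerna_pairs(net1, net2) == [("l1", "g1", frozenset({"miR-1"}))]

    def test_fully_connected_block(self):
        """2 miRNAs × 3 mRNAs × 2 lncRNAs fully crossed → 6 pairs, 2 mediators each."""
        mirnas, genes, lncs = ["miR-1", "miR-2"], ["g1", "g2", "g3"], ["l1", "l2"]
        net1 = _negative_net([(m, g) for m in mirnas for g in genes])
        net2 = _negative_net([(m, l) for m in mirnas for l in lncs], "lncRNA")
        pairs = candidate_cerna_pairs(net1, net2)
        assert len(pairs) == 6
        assert all(meds == frozenset(mirnas) for _, _, meds in pairs)

    def test_matches_bruteforce_enumeration_on_random_networks(self):
        """Oracle: direct enumeration over all (lncRNA, mRNA, miRNA) triples."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            mirnas = [f"miR-{i}" for i in range(6)]
            genes = [f"g{i}" for i in range(12)]
            lncs = [f"l{i}" for i in range(12)]
            e1 = [(m, g) for m in mirnas for g in genes if rng.random() < 0.25]
            e2 = [(m, l) for m in mirnas for l in lncs if rng.random() < 0.25]
            if not e1 or not e2:
                continue
            net1, net2 = _negative_net(e1), _negative_net(e2, "lncRNA")
            expected = {}
            for l, g, m in itertools.product(lncs, genes, mirnas):
                if (m, g) in e1 and (m, l) in e2:
                    expected.setdefault((l, g), set()).add(m)
            got = candidate_cerna_pairs(net1, net2)
            assert {(l, g): set(ms) for l, g, ms in got} == expected

    def test_wrong_polarity_rejected(self):
        net1 = _negative_net([("miR-1", "g1")])
        pos = RegulatoryNetwork(nx.Graph(), "positive")
        with pytest.raises(ValueError, match="negative-polarity"):
            candidate_cerna_pairs(net1, pos)


class TestCernaNetwork:
    def test_no_candidates_empty_network(self, toy_negative_setup):
        expr, _ = toy_negative_setup
        net = build_cerna_network([], expr)
        assert net.n_edges == 0

    def test_coupled_pair_kept_with_mediators(self, toy_negative_setup):
        expr, cat = toy_negative_setup
        net_mm = build_negative_network({"miR-a"}, {"g1"}, cat, expr, target_class="mRNA")
        net_ml = build_negative_network({"miR-a"}, {"l1"}, cat, expr, target_class="lncRNA")
        pairs = candidate_cerna_pairs(net_mm, net_ml)
        cerna = build_cerna_network(pairs, expr)
        assert cerna.graph.has_edge("l1", "g1")
        edge = cerna.graph.edges["l1", "g1"]
        assert edge["pcc"] > 0.7
        assert edge["mediators"] == frozenset({"miR-a"})
        cerna.validate()
        check_mediator_integrity(cerna, net_mm, net_ml)

    def test_independent_candidate_dropped(self, toy_negative_setup):
        expr, _ = toy_negative_setup
        pairs = [("l2", "g2", frozenset({"miR-a"}))]
        net = build_cerna_network(pairs, expr)
        assert net.n_edges == 0

    def test_mediator_integrity_violation_detected(self, toy_negative_setup):
        expr, cat = toy_negative_setup
        net_mm = build_negative_network({"miR-a"}, {"g1"}, cat, expr, target_class="mRNA")
        net_ml = build_negative_network({"miR-a"}, {"l1"}, cat, expr, target_class="lncRNA")
        cerna = build_cerna_network(
            [("l1", "g1", frozenset({"miR-b"}))], expr  # miR-b never linked
        )
        with pytest.raises(ValueError, match="mediator"):
            check_mediator_integrity(cerna, net_mm, net_ml)


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s):
    return "".join(_RC[c] for c in reversed(s))


def _write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


class TestSeedMatchScan:
    def test_constructed_hit_and_miss(self, tmp_path):
        mirna = "UGAGGUAGUAGGUUGUAUAGUU"  # seed = positions 2..8
        site = _revcomp(mirna.replace("U", "T")[1:8])
        _write_fasta(tmp_path / "m.fa", {"miR-x": mirna})
        _write_fasta(
            tmp_path / "l.fa",
            {"lnc-hit": "A" * 20 + site + "A" * 20, "lnc-miss": "A" * 50},
        )
        cat = seed_match_scan(tmp_path / "m.fa", tmp_path / "l.fa")
        assert cat.pairs() == {("miR-x", "lnc-hit")}

    def test_matches_bruteforce_substring_search(self, tmp_path):
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGT"))
        mirnas = {
            f"miR-{i}": "".join(rng.choice(bases, 21)) for i in range(5)
        }
        lncs = {f"lnc-{i}": "".join(rng.choice(bases, 500)) for i in range(20)}
        _write_fasta(tmp_path / "m.fa", mirnas)
        _write_fasta(tmp_path / "l.fa", lncs)
        cat = seed_match_scan(tmp_path / "m.fa", tmp_path / "l.fa")
        expected = {
            (m, l)
            for m, ms in mirnas.items()
            for l, ls in lncs.items()
            if _revcomp(ms[1:8]) in ls
        }
        assert cat.pairs() == expected

    def test_short_mirna_rejected(self, tmp_path):
        _write_fasta(tmp_path / "m.fa", {"miR-s": "ACGUACG"})
        _write_fasta(tmp_path / "l.fa", {"l": "ACGT" * 10})
        with pytest.raises(ValueError, match="shorter than 8"):
            seed_match_scan(tmp_path / "m.fa", tmp_path / "l.fa")

    def test_malformed_sequence_rejected(self, tmp_path):
        _write_fasta(tmp_path / "m.fa", {"miR-bad": "ACGUACGUXX"})
        _write_fasta(tmp_path / "l.fa", {"l": "ACGT" * 10})
        with pytest.raises(ValueError, match="non-nucleotide"):
            seed_match_scan(tmp_path / "m.fa", tmp_path / "l.fa")


class TestPlantedRecovery:
    def test_planted_triplet_survives_filters(self, small_cohort):
        from cernet import call_differential

        c = small_cohort
        expr = stack_expression(c.mirna, c.mrna, c.lncrna)
        de = {}
        for cls, m, fc in [
            ("miRNA", c.mirna, 1.0),
            ("mRNA", c.mrna, 1.0),
            ("lncRNA", c.lncrna, 0.58),
        ]:
            r = call_differential(m, fc, n_perm=99, seed=0)
            de[cls] = set(r.loc[r["called"], "feature_id"])
        net_mm = build_negative_network(de["miRNA"], de["mRNA"], c.catalog, expr, target_class="mRNA")
        net_ml = build_negative_network(de["miRNA"], de["lncRNA"], c.catalog, expr, target_class="lncRNA")
        assert net_mm.graph.has_edge("miR-0001", "gene-0001")
        assert net_ml.graph.has_edge("miR-0001", "lnc-0001")
        cerna = build_cerna_network(candidate_cerna_pairs(net_mm, net_ml), expr)
        assert cerna.graph.has_edge("lnc-0001", "gene-0001")
        check_mediator_integrity(cerna, net_mm, net_ml)
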