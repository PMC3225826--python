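import itertools
from collections import Counter

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from coregnet.containers import CRMDefinition, RegulatoryNetwork, TargetMap
from coregnet.network import (
    ALLOWED_PAIR,
    PatternCatalogEntry,
    build_network,
    count_patterns,
    derive_mirna_crm_edges,
    generate_pattern_catalog,
    pattern_zscores,
    random_network,
)
from coregnet.synthetic_data import gen_network


def brute_force_counts(network, catalog):
    """Exhaustive enumeration over injective node tuples, divided by
    pattern automorphisms — independent of the backtracking matcher."""
    nodes = sorted(network.nodes)
    edge_set = network.edges
    out = {}
    for entry in catalog:
        n = len(entry.node_types)
        count = 0
        for combo in itertools.permutations(nodes, n):
            if any(
                network.nodes[combo[i]] != entry.node_types[i] for i in range(n)
            ):
                continue
            ok = all(
                (
                    combo[i],
                    combo[j],
                    ALLOWED_PAIR[(entry.node_types[i], entry.node_types[j])],
                )
                in edge_set
                for i, j in entry.edges
            )
            if ok:
                count += 1
        assert count % entry.automorphisms == 0
        out[entry.pattern_id] = count // entry.automorphisms
    return out


def nx_catalog_oracle():
    """Isomorphism-class count of connected typed digraphs on <= 3 nodes,
    via brute-force enumeration deduplicated with networkx."""
    classes = []
    for n in (2, 3):
        for types in itertools.product(("CRM", "MIRNA", "GENE"), repeat=n):
            allowed = [
                (i, j)
                for i in range(n)
                for j in range(n)
                if i != j and (types[i], types[j]) in ALLOWED_PAIR
            ]
            for r in range(1, len(allowed) + 1):
                for sub in itertools.combinations(allowed, r):
                    g = nx.DiGraph()
                    for i in range(n):
                        g.add_node(i, t=types[i])
                    g.add_edges_from(sub)
                    if not nx.is_weakly_connected(g):
                        continue
                    matcher = lambda a, b: a["t"] == b["t"]
                    if any(
                        nx.is_isomorphic(g, h, node_match=matcher)
                        for h in classes
                    ):
                        continue
                    classes.append(g)
    return classes


class TestDeriveMirnaCrmEdges:
    def test_tf_gene_targeted_gives_edge(self):
        mirna = TargetMap("MIRNA", {"m1": {"Gtf"}})
        crms = [CRMDefinition("c1", frozenset({"motifA"}))]
        edges = derive_mirna_crm_edges(mirna, crms, {"motifA": {"Gtf"}})
        assert edges == [("m1", "c1")]

    def test_mirna_targeting_no_tf_gene(self):
        mirna = TargetMap("MIRNA", {"m1": {"Gother"}})
        crms = [CRMDefinition("c1", frozenset({"motifA"}))]
        assert derive_mirna_crm_edges(mirna, crms, {"motifA": {"Gtf"}}) == []

    def test_missing_motif_warns_and_skips(self):
        mirna = TargetMap("MIRNA", {"m1": {"Gtf"}})
        crms = [CRMDefinition("c1", frozenset({"nope"}))]
        with pytest.warns(UserWarning, match="nope"):
            assert derive_mirna_crm_edges(mirna, crms, {}) == []

    def test_matches_triple_loop_oracle(self, rng):
        genes = [f"g{i}" for i in range(30)]
        motifs = [f"M{i}" for i in range(10)]
        pwm_map = {m: set(rng.choice(genes, size=2, replace=False)) for m in motifs}
        crms = [
            CRMDefinition(f"c{i}", frozenset(rng.choice(motifs, size=3, replace=False)))
            for i in range(8)
        ]
        mirna = TargetMap(
            "MIRNA",
            {f"m{i}": set(rng.choice(genes, size=6, replace=False)) for i in range(8)},
        )
        got = set(derive_mirna_crm_edges(mirna, crms, pwm_map))
        expected = set()
        for mid, targets in mirna.entries.items():
            for crm in crms:
                for motif in crm.motif_ids:
                    if pwm_map[motif] & targets:
                        expected.add((mid, crm.crm_id))
        assert got == expected


class TestBuildNetwork:
    def test_small_assembly(self):
        crm = TargetMap("CRM", {"c1": {"g1"}})
        mirna = TargetMap("MIRNA", {"m1": {"g1"}})
        net = build_network(crm, mirna, [("c1", "m1")], [])
        assert len(net.nodes) == 3 and len(net.edges) == 3

    def test_empty_inputs(self):
        net = build_network(TargetMap("CRM", {}), TargetMap("MIRNA", {}), [], [])
        assert net.nodes == {} and net.edges == set()

    def test_duplicates_collapse(self):
        crm = TargetMap("CRM", {"c1": {"g1"}})
        mirna = TargetMap("MIRNA", {"m1": {"g1"}})
        net = build_network(crm, mirna, [("c1", "m1"), ("c1", "m1")], [])
        assert len(net.edges) == 3


class TestCatalog:
    def test_contains_both_ffl_variants(self):
        names = {e.name for e in generate_pattern_catalog()}
        assert {"ffl_crm_master", "ffl_mirna_master"} <= names
        assert {"coregulation_fork", "mutual_crm_mirna"} <= names

    def test_no_duplicate_edges_within_pattern(self):
        for entry in generate_pattern_catalog():
            assert len(set(entry.edges)) == len(entry.edges)

    def test_size_matches_networkx_isomorphism_oracle(self):
        assert len(generate_pattern_catalog()) == len(nx_catalog_oracle())


class TestCountPatterns:
    def test_single_ffl_contains_subpatterns(self):
        net = RegulatoryNetwork.from_edges(
            [("c", "m", "C2M"), ("c", "g", "C2G"), ("m", "g", "M2G")]
        )
        catalog = generate_pattern_catalog()
        counts = count_patterns(net, catalog)
        by_name = {e.name: counts[e.pattern_id] for e in catalog if e.name}
        assert by_name["ffl_crm_master"] == 1
        assert by_name["coregulation_fork"] == 1
        assert by_name["chain_crm_mirna_gene"] == 1
        assert by_name["ffl_mirna_master"] == 0

    def test_empty_network_all_zero(self):
        counts = count_patterns(
            RegulatoryNetwork({}, set()), generate_pattern_catalog()
        )
        assert set(counts.values()) == {0}

    def test_matches_brute_force_on_random_networks(self):
        catalog = generate_pattern_catalog()
        for seed in range(5):
            net, _ = gen_network(
                4,
                4,
                8,
                edge_probs={"C2G": 0.3, "M2G": 0.3, "C2M": 0.25, "M2C": 0.25},
                seed=seed,
            )
            assert count_patterns(net, catalog) == brute_force_counts(net, catalog)


class TestRandomNetwork:
    @staticmethod
    def degree_signature(net):
        out = Counter()
        for s, t, e in net.edges:
            out[("out", e, s)] += 1
            out[("in", e, t)] += 1
        return out

    def test_preserves_degrees_and_edge_counts(self, rng):
        net, _ = gen_network(
            6, 6, 20, edge_probs={"C2G": 0.3, "M2G": 0.3, "C2M": 0.2, "M2C": 0.2},
            seed=1,
        )
        null = random_network(net, rng)
        assert self.degree_signature(null) == self.degree_signature(net)
        for etype in ("C2G", "M2G", "C2M", "M2C"):
            assert len(null.edges_of_type(etype)) == len(net.edges_of_type(etype))
        assert null.edges != net.edges  # actually randomized

    def test_small_state_space_uniformity(self, rng):
        # two C2G edges on disjoint endpoints: exactly 2 attainable states
        net = RegulatoryNetwork.from_edges(
            [("a", "x", "C2G"), ("b", "y", "C2G"),
             ("a", "m", "C2M"), ("b", "n", "C2M")]
        )
        counts = Counter()
        for _ in range(2000):
            null = random_network(net, rng, swaps_per_edge=10)
            counts[("a", "x", "C2G") in null.edges] += 1
        freqs = np.array([counts[True], counts[False]])
        assert stats.chisquare(freqs).pvalue > 0.001


class TestPatternZscores:
    def test_planted_ffls_enriched(self):
        net, _ = gen_network(
            8, 8, 30,
            edge_probs={"C2G": 0.08, "M2G": 0.08, "C2M": 0.05, "M2C": 0.05},
            planted_ffl_count=40,
            seed=5,
        )
        catalog = generate_pattern_catalog()
        stats_ = pattern_zscores(
            net, catalog, n_random=50, rng=np.random.default_rng(6)
        )
        ffl = next(
            s for s in stats_ if s.name == "ffl_crm_master"
        )
        assert ffl.z is not None and ffl.z > 2

    def test_absent_pattern_z_undefined(self):
        net = RegulatoryNetwork.from_edges([("c", "g", "C2G")])
        catalog = generate_pattern_catalog()
        stats_ = pattern_zscores(
            net, catalog, n_random=10, rng=np.random.default_rng(0)
        )
        mutual = next(s for s in stats_ if s.name == "mutual_crm_mirna")
        assert mutual.observed == 0 and mutual.z is None
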