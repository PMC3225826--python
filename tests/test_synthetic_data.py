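import numpy as np
import pytest
from scipy import stats

from coregnet import synthetic_data as sd
from coregnet.containers import TargetMap
from coregnet.network import count_patterns, generate_pattern_catalog


class TestGenExpression:
    def test_block_pairwise_correlation_near_rho(self):
        expr, truth = sd.gen_expression(
            n_genes=20, n_samples=200, blocks=[(10, 0.9)], seed=1
        )
        block, _ = truth.planted_blocks[0]
        rows = {expr.probeset_to_gene[p]: i for i, p in enumerate(expr.probeset_ids)}
        idx = [rows[g] for g in sorted(block)]
        corr = np.corrcoef(expr.values[idx])
        off = corr[np.triu_indices(len(idx), 1)]
        assert 0.8 <= off.mean() <= 0.95

    def test_no_blocks_near_independence(self):
        expr, _ = sd.gen_expression(n_genes=30, n_samples=200, seed=2)
        corr = np.corrcoef(expr.values)
        off = corr[np.triu_indices(30, 1)]
        assert np.abs(off).mean() < 0.1

    def test_same_seed_bit_identical(self):
        a, _ = sd.gen_expression(15, 20, blocks=[(5, 0.5)], seed=3)
        b, _ = sd.gen_expression(15, 20, blocks=[(5, 0.5)], seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            sd.gen_expression(10, 10, blocks=[(5, 1.0)])

    def test_oversized_blocks_rejected(self):
        with pytest.raises(ValueError, match="block"):
            sd.gen_expression(5, 10, blocks=[(6, 0.5)])


class TestGenTargetMaps:
    def test_overlap_planted_into_both_sets(self):
        genes = [f"G{i:04d}" for i in range(1, 101)]
        block = set(genes[:5])
        crm, mirna, truth = sd.gen_target_maps(
            2, 2, genes,
            overlap_spec=[("CRM001", "MIR001", block)],
            seed=4,
        )
        assert block <= crm.entries["CRM001"] & mirna.entries["MIR001"]
        assert truth.planted_overlaps[0][2] == frozenset(block)

    def test_fixed_degree_law(self):
        genes = [f"g{i}" for i in range(50)]
        _, mirna, _ = sd.gen_target_maps(
            1, 10, genes, crm_degree_range=(5, 10),
            mirna_degree_law=("fixed", 7), seed=5,
        )
        assert all(len(t) == 7 for t in mirna.entries.values())

    def test_powerlaw_degree_distribution(self):
        law = ("powerlaw", 2.0, 5, 30)
        rng = np.random.default_rng(6)
        draws = np.array([sd._draw_degree(law, rng, 1000) for _ in range(10_000)])
        ks = np.arange(5, 31)
        a = 1.0 - 2.0
        norm = (31.0**a) - (5.0**a)
        pmf = (((ks + 1.0) ** a) - (ks**a)) / norm
        observed = np.array([(draws == k).sum() for k in ks])
        res = stats.chisquare(observed, f_exp=pmf * len(draws))
        assert res.pvalue > 0.01

    def test_degree_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            sd.gen_target_maps(1, 1, ["g1", "g2"], crm_degree_range=(3, 3))


class TestGenUpstreamSequences:
    def test_planted_sites_fall_in_cluster_window(self):
        pwms = sd.gen_pwms(3, seed=7)
        _, truth = sd.gen_upstream_sequences(
            pwms, 2, length=1000,
            planting=[("MIR001", ["M001", "M002", "M003"], 200)],
            seed=8,
        )
        starts = [s for _, _, s, _ in truth.planted_sites]
        ends = [
            s + next(p.length for p in pwms if p.motif_id == m)
            for _, m, s, _ in truth.planted_sites
        ]
        assert max(ends) - min(starts) <= 200

    def test_same_seed_identical_fasta(self):
        pwms = sd.gen_pwms(1, seed=9)
        a, _ = sd.gen_upstream_sequences(pwms, 2, length=300, seed=10)
        b, _ = sd.gen_upstream_sequences(pwms, 2, length=300, seed=10)
        assert a == b

    def test_motifs_too_big_for_window_rejected(self):
        pwms = sd.gen_pwms(2, length=30, seed=11)
        with pytest.raises(ValueError, match="fit"):
            sd.gen_upstream_sequences(
                pwms, 1, length=500, planting=[("MIR001", ["M001", "M002"], 50)]
            )

    def test_truth_positions_inside_sequence(self):
        pwms = sd.gen_pwms(2, seed=12)
        seqs, truth = sd.gen_upstream_sequences(
            pwms, 1, length=400, planting=[("MIR001", ["M001", "M002"], 100)],
            seed=13,
        )
        for seq_id, motif, start, _strand in truth.planted_sites:
            L = next(p.length for p in pwms if p.motif_id == motif)
            assert 0 <= start <= len(seqs[seq_id]) - L


class TestGenKnockdown:
    def test_noiseless_tf_only_gene(self):
        mirna = TargetMap("MIRNA", {"m1": {"g2"}})
        data, _ = sd.gen_knockdown(
            {"g1"}, mirna, a_tf=-1.5, a_mir={"m1": 0.5}, c=0.2, noise_sd=0.0,
            gene_universe=["g1", "g2", "g3"],
        )
        g = dict(zip(data.gene_ids, data.g))
        assert g["g1"] == pytest.approx(0.2 - 1.5)
        assert g["g2"] == pytest.approx(0.2 + 0.5)
        assert g["g3"] == pytest.approx(0.2)

    def test_noiseless_additive_effects(self):
        mirna = TargetMap("MIRNA", {"m1": {"g1"}, "m2": {"g1"}})
        data, _ = sd.gen_knockdown(
            {"g1"}, mirna, a_tf=-1.0, a_mir={"m1": -0.4, "m2": 0.3}, c=0.1,
            noise_sd=0.0, gene_universe=["g1"],
        )
        assert data.g[0] == pytest.approx(0.1 - 1.0 - 0.4 + 0.3)

    def test_unknown_mirna_rejected(self):
        mirna = TargetMap("MIRNA", {"m1": {"g1"}})
        with pytest.raises(ValueError, match="absent"):
            sd.gen_knockdown({"g1"}, mirna, a_tf=0.0, a_mir={"mX": 1.0})

    def test_ols_on_true_support_recovers_coefficients(self):
        rng = np.random.default_rng(14)
        genes = [f"g{i}" for i in range(5000)]
        mirna = TargetMap(
            "MIRNA",
            {
                "m1": set(rng.choice(genes, 800, replace=False)),
                "m2": set(rng.choice(genes, 800, replace=False)),
            },
        )
        tf = set(rng.choice(genes, 1000, replace=False))
        truth_coefs = {"m1": -0.7, "m2": 0.4}
        data, _ = sd.gen_knockdown(
            tf, mirna, a_tf=-1.2, a_mir=truth_coefs, c=0.3, noise_sd=1.0,
            seed=15, gene_universe=genes,
        )
        X = np.column_stack([np.ones(len(genes)), data.b_tf, data.b_mir])
        beta, _, _, _ = np.linalg.lstsq(X, data.g, rcond=None)
        resid = data.g - X @ beta
        sigma2 = resid @ resid / (len(genes) - X.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        truth_vec = [0.3, -1.2, -0.7, 0.4]
        for b, t, s in zip(beta, truth_vec, se):
            assert abs(b - t) < 3 * s


class TestGenNetwork:
    def test_planted_ffl_census(self):
        net, truth = sd.gen_network(0, 0, 0, planted_ffl_count=7, seed=16)
        catalog = generate_pattern_catalog()
        counts = count_patterns(net, catalog)
        ffl = next(e for e in catalog if e.name == "ffl_crm_master")
        assert counts[ffl.pattern_id] == 7 == len(truth.planted_ffls)

    def test_zero_probs_no_planting_empty(self):
        net, _ = sd.gen_network(3, 3, 5, seed=17)
        assert net.edges == set()

    def test_determinism(self):
        a, _ = sd.gen_network(4, 4, 10, edge_probs={"C2G": 0.3}, seed=18)
        b, _ = sd.gen_network(4, 4, 10, edge_probs={"C2G": 0.3}, seed=18)
        assert a.edges == b.edges


class TestFixture:
    def test_fixture_round_trips_through_readers(self, tmp_path):
        from coregnet import io_formats

        sd.generate_fixture(tmp_path, seed=19)
        expr = io_formats.read_expression_matrix(
            tmp_path / "expression.tsv", tmp_path / "gene_map.tsv"
        )
        assert expr.values.shape[1] == 30
        crm = io_formats.read_target_map(tmp_path / "crm_targets.tsv", "CRM")
        mirna = io_formats.read_target_map(tmp_path / "mirna_targets.tsv", "MIRNA")
        assert len(crm) == 3 and len(mirna) == 6
        pwms = io_formats.read_pwms(tmp_path / "pwms.txt")
        assert len(pwms) == 4
        seqs = io_formats.read_fasta(tmp_path / "upstream.fasta")
        assert all(len(s) == 2000 for s in seqs.values())
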