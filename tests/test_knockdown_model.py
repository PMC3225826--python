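import numpy as np
import pytest

from coregnet.containers import KnockdownDataset, TargetMap
from coregnet.knockdown_model import (
    _aic,
    fit_full_model,
    prescreen_mirna,
    stepwise_select,
)
from coregnet.synthetic_data import gen_knockdown


def ols_oracle(X, y):
    """Normal-equations OLS with classic SE and t-test p-values."""
    from scipy import stats

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, p


def make_dataset(n_genes, mirna_sizes, tf_size, a_tf, a_mir, c, noise_sd, seed):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    mirna = TargetMap(
        "MIRNA",
        {
            mid: set(rng.choice(genes, size=size, replace=False))
            for mid, size in mirna_sizes.items()
        },
    )
    tf = set(rng.choice(genes, size=tf_size, replace=False))
    data, truth = gen_knockdown(
        tf, mirna, a_tf=a_tf, a_mir=a_mir, c=c, noise_sd=noise_sd,
        seed=seed + 1, gene_universe=genes,
    )
    return data, truth


class TestPrescreen:
    def test_inactive_mirna_in_noiseless_data(self):
        # no miRNA effect at all: g = c + a_tf*b_tf exactly, so the
        # one-miRNA model recovers a zero coefficient with zero residuals
        data, _ = make_dataset(
            200, {"m1": 50}, 60, a_tf=-1.0, a_mir={}, c=0.2, noise_sd=0.0,
            seed=1,
        )
        X = np.column_stack([np.ones(data.n_genes), data.b_tf, data.b_mir[:, 0]])
        beta, _, _ = ols_oracle(X, data.g)
        assert beta[2] == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(data.g - X @ beta, 0.0, atol=1e-10)

    def test_power_at_stated_sample_size(self):
        data, _ = make_dataset(
            2000, {"m1": 200}, 500, a_tf=-1.0, a_mir={"m1": -1.0},
            c=0.0, noise_sd=0.5, seed=2,
        )
        assert prescreen_mirna(data, "m1") < 1e-6

    def test_rank_deficient_design_excluded(self):
        # miRNA targeting every gene: its column duplicates the intercept
        genes = [f"g{i}" for i in range(20)]
        data = KnockdownDataset(
            gene_ids=genes,
            g=np.arange(20, dtype=float),
            b_tf=np.array([1.0] * 10 + [0.0] * 10),
            b_mir=np.ones((20, 1)),
            mirna_ids=["mall"],
        )
        with pytest.warns(UserWarning, match="rank"):
            assert prescreen_mirna(data, "mall") is None

    def test_matches_normal_equations_oracle(self):
        data, _ = make_dataset(
            300, {"m1": 80}, 100, a_tf=-0.8, a_mir={"m1": 0.6},
            c=0.1, noise_sd=0.7, seed=3,
        )
        X = np.column_stack([np.ones(data.n_genes), data.b_tf, data.b_mir[:, 0]])
        _, _, p = ols_oracle(X, data.g)
        assert prescreen_mirna(data, "m1") == pytest.approx(p[2], abs=1e-8)


class TestFitFullModel:
    def test_noiseless_exact_recovery(self):
        data, truth = make_dataset(
            400, {"m1": 100, "m2": 120}, 150, a_tf=-1.0,
            a_mir={"m1": -0.5, "m2": 0.3}, c=0.25, noise_sd=0.0, seed=4,
        )
        fit = fit_full_model(data, ["m1", "m2"])
        assert fit.intercept == pytest.approx(0.25, abs=1e-10)
        assert fit.a_tf == pytest.approx(-1.0, abs=1e-10)
        assert fit.a_mir["m1"] == pytest.approx(-0.5, abs=1e-10)
        assert fit.a_mir["m2"] == pytest.approx(0.3, abs=1e-10)

    def test_coefficients_and_se_match_oracle(self):
        data, _ = make_dataset(
            500, {"m1": 120, "m2": 100}, 200, a_tf=-1.0,
            a_mir={"m1": -0.5}, c=0.0, noise_sd=1.0, seed=5,
        )
        fit = fit_full_model(data, ["m1", "m2"])
        X = np.column_stack(
            [np.ones(data.n_genes), data.b_tf, data.b_mir]
        )
        beta, se, p = ols_oracle(X, data.g)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.a_tf == pytest.approx(beta[1], abs=1e-8)
        assert fit.se["tf"] == pytest.approx(se[1], abs=1e-8)
        assert fit.pvalues["m1"] == pytest.approx(p[2], abs=1e-8)

    def test_aic_matches_rss_formula(self):
        data, _ = make_dataset(
            300, {"m1": 80}, 100, a_tf=-1.0, a_mir={"m1": -0.5},
            c=0.0, noise_sd=0.8, seed=6,
        )
        fit = fit_full_model(data, ["m1"])
        X = np.column_stack([np.ones(data.n_genes), data.b_tf, data.b_mir[:, 0]])
        beta, _, _ = ols_oracle(X, data.g)
        rss = float(np.sum((data.g - X @ beta) ** 2))
        n = data.n_genes
        assert fit.aic == pytest.approx(n * np.log(rss / n) + 2 * 3, abs=1e-8)

    def test_coverage_of_truth(self):
        hits = 0
        total = 0
        for seed in range(25):
            data, _ = make_dataset(
                1000, {"m1": 250}, 300, a_tf=-1.0, a_mir={"m1": -0.6},
                c=0.1, noise_sd=1.0, seed=100 + seed,
            )
            fit = fit_full_model(data, ["m1"])
            for name, truth_val in (("tf", -1.0), ("m1", -0.6)):
                est = fit.a_tf if name == "tf" else fit.a_mir["m1"]
                total += 1
                if abs(est - truth_val) < 3 * fit.se[name]:
                    hits += 1
        assert hits / total >= 0.9


class TestStepwise:
    def test_recovers_planted_mirnas(self):
        sizes = {f"m{i}": 150 for i in range(20)}
        active = {"m2": -0.8, "m7": 0.6, "m11": -0.5}
        data, _ = make_dataset(
            3000, sizes, 800, a_tf=-1.0, a_mir=active, c=0.1, noise_sd=0.3,
            seed=7,
        )
        fit = stepwise_select(data, sorted(sizes))
        assert set(active) <= set(fit.selected)
        assert len(set(fit.selected) - set(active)) <= 2

    def test_pure_noise_selects_little(self):
        sizes = {f"m{i}": 100 for i in range(10)}
        data, _ = make_dataset(
            1000, sizes, 300, a_tf=0.0, a_mir={}, c=0.0, noise_sd=1.0, seed=8,
        )
        fit = stepwise_select(data, sorted(sizes))
        assert len(fit.selected) <= 3

    def test_no_survivor_returns_tf_only(self):
        sizes = {"m1": 100}
        data, _ = make_dataset(
            500, sizes, 150, a_tf=-1.0, a_mir={}, c=0.0, noise_sd=1.0, seed=9,
        )
        fit = stepwise_select(data, ["m1"], prescreen_alpha=1e-12)
        assert fit.selected == []
        assert fit.a_mir == {}

    def test_duplicate_candidate_never_selected_with_twin(self):
        data, _ = make_dataset(
            800, {"m1": 200}, 250, a_tf=-1.0, a_mir={"m1": -0.8},
            c=0.0, noise_sd=0.3, seed=10,
        )
        # duplicate m1's indicator column as a new candidate
        dup = KnockdownDataset(
            gene_ids=data.gene_ids,
            g=data.g,
            b_tf=data.b_tf,
            b_mir=np.column_stack([data.b_mir, data.b_mir[:, 0]]),
            mirna_ids=["m1", "m1_twin"],
        )
        fit = stepwise_select(dup, ["m1", "m1_twin"])
        assert not {"m1", "m1_twin"} <= set(fit.selected)

    def test_gene_row_order_invariance(self):
        sizes = {f"m{i}": 80 for i in range(6)}
        data, _ = make_dataset(
            600, sizes, 200, a_tf=-1.0, a_mir={"m1": -0.7}, c=0.0,
            noise_sd=0.4, seed=11,
        )
        perm = np.random.default_rng(12).permutation(data.n_genes)
        shuffled = KnockdownDataset(
            gene_ids=[data.gene_ids[i] for i in perm],
            g=data.g[perm],
            b_tf=data.b_tf[perm],
            b_mir=data.b_mir[perm],
            mirna_ids=data.mirna_ids,
        )
        a = stepwise_select(data, sorted(sizes))
        b = stepwise_select(shuffled, sorted(sizes))
        assert a.selected == b.selected
        assert a.aic == pytest.approx(b.aic, abs=1e-9)

    def test_rss_never_increases_when_active_mirna_added(self):
        data, _ = make_dataset(
            500, {"m1": 150, "m2": 100}, 200, a_tf=-1.0,
            a_mir={"m1": -0.8}, c=0.0, noise_sd=0.5, seed=13,
        )
        from coregnet.knockdown_model import _design, _rss

        rss_without = _rss(_design(data, []), data.g)
        rss_with = _rss(_design(data, ["m1"]), data.g)
        assert rss_with <= rss_without
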