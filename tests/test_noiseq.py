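import numpy as np
import pandas as pd
import pytest

from hybridtrio import (
    ExpressionTable,
    NoiseParams,
    SimConfig,
    de_probability,
    md_signal,
    noise_distribution,
    run_contrast,
    simulate_replicates,
    simulate_trio,
    tmm_factors,
)
from hybridtrio._utils import sample_rng


class TestSimulateReplicates:
    def test_full_depth_no_jitter_preserves_totals(self):
        params = NoiseParams(nss=4, pnr=1.0, v=0.0, seed=1)
        counts = np.array([100, 300, 600])
        reps = simulate_replicates(counts, params, sample_rng(1, 0))
        assert (reps.sum(axis=0) == 1000).all()

    def test_replicate_mean_matches_multinomial_expectation(self):
        params = NoiseParams(nss=1000, pnr=0.2, v=0.0, seed=2)
        counts = np.array([500, 1500, 8000])
        reps = simulate_replicates(counts, params, sample_rng(2, 0))
        n = counts.sum()
        for g in range(3):
            expected = params.pnr * counts[g]
            p = counts[g] / n
            se = np.sqrt(params.pnr * n * p * (1 - p) / params.nss)
            assert abs(reps[g].mean() - expected) < 3 * se

    def test_equal_genes_split_evenly(self):
        params = NoiseParams(nss=200, pnr=0.5, v=0.0, seed=3)
        reps = simulate_replicates(np.array([1000, 1000]), params, sample_rng(3, 0))
        share = reps[0].sum() / reps.sum()
        assert share == pytest.approx(0.5, abs=0.01)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            simulate_replicates(np.zeros(5), NoiseParams(), sample_rng(0, 0))


class TestMdSignal:
    def test_identical_values_give_origin(self):
        assert md_signal(10.0, 10.0, 0.1) == (0.0, 0.0)

    def test_fourfold_change(self):
        m, d = md_signal(40.0, 10.0, 0.1)
        assert (m, d) == (2.0, 30.0)

    def test_zero_replaced_only_in_ratio(self):
        r = 0.25
        m, d = md_signal(10.0, 0.0, r)
        assert m == pytest.approx(np.log2(10.0 / r))
        assert d == 10.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            md_signal(-1.0, 2.0, 0.1)


class TestNoiseDistribution:
    def test_identical_replicates_concentrate_at_origin(self):
        reps = np.tile(np.array([[10.0], [20.0]]), (1, 3))
        m, d = noise_distribution(reps, reps, 0.1, 0.1)
        assert (m == 0).all() and (d == 0).all()

    def test_cloud_size_is_genes_times_pairs(self):
        rng = np.random.default_rng(0)
        reps_a = rng.poisson(50, size=(7, 5)).astype(float)
        reps_b = rng.poisson(50, size=(7, 5)).astype(float)
        m, d = noise_distribution(reps_a, reps_b, 0.1, 0.1)
        assert m.size == 7 * (10 + 10)  # C(5,2) pairs per condition

    def test_cloud_quantiles_stable_across_seeds(self):
        """The pooled noise cloud is an empirical distribution over
        n_genes x 20 points; its upper quantiles should be reproducible
        across independent seeds to ~10%."""
        qs = []
        for seed in (41, 42):
            cfg = SimConfig(
                n_genes=2000, mode_proportions={"conserved": 1.0}, seed=seed
            )
            table, _ = simulate_trio(cfg)
            params = NoiseParams(seed=seed)
            counts = table.counts["parent1"].to_numpy()
            reps = simulate_replicates(counts, params, sample_rng(seed, 0))
            totals = reps.sum(axis=0)
            x = reps / totals * 1e6
            k = params.k / totals * 1e6
            m, d = noise_distribution(x, x, k, k)
            qs.append((np.quantile(m, 0.9), np.quantile(d, 0.9)))
        assert qs[0][0] == pytest.approx(qs[1][0], rel=0.1)
        assert qs[0][1] == pytest.approx(qs[1][1], rel=0.1)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            noise_distribution(np.ones((3, 1)), np.ones((3, 2)), 0.1, 0.1)


class TestDeProbability:
    def test_origin_signal_dominates_nothing(self):
        cloud_m = np.array([0.5, 1.0])
        cloud_d = np.array([0.5, 1.0])
        assert de_probability(0.0, 0.0, cloud_m, cloud_d) == 0.0

    def test_total_dominance_gives_one(self):
        cloud_m = np.array([0.5, 1.0])
        cloud_d = np.array([0.5, 1.0])
        assert de_probability(5.0, 5.0, cloud_m, cloud_d) == 1.0

    def test_hand_cloud_counts_two_thirds(self):
        cloud_m = np.array([1.0, 2.0, 3.0])
        cloud_d = np.array([1.0, 2.0, 3.0])
        assert de_probability(2.5, 2.5, cloud_m, cloud_d) == pytest.approx(2 / 3)

    def test_matches_brute_force_loop_on_random_cloud(self):
        rng = np.random.default_rng(7)
        cloud_m = rng.exponential(1.0, 500)
        cloud_d = rng.exponential(10.0, 500)
        sig_m = rng.exponential(1.0, 40)
        sig_d = rng.exponential(10.0, 40)
        q = de_probability(sig_m, sig_d, cloud_m, cloud_d)
        for i in range(40):
            brute = sum(
                1
                for mm, dd in zip(cloud_m, cloud_d)
                if mm < abs(sig_m[i]) and dd < sig_d[i]
            ) / 500
            assert q[i] == pytest.approx(brute)

    def test_monotone_in_both_coordinates(self):
        rng = np.random.default_rng(8)
        cloud_m = rng.exponential(1.0, 300)
        cloud_d = rng.exponential(5.0, 300)
        ms = np.linspace(0, 4, 25)
        q_fix_d = de_probability(ms, np.full_like(ms, 10.0), cloud_m, cloud_d)
        assert (np.diff(q_fix_d) >= 0).all()
        ds = np.linspace(0, 40, 25)
        q_fix_m = de_probability(np.full_like(ds, 2.0), ds, cloud_m, cloud_d)
        assert (np.diff(q_fix_m) >= 0).all()

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            de_probability(1.0, 1.0, np.array([]), np.array([]))


def _trio_table(seed=51, n=400, conserved_only=True):
    props = {"conserved": 1.0} if conserved_only else None
    cfg = (
        SimConfig(n_genes=n, mode_proportions=props, seed=seed)
        if props
        else SimConfig(n_genes=n, seed=seed)
    )
    table, truth = simulate_trio(cfg)
    return table, truth


class TestRunContrast:
    def test_self_contrast_calls_nothing(self):
        table, _ = _trio_table()
        norm = tmm_factors(table.counts)
        res = run_contrast(table, "parent1", "parent1", norm, NoiseParams(seed=5))
        assert (res["call"] == "non").all()
        assert res["M"].to_numpy() == pytest.approx(0.0)

    def test_swapping_conditions_flips_m_and_keeps_q(self):
        table, _ = _trio_table()
        norm = tmm_factors(table.counts)
        ab = run_contrast(table, "hybrid", "parent1", norm, NoiseParams(seed=6))
        ba = run_contrast(table, "parent1", "hybrid", norm, NoiseParams(seed=6))
        assert ba["M"].to_numpy() == pytest.approx(-ab["M"].to_numpy())
        assert ba["D"].to_numpy() == pytest.approx(ab["D"].to_numpy())
        assert ba["q"].to_numpy() == pytest.approx(ab["q"].to_numpy())

    def test_deterministic_under_seed(self):
        table, _ = _trio_table()
        norm = tmm_factors(table.counts)
        r1 = run_contrast(table, "hybrid", "parent2", norm, NoiseParams(seed=7))
        r2 = run_contrast(table, "hybrid", "parent2", norm, NoiseParams(seed=7))
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_eightfold_changes_are_detected(self):
        """100 genes with an 8-fold shift at high expression (baseline 500
        counts) among 1,000 null genes: at least 90% must be called DE."""
        rng = np.random.default_rng(61)
        n_null, n_de = 1000, 100
        mu_null = rng.uniform(50, 400, n_null)
        mu_a = np.concatenate([mu_null, np.full(n_de, 4000.0)])
        mu_b = np.concatenate([mu_null, np.full(n_de, 500.0)])
        r = 1 / 0.05
        counts = pd.DataFrame(
            {
                "A": rng.negative_binomial(r, r / (r + mu_a)),
                "B": rng.negative_binomial(r, r / (r + mu_b)),
            },
            dtype=float,
        )
        table = ExpressionTable(
            counts=counts,
            lengths_bp=pd.Series(np.full(len(counts), 1000), index=counts.index),
            has_orf=pd.Series(True, index=counts.index),
        )
        norm = tmm_factors(table.counts)
        res = run_contrast(table, "A", "B", norm, NoiseParams(seed=62))
        de_frac = (res["call"].iloc[n_null:] == "up").mean()
        assert de_frac >= 0.90
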