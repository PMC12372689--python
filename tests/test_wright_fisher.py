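"""Wright-Fisher fixation simulator and pinned-background fitness trajectories."""

import math

import numpy as np
import pytest

import invfate as iv
from invfate import ModelParams, SimConfig


class TestFitnessTrajectory:
    def test_initial_fitness_near_one_plus_ux(self, make_params):
        p = make_params(h=0.25, N=1000)
        ft = iv.fitness_trajectory(p, d=0, n=2000)
        assert ft(1) == pytest.approx(1.004, rel=0.1)

    def test_unloaded_becomes_neutral(self, make_params):
        ft = iv.fitness_trajectory(make_params(h=0.25, N=1000), d=0, n=2000)
        assert ft.asymptote == 1.0
        assert ft.w_rel[-1] == pytest.approx(1.0, abs=1e-6)

    def test_loaded_keeps_permanent_cost(self, make_params):
        p = make_params(h=0.25, N=1000)
        for d in (1, 2, 5):
            ft = iv.fitness_trajectory(p, d=d, n=2000)
            assert ft.asymptote < 1.0
            assert ft(10_000_000) == ft.asymptote

    def test_monotone_decay(self, make_params):
        ft = iv.fitness_trajectory(make_params(h=0.25, N=1000), d=0, n=2000)
        assert np.all(np.diff(ft.w_rel) <= 1e-15)

    def test_horizon_padding(self, make_params):
        p = make_params(h=0.25, N=1000)
        ft = iv.fitness_trajectory(p, d=1, n=2000, horizon=20_000)
        assert len(ft) == 20_000
        assert ft.w_rel[-1] == pytest.approx(ft.asymptote)

    def test_integrated_advantage_matches_expected_load(self, make_params):
        """sum_t log w_rel(t) for d=0 equals Ux/(hs) to leading order: the
        origin of the effective initial frequency q* = q0*exp(Ux/(hs))."""
        p = make_params(h=0.25, N=1000)
        ft = iv.fitness_trajectory(p, d=0, n=2000)
        assert np.log(ft.w_rel).sum() == pytest.approx(1.6, rel=0.02)

    def test_agrees_with_full_engine_at_rare_frequency(self, params25):
        """The pinned-background approximation reproduces the full
        recursion's relative fitness when the inversion stays rare."""
        ft = iv.fitness_trajectory(params25, d=0, n=2000, horizon=5000)
        init = iv.make_initial_slr_state(params25, d=0, n=2000, q0=1e-9,
                                         equilibrate=True)
        tr = iv.slr_trajectory(init, params25, max_generations=5000,
                               extinction_threshold=0.0)
        dev = np.abs(np.asarray(tr["w_rel"]) - ft.w_rel[: len(tr)]).max()
        assert dev < 1e-4


class TestNeutralBaselines:
    def test_slr_neutral_fixation_2_over_n(self):
        p = ModelParams.from_arm_rate(U=0.0, s=0.01, h=0.25, ntot=10_000,
                                      x=0.2, N=500)
        est = iv.estimate_fixation_probability(SimConfig(params=p, mode="slr", seed=0))
        assert est.replicates == 200 * 500
        assert est.ci_low <= 2.0 / 500 <= est.ci_high
        assert est.censored == 0

    def test_autosomal_neutral_fixation_1_over_2n(self):
        p = ModelParams.from_arm_rate(U=0.0, s=0.01, h=0.25, ntot=10_000,
                                      x=0.2, N=500)
        est = iv.estimate_fixation_probability(
            SimConfig(params=p, mode="autosomal", seed=0)
        )
        assert est.ci_low <= 1.0 / 1000 <= est.ci_high

    def test_neutral_absorption_time_matches_direct_simulation(self):
        """With every fitness equal to 1 the SLR engine is a plain
        haploid-like Wright-Fisher on N/2 copies; compare mean conditional
        fixation times against an independent direct neutral simulation."""
        N, reps = 100, 100_000
        p = ModelParams.from_arm_rate(U=0.0, s=0.01, h=0.25, ntot=100,
                                      x=0.2, N=N)
        est = iv.estimate_fixation_probability(
            SimConfig(params=p, mode="slr", replicates=reps, seed=3)
        )
        # independent oracle: straightforward neutral binomial resampling
        rng = np.random.default_rng(12345)
        M = N // 2
        times = []
        for _ in range(reps):
            c, t = 1, 0
            while 0 < c < M:
                c = rng.binomial(M, c / M)
                t += 1
            if c == M:
                times.append(t)
        oracle_mean = np.mean(times)
        se = np.std(times) / math.sqrt(len(times))
        se_est = se * math.sqrt(1 + len(times) / max(est.fixations, 1))
        assert est.mean_fixation_time == pytest.approx(oracle_mean, abs=4 * se_est)

    def test_autosomal_drift_variance(self):
        """Multinomial karyotype sampling with unit fitnesses gives the
        Wright-Fisher allele-frequency variance p(1-p)/(2N) per generation."""
        from invfate.wright_fisher import _run_autosomal_batch

        N, reps, p0 = 200, 200_000, 0.3
        p = ModelParams.from_arm_rate(U=0.0, s=0.01, h=0.25, ntot=100, x=0.2, N=N)
        rng = np.random.default_rng(7)
        # one generation: run with max_gen=1 and read the censored frequencies
        pII = p0 * p0
        nII = rng.binomial(N, pII, size=reps)
        nIN = rng.binomial(N - nII, 2 * p0 * (1 - p0) / (1 - pII))
        freqs = (2 * nII + nIN) / (2 * N)
        expected = p0 * (1 - p0) / (2 * N)
        assert freqs.mean() == pytest.approx(p0, abs=4 * math.sqrt(expected / reps))
        assert freqs.var() == pytest.approx(expected, rel=0.05)


class TestSelectionEffects:
    def test_seed_determinism(self, make_params):
        p = make_params(h=0.25, N=400, x=0.1)
        c = dict(params=p, mode="slr", replicates=5000, seed=11)
        assert iv.estimate_fixation_probability(
            SimConfig(**c)
        ) == iv.estimate_fixation_probability(SimConfig(**c))

    def test_loaded_inversions_rarely_fix_large_n(self, make_params):
        """With Ns >> 1 (N=1e4) inversions that captured any deleterious
        allele essentially never fix."""
        p = make_params(h=0.25, N=10_000)
        est = iv.estimate_fixation_probability(
            SimConfig(params=p, mode="slr", replicates=400_000, seed=0)
        )
        dge1_fix = est.fixations - est.d0_fixations
        dge1_reps = est.replicates - est.d0_replicates
        assert dge1_reps > 100_000
        assert dge1_fix <= 1

    def test_small_inversions_fix_more_than_large_autosomal(self, make_params):
        """Fixation bias toward small inversions under a heavy arm-wide load."""
        ests = {}
        for x in (0.05, 0.5):
            p = make_params(h=0.25, U=0.04, x=x, N=1000)
            ests[x] = iv.estimate_fixation_probability(
                SimConfig(params=p, mode="autosomal", seed=2)
            )
        small, large = ests[0.05], ests[0.5]
        assert large.ci_high < small.ci_low

    def test_tiny_inversions_are_effectively_neutral(self, make_params):
        """When the inversion spans fewer than one locus on average, the
        estimate reduces to the neutral single-copy baseline."""
        p = make_params(h=0.25, U=0.02, x=4e-5, N=500)  # n_bar = 0.4
        est = iv.estimate_fixation_probability(
            SimConfig(params=p, mode="slr", seed=4)
        )
        assert est.ci_low <= 2.0 / 500 <= est.ci_high

    def test_censoring_is_counted_not_dropped(self, make_params):
        p = make_params(h=0.25, N=400)
        with pytest.warns(UserWarning, match="censored"):
            est = iv.estimate_fixation_probability(
                SimConfig(params=p, mode="slr", replicates=2000, seed=5,
                          max_generations=3)
            )
        assert est.censored > 0
        assert est.fixations + est.losses + est.censored == est.replicates


class TestReplicateAPI:
    def test_single_replicate_record(self, make_params):
        p = make_params(h=0.25, N=200)
        cfg = SimConfig(params=p, mode="slr", replicates=1, seed=0)
        rec = iv.simulate_slr_replicate(cfg, np.random.default_rng(0))
        assert rec.outcome in {"FIXED", "LOST", "CENSORED"}
        assert 0 <= rec.d <= rec.n
        assert rec.generation >= 1

    def test_mode_mismatch_raises(self, make_params):
        p = make_params(h=0.25, N=200)
        cfg = SimConfig(params=p, mode="autosomal", replicates=1, seed=0)
        with pytest.raises(ValueError):
            iv.simulate_slr_replicate(cfg, np.random.default_rng(0))
        rec = iv.simulate_autosomal_replicate(cfg, np.random.default_rng(0))
        assert rec.outcome in {"FIXED", "LOST", "CENSORED"}

    def test_breakdown_partitions_replicates(self, make_params):
        p = make_params(h=0.25, N=200)
        est = iv.estimate_fixation_probability(
            SimConfig(params=p, mode="slr", replicates=20_000, seed=6)
        )
        assert sum(r for r, _ in est.d_breakdown.values()) == est.replicates
        assert sum(k for _, k in est.d_breakdown.values()) == est.fixations
        assert est.d_breakdown[0][0] == est.d0_replicates
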