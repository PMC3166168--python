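"""Generators: study design, ground truth, chain rule, reproducibility."""

import numpy as np
import pytest

from fissionet.association import association_matrix
from fissionet.lar import lar_curve
from fissionet.obsdata import to_gbi, write_observations
from fissionet.synthdata import (
    ArenaParams,
    BondedMarkovParams,
    SimConfig,
    beta_dyadic_counts,
    chain_groups,
    generate_arena,
    generate_beta_dyadic,
    generate_bonded_markov,
    generate_homogeneous,
    high_risk_params,
    simulate_lar_counts,
)


class TestStudyDesignLayout:
    def test_default_layout_matches_protocol(self):
        cfg = SimConfig(seed=0)
        obs = generate_homogeneous(cfg, 0.1)
        assert obs.N == 12
        assert obs.n_periods == 120
        days = sorted({p.day for p in obs.periods})
        assert days == [1, 4, 7, 10]
        minutes = sorted({p.minute for p in obs.periods})
        assert minutes == list(range(30))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimConfig(N=1)
        with pytest.raises(ValueError):
            SimConfig(days=())

    def test_seeded_runs_bit_reproducible(self, tmp_path):
        a = generate_arena(SimConfig(seed=42, periods_per_day=10, days=(1, 2)))
        b = generate_arena(SimConfig(seed=42, periods_per_day=10, days=(1, 2)))
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_observations(a, pa)
        write_observations(b, pb)
        assert pa.read_bytes() == pb.read_bytes()


class TestHomogeneous:
    def test_p_zero_all_singletons(self):
        obs = generate_homogeneous(SimConfig(seed=1, periods_per_day=5, days=(1,)), 0.0)
        assert all(len(r.members) == 1 for r in obs.records)

    def test_p_one_single_group(self):
        obs = generate_homogeneous(SimConfig(seed=1, periods_per_day=5, days=(1,)), 1.0)
        assert all(len(r.members) == 12 for r in obs.records)

    def test_mean_ai_consistent_with_reference_simulation(self):
        # closure inflates co-membership above p; compare against an
        # independent larger replicate of the same process
        p = 0.08
        small = generate_homogeneous(SimConfig(seed=3), p)
        big = generate_homogeneous(
            SimConfig(seed=999, periods_per_day=300, days=(1, 2, 3, 4)), p
        )
        mean_small = np.nanmean(association_matrix(small).upper_triangle())
        mean_big = np.nanmean(association_matrix(big).upper_triangle())
        # dyads are correlated within a scan (components span many dyads),
        # so the MC-SE must come from the spread across periods
        same = small.membership_arrays()["same_group"]
        iu = np.triu_indices(small.N, 1)
        per_period = same[:, iu[0], iu[1]].mean(axis=1)
        se = per_period.std(ddof=1) / np.sqrt(len(per_period))
        assert abs(mean_small - mean_big) < 4 * se
        assert mean_big > p  # chaining strictly inflates


class TestBetaDyadic:
    def test_zero_cv_reduces_to_homogeneous(self):
        obs, pmat = generate_beta_dyadic(SimConfig(seed=5, periods_per_day=10, days=(1,)), 0.2, 0.0)
        off = pmat[np.triu_indices(12, 1)]
        assert np.allclose(off, 0.2)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_beta_dyadic(SimConfig(seed=1), 0.5, 1.5)

    def test_probability_matrix_cv_matches_target(self):
        cvs = []
        for seed in range(40):
            _, pmat = beta_dyadic_counts(12, 0.2, 0.5, d=10, seed=seed)
            off = pmat[np.triu_indices(12, 1)]
            cvs.append(off.std() / off.mean())
        # 66 dyads per draw: the realised CV fluctuates around the target
        assert abs(np.mean(cvs) - 0.5) < 2 * np.std(cvs) / np.sqrt(len(cvs)) + 0.02

    def test_counts_are_binomial_given_probs(self):
        am, pmat = beta_dyadic_counts(12, 0.2, 0.5, d=500, seed=7)
        iu = np.triu_indices(12, 1)
        assert np.all(am.denom[iu] == 500)
        resid = (am.ai[iu] - pmat[iu]) / np.sqrt(pmat[iu] * (1 - pmat[iu]) / 500)
        assert abs(resid.mean()) < 0.5
        assert 0.6 < resid.std() < 1.4


class TestBondedMarkov:
    def test_frozen_chains_freeze_groups(self):
        params = BondedMarkovParams(0.3, 0.2, 0.6, 0.0, 0.0)
        obs, _ = generate_bonded_markov(SimConfig(seed=8, periods_per_day=10, days=(1,)), params)
        curve = lar_curve(obs, "minute")
        assert np.allclose(curve.g[~np.isnan(curve.g)], 1.0)

    def test_two_timescale_decay_structure(self):
        obs, info = generate_bonded_markov(SimConfig(seed=9), high_risk_params())
        curve = lar_curve(obs, "minute")
        # persistence starts well above the null and decays
        assert curve.g[0] > curve.null_rate + 0.1
        assert curve.g[0] > np.nanmean(curve.g[10:20])
        # the dyad-level persistence mixture is monotone decreasing
        taus = np.arange(1.0, 30.0)
        g_true = info["dyadic_persistence"](taus)
        assert np.all(np.diff(g_true) < 0)
        assert 0 < g_true[-1] < g_true[0] <= 1

    def test_persistence_mixture_matches_chain_monte_carlo(self):
        # single-class chain: conditional persistence after tau minutes
        # should match pi + (1-pi) exp(-rho tau)
        params = BondedMarkovParams(1.0, 0.2, 0.3, 0.0, 0.25)  # all bonded
        cfg = SimConfig(seed=10, N=12, periods_per_day=30, days=tuple(range(1, 41)))
        obs, info = generate_bonded_markov(cfg, params)
        arr = obs.membership_arrays()
        # measure dyadic links directly: use pairs whose direct chain state
        # is observable via co-membership in groups of exactly 2 is messy;
        # instead rely on the returned mixture formula vs an independent
        # two-state chain simulation
        rng = np.random.default_rng(11)
        pi, rho = 0.3, 0.25 / (1 - 0.3)
        n, T = 40_000, 10
        states = rng.random(n) < pi
        start = states.copy()
        decay = np.exp(-rho)
        p_stay, p_gain = pi + (1 - pi) * decay, pi * (1 - decay)
        persist = []
        for t in range(1, T + 1):
            states = rng.random(n) < np.where(states, p_stay, p_gain)
            persist.append(states[start].mean())
        expected = info["dyadic_persistence"](np.arange(1.0, T + 1))
        assert np.allclose(persist, expected, atol=0.02)


class TestArena:
    def test_chain_rule_three_in_a_line(self):
        params = ArenaParams()
        bl = params.body_length_cm
        pos = np.array([[0.0, 0.0], [3.9 * bl, 0.0], [7.8 * bl, 0.0]])
        labels = chain_groups(pos, params.association_radius)
        assert len(set(labels)) == 1  # one shoal spanning ~8 body lengths

    def test_chain_rule_breaks_beyond_radius(self):
        params = ArenaParams()
        bl = params.body_length_cm
        pos = np.array([[0.0, 0.0], [4.1 * bl, 0.0]])
        labels = chain_groups(pos, params.association_radius)
        assert len(set(labels)) == 2

    def test_infinite_cohesion_one_permanent_group(self):
        params = ArenaParams(cohesion=1e9, fission_hazard=0.0, fusion_hazard=1.0)
        obs = generate_arena(SimConfig(seed=12, periods_per_day=10, days=(1,)), params)
        assert all(len(r.members) == 12 for r in obs.records)

    def test_emits_valid_observations(self):
        obs = generate_arena(SimConfig(seed=13, periods_per_day=15, days=(1, 2)))
        gbi = to_gbi(obs)
        # complete detection: every fish in exactly one group per period
        assert gbi.col_sums().tolist() == [obs.n_periods] * obs.N


class TestModelLevelSimulation:
    def test_counts_bounded_by_denominator(self):
        lags = np.arange(1.0, 10.0)
        den = np.full(9, 50)
        num = simulate_lar_counts("TWO_CA_RD", [0.3, 1.0, 0.5, 0.01], lags, den, seed=1)
        assert np.all(num <= den) and np.all(num >= 0)
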