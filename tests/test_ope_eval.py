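"""Off-policy evaluation estimators against exact oracles, baseline
policies, rollouts, and the Pareto sweep."""

import dataclasses
import math

import numpy as np
import pytest

from cytodose.cpql_policy import CQLConfig, Transition, cql_train
from cytodose.ope_eval import (BCRolloutPolicy, CPQLRolloutPolicy,
                               RuleBasedRolloutPolicy, episode_return,
                               fit_behavior_cloning, group_trajectories,
                               normalize_to_bc, ope_dr, ope_fqe, ope_is_wis,
                               pareto_sweep, rollout_in_environment,
                               rule_based_policy, tabular_policy_value)


def _toy_trajectories(rng, n_ep=40, horizon=5, sd=4):
    """Synthetic trajectories with known logged propensities."""
    trans = []
    for i in range(n_ep):
        for t in range(horizon):
            s = rng.normal(0, 1, sd)
            a = np.array([rng.uniform(-10, 10), rng.uniform(0, 15)])
            r = float(1.0 - 0.05 * np.abs(a[0]) + 0.1 * s[0])
            trans.append(Transition(
                state=s, action=a, reward=r, next_state=rng.normal(0, 1, sd),
                propensity=1.0 / (20.0 * 15.0),       # uniform box density
                terminal=t == horizon - 1, episode_id=f"e{i}", t_h=float(t)))
    return trans


class TestBehaviorCloning:
    def test_recovers_linear_rule(self):
        rng = np.random.default_rng(0)
        W = np.array([[0.5, -0.2], [1.0, 0.3], [0.0, 0.8]])
        trans = []
        for i in range(400):
            s = rng.normal(0, 1, 3)
            a = s @ W + rng.normal(0, 0.05, 2)
            trans.append(Transition(s, a, 0.0, s, 1.0, False, f"e{i}", 0.0))
        bc = fit_behavior_cloning(trans)
        assert np.allclose(bc.coef[:3], W, atol=0.05)

    def test_density_positive_on_dataset(self):
        rng = np.random.default_rng(1)
        trans = _toy_trajectories(rng)
        bc = fit_behavior_cloning(trans)
        for tr in trans[:50]:
            assert bc.density(tr.state, tr.action) > 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit_behavior_cloning([])


class TestRulePolicy:
    def test_light_depth_raises_propofol(self):
        d, rk = rule_based_policy({"map": 80.0, "depth": 70.0,
                                   "rp_prev": 30.0})
        assert d > 0 and rk == 0.0

    def test_in_band_no_change(self):
        d, rk = rule_based_policy({"map": 75.0, "depth": 52.0,
                                   "rp_prev": 55.0})
        assert d == pytest.approx(0.0) and rk == 0.0

    def test_hypotension_overrides_depth(self):
        d, _ = rule_based_policy({"map": 60.0, "depth": 80.0,
                                  "rp_prev": 55.0})
        assert d < 0


class TestISWIS:
    def test_identity_policy_equals_empirical_mean(self):
        rng = np.random.default_rng(2)
        trans = _toy_trajectories(rng)
        trajs = group_trajectories(trans)
        # target density ≡ behavior density → all ratios 1
        is_, wis = ope_is_wis(trajs, lambda s, a: 1.0 / (20.0 * 15.0),
                              discount=0.95)
        emp = np.mean([sum(0.95 ** t * tr.reward
                           for t, tr in enumerate(traj)) for traj in trajs])
        assert is_.raw == pytest.approx(emp)
        assert wis.raw == pytest.approx(emp)

    def test_bandit_oracle(self):
        """2-action bandit, uniform behavior, target picks the rewarding
        arm: IS recovers the known expectation 1.0."""
        rng = np.random.default_rng(3)
        trans = []
        for i in range(4000):
            arm = rng.integers(2)
            a = np.array([float(arm), 0.0])
            trans.append(Transition(np.zeros(1), a, float(arm), np.zeros(1),
                                    0.5, True, f"e{i}", 0.0))
        trajs = group_trajectories(trans)
        is_, wis = ope_is_wis(
            trajs, lambda s, a: 1.0 if a[0] == 1.0 else 0.0, discount=1.0)
        assert is_.raw == pytest.approx(1.0, abs=0.05)
        assert wis.raw == pytest.approx(1.0, abs=0.05)

    def test_zero_density_episodes_excluded_not_inf(self):
        rng = np.random.default_rng(4)
        trans = _toy_trajectories(rng, n_ep=10)
        for tr in trans[:5]:
            tr.propensity = 0.0
        trajs = group_trajectories(trans)
        is_, _ = ope_is_wis(trajs, lambda s, a: 1.0)
        assert is_.n_excluded == 1
        assert np.isfinite(is_.raw)


class TestDR:
    def test_zero_q_model_collapses_to_is(self):
        rng = np.random.default_rng(5)
        trans = _toy_trajectories(rng)
        trajs = group_trajectories(trans)
        dens = lambda s, a: 1.0 / (20.0 * 15.0) * (1 + 0.1 * np.sign(a[0]))
        is_, _ = ope_is_wis(trajs, dens, discount=0.95)
        zq = lambda s, a: np.zeros(len(np.atleast_2d(s)))
        dr = ope_dr(trajs, dens, zq, lambda s: np.zeros(2), discount=0.95)
        assert dr.raw == pytest.approx(is_.raw, rel=1e-12)

    def test_identity_policy_perfect_q_gives_empirical_mean(self):
        # one-step episodes: perfect Q(s, a) = r(s, a); target ≡ behavior
        rng = np.random.default_rng(6)
        trans = []
        for i in range(300):
            s = rng.normal(0, 1, 2)
            r = float(s[0])
            trans.append(Transition(s, np.zeros(2), r, s, 1.0, True,
                                    f"e{i}", 0.0))
        trajs = group_trajectories(trans)

        def qm(states, actions):
            return np.atleast_2d(states)[:, 0]

        dr = ope_dr(trajs, lambda s, a: 1.0, qm, lambda s: np.zeros(2),
                    discount=1.0)
        emp = np.mean([t.reward for t in trans])
        assert dr.raw == pytest.approx(emp, rel=1e-9)

    def test_good_q_model_reduces_variance_vs_is(self):
        """Across 200 replicate datasets, DR with the true Q has lower
        variance than IS (Monte-Carlo comparison)."""
        is_vals, dr_vals = [], []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            trans = []
            for i in range(20):
                s = rng.normal(0, 1, 1)
                a = np.array([rng.uniform(-1, 1), 0.0])
                r = float(s[0] + 0.2 * rng.normal())
                trans.append(Transition(s, a, r, s, 0.5, True, f"e{i}", 0.0))
            trajs = group_trajectories(trans)
            dens = lambda s, a: 0.5 + 0.4 * np.tanh(a[0])

            def qm(states, actions):
                return np.atleast_2d(states)[:, 0]   # true E[r | s]

            is_, _ = ope_is_wis(trajs, dens, discount=1.0)
            dr = ope_dr(trajs, dens, qm, lambda s: np.zeros(2), discount=1.0)
            is_vals.append(is_.raw)
            dr_vals.append(dr.raw)
        assert np.var(dr_vals) <= np.var(is_vals)


class TestFQE:
    def _tabular_setup(self):
        P = np.zeros((3, 2, 3))
        P[0, 0] = [0.8, 0.2, 0.0]
        P[0, 1] = [0.1, 0.6, 0.3]
        P[1, 0] = [0.3, 0.5, 0.2]
        P[1, 1] = [0.0, 0.2, 0.8]
        P[2, 0] = [0.5, 0.0, 0.5]
        P[2, 1] = [0.2, 0.2, 0.6]
        R = np.array([[0.5, 1.0], [0.0, 0.8], [1.2, 0.3]])
        policy = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        return P, R, policy

    def test_tabular_oracle_linear_solve(self):
        """FQE on an enumerated 3-state MDP matches exact policy evaluation
        (linear solve) within 1e-3."""
        P, R, policy = self._tabular_setup()
        gamma = 0.9
        v_exact = tabular_policy_value(P, R, policy, gamma)
        # tabular FQE: iterate Q <- R + gamma P V_pi on exact model
        Q = np.zeros((3, 2))
        for _ in range(2000):
            V = np.einsum("sa,sa->s", policy, Q)
            Q = R + gamma * np.einsum("sat,t->sa", P, V)
        v_fqe = np.einsum("sa,sa->s", policy, Q)
        assert np.max(np.abs(v_fqe - v_exact)) < 1e-3

    def test_iteration_monotone_convergence_to_oracle(self):
        P, R, policy = self._tabular_setup()
        gamma = 0.9
        v_exact = tabular_policy_value(P, R, policy, gamma)
        errs = []
        Q = np.zeros((3, 2))
        for it in range(60):
            V = np.einsum("sa,sa->s", policy, Q)
            Q = R + gamma * np.einsum("sat,t->sa", P, V)
            errs.append(np.max(np.abs(np.einsum("sa,sa->s", policy, Q)
                                      - v_exact)))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_neural_fqe_respects_geometric_bound(self, transitions, agent):
        fqe, _ = ope_fqe(list(transitions)[:400], agent.act, discount=0.99,
                         iterations=5, seed=0)
        bound = (2.0 + max(abs(t.reward) for t in transitions[:400])) / 0.01
        assert abs(fqe.raw) <= bound

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            ope_fqe([], lambda s: np.zeros(2))


class TestNormalization:
    def test_bc_normalizes_to_exactly_one(self):
        raw = {"IS": -33.2, "WIS": -31.0, "DR": -35.9, "FQE": -30.1}
        out = normalize_to_bc(raw, raw)
        for k in raw:
            assert out[k].normalized == 1.000


class TestRollouts:
    def test_identical_seeds_identical_outcomes(self, cohort, simulator):
        r1, _ = rollout_in_environment(RuleBasedRolloutPolicy(), cohort[:5],
                                       simulator)
        r2, _ = rollout_in_environment(RuleBasedRolloutPolicy(), cohort[:5],
                                       simulator)
        assert r1 == r2

    def test_rule_based_never_gives_ketamine(self, cohort, simulator):
        stats, eps = rollout_in_environment(RuleBasedRolloutPolicy(),
                                            cohort[:5], simulator)
        assert stats["ketamine_mean"] == 0.0

    def test_cpql_rollout_zero_violations(self, cohort, simulator, agent,
                                          forecaster):
        pol = CPQLRolloutPolicy(agent, forecaster, project=True)
        stats, _ = rollout_in_environment(pol, cohort[:10], simulator)
        assert stats["violation_pct"] == 0.0

    def test_policy_improvement_over_behavior_three_seeds(
            self, improvement_results):
        """CPQL's true simulated return ≥ the behavior policy's on three
        cohort seeds (ground-truth environment; direction only)."""
        for seed, (cpql, behavior) in improvement_results.items():
            assert cpql >= behavior

    def test_episode_return_uses_reward_definition(self, cohort):
        r = episode_return(cohort[0])
        assert np.isfinite(r)
        # bounded above by alpha per step
        assert r <= 2.0 * len(cohort[0].decision_steps)


class TestSurrogateEnvironment:
    def test_surrogate_rollout_reports_side_by_side_stats(self, cohort,
                                                          simulator, agent,
                                                          forecaster):
        """The learned-surrogate rollout produces the same outcome keys as
        the ground-truth environment, so model bias is directly readable."""
        from cytodose.ope_eval import surrogate_rollout
        pol = CPQLRolloutPolicy(agent, forecaster, project=True)
        sur = surrogate_rollout(pol, cohort[:5], forecaster)
        pol2 = CPQLRolloutPolicy(agent, forecaster, project=True)
        truth, _ = rollout_in_environment(pol2, cohort[:5], simulator)
        for key in ("map_in_band_pct", "il6_auc", "return",
                    "ketamine_mean"):
            assert key in sur and np.isfinite(sur[key])
            assert key in truth

    def test_surrogate_deterministic(self, cohort, forecaster, agent):
        from cytodose.ope_eval import surrogate_rollout
        a = surrogate_rollout(CPQLRolloutPolicy(agent, forecaster),
                              cohort[:3], forecaster)
        b = surrogate_rollout(CPQLRolloutPolicy(agent, forecaster),
                              cohort[:3], forecaster)
        assert a == b


class TestParetoSweep:
    def test_sweep_endpoints_and_nondomination(self, cohort, forecaster,
                                               simulator):
        cfg = dataclasses.replace(CQLConfig().smoke(), steps=120)
        df = pareto_sweep(cohort, forecaster, simulator,
                          weights=[0.0, 0.5, 1.0], seed=0, cql_config=cfg,
                          eval_episodes=10)
        assert len(df) == 3
        assert df["non_dominated"].any()
        # non-dominated definition: no swept point beats another on both axes
        nd = df[df["non_dominated"]]
        for _, r in nd.iterrows():
            dominated = ((df["map_stability"] >= r["map_stability"])
                         & (df["il6_auc"] <= r["il6_auc"])
                         & ((df["map_stability"] > r["map_stability"])
                            | (df["il6_auc"] < r["il6_auc"]))).any()
            assert not dominated

    def test_weights_outside_unit_interval_rejected(self, cohort,
                                                    forecaster, simulator):
        with pytest.raises(ValueError):
            pareto_sweep(cohort, forecaster, simulator, weights=[-0.1, 0.5])
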