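"""Mechanistic simulator: dose–response shapes, timing, confounding,
sampling, and reproducibility."""

import numpy as np
import pytest

from cytodose.synthetic_cohort import (DT_H, GroundTruthParams, SimConfig,
                                       Simulator, cytokine_dynamics,
                                       ketamine_suppression, map_dynamics,
                                       perfusion_index, sample_lab_times,
                                       simulate_cohort, true_spike_labels)

P = GroundTruthParams()


def _noise_free_trajectory(rp, rk, sev=1.3, il6_0=45.0, hours=24.0):
    cyt = np.array([il6_0, 13.0, 17.0, il6_0 * P.il10_gain])
    m = 82.0
    tg = np.arange(0, hours + 1e-9, DT_H)
    il6 = np.empty_like(tg)
    for i, t in enumerate(tg):
        il6[i] = cyt[0]
        if i == len(tg) - 1:
            break
        perf = float(perfusion_index(m, P))
        cyt = cytokine_dynamics(cyt, t, rp, rk, perf, DT_H, P, severity=sev)
        m = map_dynamics(m, rp, 0.0, DT_H, baseline=82.0, params=P)
    return tg, il6, m


class TestCytokineDynamics:
    def test_zero_drug_peak_in_8_to_12_hours(self):
        tg, il6, _ = _noise_free_trajectory(0.0, 0.0)
        t_peak = tg[il6.argmax()]
        assert 8.0 <= t_peak <= 12.0

    def test_ketamine_emax_asymptote(self):
        assert ketamine_suppression(1e9, P.e50, P.emax_il6) == \
            pytest.approx(1.0 - P.emax_il6, rel=1e-6)

    def test_propofol_u_shape_minimum_beats_low_dose(self):
        # 12-h IL-6 lower at the suppression optimum than at 15 mcg/kg/min
        i12 = int(12.0 / DT_H)
        _, at_mp, _ = _noise_free_trajectory(P.m_p, 0.0)
        _, at_15, _ = _noise_free_trajectory(15.0, 0.0)
        assert at_mp[i12] < at_15[i12]

    def test_very_high_propofol_rebounds_via_hypoperfusion(self):
        i12 = int(12.0 / DT_H)
        _, at_mp, _ = _noise_free_trajectory(P.m_p, 0.0)
        _, at_100, _ = _noise_free_trajectory(100.0, 0.0)
        assert at_100[i12] > at_mp[i12]

    def test_ketamine_suppression_monotone_on_dense_truth(self):
        i12 = int(12.0 / DT_H)
        levels = [_noise_free_trajectory(P.m_p, rk)[1][i12]
                  for rk in (0.0, 3.0, 6.0, 12.0, 20.0)]
        assert all(a > b for a, b in zip(levels, levels[1:]))

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            cytokine_dynamics(np.ones(4), 1.0, -1.0, 0.0, 1.0, DT_H, P)


class TestMapDynamics:
    def test_mean_reversion_without_drugs(self):
        m = 60.0
        for _ in range(100):
            m = map_dynamics(m, 0.0, 0.0, DT_H, baseline=82.0, params=P)
        assert m == pytest.approx(82.0, abs=0.5)

    def test_sustained_high_propofol_depresses_equilibrium(self):
        _, _, m_end = _noise_free_trajectory(100.0, 0.0)
        assert m_end < 82.0 - 10.0

    def test_vasopressor_raises_equilibrium_monotonically(self):
        def equil(v):
            m = 82.0
            for _ in range(200):
                m = map_dynamics(m, 60.0, v, DT_H, baseline=82.0, params=P)
            return m
        vals = [equil(v) for v in (0.0, 0.1, 0.2, 0.4)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestBehaviorPolicy:
    def test_hypotension_triggers_propofol_reduction(self, simulator):
        pol = simulator.behavior
        ctx = {"arm": False, "ketamine_level": 0.0, "depth_target": 52.0,
               "depth_slope": 0.75}
        state = {"map": 60.0, "rp_prev": 60.0, "rk_prev": 0.0,
                 "rp_effect": 60.0, "t_h": 1.0}
        d_rp, _ = pol.mean_action(state, ctx)
        assert d_rp < 0

    def test_light_anesthesia_raises_propofol(self, simulator):
        pol = simulator.behavior
        ctx = {"arm": False, "ketamine_level": 0.0, "depth_target": 52.0,
               "depth_slope": 0.75}
        state = {"map": 80.0, "rp_prev": 20.0, "rk_prev": 0.0,
                 "rp_effect": 20.0, "t_h": 1.0}   # depth 80 ≫ target
        d_rp, _ = pol.mean_action(state, ctx)
        assert d_rp > 0

    def test_logged_propensity_matches_density(self, simulator):
        rng = np.random.default_rng(5)
        pol = simulator.behavior
        ctx = {"arm": True, "ketamine_level": 8.0, "depth_target": 52.0,
               "depth_slope": 0.75}
        state = {"map": 75.0, "rp_prev": 50.0, "rk_prev": 6.0,
                 "rp_effect": 50.0, "t_h": 1.0}
        action, dens = pol.act(state, ctx, rng)
        assert dens == pytest.approx(pol.density(state, ctx, action))
        assert dens > 0

    def test_confounding_ketamine_arm_less_inflamed(self, cohort):
        crp_k = [c.baseline_crp for c in cohort if c.behavior_ctx["arm"]]
        crp_p = [c.baseline_crp for c in cohort if not c.behavior_ctx["arm"]]
        assert len(crp_k) >= 5 and len(crp_p) >= 5
        assert np.mean(crp_k) < np.mean(crp_p)

    def test_no_confounding_limit(self):
        import dataclasses
        from cytodose.synthetic_cohort import BehaviorConfig
        cfg = SimConfig(n_episodes=120, seed=4,
                        behavior=BehaviorConfig(ketamine_crp_coef=0.0))
        cohort = simulate_cohort(cfg)
        crp_k = [c.baseline_crp for c in cohort if c.behavior_ctx["arm"]]
        crp_p = [c.baseline_crp for c in cohort if not c.behavior_ctx["arm"]]
        # same selection distribution: arm means differ only by noise
        pooled_sd = np.std([c.baseline_crp for c in cohort])
        se = pooled_sd * np.sqrt(1 / len(crp_k) + 1 / len(crp_p))
        assert abs(np.mean(crp_k) - np.mean(crp_p)) < 3 * se


class TestLabSampling:
    def test_zero_intensity_gives_no_draws(self):
        assert len(sample_lab_times(24.0, 0.0, False, 3)) == 0

    def test_seed_determinism(self):
        a = sample_lab_times(24.0, 0.3, False, 9)
        b = sample_lab_times(24.0, 0.3, False, 9)
        assert np.array_equal(a, b)

    def test_informative_sampling_tracks_il6(self):
        rng = np.random.default_rng(0)
        counts, peaks = [], []
        for i in range(200):
            peak = float(rng.uniform(20, 300))
            il6_fn = lambda t, p=peak: p * np.exp(-0.5 * ((t - 10) / 4) ** 2)
            times = sample_lab_times(24.0, 0.2, True, int(i),
                                     il6_fn=il6_fn, informative_gain=2.0)
            counts.append(len(times))
            peaks.append(peak)
        assert np.corrcoef(counts, peaks)[0, 1] > 0.2


class TestCohort:
    def test_seed_determinism_end_to_end(self):
        a = simulate_cohort(SimConfig(n_episodes=8, seed=3))
        b = simulate_cohort(SimConfig(n_episodes=8, seed=3))
        for x, y in zip(a, b):
            assert np.array_equal(x.dense["il6"], y.dense["il6"])
            assert len(x.episode.events) == len(y.episode.events)
            assert np.array_equal(x.actions, y.actions)

    def test_tbsa_strata_proportions(self):
        cohort = simulate_cohort(SimConfig(n_episodes=614, seed=6))
        tbsa = np.array([c.episode.static.tbsa for c in cohort])
        props = [np.mean(tbsa < 20), np.mean((tbsa >= 20) & (tbsa < 40)),
                 np.mean(tbsa >= 40)]
        for got, want in zip(props, (0.645, 0.241, 0.114)):
            assert abs(got - want) < 0.05

    def test_spike_prevalence_in_plausible_band(self, cohort):
        prev = np.mean([c.spike_absolute for c in cohort])
        assert 0.15 <= prev <= 0.40

    def test_observed_labs_equal_truth_plus_noise(self, cohort):
        se = cohort[0]
        for e in se.episode.lab_events():
            truth = float(np.interp(e.t_sec / 3600.0, se.t_grid_h,
                                    se.dense[e.modality]))
            assert e.value > 0
            # multiplicative log-normal noise: within a generous factor
            assert 0.5 * truth - 1 <= e.value <= 2.0 * truth + 1

    def test_counterfactual_consistency(self, cohort, simulator):
        """Same noise draws + the factual dose sequence reproduce the
        factual trajectory exactly."""
        se = cohort[0]
        logged = {int(i): (a[0], a[1])
                  for i, a in zip(se.decision_steps, se.actions)}
        step_idx = {"i": None}

        class Replay:
            def __init__(self):
                self.k = 0

            def __call__(self, state, rng):
                i = se.decision_steps[self.k]
                self.k += 1
                return logged[int(i)]

        from cytodose.ope_eval import _base_from_sim
        base = _base_from_sim(se)
        cf = simulator.run_episode(se.episode.episode_id, se.episode.static,
                                   base, se.noise_handle, policy=Replay())
        assert np.allclose(cf.dense["il6"], se.dense["il6"])
        assert np.allclose(cf.dense["map"], se.dense["map"])

    def test_spike_labels_from_dense_series(self):
        t = np.arange(0, 24.01, DT_H)
        flat = np.full_like(t, 50.0)
        assert true_spike_labels(t, flat) == (False, False)
        rise = 50.0 + 60.0 * np.clip((t - 6.0) / 3.0, 0, 1)   # +60 in 3 h
        rel, absolute = true_spike_labels(t, rise)
        assert rel and absolute
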