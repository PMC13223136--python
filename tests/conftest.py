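"""Shared fixtures: one smoke-scale simulated cohort and one trained
forecaster/agent pair reused across the suite (session scope keeps the
whole run desk-scale)."""

import dataclasses

import numpy as np
import pytest

from cytodose.calibration_metrics import calibrate_forecaster
from cytodose.cpql_policy import CQLConfig, build_transitions, cql_train
from cytodose.latent_ctode import ForecasterConfig, train_forecaster
from cytodose.synthetic_cohort import SimConfig, Simulator, simulate_cohort

COHORT_SEED = 11


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_episodes=40, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return simulate_cohort(sim_config)


@pytest.fixture(scope="session")
def simulator(sim_config):
    return Simulator(sim_config)


@pytest.fixture(scope="session")
def episodes(cohort):
    return [c.episode for c in cohort]


@pytest.fixture(scope="session")
def trained(episodes):
    """(forecaster, train, calib, test) at smoke scale."""
    model, tr, ca, te = train_forecaster(episodes, seed=0)
    return model, tr, ca, te


@pytest.fixture(scope="session")
def forecaster(trained):
    return trained[0]


@pytest.fixture(scope="session")
def calibrator(trained):
    model, _, ca, _ = trained
    return calibrate_forecaster(model, ca)


@pytest.fixture(scope="session")
def transitions(cohort, forecaster):
    return build_transitions(cohort, forecaster)


@pytest.fixture(scope="session")
def agent(transitions):
    return cql_train(transitions, config=CQLConfig().smoke(), seed=0)


@pytest.fixture(scope="session")
def improvement_results():
    """True simulated returns {seed: (cpql, behavior)} on three cohort
    seeds; shared because the three train/rollout cycles dominate runtime."""
    from cytodose.ope_eval import CPQLRolloutPolicy, rollout_in_environment
    out = {}
    for seed in (0, 1, 2):
        cfg = SimConfig(n_episodes=40, seed=seed + 10)
        cohort = simulate_cohort(cfg)
        sim = Simulator(cfg)
        model, *_ = train_forecaster([c.episode for c in cohort], seed=seed)
        trans = build_transitions(cohort, model)
        ag = cql_train(trans, config=CQLConfig().smoke(), seed=seed)
        pol = CPQLRolloutPolicy(ag, model, project=True)
        stats, _ = rollout_in_environment(pol, cohort[:20], sim)
        base, _ = rollout_in_environment(None, cohort[:20], sim)
        out[seed] = (stats["return"], base["return"])
    return out
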