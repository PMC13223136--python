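"""End-to-end orchestration: simulate → pretrain+train forecaster →
calibrate → evaluate → build transitions → train policy → rollout → OPE →
explain, with per-stage manifests, checkpointing, and resumability.

Seeding: one global seed fans out to per-stage seeds through
``numpy.random.SeedSequence((global_seed, stage_index))`` — documented,
collision-free, and independent of execution order. Deterministic stages
rerun bit-identically from the same config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration_metrics as cm
from . import cpql_policy as cp
from . import ope_eval as oe
from .event_schema import ModalityVocabulary, Standardizer, write_episodes
from .event_transformer import EncoderConfig, EventEncoder
from .latent_ctode import (CTODEForecaster, ForecasterConfig, ODEConfig,
                           predictions_table, train_forecaster)
from .synthetic_cohort import SimConfig, Simulator, simulate_cohort

__all__ = ["run_pipeline", "stage_seed", "save_forecaster",
           "load_forecaster", "save_agent", "load_agent", "load_config",
           "STAGES"]

STAGES = ("simulate", "train-forecaster", "calibrate", "eval-forecaster",
          "build-transitions", "train-policy", "rollout", "ope", "explain")


def stage_seed(global_seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence((global_seed, idx))
               .generate_state(1)[0] % (2 ** 31))


def load_config(path=None) -> dict:
    cfg = {
        "data": {"n_episodes": 60, "seed": 0, "missingness": 0.48},
        "model": {"profile": "smoke", "epochs": 5, "pretrain": True,
                  "use_ct": True, "calibrate": True},
        "policy": {"steps": 600, "cql_weight": 5.0},
        "eval": {"rollout_episodes": 20},
    }
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            cfg.setdefault(k, {}).update(v or {})
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _write_manifest(out: Path, stage: str, cfg: dict, seed: int,
                    artifacts: list[str]):
    man = {"stage": stage, "config_hash": _config_hash(cfg), "seed": seed,
           "artifacts": sorted(artifacts),
           "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    (out / f"manifest_{stage.replace('-', '_')}.json").write_text(
        json.dumps(man, indent=2))


# --------------------------------------------------------------------------
# Checkpointing (npz weights + json metadata)

def _collect_forecaster_arrays(model: CTODEForecaster) -> dict:
    arrs = {f"enc__{k}": p.data for k, p in model.encoder.w.items()}
    for name, obj in (("init", model.init_map), ("dyn", model.dynamics)):
        for i, p in enumerate(obj.parameters()):
            arrs[f"{name}__{i}"] = p.data
    for name in ("w_mean", "b_mean", "w_sig", "b_sig", "w_map", "b_map"):
        arrs[f"head__{name}"] = getattr(model, name).data
    return arrs


def save_forecaster(model: CTODEForecaster, path):
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **_collect_forecaster_arrays(model))
    ode = dataclasses.asdict(model.cfg.ode)
    fc = dataclasses.asdict(model.cfg)
    fc["ode"] = ode
    meta = {"encoder_config": dataclasses.asdict(model.encoder.cfg),
            "forecaster_config": fc,
            "vocab": model.encoder.vocab.to_dict(),
            "standardizer": model.std.to_dict()}
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_forecaster(path) -> CTODEForecaster:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    enc_cfg = EncoderConfig(**meta["encoder_config"])
    fc_meta = dict(meta["forecaster_config"])
    fc_meta["ode"] = ODEConfig(**fc_meta["ode"])
    fc_cfg = ForecasterConfig(**fc_meta)
    vocab = ModalityVocabulary.from_dict(meta["vocab"])
    std = Standardizer.from_dict(meta["standardizer"])
    encoder = EventEncoder(enc_cfg, vocab)
    model = CTODEForecaster(encoder, std, fc_cfg)
    with np.load(path.with_suffix(".npz")) as data:
        for k, p in encoder.w.items():
            p.data = data[f"enc__{k}"]
        for name, obj in (("init", model.init_map), ("dyn", model.dynamics)):
            for i, p in enumerate(obj.parameters()):
                p.data = data[f"{name}__{i}"]
        for name in ("w_mean", "b_mean", "w_sig", "b_sig", "w_map", "b_map"):
            getattr(model, name).data = data[f"head__{name}"]
    return model


def save_agent(agent: cp.CQLAgent, path):
    path = Path(path)
    arrs = {}
    for i, p in enumerate(agent.actor.parameters()):
        arrs[f"actor__{i}"] = p.data
    for g, grp in enumerate(agent.critics):
        for k, q in enumerate(grp):
            for i, p in enumerate(q.parameters()):
                arrs[f"critic{g}_{k}__{i}"] = p.data
    np.savez(path.with_suffix(".npz"), **arrs)
    path.with_suffix(".json").write_text(json.dumps(
        {"config": dataclasses.asdict(agent.cfg),
         "state_dim": agent.state_dim}))


def load_agent(path) -> cp.CQLAgent:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    agent = cp.CQLAgent(meta["state_dim"], cp.CQLConfig(**meta["config"]))
    with np.load(path.with_suffix(".npz")) as data:
        for i, p in enumerate(agent.actor.parameters()):
            p.data = data[f"actor__{i}"]
        for g, grp in enumerate(agent.critics):
            for k, q in enumerate(grp):
                for i, p in enumerate(q.parameters()):
                    p.data = data[f"critic{g}_{k}__{i}"]
    agent._sync_targets()
    return agent


# --------------------------------------------------------------------------
# Pipeline

def run_pipeline(config: dict | None = None, out="pipeline_out",
                 ablate: set | None = None, force: bool = False) -> dict:
    """Run the full stage graph; stages with existing artifacts are skipped
    (delete a stage's files to recompute it). Returns artifact paths."""
    cfg = config or load_config()
    ablate = set(ablate or ())
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    gseed = int(cfg["data"].get("seed", 0))
    arts: dict = {}

    # -- simulate ----------------------------------------------------------
    ev_path, st_path = out / "events.csv", out / "static.csv"
    sim_cfg = SimConfig(n_episodes=int(cfg["data"]["n_episodes"]),
                        seed=stage_seed(gseed, "simulate"),
                        missingness=float(cfg["data"].get("missingness",
                                                          0.48)))
    cohort = simulate_cohort(sim_cfg)
    if force or not ev_path.exists():
        events, static = write_episodes([c.episode for c in cohort])
        events.to_csv(ev_path, index=False)
        static.to_csv(st_path, index=False)
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        pd.DataFrame({
            "episode_id": [c.episode.episode_id for c in cohort],
            "spike_relative": [c.spike_relative for c in cohort],
            "spike_absolute": [c.spike_absolute for c in cohort],
            "severity": [c.severity for c in cohort],
        }).to_csv(truth_dir / "labels.csv", index=False)
        _write_manifest(out, "simulate", cfg, sim_cfg.seed,
                        ["events.csv", "static.csv", "truth/labels.csv"])
    arts["events"], arts["static"] = ev_path, st_path

    episodes = [c.episode for c in cohort]

    # -- train-forecaster --------------------------------------------------
    fc_path = out / "forecaster"
    seed_fc = stage_seed(gseed, "train-forecaster")
    mcfg = cfg["model"]
    if force or not fc_path.with_suffix(".npz").exists():
        model, train, calib, test = train_forecaster(
            episodes, seed=seed_fc,
            pretrain=bool(mcfg.get("pretrain", True)) and "ssl" not in ablate,
            use_ct=bool(mcfg.get("use_ct", True)) and "ct" not in ablate)
        save_forecaster(model, fc_path)
        split = {"train": [e.episode_id for e in train],
                 "calib": [e.episode_id for e in calib],
                 "test": [e.episode_id for e in test],
                 "ablate": sorted(ablate)}
        (out / "splits.json").write_text(json.dumps(split))
        _write_manifest(out, "train-forecaster", cfg, seed_fc,
                        ["forecaster.npz", "splits.json"])
    model = load_forecaster(fc_path)
    split = json.loads((out / "splits.json").read_text())
    by_id = {e.episode_id: e for e in episodes}
    calib_eps = [by_id[i] for i in split["calib"]]
    test_eps = [by_id[i] for i in split["test"]]
    arts["forecaster"] = fc_path

    # -- calibrate ---------------------------------------------------------
    cal_path = out / "calibration.json"
    do_cal = bool(mcfg.get("calibrate", True)) and "calib" not in ablate
    if force or not cal_path.exists():
        calibrator = cm.calibrate_forecaster(model, calib_eps,
                                             enabled=do_cal)
        cal_path.write_text(json.dumps(
            {"temperature": calibrator.temperature.temps,
             "conformal": calibrator.conformal.offsets,
             "enabled": calibrator.enabled}))
        _write_manifest(out, "calibrate", cfg,
                        stage_seed(gseed, "calibrate"), ["calibration.json"])
    cal = json.loads(cal_path.read_text())
    calibrator = cm.Calibrator(cm.TemperatureParams(cal["temperature"]),
                               cm.ConformalOffsets(cal["conformal"]),
                               enabled=cal["enabled"])
    arts["calibration"] = cal_path

    # -- eval-forecaster ---------------------------------------------------
    metrics_path = out / "forecast_metrics.csv"
    if force or not metrics_path.exists():
        pairs = cm.matched_pairs(model, calibrator, test_eps)
        metrics = cm.forecast_metrics(pairs)
        # spike detection: model exceedance probability vs the ground-truth
        # relative-rise label over the 6 h after the forecast origin
        by_id = {c.episode.episode_id: c for c in cohort}
        scores, labels = [], []
        for ep in test_eps:
            se = by_id[ep.episode_id]
            origin = 4.0
            try:
                s = cm.spike_detector_score(model, calibrator, ep, origin)
            except ValueError:
                continue
            w = (se.t_grid_h >= origin) & (se.t_grid_h <= origin + 6.0)
            il6 = se.dense["il6"][w]
            rise = float(np.max(il6 - np.minimum.accumulate(il6)))
            labels.append(int(rise >= cm.RELATIVE_RISE_PGML))
            scores.append(s)
        try:
            auroc = cm.spike_auroc(scores, labels)
        except ValueError:
            auroc = float("nan")
        metrics = pd.concat([metrics, pd.DataFrame([{
            "cytokine": "il6", "horizon_h": 6.0, "mae": np.nan,
            "rmse": np.nan, "coverage90": np.nan, "crps": np.nan,
            "n": len(scores), "spike_auroc": auroc}])], ignore_index=True)
        metrics.insert(0, "model", "ctode" + ("".join(
            f"-{a}" for a in sorted(ablate)) if ablate else ""))
        metrics.to_csv(metrics_path, index=False)
        predictions_table(model, test_eps).to_csv(out / "predictions.csv",
                                                  index=False)
        _write_manifest(out, "eval-forecaster", cfg,
                        stage_seed(gseed, "eval-forecaster"),
                        ["forecast_metrics.csv", "predictions.csv"])
    arts["forecast_metrics"] = metrics_path

    # -- build-transitions -------------------------------------------------
    trans = cp.build_transitions(cohort, model)

    # -- train-policy ------------------------------------------------------
    ag_path = out / "agent"
    seed_pi = stage_seed(gseed, "train-policy")
    pcfg = cfg["policy"]
    if force or not ag_path.with_suffix(".npz").exists():
        ccfg = dataclasses.replace(cp.CQLConfig().smoke(),
                                   steps=int(pcfg.get("steps", 600)),
                                   cql_weight=float(pcfg.get("cql_weight",
                                                             5.0)))
        agent = cp.cql_train(trans, config=ccfg, seed=seed_pi)
        save_agent(agent, ag_path)
        _write_manifest(out, "train-policy", cfg, seed_pi, ["agent.npz"])
    agent = load_agent(ag_path)
    arts["agent"] = ag_path

    # -- rollout -----------------------------------------------------------
    roll_path = out / "rollout_outcomes.csv"
    n_eval = int(cfg["eval"].get("rollout_episodes", 20))
    sim = Simulator(sim_cfg)
    if force or not roll_path.exists():
        bc = oe.fit_behavior_cloning(trans)
        policies = {
            "behavior": None,
            "bc": oe.BCRolloutPolicy(bc, model),
            "rule-based": oe.RuleBasedRolloutPolicy(),
            "cpql": oe.CPQLRolloutPolicy(agent, model, project=True),
            "rl-unconstrained": oe.CPQLRolloutPolicy(agent, model,
                                                     project=False),
        }
        rows = []
        for name, pol in policies.items():
            stats, _ = oe.rollout_in_environment(pol, cohort[:n_eval], sim)
            stats["policy"] = name
            stats["environment"] = "simulator-truth"
            rows.append(stats)
        # learned-surrogate rollout of the proposed policy, side by side:
        # the gap to the simulator-truth row is the environment-model bias
        sur = oe.surrogate_rollout(
            oe.CPQLRolloutPolicy(agent, model, project=True),
            cohort[:n_eval], model)
        sur["policy"] = "cpql"
        sur["environment"] = "learned-surrogate"
        rows.append(sur)
        pd.DataFrame(rows).to_csv(roll_path, index=False)
        _write_manifest(out, "rollout", cfg, stage_seed(gseed, "rollout"),
                        ["rollout_outcomes.csv"])
    arts["rollout"] = roll_path

    # -- ope ---------------------------------------------------------------
    ope_path = out / "ope.csv"
    if force or not ope_path.exists():
        bc = oe.fit_behavior_cloning(trans)
        trajs = oe.group_trajectories(trans)
        discount = 0.99

        def eval_policy(act_fn, dens_fn, tag):
            is_, wis = oe.ope_is_wis(trajs, dens_fn, discount=discount)
            is_u, wis_u = oe.ope_is_wis(trajs, dens_fn, discount=1.0)
            fqe, qm = oe.ope_fqe(trans, act_fn, discount=discount,
                                 seed=seed_pi)
            dr = oe.ope_dr(trajs, dens_fn, qm, act_fn, discount=discount)
            return {"policy": tag, "IS": is_.raw, "WIS": wis.raw,
                    "DR": dr.raw, "FQE": fqe.raw,
                    "IS_undiscounted": is_u.raw,
                    "WIS_undiscounted": wis_u.raw}

        res_bc = eval_policy(bc.act, bc.density, "bc")
        res_pi = eval_policy(agent.act, agent.action_density, "cpql")
        rows = [res_bc, res_pi]
        norm_rows = []
        for r in rows:
            norm_rows.append({"policy": r["policy"], **{
                k: r[k] / res_bc[k] for k in ("IS", "WIS", "DR", "FQE")}})
        raw = pd.DataFrame(rows).assign(kind="raw")
        norm = pd.DataFrame(norm_rows).assign(kind="normalized_bc1")
        pd.concat([raw, norm]).to_csv(ope_path, index=False)
        _write_manifest(out, "ope", cfg, stage_seed(gseed, "ope"),
                        ["ope.csv"])
    arts["ope"] = ope_path

    # -- explain -----------------------------------------------------------
    pd_path = out / "partial_dependence.csv"
    if force or not pd_path.exists():
        from .interpret import partial_dependence
        curves = []
        for drug in ("propofol", "ketamine"):
            c = partial_dependence(model, episodes, drug,
                                   calibrator=calibrator)
            c["drug"] = drug
            curves.append(c)
        pd.concat(curves).to_csv(pd_path, index=False)
        _write_manifest(out, "explain", cfg, stage_seed(gseed, "explain"),
                        ["partial_dependence.csv"])
    arts["partial_dependence"] = pd_path
    return arts
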