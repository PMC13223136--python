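"""Off-policy evaluation, baseline policies, environment rollouts, Pareto sweep.

Estimators (all normalised so behavior cloning = 1.000):

* IS — per-decision importance sampling, V = mean_i Σ_t γ^t ρ^i_{0:t} r^i_t
  with cumulative ratios ρ of target to behavior action densities;
* WIS — the stepwise self-normalised variant (per-step weights sum to 1);
* DR — doubly robust: a fitted Q model supplies a control variate, so the
  estimator is consistent if *either* the density ratios or the Q model are
  correct; with a zero Q model it degenerates to IS exactly;
* FQE — fitted Q-evaluation, iterative regression of Bellman targets under
  the target policy; value = mean initial-state Q.

Behavior densities come either from the simulator's logged propensities
(oracle route, default on synthetic data) or from the fitted
behavior-cloning Gaussian (the route available on observational data).
Per-step ratios are clipped at 100 for variance control (disclosed in the
result metadata).

Rollouts execute a policy inside either the ground-truth simulator (exact
counterfactuals via the episode's frozen noise draws) or the learned
surrogate (latent dynamics + decoder heads), producing the full outcome
table: MAP-band occupancy, hypotension burden, MAP CV, vasopressor
initiation, IL-6 AUC, CRP peak, spike rate, IL-6/IL-10 ratio at 24 h, drug
exposure, unsafe-action and hard-violation rates, abstain rate.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor, no_grad
from .cpql_policy import (CQLAgent, CQLConfig, ConfidenceRamps, LatentPath,
                          RewardConfig, SafetyConfig, Transition,
                          _policy_features, build_transitions, compute_reward,
                          confidence_score, cql_train, project_action,
                          violates_constraints, _MLP)
from .latent_ctode import CTODEForecaster
from .synthetic_cohort import DT_H, SimulatedEpisode, Simulator

__all__ = [
    "BehaviorCloning", "fit_behavior_cloning", "rule_based_policy",
    "OPEResult", "ope_is_wis", "ope_dr", "ope_fqe", "tabular_policy_value",
    "group_trajectories", "rollout_in_environment", "episode_return",
    "pareto_sweep", "CPQLRolloutPolicy", "BCRolloutPolicy",
    "RuleBasedRolloutPolicy", "normalize_to_bc", "surrogate_rollout",
]

_WEIGHT_CLIP = 100.0


# --------------------------------------------------------------------------
# Baseline policies

@dataclass
class BehaviorCloning:
    """Max-likelihood Gaussian policy: linear mean + diagonal scale.

    Doubles as the fitted behavior-density model for IS/WIS when oracle
    propensities are unavailable.
    """

    coef: np.ndarray       # (state_dim + 1, 2)
    sigma: np.ndarray      # (2,)

    def mean(self, state: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(state)
        x = np.concatenate([s, np.ones((len(s), 1))], axis=1)
        out = x @ self.coef
        return out[0] if np.ndim(state) == 1 else out

    def act(self, state: np.ndarray) -> np.ndarray:
        return self.mean(state)

    def density(self, state: np.ndarray, action) -> float:
        mu = self.mean(state)
        d = (np.asarray(action, float) - mu) / self.sigma
        return float(np.exp(-0.5 * np.sum(d * d))
                     / (2.0 * math.pi * float(np.prod(self.sigma))))


def fit_behavior_cloning(transitions: list[Transition]) -> BehaviorCloning:
    if not transitions:
        raise ValueError("empty dataset")
    S = np.stack([t.state for t in transitions])
    A = np.stack([t.action for t in transitions])
    X = np.concatenate([S, np.ones((len(S), 1))], axis=1)
    coef, *_ = np.linalg.lstsq(X, A, rcond=None)
    resid = A - X @ coef
    sigma = np.maximum(resid.std(axis=0), 1e-3)
    return BehaviorCloning(coef, sigma)


def rule_based_policy(state: dict, depth_target: float = 52.0,
                      gain: float = 0.35) -> tuple[float, float]:
    """Protocolised titration: propofol toward the depth target, cut on
    hypotension, never ketamine (the protocol has no ketamine arm)."""
    if state["map"] < 65.0:
        d_rp = -5.0
    else:
        depth = state.get("depth", 95.0 - 0.75 * state["rp_prev"])
        d_rp = gain * (depth - depth_target)
    return float(np.clip(d_rp, -15.0, 15.0)), 0.0


# --------------------------------------------------------------------------
# OPE estimators

@dataclass(frozen=True)
class OPEResult:
    estimator: str
    raw: float
    normalized: float = math.nan
    n_excluded: int = 0
    weight_clip: float = _WEIGHT_CLIP


def group_trajectories(transitions: list[Transition]) -> list[list[Transition]]:
    by_ep: dict[str, list[Transition]] = {}
    for t in transitions:
        by_ep.setdefault(t.episode_id, []).append(t)
    return [sorted(v, key=lambda t: t.t_h) for v in by_ep.values()]


def _step_ratios(traj, target_density, behavior_density):
    """Per-step clipped density ratios, or None if behavior density is 0."""
    ratios = []
    for tr in traj:
        b = behavior_density(tr) if callable(behavior_density) \
            else tr.propensity
        if not np.isfinite(b) or b <= 0.0:
            return None
        p = target_density(tr.state, tr.action)
        ratios.append(min(p / b, _WEIGHT_CLIP))
    return np.array(ratios)


def ope_is_wis(trajectories, target_density, behavior_density=None,
               discount: float = 0.99):
    """Per-decision IS and stepwise WIS; returns (IS, WIS) results."""
    rho, rets, excluded = [], [], 0
    for traj in trajectories:
        r = _step_ratios(traj, target_density, behavior_density)
        if r is None:
            excluded += 1
            continue
        rho.append(np.cumprod(r))
        rets.append(np.array([tr.reward for tr in traj]))
    if not rho:
        raise ValueError("all trajectories excluded (zero behavior density)")
    T = max(len(r) for r in rho)
    n = len(rho)
    W = np.zeros((n, T))
    R = np.zeros((n, T))
    for i, (w, r) in enumerate(zip(rho, rets)):
        W[i, :len(w)] = w
        W[i, len(w):] = w[-1]     # carry final weight past termination
        R[i, :len(r)] = r
    g = discount ** np.arange(T)
    v_is = float(np.mean(np.sum(W * R * g, axis=1)))
    wsum = W.sum(axis=0)
    wn = np.divide(W, wsum, out=np.zeros_like(W), where=wsum > 0)
    v_wis = float(np.sum(np.sum(wn * R, axis=0) * g))
    return (OPEResult("IS", v_is, n_excluded=excluded),
            OPEResult("WIS", v_wis, n_excluded=excluded))


def ope_dr(trajectories, target_density, q_model, target_policy_act,
           behavior_density=None, discount: float = 0.99) -> OPEResult:
    """Per-decision doubly robust estimator.

    ``q_model(states, actions) -> values``; a zero model degenerates to IS.
    """
    vals, excluded = [], 0
    for traj in trajectories:
        r = _step_ratios(traj, target_density, behavior_density)
        if r is None:
            excluded += 1
            continue
        rho = np.cumprod(r)
        v = 0.0
        for t, tr in enumerate(traj):
            q_sa = float(q_model(tr.state[None, :], tr.action[None, :])[0])
            a_pi = np.asarray(target_policy_act(tr.state), float)
            v_s = float(q_model(tr.state[None, :], a_pi[None, :])[0])
            rho_prev = rho[t - 1] if t > 0 else 1.0
            v += discount ** t * (rho[t] * (tr.reward - q_sa)
                                  + rho_prev * v_s)
        vals.append(v)
    if not vals:
        raise ValueError("all trajectories excluded (zero behavior density)")
    return OPEResult("DR", float(np.mean(vals)), n_excluded=excluded)


class FQEModel:
    """Iteratively fitted Q under a fixed target policy (neural route)."""

    def __init__(self, state_dim: int, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed + 11)
        self.net = _MLP([state_dim + 2, hidden, hidden, 1], rng)
        self.target = _MLP([state_dim + 2, hidden, hidden, 1], rng)
        self.target.copy_from(self.net)

    def __call__(self, states, actions):
        x = Tensor(np.concatenate([np.atleast_2d(states),
                                   np.atleast_2d(actions)], axis=1))
        with no_grad():
            return self.net(x).data[:, 0]


def ope_fqe(transitions: list[Transition], target_policy_act,
            discount: float = 0.99, iterations: int = 30,
            inner_steps: int = 40, batch_size: int = 128, seed: int = 0,
            reward_bound: float = RewardConfig().alpha) -> tuple[OPEResult,
                                                                 FQEModel]:
    """Fitted Q-evaluation; value = mean Q at trajectory initial states."""
    if not transitions:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed + 23)
    S = np.stack([t.state for t in transitions])
    A = np.stack([t.action for t in transitions])
    R = np.array([t.reward for t in transitions])
    S2 = np.stack([t.next_state for t in transitions])
    D = np.array([float(t.terminal) for t in transitions])
    A2 = np.stack([np.asarray(target_policy_act(s), float) for s in S2])
    model = FQEModel(S.shape[1], seed=seed)
    opt = Adam(model.net.parameters(), lr=1e-3)
    bound = abs(reward_bound) + max(np.max(np.abs(R)), 1e-9)
    vmax = bound / (1.0 - discount)
    for _ in range(iterations):
        with no_grad():
            x2 = Tensor(np.concatenate([S2, A2], axis=1))
            y = R + discount * (1.0 - D) * model.target(x2).data[:, 0]
        for _ in range(inner_steps):
            idx = rng.integers(0, len(S), batch_size)
            xb = Tensor(np.concatenate([S[idx], A[idx]], axis=1))
            diff = model.net(xb)[:, 0] - Tensor(y[idx])
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        model.target.copy_from(model.net)
    init_states = np.stack([traj[0].state
                            for traj in group_trajectories(transitions)])
    init_actions = np.stack([np.asarray(target_policy_act(s), float)
                             for s in init_states])
    v = float(np.mean(model(init_states, init_actions)))
    if abs(v) > 2.0 * vmax:
        raise RuntimeError(f"FQE diverged: |{v:.2f}| exceeds bound {vmax:.2f}")
    return OPEResult("FQE", v), model


def tabular_policy_value(P: np.ndarray, R: np.ndarray, policy: np.ndarray,
                         discount: float) -> np.ndarray:
    """Exact policy evaluation by linear solve (oracle for FQE tests):
    v = (I − γ P_π)^{-1} r_π."""
    S = R.shape[0]
    P_pi = np.einsum("sa,sat->st", policy, P)
    r_pi = np.einsum("sa,sa->s", policy, R)
    return np.linalg.solve(np.eye(S) - discount * P_pi, r_pi)


def normalize_to_bc(results: dict[str, float],
                    bc_values: dict[str, float]) -> dict[str, OPEResult]:
    """Normalise raw estimates so BC ≡ 1.000 per estimator."""
    out = {}
    for k, v in results.items():
        out[k] = OPEResult(k, v, normalized=v / bc_values[k])
    return out


# --------------------------------------------------------------------------
# Rollout policies (closed-loop adapters over the simulator state dict)

class RuleBasedRolloutPolicy:
    name = "rule-based"
    uses_projection = True

    def reset(self, sim_episode):
        pass

    def __call__(self, state: dict, rng) -> tuple[float, float]:
        d_rp, rk = rule_based_policy(state)
        (d_rp, rk), _ = project_action((d_rp, rk), state["rp_prev"],
                                       state["rk_prev"])
        return d_rp, rk


class _FeaturePolicyBase:
    """Shares feature construction between CPQL and BC rollout adapters."""

    def __init__(self, forecaster: CTODEForecaster):
        self.fc = forecaster
        self.path = None
        self.rp_cum = 0.0
        self.rk_cum = 0.0
        self.unsafe = 0
        self.violations = 0
        self.abstained = 0
        self.steps = 0

    def reset(self, sim_episode: SimulatedEpisode):
        self.path = LatentPath(self.fc, sim_episode.episode)
        self.rp_cum = 0.0
        self.rk_cum = 0.0

    def features(self, state: dict) -> np.ndarray:
        rates = np.array([state["rp_prev"], state["rk_prev"], state["vaso"]])
        z = self.path.advance(state["t_h"], rates)
        self.rp_cum += state["rp_prev"] * 5.0
        self.rk_cum += state["rk_prev"] * 5.0
        return _policy_features(state["map"], state["hr"], state["spo2"],
                                state["rp_prev"], state["rk_prev"],
                                self.rp_cum, self.rk_cum, state["vaso"],
                                state["depth"], state["t_h"], z)


class CPQLRolloutPolicy(_FeaturePolicyBase):
    def __init__(self, agent: CQLAgent, forecaster: CTODEForecaster,
                 project: bool = True, abstain: bool = False,
                 ramps: ConfidenceRamps | None = None,
                 safety: SafetyConfig = SafetyConfig()):
        super().__init__(forecaster)
        self.agent = agent
        self.project = project
        self.abstain = abstain
        self.ramps = ramps or ConfidenceRamps()
        self.safety = safety
        self.name = "cpql" if project else "rl-unconstrained"
        self.uses_projection = project

    def __call__(self, state: dict, rng) -> tuple[float, float]:
        feats = self.features(state)
        proposal = self.agent.act(feats)
        self.steps += 1
        if violates_constraints(proposal, state["rp_prev"],
                                state["rk_prev"], self.safety):
            self.unsafe += 1
        if self.project:
            (d_rp, rk), _ = project_action(proposal, state["rp_prev"],
                                           state["rk_prev"], self.safety)
        else:
            d_rp, rk = float(proposal[0]), float(proposal[1])
        if violates_constraints((d_rp, rk), state["rp_prev"],
                                state["rk_prev"], self.safety):
            self.violations += 1
        if self.abstain:
            with no_grad():
                _, sig = self.fc.heads(self.path.z)
            width = 2 * 1.6449 * float(sig.data[0])
            qv = float(self.agent.q_values(
                feats[None, :], np.array([[d_rp, rk]])).var(axis=1)[0])
            score, abst, _ = confidence_score(width, 3.0, qv, self.ramps)
            if abst:
                self.abstained += 1
                return 0.0, state["rk_prev"]    # defer: hold current rates
        return d_rp, rk


class BCRolloutPolicy(_FeaturePolicyBase):
    name = "bc"
    uses_projection = True

    def __init__(self, bc: BehaviorCloning, forecaster: CTODEForecaster,
                 safety: SafetyConfig = SafetyConfig()):
        super().__init__(forecaster)
        self.bc = bc
        self.safety = safety

    def __call__(self, state: dict, rng) -> tuple[float, float]:
        proposal = self.bc.act(self.features(state))
        if violates_constraints(proposal, state["rp_prev"],
                                state["rk_prev"], self.safety):
            self.unsafe += 1
        (d_rp, rk), _ = project_action(proposal, state["rp_prev"],
                                       state["rk_prev"], self.safety)
        return d_rp, rk


# --------------------------------------------------------------------------
# Ground-truth rollouts and outcome statistics

def episode_return(sim_episode: SimulatedEpisode,
                   reward_cfg: RewardConfig = RewardConfig(),
                   discount: float | None = None) -> float:
    """True return of an episode from its noise-free trajectories."""
    tg = sim_episode.t_grid_h
    il6 = sim_episode.dense["il6"]
    total = 0.0
    for j, i in enumerate(sim_episode.decision_steps):
        t = tg[i]
        mask = (tg >= t) & (tg <= t + 6.0)
        auc = float(np.trapezoid(il6[mask], tg[mask]))
        r = compute_reward(float(sim_episode.dense["map"][i]), auc,
                           float(sim_episode.doses["rp"][i]),
                           float(sim_episode.doses["rk"][i]), reward_cfg)
        total += r if discount is None else discount ** j * r
    return total


def rollout_in_environment(policy, cohort: list[SimulatedEpisode],
                           simulator: Simulator,
                           reward_cfg: RewardConfig = RewardConfig()):
    """Re-run each episode's frozen noise under ``policy`` (None = logged
    behavior) in the ground-truth simulator; returns (outcome row dict,
    list of counterfactual SimulatedEpisodes)."""
    episodes = []
    for se in cohort:
        if policy is None:
            episodes.append(se)
            continue
        if hasattr(policy, "reset"):
            policy.reset(se)
        static = se.episode.static
        base = _base_from_sim(se)
        cf = simulator.run_episode(se.episode.episode_id, static, base,
                                   se.noise_handle, policy=policy)
        episodes.append(cf)
    stats = outcome_statistics(episodes, reward_cfg)
    if policy is not None and hasattr(policy, "steps") and policy.steps:
        stats["unsafe_pct"] = 100.0 * policy.unsafe / policy.steps
        stats["violation_pct"] = 100.0 * policy.violations / policy.steps
        stats["abstain_pct"] = 100.0 * policy.abstained / policy.steps
    return stats, episodes


def _base_from_sim(se: SimulatedEpisode) -> dict:
    d = {
        "il6": se.dense["il6"][0], "crp": se.dense["crp"][0],
        "tnfa": se.dense["tnfa"][0], "il10": se.dense["il10"][0],
        "map": se.dense["map"][0], "map_base": se.dense["map"][0],
        "hr": 84.0, "op_min": se.op_end_h * 60.0, "severity": se.severity,
        "rp0": float(se.doses["rp"][0]),
    }
    return d


def outcome_statistics(episodes: list[SimulatedEpisode],
                       reward_cfg: RewardConfig = RewardConfig()) -> dict:
    rows = {
        "map_in_band_pct": [], "map_below65_pct": [], "map_cv_pct": [],
        "vaso_initiation": [], "il6_auc": [], "crp_peak": [],
        "spike": [], "il6_il10_24h": [], "propofol_total": [],
        "ketamine_mean": [], "return": [],
    }
    for se in episodes:
        op = se.t_grid_h <= se.op_end_h
        m = se.dense["map"][op]
        rows["map_in_band_pct"].append(100.0 * np.mean((m >= 65) & (m <= 90)))
        rows["map_below65_pct"].append(100.0 * np.mean(m < 65))
        rows["map_cv_pct"].append(100.0 * m.std() / m.mean())
        rows["vaso_initiation"].append(float(se.doses["vaso"].max() > 0))
        rows["il6_auc"].append(float(np.trapezoid(se.dense["il6"],
                                                  se.t_grid_h)))
        rows["crp_peak"].append(float(se.dense["crp"].max()))
        rows["spike"].append(float(se.spike_absolute))
        rows["il6_il10_24h"].append(
            float(se.dense["il6"][-1] / max(se.dense["il10"][-1], 1e-9)))
        rows["propofol_total"].append(
            float(np.sum(se.doses["rp"]) * DT_H * 60.0))   # mcg/kg
        in_op_rk = se.doses["rk"][op]
        rows["ketamine_mean"].append(float(in_op_rk.mean()))
        rows["return"].append(episode_return(se, reward_cfg))
    return {k: float(np.mean(v)) for k, v in rows.items()}


# --------------------------------------------------------------------------
# Learned-surrogate rollouts

def surrogate_rollout(policy, cohort: list[SimulatedEpisode],
                      forecaster: CTODEForecaster,
                      reward_cfg: RewardConfig = RewardConfig()) -> dict:
    """Execute a policy inside the *learned* environment: the forecaster's
    latent dynamics advance under the chosen controls on the 5-min grid, and
    the MAP / IL-6 decoder heads supply the physiological feedback.

    Returns Table-3-style statistics computed from the predicted
    trajectories; comparing them with the ground-truth rollout quantifies
    environment-model bias.
    """
    import math as _m
    from .autodiff import no_grad
    stats = {"map_in_band_pct": [], "map_below65_pct": [], "il6_auc": [],
             "ketamine_mean": [], "propofol_total": [], "return": []}
    for se in cohort:
        try:
            path = LatentPath(forecaster, se.episode)
        except ValueError:
            continue
        if hasattr(policy, "reset") and policy is not None:
            policy.reset(se)
        rp = float(se.doses["rp"][0])
        rk, vaso = 0.0, 0.0
        maps, il6s, rks, rps, rewards = [], [], [], [], []
        t = path.t
        while t < se.op_end_h:
            with no_grad():
                mu, _ = forecaster.heads(path.z)
                map_hat = float(forecaster.map_head(path.z).data)
                il6_hat = _m.expm1(float(mu.data[0]))
            state = {"t_h": t, "map": map_hat, "hr": 80.0, "spo2": 97.0,
                     "rp_prev": rp, "rk_prev": rk, "vaso": vaso,
                     "depth": 95.0 - 0.75 * rp, "rp_effect": rp}
            if policy is None:
                d_rp, new_rk = 0.0, rk
            else:
                d_rp, new_rk = policy(state, None)
            rp = float(np.clip(rp + d_rp, 0.0, 100.0))
            rk = float(np.clip(new_rk, 0.0, 20.0))
            if map_hat < 63.0:
                vaso = min(0.5, vaso + 0.05)
            elif map_hat > 78.0 and vaso > 0:
                vaso = max(0.0, vaso - 0.05)
            auc6 = path.forecast_il6_auc_6h(np.array([rp, rk, vaso]))
            rewards.append(compute_reward(map_hat, auc6, rp, rk, reward_cfg))
            maps.append(map_hat)
            il6s.append(il6_hat)
            rps.append(rp)
            rks.append(rk)
            t += DT_H
            path.advance(t, np.array([rp, rk, vaso]))
        if not maps:
            continue
        m = np.array(maps)
        stats["map_in_band_pct"].append(100.0 * np.mean((m >= 65)
                                                        & (m <= 90)))
        stats["map_below65_pct"].append(100.0 * np.mean(m < 65))
        stats["il6_auc"].append(float(np.trapezoid(
            il6s, dx=DT_H)))
        stats["ketamine_mean"].append(float(np.mean(rks)))
        stats["propofol_total"].append(float(np.sum(rps) * DT_H * 60.0))
        stats["return"].append(float(np.sum(rewards)))
    return {k: float(np.mean(v)) for k, v in stats.items() if v}


# --------------------------------------------------------------------------
# Pareto sweep over the haemodynamic reward weight

def sweep_reward_config(w: float) -> RewardConfig:
    """w ∈ [0, 1]: 0 = pure IL-6 minimisation, 1 = pure MAP stability;
    w = 0.5 recovers the default coefficients."""
    return RewardConfig(alpha=2.0 * (w / 0.5),
                        beta=0.01 * ((1.0 - w) / 0.5),
                        gamma=0.005 * ((1.0 - w) / 0.5),
                        delta=0.02 * ((1.0 - w) / 0.5))


def pareto_sweep(cohort: list[SimulatedEpisode], forecaster: CTODEForecaster,
                 simulator: Simulator, weights=None, seed: int = 0,
                 cql_config: CQLConfig | None = None,
                 eval_episodes: int = 20) -> pd.DataFrame:
    """Train a reduced-budget policy per reward weight, evaluate by rollout.

    Returns a frontier table (weight, MAP-stability objective, IL-6
    objective, non-dominated flag).
    """
    weights = np.round(np.arange(0.0, 1.0001, 0.05), 3) if weights is None \
        else np.asarray(weights, float)
    if weights.min() < 0 or weights.max() > 1:
        raise ValueError("sweep weights must lie in [0, 1]")
    cfg = cql_config or dataclasses.replace(CQLConfig().smoke(), steps=150)
    rows = []
    for w in weights:
        rcfg = sweep_reward_config(float(w))
        trans = build_transitions(cohort, forecaster, reward_cfg=rcfg)
        agent = cql_train(trans, config=cfg, seed=seed)
        pol = CPQLRolloutPolicy(agent, forecaster, project=True)
        stats, _ = rollout_in_environment(pol, cohort[:eval_episodes],
                                          simulator, reward_cfg=rcfg)
        rows.append((float(w), stats["map_in_band_pct"], stats["il6_auc"]))
    df = pd.DataFrame(rows, columns=["weight", "map_stability", "il6_auc"])
    dominated = []
    for i, r in df.iterrows():
        dom = any((o["map_stability"] >= r["map_stability"])
                  and (o["il6_auc"] <= r["il6_auc"])
                  and ((o["map_stability"] > r["map_stability"])
                       or (o["il6_auc"] < r["il6_auc"]))
                  for j, o in df.iterrows() if j != i)
        dominated.append(dom)
    df["non_dominated"] = ~np.asarray(dominated)
    return df
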