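"""Safety-constrained conservative dosing agent.

State, on the 5-min decision grid: 30-min rolling vitals (MAP, HR, SpO2),
the forecaster's latent z(t) (encoded once from the admission prefix, then
propagated continuously under the applied infusions), cumulative propofol and
ketamine, vasopressor and fluid rates, and the depth-of-anesthesia proxy.

Action: (Δ propofol rate ∈ [−15, +15], ketamine rate ∈ [0, 20]) mcg/kg/min.

Reward (per step): R = α·1[MAP ∈ [65,90]] − β·IL6AUC(t, t+6 h)
− γ·r_p − δ·max(r_k − r_k_ref, 0), with (α, β, γ, δ) = (2.0, 0.01, 0.005,
0.02) and r_k_ref = 10; the IL-6 area term is in pg·h/mL, from either the
forecaster (predicted AUC via trapezoid over horizon medians) or, for oracle
experiments on synthetic data, the simulator's noise-free truth.

Learning is conservative Q-learning: Bellman error plus a penalty
E_μ[Q] − E_D[Q] (logsumexp over uniform-in-box and current-policy action
samples) that depresses Q off the data manifold. Two independently
initialised critic ensembles (min-of-means target) and a tanh-squashed actor
rescaled to the action box. Hard safety is *post-hoc projection*: clip to the
action box, then to per-5-min titration limits (propofol ≤ 20, ketamine ≤ 5)
and absolute ceilings (100 / 20) — a total, idempotent function applied to
every emitted recommendation.

An abstain gate scores confidence on [0, 5] from the calibrated IL-6 PI
width, the recency/density of lab observations, and the critic-ensemble
variance (piecewise-linear ramps frozen at the training cohort's 5th/95th
percentiles); below θ = 2.5 the agent withholds the recommendation and names
the worst component.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Adam, Parameter, Tensor, concat, no_grad
from .event_schema import Episode
from .latent_ctode import CTODEForecaster, propagate
from .synthetic_cohort import DT_H, SimulatedEpisode

__all__ = [
    "RewardConfig", "SafetyConfig", "AbstainConfig", "Transition",
    "compute_reward", "project_action", "violates_constraints",
    "build_transitions", "CQLConfig", "CQLAgent", "cql_train",
    "tabular_cql", "ConfidenceRamps", "confidence_score", "recommend",
]


@dataclass(frozen=True)
class RewardConfig:
    alpha: float = 2.0
    beta: float = 0.01
    gamma: float = 0.005
    delta: float = 0.02
    rk_ref: float = 10.0
    map_band: tuple = (65.0, 90.0)


@dataclass(frozen=True)
class SafetyConfig:
    propofol_ceiling: float = 100.0
    ketamine_ceiling: float = 20.0
    propofol_step: float = 20.0      # per 5-min interval
    ketamine_step: float = 5.0
    drp_lo: float = -15.0
    drp_hi: float = 15.0


@dataclass(frozen=True)
class AbstainConfig:
    threshold: float = 2.5           # on the 0–5 composite
    weights: tuple = (1.0, 1.0, 1.0)  # (PI width, obs density, Q variance)
    stale_lab_h: float = 12.0


def compute_reward(map_mmhg: float, il6_auc_6h: float, propofol_rate: float,
                   ketamine_rate: float,
                   cfg: RewardConfig = RewardConfig()) -> float:
    lo, hi = cfg.map_band
    in_band = 1.0 if lo <= map_mmhg <= hi else 0.0
    return (cfg.alpha * in_band - cfg.beta * il6_auc_6h
            - cfg.gamma * propofol_rate
            - cfg.delta * max(ketamine_rate - cfg.rk_ref, 0.0))


def project_action(action, prev_propofol: float, prev_ketamine: float,
                   cfg: SafetyConfig = SafetyConfig()):
    """Clip (Δrp, rk) to the action box, titration limits and ceilings.

    Total and idempotent; returns ((Δrp, rk), projected_flag).
    """
    d_rp, rk = float(action[0]), float(action[1])
    d0, k0 = d_rp, rk
    d_rp = float(np.clip(d_rp, cfg.drp_lo, cfg.drp_hi))
    d_rp = float(np.clip(d_rp, -cfg.propofol_step, cfg.propofol_step))
    new_rp = float(np.clip(prev_propofol + d_rp, 0.0, cfg.propofol_ceiling))
    d_rp = new_rp - prev_propofol
    rk = float(np.clip(rk, prev_ketamine - cfg.ketamine_step,
                       prev_ketamine + cfg.ketamine_step))
    rk = float(np.clip(rk, 0.0, cfg.ketamine_ceiling))
    projected = abs(d_rp - d0) > 1e-9 or abs(rk - k0) > 1e-9
    return (d_rp, rk), projected


def violates_constraints(action, prev_propofol: float, prev_ketamine: float,
                         cfg: SafetyConfig = SafetyConfig(),
                         tol: float = 1e-9) -> bool:
    """True if (Δrp, rk) breaches any ceiling, box or rate limit."""
    d_rp, rk = float(action[0]), float(action[1])
    new_rp = prev_propofol + d_rp
    return (d_rp < cfg.drp_lo - tol or d_rp > cfg.drp_hi + tol
            or abs(d_rp) > cfg.propofol_step + tol
            or new_rp < -tol or new_rp > cfg.propofol_ceiling + tol
            or rk < -tol or rk > cfg.ketamine_ceiling + tol
            or abs(rk - prev_ketamine) > cfg.ketamine_step + tol)


# --------------------------------------------------------------------------
# Offline dataset

@dataclass
class Transition:
    state: np.ndarray
    action: np.ndarray          # (Δrp, rk)
    reward: float
    next_state: np.ndarray
    propensity: float
    terminal: bool
    episode_id: str = ""
    t_h: float = 0.0


_SCALAR_SCALE = np.array([80.0, 80.0, 100.0, 50.0, 10.0, 8000.0, 1500.0,
                          0.2, 60.0, 12.0])


class LatentPath:
    """z(t) along an episode: one admission-prefix encode, then continuous
    propagation under the applied infusion rates."""

    def __init__(self, forecaster: CTODEForecaster, episode: Episode,
                 origin_h: float = 0.5):
        self.fc = forecaster
        self.origin_h = origin_h
        with no_grad():
            self.z = forecaster.initial_latent(episode, origin_h)
        self.t = origin_h

    def advance(self, t_h: float, rates: np.ndarray):
        """Propagate to t_h holding ``rates`` (rp, rk, vaso) constant."""
        if t_h <= self.t:
            return self.z.data
        if self.fc.cfg.use_ct:
            with no_grad():
                self.z = propagate(self.z, self.t, t_h,
                                   lambda _t: rates, self.fc.dynamics,
                                   self.fc.cfg.ode)
        self.t = t_h
        return self.z.data

    def forecast_il6_auc_6h(self, rates: np.ndarray) -> float:
        """Predicted IL-6 AUC (pg·h/mL) over the next 6 h, trapezoid over
        horizon medians under held-constant rates."""
        with no_grad():
            z = self.z
            t_prev = self.t
            ys = []
            mu, _ = self.fc.heads(z)
            ys.append(math.expm1(float(mu.data[0])))
            for h in (2.0, 4.0, 6.0):
                if self.fc.cfg.use_ct:
                    z = propagate(z, t_prev, self.t + h, lambda _t: rates,
                                  self.fc.dynamics, self.fc.cfg.ode)
                t_prev = self.t + h
                mu, _ = self.fc.heads(z)
                ys.append(math.expm1(float(mu.data[0])))
        return float(np.trapezoid(ys, [0.0, 2.0, 4.0, 6.0]))


def _policy_features(map30, hr30, spo2_30, rp_prev, rk_prev, rp_cum, rk_cum,
                     vaso, depth, t_h, z: np.ndarray) -> np.ndarray:
    scal = np.array([map30, hr30, spo2_30, rp_prev, rk_prev, rp_cum, rk_cum,
                     vaso, depth, t_h])
    return np.concatenate([scal / _SCALAR_SCALE, z])


def build_transitions(cohort: list[SimulatedEpisode],
                      forecaster: CTODEForecaster,
                      reward_cfg: RewardConfig = RewardConfig(),
                      auc_source: str = "truth") -> list[Transition]:
    """Harvest offline RL tuples from simulated episodes on the decision grid.

    ``auc_source='truth'`` integrates the simulator's noise-free IL-6 over
    [t, t+6 h] (oracle experiments); ``'forecast'`` uses the model's
    predicted AUC.
    """
    out = []
    for se in cohort:
        ep = se.episode
        try:
            path = LatentPath(forecaster, ep)
        except ValueError:
            continue
        tg = se.t_grid_h
        steps = se.decision_steps
        dense_il6 = se.dense["il6"]
        states = []
        for j, i in enumerate(steps):
            t = tg[i]
            rates = np.array([se.doses["rp"][i], se.doses["rk"][i],
                              se.doses["vaso"][i]])
            z = path.advance(t, rates)
            w = tg[steps] <= t
            w30 = (tg >= t - 0.5) & (tg <= t)
            rp_cum = float(np.sum(se.doses["rp"][:i]) * DT_H * 60.0)
            rk_cum = float(np.sum(se.doses["rk"][:i]) * DT_H * 60.0)
            states.append(_policy_features(
                float(se.dense["map"][w30].mean()), 80.0, 97.0,
                float(se.doses["rp"][i]), float(se.doses["rk"][i]),
                rp_cum, rk_cum, float(se.doses["vaso"][i]),
                95.0 - 0.75 * se.doses["rp"][i], t, z))
        for j in range(len(steps)):
            i = steps[j]
            t = tg[i]
            if auc_source == "truth":
                mask = (tg >= t) & (tg <= t + 6.0)
                auc = float(np.trapezoid(dense_il6[mask], tg[mask]))
            else:
                rates = np.array([se.doses["rp"][i], se.doses["rk"][i],
                                  se.doses["vaso"][i]])
                auc = path.forecast_il6_auc_6h(rates)
            r = compute_reward(float(se.dense["map"][i]), auc,
                               float(se.doses["rp"][i]),
                               float(se.doses["rk"][i]), reward_cfg)
            terminal = j == len(steps) - 1
            out.append(Transition(
                state=states[j], action=se.actions[j].copy(), reward=r,
                next_state=states[j] if terminal else states[j + 1],
                propensity=float(se.propensities[j]), terminal=terminal,
                episode_id=ep.episode_id, t_h=float(t)))
    return out


# --------------------------------------------------------------------------
# Networks

class _MLP:
    def __init__(self, dims, rng, out_scale=1.0):
        self.W, self.b = [], []
        for i in range(len(dims) - 1):
            s = (2.0 / (dims[i] + dims[i + 1])) ** 0.5
            if i == len(dims) - 2:
                s *= out_scale
            self.W.append(Parameter(rng.normal(0, s, (dims[i], dims[i + 1]))))
            self.b.append(Parameter(np.zeros(dims[i + 1])))

    def __call__(self, x: Tensor) -> Tensor:
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            x = x @ W + b
            if i < len(self.W) - 1:
                x = x.tanh()
        return x

    def parameters(self):
        return self.W + self.b

    def copy_from(self, other: "_MLP"):
        for p, q in zip(self.parameters(), other.parameters()):
            p.data = q.data.copy()


@dataclass(frozen=True)
class CQLConfig:
    """Continuous-action conservative Q-learning hyper-parameters."""

    ensemble_size: int = 5            # K per critic group (two groups)
    hidden: int = 64
    cql_weight: float = 1.0           # OOD penalty weight
    discount: float = 0.99            # per 5-min step
    batch_size: int = 64
    steps: int = 600
    actor_lr: float = 3e-4
    critic_lr: float = 1e-3
    target_update_every: int = 50
    n_ood_actions: int = 4            # uniform + policy samples each
    actor_sigma: float = 1.5          # Gaussian head for densities (OPE)
    bc_warmstart_steps: int = 200     # supervised actor init on data actions
    baseline_reward: bool = True      # subtract a state-only reward baseline
    # (ridge fit) before critic training; preserves the greedy policy while
    # removing patient-severity variance from the Bellman targets

    def smoke(self) -> "CQLConfig":
        """Desk-scale profile: smaller ensembles, stronger conservatism
        (stabilises the greedy step at small sample sizes)."""
        return dataclasses.replace(self, ensemble_size=2, steps=1000,
                                   cql_weight=5.0, actor_lr=3e-3)


class CQLAgent:
    """Tanh-squashed actor + two conservative critic ensembles."""

    def __init__(self, state_dim: int, cfg: CQLConfig = CQLConfig(),
                 seed: int = 0, safety: SafetyConfig = SafetyConfig()):
        self.cfg = cfg
        self.safety = safety
        self.state_dim = state_dim
        rng = np.random.default_rng(seed + 31)
        self.actor = _MLP([state_dim, cfg.hidden, cfg.hidden, 2], rng,
                          out_scale=0.1)
        self.critics = [[_MLP([state_dim + 2, cfg.hidden, cfg.hidden, 1], rng)
                         for _ in range(cfg.ensemble_size)] for _ in range(2)]
        self.targets = [[_MLP([state_dim + 2, cfg.hidden, cfg.hidden, 1], rng)
                         for _ in range(cfg.ensemble_size)] for _ in range(2)]
        self._sync_targets()
        self.loss_history: list[dict] = []

    def _sync_targets(self):
        for grp, tgrp in zip(self.critics, self.targets):
            for q, tq in zip(grp, tgrp):
                tq.copy_from(q)

    # -- action maps --------------------------------------------------------
    @staticmethod
    def _squash(raw: np.ndarray) -> np.ndarray:
        t = np.tanh(raw)
        return np.stack([15.0 * t[..., 0], 10.0 * (t[..., 1] + 1.0)], axis=-1)

    def act(self, state: np.ndarray) -> np.ndarray:
        with no_grad():
            raw = self.actor(Tensor(state)).data
        return self._squash(raw)

    def action_density(self, state: np.ndarray, action) -> float:
        """Gaussian density around the deterministic actor output (used as
        the target-policy density for importance-weighted OPE)."""
        mu = self.act(state)
        s = self.cfg.actor_sigma
        d = (np.asarray(action, float) - mu) / s
        return float(np.exp(-0.5 * np.sum(d * d))
                     / (2.0 * math.pi * s * s))

    def q_values(self, states: np.ndarray, actions: np.ndarray) -> np.ndarray:
        """(n, 2K) critic matrix for ensemble variance / pessimism checks."""
        x = Tensor(np.concatenate([np.atleast_2d(states),
                                   np.atleast_2d(actions)], axis=1))
        with no_grad():
            cols = [q(x).data[:, 0] for grp in self.critics for q in grp]
        return np.stack(cols, axis=1)

    def _warmstart_actor(self, S, A, steps: int, rng):
        """Supervised init of the actor at the dataset's action manifold."""
        a1 = np.clip(A[:, 0] / 15.0, -0.95, 0.95)
        a2 = np.clip(A[:, 1] / 10.0 - 1.0, -0.95, 0.95)
        raw_t = np.arctanh(np.stack([a1, a2], axis=1))
        opt = Adam(self.actor.parameters(), lr=3e-3)
        for _ in range(steps):
            idx = rng.integers(0, len(S), 64)
            diff = self.actor(Tensor(S[idx])) - Tensor(raw_t[idx])
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()

    # -- training -----------------------------------------------------------
    def train(self, transitions: list[Transition], seed: int = 0,
              steps: int | None = None):
        if not transitions:
            raise ValueError("empty offline dataset")
        cfg = self.cfg
        steps = steps if steps is not None else cfg.steps
        rng = np.random.default_rng(seed + 77)
        S = np.stack([t.state for t in transitions])
        A = np.stack([t.action for t in transitions])
        R = np.array([t.reward for t in transitions])
        S2 = np.stack([t.next_state for t in transitions])
        D = np.array([float(t.terminal) for t in transitions])
        if cfg.baseline_reward:
            # state-only ridge baseline: shifts Q by a state function,
            # leaving argmax_a Q(s, a) — hence the learned policy — intact
            X = np.concatenate([S, np.ones((len(S), 1))], axis=1)
            w = np.linalg.solve(X.T @ X + 1e-3 * np.eye(X.shape[1]),
                                X.T @ R)
            R = R - X @ w
        if cfg.bc_warmstart_steps > 0:
            self._warmstart_actor(S, A, cfg.bc_warmstart_steps, rng)
        critic_params = [p for grp in self.critics for q in grp
                         for p in q.parameters()]
        opt_c = Adam(critic_params, lr=cfg.critic_lr)
        opt_a = Adam(self.actor.parameters(), lr=cfg.actor_lr)
        n = len(transitions)
        for step in range(steps):
            idx = rng.integers(0, n, cfg.batch_size)
            s, a, r, s2, d = S[idx], A[idx], R[idx], S2[idx], D[idx]
            # Bellman target: min over the two target-ensemble means
            with no_grad():
                a2 = self._squash(self.actor(Tensor(s2)).data)
                x2 = Tensor(np.concatenate([s2, a2], axis=1))
                q2_groups = []
                for tgrp in self.targets:
                    q2_groups.append(np.mean(
                        [q(x2).data[:, 0] for q in tgrp], axis=0))
                q2 = np.minimum(*q2_groups)
                y = r + cfg.discount * (1.0 - d) * q2
            # OOD action set: uniform in box + current-policy proposals
            m = cfg.n_ood_actions
            unif = np.stack([rng.uniform(-15, 15, (cfg.batch_size, m)),
                             rng.uniform(0, 20, (cfg.batch_size, m))], axis=-1)
            with no_grad():
                pol = self._squash(self.actor(Tensor(s)).data)
            pol_rep = np.repeat(pol[:, None, :], m, axis=1)
            pol_rep[:, :, 0] += rng.normal(0, 2.0, (cfg.batch_size, m))
            pol_rep[:, :, 1] += rng.normal(0, 1.0, (cfg.batch_size, m))
            ood = np.concatenate([unif, pol_rep], axis=1)   # (B, 2m, 2)
            closs_val = 0.0
            xb = Tensor(np.concatenate([s, a], axis=1))
            B, M = cfg.batch_size, ood.shape[1]
            s_rep = np.repeat(s[:, None, :], M, axis=1).reshape(B * M, -1)
            x_ood = Tensor(np.concatenate([s_rep, ood.reshape(B * M, 2)],
                                          axis=1))
            opt_c.zero_grad()
            for grp in self.critics:
                for qnet in grp:
                    qd = qnet(xb)[:, 0]
                    diff = qd - Tensor(y)
                    bellman = (diff * diff).mean() * 0.5
                    q_ood = qnet(x_ood)[:, 0].reshape(B, M)
                    mx = q_ood.data.max(axis=1, keepdims=True)
                    lse = ((q_ood - Tensor(mx)).exp().mean(axis=1)).log() \
                        + Tensor(mx[:, 0])
                    gap = (lse - qd).mean()
                    loss = bellman + gap * cfg.cql_weight
                    loss.backward()
                    closs_val += loss.item()
            opt_c.step()
            # actor: distill toward the per-state sampled argmax of the
            # conservative (min-over-ensembles) Q — derivative-free greedy
            # improvement that cannot chase local wiggles of one critic
            cand = np.concatenate([
                a[:, None, :],                                   # logged
                pol[:, None, :],                                 # current
                a[:, None, :] + rng.normal(0, [[[4.0, 2.5]]],
                                           (cfg.batch_size, 2 * m, 2)),
            ], axis=1)
            cand[..., 0] = np.clip(cand[..., 0], -15.0, 15.0)
            cand[..., 1] = np.clip(cand[..., 1], 0.0, 20.0)
            C = cand.shape[1]
            s_rep2 = np.repeat(s[:, None, :], C, axis=1).reshape(-1,
                                                                 s.shape[1])
            xc = Tensor(np.concatenate([s_rep2, cand.reshape(-1, 2)], axis=1))
            with no_grad():
                qg = [np.mean([q(xc).data[:, 0].reshape(cfg.batch_size, C)
                               for q in grp], axis=0) for grp in self.critics]
            q_cons = np.minimum(*qg)
            best = cand[np.arange(cfg.batch_size), q_cons.argmax(axis=1)]
            t1 = np.arctanh(np.clip(best[:, 0] / 15.0, -0.999, 0.999))
            t2 = np.arctanh(np.clip(best[:, 1] / 10.0 - 1.0, -0.999, 0.999))
            raw_t = np.stack([t1, t2], axis=1)
            opt_a.zero_grad()
            diff = self.actor(Tensor(s)) - Tensor(raw_t)
            aloss = (diff * diff).mean()
            aloss.backward()
            opt_a.step()
            if (step + 1) % cfg.target_update_every == 0:
                self._sync_targets()
            self.loss_history.append(
                {"step": step, "critic": closs_val, "actor": aloss.item()})
        return self


def cql_train(transitions: list[Transition], state_dim: int | None = None,
              config: CQLConfig = CQLConfig(), seed: int = 0) -> CQLAgent:
    """Train a conservative dosing agent on offline transitions."""
    if not transitions:
        raise ValueError("empty offline dataset")
    sd = state_dim or len(transitions[0].state)
    agent = CQLAgent(sd, config, seed=seed)
    return agent.train(transitions, seed=seed)


# --------------------------------------------------------------------------
# Tabular conservative Q-learning (discrete oracle route)

def tabular_cql(P: np.ndarray, R: np.ndarray, transitions, discount: float,
                penalty: float = 0.0, iters: int = 2000,
                lr: float = 0.5) -> np.ndarray:
    """CQL on an enumerated MDP from logged (s, a, r, s') tuples.

    With penalty 0 and full coverage this reduces to fitted Q-iteration and
    converges to the optimal Q of the dynamic-programming oracle.
    ``P``/``R`` shapes: (S, A, S) and (S, A) — used only for shapes here;
    learning uses the logged tuples.
    """
    S, A = R.shape
    Q = np.zeros((S, A))
    data = np.asarray(transitions, dtype=float)
    counts = np.zeros((S, A))
    for s, a, *_ in data:
        counts[int(s), int(a)] += 1
    freq = counts / counts.sum()
    for _ in range(iters):
        Qn = Q.copy()
        targets = {}
        for s, a, r, s2 in data:
            key = (int(s), int(a))
            targets.setdefault(key, []).append(r + discount
                                               * Q[int(s2)].max())
        for (s, a), ys in targets.items():
            Qn[s, a] = (1 - lr) * Q[s, a] + lr * float(np.mean(ys))
        if penalty > 0:
            # depress Q uniformly off-data, relative to data frequency
            lse = np.log(np.exp(Qn - Qn.max()).mean()) + Qn.max()
            grad = np.exp(Qn - lse) / (S * A) - freq
            Qn = Qn - lr * penalty * grad
        if np.max(np.abs(Qn - Q)) < 1e-10:
            Q = Qn
            break
        Q = Qn
    return Q


# --------------------------------------------------------------------------
# Abstain mechanism

@dataclass
class ConfidenceRamps:
    """Piecewise-linear maps from raw components to [0, 5], frozen at the
    training cohort's 5th/95th percentiles."""

    pi_width: tuple = (0.5, 3.0)     # log-scale interval width; small good
    density: tuple = (0.0, 6.0)      # labs in past 12 h; large good
    q_var: tuple = (0.01, 4.0)       # ensemble variance; small good

    @staticmethod
    def _ramp_down(x, lo, hi):
        return 5.0 * float(np.clip((hi - x) / max(hi - lo, 1e-12), 0.0, 1.0))

    @staticmethod
    def _ramp_up(x, lo, hi):
        return 5.0 * float(np.clip((x - lo) / max(hi - lo, 1e-12), 0.0, 1.0))

    def scores(self, pi_width: float, density: float, q_var: float):
        return (self._ramp_down(pi_width, *self.pi_width),
                self._ramp_up(density, *self.density),
                self._ramp_down(q_var, *self.q_var))

    @classmethod
    def fit(cls, pi_widths, densities, q_vars) -> "ConfidenceRamps":
        def pct(x):
            return (float(np.percentile(x, 5)), float(np.percentile(x, 95)))
        return cls(pct(pi_widths), pct(densities), pct(q_vars))


def confidence_score(pi_width: float, lab_density: float, q_variance: float,
                     ramps: ConfidenceRamps,
                     cfg: AbstainConfig = AbstainConfig(),
                     hours_since_il6: float | None = None):
    """Composite confidence on [0, 5]; abstain below θ with the worst
    component named in a structured reason."""
    comps = ramps.scores(pi_width, lab_density, q_variance)
    w = np.asarray(cfg.weights, float)
    score = float(np.dot(comps, w) / w.sum())
    abstain = score < cfg.threshold
    reason = ""
    if abstain:
        names = ("wide IL-6 prediction interval",
                 "sparse recent observations",
                 "high dose-value ensemble disagreement")
        worst = int(np.argmin(comps))
        reason = names[worst]
        if worst == 1 and hours_since_il6 is not None \
                and hours_since_il6 > cfg.stale_lab_h:
            reason = (f"no IL-6 result recorded in the past "
                      f"{cfg.stale_lab_h:.0f} h")
    return score, abstain, reason


# --------------------------------------------------------------------------
# Recommendation loop over a logged episode

def recommend(sim_episode: SimulatedEpisode, agent: CQLAgent,
              forecaster: CTODEForecaster, calibrator=None,
              ramps: ConfidenceRamps | None = None,
              abstain_cfg: AbstainConfig = AbstainConfig(),
              safety: SafetyConfig = SafetyConfig(),
              project: bool = True) -> pd.DataFrame:
    """Per-5-min-step recommendations along a logged episode.

    Every emitted (non-abstained) recommendation is checked against the
    safety constraints; with ``project=True`` the violation count is zero by
    construction of the projection, and the check is still performed.
    """
    ramps = ramps or ConfidenceRamps()
    ep = sim_episode.episode
    path = LatentPath(forecaster, ep)
    tg = sim_episode.t_grid_h
    lab_t = np.array([e.t_sec / 3600.0 for e in ep.lab_events()])
    il6_t = np.array([e.t_sec / 3600.0 for e in ep.lab_events()
                      if e.modality == "il6"])
    rows = []
    prev_rp, prev_rk = None, None
    for j, i in enumerate(sim_episode.decision_steps):
        t = tg[i]
        rp_logged = sim_episode.doses["rp"][max(i - 1, 0)]
        rk_logged = sim_episode.doses["rk"][max(i - 1, 0)]
        prev_rp = rp_logged if prev_rp is None else prev_rp
        prev_rk = rk_logged if prev_rk is None else prev_rk
        rates = np.array([rp_logged, rk_logged,
                          sim_episode.doses["vaso"][i]])
        z = path.advance(t, rates)
        w30 = (tg >= t - 0.5) & (tg <= t)
        rp_cum = float(np.sum(sim_episode.doses["rp"][:i]) * DT_H * 60.0)
        rk_cum = float(np.sum(sim_episode.doses["rk"][:i]) * DT_H * 60.0)
        state = _policy_features(
            float(sim_episode.dense["map"][w30].mean()), 80.0, 97.0,
            rp_logged, rk_logged, rp_cum, rk_cum,
            float(sim_episode.doses["vaso"][i]),
            95.0 - 0.75 * rp_logged, t, z)
        proposal = agent.act(state)
        if project:
            (d_rp, rk), projected = project_action(proposal, rp_logged,
                                                   rk_logged, safety)
        else:
            (d_rp, rk), projected = (float(proposal[0]),
                                     float(proposal[1])), False
        # confidence components
        with no_grad():
            mu, sig = forecaster.heads(path.z)
        sig_il6 = float(sig.data[0])
        if calibrator is not None and calibrator.enabled:
            sig_il6 *= calibrator.temperature["il6"]
            width = 2 * calibrator.conformal["il6"] * sig_il6
        else:
            width = 2 * 1.6449 * sig_il6
        density = float(np.sum((lab_t >= t - 12.0) & (lab_t <= t)))
        qv = float(agent.q_values(state[None, :],
                                  np.array([[d_rp, rk]])).var(axis=1)[0])
        since_il6 = t - il6_t[il6_t <= t].max() if np.any(il6_t <= t) \
            else float("inf")
        score, abstain, reason = confidence_score(
            width, density, qv, ramps, abstain_cfg,
            hours_since_il6=since_il6)
        viol = (not abstain) and violates_constraints(
            (d_rp, rk), rp_logged, rk_logged, safety)
        rows.append((ep.episode_id, t * 3600.0, d_rp, rk, projected,
                     score, abstain, reason, viol))
    return pd.DataFrame(rows, columns=[
        "episode_id", "t_sec", "delta_propofol", "ketamine_rate",
        "projected_flag", "confidence", "abstained", "reason", "violation"])
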