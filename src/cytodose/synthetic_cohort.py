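"""Mechanistic synthetic cohort: elderly burn episodes under anesthesia.

The simulator produces perioperative episodes with the statistical structure
the downstream models assume:

* a biphasic post-induction inflammatory course — an injury drive pulses the
  four markers (IL-6, TNF-α fast; CRP, IL-10 lagging first-order responses)
  so that noise-free IL-6 peaks 8–12 h after induction and then resolves;
* a U-shaped propofol→IL-6 effect: direct NF-κB-like suppression is maximal
  near ``m_p`` (default 55 mcg/kg/min) while high rates depress MAP, and
  hypoperfusion (MAP < 65) amplifies cytokine production — the right arm of
  the U emerges from the haemodynamic coupling, not from the suppression
  curve itself;
* saturating ketamine suppression, Emax in dose with half-max ``e50`` ≈ 6
  mcg/kg/min, acting more strongly on TNF-α than IL-6;
* mean-reverting MAP with dose-proportional propofol depression and
  vasopressor offset;
* irregular informative lab draws with ordered-but-unresulted indicators,
  targeting ≈48% missingness of ordered panels;
* a stochastic clinician behavior policy that titrates propofol to a depth
  target, rescues hypotension, and assigns adjunct ketamine preferentially
  to less-inflamed patients (logistic selection on baseline CRP) — the
  measured confounding — while logging exact action propensities.

Cytokine/MAP states advance by fixed-step RK4 on a 5-min grid (the decision
grid). All randomness derives from a single seed via ``SeedSequence`` spawns;
process/measurement noise is pre-drawn per episode so that re-simulating an
episode under different doses but identical noise draws yields an exact
counterfactual trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .event_schema import (BURN_MECHANISMS, CYTOKINES, Episode, EventTriplet,
                           StaticFeatures)

__all__ = [
    "GroundTruthParams", "SimConfig", "SimulatedEpisode", "BehaviorPolicy",
    "cytokine_dynamics", "map_dynamics", "sample_lab_times",
    "simulate_cohort", "Simulator", "true_spike_labels",
]

DT_MIN = 5.0                 # decision / integration grid (minutes)
DT_H = DT_MIN / 60.0


@dataclass(frozen=True)
class GroundTruthParams:
    """Exposed, recoverable parameters of the generative model."""

    # injury drive (t/t_pk)^k exp(k(1-t/t_pk)) peaks at t_pk with value 1
    drive_peak_h: float = 6.5
    drive_shape: float = 2.0
    tnfa_drive_peak_h: float = 4.5
    # production gains (per hour) and decay time constants (hours)
    il6_gain: float = 13.0
    tnfa_gain: float = 4.0
    il6_tau: float = 5.0
    tnfa_tau: float = 3.0
    crp_gain: float = 0.30       # CRP equilibrium = gain * IL-6
    crp_tau: float = 8.0
    il10_gain: float = 0.26
    il10_tau: float = 4.0
    # propofol direct suppression: U-minimum location and depth
    m_p: float = 55.0            # mcg/kg/min, truth band [45, 65]
    propofol_supp_max: float = 0.45
    propofol_supp_logwidth: float = 0.55
    # ketamine Emax suppression
    e50: float = 6.0             # mcg/kg/min, truth band [4, 8]
    emax_il6: float = 0.35
    emax_tnfa: float = 0.55
    # hypoperfusion amplification below MAP 65
    perfusion_gain: float = 0.06  # per mmHg below 65
    # MAP dynamics
    map_tau: float = 0.5          # hours
    map_propofol_slope: float = 0.55   # mmHg/h per mcg/kg/min
    map_vaso_slope: float = 200.0      # mmHg/h per mcg/kg/min norepi-equiv
    # inter-patient random effects (log-SD)
    severity_sd: float = 0.45
    baseline_il6_med: float = 42.0
    baseline_il6_sd: float = 0.65
    baseline_crp_med: float = 13.0
    baseline_crp_sd: float = 0.60
    baseline_tnfa_med: float = 17.0
    baseline_tnfa_sd: float = 0.55
    # noise
    cytokine_meas_logsd: float = 0.12
    map_meas_sd: float = 3.0
    production_ou_sd: float = 0.18
    production_ou_tau: float = 2.0


@dataclass(frozen=True)
class BehaviorConfig:
    """Clinician-like stochastic titration policy parameters."""

    depth_target_mean: float = 52.0     # BIS-like target, band 45–60
    depth_target_sd: float = 6.0
    depth_slope_mean: float = 0.75      # depth = 95 - slope * effect-site rp
    depth_slope_sd: float = 0.18
    titration_gain: float = 0.35        # Δrp per unit depth error
    hypotension_cut: float = 5.0        # Δrp on MAP < 65
    action_sd: float = 2.0              # SD of Δrp proposal (propensity basis)
    ketamine_sd: float = 0.6            # per-step SD around the arm target
    # episode-level ketamine selection: P(arm) = sigmoid(b0 - b_crp * zCRP)
    ketamine_intercept: float = -0.5
    ketamine_crp_coef: float = 1.0      # >0 => less-inflamed get ketamine
    ketamine_level_mean: float = 8.0
    ketamine_level_sd: float = 2.0


@dataclass(frozen=True)
class SimConfig:
    n_episodes: int = 100
    seed: int = 0
    params: GroundTruthParams = field(default_factory=GroundTruthParams)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    horizon_h: float = 24.0
    op_duration_mean_min: float = 150.0
    op_duration_sd_min: float = 40.0
    lab_order_intensity: float = 0.25   # orders per hour per cytokine
    missingness: float = 0.48           # P(ordered panel unresulted)
    informative_sampling: bool = True
    # event-stream cadences (minutes); coarser than the 5-min decision grid
    # to keep encoder sequences desk-scale
    vitals_cadence_op_min: float = 15.0
    vitals_cadence_post_min: float = 90.0
    slow_obs_cadence_min: float = 240.0
    # TBSA and age strata proportions
    tbsa_strata: tuple = ((2.0, 20.0, 0.645), (20.0, 40.0, 0.241),
                          (40.0, 75.0, 0.114))
    age_strata: tuple = ((65.0, 75.0, 0.588), (75.0, 85.0, 0.322),
                         (85.0, 95.0, 0.090))


# --------------------------------------------------------------------------
# Mechanistic one-step updates

def _injury_drive(t_h: float, peak_h: float, shape: float) -> float:
    if t_h <= 0.0:
        return 0.0
    x = t_h / peak_h
    return x ** shape * math.exp(shape * (1.0 - x))


def propofol_suppression(rp, p: GroundTruthParams):
    """Direct immunosuppression factor, minimal (strongest) at ``m_p``."""
    z = np.log((np.asarray(rp, float) + 1.0) / (p.m_p + 1.0))
    return 1.0 - p.propofol_supp_max * np.exp(
        -z ** 2 / (2.0 * p.propofol_supp_logwidth ** 2))


def ketamine_suppression(rk, e50: float, emax: float):
    """Emax factor 1 - emax * rk / (rk + e50); limit 1 - emax as rk → ∞."""
    rk = np.asarray(rk, float)
    return 1.0 - emax * rk / (rk + e50)


def perfusion_index(map_mmhg, p: GroundTruthParams):
    """≥1; grows as MAP falls below 65 (hypoperfusion-driven release)."""
    deficit = np.maximum(0.0, 65.0 - np.asarray(map_mmhg, float))
    return 1.0 + p.perfusion_gain * deficit


def _cytokine_rhs(state, t_h, rp, rk, perf, p: GroundTruthParams,
                  severity: float, prod_mult: float):
    il6, crp, tnfa, il10 = state
    f_p = propofol_suppression(rp, p)
    drive6 = _injury_drive(t_h, p.drive_peak_h, p.drive_shape)
    drive_t = _injury_drive(t_h, p.tnfa_drive_peak_h, p.drive_shape)
    d_il6 = (severity * prod_mult * p.il6_gain * drive6 * f_p
             * ketamine_suppression(rk, p.e50, p.emax_il6) * perf
             - il6 / p.il6_tau)
    d_tnfa = (severity * prod_mult * p.tnfa_gain * drive_t * f_p
              * ketamine_suppression(rk, p.e50, p.emax_tnfa) * perf
              - tnfa / p.tnfa_tau)
    d_crp = (p.crp_gain * il6 - crp) / p.crp_tau
    d_il10 = (p.il10_gain * il6 - il10) / p.il10_tau
    return np.array([d_il6, d_crp, d_tnfa, d_il10])


def cytokine_dynamics(state, t_h, propofol_rate, ketamine_rate, perfusion,
                      dt_h, params: GroundTruthParams | None = None,
                      severity: float = 1.0, prod_mult: float = 1.0):
    """One deterministic RK4 step of the (IL-6, CRP, TNF-α, IL-10) system."""
    if propofol_rate < 0 or ketamine_rate < 0:
        raise ValueError("infusion rates must be nonnegative")
    if dt_h <= 0:
        raise ValueError("dt must be positive")
    p = params or GroundTruthParams()
    s = np.asarray(state, float)

    def f(y, t):
        return _cytokine_rhs(y, t, propofol_rate, ketamine_rate, perfusion,
                             p, severity, prod_mult)

    k1 = f(s, t_h)
    k2 = f(s + 0.5 * dt_h * k1, t_h + 0.5 * dt_h)
    k3 = f(s + 0.5 * dt_h * k2, t_h + 0.5 * dt_h)
    k4 = f(s + dt_h * k3, t_h + dt_h)
    out = s + dt_h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return np.maximum(out, 0.0)


def map_dynamics(map_mmhg, propofol_rate, vaso_rate, dt_h,
                 baseline: float = 82.0,
                 params: GroundTruthParams | None = None,
                 noise: float = 0.0):
    """One step of mean-reverting MAP with propofol depression and
    vasopressor offset; equilibrium = baseline − τ(k_p·rp − k_v·v)."""
    if propofol_rate < 0 or vaso_rate < 0:
        raise ValueError("infusion rates must be nonnegative")
    p = params or GroundTruthParams()

    def f(m):
        return ((baseline - m) / p.map_tau
                - p.map_propofol_slope * propofol_rate
                + p.map_vaso_slope * vaso_rate)

    k1 = f(map_mmhg)
    k2 = f(map_mmhg + 0.5 * dt_h * k1)
    k3 = f(map_mmhg + 0.5 * dt_h * k2)
    k4 = f(map_mmhg + dt_h * k3)
    return map_mmhg + dt_h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4) + noise


# --------------------------------------------------------------------------
# Lab draw schedule

def sample_lab_times(duration_h: float, intensity: float, informative: bool,
                     seed, il6_fn=None, informative_gain: float = 1.0,
                     t_min_h: float = 0.5) -> np.ndarray:
    """Inhomogeneous-Poisson draw times on (t_min, duration].

    With ``informative`` set, the instantaneous rate is
    ``intensity * (1 + gain * IL6(t)/100)`` — a clinician-suspicion proxy —
    sampled by thinning against the maximal rate.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if intensity <= 0:
        return np.array([])
    if not informative or il6_fn is None:
        n = rng.poisson(intensity * (duration_h - t_min_h))
        return np.sort(rng.uniform(t_min_h, duration_h, n))
    grid = np.linspace(t_min_h, duration_h, 200)
    rates = intensity * (1.0 + informative_gain
                         * np.asarray([il6_fn(t) for t in grid]) / 100.0)
    rmax = float(rates.max())
    n = rng.poisson(rmax * (duration_h - t_min_h))
    cand = rng.uniform(t_min_h, duration_h, n)
    keep = rng.uniform(0, rmax, n) < intensity * (
        1.0 + informative_gain * np.asarray([il6_fn(t) for t in cand]) / 100.0)
    return np.sort(cand[keep])


# --------------------------------------------------------------------------
# Behavior policy

def _truncnorm_sample(rng, mu, sd, lo, hi):
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def _truncnorm_pdf(x, mu, sd, lo, hi):
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(truncnorm.pdf(x, a, b, loc=mu, scale=sd))


@dataclass
class BehaviorPolicy:
    """Stochastic clinician-like titration with exact logged propensities.

    Action = (Δ propofol rate, ketamine rate), truncated-Gaussian around a
    deterministic titration rule, so every logged action has a positive,
    exactly computable density. Ketamine arm membership is drawn once per
    episode by logistic selection on baseline CRP (the confounder).
    """

    cfg: BehaviorConfig
    params: GroundTruthParams

    def episode_context(self, static: StaticFeatures, baseline_crp: float,
                        rng: np.random.Generator) -> dict:
        z = (math.log(baseline_crp) - math.log(self.params.baseline_crp_med)) \
            / self.params.baseline_crp_sd
        logit = self.cfg.ketamine_intercept - self.cfg.ketamine_crp_coef * z
        p_arm = 1.0 / (1.0 + math.exp(-logit))
        arm = rng.uniform() < p_arm
        level = _truncnorm_sample(rng, self.cfg.ketamine_level_mean,
                                  self.cfg.ketamine_level_sd, 3.0, 14.0) \
            if arm else 0.0
        return {
            "arm": bool(arm), "p_arm": p_arm, "ketamine_level": level,
            "depth_target": rng.normal(self.cfg.depth_target_mean,
                                       self.cfg.depth_target_sd),
            "depth_slope": max(0.4, rng.normal(self.cfg.depth_slope_mean,
                                               self.cfg.depth_slope_sd)),
        }

    def mean_action(self, state: dict, ctx: dict) -> tuple[float, float]:
        depth = 95.0 - ctx["depth_slope"] * state["rp_effect"]
        if state["map"] < 65.0:
            d_rp = -self.cfg.hypotension_cut
        else:
            d_rp = self.cfg.titration_gain * (depth - ctx["depth_target"])
        d_rp = float(np.clip(d_rp, -15.0, 15.0))
        target_rk = ctx["ketamine_level"] if state["t_h"] * 60.0 >= 20.0 else 0.0
        rk = float(np.clip(target_rk, max(0.0, state["rk_prev"] - 5.0),
                           min(20.0, state["rk_prev"] + 5.0)))
        return d_rp, rk

    def _bounds(self, state: dict):
        # intersection of the action box with safety rate limits
        lo_d = max(-15.0, -state["rp_prev"], -20.0)
        hi_d = min(15.0, 100.0 - state["rp_prev"], 20.0)
        lo_k = max(0.0, state["rk_prev"] - 5.0)
        hi_k = min(20.0, state["rk_prev"] + 5.0)
        return lo_d, hi_d, lo_k, hi_k

    def act(self, state: dict, ctx: dict, rng: np.random.Generator):
        mu_d, mu_k = self.mean_action(state, ctx)
        lo_d, hi_d, lo_k, hi_k = self._bounds(state)
        d_rp = _truncnorm_sample(rng, mu_d, self.cfg.action_sd, lo_d, hi_d)
        rk = _truncnorm_sample(rng, mu_k, self.cfg.ketamine_sd, lo_k, hi_k)
        dens = (_truncnorm_pdf(d_rp, mu_d, self.cfg.action_sd, lo_d, hi_d)
                * _truncnorm_pdf(rk, mu_k, self.cfg.ketamine_sd, lo_k, hi_k))
        return (d_rp, rk), dens

    def density(self, state: dict, ctx: dict, action) -> float:
        mu_d, mu_k = self.mean_action(state, ctx)
        lo_d, hi_d, lo_k, hi_k = self._bounds(state)
        return (_truncnorm_pdf(action[0], mu_d, self.cfg.action_sd, lo_d, hi_d)
                * _truncnorm_pdf(action[1], mu_k, self.cfg.ketamine_sd,
                                 lo_k, hi_k))


# --------------------------------------------------------------------------
# Episode simulation

@dataclass
class SimulatedEpisode:
    """Observed episode plus hidden ground truth for evaluation."""

    episode: Episode
    t_grid_h: np.ndarray            # dense 5-min grid
    dense: dict                      # noise-free il6/crp/tnfa/il10/map arrays
    doses: dict                      # rp/rk/vaso arrays on the grid
    op_end_h: float
    decision_steps: np.ndarray       # grid indices where the policy acted
    actions: np.ndarray              # (n_steps, 2): (Δrp, rk)
    propensities: np.ndarray
    behavior_ctx: dict
    severity: float
    spike_relative: bool
    spike_absolute: bool
    noise_handle: "EpisodeNoise" = None  # type: ignore[assignment]
    baseline_crp: float = float("nan")


@dataclass
class EpisodeNoise:
    """Pre-drawn noise: identical draws + identical doses => identical
    trajectories (exact counterfactual consistency)."""

    seed_static: np.random.Generator
    ou_increments: np.ndarray       # production multiplier OU, per grid step
    map_process: np.ndarray
    measure_seed: int
    policy_seed: int
    labs_seed: int


class Simulator:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.params = config.params
        self.behavior = BehaviorPolicy(config.behavior, config.params)
        n_steps = int(round(config.horizon_h / DT_H))
        self.t_grid = np.arange(n_steps + 1) * DT_H

    # -- patient-level draws ------------------------------------------------
    def draw_static(self, rng) -> tuple[StaticFeatures, dict]:
        cfg, p = self.cfg, self.params
        a_lo, a_hi, _ = cfg.age_strata[
            rng.choice(len(cfg.age_strata), p=[s[2] for s in cfg.age_strata])]
        age = rng.uniform(a_lo, a_hi)
        t_lo, t_hi, _ = cfg.tbsa_strata[
            rng.choice(len(cfg.tbsa_strata), p=[s[2] for s in cfg.tbsa_strata])]
        tbsa = rng.uniform(t_lo, t_hi)
        static = StaticFeatures(
            age=round(age, 1), sex=int(rng.uniform() < 0.42),
            bmi=round(float(np.clip(rng.normal(26.8, 5.4), 16, 45)), 1),
            cci=int(np.clip(rng.poisson(3.8), 0, 12)), tbsa=round(tbsa, 1),
            mechanism=BURN_MECHANISMS[rng.choice(4, p=[0.7, 0.15, 0.1, 0.05])],
            inhalation=int(rng.uniform() < 0.231))
        sev_tbsa = 0.55 + 0.035 * tbsa
        base = {
            "severity": sev_tbsa * math.exp(rng.normal(0.0, p.severity_sd)),
            "il6": p.baseline_il6_med * sev_tbsa / 1.2
            * math.exp(rng.normal(0.0, p.baseline_il6_sd)),
            "crp": p.baseline_crp_med * math.exp(
                rng.normal(0.0, p.baseline_crp_sd) + 0.2 * (sev_tbsa - 1.2)),
            "tnfa": p.baseline_tnfa_med * math.exp(
                rng.normal(0.0, p.baseline_tnfa_sd)),
            "map": float(np.clip(rng.normal(82.0, 6.0), 65, 100)),
            "hr": float(np.clip(rng.normal(84.0, 9.0), 55, 130)),
            "op_min": float(np.clip(rng.normal(cfg.op_duration_mean_min,
                                               cfg.op_duration_sd_min),
                                    60.0, 240.0)),
            "rp0": float(np.clip(rng.normal(60.0, 12.0), 35.0, 85.0)),
        }
        base["il10"] = base["il6"] * p.il10_gain \
            * math.exp(rng.normal(0.0, 0.3))
        return static, base

    def draw_noise(self, ss: np.random.SeedSequence) -> EpisodeNoise:
        s_static, s_proc, s_meas, s_pol, s_lab = ss.spawn(5)
        rng = np.random.default_rng(s_proc)
        n = len(self.t_grid)
        p = self.params
        # OU log production multiplier
        ou = np.zeros(n)
        rho = math.exp(-DT_H / p.production_ou_tau)
        innov_sd = p.production_ou_sd * math.sqrt(1 - rho ** 2)
        for i in range(1, n):
            ou[i] = rho * ou[i - 1] + rng.normal(0.0, innov_sd)
        map_proc = rng.normal(0.0, 0.8, n)
        return EpisodeNoise(
            seed_static=np.random.default_rng(s_static),
            ou_increments=ou, map_process=map_proc,
            measure_seed=int(s_meas.generate_state(1)[0] % (2 ** 31)),
            policy_seed=int(s_pol.generate_state(1)[0] % (2 ** 31)),
            labs_seed=int(s_lab.generate_state(1)[0] % (2 ** 31)))

    # -- core rollout -------------------------------------------------------
    def run_episode(self, episode_id: str, static: StaticFeatures,
                    base: dict, noise: EpisodeNoise, policy=None,
                    policy_ctx=None) -> SimulatedEpisode:
        """Integrate one episode under ``policy`` (default: behavior policy).

        ``policy(state_dict, rng) -> (Δrp, rk) [, propensity]``. The
        vasopressor rescue rule is environment-side and identical for every
        policy. Identical ``noise`` and identical emitted doses reproduce the
        trajectory exactly.
        """
        cfg, p = self.cfg, self.params
        tg = self.t_grid
        n = len(tg)
        op_end_h = base["op_min"] / 60.0
        rng_pol = np.random.default_rng(noise.policy_seed)

        behavior = policy is None
        if behavior:
            ctx = self.behavior.episode_context(static, base["crp"], rng_pol)
        else:
            ctx = policy_ctx or {}

        cyt = np.array([base["il6"], base["crp"], base["tnfa"], base["il10"]])
        m = base["map"]
        dense = {k: np.zeros(n) for k in
                 ("il6", "crp", "tnfa", "il10", "map")}
        doses = {k: np.zeros(n) for k in ("rp", "rk", "vaso")}
        # induction infusion start: clinician-to-clinician variation
        rp = base.get("rp0", 60.0)
        rk, vaso = 0.0, 0.0
        rp_effect = 0.0    # effect-site (10-min first-order lag)
        steps, acts, dens_log = [], [], []
        for i in range(n):
            t = tg[i]
            for k, v in zip(("il6", "crp", "tnfa", "il10"), cyt):
                dense[k][i] = v
            dense["map"][i] = m
            in_op = t < op_end_h
            # decision point: every 5-min step inside the operative window
            if in_op and i > 0:
                state = self._policy_state(t, m, rp, rk, vaso, rp_effect,
                                           base, cyt)
                if behavior:
                    (d_rp, new_rk), dens = self.behavior.act(state, ctx,
                                                             rng_pol)
                else:
                    d_rp, new_rk = policy(state, rng_pol)
                    dens = np.nan
                steps.append(i)
                acts.append((d_rp, new_rk))
                dens_log.append(dens if dens is not None else np.nan)
                rp = float(np.clip(rp + d_rp, 0.0, 100.0))
                rk = float(np.clip(new_rk, 0.0, 20.0))
            elif not in_op:
                rp = max(0.0, rp - 20.0)       # post-op taper
                rk = max(0.0, rk - 5.0)
            # environment-side vasopressor rescue (same rule for any policy)
            if m < 63.0:
                vaso = min(0.5, vaso + 0.05)
            elif m > 78.0 and vaso > 0:
                vaso = max(0.0, vaso - 0.05)
            doses["rp"][i], doses["rk"][i], doses["vaso"][i] = rp, rk, vaso
            if i == n - 1:
                break
            # advance mechanistic state
            prod = math.exp(noise.ou_increments[i])
            perf = float(perfusion_index(m, p))
            cyt = cytokine_dynamics(cyt, t, rp, rk, perf, DT_H, p,
                                    severity=base["severity"],
                                    prod_mult=prod)
            m = map_dynamics(m, rp, vaso, DT_H, baseline=base["map_base"],
                             params=p, noise=noise.map_process[i])
            rp_effect += DT_H / (10.0 / 60.0) * (rp - rp_effect)

        rel, absolute = true_spike_labels(tg, dense["il6"])
        episode = self._emit_events(episode_id, static, base, noise, tg,
                                    dense, doses, op_end_h)
        return SimulatedEpisode(
            episode=episode, t_grid_h=tg, dense=dense, doses=doses,
            op_end_h=op_end_h, decision_steps=np.array(steps, dtype=int),
            actions=np.array(acts) if acts else np.zeros((0, 2)),
            propensities=np.array(dens_log), behavior_ctx=ctx,
            severity=base["severity"], spike_relative=rel,
            spike_absolute=absolute, noise_handle=noise,
            baseline_crp=base["crp"])

    def _policy_state(self, t, m, rp, rk, vaso, rp_effect, base, cyt):
        return {
            "t_h": t, "map": m, "hr": base["hr"] + 0.4 * (base["map"] - m),
            "spo2": 97.0,
            "rp_prev": rp, "rk_prev": rk, "vaso": vaso,
            "rp_effect": rp_effect,
            "depth": 95.0 - 0.75 * rp_effect,
            "baseline_crp": base["crp"], "true_il6": cyt[0],
        }

    # -- observation stream -------------------------------------------------
    def _emit_events(self, episode_id, static, base, noise, tg, dense, doses,
                     op_end_h) -> Episode:
        cfg, p = self.cfg, self.params
        rng = np.random.default_rng(noise.measure_seed)
        rng_lab = np.random.default_rng(noise.labs_seed)
        events: list[EventTriplet] = []

        def dense_at(key, t):
            return float(np.interp(t, tg, dense[key]))

        # vitals: coarser cadence than the decision grid, noisy
        vit_times = np.concatenate([
            np.arange(0.0, min(op_end_h, cfg.horizon_h),
                      cfg.vitals_cadence_op_min / 60.0),
            np.arange(op_end_h, cfg.horizon_h,
                      cfg.vitals_cadence_post_min / 60.0)])
        for t in vit_times:
            events.append(EventTriplet(
                dense_at("map", t) + rng.normal(0, p.map_meas_sd), t * 3600,
                "map"))
            hr = base["hr"] + 0.4 * (base["map"] - dense_at("map", t))
            events.append(EventTriplet(hr + rng.normal(0, 4.0), t * 3600,
                                       "hr"))
            events.append(EventTriplet(
                float(np.clip(97.0 + rng.normal(0, 1.0), 85, 100)), t * 3600,
                "spo2"))
            if t < op_end_h:
                rp_t = float(np.interp(t, tg, doses["rp"]))
                events.append(EventTriplet(
                    95.0 - 0.75 * rp_t + rng.normal(0, 2.0), t * 3600,
                    "depth_proxy"))
        for t in np.arange(0.0, cfg.horizon_h, cfg.slow_obs_cadence_min / 60.0):
            events.append(EventTriplet(36.8 + rng.normal(0, 0.3), t * 3600,
                                       "temp"))
            events.append(EventTriplet(16.0 + rng.normal(0, 2.0), t * 3600,
                                       "resp_rate"))
            events.append(EventTriplet(max(0.0, rng.normal(60, 25)), t * 3600,
                                       "urine_output"))
            events.append(EventTriplet(rng.normal(250, 120), t * 3600,
                                       "fluid_balance"))
        for t in np.arange(0.0, min(op_end_h, cfg.horizon_h), 1.0):
            events.append(EventTriplet(50.0 * (t + 1), t * 3600,
                                       "fentanyl_cum"))
        # infusion streams: change points on the 5-min grid
        for key, tok in (("rp", "propofol_rate"), ("rk", "ketamine_rate"),
                         ("vaso", "vasopressor_rate")):
            arr = doses[key]
            last_emit = -10
            for i in range(len(tg)):
                changed = i == 0 or arr[i] != arr[i - 1]
                # record change points, thinned to a 15-min charting cadence
                if changed and (i - last_emit >= 3 or i == 0):
                    events.append(EventTriplet(arr[i], tg[i] * 3600, tok))
                    last_emit = i
        # labs: informative Poisson orders, thinned results, baseline panel
        il6_fn = (lambda t: dense_at("il6", t)) \
            if cfg.informative_sampling else None
        for cyt_key in CYTOKINES:
            orders = sample_lab_times(cfg.horizon_h, cfg.lab_order_intensity,
                                      cfg.informative_sampling, rng_lab,
                                      il6_fn=il6_fn)
            orders = np.concatenate([[0.25], orders])   # admission panel
            for j, t in enumerate(orders):
                resulted = j == 0 or rng_lab.uniform() >= cfg.missingness
                if resulted:
                    v = dense_at(cyt_key, t) * math.exp(
                        rng.normal(0, p.cytokine_meas_logsd))
                    events.append(EventTriplet(max(v, 0.05), t * 3600,
                                               cyt_key))
                else:
                    events.append(EventTriplet(1.0, t * 3600,
                                               "lab_ordered_missing"))
        exposure = "propofol+ketamine" if doses["rk"].max() > 2.0 \
            else "propofol-only"
        return Episode(episode_id, static, events, exposure)


def true_spike_labels(t_grid_h: np.ndarray, il6_dense: np.ndarray):
    """(relative, absolute) spike labels from the noise-free IL-6 curve.

    Relative: a rise ≥ 40 pg/mL within some ≤6-h window; absolute: IL-6
    reaches ≥ 100 pg/mL.
    """
    window = int(round(6.0 / DT_H))
    rel = False
    running_min = il6_dense[0]
    mins = np.empty_like(il6_dense)
    for i in range(len(il6_dense)):
        lo = max(0, i - window)
        mins[i] = il6_dense[lo:i + 1].min()
        if il6_dense[i] - mins[i] >= 40.0:
            rel = True
    return rel, bool(il6_dense.max() >= 100.0)


def simulate_cohort(config: SimConfig) -> list[SimulatedEpisode]:
    """Fully seed-deterministic cohort of :class:`SimulatedEpisode`."""
    sim = Simulator(config)
    root = np.random.SeedSequence(config.seed)
    out = []
    for i, ss in enumerate(root.spawn(config.n_episodes)):
        noise = sim.draw_noise(ss)
        static, base = sim.draw_static(noise.seed_static)
        base["map_base"] = base["map"]
        out.append(sim.run_episode(f"ep{i:04d}", static, base, noise))
    return out
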