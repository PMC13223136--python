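"""Dose–response partial dependence, joint dose surface, and
integrated-gradients attribution for the fitted forecaster.

Partial dependence varies one drug across its clinically observed range while
every other covariate is pinned at the cohort median (a synthetic
median-patient episode with a constant infusion), reading the predicted IL-6
(and TNF-α for ketamine) 12 h post-induction with calibrated 90% bands.

Integrated gradients attribute a scalar model output F to its inputs along
the straight path from a baseline x' (the cohort-median event sequence at
matched timestamps) to the input x:
IG_i = (x_i − x'_i) · ∫ ∂F/∂x_i (x' + α(x − x')) dα, approximated by a
midpoint Riemann sum; completeness (Σ IG ≈ F(x) − F(x')) holds to <1% at
≥256 steps. Event-level attributions are aggregated per modality (mean
absolute across episodes) and normalised to sum to 1 per output cytokine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor, concat
from .event_schema import (CYTOKINES, Episode, EventTriplet,
                           StaticFeatures)
from .latent_ctode import CTODEForecaster, interpolate_controls

__all__ = [
    "integrated_gradients", "episode_attribution", "attribution_table",
    "partial_dependence", "dose_surface", "median_episode",
]


# --------------------------------------------------------------------------
# Cohort-median reference patient

def _median_statics(episodes) -> StaticFeatures:
    arr = np.array([[e.static.age, e.static.sex, e.static.bmi, e.static.cci,
                     e.static.tbsa, e.static.inhalation] for e in episodes])
    med = np.median(arr, axis=0)
    return StaticFeatures(age=float(med[0]), sex=int(round(med[1])),
                          bmi=float(med[2]), cci=int(round(med[3])),
                          tbsa=float(med[4]), mechanism="flame",
                          inhalation=int(round(med[5])))


def _modality_medians(episodes) -> dict:
    vals: dict[str, list] = {}
    for ep in episodes:
        for e in ep.events:
            vals.setdefault(e.modality, []).append(e.value)
    return {m: float(np.median(v)) for m, v in vals.items()}


def median_episode(episodes, propofol_rate: float, ketamine_rate: float,
                   op_hours: float = 12.0) -> Episode:
    """Synthetic cohort-median patient on a constant infusion.

    The rate is held through the forecast horizon: the dose–response of a
    *rate* covariate is defined under sustained exposure, not under a brief
    operative bolus whose effect on the 12-h level is negligible.
    """
    med = _modality_medians(episodes)
    ev = []
    for c in CYTOKINES:
        ev.append(EventTriplet(med.get(c, 10.0), 0.25 * 3600, c))
    for t in (0.0, 0.25, 0.5):
        ev.append(EventTriplet(med.get("map", 80.0), t * 3600, "map"))
        ev.append(EventTriplet(med.get("hr", 82.0), t * 3600, "hr"))
        ev.append(EventTriplet(med.get("spo2", 97.0), t * 3600, "spo2"))
    ev.append(EventTriplet(med.get("temp", 36.8), 0.0, "temp"))
    ev.append(EventTriplet(propofol_rate, 0.0, "propofol_rate"))
    ev.append(EventTriplet(propofol_rate, op_hours * 3600, "propofol_rate"))
    ev.append(EventTriplet(0.0, (op_hours + 0.25) * 3600, "propofol_rate"))
    ev.append(EventTriplet(ketamine_rate, 0.0, "ketamine_rate"))
    ev.append(EventTriplet(ketamine_rate, op_hours * 3600, "ketamine_rate"))
    ev.append(EventTriplet(0.0, (op_hours + 0.25) * 3600, "ketamine_rate"))
    ev.append(EventTriplet(0.0, 0.0, "vasopressor_rate"))
    return Episode("median-ref", _median_statics(episodes), ev)


# --------------------------------------------------------------------------
# Partial dependence and the joint dose surface

def _observed_range(episodes, modality: str):
    v = np.concatenate([ep.values(modality) for ep in episodes])
    return float(v.min()), float(v.max())


def partial_dependence(model: CTODEForecaster, episodes, drug: str,
                       grid=None, calibrator=None, horizon_h: float = 12.0,
                       origin_h: float = 0.5) -> pd.DataFrame:
    """Predicted 12-h IL-6 (and TNF-α for ketamine) along a dose grid,
    other covariates at cohort-median values; 90% bands if calibrated."""
    if drug not in ("propofol", "ketamine"):
        raise ValueError("drug must be 'propofol' or 'ketamine'")
    modality = f"{drug}_rate"
    lo, hi = _observed_range(episodes, modality)
    if grid is None:
        grid = np.linspace(lo, max(hi, lo + 1.0), 13)
    else:
        grid = np.asarray(grid, float)
        if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
            import warnings
            warnings.warn("grid outside the observed dose range; clamping")
            grid = np.clip(grid, lo, hi)
    med_rk = 0.0
    med_rp = 55.0
    rows = []
    for r in grid:
        rp = r if drug == "propofol" else med_rp
        rk = r if drug == "ketamine" else med_rk
        ep = median_episode(episodes, rp, rk)
        dists = model.forecast_episode(ep, origin_h)
        if calibrator is not None:
            dists = calibrator.apply_all(dists)
        row = {"dose": float(r)}
        for d in dists:
            if d.horizon_h == horizon_h and d.cytokine in ("il6", "tnfa"):
                row[f"{d.cytokine}_pred"] = d.median
                if calibrator is not None:
                    row[f"{d.cytokine}_lo90"] = d.lo90
                    row[f"{d.cytokine}_hi90"] = d.hi90
        rows.append(row)
    return pd.DataFrame(rows)


def dose_surface(model: CTODEForecaster, episodes, propofol_grid,
                 ketamine_grid, horizon_h: float = 12.0,
                 origin_h: float = 0.5, policy_centroid=None):
    """Joint (propofol × ketamine) predicted 12-h IL-6 surface + argmin."""
    P = np.asarray(propofol_grid, float)
    K = np.asarray(ketamine_grid, float)
    surf = np.zeros((len(P), len(K)))
    for i, rp in enumerate(P):
        for j, rk in enumerate(K):
            ep = median_episode(episodes, rp, rk)
            dists = model.forecast_episode(ep, origin_h)
            il6 = [d for d in dists
                   if d.cytokine == "il6" and d.horizon_h == horizon_h][0]
            surf[i, j] = il6.median
    i0, j0 = np.unravel_index(np.argmin(surf), surf.shape)
    out = {"surface": surf, "propofol_grid": P, "ketamine_grid": K,
           "argmin": (float(P[i0]), float(K[j0]))}
    if policy_centroid is not None:
        out["policy_centroid"] = tuple(map(float, policy_centroid))
    return out


# --------------------------------------------------------------------------
# Integrated gradients

def integrated_gradients(f, x: np.ndarray, baseline: np.ndarray,
                         steps: int = 64) -> np.ndarray:
    """IG of a scalar autodiff function ``f(Tensor) -> Tensor`` at x.

    Midpoint Riemann approximation of the path integral; exact for linear f
    at any step count.
    """
    if steps < 1:
        raise ValueError("steps must be ≥ 1")
    x = np.asarray(x, float)
    baseline = np.asarray(baseline, float)
    grads = np.zeros_like(x)
    for k in range(steps):
        alpha = (k + 0.5) / steps
        xt = Tensor(baseline + alpha * (x - baseline), requires_grad=True)
        y = f(xt)
        y.backward()
        grads += xt.grad
    return (x - baseline) * grads / steps


def _forecast_scalar(model: CTODEForecaster, episode: Episode,
                     prefix: Episode, value_leaves: list[Tensor],
                     static_leaf: Tensor, origin_h: float, horizon_h: float,
                     cyt_index: int):
    """Differentiable path: (event values, statics) → predicted log1p level."""
    z_obs = model.encoder.encode(prefix, model.std,
                                 value_tensors=value_leaves)
    z0 = model.init_map(concat([z_obs, static_leaf], axis=0))
    control = interpolate_controls(episode)
    z = z0
    if model.cfg.use_ct:
        from .latent_ctode import propagate
        z = propagate(z0, origin_h, origin_h + horizon_h, control,
                      model.dynamics, model.cfg.ode)
    mu, _ = model.heads(z)
    return mu[cyt_index]


def episode_attribution(model: CTODEForecaster, episode: Episode,
                        modality_medians: dict, origin_h: float = 2.0,
                        horizon_h: float = 12.0, steps: int = 64,
                        targets=("il6", "crp", "tnfa")) -> pd.DataFrame:
    """Per-feature IG rows for one episode (features = modalities of the
    prefix events, plus static features)."""
    if steps < 1:
        raise ValueError("steps must be ≥ 1")
    prefix_events = [e for e in episode.events if e.t_sec <= origin_h * 3600.0]
    prefix_events = prefix_events[-model.encoder.cfg.max_events:]
    if not prefix_events:
        raise ValueError("no events before attribution origin")
    prefix = Episode(episode.episode_id, episode.static, list(prefix_events),
                     episode.exposure, episode.vocab)
    prefix_events = prefix.events      # canonical order after sorting
    x_vals = np.array([model.std.transform_value(e.modality, e.value)
                       for e in prefix_events])
    b_vals = np.array([model.std.transform_value(
        e.modality, modality_medians.get(e.modality, e.value))
        for e in prefix_events])
    x_stat = model.std.transform_static(episode.static.as_vector())
    b_stat = np.zeros_like(x_stat)       # cohort mean in standardized units
    nx = len(x_vals)
    x_full = np.concatenate([x_vals, x_stat])
    b_full = np.concatenate([b_vals, b_stat])
    rows = []
    for cyt in targets:
        ci = CYTOKINES.index(cyt)

        def f(xt: Tensor):
            leaves = [xt[i] for i in range(nx)]
            return _forecast_scalar(model, episode, prefix, leaves, xt[nx:],
                                    origin_h, horizon_h, ci)

        ig = integrated_gradients(f, x_full, b_full, steps)
        per_feature: dict[str, float] = {}
        for i, e in enumerate(prefix_events):
            per_feature[e.modality] = per_feature.get(e.modality, 0.0) + ig[i]
        for name, v in zip(StaticFeatures.vector_names(), ig[nx:]):
            per_feature[name] = float(v)
        for feat, v in per_feature.items():
            rows.append((episode.episode_id, cyt, feat, float(v)))
    return pd.DataFrame(rows, columns=["episode_id", "target", "feature",
                                       "ig"])


def attribution_table(per_episode: pd.DataFrame) -> pd.DataFrame:
    """Aggregate signed IG rows: mean |IG| per (feature, target), normalised
    to sum to 1 within each target column; composite = renormalised mean."""
    agg = (per_episode.assign(a=lambda d: d["ig"].abs())
           .groupby(["feature", "target"])["a"].mean().unstack(fill_value=0.0))
    norm = agg / agg.sum(axis=0)
    norm["composite"] = norm.mean(axis=1)
    norm["composite"] /= norm["composite"].sum()
    return norm.sort_values("composite", ascending=False)
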