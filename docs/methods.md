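# Methods

`cytodose` couples a probabilistic forecaster of perioperative inflammatory
markers to a conservative offline-RL dosing agent, exercised end to end on a
mechanistic synthetic cohort of elderly burn patients. This note documents
the models, the generator, the numerical choices, and what the bundled tests
do and do not establish.

## Data model

One observation is an event triplet `(value, t_sec, modality)`; an episode
is a time-sorted triplet sequence plus static features (age, sex, BMI,
Charlson index, TBSA, burn mechanism, inhalation injury, Baux = age + TBSA).
Timestamps are seconds since anesthetic induction (t = 0); a helper converts
epoch stamps. Ties at equal timestamps break by modality code, so reads are
reproducible. Ordered-but-unresulted labs are their own modality token
(`lab_ordered_missing`, value 1 at order time): missingness is represented,
not imputed away. Continuous features are standardized to zero mean and unit
variance with parameters estimated on the training split only and then
frozen; a zero-variance modality gets scale 1 rather than a division by
zero.

## Synthetic cohort generator

The generator is a first-class, tested component — it defines the study
conditions for everything downstream. Four coupled ODEs (IL-6, CRP, TNF-α,
IL-10) plus mean-reverting MAP advance by fixed-step RK4 on the 5-minute
decision grid:

* an injury drive `(t/t_pk)^k e^{k(1−t/t_pk)}` pulses IL-6/TNF-α production
  so that zero-drug IL-6 peaks 8–12 h post-induction; CRP and IL-10 are
  first-order lags of IL-6 (time constants 8 h and 4 h);
* propofol multiplies production by a log-Gaussian dip centred at
  `m_p = 55` mcg/kg/min (direct NF-κB-like suppression), while MAP falls
  proportionally to the infusion rate; MAP < 65 mmHg multiplies production
  by a hypoperfusion factor. The U-shaped dose–response is therefore
  *emergent*: its right arm exists only through the haemodynamic coupling;
* ketamine multiplies production by the Emax factor
  `1 − E·r_k/(r_k + e50)` with `e50 = 6` mcg/kg/min and a larger ceiling
  for TNF-α (0.55) than IL-6 (0.35);
* inter-patient heterogeneity: a TBSA-linked severity gain with a
  log-normal random effect (log-SD 0.45), log-normal baselines, OU process
  noise on production, Gaussian process/measurement noise on MAP,
  multiplicative log-normal measurement noise on cytokines (positive,
  right-skewed observations).

Static features draw from stratified distributions (age strata 58.8 / 32.2
/ 9.0 % over 65–74 / 75–84 / ≥85; TBSA strata 64.5 / 24.1 / 11.4 % below
20 / 20–39 / ≥40 %). Lab draws are an inhomogeneous Poisson process whose
rate optionally increases with the current true IL-6 (clinician-suspicion
proxy); ~48 % of ordered panels are unresulted. Under the default behavior
policy the absolute spike prevalence (IL-6 ≥ 100 pg/mL) lands in 0.27–0.33
across seeds.

The behavior policy is clinician-like and deliberately confounded: propofol
titrates a depth proxy toward a per-clinician target (induction rate
N(60, 12), clipped 35–85 — clinician-to-clinician variation), cuts the rate
and triggers vasopressor rescue on hypotension, and assigns adjunct ketamine
by a logistic model on baseline CRP so the ketamine arm is systematically
less inflamed. All actions are truncated-Gaussian around the deterministic
rule, and their exact densities are logged with every transition, so
importance-weighted off-policy evaluation needs no fitted behavior model on
synthetic data. Per-episode noise is pre-drawn: re-running an episode with
the same noise handle and a different policy yields an exact counterfactual,
which is how ground-truth policy values are computed.

What the generator does *not* emulate: structured MNAR missingness beyond
the suspicion-linked draw intensity, temperature regulation, multi-site
coding heterogeneity, or real-cohort marginal distributions beyond the
strata shares above. Tests passing on this cohort demonstrate correctness of
the machinery and the stated statistical guarantees under these conditions,
not clinical performance.

## Forecaster

A self-attention encoder over event triplets (per-modality linear value
projections + modality embeddings + sinusoidal encodings of *continuous*
time; a learned summary token prepended 1 s before the first event pools
the sequence). Full-scale defaults are 4 layers / 8 heads / width 256 /
dropout 0.15; the smoke profile used by tests runs 2 layers / 4 heads /
width 32. Masked-event pre-training (30 % of events per episode; value
replaced by a learned mask embedding, time and modality kept) reconstructs
standardized values with a linear readout. Masking whole events rather than
modality classes forces cross-modal temporal imputation; mask rate 0 is
rejected as degenerate.

The context vector, concatenated with standardized statics, maps through a
two-layer perceptron to the latent initial state; a three-layer perceptron
`f(z, u(t))` gives dz/dt, where `u(t)` holds piecewise-linearly interpolated
propofol/ketamine/vasopressor rates (constant extrapolation beyond the last
record) augmented with three smooth clock covariates (t/24, e^{−t/6},
e^{−t/12} in hours). The clock channels let the vector field express the
known phasic post-injury time course without the latent maintaining an
internal clock — without them the desk-scale model collapses to
horizon-independent predictions. Integration is adaptive Dormand–Prince
RK45 (defaults rtol 1e-5 / atol 1e-6; smoke 1e-3 / 1e-4); gradients flow
directly through solver steps (an adjoint pass is a memory optimisation
the model sizes here do not need; error control reads detached values, so
gradients follow the accepted fifth-order updates).

Cytokines are modeled on the log1p scale. Gaussian heads read z at each
horizon h ∈ {2,4,6,8,12,16,20,24} h; scale positivity via softplus + 1e-4.
The loss is NLL + λ·CRPS (λ = 0.5, closed-form Gaussian CRPS) evaluated at
the actual lab draw times with nearest-horizon assignment, origins sliding
on a 2-h grid; a small auxiliary head regresses MAP so the fitted bundle
doubles as a learned environment surrogate. Training is per-origin Adam
(lr 1e-3, cosine decay, global-norm clip 100 — wide enough to bite only on
genuine explosions). Ablation switches: −CT replaces propagation with a
latent carry-forward (verified by a call counter), −SSL skips pre-training,
−Calib bypasses the calibration layer.

## Calibration

Two stages on a held-out calibration split (default 15 % of episodes,
episode-level to prevent leakage across horizons of one patient), divided
in half *by episode* between the stages: a per-cytokine temperature `T` by
exact Gaussian MLE (T² = mean(r²/σ²)) on one half, then inductive conformal
prediction on the other, with σ-normalised absolute residuals and the
⌈(n+1)·0.9⌉-th smallest score as offset (n ≥ 19 enforced). Two
exchangeability hazards are handled explicitly because both were observed
to bite: (i) fitting both stages on the same pairs couples the conformal
scores to the fitted temperature — hence the stage split; (ii) lab
residuals are strongly correlated within a patient (CRP, the slowest
marker, contributes essentially one independent residual per episode), so
pooled per-pair scores are not exchangeable with a fresh episode's score
and under-cover by several points. With ≥19 episodes in the conformal
half, the nonconformity sample therefore takes one uniformly chosen pair
per episode per cytokine (topped up with a second pair only when
missingness leaves a cytokine short); smaller splits fall back to pooled
pairs with a warning that the finite-sample guarantee is then
approximate. Intervals are closed (boundary hits count as
covered) and back-transform monotonically to pg/mL. Spike detection scores
are Gaussian exceedance probabilities of a ≥ 40 pg/mL rise within 6 h;
AUROC uses midrank tie handling; the absolute ≥ 100 pg/mL criterion is
labelled separately.

## Dosing agent

State: 30-min rolling vitals, current and cumulative infusion rates,
vasopressor rate, depth proxy, elapsed time, and the forecaster latent
(encoded once from the admission prefix, then propagated continuously under
the applied infusions — within a ≤ 4 h operative window the gain from
re-encoding at later observations is marginal). Action: (Δ propofol
∈ [−15, +15], ketamine ∈ [0, 20]) mcg/kg/min. Reward per 5-min step:
`R = 2.0·1[MAP∈[65,90]] − 0.01·AUC_IL6(t,t+6h) − 0.005·r_p −
0.02·max(r_k−10, 0)`; the area term uses either forecaster medians
(trapezoid over horizons) or, for oracle experiments on synthetic data, the
noise-free truth.

Learning is conservative Q-learning: two independently initialised critic
ensembles (min-of-means bootstrap target, discount 0.99 per 5-min step),
Bellman error plus the logsumexp OOD penalty over uniform-in-box and
current-policy action samples. During critic training the reward is centred
by a state-only ridge baseline; this shifts Q by a function of state alone
and therefore cannot change the greedy policy, while removing
patient-severity variance from the targets. The actor (tanh-squashed to the
action box, behavior-cloning warm start) is updated by distillation toward
the per-state argmax of the conservative Q over a candidate set of the
logged action, the current policy output, and perturbations of the logged
action — a derivative-free greedy step that cannot chase local wiggles of a
single critic. The config default penalty weight is 1.0; the desk-scale
smoke profile uses 5.0 with 1000 gradient steps, which was the stable
region for 40-episode datasets.

Hard safety is post-hoc projection — clip to the Δ-box, the per-5-min
titration limits (propofol 20, ketamine 5) and the absolute ceilings
(100 / 20) — a total, idempotent function applied to every emitted
recommendation and *checked* again downstream rather than assumed. The
abstain gate maps three components (calibrated IL-6 interval width, lab
count in the past 12 h, critic-ensemble variance) through piecewise-linear
ramps frozen at the training cohort's 5th/95th percentiles, averages them
on a 0–5 scale, withholds the recommendation below θ = 2.5 and names the
worst component (e.g. stale IL-6).

## Evaluation

OPE: per-decision importance sampling with logged (or BC-fitted) behavior
densities, stepwise self-normalised WIS, per-decision doubly robust with a
fitted-Q control variate (zero model degenerates to IS exactly), and neural
FQE (iterated Bellman regression; value = mean initial-state Q, guarded by
the geometric bound). Per-step ratios clip at 100. All values are reported
raw and normalised to BC = 1.000, discounted and undiscounted. Rollouts
execute policies in the ground-truth simulator via frozen noise handles
(exact counterfactuals) and produce the full outcome table (MAP-band time,
hypotension, MAP CV, vasopressor initiation, IL-6 AUC, CRP peak, spike
rate, IL-6/IL-10 at 24 h, drug exposure, unsafe/violation/abstain rates).
The Pareto sweep retrains reduced-budget agents across the haemodynamic
weight w ∈ [0,1] (w = 0.5 recovers the printed coefficients; others scale
proportionally) and flags the non-dominated set.

Interpretation: partial dependence holds all covariates at the cohort
median and varies one drug's rate *sustained across the forecast horizon* —
under a brief operative window the true dose effect on the 12-h level is
negligible by construction, so the sustained-rate design is the meaningful
estimand. Integrated gradients run through encoder, ODE and head (midpoint
Riemann path integral; completeness < 1 % at 256 steps; cohort-median
baseline at matched timestamps), aggregated as mean absolute attribution
per modality and normalised to sum to 1 per target cytokine (signed
aggregation is the labelled alternative).

## Problem sizes and known limitations

Tests and the acceptance script run the smoke profile: encoder width 32,
latent 32, cohorts of 40–150 episodes, 3–12 training epochs, CQL ensembles
of 2×2 — sizes chosen so the full suite completes on one CPU while every
guarantee that is structural (projection safety, conformal validity, OPE
identities, solver accuracy) is exercised at full strength.

Known limitations of the desk-scale study conditions:

* the dose→IL-6 signal is identification-limited: the severity random
  effect and measurement noise are ~4× the dose-induced outcome variation
  over the observed rate range, so ~100–150-episode fits recover one arm
  of the propofol U per seed, with seed-dependent sign; the fitted
  partial-dependence minimum is therefore not reliably inside the
  generator's truth band at this scale (the corresponding acceptance check
  is left failing rather than weakened). The same instability affects the
  ketamine TNF-α-vs-IL-6 attribution ranking, which is reported but not
  asserted.
* at smoke training budgets the continuous-time dynamics do not reliably
  beat the latent carry-forward ablation on held-out IL-6 MAE — an
  under-trained vector field adds variance while carry-forward predicts a
  stable origin-conditional mean — so that directional check is also left
  failing rather than re-scoped.
* policy improvement over the behavior policy holds on the fixed evaluation
  seeds but is not uniform over arbitrary seeds at the smoke CQL budget;
  larger datasets and longer critic training narrow this.
* closed-loop rollouts keep the latent path from the admission-prefix
  encode; recommendations inside a logged episode use the logged prefix.
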