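# Methods

## The model

Drug removal by a continuous renal-replacement-therapy (RRT) circuit is
described by a one-compartment pharmacokinetic model with two elimination
routes — body clearance `CL_body` and circuit clearance `CL_RRT` — extended
with a membrane-adsorption site and an effluent-collection (bag) compartment:

```
dA1/dt = R(t) − CL_body/V · A1 − CL_RRT/V · A1
dA2/dt = CL_RRT/V · A1 · F_Ads · (1 − A2/Ads_max) − k_ads_rev · A2
dA3/dt = CL_RRT/V · A1 · (1 − F_Ads · (1 − A2/Ads_max)) + k_ads_rev · A2 − k_deg · A3
dA4/dt = Q_effl
```

`A1` is the amount in the central compartment (mg), `A2` the amount bound to
the dialysis membrane, `A3` the amount in the cumulated-effluent bag, `A4`
the bag volume (L), and `R(t)` the zero-order infusion input.  A fraction
`F_Ads` of the circuit clearance is routed to the membrane, optionally
capacity-limited (`Ads_max`, mg) and reversible (`k_ads_rev`, 1/h); drug in
the bag may degrade at `k_deg` (1/h).  `A2` opens with the first dose and
resets at filter changes; `A3`/`A4` reset at bag changes.  While the circuit
is interrupted all filter exchange stops; bag degradation continues.

Two parameterizations of the adsorption split are available.  Under
`constant_total_clrrt` (the default, shown above) the total clearance out of
plasma is constant: as the membrane saturates, the dialytic flux compensates.
Under `constant_dialysis_clrrt` the dialytic flux is the constant
`CL_RRT·(1 − F_Ads)` and the total declines as the membrane fills; the bag
equation is adjusted so the plasma outflow always equals adsorption flux plus
dialytic flux (mass balance).  The two coincide when `F_Ads = 0` or the
membrane is far from capacity.

### Observations

Five specimens are predicted from the state without any assumption about
filter or tubing volumes:

* pre-filter plasma: `A1/V`
* post-filter plasma: `A1/V · (1 − CL_RRT/Q_blood_adj · κ)`, where
  `Q_blood_adj = Q_blood·(1 − Hct + Hct·C_RBC/C_pl)` and `κ` corrects for
  post-filter replacement fluid and fluid removal when sampling precedes
  fluid addition (`κ = Q_adj/(Q_adj − (Q_RF_post + Q_FRR))`, else 1)
* effluent: `(A1/V · CL_RRT − dA2/dt)/Q_effl` — the instantaneous removal
  flux minus what the membrane is currently taking up (or plus what it is
  releasing), per effluent flow `Q_effl = Q_dial + Q_RF_pre + Q_RF_post + Q_FRR`
* cumulated-effluent concentration: `A3/A4`
* cumulated-effluent volume: `A4`

`dA2/dt` is emitted analytically from the same right-hand-side evaluation as
the state, never by finite differences.  An alternative hematocrit-based
post-filter dilution correction (paired pre/post hematocrit) is available and
mutually exclusive with the flow-based one.

### Conventional clearance estimators

The four conventional estimators are closed-form: extraction-based
(`Q_adj·(c_pre − c_post)/c_pre`), saturation-coefficient
(`Q_effl·c_effl/c_pre`), and the mass-balance amount in the bag; the
"reduced" approach infers `CL_RRT` purely from the plasma contrast between
patients on and off RRT.

## Numerical solution

Between events the system is integrated in closed form whenever the membrane
is non-saturable (`Ads_max = ∞`): the cascade is then linear and lower
triangular, and each coefficient-constant segment is propagated with
exponential convolution identities (with a matrix-exponential fallback when
two rate constants nearly coincide).  Saturable runs use LSODA with relative
tolerance 1e-8 and absolute tolerance 1e-10 mg, stopping and restarting at
every event so resets are exact jumps, with dense output between events.
Both paths agree to ~1e-9 relative on the trial schedules.

During estimation the candidate model is additionally time-invariant (doses
and bag changes only), so trajectories are evaluated by superposition of
per-dose step/impulse responses, vectorized over all doses and observation
times; bag resets subtract the carried-over bag state using linearity.  This
is exact and roughly an order of magnitude faster than segment marching,
which is what makes the replicated simulation–estimation studies tractable.
Because flow rates never enter the mass dynamics, subjects who share a
schedule share one trajectory per likelihood evaluation; volumes and effluent
concentrations rescale per subject by their individual effluent flow.

A mass-balance audit integrates the full system numerically with two
bookkeeping ledgers (drug degraded in the bag, drug eliminated by the body)
plus a discard ledger for bag/filter changes, and verifies that dosed drug is
fully accounted for at every grid point to 1e-6 relative.

## The virtual-trial generator

The generator emulates a CVVHD study: 10 dialysis patients (blood flow
10 L/h, hematocrit 0.3, red-cell drug concentration zero, dialysate flow
drawn once per subject from U(3.0, 3.3) L/h) and 10 patients off RRT
(`CL_RRT = 0`, pre-filter plasma only).  Five doses are given as 0.5 h
infusions; pre-filter, post-filter and effluent samples are drawn at
0.5/1/2/4/6/8 h (8 h interval) or 1/2/4/6/8/12 h (12 h interval) after the
first and the fifth dose, and one cumulated-effluent collection
(concentration + bag volume) spans each sampled interval, the bag being
reset at the interval start.  Residual error is proportional with 25% CV on
all concentrations and 10% on volumes; an optional additive component exists
but is off by default.  Inter-individual variability is log-normal with 30%
CV on `CL_body` and `V_cent`.  `CL_RRT` and the adsorption/degradation
constants carry no between-subject variability: they are properties of the
drug, circuit and membrane rather than of the patient.  Simulated values are
floored at 1e-9 mg/L (a 3.9-sigma event for the 25% error) so proportional
likelihoods remain defined.

Randomness is split hierarchically (trial → subject → parameter/noise
streams), so a subject's parameters are invariant to edits elsewhere in the
design and a seed fully determines a trial.

### Drug library

Two library constants are anchored: piperacillin body clearance 3 L/h and
colistin body clearance 2 L/h.  All other constants are literature-typical
reconstructions for critically ill patients and are flagged as such:
piperacillin 4000 mg q8h, V 22 L (t½ ≈ 5 h off RRT); colistin 150 mg q12h,
V 35 L (t½ ≈ 12 h); linezolid 600 mg q12h, CL 7 L/h, V 45 L; tigecycline
50 mg q12h, CL 20 L/h, V 350 L.  Scenario presets: the four base drugs with
`CL_RRT = CL_body`; piperacillin with bag degradation `k_deg = 0.03` 1/h
(half-life ≈ 24 h) at an 8 h or 12 h collection interval; colistin with 65%
irreversible non-saturable adsorption; colistin with 95% reversible
adsorption at `k_ads_rev = 0.07` 1/h.

## Estimation

Five model variants are fitted by maximum likelihood, distinguished by the
specimens they use: reduced (pre-filter plasma only), post-filter, effluent,
cumulated-effluent (concentration and volume enter as separate observations,
so concentrations without a paired volume still contribute), and the
integrated model using all five specimens, which alone may estimate the
adsorption parameters (`F_Ads`, optionally `k_ads_rev` and `Ads_max`) and the
degradation rate.  Estimating adsorption requires at least two specimen
families among post-filter, effluent and cumulated effluent; the fit refuses
otherwise.  Conventional variants force `F_Ads = k_deg = 0`.

Residual error is proportional per observation class (concentrations vs
volumes) with the error variances profiled out analytically at their
conditional maxima.  Parameters are optimized on log scales (`F_Ads` on
logit) by Nelder–Mead, with data-driven initial estimates (log-linear plasma
regression; specimen-ratio heuristics) and optional jittered multi-starts.
BLQ records are excluded from the likelihood (loaded as missing).  Records
with non-positive predictions for positive observations make the candidate
infeasible (fixed large penalty).

Two population approximations are provided:

* **Naive pooled** — one typical parameter vector for the whole trial.  Used
  for the likelihood-ratio power analyses, where the reduced model's
  information *is* the pooled contrast between the on- and off-RRT arms.
* **Two-stage (default for accuracy/precision studies)** — every subject is
  fitted individually (off-RRT subjects contribute `CL_body`, `V_cent`
  only), parameters are aggregated as geometric means (the natural location
  estimate under log-normal variability), and the circuit-shared parameters
  (`CL_RRT`, `F_Ads`, `k_ads_rev`, `Ads_max`, `k_deg`) are then re-estimated
  by pooled maximum likelihood across the dialysis subjects with each
  subject's volume and *total* plasma clearance fixed at their stage-1
  values (body clearance absorbs the complement so plasma decays are
  preserved).

The two-stage design is deliberate.  A naive pooled fit with a control arm
cannot let the body clearance absorb elimination the model does not describe
(e.g. unmodelled adsorption), because the off-RRT arm pins it; a hierarchical
model resolves this through individual parameters.  The two-stage estimator
restores exactly that flexibility at a fraction of the cost of a marginal
(FOCE/Laplace-type) likelihood, and the pooled refinement stage reflects that
the adsorption/degradation constants are shared across subjects — a single
subject's one or two bag collections carry almost no information about
`k_deg` on their own.

### Detection of a circuit clearance

`dOFV = OFV(null) − OFV(full) > 3.84` (χ², 1 df, α = 0.05) declares
detection.  For the test, `CL_RRT` is estimated on an unconstrained (linear)
scale so the null lies in the parameter interior and the asymptotic χ²
calibration holds; the type-I error is ~5% when the pooled likelihood is
correctly specified (no IIV).  With IIV present the pooled test is
anticonservative — it trades calibration for sensitivity and is used for
power comparisons between variants, not for inference on real data.  When
the null model cannot predict positive effluent observations at all (its
likelihood is zero), the test is decided for detection outright.
Non-converged fits count as "not detected".

Replicated simulation–estimation fits start from the simulated true values,
following the convention of the established SSE tooling in this field.

## Simulation–estimation studies

Per replicate: simulate a trial, fit the requested variants, record
estimates and (optionally) the detection flag.  Aggregates follow the usual
conventions: `rBias = 100·mean((est − true)/true)`,
`rRMSE = 100·sqrt(mean(((est − true)/true)²))`, power = percent detected,
with binomial Monte-Carlo standard errors reported for power.  Non-converged
replicates are excluded from rBias/rRMSE (and counted) and scored undetected
for power.  The default replicate count is 1000; the packaged studies and
`scripts/acceptance.py` use 100 replicates per condition (20 per point on
the five-point clearance grid), which keeps every study within a few minutes
on one CPU at Monte-Carlo standard errors of roughly 0.4–4 percentage points
depending on the metric.

## What the virtual trials do and do not show

The generator reproduces the stated design faithfully — arm sizes, sampling
times, flow settings, residual magnitudes, preset process parameters — but
real dialysis data differ in ways the tests cannot probe: multi-compartment
disposition, time-varying circuit settings, clotting-driven filter changes,
BLQ censoring, assay-specific error structure, and intermittent RRT (out of
scope).  Conclusions about estimator *structure* (which specimen identifies
which process, which biases are forced by unmodelled adsorption or
degradation) transfer; exact bias magnitudes in the adsorption scenarios
depend on the reconstructed drug constants (volume, dose, interval), since
they set how much of the membrane depot returns within the sampled window.

## Known limitations

* No marginal-likelihood (FOCE/Laplace/SAEM) estimation and no IIV or
  standard-error estimation; the two-stage estimator is the population
  approximation.
* The effluent-flow covariate on `CL_RRT` is implemented
  (linear-proportional, normalized to 3 L/h) but off by default; enabling it
  disables trajectory sharing across subjects.
* Pre-dilution "efficiency correction factors" are intentionally absent: the
  mass balance needs none.
* BLQ handling is exclusion-only; likelihood-based censoring methods are not
  implemented.
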