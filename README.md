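# rrtpk

Pharmacokinetic modelling of drug removal by continuous renal replacement
therapy (RRT).

When a patient is on continuous dialysis (CVVHD/CVVH/CVVHDF), the
extracorporeal circuit is an extra elimination route whose size —
CL<sub>RRT</sub> — drives dose adjustment, yet it is usually estimated from a
single specimen at a time: pre/post-filter plasma pairs, spot effluent
samples, or the drug amount collected in the effluent waste bag.  Each of
those conventional estimates is blind to part of the physics: drug that
adsorbs to the dialysis membrane never reaches the bag, and drug that
degrades while the bag fills is not there when the bag is measured.

`rrtpk` is for pharmacometricians and clinical-pharmacology researchers who
design or analyze dialysis PK studies.  It provides:

* an **integrated multi-specimen dialysis model** — a one-compartment PK
  model with circuit clearance, a saturable/reversible membrane-adsorption
  compartment and effluent degradation, describing all five measurable
  specimens simultaneously:

  dA₁/dt = R(t) − (CL_body + CL_RRT)/V · A₁
  dA₂/dt = CL_RRT/V · A₁ · F_Ads · (1 − A₂/Ads_max) − k_ads,rev · A₂
  dA₃/dt = CL_RRT/V · A₁ · (1 − F_Ads · (1 − A₂/Ads_max)) + k_ads,rev · A₂ − k_deg · A₃
  dA₄/dt = Q_effl

  with observations c_pre = A₁/V, c_post = c_pre·(1 − CL_RRT/Q_blood,adj·κ),
  c_effl = (c_pre·CL_RRT − dA₂/dt)/Q_effl, c_cum = A₃/A₄ and V_cum = A₄;

* the four **conventional clearance estimators** (hematocrit-adjusted
  extraction, saturation coefficient, cumulated-effluent mass balance,
  on/off-RRT plasma contrast);
* a **virtual dialysis-trial simulator** (10 CVVHD + 10 off-RRT patients,
  rich sampling at the first and fifth dose, 25%/10% proportional residual
  error) with presets for degradation and adsorption conditions;
* **maximum-likelihood estimation** of five model variants (reduced,
  post-filter, effluent, cumulated-effluent, integrated) plus
  likelihood-ratio detection of CL_RRT;
* a **simulation–estimation engine** producing relative bias, relative RMSE
  and detection power across replicated virtual trials.

See `docs/methods.md` for the model, the estimators and the design choices.

## Worked example

Spot clearance algebra from a single sampling instant — blood flow 10 L/h,
hematocrit 0.3, dialysate flow 3 L/h, pre-filter plasma 10 mg/L, post-filter
5 mg/L, effluent 4 mg/L:

```text
$ rrtpk calc --q-blood 10 --hct 0.3 --q-dial 3 --c-pre 10 --c-post 5 --c-effl 4
Q_blood_adj = 7 L/h
Q_effl      = 3 L/h
CL_RRT (post-filter) = 3.5 L/h
CL_RRT (effluent)    = 1.2 L/h
```

The adjusted blood flow is 10·(1 − 0.3) = 7 L/h; the extraction-based
clearance is 7·(10 − 5)/10 = 3.5 L/h while the effluent-based one is only
3·4/10 = 1.2 L/h — exactly the kind of discrepancy (membrane adsorption, or
a real mass-balance problem) the integrated model is built to resolve.

Simulate a virtual trial in which piperacillin degrades in the effluent bag
(half-life ≈ 24 h) and fit the conventional cumulated-effluent model, which
ignores degradation:

```text
$ rrtpk simulate --scenario degradation_8h --seed 1 --out trial.csv
$ rrtpk fit --data trial.csv --variant cum_effluent --n-starts 1
{
  "converged": true,
  "n_obs": 280,
  "params": {
    "CL_RRT": 2.755,
    "CL_body": 2.681,
    "V_cent": 24.31
  },
  ...
}
```

The true circuit clearance is 3 L/h: this single replicate under-estimates
it by ~8% because part of the removed drug degraded before the bag was
measured (across 100 replicates the bias settles near −13%).  Fitting the
integrated variant with `--estimate-degradation` recovers both the clearance
and the degradation rate.

Replicated studies run through the `sse` subcommand, e.g.

```bash
rrtpk sse --scenario adsorption_irreversible --variant effluent --variant idp \
      --reps 100 --seed 1 --lrt --out summary.csv
```

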