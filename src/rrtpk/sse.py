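"""Stochastic simulation-estimation (SSE) studies.

Repeated simulate-then-refit cycles quantify how well each model variant
recovers the circuit clearance (and, for the integrated variant, the
adsorption and degradation parameters) under a given study condition:

* accuracy — relative bias, ``rBias = 100 * mean((est - true) / true)``,
* precision — ``rRMSE = 100 * sqrt(mean(((est - true) / true)^2))``,
* sensitivity — power, the fraction of replicates in which the
  likelihood-ratio test detects the clearance.

Following common practice for simulation-estimation tooling, each replicate
is re-estimated starting from the simulated true values; non-converged
replicates are excluded from the bias/precision aggregates (and counted) and
scored as not-detected for power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .fitting import ModelVariant, fit, fit_two_stage, lrt_detect_clrrt, prepare_subjects
from .trial import ScenarioPreset, make_scenario, simulate_trial

__all__ = [
    "SSEConfig",
    "SSEResult",
    "rbias",
    "rrmse",
    "power",
    "power_se",
    "run_sse",
    "run_power",
    "variant_for_scenario",
]


def rbias(estimates: Sequence[float], truth: float) -> float:
    """Relative bias in percent: ``100 * mean((est - truth) / truth)``."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("empty estimate sequence")
    if truth == 0:
        raise ValueError("relative bias undefined for a zero truth (report power instead)")
    return 100.0 * float(np.mean((est - truth) / truth))


def rrmse(estimates: Sequence[float], truth: float) -> float:
    """Relative root-mean-squared error in percent."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("empty estimate sequence")
    if truth == 0:
        raise ValueError("relative RMSE undefined for a zero truth")
    rel = (est - truth) / truth
    return 100.0 * float(math.sqrt(np.mean(rel * rel)))


def power(detected: Sequence[bool]) -> float:
    """Detection rate in percent; non-converged replicates enter as False."""
    det = np.asarray(detected, dtype=bool)
    if det.size == 0:
        raise ValueError("empty detection sequence")
    return 100.0 * float(np.mean(det))


def power_se(p_percent: float, n: int) -> float:
    """Binomial Monte-Carlo standard error of a power estimate, in percent."""
    p = p_percent / 100.0
    return 100.0 * math.sqrt(max(p * (1.0 - p), 0.0) / n)


def variant_for_scenario(name: str, scenario: Union[str, ScenarioPreset]) -> ModelVariant:
    """The model variant to fit for a scenario.

    The integrated variant estimates the processes the scenario simulates
    (degradation rate, adsorbed fraction, desorption rate); conventional
    variants never do.
    """
    sc_name = scenario if isinstance(scenario, str) else scenario.name
    if name != "idp":
        return ModelVariant(name)
    if sc_name.startswith("degradation"):
        return ModelVariant("idp", estimate_degradation=True)
    if sc_name == "adsorption_irreversible":
        return ModelVariant("idp", estimate_adsorption=True)
    if sc_name == "adsorption_reversible":
        return ModelVariant("idp", estimate_adsorption=True, adsorption_reversible=True)
    return ModelVariant("idp")


@dataclass(frozen=True)
class SSEConfig:
    scenario: Union[str, ScenarioPreset]
    variants: Tuple[Union[str, ModelVariant], ...]
    n_replicates: int = 1000
    seed: int = 1
    clrrt: Optional[float] = None  # absolute truth override, L/h
    clrrt_frac: Optional[float] = None  # truth as a fraction of CL_body
    do_lrt: bool = False  # likelihood-ratio detection per replicate
    n_starts: int = 1  # optimizer starts per fit (replicates start at truth)
    approximation: str = "two_stage"  # "two_stage" or "pooled" population fits

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SSEResult:
    config: SSEConfig
    replicates: pd.DataFrame  # one row per (replicate, variant)
    summary: pd.DataFrame  # one row per (variant, parameter) with rBias/rRMSE
    truth: Dict[str, float] = field(default_factory=dict)
    n_nonconverged: Dict[str, int] = field(default_factory=dict)

    def metric(self, variant: str, parameter: str, name: str) -> float:
        row = self.summary[
            (self.summary["variant"] == variant) & (self.summary["parameter"] == parameter)
        ]
        if row.empty:
            raise KeyError(f"no summary row for ({variant}, {parameter})")
        return float(row.iloc[0][name])


_TRACKED = ["CL_RRT", "CL_body", "V_cent", "F_Ads", "k_ads_rev", "k_deg"]


def run_sse(config: SSEConfig) -> SSEResult:
    """Run the full simulate-fit loop for one scenario.

    Deterministic given ``(config, seed)``: replicate random streams are
    spawned from the root seed, and every fit starts from the simulated
    truth (plus optional jittered extra starts).
    """
    design, population, preset = make_scenario(
        config.scenario, clrrt=config.clrrt, clrrt_frac=config.clrrt_frac
    )
    variants = [
        v if isinstance(v, ModelVariant) else variant_for_scenario(v, preset)
        for v in config.variants
    ]
    typ = population.typical
    truth = {
        "CL_RRT": typ.CL_RRT, "CL_body": typ.CL_body, "V_cent": typ.V_cent,
        "F_Ads": typ.F_Ads, "k_ads_rev": typ.k_ads_rev, "k_deg": typ.k_deg,
    }
    init = {k: v for k, v in truth.items() if v > 0}

    root = np.random.SeedSequence(config.seed)
    rep_seeds = root.spawn(config.n_replicates)
    rows: List[dict] = []
    for r in range(config.n_replicates):
        trial = simulate_trial(design, population, rep_seeds[r])
        subjects = prepare_subjects(trial.noisy)
        for variant in variants:
            row = {"replicate": r, "variant": variant.name}
            if config.do_lrt:
                lrt = lrt_detect_clrrt(subjects, variant, init=init,
                                       n_starts=config.n_starts, seed=r)
                row.update(
                    dofv=lrt.dofv, detected=lrt.detected, converged=lrt.converged
                )
                for p in _TRACKED:
                    row[p] = lrt.fit_full.params.get(p, np.nan)
            else:
                if config.approximation == "two_stage" and variant.name != "reduced":
                    fr = fit_two_stage(subjects, variant, init=init,
                                       n_starts=config.n_starts, seed=r)
                else:
                    fr = fit(subjects, variant, init=init,
                             n_starts=config.n_starts, seed=r)
                row.update(converged=fr.converged, ofv=fr.ofv)
                for p in _TRACKED:
                    row[p] = fr.params.get(p, np.nan)
            rows.append(row)

    reps = pd.DataFrame(rows)
    summary_rows = []
    nonconv: Dict[str, int] = {}
    for variant in variants:
        sel = reps[reps["variant"] == variant.name]
        conv = sel[sel["converged"]]
        nonconv[variant.name] = int(len(sel) - len(conv))
        for p in _TRACKED:
            if truth[p] <= 0 or p not in conv or conv[p].isna().all():
                continue
            est = conv[p].dropna().to_numpy()
            if est.size == 0:
                continue
            summary_rows.append(
                {
                    "variant": variant.name,
                    "parameter": p,
                    "truth": truth[p],
                    "n": est.size,
                    "rbias": rbias(est, truth[p]),
                    "rrmse": rrmse(est, truth[p]),
                }
            )
        if config.do_lrt:
            det = sel["detected"].to_numpy(dtype=bool)  # non-converged stay False
            summary_rows.append(
                {
                    "variant": variant.name,
                    "parameter": "power",
                    "truth": np.nan,
                    "n": det.size,
                    "rbias": np.nan,
                    "rrmse": np.nan,
                    "power": power(det),
                    "power_se": power_se(power(det), det.size),
                }
            )
    summary = pd.DataFrame(summary_rows)
    return SSEResult(
        config=config, replicates=reps, summary=summary, truth=truth,
        n_nonconverged=nonconv,
    )


def run_power(
    scenario: Union[str, ScenarioPreset],
    variant: Union[str, ModelVariant],
    clrrt_frac: float,
    n_replicates: int = 100,
    seed: int = 1,
) -> Tuple[float, float]:
    """Detection power (and its binomial SE) at one point of a power curve."""
    cfg = SSEConfig(
        scenario=scenario,
        variants=(variant,),
        n_replicates=n_replicates,
        seed=seed,
        clrrt_frac=clrrt_frac,
        do_lrt=True,
    )
    res = run_sse(cfg)
    name = variant if isinstance(variant, str) else variant.name
    row = res.summary[
        (res.summary["variant"] == name) & (res.summary["parameter"] == "power")
    ].iloc[0]
    return float(row["power"]), float(row["power_se"])
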