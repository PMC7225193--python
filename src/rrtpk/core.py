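"""Domain types and mass-balance algebra for drug clearance by continuous RRT.

Continuous renal replacement therapy (CRRT) removes drug from blood passing
through an extracorporeal circuit.  The clearance mediated by the circuit
(``CL_RRT``) can be computed from several specimens:

* pre-/post-filter plasma concentrations together with the hematocrit-adjusted
  blood flow rate (extraction-based clearance),
* the effluent concentration together with the total effluent flow rate
  (saturation-coefficient clearance),
* the drug amount recovered in the cumulated effluent bag (mass balance).

This module holds the parameter containers, the closed-form clearance algebra
for the conventional estimators, and the pointwise observation model that maps
a compartmental state onto each of the five measurable specimens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

__all__ = [
    "SpecimenType",
    "RRTSettings",
    "PKParameters",
    "StateVector",
    "ObservationRecord",
    "UndefinedClearanceError",
    "InvalidSettingsError",
    "InvalidParameterError",
    "adjusted_blood_flow",
    "clrrt_from_postfilter",
    "correct_postfilter_conc",
    "total_effluent_flow",
    "clrrt_from_effluent",
    "predict_observation",
    "CONSTANT_TOTAL_CLRRT",
    "CONSTANT_DIALYSIS_CLRRT",
]

CONSTANT_TOTAL_CLRRT = "constant_total_clrrt"
CONSTANT_DIALYSIS_CLRRT = "constant_dialysis_clrrt"


class UndefinedClearanceError(ValueError):
    """Raised when a clearance is requested for a zero reference concentration."""


class InvalidSettingsError(ValueError):
    """Raised when circuit settings make a requested computation meaningless."""


class InvalidParameterError(ValueError):
    """Raised for inconsistent pharmacokinetic parameter combinations."""


class SpecimenType(IntEnum):
    """The five measurable RRT specimens.

    Integer codes double as the ``DVID`` column values of the CSV dialect.
    """

    PRE_PLASMA = 1
    POST_PLASMA = 2
    EFFLUENT = 3
    CUM_EFFL_CONC = 4
    CUM_EFFL_VOL = 5

    @property
    def is_concentration(self) -> bool:
        return self is not SpecimenType.CUM_EFFL_VOL


@dataclass(frozen=True)
class RRTSettings:
    """Machine settings of one continuous RRT circuit.

    All flow rates are in L/h.  ``c_rbc_ratio`` is the ratio of the drug
    concentration in red blood cells to the pre-filter plasma concentration
    (dimensionless); for drugs that do not enter erythrocytes it is zero.
    ``postfilter_sampled_before_RF`` marks post-filter plasma samples drawn
    before post-filter replacement fluid is added, which requires a dilution
    correction in both the clearance algebra and the observation model.
    """

    Q_blood: float
    Hct: float
    Q_dial: float = 0.0
    Q_RF_pre: float = 0.0
    Q_RF_post: float = 0.0
    Q_FRR: float = 0.0
    c_rbc_ratio: float = 0.0
    membrane_id: str = ""
    postfilter_sampled_before_RF: bool = False

    def __post_init__(self) -> None:
        for name in ("Q_blood", "Q_dial", "Q_RF_pre", "Q_RF_post", "Q_FRR"):
            if getattr(self, name) < 0:
                raise InvalidSettingsError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.Hct < 1.0:
            raise InvalidSettingsError(f"Hct must be in [0, 1), got {self.Hct}")
        if self.c_rbc_ratio < 0:
            raise InvalidSettingsError(f"c_rbc_ratio must be >= 0, got {self.c_rbc_ratio}")


@dataclass(frozen=True)
class PKParameters:
    """Structural parameters of one individual.

    ``CL_body`` (L/h) and ``V_cent`` (L) describe the patient; ``CL_RRT``
    (L/h) the total circuit-mediated clearance, of which the fraction
    ``F_Ads`` is routed to the membrane adsorption site.  ``Ads_max`` (mg) is
    the membrane binding capacity (``inf`` = non-saturable), ``k_ads_rev``
    (1/h) the desorption rate and ``k_deg`` (1/h) the first-order degradation
    rate of drug in the collected effluent bag.

    Two parameterizations of the adsorption split are supported: under
    ``constant_total_clrrt`` the total clearance out of the central
    compartment is constant and dialytic removal compensates as the membrane
    saturates; under ``constant_dialysis_clrrt`` the dialytic component is
    constant so the total declines as the membrane fills.
    """

    CL_body: float
    V_cent: float
    CL_RRT: float = 0.0
    F_Ads: float = 0.0
    Ads_max: float = math.inf
    k_ads_rev: float = 0.0
    k_deg: float = 0.0
    parameterization: str = CONSTANT_TOTAL_CLRRT

    def __post_init__(self) -> None:
        if self.CL_body <= 0 or self.V_cent <= 0:
            raise InvalidParameterError("CL_body and V_cent must be > 0")
        if self.CL_RRT < 0:
            raise InvalidParameterError("CL_RRT must be >= 0")
        if not 0.0 <= self.F_Ads <= 1.0:
            raise InvalidParameterError("F_Ads must be within [0, 1]")
        if self.Ads_max <= 0:
            raise InvalidParameterError("Ads_max must be > 0 (use inf for non-saturable)")
        if self.k_ads_rev < 0 or self.k_deg < 0:
            raise InvalidParameterError("k_ads_rev and k_deg must be >= 0")
        if self.parameterization not in (CONSTANT_TOTAL_CLRRT, CONSTANT_DIALYSIS_CLRRT):
            raise InvalidParameterError(f"unknown parameterization {self.parameterization!r}")


@dataclass
class StateVector:
    """Compartmental amounts: central (mg), membrane-bound (mg), cumulated
    effluent (mg) and cumulated effluent volume (L)."""

    A1: float = 0.0
    A2: float = 0.0
    A3: float = 0.0
    A4: float = 0.0


@dataclass(frozen=True)
class ObservationRecord:
    """A single measured value of one specimen at one time point."""

    subject_id: str
    time: float
    specimen: SpecimenType
    value: float
    blq_flag: bool = False
    occasion: int = 1

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be >= 0")


def adjusted_blood_flow(settings: RRTSettings) -> float:
    """Blood flow corrected for hematocrit and red-blood-cell partitioning.

    ``Q_adj = Q_blood * (1 - Hct + Hct * c_rbc_ratio)``.  For a drug absent
    from erythrocytes only the plasma fraction of blood carries drug; a drug
    partitioning equally (ratio 1) sees the full blood flow.
    """
    return settings.Q_blood * (1.0 - settings.Hct + settings.Hct * settings.c_rbc_ratio)


def clrrt_from_postfilter(c_pre: float, c_post: float, q_adj: float) -> float:
    """Extraction-based RRT clearance from paired pre-/post-filter plasma.

    ``CL_RRT = Q_adj * (c_pre - c_post) / c_pre``.  ``c_post > c_pre``
    (negative extraction) is accepted — residual assay error can produce it —
    and simply yields a negative clearance for the caller to flag.
    """
    if c_pre <= 0:
        raise UndefinedClearanceError("pre-filter concentration must be > 0")
    return q_adj * (c_pre - c_post) / c_pre


def correct_postfilter_conc(
    c_post_meas: float,
    settings: RRTSettings,
    mode: str = "flow",
    hct_pre: Optional[float] = None,
    hct_post: Optional[float] = None,
) -> float:
    """Correct a post-filter plasma concentration for replacement-fluid dilution.

    ``mode="flow"`` rescales by the plasma flow lost to fluid removal and
    post-filter replacement:
    ``c_corr = c_meas * (Q_adj - (Q_RF_post + Q_FRR)) / Q_adj``.

    ``mode="hematocrit"`` instead normalizes by paired hematocrit
    measurements, which captures dilution without knowing the flow rates:
    the red-cell volume stream is conserved across the filter, so the
    plasma-flow ratio post/pre is ``(hct_pre / hct_post) *
    ((1 - hct_post) / (1 - hct_pre))`` and concentrations are rescaled by it.
    The two modes are mutually exclusive.
    """
    if mode == "flow":
        q_adj = adjusted_blood_flow(settings)
        removed = settings.Q_RF_post + settings.Q_FRR
        if q_adj - removed <= 0:
            raise InvalidSettingsError(
                "adjusted blood flow must exceed Q_RF_post + Q_FRR for the "
                f"dilution correction (Q_adj={q_adj:.4g}, removed={removed:.4g})"
            )
        return c_post_meas * (q_adj - removed) / q_adj
    if mode == "hematocrit":
        if hct_pre is None or hct_post is None:
            raise InvalidSettingsError("hematocrit mode requires paired hct_pre and hct_post")
        if not (0 < hct_pre < 1 and 0 < hct_post < 1):
            raise InvalidSettingsError("hematocrit values must lie in (0, 1)")
        plasma_flow_ratio = (hct_pre / hct_post) * ((1.0 - hct_post) / (1.0 - hct_pre))
        return c_post_meas * plasma_flow_ratio
    raise ValueError(f"unknown correction mode {mode!r}")


def total_effluent_flow(settings: RRTSettings) -> float:
    """Total effluent flow: dialysate + both replacement fluids + fluid removal."""
    return settings.Q_dial + settings.Q_RF_pre + settings.Q_RF_post + settings.Q_FRR


def clrrt_from_effluent(c_effl: float, c_pre: float, q_effl: float) -> float:
    """Saturation-coefficient RRT clearance: ``Q_effl * c_effl / c_pre``."""
    if c_pre <= 0:
        raise UndefinedClearanceError("pre-filter concentration must be > 0")
    return q_effl * c_effl / c_pre


def rrt_bounds_ok(params: PKParameters, settings: RRTSettings) -> bool:
    """True when CL_RRT respects both physical flow bounds.

    A clearance exceeding the adjusted blood flow or the effluent flow would
    imply negative post-filter or super-unity saturation predictions.
    """
    q_adj = adjusted_blood_flow(settings)
    q_effl = total_effluent_flow(settings)
    ok = params.CL_RRT <= q_adj
    if q_effl > 0:
        ok = ok and params.CL_RRT <= q_effl
    return ok


def predict_observation(
    state: StateVector,
    params: PKParameters,
    settings: RRTSettings,
    specimen: SpecimenType,
    dA2_dt: Optional[float] = None,
) -> float:
    """Noise-free prediction of one specimen from the compartmental state.

    * pre-filter plasma: ``A1 / V_cent``
    * post-filter plasma: pre-filter times ``(1 - CL_RRT / Q_adj)``, with the
      replacement-fluid factor when sampling precedes fluid addition
    * effluent: the instantaneous removal flux minus the adsorption flux, per
      effluent flow — requires ``dA2_dt`` from the same model evaluation
    * cumulated effluent concentration: ``A3 / A4``
    * cumulated effluent volume: ``A4``
    """
    c_pre = state.A1 / params.V_cent
    if specimen is SpecimenType.PRE_PLASMA:
        return c_pre
    if specimen is SpecimenType.POST_PLASMA:
        q_adj = adjusted_blood_flow(settings)
        factor = 1.0
        if settings.postfilter_sampled_before_RF:
            removed = settings.Q_RF_post + settings.Q_FRR
            if q_adj - removed <= 0:
                raise InvalidSettingsError("Q_adj must exceed Q_RF_post + Q_FRR")
            factor = q_adj / (q_adj - removed)
        return c_pre - c_pre * (params.CL_RRT / q_adj) * factor
    if specimen is SpecimenType.EFFLUENT:
        q_effl = total_effluent_flow(settings)
        if q_effl <= 0:
            raise InvalidSettingsError("effluent prediction requires Q_effl > 0")
        if dA2_dt is None:
            raise ValueError("effluent prediction requires the instantaneous dA2/dt")
        return c_pre * params.CL_RRT / q_effl - dA2_dt / q_effl
    if specimen is SpecimenType.CUM_EFFL_CONC:
        if state.A4 <= 0:
            raise UndefinedClearanceError("cumulated effluent concentration undefined for A4 = 0")
        return state.A3 / state.A4
    if specimen is SpecimenType.CUM_EFFL_VOL:
        return state.A4
    raise ValueError(f"unknown specimen {specimen!r}")
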