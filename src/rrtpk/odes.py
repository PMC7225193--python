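"""Compartmental dynamics of drug removal by a continuous RRT circuit.

The model tracks four amounts per subject: drug in the central compartment
(``A1``, mg), drug bound to the dialysis membrane (``A2``, mg), drug in the
cumulated effluent bag (``A3``, mg) and the bag volume (``A4``, L).  Removal
from plasma splits into a membrane-adsorption flux — a fraction ``F_Ads`` of
the circuit clearance, optionally saturable (``Ads_max``) and reversible
(``k_ads_rev``) — and a dialytic flux collected in the bag, where the drug may
degrade with rate ``k_deg``.  Dosing, filter changes (``A2 -> 0``), bag
changes (``A3, A4 -> 0``) and circuit interruptions are hard state events.

Two solvers are provided.  When the membrane is non-saturable the system is
linear with piecewise-constant coefficients and is propagated segment-by-
segment in closed form (exponential convolutions), which is exact and fast
enough for simulation-estimation studies.  The general solver integrates the
full right-hand side numerically with a stiff-capable method and is also the
reference for the mass-balance audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .core import (
    CONSTANT_TOTAL_CLRRT,
    PKParameters,
    RRTSettings,
    total_effluent_flow,
)

__all__ = [
    "EventKind",
    "EventRecord",
    "Trajectory",
    "IntegrationError",
    "rhs",
    "solve_subject",
    "mass_balance_audit",
    "AuditReport",
]


class IntegrationError(RuntimeError):
    """Numeric integration failed; carries subject id and time context."""


class EventKind(Enum):
    DOSE = "dose"
    FILTER_CHANGE = "filter_change"
    BAG_CHANGE = "bag_change"
    RRT_ON = "rrt_on"
    RRT_OFF = "rrt_off"
    SETTINGS_CHANGE = "settings_change"


@dataclass(frozen=True)
class EventRecord:
    subject_id: str
    time: float
    kind: EventKind
    amount: float = 0.0  # mg, DOSE only
    duration: float = 0.0  # h; 0 = bolus
    settings: Optional[RRTSettings] = None  # SETTINGS_CHANGE only

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.kind is EventKind.DOSE and self.amount <= 0:
            raise ValueError("dose amount must be > 0")
        if self.kind is EventKind.SETTINGS_CHANGE and self.settings is None:
            raise ValueError("settings change requires new settings")


@dataclass
class Trajectory:
    """State evaluated at requested times, with the fluxes the observation
    model needs (instantaneous ``dA2/dt`` and pre-degradation effluent
    inflow) emitted from the same model evaluation."""

    times: np.ndarray
    states: np.ndarray  # (n, 4): A1, A2, A3, A4
    dA2_dt: np.ndarray
    effl_inflow: np.ndarray  # mg/h into the bag, before degradation
    q_effl: np.ndarray  # effluent flow in effect at each time
    rrt_active: np.ndarray
    discard_events: List[Tuple[float, float]] = field(default_factory=list)
    degraded: Optional[np.ndarray] = None  # numeric path only
    eliminated_body: Optional[np.ndarray] = None  # numeric path only

    @property
    def A1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def A2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def A3(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def A4(self) -> np.ndarray:
        return self.states[:, 3]


def rhs(
    state: Sequence[float],
    params: PKParameters,
    settings: RRTSettings,
    rrt_active: bool = True,
    infusion_rate: float = 0.0,
) -> np.ndarray:
    """Time derivative of (A1, A2, A3, A4).

    While the circuit is interrupted all exchange with the membrane and the
    bag stops (no flow through the filter) but degradation in the already
    collected effluent continues.
    """
    A1, A2, A3, _A4 = state
    v = params.V_cent
    d1 = infusion_rate - params.CL_body / v * A1
    if not rrt_active or params.CL_RRT == 0.0:
        return np.array([d1, 0.0, -params.k_deg * A3, 0.0])

    sat = 1.0 if math.isinf(params.Ads_max) else 1.0 - A2 / params.Ads_max
    ads_flux = params.CL_RRT / v * A1 * params.F_Ads * sat
    if params.parameterization == CONSTANT_TOTAL_CLRRT:
        rrt_out = params.CL_RRT / v * A1
        dial_flux = rrt_out - ads_flux
    else:
        dial_flux = params.CL_RRT * (1.0 - params.F_Ads) / v * A1
        rrt_out = dial_flux + ads_flux
    d1 -= rrt_out
    d2 = ads_flux - params.k_ads_rev * A2
    d3 = dial_flux + params.k_ads_rev * A2 - params.k_deg * A3
    d4 = total_effluent_flow(settings)
    return np.array([d1, d2, d3, d4])


# ---------------------------------------------------------------------------
# closed-form helpers for the linear (non-saturable) system
# ---------------------------------------------------------------------------


def _psi(k: float, tau: np.ndarray) -> np.ndarray:
    """(1 - exp(-k*tau)) / k, with the k -> 0 limit tau."""
    if k <= 0.0:
        return tau.astype(float, copy=True)
    return -np.expm1(-k * tau) / k


def _phi(a: float, b: float, tau: np.ndarray) -> np.ndarray:
    """Convolution integral of exp(-a s) against exp(-b (tau-s)) on [0, tau]."""
    d = b - a
    x = d * tau
    small = np.abs(x) < 1e-6
    denom = np.where(small, 1.0, d)
    exact = np.exp(-a * tau) * (-np.expm1(-x)) / denom
    series = tau * np.exp(-a * tau) * (1.0 - x / 2.0 + x * x / 6.0)
    return np.where(small, series, exact)


def _linear_segment(
    a0: np.ndarray,
    rate: float,
    ke: float,
    kr: float,
    kd: float,
    fa: float,
    fd: float,
    q: float,
    tau: np.ndarray,
) -> np.ndarray:
    """Propagate the linear cascade over one coefficient-constant segment.

    Returns an (len(tau), 4) array of states.  ``ke`` is the total central
    elimination rate, ``fa``/``fd`` the adsorption/dialytic inflow rate
    coefficients (1/h scaled by CL/V splits), ``kr`` the desorption rate,
    ``kd`` the bag degradation rate, ``q`` the effluent flow and ``rate`` the
    zero-order infusion rate in effect.
    """
    A1_0, A2_0, A3_0, A4_0 = a0
    c1 = rate / ke
    c0 = A1_0 - c1

    if kr > 0.0 and abs(kr - ke) < 1e-8 * max(kr, ke, 1.0):
        return _expm_segment(a0, rate, ke, kr, kd, fa, fd, q, tau)

    A1 = c0 * np.exp(-ke * tau) + c1
    A2 = A2_0 * np.exp(-kr * tau) + fa * (c0 * _phi(ke, kr, tau) + c1 * _psi(kr, tau))
    A3 = A3_0 * np.exp(-kd * tau) + fd * (c0 * _phi(ke, kd, tau) + c1 * _psi(kd, tau))
    if kr > 0.0:
        # decompose A2(s) = alpha e^{-kr s} + beta e^{-ke s} + gamma
        beta = fa * c0 / (kr - ke)
        gamma = fa * c1 / kr
        alpha = A2_0 - beta - gamma
        A3 = A3 + kr * (
            alpha * _phi(kr, kd, tau) + beta * _phi(ke, kd, tau) + gamma * _psi(kd, tau)
        )
    A4 = A4_0 + q * tau
    return np.column_stack([A1, A2, A3, A4])


def _expm_segment(
    a0: np.ndarray,
    rate: float,
    ke: float,
    kr: float,
    kd: float,
    fa: float,
    fd: float,
    q: float,
    tau: np.ndarray,
) -> np.ndarray:
    """Matrix-exponential fallback for (near-)degenerate rate constants."""
    m = np.array(
        [
            [-ke, 0.0, 0.0, rate],
            [fa, -kr, 0.0, 0.0],
            [fd, kr, -kd, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    v0 = np.array([a0[0], a0[1], a0[2], 1.0])
    out = np.empty((len(tau), 4))
    for i, t in enumerate(tau):
        w = expm(m * t) @ v0
        out[i, :3] = w[:3]
        out[i, 3] = a0[3] + q * t
    return out


# ---------------------------------------------------------------------------
# event timeline
# ---------------------------------------------------------------------------


def _build_timeline(events: Sequence[EventRecord], horizon: float):
    """Sorted breakpoints plus the infusion windows derived from dose events."""
    infusions = []  # (start, end, rate); bolus encoded as rate 0, jump handled at event
    times = {0.0, float(horizon)}
    for ev in events:
        if ev.time > horizon + 1e-12:
            raise ValueError(f"event at t={ev.time} beyond horizon {horizon}")
        times.add(float(ev.time))
        if ev.kind is EventKind.DOSE and ev.duration > 0:
            end = min(ev.time + ev.duration, horizon)
            infusions.append((float(ev.time), float(end), ev.amount / ev.duration))
            times.add(float(end))
    return sorted(times), infusions


def _infusion_rate(infusions, t0: float, t1: float) -> float:
    mid = 0.5 * (t0 + t1)
    return sum(r for (s, e, r) in infusions if s <= mid < e)


def solve_subject(
    events: Sequence[EventRecord],
    params: PKParameters,
    settings: RRTSettings,
    horizon: float,
    obs_times: Optional[Sequence[float]] = None,
    method: str = "auto",
    rrt_active: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Solve one subject's trajectory through all dosing and circuit events.

    ``obs_times`` default to a dense uniform grid.  Observations falling
    exactly on an event time are evaluated immediately *before* the event
    (trough before the next dose, bag content before the bag change).

    ``method`` is ``"analytic"`` (closed-form propagation; requires a
    non-saturable membrane), ``"numeric"`` (stiff-capable ODE integration) or
    ``"auto"``.
    """
    if obs_times is None:
        obs_times = np.linspace(0.0, horizon, 201)
    obs_times = np.asarray(obs_times, dtype=float)
    if obs_times.size and (obs_times.min() < -1e-12 or obs_times.max() > horizon + 1e-9):
        raise ValueError("observation times must lie within [0, horizon]")
    order = np.argsort(obs_times, kind="stable")
    sorted_obs = obs_times[order]

    if method == "auto":
        method = "analytic" if math.isinf(params.Ads_max) else "numeric"
    if method == "analytic" and not math.isinf(params.Ads_max):
        raise ValueError("analytic propagation requires a non-saturable membrane")

    events = sorted(events, key=lambda e: e.time)
    bps, infusions = _build_timeline(events, horizon)
    ev_by_time: dict = {}
    for ev in events:
        ev_by_time.setdefault(float(ev.time), []).append(ev)

    n = sorted_obs.size
    track_ledgers = method == "numeric"
    state = np.zeros(6 if track_ledgers else 4)
    cur_settings = settings
    active = rrt_active
    discard: List[Tuple[float, float]] = []

    out_states = np.empty((n, 4))
    out_d2 = np.empty(n)
    out_inflow = np.empty(n)
    out_q = np.empty(n)
    out_active = np.empty(n, dtype=bool)
    out_deg = np.empty(n) if track_ledgers else None
    out_elim = np.empty(n) if track_ledgers else None

    def fluxes(a1: np.ndarray, a2: np.ndarray, is_active: bool):
        """(dA2/dt, bag inflow) for vectors of A1, A2 under current coeffs."""
        v = params.V_cent
        if not is_active or params.CL_RRT == 0.0:
            z = np.zeros_like(a1)
            return z, z
        sat = 1.0 if math.isinf(params.Ads_max) else 1.0 - a2 / params.Ads_max
        ads = params.CL_RRT / v * a1 * params.F_Ads * sat
        if params.parameterization == CONSTANT_TOTAL_CLRRT:
            dial = params.CL_RRT / v * a1 - ads
        else:
            dial = params.CL_RRT * (1.0 - params.F_Ads) / v * a1
        return ads - params.k_ads_rev * a2, dial + params.k_ads_rev * a2

    def record(idx: np.ndarray, st: np.ndarray, is_active: bool, q: float) -> None:
        out_states[idx] = st[:, :4]
        d2, inflow = fluxes(st[:, 0], st[:, 1], is_active)
        out_d2[idx] = d2
        out_inflow[idx] = inflow
        out_q[idx] = q if is_active else 0.0
        out_active[idx] = is_active
        if track_ledgers:
            out_deg[idx] = st[:, 4]
            out_elim[idx] = st[:, 5]

    # observations exactly at t = 0 see the pre-dose (empty) state
    i_obs = int(np.count_nonzero(sorted_obs <= 1e-12))
    if i_obs:
        q0 = total_effluent_flow(cur_settings) if active else 0.0
        record(np.arange(i_obs), np.tile(state, (i_obs, 1)), active, q0)

    for k in range(len(bps)):
        t0 = bps[k]
        # apply instantaneous events at t0
        for ev in ev_by_time.get(t0, []):
            if ev.kind is EventKind.DOSE and ev.duration <= 0:
                state[0] += ev.amount
            elif ev.kind is EventKind.FILTER_CHANGE:
                if state[1] > 0:
                    discard.append((t0, float(state[1])))
                state[1] = 0.0
            elif ev.kind is EventKind.BAG_CHANGE:
                if state[2] > 0:
                    discard.append((t0, float(state[2])))
                state[2] = 0.0
                state[3] = 0.0
            elif ev.kind is EventKind.RRT_ON:
                active = True
            elif ev.kind is EventKind.RRT_OFF:
                active = False
            elif ev.kind is EventKind.SETTINGS_CHANGE:
                cur_settings = ev.settings

        if k == len(bps) - 1:
            break
        t1 = bps[k + 1]
        rate = _infusion_rate(infusions, t0, t1)
        q = total_effluent_flow(cur_settings) if active else 0.0

        j = i_obs
        while j < n and sorted_obs[j] <= t1 + 1e-12:
            j += 1
        seg_obs = sorted_obs[i_obs:j]
        taus = np.concatenate([seg_obs - t0, [t1 - t0]])

        if method == "analytic":
            v = params.V_cent
            clr = params.CL_RRT if active else 0.0
            ke = (params.CL_body + clr) / v
            fa = clr * params.F_Ads / v
            fd = clr * (1.0 - params.F_Ads) / v
            kr = params.k_ads_rev if active else 0.0
            st = _linear_segment(state[:4], rate, ke, kr, params.k_deg, fa, fd, q, taus)
        else:
            st = _numeric_segment(
                state, rate, params, cur_settings, active, q, taus, rtol, atol,
                subject_id=events[0].subject_id if events else "?", t0=t0,
            )

        if j > i_obs:
            record(np.arange(i_obs, j), st[:-1], active, q)
        state[: st.shape[1]] = st[-1]
        i_obs = j

    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    traj = Trajectory(
        times=obs_times,
        states=out_states[inv],
        dA2_dt=out_d2[inv],
        effl_inflow=out_inflow[inv],
        q_effl=out_q[inv],
        rrt_active=out_active[inv],
        discard_events=discard,
        degraded=out_deg[inv] if track_ledgers else None,
        eliminated_body=out_elim[inv] if track_ledgers else None,
    )
    return traj


def _numeric_segment(
    state6: np.ndarray,
    rate: float,
    params: PKParameters,
    settings: RRTSettings,
    active: bool,
    q: float,
    taus: np.ndarray,
    rtol: float,
    atol: float,
    subject_id: str,
    t0: float,
) -> np.ndarray:
    """Integrate one segment of the full (possibly saturable) system.

    State layout: A1..A4 plus two bookkeeping integrals — drug degraded in
    the bag and drug eliminated by the body — used by the mass-balance audit.
    """

    def f(_t, y):
        d = rhs(y[:4], params, settings, rrt_active=active, infusion_rate=rate)
        ddeg = params.k_deg * y[2]
        delim = params.CL_body / params.V_cent * y[0]
        return np.array([d[0], d[1], d[2], d[3], ddeg, delim])

    tmax = float(taus[-1])
    if tmax <= 0:
        return np.tile(state6, (len(taus), 1))
    sol = solve_ivp(
        f,
        (0.0, tmax),
        state6,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed for subject {subject_id} in segment starting t={t0:.4g}: "
            f"{sol.message}"
        )
    ys = sol.sol(np.clip(taus, 0.0, tmax)).T
    return ys


# ---------------------------------------------------------------------------
# mass-balance audit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AuditReport:
    ok: bool
    max_rel_err: float
    worst_time: float
    dosed_total: float


def mass_balance_audit(
    events: Sequence[EventRecord],
    params: PKParameters,
    settings: RRTSettings,
    horizon: float,
    n_grid: int = 201,
    tol: float = 1e-6,
) -> AuditReport:
    """Verify conservation of drug mass along a numerically solved trajectory.

    At every grid point the cumulative dosed amount must equal the sum of the
    amounts in plasma, on the membrane and in the bag, plus the drug
    eliminated by the body, degraded in the bag, and discarded at bag or
    filter changes.
    """
    times = np.linspace(0.0, horizon, n_grid)
    traj = solve_subject(events, params, settings, horizon, times, method="numeric")

    dosed = np.zeros_like(times)
    for ev in events:
        if ev.kind is not EventKind.DOSE:
            continue
        if ev.duration > 0:
            frac = np.clip((times - ev.time) / ev.duration, 0.0, 1.0)
        else:
            frac = (times >= ev.time - 1e-12).astype(float)
        dosed += ev.amount * frac

    # states at an event time are pre-event, so discards count strictly after
    discarded = np.zeros_like(times)
    for t_ev, amt in traj.discard_events:
        discarded += amt * (times > t_ev + 1e-12)

    accounted = (
        traj.A1 + traj.A2 + traj.A3 + traj.degraded + traj.eliminated_body + discarded
    )
    scale = np.maximum(dosed, 1e-9)
    rel = np.abs(accounted - dosed) / scale
    worst = int(np.argmax(rel))
    return AuditReport(
        ok=bool(rel[worst] < tol),
        max_rel_err=float(rel[worst]),
        worst_time=float(times[worst]),
        dosed_total=float(dosed[-1]),
    )
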