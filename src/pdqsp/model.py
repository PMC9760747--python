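"""Tumor-compartment mechanistic model: control functions, ODE right-hand
side, tumor-volume mapping, baseline steady states and calibrations.

The CD8+ T-cell life cycle is a linear stage chain: inactive cells enter
the tumor at a binding-controlled influx, activate (binding-controlled)
into the first of eight proliferation stages, double at each transit
(2^8 = 256-fold expansion across the chain), then become CTLs with a
ten-kill capacity ladder; each kill moves one tumor cell into the damaged
pool and the CTL one rung down; exhausted CTLs no longer kill. Tumor cells
grow logistically in volume units, are damaged by CTL kills and by ADCC of
effector-competent anti-PD-L1, and damaged cells apoptose at a constant
rate.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq, root

from . import _kernel, _layout as L
from .binding import BindingSolution, solve_binding_equilibrium
from .errors import CalibrationError, ConfigError
from .params import ModelParameters

__all__ = [
    "influx_rate", "activation_rate", "rhs", "tumor_volume",
    "baseline_steady_state", "calibrate_binding_anchor",
    "calibrate_tcell_kinetics", "stage_totals", "make_state",
]

STAGE_NAMES = ("inactive", "active", "proliferating", "ctl", "exhausted")


def influx_rate(x: float, p: ModelParameters) -> float:
    """Influx of inactive CD8+ T cells (cells/day) given complexes per cell.

    The bracketed difference vanishes at the baseline anchor ``x_ref``
    (influx equals ``ks_IVt`` in the untreated state), grows as receptor
    blockade lowers ``x``, and is clamped at zero for ``x > x_ref``.
    """
    if x < 0:
        raise ValueError("complexes per cell must be non-negative")
    return _kernel.influx_fn(x, p.to_array())


def activation_rate(x: float, p: ModelParameters) -> float:
    """Activation rate (1/day): maximal at x=0, half-maximal at x=EC50."""
    if x < 0:
        raise ValueError("complexes per cell must be non-negative")
    return _kernel.activation_fn(x, p.to_array())


def rhs(t: float, state: np.ndarray, p: ModelParameters | np.ndarray) -> np.ndarray:
    """Time derivative of the packed state vector."""
    y = np.asarray(state, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("non-finite state passed to rhs")
    parr = p.to_array() if isinstance(p, ModelParameters) else np.asarray(p, float)
    dy = np.empty(L.NSTATE)
    _kernel.rhs(t, y, parr, dy)
    return dy


def tumor_volume(state: np.ndarray, p: ModelParameters) -> float:
    """Tumor volume V = (T + T_D) * v_cell / (1 - void_fraction), mm^3."""
    if p.void_fraction >= 1.0:
        raise ConfigError("void_fraction must be < 1")
    y = np.asarray(state, dtype=float)
    return float((y[L.I_T] + y[L.I_TD]) * p.v_cell / (1.0 - p.void_fraction))


def stage_totals(state: np.ndarray) -> dict[str, float]:
    """Aggregate the chain into the five observable stages.

    ``ctl`` is the sum of CTLs with remaining kill capacity (ED10..ED1);
    exhausted CTLs are reported separately.
    """
    y = np.asarray(state, dtype=float)
    return {
        "inactive": float(y[L.I_EI]),
        "active": float(y[L.I_EA]),
        "proliferating": float(np.sum(y[L.I_EP1 : L.I_EP7 + 1])),
        "ctl": float(np.sum(y[L.I_ED10 : L.I_ED1 + 1])),
        "exhausted": float(y[L.I_ED0]),
    }


def make_state(
    tumor_cells: float = 0.0,
    damaged: float = 0.0,
    tcells: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble a packed state vector (PK amounts start at zero)."""
    y = np.zeros(L.NSTATE)
    y[L.I_T] = tumor_cells
    y[L.I_TD] = damaged
    if tcells is not None:
        y[L.I_EI : L.I_ED0 + 1] = tcells
    return y


# ----------------------------------------------------------------------
# steady states
# ----------------------------------------------------------------------

def chain_steady_state_arr(parr: np.ndarray, tumor_burden: float,
                           x: float | None = None) -> np.ndarray:
    """Closed-form fixed point of the linear T-cell chain at a given x.

    Operates on the packed parameter array (fast path used by the fitting
    machinery); ``x`` defaults to the baseline anchor ``x_ref``.
    """
    if x is None:
        x = parr[L.P_XREF]
    fin = _kernel.influx_fn(x, parr)
    fact = _kernel.activation_fn(x, parr)
    ktr = parr[L.P_KTR]
    kd8, kdc, ka2i = parr[L.P_KD_CD8], parr[L.P_KD_CTL], parr[L.P_KA2I]
    c = fact / (kd8 + ka2i + ktr)          # EA = c * EI
    denom = kd8 + fact - ka2i * c
    if denom <= 0:
        raise CalibrationError("inactive-cell balance has no positive fixed point")
    EI = fin / denom
    EA = c * EI
    kkT = parr[L.P_KKILL] * tumor_burden
    stages = np.empty(L.I_ED0 + 1 - L.I_EI)
    stages[0] = EI
    stages[1] = EA
    prev = EA
    for i in range(L.N_PROLIF_STAGES - 1):  # EP1..EP7
        prev = 2.0 * ktr * prev / (kd8 + ktr)
        stages[2 + i] = prev
    ed = 2.0 * ktr * prev / (kdc + kkT)      # ED10
    stages[9] = ed
    for i in range(1, L.N_KILLS_PER_CTL):    # ED9..ED1
        ed = kkT * ed / (kdc + kkT)
        stages[9 + i] = ed
    stages[19] = kkT * ed / kdc              # ED0
    return make_state(tumor_cells=tumor_burden, tcells=stages)


def _chain_steady_state(p: ModelParameters, tumor_burden: float, x: float) -> np.ndarray:
    return chain_steady_state_arr(p.to_array(), tumor_burden, x)


def baseline_state_arr(parr: np.ndarray, tumor_burden: float,
                       tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Array-based untreated fixed point (same damped iteration as
    :func:`baseline_steady_state`); fast path for the fitting machinery."""
    if tumor_burden < 1.0:
        return chain_steady_state_arr(parr, 0.0, 0.0)
    x = parr[L.P_XREF]
    x_new = x
    for _ in range(max_iter):
        y = chain_steady_state_arr(parr, tumor_burden, x)
        xb, _, _ = _kernel.binding_xocc(y, parr)
        x_new = 0.5 * x + 0.5 * xb
        if abs(x_new - x) <= tol * max(1.0, abs(x)):
            return chain_steady_state_arr(parr, tumor_burden, x_new)
        x = x_new
    raise CalibrationError(
        f"baseline fixed point did not converge; last residual {abs(x_new - x):.3e}"
    )


def baseline_steady_state(
    p: ModelParameters,
    tumor_burden: float,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> np.ndarray:
    """Untreated fixed point of the T-cell subsystem at a fixed tumor burden.

    Solved by damped fixed-point iteration between the closed-form chain
    steady state at a given complexes-per-cell value and the binding
    equilibrium the resulting populations imply. After
    :func:`calibrate_binding_anchor` the converged value equals ``x_ref``.
    """
    if tumor_burden < 0:
        raise ConfigError("tumor burden must be non-negative")
    if tumor_burden < 1.0:
        # no tumor, no PD-L1: x = 0, influx at its maximum
        return _chain_steady_state(p, 0.0, 0.0)
    x = p.x_ref
    for _ in range(max_iter):
        state = _chain_steady_state(p, tumor_burden, x)
        sol = solve_binding_equilibrium(state, (0.0, 0.0), p)
        x_new = 0.5 * x + 0.5 * sol.x
        if abs(x_new - x) <= tol * max(1.0, abs(x)):
            return _chain_steady_state(p, tumor_burden, x_new)
        x = x_new
    raise CalibrationError(
        f"baseline fixed point did not converge; last residual {abs(x_new - x):.3e}"
    )


def baseline_binding(p: ModelParameters, tumor_burden: float) -> BindingSolution:
    """Binding solution at the untreated baseline state."""
    state = baseline_steady_state(p, tumor_burden)
    return solve_binding_equilibrium(state, (0.0, 0.0), p)


# ----------------------------------------------------------------------
# calibrations
# ----------------------------------------------------------------------

def calibrate_binding_anchor(
    p: ModelParameters,
    tumor_burden: float,
    bounds: tuple[float, float] = (1.0, 1.0e9),
) -> ModelParameters:
    """Pin R_PDL1 so the untreated equilibrium sits at x = x_ref.

    Complexes per cell increase monotonically with PD-L1 per tumor cell,
    so a 1-D bracketing root solve on log R_PDL1 suffices.
    """
    if p.x_ref <= 0:
        raise CalibrationError("x_ref must be positive to calibrate the anchor")
    if tumor_burden < 1.0:
        raise CalibrationError("binding anchor needs a positive tumor burden")

    def f(logr: float) -> float:
        q = p.updated(R_PDL1=math.exp(logr))
        return baseline_binding(q, tumor_burden).x - p.x_ref

    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise CalibrationError(
            f"x = x_ref unreachable for R_PDL1 in [{bounds[0]:g}, {bounds[1]:g}]"
        )
    logr = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    return p.updated(R_PDL1=math.exp(logr))


def _stage_fractions(p: ModelParameters, tumor_burden: float) -> np.ndarray:
    state = _chain_steady_state(p, tumor_burden, p.x_ref)
    tot = stage_totals(state)
    vals = np.array([tot[k] for k in STAGE_NAMES])
    return vals / vals.sum()


def calibrate_tcell_kinetics(
    target_stage_fractions,
    p: ModelParameters,
    tumor_burden: float = 8.0e6,
    total_cd8: float | None = None,
    tol: float = 1e-9,
) -> ModelParameters:
    """Constrain T-cell kinetic parameters to baseline stage composition.

    Solves for {Emax_activate, kd_CD8, kd_CTL, Thalf_CD8pfr} (log scale)
    so that the untreated steady-state fractions of the five stages
    (inactive, active, proliferating, CTL, exhausted) match the targets;
    ``ks_IVt`` is optionally rescaled so the total CD8+ count matches
    ``total_cd8`` (fractions are invariant to ``ks_IVt``).

    The targets mirror intra-tumoral flow-cytometry composition of
    untreated tumors at the profiling burden.
    """
    tgt = np.asarray(target_stage_fractions, dtype=float)
    if tgt.shape != (5,):
        raise CalibrationError("expected five stage fractions")
    if np.any(tgt <= 0):
        raise CalibrationError(
            "all stage fractions must be positive: killing always populates "
            "the exhausted pool and the chain populates every stage"
        )
    if abs(tgt.sum() - 1.0) > 1e-8:
        raise CalibrationError("stage fractions must sum to 1")
    if p.k_kill * tumor_burden <= 0:
        raise CalibrationError(
            "a positive kill rate and tumor burden are required to reach a "
            "positive exhausted fraction"
        )

    x0 = np.log([p.Emax_activate, p.kd_CD8, p.kd_CTL, p.Thalf_CD8pfr])

    def resid(logq: np.ndarray) -> np.ndarray:
        q = p.updated(
            Emax_activate=math.exp(logq[0]), kd_CD8=math.exp(logq[1]),
            kd_CTL=math.exp(logq[2]), Thalf_CD8pfr=math.exp(logq[3]),
        )
        try:
            fr = _stage_fractions(q, tumor_burden)
        except CalibrationError:
            return np.full(4, 1e3)
        return np.log(fr[1:] / fr[0]) - np.log(tgt[1:] / tgt[0])

    sol = root(resid, x0, method="hybr", tol=1e-13)
    if not sol.success or np.max(np.abs(sol.fun)) > tol:
        raise CalibrationError(
            "no positive-rate solution matches the target composition "
            f"(residual {np.max(np.abs(sol.fun)):.3e}); the violated "
            "constraint is the stage-ratio system for "
            "{Emax_activate, kd_CD8, kd_CTL, Thalf_CD8pfr}"
        )
    out = p.updated(
        Emax_activate=math.exp(sol.x[0]), kd_CD8=math.exp(sol.x[1]),
        kd_CTL=math.exp(sol.x[2]), Thalf_CD8pfr=math.exp(sol.x[3]),
    )
    if total_cd8 is not None:
        state = _chain_steady_state(out, tumor_burden, out.x_ref)
        current = float(np.sum(state[L.I_EI : L.I_ED0 + 1]))
        out = out.updated(ks_IVt=out.ks_IVt * total_cd8 / current)
    return out
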