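"""Competitive PD-1 / PD-L1 / antibody binding at quasi-equilibrium.

Three reversible reactions are assumed to equilibrate instantaneously on
the time scale of cell kinetics:

    PD-1 + PD-L1      <->  PD-1:PD-L1      (KD_PL)
    PD-1 + anti-PD-1  <->  PD-1:Ab         (KD_A1)
    PD-L1 + anti-PD-L1<->  PD-L1:Ab        (KD_AL1)

Antibody concentrations are clamped at the tumor interstitial value (taken
equal to the central-compartment plasma concentration; the receptor pool
does not measurably deplete the plasma pool). With the antibodies clamped,
eliminating free PD-L1 from the two mass balances reduces the system to a
single quadratic in free PD-1, solved in closed form with the numerically
stable root formula. Receptor totals are converted to interstitial
concentrations using the tumor void volume.

All PD-1+ cells carry the same number of PD-1 receptors, so PD-1:PD-L1
complexes are shared equally across PD-1+ cells; ``x`` is the
complexes-per-cell readout that drives the influx and activation control
functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _layout as L
from .errors import BindingSolveError
from .params import ModelParameters

__all__ = ["BindingSolution", "solve_binding_equilibrium", "binding_from_totals"]


@dataclass(frozen=True)
class BindingSolution:
    """Interstitial concentrations (nM) of the five species at equilibrium."""

    free_PD1: float
    free_PDL1: float
    complex_PL: float        # PD-1:PD-L1
    complex_PD1_ab: float    # PD-1:anti-PD-1
    complex_PDL1_ab: float   # PD-L1:anti-PD-L1
    x: float                 # PD-1:PD-L1 complexes per PD-1+ cell
    occ_PD1: float           # fraction of PD-1 bound by antibody
    occ_PDL1: float          # fraction of PD-L1 bound by antibody
    total_PD1: float
    total_PDL1: float

    def mass_balance_residuals(self) -> tuple[float, float]:
        """Relative residuals of the PD-1 and PD-L1 mass balances."""
        r1 = self.free_PD1 + self.complex_PL + self.complex_PD1_ab - self.total_PD1
        r2 = self.free_PDL1 + self.complex_PL + self.complex_PDL1_ab - self.total_PDL1
        s1 = self.total_PD1 if self.total_PD1 > 0 else 1.0
        s2 = self.total_PDL1 if self.total_PDL1 > 0 else 1.0
        return abs(r1) / s1, abs(r2) / s2


def _stable_positive_root(a: float, b: float, c: float) -> float:
    """Positive root of a*P^2 + b*P + c = 0 with a > 0, c <= 0."""
    disc = b * b - 4.0 * a * c
    if disc < 0.0:  # cannot happen with c <= 0; guard against FP noise
        disc = 0.0
    sq = math.sqrt(disc)
    if b <= 0.0:
        return (-b + sq) / (2.0 * a)
    return (-2.0 * c) / (b + sq)


def binding_from_totals(
    P_tot: float,
    L_tot: float,
    ab1: float,
    ab2: float,
    p: ModelParameters,
) -> tuple[float, float, float, float, float]:
    """Solve the equilibrium for given total concentrations (all nM).

    Returns ``(free_P, free_L, PL, P_ab, L_ab)``.
    """
    a1 = 1.0 + ab1 / p.KD_A1
    aL = 1.0 + ab2 / p.KD_AL1
    K = p.KD_PL
    b = a1 * K * aL + L_tot - P_tot
    c = -P_tot * K * aL
    free_P = _stable_positive_root(a1, b, c)
    free_L = L_tot / (aL + free_P / K)
    PL = free_P * free_L / K
    # recompute free_P from its own balance to keep both residuals at
    # rounding level even when the quadratic is ill-conditioned
    free_P = P_tot / (1.0 + free_L / K + ab1 / p.KD_A1)
    PL = free_P * free_L / K
    return free_P, free_L, PL, free_P * ab1 / p.KD_A1, free_L * ab2 / p.KD_AL1


def solve_binding_equilibrium(
    state: np.ndarray,
    ab_conc: tuple[float, float],
    p: ModelParameters,
    tumor_volume: float | None = None,
    residual_tol: float = 1e-9,
) -> BindingSolution:
    """Binding quasi-equilibrium for a packed state vector.

    Parameters
    ----------
    state
        Flat state vector (see :mod:`pdqsp._layout`).
    ab_conc
        Clamped interstitial concentrations ``(anti-PD-1, anti-PD-L1)`` in nM.
    p
        Model parameters.
    tumor_volume
        Tumor volume in mm^3; computed from the state if omitted.

    Raises
    ------
    BindingSolveError
        If the mass-balance residuals at the returned solution exceed
        ``residual_tol`` (relative).
    """
    y = np.maximum(np.asarray(state, dtype=float), 0.0)
    tumor_cells = y[L.I_T] + y[L.I_TD]
    n_pd1_cells = float(np.sum(y[L.I_EI : L.I_ED0 + 1])) + p.N_other
    ab1, ab2 = float(ab_conc[0]), float(ab_conc[1])
    if ab1 < 0 or ab2 < 0:
        raise BindingSolveError("antibody concentrations must be non-negative")

    if tumor_volume is None:
        tumor_volume = tumor_cells * p.v_cell / (1.0 - p.void_fraction)
    if tumor_cells < 1.0 or tumor_volume <= 0.0:
        # vanishing tumor: no PD-L1, occupancy set by clamped antibody alone
        return BindingSolution(
            free_PD1=0.0, free_PDL1=0.0, complex_PL=0.0,
            complex_PD1_ab=0.0, complex_PDL1_ab=0.0, x=0.0,
            occ_PD1=ab1 / (ab1 + p.KD_A1), occ_PDL1=ab2 / (ab2 + p.KD_AL1),
            total_PD1=0.0, total_PDL1=0.0,
        )

    v_int = p.void_fraction * tumor_volume  # interstitial volume, mm^3
    conv = 1.0 / (L.AVOGADRO_NM * v_int)    # counts -> nM
    P_tot = p.R_PD1 * n_pd1_cells * conv
    L_tot = p.R_PDL1 * tumor_cells * conv

    free_P, free_L, PL, P_ab, L_ab = binding_from_totals(P_tot, L_tot, ab1, ab2, p)
    x = PL / conv / n_pd1_cells

    sol = BindingSolution(
        free_PD1=free_P, free_PDL1=free_L, complex_PL=PL,
        complex_PD1_ab=P_ab, complex_PDL1_ab=L_ab, x=x,
        occ_PD1=P_ab / P_tot if P_tot > 0 else 0.0,
        occ_PDL1=L_ab / L_tot if L_tot > 0 else 0.0,
        total_PD1=P_tot, total_PDL1=L_tot,
    )
    r1, r2 = sol.mass_balance_residuals()
    if r1 > residual_tol or r2 > residual_tol:
        raise BindingSolveError(
            f"binding equilibrium residuals too large: PD-1 {r1:.3e}, PD-L1 {r2:.3e}"
        )
    return sol
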