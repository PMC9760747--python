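"""Two-compartment antibody pharmacokinetics and dosing regimens.

Doses printed as mg/kg are converted to nmol with the antibody molecular
weight and body weight. IV doses are boluses into the central compartment;
IP doses enter a depot with first-order absorption ``ka_IP`` and
bioavailability ``F_IP``. Elimination is linear from the central
compartment (no target-mediated disposition).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, RegimenParseError
from .params import Analyte, ModelParameters, PKParameters

__all__ = ["DoseEvent", "DoseRegimen", "dose_to_moles", "parse_regimen",
           "plasma_concentration"]

Route = ("IV", "IP")


@dataclass(frozen=True)
class DoseEvent:
    time: float          # days
    amount: float        # nmol
    route: str           # "IV" | "IP"
    analyte: Analyte     # "antiPD1" | "antiPDL1"

    def __post_init__(self):
        if self.route not in Route:
            raise ConfigError(f"unknown route {self.route!r}")
        if self.analyte not in ("antiPD1", "antiPDL1"):
            raise ConfigError(f"unknown analyte {self.analyte!r}")
        if self.amount < 0:
            raise ConfigError("dose amount must be non-negative")


@dataclass(frozen=True)
class DoseRegimen:
    """Ordered dose events with a human-readable label (e.g. 'Q3Dx3')."""

    events: tuple[DoseEvent, ...]
    label: str = ""

    def __post_init__(self):
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ConfigError("dose event times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])

    def for_analyte(self, analyte: Analyte) -> "DoseRegimen":
        return DoseRegimen(
            tuple(e for e in self.events if e.analyte == analyte), self.label
        )


EMPTY_REGIMEN = DoseRegimen(events=(), label="control")


def dose_to_moles(dose_mg_per_kg: float, BW: float, MW: float) -> float:
    """mg/kg -> nmol: dose * BW / MW * 1e6."""
    if BW <= 0 or MW <= 0:
        raise ConfigError("body weight and molecular weight must be positive")
    if dose_mg_per_kg < 0:
        raise ConfigError("dose must be non-negative")
    return dose_mg_per_kg * BW / MW * 1.0e6


_REGIMEN_RE = re.compile(r"^Q(\d+)Dx(\d+)(?:\s+start\s+(\d+(?:\.\d+)?))?$")


def parse_regimen(
    spec: str,
    dose_mg_per_kg: float,
    route: str,
    analyte: Analyte,
    p: ModelParameters | None = None,
    start: float | None = None,
) -> DoseRegimen:
    """Parse a 'QkDxn [start d]' schedule into a concrete regimen.

    ``QkDxn`` means n doses given every k days; the first dose is given at
    ``start`` days after tumor implantation (from the string or argument).
    """
    m = _REGIMEN_RE.match(spec.strip())
    if not m:
        token = spec.strip().split()[0] if spec.strip() else spec
        raise RegimenParseError(f"malformed regimen spec: {token!r}")
    k, n = int(m.group(1)), int(m.group(2))
    if m.group(3) is not None:
        start = float(m.group(3))
    if start is None:
        raise RegimenParseError(f"no treatment start given in {spec!r}")
    if k < 1 or n < 1 or start < 0:
        raise RegimenParseError(f"invalid schedule numbers in {spec!r}")
    params = p if p is not None else ModelParameters()
    amount = dose_to_moles(dose_mg_per_kg, params.BW, params.pk_block(analyte).MW)
    events = tuple(
        DoseEvent(time=start + i * k, amount=amount, route=route, analyte=analyte)
        for i in range(n)
    )
    return DoseRegimen(events=events, label=f"Q{k}Dx{n}")


# ----------------------------------------------------------------------
# closed-form concentration
# ----------------------------------------------------------------------

def _pk_matrix(blk: PKParameters) -> np.ndarray:
    return np.array([
        [-blk.ka_IP, 0.0, 0.0],
        [blk.ka_IP, -(blk.k10 + blk.k12), blk.k21],
        [0.0, blk.k12, -blk.k21],
    ])


def plasma_concentration(
    t: float | np.ndarray,
    pk: PKParameters,
    regimen: DoseRegimen,
) -> np.ndarray:
    """Central-compartment concentration (nM) at times t (days).

    Exact solution by eigendecomposition of the linear depot/central/
    peripheral system, superposed over dose events. ``A_c/V1`` in nmol/mL
    equals micromolar, hence the 1e3 factor to nM.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ConfigError("times must be non-negative")
    A = _pk_matrix(pk)
    lam, S = np.linalg.eig(A)
    Sinv = np.linalg.inv(S)
    ac = np.zeros_like(t)
    for ev in regimen.events:
        y0 = np.zeros(3)
        if ev.route == "IV":
            y0[1] = ev.amount
        else:
            y0[0] = pk.F_IP * ev.amount
        coef = Sinv @ y0
        dt = t - ev.time
        mask = dt >= 0
        if not np.any(mask):
            continue
        modes = np.exp(np.outer(dt[mask], lam)) * coef  # (nt, 3)
        ac[mask] += (modes @ S[1].T).real
    return ac / pk.V1 * 1.0e3
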