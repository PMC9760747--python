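"""Virtual mice and synthetic tumor-volume tables.

The generator emulates the five CT26 tumor-growth-inhibition studies
(two study sites, group sizes 10/10/10/12/21, IV or IP dosing, Q5Dx2 /
Q4Dx4 / Q3Dx3 schedules, treatment starts on days 7-11, inocula of 2e6 or
2e5 cells) with log-normal inter-individual variability on the tumor cell
proliferation rate, the tumor carrying capacity and the CD8+ proliferation
half-life, an exponential study-site covariate on the first two, and a
combined-2 residual error on observed volumes.

Individual parameters follow the exponential covariate model

    theta_i = theta_pop * exp(beta * 1[site=2]) * exp(eta_i),
    eta_i ~ Normal(0, omega^2).

By default the random-effect draws of a cohort are moment-matched within
each site stratum (sample mean 0 and SD omega enforced exactly), the
virtual-population practice of making a small cohort representative of
its generating distribution; set ``eta_balance="iid"`` for plain sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .params import ModelParameters
from .pk import EMPTY_REGIMEN, DoseRegimen, parse_regimen
from .simulate import simulate_individual

__all__ = ["ArmSpec", "StudyDesign", "VirtualMouse", "CohortTable",
           "default_designs", "recovery_designs", "sample_individual",
           "add_measurement_error", "generate_cohort", "observation_days"]

ARMS = ("control", "antiPD1", "antiPDL1")


@dataclass(frozen=True)
class ArmSpec:
    arm: str                     # control | antiPD1 | antiPDL1
    dose_mg_per_kg: float = 0.0
    schedule: str = ""           # e.g. "Q3Dx3"; empty for control
    route: str = "IV"

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ConfigError(f"unknown arm {self.arm!r}")


@dataclass(frozen=True)
class StudyDesign:
    study: int
    site: int
    n_per_group: int
    arms: tuple[ArmSpec, ...]
    inoculum: float
    treatment_start: float
    duration: float

    def __post_init__(self):
        if self.site not in (1, 2):
            raise ConfigError(f"site must be 1 or 2, got {self.site}")

    def regimen(self, spec: ArmSpec, p: ModelParameters) -> DoseRegimen:
        if spec.arm == "control":
            return EMPTY_REGIMEN
        return parse_regimen(spec.schedule, spec.dose_mg_per_kg, spec.route,
                             spec.arm, p=p, start=self.treatment_start)


def default_designs() -> tuple[StudyDesign, ...]:
    """The five CT26 studies (sites 1-3 at site 1, 4-5 at site 2)."""
    return (
        StudyDesign(1, 1, 10, (ArmSpec("control"),
                               ArmSpec("antiPD1", 10.0, "Q5Dx2", "IV")),
                    2.0e6, 8.0, 148.0),
        StudyDesign(2, 1, 10, (ArmSpec("control"),
                               ArmSpec("antiPD1", 5.0, "Q4Dx4", "IV")),
                    2.0e6, 10.0, 56.0),
        StudyDesign(3, 1, 10, (ArmSpec("control"),
                               ArmSpec("antiPD1", 10.0, "Q3Dx3", "IV"),
                               ArmSpec("antiPDL1", 10.0, "Q3Dx3", "IV")),
                    2.0e6, 7.0, 242.0),
        StudyDesign(4, 2, 12, (ArmSpec("control"),
                               ArmSpec("antiPDL1", 10.0, "Q3Dx3", "IP")),
                    2.0e5, 11.0, 52.0),
        StudyDesign(5, 2, 21, (ArmSpec("control"),
                               ArmSpec("antiPDL1", 10.0, "Q3Dx3", "IP")),
                    2.0e5, 8.0, 40.0),
    )


def recovery_designs(n_per_group: int = 10) -> tuple[StudyDesign, ...]:
    """Reduced two-site design used for parameter-recovery runs.

    One study per site, control + anti-PD-L1 10 mg/kg Q3Dx3 arms,
    40-day horizon; inocula and routes mirror the site conventions of the
    full designs.
    """
    return (
        StudyDesign(1, 1, n_per_group, (ArmSpec("control"),
                                        ArmSpec("antiPDL1", 10.0, "Q3Dx3", "IV")),
                    2.0e6, 7.0, 40.0),
        StudyDesign(2, 2, n_per_group, (ArmSpec("control"),
                                        ArmSpec("antiPDL1", 10.0, "Q3Dx3", "IP")),
                    2.0e5, 8.0, 40.0),
    )


@dataclass
class VirtualMouse:
    mouse_id: str
    study: int
    site: int
    arm: str
    kpfr_i: float
    klimit_i: float
    Thalf_i: float
    eta: np.ndarray              # (eta_kpfr, eta_klimit, eta_Thalf)
    inoculum: float = 2.0e6
    treatment_start: float = 7.0

    def individual_parameters(self, pop: ModelParameters) -> ModelParameters:
        return pop.updated(kpfr_T=self.kpfr_i, klimit_T=self.klimit_i,
                           Thalf_CD8pfr=self.Thalf_i)


def sample_individual(
    pop: ModelParameters,
    site: int,
    rng: np.random.Generator | int | None = None,
    eta: np.ndarray | None = None,
    mouse_id: str = "m0",
    study: int = 0,
    arm: str = "control",
) -> VirtualMouse:
    """Draw one virtual mouse from the population model.

    The site covariate acts on the proliferation rate and carrying
    capacity only; the proliferation half-life carries a random effect
    but no covariate.
    """
    if site not in (1, 2):
        raise ConfigError(f"site must be 1 or 2, got {site}")
    if eta is None:
        gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        eta = gen.normal(0.0, 1.0, 3) * np.array(
            [pop.omega_kpfr, pop.omega_klimit, pop.omega_Thalf])
    eta = np.asarray(eta, dtype=float)
    s2 = 1.0 if site == 2 else 0.0
    return VirtualMouse(
        mouse_id=mouse_id, study=study, site=site, arm=arm,
        kpfr_i=pop.kpfr_T * np.exp(pop.beta_kpfr_site2 * s2 + eta[0]),
        klimit_i=pop.klimit_T * np.exp(pop.beta_klimit_site2 * s2 + eta[1]),
        Thalf_i=pop.Thalf_CD8pfr * np.exp(eta[2]),
        eta=eta,
    )


def add_measurement_error(
    f: float | np.ndarray,
    err_a: float,
    err_b: float,
    rng: np.random.Generator | None = None,
    eps: float | np.ndarray | None = None,
    floor: float = 1.0,
) -> np.ndarray:
    """Combined-2 residual error: y = f + sqrt(a^2 + b^2 f^2) * eps.

    Non-positive observations are truncated at the measurement floor
    (1 mm^3 by default).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ConfigError("model-predicted volumes must be non-negative")
    if eps is None:
        if rng is None:
            raise ConfigError("either rng or eps must be given")
        eps = rng.standard_normal(f.shape)
    sd = np.sqrt(err_a**2 + err_b**2 * f**2)
    y = f + sd * np.asarray(eps, dtype=float)
    return np.where(y <= 0.0, floor, y)


def observation_days(duration: float, first: float = 4.0) -> np.ndarray:
    """Twice-weekly caliper schedule (alternating 3/4-day gaps)."""
    days = [first]
    step3 = True
    while True:
        nxt = days[-1] + (3.0 if step3 else 4.0)
        if nxt > duration + 1e-9:
            break
        days.append(nxt)
        step3 = not step3
    return np.array(days)


@dataclass
class CohortTable:
    """Long-format observed tumor volumes plus per-mouse metadata."""

    obs: pd.DataFrame                  # study, site, mouse, arm, day, volume_mm3
    mice: list[VirtualMouse]
    designs: tuple[StudyDesign, ...]
    seed: int | None = None

    def mouse_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "mouse": m.mouse_id, "study": m.study, "site": m.site,
            "arm": m.arm, "kpfr_i": m.kpfr_i, "klimit_i": m.klimit_i,
            "Thalf_i": m.Thalf_i, "inoculum": m.inoculum,
            "treatment_start": m.treatment_start,
        } for m in self.mice])

    def to_csv(self, path: str | Path) -> None:
        self.obs.to_csv(path, index=False)

    def regimen_for(self, mouse: VirtualMouse, p: ModelParameters) -> DoseRegimen:
        design = next(d for d in self.designs if d.study == mouse.study)
        spec = next(a for a in design.arms if a.arm == mouse.arm)
        return design.regimen(spec, p)


def generate_cohort(
    designs: tuple[StudyDesign, ...],
    pop: ModelParameters,
    seed: int,
    horizon: float = 40.0,
    eta_balance: str = "match_moments",
    method: str = "rk4",
    rk4_dt: float = 0.005,
) -> CohortTable:
    """Simulate every mouse of the given designs and observe with error.

    Fully reproducible from ``seed``; observation days follow the
    twice-weekly caliper schedule up to ``min(duration, horizon)``.
    """
    if eta_balance not in ("match_moments", "iid"):
        raise ConfigError(f"unknown eta_balance {eta_balance!r}")
    rng = np.random.default_rng(seed)
    omegas = np.array([pop.omega_kpfr, pop.omega_klimit, pop.omega_Thalf])

    # enumerate mice in a fixed order
    roster: list[tuple[StudyDesign, ArmSpec, str]] = []
    for d in designs:
        for a in d.arms:
            if a.arm not in [x.arm for x in d.arms]:
                raise ConfigError(f"unknown arm {a.arm!r}")
            for i in range(d.n_per_group):
                roster.append((d, a, f"s{d.study}_{a.arm}_{i:02d}"))

    raw = rng.standard_normal((len(roster), 3))
    etas = raw * omegas
    if eta_balance == "match_moments":
        sites = np.array([d.site for d, _, _ in roster])
        for s in np.unique(sites):
            sel = sites == s
            if sel.sum() >= 3:
                block = raw[sel]
                mu = block.mean(axis=0)
                sd = block.std(axis=0)
                sd[sd == 0] = 1.0
                etas[sel] = (block - mu) / sd * omegas

    mice: list[VirtualMouse] = []
    records = []
    for k, (d, a, mid) in enumerate(roster):
        m = sample_individual(pop, d.site, eta=etas[k], mouse_id=mid,
                              study=d.study, arm=a.arm)
        m.inoculum = d.inoculum
        m.treatment_start = d.treatment_start
        mice.append(m)
        end = min(d.duration, horizon)
        days = observation_days(end)
        p_i = m.individual_parameters(pop)
        traj = simulate_individual(
            p_i, d.regimen(a, pop), t_end=end, inoculum=d.inoculum,
            grid=np.union1d([0.0], days), method=method, rk4_dt=rk4_dt)
        f = traj.volume_at(days)
        y = add_measurement_error(f, pop.err_a, pop.err_b, rng=rng)
        for day, vol in zip(days, y):
            records.append((d.study, d.site, mid, a.arm, day, vol))

    obs = pd.DataFrame(records, columns=["study", "site", "mouse", "arm",
                                         "day", "volume_mm3"])
    return CohortTable(obs=obs, mice=mice, designs=tuple(designs), seed=seed)
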