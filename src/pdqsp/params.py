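"""Model parameters: fixed effects, binding/expression constants, PK blocks,
inter-individual variability and residual-error terms.

Every quantity the tumor-compartment ODE system, the PK model, the virtual
cohort generator and the population fit touch lives in :class:`ModelParameters`.
Parameters carry a provenance tag (see :data:`PROVENANCE`): ``"fitted"``
values come from the published population analysis of the CT26 studies,
``"assumed"`` values are literature-informed defaults of this package, and
``"calibrated"`` values are pinned by the calibration routines in
:mod:`pdqsp.model` (baseline complexes-per-cell anchor, intra-tumoral
T-cell stage composition).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import _layout as L
from .errors import ConfigError

Analyte = Literal["antiPD1", "antiPDL1"]


class PKParameters(BaseModel):
    """Two-compartment linear-elimination PK block for one antibody.

    Units: CL, Q in mL/day; V1, V2 in mL; ka_IP in 1/day; MW in g/mol.
    """

    model_config = ConfigDict(extra="forbid")

    CL: float = Field(gt=0)
    V1: float = Field(gt=0)
    V2: float = Field(gt=0)
    Q: float = Field(ge=0)
    ka_IP: float = Field(default=1.0, gt=0)
    F_IP: float = Field(default=0.8, gt=0, le=1.0)
    MW: float = Field(default=1.5e5, gt=0)

    @property
    def k10(self) -> float:
        return self.CL / self.V1

    @property
    def k12(self) -> float:
        return self.Q / self.V1

    @property
    def k21(self) -> float:
        return self.Q / self.V2


class ModelParameters(BaseModel):
    """Complete parameter set of the tumor-immune QSP model.

    Rates are per day, volumes in mm^3 (tumor) or mL (PK), receptor counts
    per cell, dissociation constants in nM, cell influx in cells/day.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # -- tumor growth (population fixed effects) --
    kpfr_T: float = Field(default=0.199, gt=0, description="tumor cell proliferation rate, 1/day")
    klimit_T: float = Field(default=8370.0, gt=0, description="tumor carrying capacity, mm^3")

    # -- T-cell influx / activation control --
    Emax_influx: float = Field(default=8.43e7, gt=0, description="max influx of inactive CD8+ cells, cells/day")
    ks_IVt: float = Field(default=900.0, gt=0, description="baseline inactive-cell influx, cells/day")
    EC50: float = Field(default=0.5, gt=0, description="half-maximal complexes per inactive cell")
    x_ref: float = Field(default=6.6, gt=0, description="baseline complexes-per-inactive-cell anchor")
    Emax_activate: float = Field(default=0.5, gt=0, description="max activation rate, 1/day")
    kA2I_basal: float = Field(default=0.1, gt=0, description="active->inactive reversion, 1/day")

    # -- T-cell life cycle --
    kd_CD8: float = Field(default=0.5, gt=0, description="death rate of inactive/active/proliferating CD8+, 1/day")
    kd_CTL: float = Field(default=1.5, gt=0, description="CTL death rate, 1/day")
    Thalf_CD8pfr: float = Field(default=0.418, gt=0, description="CD8+ proliferation half-life, days")
    k_kill: float = Field(default=5.0e-10, gt=0, description="CTL-mediated killing, 1/(cell*day)")

    # -- treatment effects on tumor --
    Emax_ADCC: float = Field(default=0.146, gt=0, description="max ADCC damage rate, 1/day")
    kapop: float = Field(default=0.191, gt=0, description="damaged-cell apoptosis rate, 1/day")

    # -- receptors and binding --
    R_PD1: float = Field(default=3.0e3, gt=0, description="PD-1 receptors per CD8+ T cell")
    R_PDL1: float = Field(default=1.0e5, gt=0, description="PD-L1 per tumor cell (calibrated)")
    N_other: float = Field(default=5.0e4, gt=0, description="other PD-1+ T cells, cells")
    KD_PL: float = Field(default=8200.0, gt=0, description="PD-1:PD-L1 KD, nM")
    KD_A1: float = Field(default=10.0, gt=0, description="anti-PD-1:PD-1 KD, nM")
    KD_AL1: float = Field(default=1.0, gt=0, description="anti-PD-L1:PD-L1 KD, nM")

    # -- geometry --
    void_fraction: float = Field(default=0.5, gt=0, lt=1, description="tumor volume fraction not occupied by cells")
    v_cell: float = Field(default=1.0e-6, gt=0, description="volume per tumor cell, mm^3")

    # -- study-site covariates (exponential model) --
    beta_kpfr_site2: float = Field(default=0.444)
    beta_klimit_site2: float = Field(default=-1.47)

    # -- inter-individual variability (log-scale SDs) --
    omega_kpfr: float = Field(default=0.21, ge=0)
    omega_klimit: float = Field(default=0.438, ge=0)
    omega_Thalf: float = Field(default=0.35, ge=0)

    # -- combined-2 residual error --
    err_a: float = Field(default=53.0, ge=0, description="additive residual term, mm^3")
    err_b: float = Field(default=0.142, ge=0, description="proportional residual term")

    # -- PK --
    BW: float = Field(default=0.02, gt=0, description="body weight, kg")
    pk_antiPD1: PKParameters = Field(
        default_factory=lambda: PKParameters(CL=1.2, V1=1.5, V2=1.5, Q=0.5)
    )
    pk_antiPDL1: PKParameters = Field(
        default_factory=lambda: PKParameters(CL=1.2, V1=1.5, V2=1.5, Q=0.5)
    )

    # -- simulator switch: replace the binding-dependent influx by ks_IVt --
    constant_influx: bool = Field(default=False)

    @model_validator(mode="after")
    def _check(self) -> "ModelParameters":
        if not (0.0 < self.void_fraction < 1.0):
            raise ConfigError("void_fraction must lie strictly in (0, 1)")
        return self

    # ------------------------------------------------------------------
    @property
    def k_tr(self) -> float:
        """Proliferation-chain transit rate, ln2 / Thalf_CD8pfr (1/day)."""
        return math.log(2.0) / self.Thalf_CD8pfr

    def pk_block(self, analyte: Analyte) -> PKParameters:
        return self.pk_antiPD1 if analyte == "antiPD1" else self.pk_antiPDL1

    def to_array(self) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the ODE kernel."""
        p = np.empty(L.NPAR)
        p[L.P_KPFR] = self.kpfr_T
        p[L.P_KLIMIT] = self.klimit_T
        p[L.P_EMAX_INFLUX] = self.Emax_influx
        p[L.P_KS_IVT] = self.ks_IVt
        p[L.P_EC50] = self.EC50
        p[L.P_XREF] = self.x_ref
        p[L.P_EMAX_ACT] = self.Emax_activate
        p[L.P_KA2I] = self.kA2I_basal
        p[L.P_KD_CD8] = self.kd_CD8
        p[L.P_KD_CTL] = self.kd_CTL
        p[L.P_KTR] = self.k_tr
        p[L.P_KKILL] = self.k_kill
        p[L.P_EMAX_ADCC] = self.Emax_ADCC
        p[L.P_KAPOP] = self.kapop
        p[L.P_RPD1] = self.R_PD1
        p[L.P_RPDL1] = self.R_PDL1
        p[L.P_NOTHER] = self.N_other
        p[L.P_KDPL] = self.KD_PL
        p[L.P_KDA1] = self.KD_A1
        p[L.P_KDAL1] = self.KD_AL1
        p[L.P_VOID] = self.void_fraction
        p[L.P_VCELL] = self.v_cell
        p[L.P_INFLUX_MODE] = 1.0 if self.constant_influx else 0.0
        for base, blk in ((L.P_A1_K10, self.pk_antiPD1), (L.P_A2_K10, self.pk_antiPDL1)):
            p[base + 0] = blk.k10
            p[base + 1] = blk.k12
            p[base + 2] = blk.k21
            p[base + 3] = blk.V1
            p[base + 4] = blk.ka_IP
        return p

    def updated(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        data = self.model_dump()
        for key, value in kwargs.items():
            if key not in data:
                raise ConfigError(f"unknown parameter {key!r}")
            data[key] = value
        return ModelParameters.model_validate(data)

    # -- serialization --------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.model_validate(data)


#: provenance of each default value
PROVENANCE: dict[str, str] = {
    "kpfr_T": "fitted (population)",
    "klimit_T": "fitted (population)",
    "beta_kpfr_site2": "fitted (population)",
    "beta_klimit_site2": "fitted (population)",
    "Thalf_CD8pfr": "fitted (population)",
    "Emax_ADCC": "fitted (population)",
    "kapop": "fitted (population)",
    "Emax_influx": "fitted (population)",
    "omega_kpfr": "fitted (population)",
    "omega_klimit": "fitted (population), rescaled to log scale",
    "omega_Thalf": "assumed (printed value data-uninformed)",
    "err_a": "fitted (population)",
    "err_b": "fitted (population)",
    "ks_IVt": "assumed/calibrated",
    "EC50": "assumed",
    "x_ref": "calibrated anchor",
    "Emax_activate": "assumed/calibrated",
    "kA2I_basal": "assumed",
    "kd_CD8": "assumed/calibrated",
    "kd_CTL": "assumed/calibrated",
    "k_kill": "assumed",
    "R_PD1": "assumed (literature order of magnitude)",
    "R_PDL1": "calibrated (binding anchor)",
    "N_other": "assumed",
    "KD_PL": "assumed (literature SPR)",
    "KD_A1": "assumed",
    "KD_AL1": "assumed",
    "void_fraction": "assumed",
    "v_cell": "assumed (1e6 cells per mm^3)",
    "BW": "assumed",
    "pk_antiPD1": "assumed",
    "pk_antiPDL1": "assumed",
    "err": "fitted (population)",
}


def default_parameters() -> ModelParameters:
    """The package's default parameter set (binding anchor not yet applied).

    Call :func:`pdqsp.model.calibrate_binding_anchor` to pin ``R_PDL1`` so
    that the untreated equilibrium sits at ``x_ref`` complexes per cell.
    """
    return ModelParameters()
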