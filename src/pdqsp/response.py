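"""Treatment-response metrics: day 7-13 growth rates, the 25 mm^3/day
responder threshold, nonparametric group comparisons with Bonferroni
thresholds, and the PD-1/PD-L1 expression sweep.

A mouse is a *responder* if the observed rate of tumor-volume change over
days 7-13 after treatment start is strictly below 25 mm^3/day — the
threshold that captures regressing tumors and those with a period of
regression followed by progression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, VirtualMouse
from .errors import ConfigError
from .params import ModelParameters
from .pk import DoseRegimen
from .simulate import simulate_individual

__all__ = ["ResponseRecord", "observed_growth_rate", "classify_response",
           "response_table", "compare_groups", "expression_sweep",
           "RESPONDER_THRESHOLD"]

RESPONDER_THRESHOLD = 25.0   # mm^3/day


@dataclass(frozen=True)
class ResponseRecord:
    mouse_id: str
    study: int
    arm: str
    growth_rate: float           # mm^3/day, NaN when unclassifiable
    label: str | None            # "responder" | "non-responder" | None


def observed_growth_rate(
    profile: pd.DataFrame,
    treatment_start: float,
    window: tuple[float, float] = (7.0, 13.0),
    widen: float = 2.0,
) -> float:
    """Least-squares slope of volume vs day over the response window.

    The window is [start+7, start+13]; when no observation falls exactly
    on a window edge, the nearest observation within ``widen`` days
    outside that edge is included. Returns NaN (with a warning via the
    caller) when fewer than two usable observations exist. With exactly
    two points the slope reduces to the difference quotient.
    """
    lo = treatment_start + window[0]
    hi = treatment_start + window[1]
    days = profile["day"].to_numpy(float)
    vols = profile["volume_mm3"].to_numpy(float)
    sel = (days >= lo - 1e-9) & (days <= hi + 1e-9)
    if not np.any(np.isclose(days, lo)):
        before = np.where((days >= lo - widen) & (days < lo))[0]
        if len(before):
            sel[before[np.argmax(days[before])]] = True
    if not np.any(np.isclose(days, hi)):
        after = np.where((days > hi) & (days <= hi + widen))[0]
        if len(after):
            sel[after[np.argmin(days[after])]] = True
    if sel.sum() < 2:
        return math.nan
    slope, _ = np.polyfit(days[sel], vols[sel], 1)
    return float(slope)


def classify_response(rate: float,
                      threshold: float = RESPONDER_THRESHOLD) -> str | None:
    """Strictly-below-threshold rule; NaN rates are unclassified (None)."""
    if math.isnan(rate):
        return None
    return "responder" if rate < threshold else "non-responder"


def response_table(data: CohortTable) -> pd.DataFrame:
    """Growth rate and responder label for every mouse of a cohort."""
    start_by_mouse = {m.mouse_id: m.treatment_start for m in data.mice}
    rows = []
    for mid, g in data.obs.groupby("mouse", sort=True):
        rate = observed_growth_rate(g.sort_values("day"),
                                    start_by_mouse[mid])
        rows.append({
            "mouse": mid, "study": int(g["study"].iloc[0]),
            "arm": str(g["arm"].iloc[0]), "growth_rate": rate,
            "label": classify_response(rate),
        })
    return pd.DataFrame(rows)


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    if len(np.unique(np.concatenate([x, y]))) == 1:
        return 1.0   # degenerate all-tied input
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="auto").pvalue)


def compare_groups(
    rates: pd.DataFrame,
    family_alpha: tuple[float, ...] = (0.01, 0.05),
) -> tuple[pd.DataFrame, dict]:
    """Kruskal-Wallis across studies plus within-study Wilcoxon tests.

    ``rates`` needs columns study/arm/growth_rate. P-values are reported
    unadjusted; the metadata carries the Bonferroni-corrected
    significance thresholds (family level / number of within-study
    treatment-vs-control comparisons) for each requested family level.
    """
    rates = rates.dropna(subset=["growth_rate"])
    groups = [g["growth_rate"].to_numpy() for _, g in rates.groupby("study")]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ConfigError("need at least two non-empty study groups")
    if all(len(np.unique(g)) == 1 for g in groups) and \
            len(np.unique(rates["growth_rate"])) == 1:
        kw_p = 1.0
    else:
        kw_p = float(stats.kruskal(*groups).pvalue)

    rows = []
    for study, g in rates.groupby("study"):
        ctrl = g.loc[g["arm"] == "control", "growth_rate"].to_numpy()
        for arm in sorted(set(g["arm"]) - {"control"}):
            trt = g.loc[g["arm"] == arm, "growth_rate"].to_numpy()
            if len(ctrl) == 0 or len(trt) == 0:
                continue
            rows.append({"study": study, "arm": arm,
                         "p_value": _wilcoxon_rank_sum(trt, ctrl)})
    table = pd.DataFrame(rows)
    n_comp = max(len(table), 1)
    meta = {
        "kruskal_wallis_p": kw_p,
        "n_comparisons": len(table),
        "bonferroni_thresholds": {
            alpha: alpha / n_comp for alpha in family_alpha
        },
    }
    return table, meta


def expression_sweep(
    individuals: list[VirtualMouse],
    pop: ModelParameters,
    grid: np.ndarray,
    scenarios: dict[str, DoseRegimen],
    receptor: str = "R_PDL1",
    readout_day: float = 12.0,
    method: str = "rk4",
) -> pd.DataFrame:
    """Percent tumor-volume change at ``readout_day`` after treatment
    start for each (mouse, expression level, scenario).

    ``receptor`` selects which expression level is swept ("R_PD1" or
    "R_PDL1"); grid values are absolute receptors per cell. For every
    level the untreated T-cell baseline is re-equilibrated before dosing
    so day-0 transients do not contaminate the readout. Mice are ordered
    by their individual proliferation rates; failed re-equilibrations
    yield NaN cells.
    """
    if receptor not in ("R_PD1", "R_PDL1"):
        raise ConfigError("receptor must be R_PD1 or R_PDL1")
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ConfigError("expression levels must be positive")
    ordered = sorted(individuals, key=lambda m: m.kpfr_i)
    rows = []
    for m in ordered:
        p_i = m.individual_parameters(pop)
        for level in grid:
            q = p_i.updated(**{receptor: float(level)})
            for sname, reg in scenarios.items():
                start = m.treatment_start
                try:
                    traj = simulate_individual(
                        q, reg, t_end=start + readout_day,
                        inoculum=m.inoculum, method=method)
                    v0 = float(traj.volume_at(start))
                    v1 = float(traj.volume_at(start + readout_day))
                    pct = 100.0 * (v1 - v0) / v0
                except Exception:
                    pct = math.nan
                rows.append({"mouse": m.mouse_id, "kpfr_i": m.kpfr_i,
                             "level": float(level), "scenario": sname,
                             "pct_volume_change": pct})
    return pd.DataFrame(rows)
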