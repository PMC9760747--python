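"""Responder classification, group comparisons and the expression sweep."""

import numpy as np
import pandas as pd
import pytest

from pdqsp.cohort import generate_cohort, recovery_designs, sample_individual
from pdqsp.pk import EMPTY_REGIMEN, parse_regimen
from pdqsp.response import (classify_response, compare_groups,
                            expression_sweep, observed_growth_rate,
                            response_table)


def profile(days, vols):
    return pd.DataFrame({"day": days, "volume_mm3": vols})


class TestObservedGrowthRate:
    def test_two_point_slope(self):
        rate = observed_growth_rate(profile([14.0, 20.0], [200.0, 500.0]),
                                    treatment_start=7.0)
        assert rate == pytest.approx(50.0)

    def test_constant_volume(self):
        rate = observed_growth_rate(
            profile([14.0, 17.0, 20.0], [300.0, 300.0, 300.0]), 7.0)
        assert rate == pytest.approx(0.0)

    def test_matches_normal_equations(self, rng):
        days = np.array([14.0, 16.0, 18.0, 20.0])
        vols = 100 + 30 * days + rng.normal(0, 20, 4)
        rate = observed_growth_rate(profile(days, vols), 7.0)
        X = np.column_stack([days, np.ones(4)])
        beta = np.linalg.solve(X.T @ X, X.T @ vols)
        assert rate == pytest.approx(beta[0], abs=1e-10)

    def test_widening_includes_nearest_neighbors(self):
        # no observation at day 14 or 20; days 12.5 and 21.5 are pulled in
        rate = observed_growth_rate(
            profile([12.5, 17.0, 21.5], [100.0, 200.0, 300.0]), 7.0)
        assert rate == pytest.approx(
            np.polyfit([12.5, 17.0, 21.5], [100.0, 200.0, 300.0], 1)[0])

    def test_too_few_observations_gives_nan(self):
        rate = observed_growth_rate(profile([15.0], [100.0]), 7.0)
        assert np.isnan(rate)


class TestClassifyResponse:
    @pytest.mark.parametrize("rate,label", [
        (24.9, "responder"),
        (25.0, "non-responder"),
        (-10.0, "responder"),
        (np.nan, None),
    ])
    def test_strict_threshold(self, rate, label):
        assert classify_response(rate) == label


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        rates = pd.DataFrame({
            "study": [1] * 6 + [2] * 6,
            "arm": (["control"] * 3 + ["antiPD1"] * 3) * 2,
            "growth_rate": [5.0] * 12,
        })
        table, meta = compare_groups(rates)
        assert np.all(table["p_value"] == 1.0)
        assert meta["kruskal_wallis_p"] == 1.0

    def test_bonferroni_thresholds(self):
        rng = np.random.default_rng(0)
        rows = []
        for study in range(1, 4):
            for arm in ("control", "antiPD1"):
                for _ in range(5):
                    rows.append({"study": study, "arm": arm,
                                 "growth_rate": rng.normal(30, 5)})
        # six comparisons: force two treatment arms in each study
        rates = pd.DataFrame(rows)
        extra = rates[rates["arm"] == "antiPD1"].assign(arm="antiPDL1")
        rates = pd.concat([rates, extra], ignore_index=True)
        table, meta = compare_groups(rates)
        assert meta["n_comparisons"] == 6
        assert meta["bonferroni_thresholds"][0.01] == pytest.approx(0.01 / 6)
        assert meta["bonferroni_thresholds"][0.01] == pytest.approx(0.0016, abs=1e-4)

    def test_three_comparison_threshold(self):
        rng = np.random.default_rng(1)
        rows = []
        for study in (1, 2, 3):
            for arm in ("control", "antiPDL1"):
                for _ in range(4):
                    rows.append({"study": study, "arm": arm,
                                 "growth_rate": rng.normal(30, 5)})
        _, meta = compare_groups(pd.DataFrame(rows))
        assert meta["n_comparisons"] == 3
        assert meta["bonferroni_thresholds"][0.05] == pytest.approx(0.05 / 3)
        assert meta["bonferroni_thresholds"][0.05] == pytest.approx(0.016, abs=7e-4)


class TestDoseResponseProperty:
    def test_responder_fraction_nondecreasing_in_dose(self, params):
        """Across 0 / 5 mg/kg Q4Dx4 / 10 mg/kg Q3Dx3 anti-PD-1 arms the
        fraction of slow-growing (responder) mice does not decrease.

        Arms are compared on the same virtual mice with the same
        measurement-noise draws (common random numbers), isolating the
        treatment effect from cohort-assignment noise."""
        from pdqsp.cohort import add_measurement_error, sample_individual
        from pdqsp.simulate import simulate_individual
        regs = {
            "ctrl": EMPTY_REGIMEN,
            "lo": parse_regimen("Q4Dx4 start 7", 5.0, "IV", "antiPD1",
                                p=params),
            "hi": parse_regimen("Q3Dx3 start 7", 10.0, "IV", "antiPD1",
                                p=params),
        }
        days = np.array([4., 7., 11., 14., 18., 21., 25., 28.])
        gen = np.random.default_rng(17)
        n = 8
        frac = {k: 0 for k in regs}
        for _ in range(n):
            m = sample_individual(params, 1, rng=gen)
            eps = gen.standard_normal(len(days))
            for arm, reg in regs.items():
                traj = simulate_individual(
                    m.individual_parameters(params), reg, t_end=28.0,
                    inoculum=2e6, grid=np.union1d([0], days), method="rk4")
                y = add_measurement_error(traj.volume_at(days), params.err_a,
                                          params.err_b, eps=eps)
                rate = observed_growth_rate(
                    pd.DataFrame({"day": days, "volume_mm3": y}), 7.0)
                frac[arm] += classify_response(rate) == "responder"
        assert frac["ctrl"] <= frac["lo"] <= frac["hi"]


@pytest.fixture(scope="module")
def mice(params):
    gen = np.random.default_rng(4)
    out = []
    for i, site in enumerate((1, 1)):
        m = sample_individual(params, site, rng=gen,
                              mouse_id=f"m{i}", study=site)
        m.inoculum = 2.0e6
        m.treatment_start = 7.0
        out.append(m)
    return out


class TestExpressionSweep:
    def test_nominal_level_matches_unswept(self, params, mice):
        from pdqsp.simulate import simulate_individual
        scen = {"control": EMPTY_REGIMEN}
        df = expression_sweep(mice, params, [params.R_PDL1], scen,
                              receptor="R_PDL1", readout_day=10.0)
        m = mice[0]
        traj = simulate_individual(m.individual_parameters(params),
                                   t_end=17.0, inoculum=m.inoculum,
                                   method="rk4")
        v0, v1 = traj.volume_at(7.0), traj.volume_at(17.0)
        want = 100.0 * (v1 - v0) / v0
        got = df[df["mouse"] == m.mouse_id]["pct_volume_change"].iloc[0]
        assert got == pytest.approx(want, rel=1e-9)

    def test_shape_and_ordering(self, params, mice):
        scen = {"control": EMPTY_REGIMEN,
                "antiPDL1": parse_regimen("Q3Dx3 start 7", 10.0, "IV",
                                          "antiPDL1", p=params)}
        grid = params.R_PDL1 * np.array([0.5, 1.0, 2.0])
        df = expression_sweep(mice, params, grid, scen, readout_day=8.0)
        assert len(df) == len(mice) * len(grid) * len(scen)
        kpfrs = df.groupby("mouse", sort=False)["kpfr_i"].first().to_numpy()
        assert np.all(np.diff(kpfrs) >= 0)

    def test_control_monotone_in_pdl1_expression(self, params, mice):
        """Under control, raising PD-L1 expression cannot help the host:
        percent volume change is non-decreasing in the expression level
        (low expression favors spontaneous regression)."""
        scen = {"control": EMPTY_REGIMEN}
        grid = params.R_PDL1 * np.array([0.05, 0.3, 1.0, 4.0])
        df = expression_sweep(mice, params, grid, scen, readout_day=10.0)
        for _, g in df.groupby("mouse"):
            v = g.sort_values("level")["pct_volume_change"].to_numpy()
            assert np.all(np.diff(v) >= -1e-6)
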