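"""Individual simulation: analytic oracles, event handling, summaries,
and the qualitative treatment-response properties of the coupled model."""

import numpy as np
import pytest

from pdqsp import _layout as L
from pdqsp.errors import ConfigError
from pdqsp.pk import parse_regimen
from pdqsp.simulate import (Trajectory, auc_tumor_volume,
                            percent_change_vs_control, simulate_individual)


def logistic_volume(t, v0, r, K):
    return K / (1.0 + (K / v0 - 1.0) * np.exp(-r * t))


@pytest.fixture(scope="module")
def regimens(params):
    return {
        "antiPD1": parse_regimen("Q3Dx3 start 7", 10.0, "IV", "antiPD1", p=params),
        "antiPDL1": parse_regimen("Q3Dx3 start 7", 10.0, "IV", "antiPDL1", p=params),
    }


@pytest.fixture(scope="module")
def control_traj(params):
    return simulate_individual(params, t_end=30.0, method="rk4")


class TestSimulateIndividual:
    def test_untreated_growth_matches_logistic_closed_form(self, params):
        """With killing and ADCC switched off the tumor follows the
        logistic solution in volume units to <0.1%."""
        p = params.updated(k_kill=1e-30, Emax_ADCC=1e-30)
        traj = simulate_individual(p, t_end=40.0, inoculum=2e6, method="rk4")
        v0 = 2e6 * p.v_cell / (1 - p.void_fraction)
        want = logistic_volume(traj.t, v0, p.kpfr_T, p.klimit_T)
        np.testing.assert_allclose(traj.volume, want, rtol=1e-3)

    def test_lsoda_and_rk4_agree(self, params, regimens):
        t1 = simulate_individual(params, regimens["antiPDL1"], t_end=25.0,
                                 method="lsoda")
        t2 = simulate_individual(params, regimens["antiPDL1"], t_end=25.0,
                                 method="rk4")
        np.testing.assert_allclose(t1.volume[-1], t2.volume[-1], rtol=1e-4)

    def test_iv_dose_jumps_central_amount(self, params):
        """At an IV dose time the central amount jumps by the dose."""
        reg = parse_regimen("Q3Dx1 start 5", 10.0, "IV", "antiPD1", p=params)
        grid = np.array([0.0, 4.999, 5.0, 5.001, 6.0])
        traj = simulate_individual(params, reg, t_end=6.0, grid=grid,
                                   method="rk4")
        pre = traj.states[np.searchsorted(traj.t, 5.0), L.I_AC1]
        post = np.interp(5.001, traj.t, traj.states[:, L.I_AC1])
        assert post - pre == pytest.approx(reg.events[0].amount, rel=2e-3)

    def test_step_refinement_converges(self, params, regimens):
        a = simulate_individual(params, regimens["antiPD1"], t_end=20.0,
                                method="rk4", rk4_dt=0.01)
        b = simulate_individual(params, regimens["antiPD1"], t_end=20.0,
                                method="rk4", rk4_dt=0.005)
        assert abs(a.volume[-1] - b.volume[-1]) / b.volume[-1] < 1e-4

    def test_nonnegativity_over_150_days(self, params, regimens):
        """No state goes materially negative over a long horizon, with
        the adaptive integrator."""
        traj = simulate_individual(params, regimens["antiPDL1"], t_end=150.0,
                                   method="lsoda")
        scale = np.abs(traj.states).max(axis=0)
        assert np.all(traj.states >= -1e-9 * np.maximum(scale, 1.0))

    def test_invalid_t_end_rejected(self, params):
        with pytest.raises(ConfigError):
            simulate_individual(params, t_end=-1.0)


class TestAucTumorVolume:
    def test_constant_and_triangle(self):
        t = np.linspace(0, 30, 301)
        traj = Trajectory(t=t, states=np.zeros((301, L.NSTATE)),
                          volume=np.full(301, 100.0), ctl=np.zeros(301),
                          occ_pd1=np.zeros(301), occ_pdl1=np.zeros(301),
                          x=np.zeros(301))
        assert auc_tumor_volume(traj, (0, 30)) == pytest.approx(3000.0)
        traj.volume = t.copy()
        assert auc_tumor_volume(traj, (0, 30)) == pytest.approx(450.0)

    def test_matches_fine_grid_quadrature(self, params, control_traj):
        fine = simulate_individual(params, t_end=30.0, grid=0.005,
                                   method="rk4")
        coarse_auc = auc_tumor_volume(control_traj, (0, 30))
        fine_auc = np.trapezoid(fine.volume, fine.t)
        assert coarse_auc == pytest.approx(fine_auc, rel=1e-4)

    def test_window_outside_span_rejected(self, control_traj):
        with pytest.raises(ConfigError):
            auc_tumor_volume(control_traj, (0, 60))


class TestPercentChange:
    @pytest.mark.parametrize("treated,control,expected", [
        (1000.0, 1000.0, 0.0),
        (750.0, 1000.0, -25.0),
        (651.0, 1.0, 65000.0),
    ])
    def test_convention(self, treated, control, expected):
        assert percent_change_vs_control(treated, control) == pytest.approx(expected)

    def test_zero_control_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_change_vs_control(1.0, 0.0)


class TestTreatmentProperties:
    def test_monotone_dose_response(self, params, control_traj):
        """30-day tumor AUC is non-increasing in anti-PD-L1 dose."""
        aucs = [auc_tumor_volume(control_traj, (0, 30))]
        for dose in (1.0, 10.0):
            reg = parse_regimen("Q3Dx3 start 7", dose, "IV", "antiPDL1",
                                p=params)
            traj = simulate_individual(params, reg, t_end=30.0, method="rk4")
            aucs.append(auc_tumor_volume(traj, (0, 30)))
        assert aucs[0] >= aucs[1] >= aucs[2]

    def test_mechanism_contrast_constant_vs_binding_influx(
            self, params, regimens, control_traj):
        """With the influx clamped at its baseline value, anti-PD-1
        barely changes tumor volume ten days after treatment start;
        with the binding-dependent influx both antibodies expand CTLs
        >10-fold and shrink the tumor >25%, and the anti-PD-L1 effect is
        at least as large as the anti-PD-1 effect in both modes."""
        day10 = 17.0  # treatment starts day 7

        def readout(p, reg):
            traj = simulate_individual(p, reg, t_end=20.0, method="rk4")
            return (float(traj.volume_at(day10)),
                    float(np.interp(day10, traj.t, traj.ctl)))

        vc, cc = (float(control_traj.volume_at(day10)),
                  float(np.interp(day10, control_traj.t, control_traj.ctl)))
        v1, c1 = readout(params, regimens["antiPD1"])
        v2, c2 = readout(params, regimens["antiPDL1"])
        assert c1 / cc > 10 and c2 / cc > 10
        assert (vc - v1) / vc > 0.25 and (vc - v2) / vc > 0.25
        assert v2 <= v1  # anti-PD-L1 at least as effective

        pc = params.updated(constant_influx=True)
        ctrl_c = simulate_individual(pc, t_end=20.0, method="rk4")
        vcc = float(ctrl_c.volume_at(day10))
        v1c, _ = readout(pc, regimens["antiPD1"])
        v2c, _ = readout(pc, regimens["antiPDL1"])
        assert abs(v1c - vcc) / vcc < 0.01   # resident T cells alone: <1%
        assert v2c <= v1c

    def test_trough_occupancy_ordering(self, params, regimens):
        """Trough PD-L1 occupancy under anti-PD-L1 exceeds trough PD-1
        occupancy under anti-PD-1 during the dosing window."""
        t1 = simulate_individual(params, regimens["antiPD1"], t_end=16.0,
                                 method="rk4")
        t2 = simulate_individual(params, regimens["antiPDL1"], t_end=16.0,
                                 method="rk4")
        sel = (t1.t >= 7.05) & (t1.t <= 16.0)
        assert t2.occ_pdl1[sel].min() > t1.occ_pd1[sel].min()

    def test_drug_conservation_without_elimination(self, params):
        """With CL = 0 the total IV drug amount is conserved."""
        from pdqsp.params import PKParameters
        pk0 = PKParameters(CL=1e-12, V1=1.5, V2=1.5, Q=0.5)
        p = params.updated(pk_antiPD1=pk0.model_dump())
        reg = parse_regimen("Q3Dx1 start 2", 10.0, "IV", "antiPD1", p=p)
        traj = simulate_individual(p, reg, t_end=20.0, method="lsoda")
        total = traj.states[:, L.I_AC1] + traj.states[:, L.I_AP1]
        after = traj.t > 2.0
        np.testing.assert_allclose(total[after], reg.events[0].amount,
                                   rtol=1e-8)
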