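"""Control functions, RHS bookkeeping, steady states and calibrations."""

import numpy as np
import pytest

from pdqsp import _layout as L
from pdqsp.binding import solve_binding_equilibrium
from pdqsp.errors import CalibrationError, ConfigError
from pdqsp.model import (
    activation_rate, baseline_steady_state, calibrate_binding_anchor,
    calibrate_tcell_kinetics, chain_steady_state_arr, influx_rate,
    make_state, rhs, stage_totals, tumor_volume, STAGE_NAMES,
)
from pdqsp.params import ModelParameters, default_parameters


class TestInfluxRate:
    def test_cancels_exactly_at_anchor(self, params):
        """At x = x_ref the two saturating terms cancel and the influx
        equals the baseline rate ks_IVt."""
        assert influx_rate(params.x_ref, params) == pytest.approx(
            params.ks_IVt, rel=1e-12)

    def test_limits(self, params):
        hi = params.Emax_influx / (1 + params.EC50 / params.x_ref) + params.ks_IVt
        assert influx_rate(1e-12, params) == pytest.approx(hi, rel=1e-6)
        assert influx_rate(1e12, params) == pytest.approx(params.ks_IVt)

    def test_monotone_nonincreasing_and_bounded(self, params):
        xs = np.logspace(-3, 3, 100)
        vals = np.array([influx_rate(x, params) for x in xs])
        assert np.all(np.diff(vals) <= 1e-9)
        hi = params.Emax_influx / (1 + params.EC50 / params.x_ref) + params.ks_IVt
        assert np.all(vals >= 0) and np.all(vals <= hi + 1e-9)

    def test_negative_x_rejected(self, params):
        with pytest.raises(ValueError):
            influx_rate(-0.1, params)


class TestActivationRate:
    def test_limits_and_half_max(self, params):
        assert activation_rate(1e-12, params) == pytest.approx(
            params.Emax_activate, rel=1e-6)
        assert activation_rate(params.EC50, params) == pytest.approx(
            params.Emax_activate / 2)
        assert activation_rate(1e12, params) == pytest.approx(0.0, abs=1e-6)

    def test_monotone_decreasing(self, params):
        xs = np.logspace(-3, 3, 100)
        vals = np.array([activation_rate(x, params) for x in xs])
        assert np.all(np.diff(vals) < 0)
        assert np.all((0 <= vals) & (vals <= params.Emax_activate))

    def test_blockade_raises_both_rates(self, params):
        """Lowering complexes per cell (receptor blockade) strictly
        increases influx and activation."""
        x0, x1 = params.x_ref, 0.3 * params.x_ref
        assert influx_rate(x1, params) > influx_rate(x0, params)
        assert activation_rate(x1, params) > activation_rate(x0, params)


class TestRhs:
    def test_zero_tumor_is_absorbing(self, params):
        y = baseline_steady_state(params, 0.0)
        dy = rhs(0.0, y, params)
        assert dy[L.I_T] == 0.0
        assert dy[L.I_TD] == 0.0

    def test_kill_bookkeeping(self, params):
        """Each CTL stage advance moves exactly one tumor cell to the
        damaged pool: without ADCC, dT_D/dt + kapop*T_D equals the total
        stage-advance flux, and dT/dt equals logistic growth minus it."""
        y = baseline_steady_state(params, 5.0e6)
        y[L.I_ED10:L.I_ED1 + 1] = np.linspace(2e5, 3e4, 10)
        y[L.I_TD] = 1e4
        dy = rhs(0.0, y, params)
        kkT = params.k_kill * y[L.I_T]
        kill_flux = kkT * np.sum(y[L.I_ED10:L.I_ED1 + 1])
        vol = tumor_volume(y, params)
        growth = params.kpfr_T * y[L.I_T] * (1 - vol / params.klimit_T)
        assert dy[L.I_TD] + params.kapop * y[L.I_TD] == pytest.approx(
            kill_flux, rel=1e-12)
        assert dy[L.I_T] == pytest.approx(growth - kill_flux, rel=1e-12)

    def test_chain_amplifies_256_fold(self, params):
        """With deaths and killing negligible, steady throughput from
        activation to the CTL inflow is amplified 2^8-fold."""
        p = params.updated(kd_CD8=1e-12, kA2I_basal=1e-12, kd_CTL=1.0, k_kill=1e-30)
        y = chain_steady_state_arr(p.to_array(), 1e6)
        activation_flux = activation_rate(p.x_ref, p) * y[L.I_EI]
        ctl_inflow = 2.0 * p.k_tr * y[L.I_EP7]
        assert ctl_inflow / activation_flux == pytest.approx(256.0, rel=1e-6)

    def test_nonfinite_state_rejected(self, params):
        y = make_state(1e6)
        y[L.I_EI] = np.nan
        with pytest.raises(ValueError):
            rhs(0.0, y, params)


class TestTumorVolume:
    def test_hand_arithmetic(self):
        p = ModelParameters(v_cell=1e-6, void_fraction=0.5)
        y = make_state(tumor_cells=6e5, damaged=4e5)
        assert tumor_volume(y, p) == pytest.approx(2.0)

    def test_zero_and_linearity(self, params):
        assert tumor_volume(make_state(0.0), params) == 0.0
        v1 = tumor_volume(make_state(1e6, 2e5), params)
        v2 = tumor_volume(make_state(2e6, 4e5), params)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_invalid_void_fraction_rejected(self):
        with pytest.raises((ConfigError, ValueError)):
            ModelParameters(void_fraction=1.2)


class TestBaselineSteadyState:
    def test_tcell_derivatives_vanish(self, params):
        """The returned state is a fixed point of the T-cell subsystem."""
        y = baseline_steady_state(params, 8.0e6)
        dy = rhs(0.0, y, params)
        scale = np.maximum(y[L.I_EI:L.I_ED0 + 1], 1.0)
        assert np.all(np.abs(dy[L.I_EI:L.I_ED0 + 1]) / scale < 1e-8)

    def test_anchor_value_after_calibration(self, params):
        sol = solve_binding_equilibrium(
            baseline_steady_state(params, 8.0e6), (0.0, 0.0), params)
        assert sol.x == pytest.approx(6.6, abs=1e-6)

    def test_zero_burden_pure_chain(self, params):
        """No tumor: x = 0, influx at its maximum, empty kill ladder."""
        y = baseline_steady_state(params, 0.0)
        denom_rate = params.kd_CD8 + activation_rate(0.0, params) \
            - params.kA2I_basal * activation_rate(0.0, params) \
            / (params.kd_CD8 + params.kA2I_basal + params.k_tr)
        assert y[L.I_EI] == pytest.approx(
            influx_rate(0.0, params) / denom_rate, rel=1e-9)
        assert np.all(y[L.I_ED10 + 1:L.I_ED0 + 1] == 0.0)


class TestCalibrateBindingAnchor:
    def test_reaches_anchor(self):
        p = calibrate_binding_anchor(default_parameters(), 8.0e6)
        sol = solve_binding_equilibrium(
            baseline_steady_state(p, 8.0e6), (0.0, 0.0), p)
        assert sol.x == pytest.approx(p.x_ref, abs=1e-6)

    def test_weaker_affinity_needs_more_ligand(self, params):
        """Doubling KD_PL and recalibrating yields a larger R_PDL1."""
        p2 = calibrate_binding_anchor(
            params.updated(KD_PL=2 * params.KD_PL), 8.0e6)
        assert p2.R_PDL1 > params.R_PDL1

    def test_zero_anchor_rejected(self, params):
        with pytest.raises((ConfigError, ValueError)):
            params.updated(x_ref=0.0)


class TestCalibrateTcellKinetics:
    def test_round_trip(self, params):
        """Calibrating to the fractions produced by a known parameter set
        recovers a steady state matching those fractions to <1e-6."""
        y = baseline_steady_state(params, 8.0e6)
        tot = stage_totals(y)
        total = sum(tot.values())
        targets = np.array([tot[k] / total for k in STAGE_NAMES])
        start = params.updated(Emax_activate=params.Emax_activate * 1.7,
                               kd_CD8=params.kd_CD8 * 0.6,
                               kd_CTL=params.kd_CTL * 1.4,
                               Thalf_CD8pfr=params.Thalf_CD8pfr * 1.3)
        cal = calibrate_tcell_kinetics(targets, start, tumor_burden=8.0e6)
        y2 = chain_steady_state_arr(cal.to_array(), 8.0e6)
        tot2 = stage_totals(y2)
        total2 = sum(tot2.values())
        got = np.array([tot2[k] / total2 for k in STAGE_NAMES])
        np.testing.assert_allclose(got, targets, rtol=1e-6)
        # identifiability: the generating rates themselves are recovered
        assert cal.Emax_activate == pytest.approx(params.Emax_activate, rel=1e-5)
        assert cal.kd_CD8 == pytest.approx(params.kd_CD8, rel=1e-5)
        assert cal.kd_CTL == pytest.approx(params.kd_CTL, rel=1e-5)
        assert cal.Thalf_CD8pfr == pytest.approx(params.Thalf_CD8pfr, rel=1e-5)

    def test_total_count_rescaling(self, params):
        y = baseline_steady_state(params, 8.0e6)
        tot = stage_totals(y)
        total = sum(tot.values())
        targets = np.array([tot[k] / total for k in STAGE_NAMES])
        cal = calibrate_tcell_kinetics(targets, params, tumor_burden=8.0e6,
                                       total_cd8=1e5)
        y2 = chain_steady_state_arr(cal.to_array(), 8.0e6)
        assert float(np.sum(y2[L.I_EI:L.I_ED0 + 1])) == pytest.approx(1e5, rel=1e-9)

    def test_zero_exhausted_fraction_infeasible(self, params):
        """Killing always populates the exhausted pool, so a zero
        exhausted-fraction target cannot be met."""
        with pytest.raises(CalibrationError):
            calibrate_tcell_kinetics(
                np.array([0.4, 0.2, 0.25, 0.15, 0.0]), params)

    def test_bad_sum_rejected(self, params):
        with pytest.raises(CalibrationError):
            calibrate_tcell_kinetics(
                np.array([0.4, 0.2, 0.25, 0.15, 0.2]), params)
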