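"""Mean-field rate model: transfer, fixed points, closed forms, stability."""

import numpy as np
import pytest

from striatal_dtt.meanfield import (
    AnatomicalParams,
    EffectiveWeights,
    FsiDriveModel,
    NotAFixedPointError,
    RateState,
    ScenarioInput,
    TABLE_ANATOMY,
    delta_msn_closed_form,
    effective_weight_from_anatomy,
    fixed_point,
    jacobian_stability,
    linear_fixed_points,
    msn_weights_from_anatomy,
    projected_residual,
    rate_dynamics,
    transfer,
    transfer_deriv,
)

from conftest import random_weights, scenario_input_for


class TestTransfer:
    def test_values(self):
        assert transfer(0.0) == 0.0
        assert transfer(1.0) == pytest.approx(1.0 / np.sqrt(2.0))
        assert transfer(1e6) == pytest.approx(1.0, abs=1e-9)
        assert transfer(-1e6) == pytest.approx(-1.0, abs=1e-9)

    def test_odd_and_increasing(self):
        z = np.linspace(-5, 5, 201)
        s = transfer(z)
        assert np.allclose(s, -transfer(-z))
        assert np.all(np.diff(s) > 0)
        assert np.all(np.abs(s) < 1.0)

    def test_derivative_matches_finite_difference(self):
        z = np.linspace(-3, 3, 41)
        h = 1e-6
        fd = (transfer(z + h) - transfer(z - h)) / (2 * h)
        assert np.allclose(transfer_deriv(z), fd, atol=1e-8)


class TestLinearClosedForms:
    def test_additive_reference_point(self, weights, clamped_fsi_10):
        # hand-solved 2x2 balance: J11 L1 + J12 L2 = lam + dctx - J1F*F, etc.
        inp = ScenarioInput("additive", lam_ctx=10.0, delta_ctx=1.0,
                            fsi_drive=clamped_fsi_10)
        res = linear_fixed_points(weights, inp)
        assert res.lam_d1 == pytest.approx(51.666666, abs=1e-4)
        assert res.lam_d2 == pytest.approx(33.333333, abs=1e-4)
        assert res.delta_msn == pytest.approx(18.333333, abs=1e-4)
        assert res.decomposition["inp_str"] == pytest.approx(-35.833333, abs=1e-4)
        assert res.decomposition["inp_add"] == pytest.approx(54.166666, abs=1e-4)

    def test_additive_sign_reversal_at_higher_drive(self, weights):
        drv = FsiDriveModel(mode="clamped", clamped_rate=20.0)
        inp = ScenarioInput("additive", lam_ctx=20.0, delta_ctx=1.0, fsi_drive=drv)
        assert delta_msn_closed_form(weights, inp).delta_msn == pytest.approx(
            -17.5, abs=1e-4
        )

    def test_equal_drive_always_favours_d2(self, weights, unit_gain_fsi):
        # no extra D1 input, co-modulated FSI: D2 rate exceeds D1 at any drive
        for lam in np.linspace(0.5, 40.0, 40):
            inp = ScenarioInput("additive", lam_ctx=float(lam), delta_ctx=0.0,
                                fsi_drive=unit_gain_fsi)
            res = linear_fixed_points(weights, inp)
            assert res.lam_d2 > res.lam_d1

    def test_multiplicative_reference_point(self, weights):
        drv = FsiDriveModel(mode="clamped", clamped_rate=0.0)
        inp = ScenarioInput("multiplicative", lam_ctx=10.0, fsi_drive=drv)
        res = delta_msn_closed_form(weights, inp)
        assert res.delta_msn == pytest.approx(11.666666, abs=1e-4)
        assert res.decomposition["d1_eff"] + res.decomposition["d2_eff"] == (
            pytest.approx(res.delta_msn)
        )

    def test_symmetric_additive_reference_point(self, weights, clamped_fsi_10):
        w = EffectiveWeights(jf_sym=0.075)
        inp = ScenarioInput("symmetric_additive", lam_ctx=10.0, delta_ctx=1.0,
                            fsi_drive=clamped_fsi_10)
        res = delta_msn_closed_form(w, inp)
        assert res.delta_msn == pytest.approx(34.8958333, abs=1e-3)

    def test_degenerate_weights_rejected(self):
        w = EffectiveWeights(j11=0.1, j22=0.1, j12=0.1, j21=0.1)
        from striatal_dtt.meanfield import DegenerateWeightsError

        with pytest.raises(DegenerateWeightsError):
            delta_msn_closed_form(w, ScenarioInput("additive"))

    @pytest.mark.parametrize(
        "scenario",
        ["additive", "multiplicative", "symmetric_additive",
         "symmetric_multiplicative"],
    )
    def test_closed_forms_match_linear_solver_oracle(self, scenario, rng):
        """Printed decompositions vs a generic numpy solve of the balance system."""
        for _ in range(250):
            w = random_weights(rng)
            inp = scenario_input_for(scenario, rng)
            j1f, j2f = w.fsi_weights(scenario)
            lam_fsi = inp.fsi_rate()
            if "additive" in scenario:
                e1, e2 = inp.lam_ctx + inp.delta_ctx, inp.lam_ctx
            else:
                e1, e2 = w.jc1 * inp.lam_ctx, w.jc2 * inp.lam_ctx
            a = np.array([[w.j11, w.j12], [w.j21, w.j22]])
            b = np.array([e1 - j1f * lam_fsi, e2 - j2f * lam_fsi])
            lam = np.linalg.solve(a, b)

            res = delta_msn_closed_form(w, inp)
            assert res.lam_d1 == pytest.approx(lam[0], rel=1e-9, abs=1e-9)
            assert res.lam_d2 == pytest.approx(lam[1], rel=1e-9, abs=1e-9)
            # decomposition identity: terms sum to lam_d1 - lam_d2
            assert sum(res.decomposition.values()) == pytest.approx(
                lam[0] - lam[1], rel=1e-9, abs=1e-9
            )


class TestDynamicsAndFixedPoints:
    def test_origin_is_fixed_point_without_input(self, weights):
        inp = ScenarioInput("additive", lam_ctx=0.0, delta_ctx=0.0,
                            fsi_drive=FsiDriveModel(mode="clamped", clamped_rate=0.0))
        traj = rate_dynamics(weights, inp, T=200.0)
        assert np.all(traj.lam_d1 == 0.0) and np.all(traj.lam_d2 == 0.0)
        fp = fixed_point(weights, inp)
        assert fp.lam_d1 == 0.0 and fp.lam_d2 == 0.0

    def test_steady_rates_bounded_by_saturation(self, weights):
        # steady state lam = 100 * S(z) with S <= 1
        for lam in (5.0, 10.0, 20.0, 50.0):
            fp = fixed_point(weights, ScenarioInput("multiplicative", lam_ctx=lam))
            assert 0.0 <= fp.lam_d1 <= 100.0
            assert 0.0 <= fp.lam_d2 <= 100.0

    @pytest.mark.parametrize("scenario,dctx", [("multiplicative", 0.0),
                                               ("additive", 1.0)])
    def test_fixed_point_matches_long_simulation(self, weights, scenario, dctx):
        for lam in (0.0, 2.0, 10.0, 17.0):
            inp = ScenarioInput(scenario, lam_ctx=lam, delta_ctx=dctx)
            fp = fixed_point(weights, inp)
            term = rate_dynamics(weights, inp, T=5000.0).terminal
            assert fp.lam_d1 == pytest.approx(term.lam_d1, abs=1e-4)
            assert fp.lam_d2 == pytest.approx(term.lam_d2, abs=1e-4)
            assert projected_residual(weights, inp, fp) < 1e-8

    def test_boundary_fixed_point_with_pinned_population(self, weights):
        # at zero cortical rate the extra D1 drive silences D2 entirely
        inp = ScenarioInput("additive", lam_ctx=0.0, delta_ctx=1.0,
                            fsi_drive=FsiDriveModel(mode="clamped", clamped_rate=0.0))
        fp = fixed_point(weights, inp)
        assert fp.lam_d2 == 0.0
        assert fp.lam_d1 > 0.0
        term = rate_dynamics(weights, inp, T=5000.0).terminal
        assert fp.lam_d1 == pytest.approx(term.lam_d1, abs=1e-4)


class TestStability:
    def test_jacobian_at_origin(self, weights):
        # S'(0) = 1: J = [[-0.07, -0.21], [-0.04, -0.23]]
        inp = ScenarioInput("additive", lam_ctx=0.0, delta_ctx=0.0,
                            fsi_drive=FsiDriveModel(mode="clamped", clamped_rate=0.0))
        eig = jacobian_stability(weights, inp, RateState(0.0, 0.0, 0.0))
        assert np.allclose(sorted(eig.real), [-0.27165526, -0.02834474], atol=1e-6)
        assert np.allclose(eig.imag, 0.0)

    def test_all_sweep_fixed_points_stable(self, weights):
        for lam in np.arange(0.0, 20.1, 1.0):
            inp = ScenarioInput("multiplicative", lam_ctx=float(lam))
            fp = fixed_point(weights, inp)
            eig = jacobian_stability(weights, inp, fp)
            assert np.all(eig.imag == 0.0)
            assert np.all(eig.real < 0.0)

    def test_perturbed_fixed_point_relaxes_back(self, weights):
        inp = ScenarioInput("multiplicative", lam_ctx=10.0)
        fp = fixed_point(weights, inp)
        start = RateState(fp.lam_d1 + 0.1, fp.lam_d2 + 0.1, fp.lam_fsi)
        term = rate_dynamics(weights, inp, initial=start, T=3000.0).terminal
        assert term.lam_d1 == pytest.approx(fp.lam_d1, abs=1e-4)
        assert term.lam_d2 == pytest.approx(fp.lam_d2, abs=1e-4)

    def test_non_fixed_point_rejected(self, weights):
        inp = ScenarioInput("multiplicative", lam_ctx=10.0)
        with pytest.raises(NotAFixedPointError):
            jacobian_stability(weights, inp, RateState(1.0, 1.0, inp.fsi_rate()))


class TestAnatomyToWeights:
    def test_fsi_projection_ratio(self):
        # equal unitary strength, probabilities 0.54 vs 0.36 -> ratio 1.5
        common = dict(n_source=80, ipsc=100.0, r_in=238.0, tau=8.0)
        j1f = effective_weight_from_anatomy(AnatomicalParams(rho=0.54, **common))
        j2f = effective_weight_from_anatomy(AnatomicalParams(rho=0.36, **common))
        assert j1f / j2f == pytest.approx(1.5)
        assert 0.09 / 0.06 == pytest.approx(1.5)

    def test_d2_to_d1_over_d1_to_d1_ratio(self):
        j12 = effective_weight_from_anatomy(TABLE_ANATOMY[("d1", "d2")])
        j11 = effective_weight_from_anatomy(TABLE_ANATOMY[("d1", "d1")])
        assert j12 / j11 == pytest.approx((0.27 * 133) / (0.26 * 42), rel=1e-12)
        # within 10% of the reference-table ratio 0.21 / 0.06
        assert j12 / j11 == pytest.approx(0.21 / 0.06, rel=0.1)

    def test_normalized_magnitudes_match_reference_within_10pct(self):
        got = msn_weights_from_anatomy()
        ref = {"j11": 0.06, "j12": 0.21, "j21": 0.04, "j22": 0.22}
        assert got["j22"] == pytest.approx(0.22)
        for k, v in ref.items():
            assert got[k] == pytest.approx(v, rel=0.10), k
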