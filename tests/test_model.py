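"""Unit and property tests for the three-compartment assay model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cartkin.estimation import DEFAULT_BOUNDS
from cartkin.model import (
    AssayProtocol,
    ModelParameters,
    REFERENCE_PARAMS,
    StateVector,
    cytolysis_rate,
    derivatives,
    legacy_derivatives,
    logistic_solution,
    percent_cytolysis,
    proliferation_rate,
    simulate_assay,
)


def params_with(**kw):
    return REFERENCE_PARAMS.replace(**kw)


class TestRateFunctions:
    def test_cytolysis_hand_evaluated(self):
        # kc * r^n/(Kmr^n + r^n) * T with r=2, Kmr=1, n=2: 0.1*(4/5)*1e4
        p = params_with(kc=0.1, Kmr=1.0, n=2.0)
        assert cytolysis_rate(p, StateVector(1e4, 2e4, 0)) == pytest.approx(800.0)

    def test_cytolysis_vanishes_without_effectors(self):
        assert cytolysis_rate(REFERENCE_PARAMS, StateVector(1e5, 0, 0)) == 0.0

    def test_cytolysis_vanishes_without_tumor(self):
        assert cytolysis_rate(REFERENCE_PARAMS, StateVector(0, 1e5, 0)) == 0.0

    def test_cytolysis_half_saturation_identity(self):
        # CART/T = Kmr puts the Hill term exactly at 1/2
        p = REFERENCE_PARAMS
        state = StateVector(1e4, p.Kmr * 1e4, 0)
        assert cytolysis_rate(p, state) == pytest.approx(p.kc * 1e4 / 2)

    def test_proliferation_hand_evaluated(self):
        # kp2 * fc^2/(Kmp^2+fc^2) * cart: 0.05*(9e4/1e5)*1e4
        p = params_with(kp2=0.05, Kmp=100.0)
        assert proliferation_rate(p, 300.0, 1e4) == pytest.approx(450.0)

    def test_proliferation_zero_and_half_saturation(self):
        p = REFERENCE_PARAMS
        assert proliferation_rate(p, 0.0, 1e4) == 0.0
        assert proliferation_rate(p, p.Kmp, 1e4) == pytest.approx(p.kp2 * 1e4 / 2)

    def test_proliferation_rejects_negative(self):
        with pytest.raises(ValueError):
            proliferation_rate(REFERENCE_PARAMS, -1.0, 1e4)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        T=st.floats(1.0, 1e7),
        CART=st.floats(0.0, 1e7),
        kc=st.floats(1e-3, 1.0),
        Kmr=st.floats(1e-2, 1e2),
        n=st.floats(0.1, 5.0),
        kp2=st.floats(1e-3, 1.0),
        Kmp=st.floats(1.0, 1e5),
    )
    def test_hill_terms_are_bounded(self, T, CART, kc, Kmr, n, kp2, Kmp):
        """The saturating fractions never exceed their plateau rates."""
        p = params_with(kc=kc, Kmr=Kmr, n=n, kp2=kp2, Kmp=Kmp)
        fc = cytolysis_rate(p, StateVector(T, CART, 0))
        assert 0.0 <= fc <= kc * T * (1 + 1e-12)
        fp = proliferation_rate(p, fc, CART)
        assert 0.0 <= fp <= kp2 * CART * (1 + 1e-12)


class TestDerivatives:
    def test_absorbing_origin(self):
        np.testing.assert_array_equal(
            derivatives(REFERENCE_PARAMS, StateVector(0, 0, 0)), np.zeros(3)
        )

    def test_logistic_fixed_point(self):
        p = REFERENCE_PARAMS
        d = derivatives(p, StateVector(p.CT, 0, 0))
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_untransduced_decay(self):
        p = params_with(kd=0.01)
        d = derivatives(p, StateVector(0, 0, 1e5))
        assert d[2] == pytest.approx(-1000.0)

    def test_matches_independent_rhs_on_random_states(self, rng):
        """Oracle: an independently coded analytic right-hand side."""
        p = REFERENCE_PARAMS

        def oracle(T, C, TC):
            r = C / T if T > 0 else 0.0
            hill = r**p.n / (p.Kmr**p.n + r**p.n) if (T > 0 and C > 0) else 0.0
            fc = p.kc * hill * T
            fp = p.kp2 * fc**2 / (p.Kmp**2 + fc**2) * C if fc > 0 else 0.0
            g = math.log(p.CE / max(C + TC, 1.0))
            return np.array([
                p.kp1 * T * (1 - T / p.CT) - fc,
                fp * g - p.kd * C,
                -p.kd * TC,
            ])

        for _ in range(100):
            T, C, TC = rng.uniform(0, 1e6, 3)
            got = derivatives(p, StateVector(T, C, TC))
            want = oracle(T, C, TC)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-10)

    def test_gompertz_capped_at_one_cell(self):
        d = derivatives(REFERENCE_PARAMS, StateVector(1e5, 0, 0))
        assert np.all(np.isfinite(d))

    def test_gompertz_orientation_flag_flips_sign(self):
        p = REFERENCE_PARAMS
        state = StateVector(1e5, 1e4, 1e4)
        normal = derivatives(p, state)
        flipped = derivatives(p, state, gompertz_inverted=True)
        fp_term = normal[1] + p.kd * state.CART
        fp_term_flipped = flipped[1] + p.kd * state.CART
        assert fp_term_flipped == pytest.approx(-fp_term)


class TestLegacyModel:
    def test_absorbing_origin(self):
        np.testing.assert_array_equal(
            legacy_derivatives(REFERENCE_PARAMS, StateVector(0, 0, 0)), np.zeros(3)
        )

    def test_mass_action_killing_product(self):
        p = params_with(kc=1e-6, kp1=0.04)
        d = legacy_derivatives(p, StateVector(1e4, 1e4, 0))
        fc = 1e-6 * 1e4 * 1e4  # = 100 cells/hour
        expected_dT = 0.04 * 1e4 * (1 - 1e4 / p.CT) - fc
        assert d[0] == pytest.approx(expected_dT)

    def test_no_tumor_drive(self):
        p = REFERENCE_PARAMS
        d = legacy_derivatives(p, StateVector(0, 2e4, 0))
        assert d[1] == pytest.approx(-p.kd * 2e4)

    def test_simulation_provenance_flags_variant(self, protocol):
        assert simulate_assay(REFERENCE_PARAMS, protocol, 1.0).model == "ratio-dependent"
        assert simulate_assay(REFERENCE_PARAMS, protocol, 1.0,
                              legacy=True).model == "mass-action"


class TestParameterValidation:
    def test_rejects_nonpositive_capacity(self):
        with pytest.raises(ValueError):
            params_with(CT=0.0)

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            params_with(kc=-0.1)

    def test_zero_rates_allowed(self):
        params_with(kc=0.0, kp2=0.0, kd=0.0)

    def test_array_round_trip(self):
        p = REFERENCE_PARAMS
        assert ModelParameters.from_array(p.as_array()) == p

    def test_state_rejects_negative(self):
        with pytest.raises(ValueError):
            StateVector(-1.0, 0, 0)


class TestSimulateAssay:
    def test_default_protocol_has_289_readings(self, protocol):
        sim = simulate_assay(REFERENCE_PARAMS, protocol, 25.0)
        assert len(sim.times) == 289

    def test_phase1_matches_logistic_closed_form(self, protocol):
        sim = simulate_assay(REFERENCE_PARAMS, protocol, 0.0)
        i = protocol.addition_index
        expected = logistic_solution(
            sim.times[: i + 1], protocol.target_seed,
            REFERENCE_PARAMS.kp1, REFERENCE_PARAMS.CT,
        )
        np.testing.assert_allclose(sim.T[: i + 1], expected, rtol=1e-6)

    def test_no_killing_equals_target_control(self, protocol):
        p = params_with(kc=0.0)
        cocult = simulate_assay(p, protocol, 25.0)
        control = simulate_assay(p, protocol, 0.0)
        np.testing.assert_allclose(cocult.T, control.T, rtol=1e-6)

    def test_effector_decay_limit(self):
        """With no targets, effectors decay as a pure exponential."""
        p = params_with(kd=0.01)
        protocol = AssayProtocol(target_seed=0.0)
        e0 = 2.5e5
        sim = simulate_assay(p, protocol, 0.0, effector_count=e0)
        i = protocol.addition_index
        tau = sim.times[i:] - protocol.effector_addition_time
        te = protocol.transduction_efficiency
        np.testing.assert_allclose(
            sim.CART[i:], te * e0 * np.exp(-0.01 * tau), rtol=1e-6
        )
        np.testing.assert_allclose(
            sim.TC[i:], (1 - te) * e0 * np.exp(-0.01 * tau), rtol=1e-6
        )

    def test_full_transduction_splits_pool(self):
        protocol = AssayProtocol(transduction_efficiency=1.0)
        sim = simulate_assay(REFERENCE_PARAMS, protocol, 1.0)
        i = protocol.addition_index
        assert sim.CART[i] == pytest.approx(4e4)
        assert sim.TC[i] == pytest.approx(0.0)

    def test_nonnegativity_across_random_parameters(self, protocol, rng):
        for _ in range(8):
            values = {
                name: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                for name, (lo, hi) in DEFAULT_BOUNDS.items()
            }
            sim = simulate_assay(ModelParameters(**values), protocol, 6.25)
            assert sim.states.min() >= -1e-6

    def test_condition_labels(self, protocol):
        assert simulate_assay(REFERENCE_PARAMS, protocol, 0.0).condition == "target_control"
        assert simulate_assay(REFERENCE_PARAMS, protocol, 25.0).condition == "coculture"
        ec = simulate_assay(
            REFERENCE_PARAMS, AssayProtocol(target_seed=0.0), 0.0, effector_count=1e5
        )
        assert ec.condition == "effector_control"

    def test_tidy_frame_columns(self, protocol):
        frame = simulate_assay(REFERENCE_PARAMS, protocol, 1.0).to_frame()
        assert list(frame.columns) == ["time_h", "T", "CART", "TC", "condition", "et_ratio"]
        assert len(frame) == 289


class TestPercentCytolysis:
    def test_reference_cases(self, protocol):
        control = simulate_assay(REFERENCE_PARAMS, protocol, 0.0)
        assert percent_cytolysis(control, control, 72.0) == 0.0
        cocult = simulate_assay(REFERENCE_PARAMS, protocol, 25.0)
        # hand arithmetic on synthetic values via a modified copy
        import dataclasses

        states = control.states.copy()
        states[-1, 0] = 0.25 * control.T[-1]
        fake = dataclasses.replace(cocult, states=states)
        assert percent_cytolysis(fake, control, 72.0) == pytest.approx(75.0)

    def test_complete_lysis_caps_at_100(self, protocol):
        import dataclasses

        control = simulate_assay(REFERENCE_PARAMS, protocol, 0.0)
        states = control.states.copy()
        states[-1, 0] = 0.0
        fake = dataclasses.replace(control, states=states, condition="coculture")
        assert percent_cytolysis(fake, control, 72.0) == 100.0

    def test_rejects_wrong_control(self, protocol):
        cocult = simulate_assay(REFERENCE_PARAMS, protocol, 25.0)
        with pytest.raises(ValueError):
            percent_cytolysis(cocult, cocult, 72.0)

    def test_monotone_in_kc_and_Kmr(self, protocol):
        """More saturated killing, more cytolysis; higher half-saturation
        ratio, less cytolysis (numeric check on a 5-point grid)."""
        def final_pc(p):
            control = simulate_assay(p, protocol, 0.0)
            sim = simulate_assay(p, protocol, 6.25)
            return percent_cytolysis(sim, control, 72.0)

        pcs = [final_pc(params_with(kc=kc)) for kc in np.linspace(0.02, 0.5, 5)]
        assert all(b >= a - 1e-9 for a, b in zip(pcs, pcs[1:]))
        pcs = [final_pc(params_with(Kmr=k)) for k in np.geomspace(0.5, 8.0, 5)]
        assert all(b <= a + 1e-9 for a, b in zip(pcs, pcs[1:]))
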