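"""Tests for impedance-trace preprocessing and CI/cell calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cartkin.calibration import (
    CalibrationCurve,
    CalibrationError,
    ImpedanceTrace,
    ProductDataset,
    build_mean_dataset,
    cells_from_ci,
    ci_from_cells,
    fit_calibration,
    impute_addition_ci,
    normalize_product,
    resolve_addition_time,
    shift_dataset_to_start,
    shift_to_start,
)
from cartkin.model import AssayProtocol, StateVector


def make_trace(ci, condition="target_control", et_ratio=None, times=None, **kw):
    ci = np.asarray(ci, dtype=float)
    if times is None:
        times = np.arange(ci.size, dtype=float)
    return ImpedanceTrace(times=times, ci=ci, condition=condition,
                          et_ratio=et_ratio, **kw)


class TestNormalization:
    def test_pooled_affine_map(self):
        tr = make_trace([0.5, 1.5, 2.5])
        (out,) = normalize_product([tr])
        np.testing.assert_allclose(out.ci, [0.0, 2.0, 4.0])

    def test_pooled_extremes_map_to_0_and_4(self):
        traces = [make_trace([1.0, 3.0]), make_trace([2.0, 5.0])]
        out = normalize_product(traces)
        pooled = np.concatenate([t.ci for t in out])
        assert pooled.min() == pytest.approx(0.0)
        assert pooled.max() == pytest.approx(4.0)

    def test_idempotent(self):
        traces = normalize_product([make_trace([0.2, 1.1, 0.9, 3.3])])
        again = normalize_product(traces)
        np.testing.assert_allclose(traces[0].ci, again[0].ci)

    def test_rejects_constant_pool(self):
        with pytest.raises(CalibrationError):
            normalize_product([make_trace([1.0, 1.0, 1.0])])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
    )
    def test_invariant_to_positive_affine_transforms(self, scale, offset):
        raw = np.array([0.1, 0.9, 0.4, 2.2, 1.7])
        a = normalize_product([make_trace(raw)])[0].ci
        b = normalize_product([make_trace(raw * scale + offset)])[0].ci
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestShift:
    def test_anchors_at_one(self):
        tr = make_trace([2.4, 2.9, 3.1])
        out = shift_to_start(tr, 0.0)
        assert out.ci[0] == pytest.approx(1.0)
        np.testing.assert_allclose(out.ci, tr.ci - 1.4)

    def test_identity_when_already_anchored(self):
        tr = make_trace([1.0, 1.4, 2.0])
        np.testing.assert_array_equal(shift_to_start(tr, 0.0).ci, tr.ci)

    def test_constant_zero_trace_becomes_one(self):
        out = shift_to_start(make_trace([0.0, 0.0, 0.0]), 0.0)
        np.testing.assert_allclose(out.ci, 1.0)

    def test_rejects_anchor_off_grid(self):
        with pytest.raises(ValueError):
            shift_to_start(make_trace([1.0, 2.0]), 0.5)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=20))
    def test_preserves_first_differences(self, values):
        tr = make_trace(values)
        out = shift_to_start(tr, 0.0)
        np.testing.assert_allclose(np.diff(out.ci), np.diff(tr.ci), atol=1e-12)

    def test_dataset_shift_uses_single_offset(self):
        target = make_trace([1.8, 2.0, 2.4])
        cocult = make_trace([2.2, 2.3, 2.5], "coculture", et_ratio=1.0)
        effector = make_trace([0.0, 0.1, 0.1], "effector_control")
        shifted, delta = shift_dataset_to_start([target, cocult, effector])
        assert delta == pytest.approx(1.0 - 2.0)
        # all traces moved by the same delta, including the effector control
        np.testing.assert_allclose(shifted[2].ci, effector.ci + delta)


class TestAdditionTime:
    def test_declared_passthrough(self, noisy_product):
        assert resolve_addition_time(noisy_product.dataset, 24.0) == 24.0

    def test_detects_injected_step(self):
        times = np.arange(0, 40.25, 0.25)
        ci = np.linspace(1.0, 2.0, times.size)
        ci[times >= 24.25] += 0.8  # bolus at 24.25 h
        ds = ProductDataset(
            traces=[
                make_trace(np.linspace(1, 2, times.size), times=times),
                make_trace(ci, "coculture", et_ratio=1.0, times=times),
            ],
            transduction_efficiency=0.3,
        )
        assert resolve_addition_time(ds) == pytest.approx(24.25)

    def test_smooth_trace_raises(self):
        times = np.arange(0, 40.25, 0.25)
        ds = ProductDataset(
            traces=[
                make_trace(np.linspace(1, 2, times.size), times=times),
                make_trace(np.linspace(2, 1, times.size), "coculture",
                           et_ratio=1.0, times=times),
            ],
            transduction_efficiency=0.3,
        )
        with pytest.raises(CalibrationError):
            resolve_addition_time(ds)


class TestCalibrationFit:
    @staticmethod
    def dataset(jump=0.5, rho=1.0, ci0=1.0):
        times = np.arange(0, 48.25, 0.25)
        i_add = int(24 / 0.25)
        # flat target control: no growth increment to correct for
        target = make_trace(np.full(times.size, ci0), times=times)
        cc = np.full(times.size, ci0)
        cc[i_add:] += jump
        cocult = make_trace(cc, "coculture", et_ratio=rho, times=times)
        return ProductDataset(traces=[target, cocult], transduction_efficiency=0.3)

    def test_slopes_from_known_conditions(self):
        curve = fit_calibration(self.dataset(), AssayProtocol(), t_add=24.0)
        assert curve.target_slope == pytest.approx(1.0 / 4e4)  # = 2.5e-5
        assert curve.effector_slope == pytest.approx(0.5 / 4e4)  # = 1.25e-5

    def test_zero_jump_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration(self.dataset(jump=0.0), AssayProtocol(), t_add=24.0)

    def test_growth_increment_correction(self):
        """Tumor growth during the addition step must not count as
        effector signal: a growing target control shrinks the jump."""
        ds = self.dataset(jump=0.5)
        grow = ds.traces[0].ci + 0.002 * np.arange(ds.traces[0].ci.size)
        cc = ds.traces[1].ci + 0.002 * np.arange(ds.traces[1].ci.size)
        ds2 = ProductDataset(
            traces=[ds.traces[0].with_ci(grow), ds.traces[1].with_ci(cc)],
            transduction_efficiency=0.3,
        )
        curve = fit_calibration(ds2, AssayProtocol(), t_add=24.0)
        assert curve.effector_slope == pytest.approx(0.5 / 4e4)


class TestCellCIConversion:
    curve = CalibrationCurve(target_slope=2.5e-5, effector_slope=1.25e-5)

    def test_empty_well_is_baseline(self):
        assert ci_from_cells(StateVector(0, 0, 0), self.curve) == 0.0

    def test_target_seed_maps_to_one(self):
        assert ci_from_cells(StateVector(4e4, 0, 0), self.curve) == pytest.approx(1.0)

    def test_effector_contribution_independent_of_targets(self):
        a = ci_from_cells(StateVector(1e4, 2e4, 1e4), self.curve) - ci_from_cells(
            StateVector(1e4, 0, 0), self.curve
        )
        b = ci_from_cells(StateVector(9e5, 2e4, 1e4), self.curve) - ci_from_cells(
            StateVector(9e5, 0, 0), self.curve
        )
        assert a == pytest.approx(b)

    def test_round_trip_single_population(self, rng):
        for _ in range(20):
            cells = rng.uniform(1.0, 1e7)
            ci = ci_from_cells(StateVector(cells, 0, 0), self.curve)
            back = cells_from_ci(ci, self.curve, "target")
            assert back == pytest.approx(cells, rel=1e-10)
            ci = ci_from_cells(StateVector(0, cells / 2, cells / 2), self.curve)
            back = cells_from_ci(ci, self.curve, "effector")
            assert back == pytest.approx(cells, rel=1e-10)


class TestImputation:
    def test_sums_prior_and_effector_control(self):
        times = np.arange(0, 2.25, 0.25)
        cc = make_trace([1.0, 1.2, 1.2, 1.2, 9.9, 1.6, 1.6, 1.5, 1.5],
                        "coculture", et_ratio=1.0, times=times)
        ec = make_trace([0.0, 0.0, 0.0, 0.0, 0.3, 0.3, 0.3, 0.3, 0.3],
                        "effector_control", times=times)
        out = impute_addition_ci(cc, ec, 1.0)
        assert out.ci[4] == pytest.approx(1.2 + 0.3)
        np.testing.assert_array_equal(np.delete(out.ci, 4), np.delete(cc.ci, 4))

    def test_zero_effector_control_keeps_prior(self):
        times = np.arange(0, 1.25, 0.25)
        cc = make_trace([1.0, 1.2, 0.0, 1.3, 1.3], "coculture", et_ratio=1.0,
                        times=times)
        ec = make_trace(np.zeros(5), "effector_control", times=times)
        assert impute_addition_ci(cc, ec, 0.5).ci[2] == pytest.approx(1.2)

    def test_first_point_rejected(self):
        times = np.arange(0, 1.25, 0.25)
        cc = make_trace(np.ones(5), "coculture", et_ratio=1.0, times=times)
        ec = make_trace(np.zeros(5), "effector_control", times=times)
        with pytest.raises(ValueError):
            impute_addition_ci(cc, ec, 0.0)


class TestMeanDataset:
    @staticmethod
    def product(scale, t_add=24.0):
        times = np.arange(0, 72.25, 0.25)
        i_add = int(round(t_add / 0.25))
        target = make_trace(scale * np.linspace(1, 2, times.size), times=times)
        ec_ci = np.zeros(times.size)
        ec_ci[i_add:] = scale * 0.5
        ec = make_trace(ec_ci, "effector_control", times=times)
        cc_ci = scale * np.linspace(1, 2, times.size)
        cc_ci[i_add:] += scale  # bolus
        cc = make_trace(cc_ci, "coculture", et_ratio=1.0, times=times)
        return ProductDataset(traces=[target, ec, cc], transduction_efficiency=0.3)

    def test_identical_products_reproduce_member(self):
        a, b = self.product(1.0), self.product(1.0)
        mean = build_mean_dataset([a, b])
        np.testing.assert_allclose(
            mean.select("target_control")[0].ci, a.select("target_control")[0].ci
        )

    def test_pointwise_average(self):
        mean = build_mean_dataset([self.product(1.0), self.product(3.0)])
        np.testing.assert_allclose(
            mean.select("target_control")[0].ci,
            (self.product(1.0).select("target_control")[0].ci
             + self.product(3.0).select("target_control")[0].ci) / 2,
        )

    def test_alignment_at_individual_addition_times(self):
        """Products added at 24.0 and 24.5 h are averaged on relative
        post-addition time, so the mean preserves the bolus step."""
        a, b = self.product(1.0, t_add=24.0), self.product(1.0, t_add=24.5)
        mean = build_mean_dataset([a, b])
        cc = mean.select("coculture", et_ratio=1.0)[0]
        i = cc.index_of(24.25)  # mean addition time, rounded to grid
        jump = cc.ci[i] - cc.ci[i - 1]
        assert jump == pytest.approx(1.0, rel=0.02)  # full bolus, not half

    def test_inconsistent_ratios_rejected(self):
        a = self.product(1.0)
        b = self.product(1.0)
        other = [
            tr if tr.condition != "coculture"
            else make_trace(tr.ci, "coculture", et_ratio=6.25, times=tr.times)
            for tr in b.traces
        ]
        b2 = ProductDataset(traces=other, transduction_efficiency=0.3)
        with pytest.raises(ValueError):
            build_mean_dataset([a, b2])

    def test_flagged_as_synthetic_mean(self):
        mean = build_mean_dataset([self.product(1.0), self.product(2.0)])
        assert mean.product_id == "synthetic-mean"
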