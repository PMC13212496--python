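"""Impedance-trace preprocessing and cell-count calibration.

Real-time impedance instruments report a dimensionless cell index (CI)
per well.  Raw traces vary in starting CI and overall magnitude between
products, so each product's pooled traces are rescaled to a common 0-4
CI range, aligned so the target-only phase starts at 1 CI, and the
effector-addition time is located (from the instrument log when
available, otherwise from the CI step the effector bolus produces).

Model fitting happens in cell counts, so each product also gets a linear
calibration between counts and CI: adherent targets and suspended
effectors alter impedance with distinct slopes, estimated from the known
seeding conditions (target seed at time zero, effector bolus size at the
addition jump).  Lysed cells contribute no impedance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np

from .model import AssayProtocol, StateVector

__all__ = [
    "CONDITIONS",
    "ImpedanceTrace",
    "ProductDataset",
    "CalibrationCurve",
    "CalibrationError",
    "normalize_product",
    "shift_to_start",
    "resolve_addition_time",
    "fit_calibration",
    "ci_from_cells",
    "cells_from_ci",
    "impute_addition_ci",
    "build_mean_dataset",
]

CONDITIONS = ("target_control", "effector_control", "coculture", "positive_control")

#: normalized CI range ceiling
CI_SCALE = 4.0


class CalibrationError(ValueError):
    """Raised when traces violate assay polarity or lack required signal."""


@dataclass(frozen=True)
class ImpedanceTrace:
    """One well's cell-index time series plus condition metadata."""

    times: np.ndarray
    ci: np.ndarray
    condition: str
    et_ratio: float | None = None
    replicate: int = 0
    product_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ci = np.asarray(self.ci, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ci", ci)
        if times.ndim != 1 or times.shape != ci.shape:
            raise ValueError("times and ci must be matching 1-D arrays")
        if times.size and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(ci)):
            raise ValueError("ci values must be finite")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "coculture":
            if self.et_ratio is None or self.et_ratio <= 0:
                raise ValueError("coculture traces need a positive et_ratio")
        elif self.et_ratio is not None:
            raise ValueError(f"{self.condition} traces must not carry an et_ratio")

    def with_ci(self, ci: np.ndarray) -> "ImpedanceTrace":
        return dc_replace(self, ci=np.asarray(ci, dtype=float))

    def index_of(self, t: float) -> int:
        hits = np.isclose(self.times, t, rtol=0.0, atol=1e-9)
        if not hits.any():
            raise ValueError(f"time {t} is not on the trace grid")
        return int(np.argmax(hits))


@dataclass
class ProductDataset:
    """All traces plus metadata and clinical outcomes for one product."""

    traces: list
    transduction_efficiency: float
    cd4_cd8_ratio: float | None = None
    disease: str | None = None
    manufacturing_days: float | None = None
    outcomes: object | None = None
    product_id: str = ""

    def __post_init__(self) -> None:
        self.traces = list(self.traces)
        if not any(t.condition == "target_control" for t in self.traces):
            raise ValueError("a product dataset needs at least one target-control trace")
        if not 0 < self.transduction_efficiency <= 1:
            raise ValueError("transduction_efficiency must be in (0, 1]")

    def select(self, condition: str, et_ratio: float | None = None) -> list:
        out = [t for t in self.traces if t.condition == condition]
        if et_ratio is not None:
            out = [t for t in out if t.et_ratio is not None
                   and math.isclose(t.et_ratio, et_ratio)]
        return out

    @property
    def coculture_ratios(self) -> list:
        return sorted({t.et_ratio for t in self.traces if t.condition == "coculture"})

    def replace_traces(self, traces: Iterable[ImpedanceTrace]) -> "ProductDataset":
        new = ProductDataset(
            traces=list(traces),
            transduction_efficiency=self.transduction_efficiency,
            cd4_cd8_ratio=self.cd4_cd8_ratio,
            disease=self.disease,
            manufacturing_days=self.manufacturing_days,
            outcomes=self.outcomes,
            product_id=self.product_id,
        )
        return new


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-product linear maps between cell counts and CI."""

    target_slope: float   # CI per adherent tumor cell
    effector_slope: float  # CI per suspended effector cell
    baseline: float = 0.0  # CI of an empty well

    def __post_init__(self) -> None:
        for name in ("target_slope", "effector_slope"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise CalibrationError(f"{name} must be positive and finite, got {v}")
        if not math.isfinite(self.baseline):
            raise CalibrationError("baseline must be finite")


def normalize_product(traces: Sequence[ImpedanceTrace]) -> list:
    """Rescale a product's pooled CI values onto [0, 4].

    All of the product's traces are normalized collectively with the
    pooled minimum and maximum: ``(ci - min) / (max - min) * 4``.  The
    map is affine, so it is idempotent and invariant to positive affine
    transforms of the raw data.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    pooled = np.concatenate([t.ci for t in traces])
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        raise CalibrationError("pooled CI range is zero; cannot normalize")
    scale = CI_SCALE / (hi - lo)
    return [t.with_ci((t.ci - lo) * scale) for t in traces]


def shift_to_start(trace: ImpedanceTrace, anchor_time: float = 0.0) -> ImpedanceTrace:
    """Additively shift a trace so its CI equals 1 at ``anchor_time``."""
    i = trace.index_of(anchor_time)
    return trace.with_ci(trace.ci + (1.0 - trace.ci[i]))


def shift_dataset_to_start(
    traces: Sequence[ImpedanceTrace], anchor_time: float = 0.0
) -> tuple[list, float]:
    """Shift all of a product's traces by one common offset.

    The offset anchors the mean CI of target-bearing wells (target
    control and co-culture) at 1 CI at ``anchor_time``; applying a single
    offset product-wide keeps wells mutually comparable.  Returns the
    shifted traces and the offset (which becomes the post-shift baseline
    when the pooled pre-shift minimum sat at 0).
    """
    traces = list(traces)
    anchored = [t for t in traces if t.condition in ("target_control", "coculture")]
    if not anchored:
        raise ValueError("no target-bearing traces to anchor the shift")
    start_ci = float(np.mean([t.ci[t.index_of(anchor_time)] for t in anchored]))
    delta = 1.0 - start_ci
    return [t.with_ci(t.ci + delta) for t in traces], delta


def resolve_addition_time(
    dataset: ProductDataset,
    declared: float | None = None,
    window: tuple = (20.0, 28.0),
) -> float:
    """Locate the effector-addition time.

    A declared time (instrument log, or the generating protocol) is
    authoritative.  Otherwise the addition is taken as the grid time of
    the largest single-step positive CI jump across the co-culture
    traces inside ``window`` — the effector bolus raises impedance
    discontinuously.
    """
    if declared is not None:
        return float(declared)
    cocultures = dataset.select("coculture")
    if not cocultures:
        raise ValueError("dataset has no coculture traces")
    best_jump = 0.0
    best_time = None
    for tr in cocultures:
        diffs = np.diff(tr.ci)
        t_after = tr.times[1:]
        mask = (t_after >= window[0]) & (t_after <= window[1])
        if not mask.any():
            continue
        j = int(np.argmax(np.where(mask, diffs, -np.inf)))
        if diffs[j] > best_jump:
            best_jump = float(diffs[j])
            best_time = float(t_after[j])
    if best_time is None or best_jump <= 0:
        raise CalibrationError(
            "no positive CI jump found in the addition window; "
            "cannot locate effector addition"
        )
    return best_time


def fit_calibration(
    dataset: ProductDataset,
    protocol: AssayProtocol,
    t_add: float | None = None,
    baseline: float = 0.0,
    effector_slope_from: str = "coculture",
    effector_control_count: float | None = None,
) -> CalibrationCurve:
    """Build the per-product linear CI/cell calibration.

    The target slope comes from the known seed: the mean target-control
    CI at time zero, above baseline, divided by the seeded target count.
    The effector slope comes from the CI jump at effector addition in
    each co-culture well divided by the known effector bolus, averaged
    (unweighted) over ratios.  The mean target-control increment over the
    same sampling step is subtracted from each jump so tumor growth
    during the addition interval does not inflate the effector slope.

    ``effector_slope_from="effector_control"`` instead derives the slope
    from the effector-control wells' own addition jump divided by
    ``effector_control_count`` — required when the co-culture addition
    reading was missed and imputed (the imputed value carries the
    effector-control bolus, not the co-culture bolus).
    """
    if t_add is None:
        t_add = resolve_addition_time(dataset)
    targets = dataset.select("target_control")
    if not targets:
        raise CalibrationError("no target-control traces")
    ci0 = float(np.mean([t.ci[t.index_of(0.0)] for t in targets]))
    if protocol.target_seed <= 0:
        raise CalibrationError("protocol target seed must be positive")
    target_slope = (ci0 - baseline) / protocol.target_seed

    ratios = dataset.coculture_ratios
    if not ratios:
        raise CalibrationError("no coculture traces")

    def step_increment(trace):
        i = trace.index_of(t_add)
        if i == 0:
            raise CalibrationError("addition time has no preceding timepoint")
        return trace.ci[i] - trace.ci[i - 1]

    if effector_slope_from == "coculture":
        # tumor keeps growing during the addition interval; its mean CI
        # increment (from the target controls) is removed from the jump
        growth_increment = float(np.mean([step_increment(t) for t in targets]))
        jumps, boluses = [], []
        for rho in ratios:
            for tr in dataset.select("coculture", et_ratio=rho):
                jumps.append(step_increment(tr) - growth_increment)
                boluses.append(rho * protocol.target_seed)
        jumps = np.asarray(jumps)
        boluses = np.asarray(boluses)
        # through-origin regression of jump on bolus: with homoscedastic
        # reading noise this is the minimum-variance slope, instead of an
        # unweighted per-ratio mean that lets the smallest (noisiest)
        # bolus dominate the error
        effector_slope = float((jumps * boluses).sum() / (boluses**2).sum())
    elif effector_slope_from == "effector_control":
        if effector_control_count is None or effector_control_count <= 0:
            raise CalibrationError(
                "effector_control_count required to calibrate from controls"
            )
        controls = dataset.select("effector_control")
        if not controls:
            raise CalibrationError("no effector-control traces to calibrate from")
        jumps = [step_increment(tr) for tr in controls]
        effector_slope = float(np.mean(jumps) / effector_control_count)
    else:
        raise ValueError(
            "effector_slope_from must be 'coculture' or 'effector_control'"
        )

    if target_slope <= 0 or effector_slope <= 0:
        raise CalibrationError(
            "estimated slope is not positive; assay polarity violated "
            f"(target {target_slope:.3g}, effector {effector_slope:.3g})"
        )
    return CalibrationCurve(
        target_slope=float(target_slope),
        effector_slope=effector_slope,
        baseline=float(baseline),
    )


def ci_from_cells(state, curve: CalibrationCurve):
    """Map cell counts to CI: ``baseline + sT*T + sE*(CART + TC)``.

    ``state`` may be a :class:`~cartkin.model.StateVector` or an array
    whose last axis holds (T, CART, TC).
    """
    if isinstance(state, StateVector):
        arr = state.as_array()
    else:
        arr = np.asarray(state, dtype=float)
    T = arr[..., 0]
    effectors = arr[..., 1] + arr[..., 2]
    return curve.baseline + curve.target_slope * T + curve.effector_slope * effectors


def cells_from_ci(ci, curve: CalibrationCurve, population: str = "target"):
    """Invert the calibration for a well holding a single population."""
    ci = np.asarray(ci, dtype=float)
    if population == "target":
        return (ci - curve.baseline) / curve.target_slope
    if population == "effector":
        return (ci - curve.baseline) / curve.effector_slope
    raise ValueError("population must be 'target' or 'effector'")


def impute_addition_ci(
    coculture: ImpedanceTrace,
    effector_control: ImpedanceTrace,
    t_add: float,
) -> ImpedanceTrace:
    """Reconstruct the reading missed while the plate was out for addition.

    The CI at the addition timepoint is replaced by the co-culture CI at
    the preceding timepoint (targets only, just before addition) plus the
    effector-control CI at the addition timepoint (the effector bolus
    contribution).  All other points are unchanged.
    """
    if not np.array_equal(coculture.times, effector_control.times):
        raise ValueError("coculture and effector control must share the grid")
    i = coculture.index_of(t_add)
    if i == 0:
        raise ValueError("addition time has no preceding timepoint")
    ci = coculture.ci.copy()
    ci[i] = coculture.ci[i - 1] + effector_control.ci[i]
    return coculture.with_ci(ci)


def _mean_of(stacks: list) -> np.ndarray:
    return np.mean(np.vstack(stacks), axis=0)


def build_mean_dataset(cohort: Sequence[ProductDataset]) -> ProductDataset:
    """Pointwise-mean dataset across a cohort of products.

    Per condition and ratio, traces are averaged on a common relative
    grid: the target-only phase is aligned at time zero and the
    post-addition phase of co-culture and effector-control wells is
    aligned at each product's own addition time.  The mean co-culture
    trace uses the mean target control before addition and the aligned
    co-culture mean afterward; the output is flagged as a synthetic mean
    (product_id ``"synthetic-mean"``), with addition placed at the mean
    addition time rounded to the grid.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise ValueError("need at least two products to build a mean dataset")
    ratio_sets = [tuple(d.coculture_ratios) for d in cohort]
    if len(set(ratio_sets)) != 1:
        raise ValueError("inconsistent coculture ratios across products")
    ratios = ratio_sets[0]
    if not ratios:
        raise ValueError("cohort has no coculture traces")

    t_adds = [resolve_addition_time(d) for d in cohort]
    base = cohort[0].select("target_control")[0]
    step = float(np.median(np.diff(base.times)))
    total = float(base.times[-1])
    mean_t_add = step * round(np.mean(t_adds) / step)
    grid = np.round(np.arange(0.0, total + step / 2, step), 9)
    idx_add = int(round(mean_t_add / step))
    # the common grid ends where the shortest post-addition segment does
    n_post = min(
        len(d.select("coculture", et_ratio=ratios[0])[0].times)
        - d.select("coculture", et_ratio=ratios[0])[0].index_of(ta)
        for d, ta in zip(cohort, t_adds)
    )
    grid = grid[: idx_add + n_post]

    def product_mean(dataset, condition, rho=None):
        traces = dataset.select(condition, et_ratio=rho)
        if not traces:
            raise ValueError(f"product {dataset.product_id!r} lacks {condition} traces")
        return _mean_of([t.ci for t in traces])

    def post_addition_segment(dataset, t_add, condition, rho=None):
        ci = product_mean(dataset, condition, rho)
        traces = dataset.select(condition, et_ratio=rho)
        i = traces[0].index_of(t_add)
        seg = ci[i:]
        if len(seg) < n_post:
            raise ValueError("post-addition segment shorter than the common grid")
        return seg[:n_post]

    tc_mean = _mean_of([product_mean(d, "target_control")[: len(grid)] for d in cohort])
    out_traces = [
        ImpedanceTrace(grid, tc_mean, "target_control", replicate=0,
                       product_id="synthetic-mean")
    ]

    if all(d.select("effector_control") for d in cohort):
        ec_post = _mean_of([
            post_addition_segment(d, ta, "effector_control")
            for d, ta in zip(cohort, t_adds)
        ])
        ec = np.concatenate([
            _mean_of([product_mean(d, "effector_control")[:idx_add] for d in cohort]),
            ec_post,
        ])
        out_traces.append(
            ImpedanceTrace(grid, ec, "effector_control", replicate=0,
                           product_id="synthetic-mean")
        )

    for rho in ratios:
        post = _mean_of([
            post_addition_segment(d, ta, "coculture", rho)
            for d, ta in zip(cohort, t_adds)
        ])
        ci = np.concatenate([tc_mean[:idx_add], post])
        out_traces.append(
            ImpedanceTrace(grid, ci, "coculture", et_ratio=rho, replicate=0,
                           product_id="synthetic-mean")
        )

    return ProductDataset(
        traces=out_traces,
        transduction_efficiency=float(np.mean(
            [d.transduction_efficiency for d in cohort]
        )),
        product_id="synthetic-mean",
    )
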