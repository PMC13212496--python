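"""Sensitivity and identifiability analysis of the effector parameters.

Three complementary views of how informative the assay is about each
parameter:

* **error sensitivity** — one-at-a-time relative perturbations of the
  fitted effector parameters, recording the change in the co-culture SSR;
  large |ΔSSR| marks a parameter the data actually constrain;
* **parameter correlations** — the correlation matrix implied by the
  Gauss-Newton approximation to the objective Hessian at the optimum
  (finite-difference residual Jacobian on log-parameters), with the
  conventional 0.80 (high) and 0.93 (practically non-identifiable)
  flags; an empirical multi-start alternative is exposed;
* **global sensitivity** — one-at-a-time sweeps of each effector
  parameter across its bounds crossed with a grid of initial E:T ratios,
  recording percent tumor cytolysis at a fixed horizon after effector
  addition.

An E:T sweep summarizes the predicted ratio dependence: the smallest
ratio whose cytolysis sits within a tolerance of the top ratio
("saturation ratio") and the largest ratio whose cytolysis stays below a
negligibility floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibration as cal
from .estimation import STAGE3_PARAMS, FitConfig, ParameterBounds, _CocultureObjective
from .model import (
    AssayProtocol,
    ModelParameters,
    percent_cytolysis,
    simulate_assay,
)

__all__ = [
    "EFFECTOR_PARAMETERS",
    "SensitivityReport",
    "CorrelationMatrix",
    "error_sensitivity",
    "global_sensitivity",
    "parameter_correlation",
    "correlation_from_jacobian",
    "et_sweep",
]

#: the seven effector-side parameters (stage-3 free parameters plus the
#: separately estimated decay rate)
EFFECTOR_PARAMETERS = STAGE3_PARAMS + ("kd",)

DEFAULT_PERTURBATIONS = (-0.5, -0.25, -0.1, 0.1, 0.25, 0.5)
DEFAULT_ET_GRID = (0.25, 0.5, 1.0, 6.25, 12.5, 25.0)

HIGH_CORRELATION = 0.80
NON_IDENTIFIABLE = 0.93


@dataclass(frozen=True)
class SensitivityReport:
    """SSR change for one parameter at one relative perturbation."""

    parameter: str
    perturbation: float
    delta_ssr: float
    baseline_ssr: float
    out_of_bounds: bool = False


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise parameter correlations with identifiability flags."""

    names: tuple
    matrix: np.ndarray
    method: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape does not match names")

    def pairs_above(self, threshold: float) -> list:
        out = []
        for i in range(len(self.names)):
            for j in range(i + 1, len(self.names)):
                if abs(self.matrix[i, j]) > threshold:
                    out.append((self.names[i], self.names[j],
                                float(self.matrix[i, j])))
        return out

    @property
    def high_pairs(self) -> list:
        return self.pairs_above(HIGH_CORRELATION)

    @property
    def non_identifiable_pairs(self) -> list:
        return self.pairs_above(NON_IDENTIFIABLE)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.names, columns=self.names)


def _coculture_objective(dataset, params, curve, protocol, t_add, substeps):
    return _CocultureObjective(
        dataset, (params.kp1, params.CT, params.kd), curve, protocol, t_add,
        substeps,
    )


def _stage3_ssr(objective, params: ModelParameters) -> float:
    free = np.array([getattr(params, k) for k in STAGE3_PARAMS])
    return objective.ssr(free)


def error_sensitivity(
    dataset: cal.ProductDataset,
    params: ModelParameters,
    curve: cal.CalibrationCurve,
    perturbations: Sequence[float] = DEFAULT_PERTURBATIONS,
    bounds: ParameterBounds | None = None,
    protocol: AssayProtocol | None = None,
    t_add: float | None = None,
    substeps: int = 4,
) -> list:
    """One-at-a-time error sensitivity of the effector parameters.

    Each effector parameter is scaled by (1 + perturbation) while the
    rest stay at the fitted values; the report records
    ``SSR(perturbed) - SSR(baseline)`` over the co-culture wells.
    Perturbations leaving the bounds are still evaluated but flagged.
    """
    bounds = bounds or ParameterBounds()
    protocol = protocol or AssayProtocol()
    if t_add is None:
        t_add = cal.resolve_addition_time(dataset, protocol.effector_addition_time)
    objective = _coculture_objective(dataset, params, curve, protocol, t_add, substeps)
    baseline = _stage3_ssr(objective, params)
    reports = []
    for name in EFFECTOR_PARAMETERS:
        lo, hi = bounds.bounds[name]
        for eps in perturbations:
            value = getattr(params, name) * (1.0 + eps)
            perturbed = params.replace(**{name: value})
            if name == "kd":
                # kd sits outside the stage-3 objective's free block
                obj = _coculture_objective(
                    dataset, perturbed, curve, protocol, t_add, substeps
                )
                ssr = _stage3_ssr(obj, perturbed)
            else:
                ssr = _stage3_ssr(objective, perturbed)
            reports.append(SensitivityReport(
                parameter=name,
                perturbation=float(eps),
                delta_ssr=float(ssr - baseline),
                baseline_ssr=float(baseline),
                out_of_bounds=not (lo <= value <= hi),
            ))
    return reports


def sensitivity_to_frame(reports: Sequence[SensitivityReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])


def global_sensitivity(
    params: ModelParameters,
    bounds: ParameterBounds | None = None,
    et_grid: Sequence[float] = DEFAULT_ET_GRID,
    horizon: float = 48.0,
    protocol: AssayProtocol | None = None,
    n_values: int = 8,
) -> pd.DataFrame:
    """Percent-cytolysis surface over parameter sweeps crossed with E:T.

    Each effector parameter is swept geometrically across its bounds
    (others held at the reference values) for every ratio in ``et_grid``;
    the response is percent tumor cytolysis ``horizon`` hours after
    effector addition.  Failed simulations are recorded as NaN rather
    than aborting the surface.
    """
    bounds = bounds or ParameterBounds()
    protocol = protocol or AssayProtocol()
    t_eval = protocol.effector_addition_time + horizon
    if t_eval > protocol.total_duration + 1e-9:
        raise ValueError("horizon extends past the assay duration")
    control = simulate_assay(params, protocol, 0.0)
    rows = []
    for name in EFFECTOR_PARAMETERS:
        lo, hi = bounds.bounds[name]
        values = np.geomspace(lo, hi, n_values)
        for value in values:
            swept = params.replace(**{name: float(value)})
            for rho in et_grid:
                try:
                    sim = simulate_assay(swept, protocol, rho)
                    pc = percent_cytolysis(sim, control, t_eval)
                except Exception as exc:  # recorded, surface continues
                    pc = math.nan
                rows.append({
                    "parameter": name,
                    "value": float(value),
                    "et_ratio": float(rho),
                    "percent_cytolysis": pc,
                })
    return pd.DataFrame(rows)


def correlation_from_jacobian(J: np.ndarray, names: Sequence[str],
                              method: str = "fim") -> CorrelationMatrix:
    """Correlation matrix from a residual Jacobian.

    The Gauss-Newton information matrix is J'J; its (pseudo)inverse is
    the asymptotic covariance, normalized to correlations.  A singular
    information matrix (e.g. perfectly confounded parameters) yields
    |r| = 1 entries for the affected pairs via the pseudoinverse route.
    """
    J = np.asarray(J, dtype=float)
    info = J.T @ J
    try:
        cov = np.linalg.inv(info)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    denom = np.outer(sd, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / denom
    corr = np.where(np.isfinite(corr), corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    # exact confounding leaves a zero-information subspace; report the
    # affected pairs as perfectly correlated
    if np.linalg.matrix_rank(info, tol=np.max(np.abs(info)) * 1e-10) < info.shape[0]:
        null = _null_space_pairs(info)
        for i, j in null:
            corr[i, j] = math.copysign(1.0, corr[i, j]) if corr[i, j] != 0 else 1.0
            corr[j, i] = corr[i, j]
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return CorrelationMatrix(names=tuple(names), matrix=corr, method=method)


def _null_space_pairs(info: np.ndarray) -> list:
    w, v = np.linalg.eigh(info)
    tol = max(abs(w)) * 1e-10 if w.size else 0.0
    pairs = set()
    for k in np.where(np.abs(w) <= tol)[0]:
        involved = np.where(np.abs(v[:, k]) > 1e-8)[0]
        for a in involved:
            for b in involved:
                if a < b:
                    pairs.add((int(a), int(b)))
    return sorted(pairs)


def parameter_correlation(
    dataset: cal.ProductDataset,
    params: ModelParameters,
    curve: cal.CalibrationCurve,
    method: str = "fim",
    protocol: AssayProtocol | None = None,
    t_add: float | None = None,
    substeps: int = 4,
    rel_step: float = 1e-4,
    multistart_samples: int = 40,
    seed: int = 0,
) -> CorrelationMatrix:
    """Identifiability correlations of the effector parameters.

    ``method='fim'`` (default): finite-difference Jacobian of the
    co-culture residuals with respect to log-parameters at the fitted
    values, turned into a correlation matrix through the Gauss-Newton
    covariance approximation.  ``method='multistart'``: empirical
    correlation of parameter estimates across short refits from random
    starts, keeping refits whose SSR lands within a factor of two of the
    best (the near-optimal manifold).
    """
    protocol = protocol or AssayProtocol()
    if t_add is None:
        t_add = cal.resolve_addition_time(dataset, protocol.effector_addition_time)
    names = EFFECTOR_PARAMETERS

    if method == "fim":
        def residuals(values: np.ndarray) -> np.ndarray:
            p = params.replace(**dict(zip(names, values)))
            obj = _coculture_objective(dataset, p, curve, protocol, t_add, substeps)
            free = np.array([getattr(p, k) for k in STAGE3_PARAMS])
            return obj.residuals_log(np.log10(free))

        x0 = np.array([getattr(params, k) for k in names])
        r0 = residuals(x0)
        J = np.empty((r0.size, len(names)))
        for j in range(len(names)):
            x = x0.copy()
            h = x0[j] * rel_step
            x[j] += h
            # d residual / d log(parameter): scale-free comparison
            J[:, j] = (residuals(x) - r0) / (h / x0[j])
        return correlation_from_jacobian(J, names, method="fim")

    if method == "multistart":
        from .estimation import fit_coculture

        estimates = []
        for k in range(multistart_samples):
            fr = fit_coculture(
                dataset,
                fixed=(params.kp1, params.CT, params.kd),
                curve=curve,
                bounds=ParameterBounds(),
                n_starts=1,
                seed=seed + 1000 + k,
                protocol=protocol,
                t_add=t_add,
                substeps=substeps,
            )
            estimates.append(
                [fr.ssr] + [getattr(fr.params, name) for name in names]
            )
        arr = np.array(estimates)
        keep = arr[arr[:, 0] <= 2.0 * arr[:, 0].min(), 1:]
        if keep.shape[0] < 3:
            raise ValueError("too few near-optimal refits for empirical correlations")
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(np.log10(keep), rowvar=False)
        # a parameter pinned across refits has zero variance; report it
        # as uncorrelated rather than undefined
        corr = np.where(np.isfinite(corr), corr, 0.0)
        np.fill_diagonal(corr, 1.0)
        return CorrelationMatrix(names=tuple(names), matrix=corr, method="multistart")

    raise ValueError("method must be 'fim' or 'multistart'")


def et_sweep(
    params: ModelParameters,
    protocol: AssayProtocol | None = None,
    ratio_grid: Sequence[float] = DEFAULT_ET_GRID,
    horizon: float = 48.0,
    saturation_tolerance: float = 5.0,
    negligible_floor: float = 10.0,
) -> dict:
    """Forward-simulated cytolysis across initial E:T ratios.

    Returns the per-ratio table (ratio, percent cytolysis at the horizon,
    final predicted tumor count) plus two summaries: ``saturation_ratio``,
    the smallest ratio within ``saturation_tolerance`` percentage points
    of the top ratio's cytolysis (None when the top ratio achieves no
    cytolysis), and ``negligible_below``, the largest ratio with
    cytolysis under ``negligible_floor`` percent.
    """
    protocol = protocol or AssayProtocol()
    ratios = sorted(float(r) for r in ratio_grid)
    t_eval = protocol.effector_addition_time + horizon
    control = simulate_assay(params, protocol, 0.0)
    rows = []
    for rho in ratios:
        sim = simulate_assay(params, protocol, rho)
        rows.append({
            "et_ratio": rho,
            "percent_cytolysis": percent_cytolysis(sim, control, t_eval),
            "final_T": float(sim.T[-1]),
        })
    table = pd.DataFrame(rows)
    top = table["percent_cytolysis"].iloc[-1]
    saturation = None
    if top > 0:
        within = table[table["percent_cytolysis"] >= top - saturation_tolerance]
        saturation = float(within["et_ratio"].min())
    negligible = table[table["percent_cytolysis"] < negligible_floor]
    return {
        "table": table,
        "saturation_ratio": saturation,
        "negligible_below": (
            float(negligible["et_ratio"].max()) if len(negligible) else None
        ),
    }
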