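"""Three-compartment kinetic model of CAR-T cell cytotoxicity assays.

The model tracks tumor cells (``T``), CAR-T cells (``CART``) and
untransduced T cells (``TC``) in an impedance cytotoxicity assay well:

* tumor cells grow logistically at rate ``kp1`` toward a carrying
  capacity ``CT``;
* CAR-T cells lyse tumor cells through a ratio-dependent Hill term
  ``FC = kc * r^n / (Kmr^n + r^n) * T`` with ``r = CART / T`` — killing
  saturates in the effector:tumor ratio, with half-saturation ``Kmr``
  and cooperativity exponent ``n``;
* CAR-T cells proliferate in response to tumor cytolysis,
  ``FP = kp2 * FC^2 / (Kmp^2 + FC^2) * CART``, restricted by a Gompertz
  crowding factor ``ln(CE / (CART + TC))`` toward an effector carrying
  capacity ``CE``;
* CAR-T and untransduced T cells decay at a shared basal rate ``kd``;
  untransduced T cells are assumed to have no anti-tumor activity.

A mass-action variant (``FC = kc*CART*T``, ``FP = kp2*CART*T``) is kept
as a comparison baseline; it cannot describe assays across multiple
effector:target seeding ratios with a single parameter set.

The assay protocol is two-phase: targets are seeded and grow alone for
~24 h, then the effector pool is added as an instantaneous state jump
and the co-culture is followed to 72 h with 15-minute impedance
sampling (289 readings per well by default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "PARAM_NAMES",
    "ModelParameters",
    "StateVector",
    "AssayProtocol",
    "SimulationResult",
    "SimulationError",
    "REFERENCE_PARAMS",
    "cytolysis_rate",
    "proliferation_rate",
    "derivatives",
    "legacy_derivatives",
    "simulate_assay",
    "percent_cytolysis",
    "logistic_solution",
]

#: canonical parameter order used by array conversions everywhere
PARAM_NAMES = ("kp1", "CT", "kc", "Kmr", "n", "kp2", "Kmp", "CE", "kd")

#: floor on the effector pool inside the Gompertz crowding term; the
#: logarithm is evaluated at max(N, 1 cell) so it never diverges
GOMPERTZ_FLOOR = 1.0


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or produces non-finite states."""


@dataclass(frozen=True)
class ModelParameters:
    """The nine kinetic parameters of the assay model.

    Units: rates (``kp1``, ``kc``, ``kp2``, ``kd``) are 1/hour;
    capacities (``CT``, ``CE``) are cells; ``Kmr`` and ``n`` are
    dimensionless; ``Kmp`` is cells/hour (half-saturation of the
    proliferation response in units of the cytolysis rate ``FC``).
    """

    kp1: float
    CT: float
    kc: float
    Kmr: float
    n: float
    kp2: float
    Kmp: float
    CE: float
    kd: float

    def __post_init__(self) -> None:
        # rates may be zero (no-killing / no-proliferation / no-decay
        # limits are meaningful controls); capacities and half-saturation
        # constants must be strictly positive
        strictly_positive = {"CT", "Kmr", "Kmp", "CE"}
        for name in PARAM_NAMES:
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name} must be finite, got {value}")
            if name in strictly_positive:
                if value <= 0:
                    raise ValueError(f"parameter {name} must be > 0, got {value}")
            elif value < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {value}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ModelParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values)))

    def replace(self, **kwargs: float) -> "ModelParameters":
        data = {k: getattr(self, k) for k in PARAM_NAMES}
        data.update(kwargs)
        return ModelParameters(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_NAMES}


#: reference parameter set used as the center of the synthetic cohort
#: priors and for sensitivity sweeps.  Chosen to reproduce the
#: qualitative assay behavior of clinical products: strong, saturating
#: cytolysis at high effector:target ratios, negligible killing at or
#: below 1:2, and a ratio pivot (Kmr) above the initial CAR-T:tumor
#: ratio of a 1:1 well so the cooperativity exponent n acts in opposite
#: directions at high and low seeding ratios.
REFERENCE_PARAMS = ModelParameters(
    kp1=0.04,   # Raji-like doubling time ~ 20 h
    CT=1.0e6,   # well saturates around 10^6 adherent targets
    kc=0.25,    # saturated killing outpaces growth roughly sixfold
    Kmr=2.0,    # half-maximal killing at a 2:1 CAR-T:tumor ratio
    n=1.0,
    kp2=0.08,
    Kmp=2.0e4,  # proliferation responds only to substantial cytolysis
    CE=2.0e6,
    kd=0.008,   # basal T-cell decay, half-life ~ 3.6 days
)


@dataclass(frozen=True)
class StateVector:
    """Cell counts for one well: tumor, CAR-T, untransduced T cells."""

    T: float
    CART: float
    TC: float

    def __post_init__(self) -> None:
        for name in ("T", "CART", "TC"):
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"state component {name} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.T, self.CART, self.TC], dtype=float)


@dataclass(frozen=True)
class AssayProtocol:
    """Plate-level design of the two-phase cytotoxicity assay."""

    target_seed: float = 4.0e4
    effector_addition_time: float = 24.0
    total_duration: float = 72.0
    sampling_interval: float = 0.25
    et_ratios: tuple = (1.0, 6.25, 25.0)
    replicates: int = 3
    transduction_efficiency: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "et_ratios", tuple(float(r) for r in self.et_ratios))
        if not 0 < self.effector_addition_time < self.total_duration:
            raise ValueError("effector addition must fall strictly inside the assay")
        for label, span in (
            ("pre-addition phase", self.effector_addition_time),
            ("post-addition phase", self.total_duration - self.effector_addition_time),
        ):
            steps = span / self.sampling_interval
            if abs(steps - round(steps)) > 1e-9:
                raise ValueError(f"sampling interval does not divide the {label}")
        if any(r <= 0 for r in self.et_ratios):
            raise ValueError("et_ratios must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.transduction_efficiency <= 1:
            raise ValueError("transduction_efficiency must be in (0, 1]")
        if self.target_seed < 0:
            raise ValueError("target_seed must be >= 0")

    @property
    def times(self) -> np.ndarray:
        """The full sampling grid, 0 .. total_duration inclusive."""
        n_steps = int(round(self.total_duration / self.sampling_interval))
        return np.linspace(0.0, self.total_duration, n_steps + 1)

    @property
    def addition_index(self) -> int:
        return int(round(self.effector_addition_time / self.sampling_interval))

    def effector_count(self, et_ratio: float) -> float:
        return float(et_ratio) * self.target_seed


@dataclass(frozen=True)
class SimulationResult:
    """Sampled trajectories of one simulated well."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 3): columns T, CART, TC
    protocol: AssayProtocol
    params: ModelParameters
    et_ratio: float
    condition: str
    #: which right-hand side produced this trajectory; the mass-action
    #: baseline ignores Kmr, n, Kmp and CE
    model: str = "ratio-dependent"

    @property
    def T(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def CART(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def TC(self) -> np.ndarray:
        return self.states[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "T": self.T,
                "CART": self.CART,
                "TC": self.TC,
                "condition": self.condition,
                "et_ratio": self.et_ratio,
            }
        )

    def to_json(self) -> str:
        payload = {
            "condition": self.condition,
            "model": self.model,
            "et_ratio": self.et_ratio,
            "protocol": asdict(self.protocol),
            "params": self.params.to_dict(),
            "times": self.times.tolist(),
            "T": self.T.tolist(),
            "CART": self.CART.tolist(),
            "TC": self.TC.tolist(),
        }
        return json.dumps(payload)


def _hill_ratio(Kmr: float, n: float, T: float, CART: float) -> float:
    """Saturating killing fraction in [0, 1]; 0 when either pool is empty.

    Evaluated as 1 / (1 + (Kmr/r)^n) which is numerically stable for
    extreme ratios (overflow in (Kmr/r)^n cleanly drives the value to 0).
    """
    if T <= 0.0 or CART <= 0.0:
        return 0.0
    r = CART / T
    try:
        with np.errstate(over="ignore"):
            denom = 1.0 + (Kmr / r) ** n
    except OverflowError:
        return 0.0
    if not math.isfinite(denom):
        return 0.0
    return 1.0 / denom


def cytolysis_rate(params: ModelParameters, state: StateVector) -> float:
    """Tumor-cell kill rate ``FC`` in cells/hour.

    ``FC = kc * r^n / (Kmr^n + r^n) * T`` with ``r = CART/T``; returns 0
    at ``T = 0`` by continuity (no division is performed).
    """
    frac = _hill_ratio(params.Kmr, params.n, state.T, state.CART)
    return params.kc * frac * state.T


def proliferation_rate(params: ModelParameters, fc: float, cart: float) -> float:
    """CAR-T proliferation rate ``FP`` in cells/hour.

    ``FP = kp2 * fc^2 / (Kmp^2 + fc^2) * cart`` — proliferation is driven
    by the cytolysis rate itself, saturating at half-constant ``Kmp``.
    """
    if fc < 0 or cart < 0:
        raise ValueError("fc and cart must be non-negative")
    if fc == 0.0:
        return 0.0
    try:
        with np.errstate(over="ignore"):
            denom = 1.0 + (params.Kmp / fc) ** 2
    except OverflowError:
        return 0.0
    if not math.isfinite(denom):
        return 0.0
    return params.kp2 * cart / denom


def _gompertz(params: ModelParameters, n_effectors: float, inverted: bool) -> float:
    n_eff = max(n_effectors, GOMPERTZ_FLOOR)
    if inverted:
        return math.log(n_eff / params.CE)
    return math.log(params.CE / n_eff)


def derivatives(
    params: ModelParameters,
    state: StateVector,
    *,
    gompertz_inverted: bool = False,
) -> np.ndarray:
    """Right-hand side of the ratio-dependent model, cells/hour.

    Returns ``(dT/dt, dCART/dt, dTC/dt)``.  The CAR-T equation multiplies
    the proliferation response by a Gompertz crowding factor
    ``ln(CE / (CART + TC))`` (zero at capacity, capped at a one-cell
    floor); ``gompertz_inverted`` flips the logarithm's orientation for
    sensitivity checks.
    """
    fc = cytolysis_rate(params, state)
    fp = proliferation_rate(params, fc, state.CART)
    g = _gompertz(params, state.CART + state.TC, gompertz_inverted)
    dT = params.kp1 * state.T * (1.0 - state.T / params.CT) - fc
    dCART = fp * g - params.kd * state.CART
    dTC = -params.kd * state.TC
    return np.array([dT, dCART, dTC])


def legacy_derivatives(params: ModelParameters, state: StateVector) -> np.ndarray:
    """Mass-action baseline: ``FC = kc*CART*T``, ``FP = kp2*CART*T``.

    Kept for comparison only — a single parameter set cannot reproduce
    assays across effector:target ratios.  ``Kmr``, ``n``, ``Kmp`` and
    ``CE`` are ignored; there is no untransduced compartment coupling
    beyond basal decay.
    """
    fc = params.kc * state.CART * state.T
    fp = params.kp2 * state.CART * state.T
    dT = params.kp1 * state.T * (1.0 - state.T / params.CT) - fc
    dCART = fp - params.kd * state.CART
    dTC = -params.kd * state.TC
    return np.array([dT, dCART, dTC])


def logistic_solution(t, T0: float, kp1: float, CT: float) -> np.ndarray:
    """Closed-form logistic tumor growth from seed ``T0``."""
    t = np.asarray(t, dtype=float)
    if T0 == 0:
        return np.zeros_like(t)
    return CT / (1.0 + ((CT - T0) / T0) * np.exp(-kp1 * t))


def _rhs_factory(params: ModelParameters, legacy: bool, gompertz_inverted: bool):
    kp1, CT, kc, Kmr, n, kp2, Kmp, CE, kd = params.as_array()

    if legacy:

        def rhs(t, y):
            T = max(y[0], 0.0)
            C = max(y[1], 0.0)
            TC = max(y[2], 0.0)
            fc = kc * C * T
            fp = kp2 * C * T
            return (
                kp1 * T * (1.0 - T / CT) - fc,
                fp - kd * C,
                -kd * TC,
            )

        return rhs

    sign = -1.0 if gompertz_inverted else 1.0

    def rhs(t, y):
        T = max(y[0], 0.0)
        C = max(y[1], 0.0)
        TC = max(y[2], 0.0)
        fc = kc * _hill_ratio(Kmr, n, T, C) * T
        if fc > 0.0:
            with np.errstate(over="ignore"):
                denom = 1.0 + (Kmp / fc) ** 2
            fp = kp2 * C / denom if math.isfinite(denom) else 0.0
        else:
            fp = 0.0
        g = sign * math.log(CE / max(C + TC, GOMPERTZ_FLOOR))
        return (
            kp1 * T * (1.0 - T / CT) - fc,
            fp * g - kd * C,
            -kd * TC,
        )

    return rhs


def _integrate(rhs, y0, t_eval, rtol, atol, context):
    if len(t_eval) == 1:
        return np.asarray(y0, dtype=float)[None, :]
    sol = solve_ivp(
        rhs,
        (t_eval[0], t_eval[-1]),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"ODE solver failed ({context}): {sol.message}")
    y = sol.y.T
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"non-finite state encountered ({context})")
    return y


def simulate_assay(
    params: ModelParameters,
    protocol: AssayProtocol,
    et_ratio: float,
    *,
    effector_count: float | None = None,
    legacy: bool = False,
    gompertz_inverted: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> SimulationResult:
    """Forward-simulate one well through the two-phase assay protocol.

    Phase 1 integrates targets alone from ``(target_seed, 0, 0)`` up to
    the effector addition time.  There the effector pool
    ``E = et_ratio * target_seed`` (or ``effector_count`` when given, as
    for effector-only control wells) is added instantaneously and split
    by transduction efficiency into CAR-T and untransduced compartments;
    integration restarts at the jump.  The stored value at the addition
    timepoint is the post-addition state, matching how the instrument's
    first post-addition reading includes the effectors.

    ``et_ratio = 0`` with no ``effector_count`` yields a target-only
    control; ``target_seed = 0`` with an ``effector_count`` yields an
    effector-only control.
    """
    if et_ratio < 0:
        raise ValueError("et_ratio must be >= 0")
    times = protocol.times
    idx_add = protocol.addition_index
    rhs = _rhs_factory(params, legacy, gompertz_inverted)
    context = f"et_ratio={et_ratio}, params={params.to_dict()}"

    y0 = np.array([protocol.target_seed, 0.0, 0.0])
    pre = _integrate(rhs, y0, times[: idx_add + 1], rtol, atol, context)

    E = protocol.effector_count(et_ratio) if effector_count is None else float(effector_count)
    te = protocol.transduction_efficiency
    y_add = np.array([max(pre[-1, 0], 0.0), te * E, (1.0 - te) * E])
    post = _integrate(rhs, y_add, times[idx_add:], rtol, atol, context)

    states = np.vstack([pre[:-1], post])
    if protocol.target_seed == 0:
        condition = "effector_control"
    elif E == 0:
        condition = "target_control"
    else:
        condition = "coculture"
    return SimulationResult(
        times=times,
        states=states,
        protocol=protocol,
        params=params,
        et_ratio=float(et_ratio),
        condition=condition,
        model="mass-action" if legacy else "ratio-dependent",
    )


def percent_cytolysis(
    coculture: SimulationResult,
    control: SimulationResult,
    t: float,
) -> float:
    """Percent tumor cytolysis at time ``t`` relative to the target-only
    control simulated with the same protocol: ``100*(1 - T_cc/T_ctrl)``,
    clipped to [0, 100].  The control, not the initial seed, is the
    reference because untreated targets keep growing over the assay.
    """
    if not np.array_equal(coculture.times, control.times):
        raise ValueError("coculture and control must share the sampling grid")
    if control.condition != "target_control":
        raise ValueError("control must be a target-only simulation")
    matches = np.isclose(coculture.times, t, rtol=0, atol=1e-9)
    if not matches.any():
        raise ValueError(f"t={t} is not on the sampling grid")
    i = int(np.argmax(matches))
    T_ctrl = control.T[i]
    if T_ctrl <= 0:
        raise ValueError("control tumor population is zero at the requested time")
    value = 100.0 * (1.0 - coculture.T[i] / T_ctrl)
    return float(np.clip(value, 0.0, 100.0))
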