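"""Core two-compartment model of exercise-induced plasma IL-6 kinetics.

The model couples three linear first-order states:

* ``PVO2max(t)`` — suprabasal oxygen consumption, in percent of VO2max,
  relaxing with rate ``ramp_rate`` (0.8 min⁻¹) toward the piecewise-constant
  exercise target ``u(t)`` (0 at rest, ``T_v`` during the bout);
* ``IL6_m(t)`` — IL-6 concentration in the contracting-muscle compartment,
  produced proportionally to ``PVO2max`` with secretion rate ``SR_ex`` and
  transferred to plasma with rate ``k_m``;
* ``IL6_p(t)`` — plasma IL-6 concentration, fed by the muscle compartment,
  cleared by the hepatosplanchnic viscera with turnover rate ``k_e``, and
  sustained at rest by a constant adipose-tissue production ``Ra_IL6 / V``.

``Ra_IL6`` is not a free parameter: it is pinned by the resting steady state
``Ra_IL6 = k_e · IL6_b · V`` so that a protocol with no exercise leaves plasma
IL-6 at its baseline ``IL6_b`` exactly.

Intensities carry the numeric percent value (67, not 0.67) and the
distribution volume ``V`` is stored in millilitres, so ``Ra_IL6`` comes out in
pg·min⁻¹ directly.

Besides the ODE right-hand side this module provides the exact
piecewise sum-of-exponentials solution of the cascade
(:func:`closed_form_state`), which serves as the oracle for the numerical
integrator in :mod:`il6kin.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

__all__ = [
    "RAMP_RATE_DEFAULT",
    "BASAL_VO2_PERCENT",
    "DISTRIBUTION_VOLUME_ML",
    "T_V_MAX",
    "DegenerateRatesError",
    "ExerciseProtocol",
    "ModelParameters",
    "ModelState",
    "input_u",
    "rhs",
    "steady_state_ra",
    "half_life",
    "closed_form_state",
]

#: First-order rate of the oxygen-uptake ramp, min⁻¹.  With 0.8 min⁻¹ the
#: suprabasal oxygen consumption reaches 99% of its target in ln(100)/0.8
#: ≈ 5.76 min, i.e. within 5–6 minutes of exercise onset.
RAMP_RATE_DEFAULT = 0.8

#: Basal oxygen consumption as percent of VO2max.  Documentation constant
#: only: PVO2max is defined suprabasal, so this value never enters the
#: equations; it explains why the target intensity is capped at 92%.
BASAL_VO2_PERCENT = 8.0

#: IL-6 distribution volume, ml (14 litres).
DISTRIBUTION_VOLUME_ML = 14_000.0

#: Maximum admissible target suprabasal intensity, % of VO2max.
T_V_MAX = 92.0

#: Relative separation below which two kinetic rates are considered
#: coincident and the sum-of-exponentials form loses precision.
_DEGENERACY_RTOL = 1e-10


class DegenerateRatesError(ValueError):
    """Raised when two of (ramp_rate, k_m, k_e) (nearly) coincide.

    The closed-form solution is a sum of distinct exponentials; coincident
    rates would require secular (t·e^{-rt}) terms.  Use the numerical
    integrator in :mod:`il6kin.simulate` for such parameter sets.
    """


@dataclass(frozen=True)
class ExerciseProtocol:
    """An exercise bout: when it happens, how hard, and the IL-6 baseline.

    Parameters
    ----------
    label : str
        Free-text identifier (e.g. the source study).
    t_ex_start, t_ex_end : float
        Exercise window, minutes; ``0 <= t_ex_start < t_ex_end``.
    T_v : float
        Target suprabasal exercise intensity, percent of VO2max (0–92).
    IL6_b : float
        Fasting pre-exercise plasma IL-6, pg·ml⁻¹; strictly positive.
    basal_fraction : float
        Basal oxygen consumption, % of VO2max (informational; default 8).
    """

    label: str
    t_ex_start: float
    t_ex_end: float
    T_v: float
    IL6_b: float
    basal_fraction: float = BASAL_VO2_PERCENT

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t_ex_start) and math.isfinite(self.t_ex_end)):
            raise ValueError("exercise window must be finite")
        if self.t_ex_start < 0 or self.t_ex_start >= self.t_ex_end:
            raise ValueError(
                f"require 0 <= t_ex_start < t_ex_end, got "
                f"[{self.t_ex_start}, {self.t_ex_end}]"
            )
        if not 0.0 <= self.T_v <= T_V_MAX:
            raise ValueError(
                f"T_v must lie in [0, {T_V_MAX}] %VO2max, got {self.T_v}"
            )
        if not self.IL6_b > 0:
            raise ValueError(f"IL6_b must be positive, got {self.IL6_b}")

    @property
    def duration(self) -> float:
        """Exercise duration, minutes."""
        return self.t_ex_end - self.t_ex_start


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic parameters of the IL-6 cascade.

    ``SR_ex`` is the muscular secretion rate in pg·ml⁻¹·min⁻¹ per percent of
    suprabasal VO2max; ``k_m`` (muscle→plasma transfer) and ``k_e`` (plasma
    turnover) are first-order rates in min⁻¹.  ``V`` is the IL-6 distribution
    volume in millilitres — stored in ml by construction so that
    ``k_e·IL6_b·V`` is a pg·min⁻¹ production rate.
    """

    SR_ex: float
    k_m: float
    k_e: float
    V: float = DISTRIBUTION_VOLUME_ML
    ramp_rate: float = RAMP_RATE_DEFAULT

    def __post_init__(self) -> None:
        if self.SR_ex < 0:
            raise ValueError(f"SR_ex must be >= 0, got {self.SR_ex}")
        for name in ("k_m", "k_e", "V", "ramp_rate"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")

    @property
    def free_values(self) -> np.ndarray:
        """The three estimable parameters as ``[SR_ex, k_m, k_e]``."""
        return np.array([self.SR_ex, self.k_m, self.k_e])


FREE_PARAMETER_NAMES = ("SR_ex", "k_m", "k_e")


@dataclass(frozen=True)
class ModelState:
    """State of the cascade: ``(PVO2max, IL6_m, IL6_p)``.

    Components may be scalars or aligned arrays (a state trajectory).
    """

    PVO2max: Union[float, np.ndarray]
    IL6_m: Union[float, np.ndarray]
    IL6_p: Union[float, np.ndarray]

    def as_array(self) -> np.ndarray:
        return np.asarray([self.PVO2max, self.IL6_m, self.IL6_p], dtype=float)


def input_u(t: Union[float, np.ndarray], protocol: ExerciseProtocol):
    """Exercise input: ``T_v`` during the bout, 0 elsewhere.

    Piecewise constant with closed endpoints at ``t_ex_start``/``t_ex_end``;
    no interpolation.  Accepts scalar or array time.
    """
    t = np.asarray(t, dtype=float)
    u = np.where(
        (t >= protocol.t_ex_start) & (t <= protocol.t_ex_end), protocol.T_v, 0.0
    )
    return float(u) if u.ndim == 0 else u


def rhs(
    t: float,
    state: Union[ModelState, Sequence[float], np.ndarray],
    params: ModelParameters,
    protocol: ExerciseProtocol,
    Ra_IL6: float,
) -> np.ndarray:
    """Time derivatives of ``(PVO2max, IL6_m, IL6_p)`` at time ``t``.

    dPVO2max/dt = -ramp·PVO2max + ramp·u(t)
    dIL6_m/dt   = SR_ex·PVO2max - k_m·IL6_m
    dIL6_p/dt   = k_m·IL6_m - k_e·IL6_p + Ra_IL6/V

    ``Ra_IL6`` is in pg·min⁻¹ and ``V`` in ml, so ``Ra_IL6/V`` is a
    pg·ml⁻¹·min⁻¹ concentration rate.
    """
    if isinstance(state, ModelState):
        p, m, c = state.PVO2max, state.IL6_m, state.IL6_p
    else:
        p, m, c = state
    u = input_u(t, protocol)
    return np.array(
        [
            params.ramp_rate * (u - p),
            params.SR_ex * p - params.k_m * m,
            params.k_m * m - params.k_e * c + Ra_IL6 / params.V,
        ]
    )


def steady_state_ra(k_e: float, IL6_b: float, V: float) -> float:
    """Adipose-tissue IL-6 production rate pinned by the resting steady state.

    Setting ``dIL6_p/dt = 0`` with no muscle contribution gives
    ``Ra_IL6 = k_e · IL6_b · V`` (pg·min⁻¹ with V in ml).
    """
    if k_e < 0 or IL6_b < 0 or V < 0:
        raise ValueError("k_e, IL6_b and V must be non-negative")
    return k_e * IL6_b * V


def half_life(k_e: float) -> float:
    """Plasma IL-6 half-life ln(2)/k_e in minutes."""
    if not k_e > 0:
        raise ValueError(f"half-life requires k_e > 0, got {k_e}")
    return math.log(2.0) / k_e


def _check_distinct_rates(params: ModelParameters) -> None:
    rates = {
        "ramp_rate": params.ramp_rate,
        "k_m": params.k_m,
        "k_e": params.k_e,
    }
    tol = _DEGENERACY_RTOL * max(rates.values())
    names = list(rates)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if abs(rates[a] - rates[b]) < tol:
                raise DegenerateRatesError(
                    f"rates {a}={rates[a]} and {b}={rates[b]} coincide within "
                    f"{_DEGENERACY_RTOL:g} relative tolerance; the "
                    "sum-of-exponentials solution is ill-conditioned here — "
                    "use il6kin.simulate.simulate instead"
                )


def _segment_state(
    dt: np.ndarray,
    x0: np.ndarray,
    u: float,
    params: ModelParameters,
    q: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact solution on a segment with constant input ``u``.

    ``dt`` is time since segment start, ``x0`` the state at segment start and
    ``q = Ra_IL6 / V`` the constant plasma source term.  Valid only for
    pairwise-distinct rates (checked by the caller).
    """
    a, km, ke, sr = params.ramp_rate, params.k_m, params.k_e, params.SR_ex
    p0, m0, c0 = x0

    ea = np.exp(-a * dt)
    em = np.exp(-km * dt)
    ee = np.exp(-ke * dt)

    # PVO2max: relaxation toward u
    p = u + (p0 - u) * ea

    # Muscle IL-6: steady part + forced (ramp) exponential + homogeneous
    m_ss = sr * u / km
    b_ramp = sr * (p0 - u) / (km - a)
    m_hom = m0 - m_ss - b_ramp
    m = m_ss + b_ramp * ea + m_hom * em

    # Plasma IL-6: forced by the muscle terms and the constant source q
    c_ss = (km * m_ss + q) / ke
    c_ramp = km * b_ramp / (ke - a)
    c_mus = km * m_hom / (ke - km)
    c_hom = c0 - c_ss - c_ramp - c_mus
    c = c_ss + c_ramp * ea + c_mus * em + c_hom * ee

    return p, m, c


def closed_form_state(
    t: Union[float, np.ndarray],
    protocol: ExerciseProtocol,
    params: ModelParameters,
    Ra_IL6: float | None = None,
) -> ModelState:
    """Exact state at time(s) ``t`` under the piecewise-constant input.

    The linear cascade is solved segment by segment (rest → exercise → rest),
    propagating the state across the input breakpoints ``t_ex_start`` and
    ``t_ex_end``.  For ``t <= 0`` the initial condition ``(0, 0, IL6_b)``
    is returned.

    Raises
    ------
    DegenerateRatesError
        If two of (ramp_rate, k_m, k_e) coincide within 1e-10 relative; the
        numerical integrator has no such restriction.
    """
    _check_distinct_rates(params)
    if Ra_IL6 is None:
        Ra_IL6 = steady_state_ra(params.k_e, protocol.IL6_b, params.V)
    q = Ra_IL6 / params.V

    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("times must be finite")

    # Segment boundaries and the constant input on each open segment.
    bounds = [0.0]
    inputs: list[float] = []
    if protocol.t_ex_start > 0.0:
        bounds.append(protocol.t_ex_start)
        inputs.append(0.0)
    bounds.append(protocol.t_ex_end)
    inputs.append(protocol.T_v)
    inputs.append(0.0)  # post-exercise, unbounded

    p_out = np.empty_like(t_arr)
    m_out = np.empty_like(t_arr)
    c_out = np.empty_like(t_arr)

    before = t_arr <= 0.0
    p_out[before], m_out[before], c_out[before] = 0.0, 0.0, protocol.IL6_b

    x0 = np.array([0.0, 0.0, protocol.IL6_b])
    for i, u in enumerate(inputs):
        lo = bounds[i]
        hi = bounds[i + 1] if i + 1 < len(bounds) else np.inf
        sel = (t_arr > lo) & (t_arr <= hi) & ~before
        if np.any(sel):
            p_out[sel], m_out[sel], c_out[sel] = _segment_state(
                t_arr[sel] - lo, x0, u, params, q
            )
        if np.isfinite(hi):
            x0 = np.array(
                [z.item() for z in _segment_state(np.asarray(hi - lo), x0, u, params, q)]
            )

    if np.ndim(t) == 0:
        return ModelState(float(p_out[0]), float(m_out[0]), float(c_out[0]))
    return ModelState(p_out, m_out, c_out)
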