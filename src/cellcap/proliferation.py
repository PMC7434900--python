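"""Proliferation capacity: divisions completed within a fixed culture horizon.

Starting from a single newborn of size ``V0``, the number of completed
divisions within a horizon ``T_f`` is

    D = max{ m ≥ 0 : Σ_{n=0}^{m−1} T(V_n) ≤ T_f },

and the proliferation capacity — the model's prediction for the relative
fold-change in cell count of a (deterministic) population founded by that
cell — interpolates between powers of two using the fraction of the
in-progress cycle elapsed at the horizon:

    capacity = 2^(D + r),   r = (T_f − Σ_{n=0}^{D−1} T(V_n)) / T(V_D).

The capacity is continuous and non-decreasing in ``T_f`` and lies in
[2^D, 2^(D+1)).  When even the first cycle outlasts the horizon (D = 0) the
same interpolator yields a capacity in [1, 2).

The module also carries closed-form cycle sums for the exponential and
linear laws, the sizer cycle-count formula, and an adder change-of-variables
quadrature — independent routes used to cross-check the lineage-based
computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad

from .errors import DomainError, UsageError
from .growth_laws import GrowthLaw, growth_rate, inverse_rate_integral
from .size_dynamics import (
    DEFAULT_GENERATION_CAP,
    DivisionRule,
    cycle_duration,
    lineage,
)

__all__ = [
    "ExperimentConfig",
    "ProliferationResult",
    "proliferation_capacity",
    "real_valued_cycle_count",
    "sizer_cycle_count",
    "exponential_cycle_sum",
    "linear_cycle_sum",
    "adder_cycle_sum_quadrature",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Culture horizon ``t_f`` (hours) and founder newborn size ``v0``."""

    t_f: float
    v0: float

    def __post_init__(self) -> None:
        if not self.t_f > 0:
            raise DomainError(f"t_f must be > 0, got {self.t_f}")
        if not self.v0 > 0:
            raise DomainError(f"v0 must be > 0, got {self.v0}")


@dataclass(frozen=True)
class ProliferationResult:
    """Completed divisions, in-progress fraction and interpolated capacity.

    ``cumulative_times[m-1]`` is the total duration of the first ``m``
    cycles; the array extends one entry past ``completed_divisions`` to
    cover the cycle in progress at the horizon.
    """

    completed_divisions: int
    residual_fraction: float
    capacity: float
    cumulative_times: np.ndarray

    def __post_init__(self) -> None:
        assert 0.0 <= self.residual_fraction < 1.0


def proliferation_capacity(
    rule: DivisionRule,
    law: GrowthLaw,
    cfg: ExperimentConfig,
    max_generations: int = DEFAULT_GENERATION_CAP,
) -> ProliferationResult:
    """Count completed divisions within ``cfg.t_f`` and interpolate the capacity."""
    records = lineage(rule, law, cfg.v0, cfg.t_f, max_generations=max_generations)
    durations = np.array([r.cycle_duration for r in records])
    cumulative = np.cumsum(durations)
    # the last record is the cycle in progress: cumulative[-1] > t_f >= cumulative[-2]
    completed = len(records) - 1
    elapsed = cumulative[completed - 1] if completed > 0 else 0.0
    in_progress = durations[-1]
    residual = (cfg.t_f - elapsed) / in_progress
    capacity = 2.0 ** (completed + residual)
    return ProliferationResult(
        completed_divisions=completed,
        residual_fraction=float(residual),
        capacity=float(capacity),
        cumulative_times=cumulative,
    )


def real_valued_cycle_count(
    rule: DivisionRule, law: GrowthLaw, cfg: ExperimentConfig
) -> float:
    """Real-valued solution ``m`` of ``CycleSum(m) = t_f`` (linear between integers).

    This is the smooth cycle count whose floor equals the integer number of
    completed divisions.  Only meaningful without a cycle-time floor, so a
    rule with ``tmin != 0`` is rejected.
    """
    if rule.tmin != 0.0:
        raise UsageError(
            f"real_valued_cycle_count requires tmin = 0 (got tmin={rule.tmin})"
        )
    result = proliferation_capacity(rule, law, cfg)
    return result.completed_divisions + result.residual_fraction


def sizer_cycle_count(
    law: GrowthLaw, vbar: float, v0: float, t_f: float, t_min: float = 0.0
) -> float:
    """Cycle count for a pure sizer (a = 0): ``(t_f − T(V0)) / T(V̄) + 1``.

    A sizer divides at the fixed threshold 2V̄, so every generation after the
    first starts at V̄ with the constant duration T(V̄); only the first cycle
    depends on the founder size.  Both durations are floored at ``t_min``,
    and a founder at or above the threshold has a first-cycle duration of
    ``t_min`` exactly.
    """
    if not vbar > 0:
        raise DomainError(f"vbar must be > 0, got {vbar}")
    if not v0 > 0:
        raise DomainError(f"v0 must be > 0, got {v0}")
    t0 = max(t_min, inverse_rate_integral(law, v0, 2.0 * vbar))
    tbar = max(t_min, inverse_rate_integral(law, vbar, 2.0 * vbar))
    return (t_f - t0) / tbar + 1.0


def exponential_cycle_sum(a: float, vbar: float, v0: float, alpha: float, m: int) -> float:
    """Total duration of the first ``m`` cycles under exponential growth, no floor.

    Closed form ``(1/α)·log(a^m + (2^m − a^m)·V̄/V0)``; each cycle's duration
    telescopes to a log size ratio, so the sum collapses to a single
    logarithm.  Decreasing in ``v0`` for every ``a``.
    """
    if not v0 > 0:
        raise DomainError(f"v0 must be > 0, got {v0}")
    if m < 0:
        raise DomainError(f"cycle count m must be >= 0, got {m}")
    return math.log(a**m + (2.0**m - a**m) * vbar / v0) / alpha


def linear_cycle_sum(a: float, vbar: float, v0: float, alpha: float, m: int) -> float:
    """Total duration of the first ``m`` cycles under linear growth, no floor.

    Closed form ``m·V̄/α + ((a−1)(V0−V̄)/α)·(1−(a/2)^m)/(1−a/2)``; each cycle
    lasts (division size − newborn size)/α.  For ``a = 2`` the geometric
    factor degenerates and the sum is evaluated directly (every cycle adds
    ``V0``).
    """
    if not v0 > 0:
        raise DomainError(f"v0 must be > 0, got {v0}")
    if m < 0:
        raise DomainError(f"cycle count m must be >= 0, got {m}")
    if a == 2.0:
        return m * v0 / alpha
    geometric = (1.0 - (a / 2.0) ** m) / (1.0 - a / 2.0)
    return m * vbar / alpha + (a - 1.0) * (v0 - vbar) / alpha * geometric


def adder_cycle_sum_quadrature(
    law: GrowthLaw, vbar: float, v0: float, m: int
) -> float:
    """Total duration of the first ``m`` adder cycles via change of variables.

    For an adder the n-th cycle grows from ``V_n`` to ``V_n + V̄`` with
    ``V_n = V̄ + (V0 − V̄)/2^n``; substituting the size added since birth as
    the integration variable gives ``∫_0^{V̄} dz / f(z + V_n)`` per cycle,
    summed here by adaptive quadrature.  Independent of the closed-form
    integral route, hence usable as a cross-check.
    """
    if not v0 > 0:
        raise DomainError(f"v0 must be > 0, got {v0}")
    if m < 0:
        raise DomainError(f"cycle count m must be >= 0, got {m}")
    total = 0.0
    for n in range(m):
        vn = vbar + (v0 - vbar) / 2.0**n

        def integrand(z: float, vn: float = vn) -> float:
            return 1.0 / growth_rate(law, z + vn)

        value, _ = quad(integrand, 0.0, vbar, epsrel=1e-11, epsabs=1e-13, limit=200)
        total += value
    return total
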