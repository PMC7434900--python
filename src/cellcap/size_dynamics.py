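"""The discrete division-timing map and per-cycle durations.

Newborn sizes across generations follow the one-parameter map

    V_{n+1} = (a·V_n + (2 − a)·V̄) / 2,   a ∈ [0, 2],

where ``a·V_n + (2 − a)·V̄`` is the mother size just before mitosis and the
factor 2 encodes symmetric division.  ``a = 0`` is a sizer (division at the
fixed threshold 2V̄), ``a = 1`` an adder (a fixed increment V̄ is added each
cycle), ``a = 2`` a timer (size-independent cycle length under exponential
growth; neutrally stable).  For 0 ≤ a < 2 newborn sizes converge
geometrically to the fixed point V̄ at rate a/2 per generation.

The duration of a cycle started at size ``V_n`` is the time to grow to the
division size, floored at a minimum cycle time ``T_min``:

    T(V_n) = max(T_min, ∫_{V_n}^{a·V_n + (2−a)·V̄} dv / f(v)).

When the division size falls below the newborn size (possible for a < 1 and
very large newborns) the signed integral is ≤ 0 and the cell divides after
exactly ``T_min``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DivergenceError, DomainError
from .growth_laws import GrowthLaw, inverse_rate_integral

__all__ = [
    "DivisionRule",
    "GenerationRecord",
    "next_newborn",
    "newborn_trajectory",
    "cycle_duration",
    "lineage",
    "lineage_frame",
]

#: generations after which a lineage that has not reached the horizon aborts
DEFAULT_GENERATION_CAP = 10_000


@dataclass(frozen=True)
class DivisionRule:
    """Division-timing rule: parameter ``a``, fixed point ``vbar``, floor ``tmin``.

    ``a`` interpolates between the canonical strategies (0 sizer, 1 adder,
    2 timer); ``vbar`` is the homeostatic newborn size the map converges to
    for a < 2; ``tmin`` is the minimum permissible cycle duration in hours.
    """

    a: float
    vbar: float
    tmin: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 2.0:
            raise ConfigurationError(f"division parameter a must lie in [0, 2], got {self.a}")
        if not self.vbar > 0:
            raise ConfigurationError(f"vbar must be > 0, got {self.vbar}")
        if self.tmin < 0:
            raise ConfigurationError(f"tmin must be >= 0, got {self.tmin}")

    @property
    def label(self) -> str:
        """Canonical name of the strategy this ``a`` encodes."""
        if self.a == 0.0:
            return "sizer"
        if self.a == 1.0:
            return "adder"
        if self.a == 2.0:
            return "timer"
        return "sizer-adder mixture" if self.a < 1.0 else "adder-timer mixture"

    def division_size(self, vn: float) -> float:
        """Mother size just prior to mitosis for a newborn of size ``vn``."""
        if not vn > 0:
            raise DomainError(f"newborn size must be > 0, got {vn}")
        return self.a * vn + (2.0 - self.a) * self.vbar

    @classmethod
    def from_mapping(cls, mapping: dict) -> "DivisionRule":
        allowed = {"a", "vbar", "tmin"}
        unknown = set(mapping) - allowed
        if unknown:
            raise ConfigurationError(
                f"division_rule: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
            )
        for key in ("a", "vbar"):
            if key not in mapping:
                raise ConfigurationError(f"division_rule: missing required key {key!r}")
        return cls(a=mapping["a"], vbar=mapping["vbar"], tmin=mapping.get("tmin", 0.0))

    def to_mapping(self) -> dict:
        return {"a": self.a, "vbar": self.vbar, "tmin": self.tmin}


@dataclass(frozen=True)
class GenerationRecord:
    """One completed-or-in-progress cell cycle in a lineage."""

    n: int
    newborn_size: float
    division_size: float
    cycle_duration: float


def next_newborn(rule: DivisionRule, vn: float) -> float:
    """One application of the division map: newborn size of generation n+1."""
    return rule.division_size(vn) / 2.0


def newborn_trajectory(rule: DivisionRule, v0: float, n_max: int) -> np.ndarray:
    """Closed-form newborn sizes ``V_n = V̄ + (a/2)^n (V0 − V̄)`` for n = 0…n_max."""
    if not v0 > 0:
        raise DomainError(f"initial size must be > 0, got {v0}")
    if n_max < 0:
        raise DomainError(f"n_max must be >= 0, got {n_max}")
    n = np.arange(n_max + 1)
    return rule.vbar + (rule.a / 2.0) ** n * (v0 - rule.vbar)


def cycle_duration(rule: DivisionRule, law: GrowthLaw, vn: float) -> float:
    """Cycle duration ``max(tmin, ∫_{vn}^{division size} dv/f(v))``.

    The floor binds when the growth integral is short (very large newborns
    under a fast law) and, in particular, whenever the division size does not
    exceed ``vn`` — the signed integral is then ≤ 0 and the cell divides
    immediately after the minimum cycle time.
    """
    return max(rule.tmin, inverse_rate_integral(law, vn, rule.division_size(vn)))


def lineage(
    rule: DivisionRule,
    law: GrowthLaw,
    v0: float,
    t_f: float,
    max_generations: int = DEFAULT_GENERATION_CAP,
) -> List[GenerationRecord]:
    """Generation records from ``v0`` until cumulative cycle time first exceeds ``t_f``.

    The final record is the cycle in progress at the horizon.  If the
    cumulative time fails to reach ``t_f`` within ``max_generations``
    (possible only when ``tmin = 0`` and durations collapse toward zero) a
    :class:`DivergenceError` is raised.
    """
    if not v0 > 0:
        raise DomainError(f"initial size must be > 0, got {v0}")
    if not t_f > 0:
        raise DomainError(f"horizon t_f must be > 0, got {t_f}")
    records: List[GenerationRecord] = []
    vn = float(v0)
    cumulative = 0.0
    for n in range(max_generations):
        d = rule.division_size(vn)
        t = cycle_duration(rule, law, vn)
        records.append(GenerationRecord(n=n, newborn_size=vn, division_size=d, cycle_duration=t))
        cumulative += t
        if cumulative > t_f:
            return records
        vn = d / 2.0
    raise DivergenceError(
        f"lineage did not reach t_f={t_f} within {max_generations} generations "
        f"(cumulative time {cumulative}); durations may be collapsing toward zero"
    )


def lineage_frame(records: List[GenerationRecord]) -> pd.DataFrame:
    """Tidy table of a lineage with a running cumulative_time column."""
    frame = pd.DataFrame(
        {
            "generation": [r.n for r in records],
            "newborn_size": [r.newborn_size for r in records],
            "division_size": [r.division_size for r in records],
            "cycle_duration": [r.cycle_duration for r in records],
        }
    )
    frame["cumulative_time"] = frame["cycle_duration"].cumsum()
    return frame
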