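"""Size-dependent growth laws and their inverse-rate time integrals.

A growth law is a positive rate function ``f(v)`` giving the instantaneous
change in cell size per unit time as a function of the current size ``v``
(``dv/dt = f(v)``).  The time a cell needs to grow from ``v_lo`` to ``v_hi``
is the inverse-rate integral ``∫ dv / f(v)``, which every built-in law
evaluates in closed form; an adaptive-quadrature route is kept alongside as a
generic oracle and as the only route for user-supplied rate functions.

Built-in laws
-------------
``exponential``
    ``f(v) = α·v`` — growth rate proportional to size.
``linear``
    ``f(v) = α`` — constant rate (linear size increase in time).
``saturating``
    ``f(v) = α·v / (1 + v/V_th)`` — exponential for small cells, approaching
    the constant ``α·V_th`` for large cells.
``power_saturating``
    ``f(v) = α·v / (1 + (v/V_th)^k)`` — a Hill-type law; for ``k > 1`` the
    rate rises with size for small cells and falls for large cells
    (non-monotone), peaking at ``v = V_th·(k−1)^(−1/k)``.  ``k = 1``
    reduces exactly to ``saturating``.
``reciprocal``
    ``f(v) = α·V_th² / v`` — a strictly decreasing positive rate, the
    simplest representative of "growth slows with size" regulation.
``custom``
    Any user-supplied positive callable; integrals go through quadrature.

Sizes and times carry the units of the configuring parameters (here, μm and
hours by convention); the code never converts units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

from scipy.integrate import quad

from .errors import ConfigurationError, DomainError, NumericalError

__all__ = [
    "GrowthLaw",
    "growth_rate",
    "inverse_rate_integral",
    "inverse_rate_integral_quadrature",
    "BUILTIN_KINDS",
]

BUILTIN_KINDS = ("exponential", "linear", "saturating", "power_saturating", "reciprocal")

#: quadrature tolerances used whenever the integral is evaluated numerically
_QUAD_EPSREL = 1e-10
_QUAD_EPSABS = 1e-12


@dataclass(frozen=True)
class GrowthLaw:
    """A named size-dependent growth-rate function ``f(v)``.

    Parameters
    ----------
    kind
        One of ``exponential``, ``linear``, ``saturating``,
        ``power_saturating``, ``reciprocal`` or ``custom``.
    alpha
        Rate coefficient, > 0.  Units: 1/hour for the exponential family,
        size-units/hour for ``linear``.
    v_th
        Size scale (same units as ``v``); required for ``saturating``,
        ``power_saturating`` and ``reciprocal``.
    k
        Dimensionless Hill exponent for ``power_saturating``; the rate is
        non-monotone in size only for ``k > 1`` (``k = 1`` is the
        saturating law).
    custom_rate
        Positive callable ``f(v)``, only for ``kind='custom'``.
    """

    kind: str
    alpha: float = 1.0
    v_th: Optional[float] = None
    k: Optional[float] = None
    custom_rate: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.kind not in BUILTIN_KINDS + ("custom",):
            raise ConfigurationError(
                f"unknown growth-law kind {self.kind!r}; "
                f"expected one of {BUILTIN_KINDS + ('custom',)}"
            )
        if self.kind == "custom":
            if self.custom_rate is None:
                raise ConfigurationError("kind='custom' requires custom_rate")
            return
        if not self.alpha > 0:
            raise ConfigurationError(f"alpha must be > 0, got {self.alpha}")
        if self.kind in ("saturating", "power_saturating", "reciprocal"):
            if self.v_th is None or not self.v_th > 0:
                raise ConfigurationError(
                    f"kind={self.kind!r} requires v_th > 0, got {self.v_th}"
                )
        if self.kind == "power_saturating":
            if self.k is None or not self.k > 0:
                raise ConfigurationError(
                    f"kind='power_saturating' requires exponent k > 0, got {self.k}"
                )

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def exponential(cls, alpha: float) -> "GrowthLaw":
        return cls("exponential", alpha=alpha)

    @classmethod
    def linear(cls, alpha: float) -> "GrowthLaw":
        return cls("linear", alpha=alpha)

    @classmethod
    def saturating(cls, alpha: float, v_th: float) -> "GrowthLaw":
        return cls("saturating", alpha=alpha, v_th=v_th)

    @classmethod
    def power_saturating(cls, alpha: float, v_th: float, k: float) -> "GrowthLaw":
        return cls("power_saturating", alpha=alpha, v_th=v_th, k=k)

    @classmethod
    def reciprocal(cls, alpha: float, v_th: float) -> "GrowthLaw":
        return cls("reciprocal", alpha=alpha, v_th=v_th)

    @classmethod
    def custom(cls, rate: Callable[[float], float]) -> "GrowthLaw":
        return cls("custom", custom_rate=rate)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "GrowthLaw":
        """Build a law from a config mapping ``{kind, alpha, v_th, k}``.

        Unknown keys are rejected so that typos in config files fail loudly.
        """
        allowed = {"kind", "alpha", "v_th", "k"}
        unknown = set(mapping) - allowed
        if unknown:
            raise ConfigurationError(
                f"growth_law: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
            )
        if "kind" not in mapping:
            raise ConfigurationError("growth_law: missing required key 'kind'")
        return cls(
            kind=mapping["kind"],
            alpha=mapping.get("alpha", 1.0),
            v_th=mapping.get("v_th"),
            k=mapping.get("k"),
        )

    def to_mapping(self) -> dict:
        out = {"kind": self.kind, "alpha": self.alpha}
        if self.v_th is not None:
            out["v_th"] = self.v_th
        if self.k is not None:
            out["k"] = self.k
        return out

    # -- evaluation ---------------------------------------------------------------

    def rate(self, v: float) -> float:
        return growth_rate(self, v)

    def time_between(self, v_lo: float, v_hi: float) -> float:
        return inverse_rate_integral(self, v_lo, v_hi)


def growth_rate(law: GrowthLaw, v: float) -> float:
    """Evaluate the growth rate ``f(v)`` (size units per hour).

    Raises :class:`DomainError` for non-positive ``v``.
    """
    if not v > 0:
        raise DomainError(f"size must be > 0, got {v}")
    a = law.alpha
    if law.kind == "exponential":
        return a * v
    if law.kind == "linear":
        return a
    if law.kind == "saturating":
        return a * v / (1.0 + v / law.v_th)
    if law.kind == "power_saturating":
        return a * v / (1.0 + (v / law.v_th) ** law.k)
    if law.kind == "reciprocal":
        return a * law.v_th**2 / v
    # custom
    r = float(law.custom_rate(v))
    if not r > 0:
        raise DomainError(f"custom rate must be > 0, got f({v}) = {r}")
    return r


def inverse_rate_integral(law: GrowthLaw, v_lo: float, v_hi: float) -> float:
    """Time to grow from ``v_lo`` to ``v_hi``: ``∫_{v_lo}^{v_hi} dv / f(v)``.

    Uses the closed form for every built-in kind and adaptive quadrature for
    ``custom``.  The integral is signed: ``v_hi < v_lo`` yields a negative
    duration, which downstream code uses to detect cells born above their
    division size.
    """
    if not v_lo > 0:
        raise DomainError(f"v_lo must be > 0, got {v_lo}")
    if not v_hi > 0:
        raise DomainError(f"v_hi must be > 0, got {v_hi}")
    a = law.alpha
    if law.kind == "exponential":
        return math.log(v_hi / v_lo) / a
    if law.kind == "linear":
        return (v_hi - v_lo) / a
    if law.kind == "saturating":
        return (math.log(v_hi / v_lo) + (v_hi - v_lo) / law.v_th) / a
    if law.kind == "power_saturating":
        k = law.k
        return (math.log(v_hi / v_lo) + (v_hi**k - v_lo**k) / (k * law.v_th**k)) / a
    if law.kind == "reciprocal":
        return (v_hi**2 - v_lo**2) / (2.0 * a * law.v_th**2)
    return inverse_rate_integral_quadrature(law, v_lo, v_hi)


def inverse_rate_integral_quadrature(law: GrowthLaw, v_lo: float, v_hi: float) -> float:
    """Adaptive-quadrature evaluation of ``∫ dv/f(v)``.

    Generic route used for custom laws and as an independent cross-check of
    the closed forms.  Signed like :func:`inverse_rate_integral`.
    """
    if not v_lo > 0:
        raise DomainError(f"v_lo must be > 0, got {v_lo}")
    if not v_hi > 0:
        raise DomainError(f"v_hi must be > 0, got {v_hi}")
    if v_hi == v_lo:
        return 0.0

    def integrand(v: float) -> float:
        return 1.0 / growth_rate(law, v)

    value, abserr = quad(
        integrand, v_lo, v_hi, epsrel=_QUAD_EPSREL, epsabs=_QUAD_EPSABS, limit=200
    )
    if abserr > max(_QUAD_EPSABS, 1e-7 * abs(value)):
        raise NumericalError(
            f"quadrature of 1/f over [{v_lo}, {v_hi}] did not converge: "
            f"value={value}, abserr={abserr}"
        )
    return value
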