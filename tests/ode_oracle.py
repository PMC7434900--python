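"""Brute-force oracle: fixed-step RK4 integration of dv/dt = f(v).

Independent of the package's closed forms and of scipy quadrature; the only
shared ingredient is the algebraic definition of each rate function, written
out again here.  Compiled with numba so the 1e-3 h step stays cheap.
"""

import numba

EXPONENTIAL, LINEAR, SATURATING, POWER_SATURATING, RECIPROCAL = 0, 1, 2, 3, 4

KIND_CODES = {
    "exponential": EXPONENTIAL,
    "linear": LINEAR,
    "saturating": SATURATING,
    "power_saturating": POWER_SATURATING,
    "reciprocal": RECIPROCAL,
}


@numba.njit(cache=False)
def _rate(code, alpha, v_th, k, v):
    if code == EXPONENTIAL:
        return alpha * v
    if code == LINEAR:
        return alpha
    if code == SATURATING:
        return alpha * v / (1.0 + v / v_th)
    if code == POWER_SATURATING:
        return alpha * v / (1.0 + (v / v_th) ** k)
    return alpha * v_th * v_th / v


@numba.njit(cache=False)
def rk4_time_to_reach(code, alpha, v_th, k, v_lo, v_hi, dt=1e-3):
    """Elapsed time for a cell growing as dv/dt = f(v) to go from v_lo to v_hi."""
    t = 0.0
    v = v_lo
    while v < v_hi:
        v_prev = v
        k1 = _rate(code, alpha, v_th, k, v)
        k2 = _rate(code, alpha, v_th, k, v + 0.5 * dt * k1)
        k3 = _rate(code, alpha, v_th, k, v + 0.5 * dt * k2)
        k4 = _rate(code, alpha, v_th, k, v + dt * k3)
        v = v + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
        t += dt
    # interpolate within the final step for the exact crossing time
    if v > v_prev:
        t -= dt * (v - v_hi) / (v - v_prev)
    return t


def time_to_reach(law, v_lo, v_hi, dt=1e-3):
    """Oracle elapsed time for a package GrowthLaw instance."""
    code = KIND_CODES[law.kind]
    v_th = law.v_th if law.v_th is not None else 1.0
    k = law.k if law.k is not None else 1.0
    return rk4_time_to_reach(code, law.alpha, v_th, k, v_lo, v_hi, dt)
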