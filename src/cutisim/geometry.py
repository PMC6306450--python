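"""Spherical-cap droplet geometry and the Popov evaporation kernel.

A sessile drop on the cuticle is a spherical cap described by its water
volume V and contact angle theta.  Evaporation follows the quasi-steady
vapor-diffusion model of Popov: the rate is proportional to the contact
radius times a shape function f(theta) given by a semi-infinite integral.
f is expensive, so a cubic-spline table on a 0.1 degree grid is built
lazily for use inside ODE right-hand sides; direct adaptive quadrature is
retained for verification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .params import DEG

__all__ = [
    "SphericalCap", "cap_g", "popov_f", "theta0_from_area",
    "receding_angle", "cap_from_volume", "receding_time", "cap_profile",
]


@dataclass(frozen=True)
class SphericalCap:
    """Instantaneous spherical-cap droplet geometry (SI units)."""

    V: float        # water volume, m^3
    theta: float    # contact angle, rad
    r_drop: float   # contact radius, m
    A_drop: float   # contact area, m^2
    h: float        # apex height, m
    R_s: float      # radius of the full sphere, m


def _check_theta(theta: float, *, closed_zero: bool = False) -> None:
    lo_ok = theta >= 0.0 if closed_zero else theta > 0.0
    if not (lo_ok and theta < math.pi):
        raise ValueError(f"contact angle {theta!r} rad outside the valid cap range")
    if theta > 150 * DEG:
        warnings.warn("Popov evaporation kernel is validated up to 150 deg; "
                      f"theta = {theta/DEG:.1f} deg", stacklevel=3)


def cap_g(theta: float) -> float:
    """Shape factor g(theta) = sin^3(theta) / [(1-cos theta)^2 (2+cos theta)].

    Relates cap volume to contact radius: V = pi r^3 / (3 g).  Strictly
    decreasing on (0, pi); g(pi/2) = 1/2.
    """
    _check_theta(theta)
    c = math.cos(theta)
    return math.sin(theta) ** 3 / ((1.0 - c) ** 2 * (2.0 + c))


def _f_integrand(u: float, theta: float) -> float:
    # cosh^2(theta u) csch(2 pi u) tanh((pi-theta) u), written with
    # decaying exponentials so large u cannot overflow.
    if u == 0.0:
        return (math.pi - theta) / (2.0 * math.pi)
    e = math.exp
    num = e(-2.0 * math.pi * u) + 0.5 * (e(-2.0 * (math.pi - theta) * u)
                                         + e(-2.0 * (math.pi + theta) * u))
    return num / (1.0 - e(-4.0 * math.pi * u)) * math.tanh((math.pi - theta) * u)


def popov_f(theta: float) -> float:
    """Popov shape function f(theta) by adaptive quadrature.

    f(0+) = 4/pi (flat disk) and f(pi/2) = 2 (hemisphere) are the analytic
    limits.  The integrand decays like exp(-2 (pi-theta) u).
    """
    _check_theta(theta, closed_zero=True)
    # truncate where the exponential envelope is < 1e-16 of its peak
    u_max = 40.0 / max(2.0 * (math.pi - theta), 1e-3)
    val, err = quad(_f_integrand, 0.0, u_max, args=(theta,), limit=200,
                    epsabs=1e-13, epsrel=1e-12)
    if not math.isfinite(val) or err > 1e-8:
        raise ArithmeticError(f"Popov quadrature did not converge at theta={theta}"
                              f" (estimate {val}, error {err})")
    return math.tan(theta / 2.0) + 8.0 * val


_F_TABLE: CubicSpline | None = None


def _f_spline() -> CubicSpline:
    """Cubic interpolant of f on a 0.1 deg grid over (0, 179] deg."""
    global _F_TABLE
    if _F_TABLE is None:
        grid = np.arange(0.0, 179.0 + 1e-9, 0.1) * DEG
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals = np.array([popov_f(t) for t in grid])
        _F_TABLE = CubicSpline(grid, vals)
    return _F_TABLE


def popov_f_fast(theta: float) -> float:
    """Tabulated f(theta) (interpolation error < 1e-6); used in ODE RHS."""
    return float(_f_spline()(theta))


def cap_from_volume(V: float, theta: float) -> SphericalCap:
    """Spherical cap from water volume and contact angle.

    r_drop = (3 g(theta) V / pi)^(1/3);  A_drop = pi r_drop^2.
    V = 0 yields the degenerate zero cap.
    """
    _check_theta(theta)
    if V < 0:
        raise ValueError("volume must be non-negative")
    if V == 0.0:
        return SphericalCap(V=0.0, theta=theta, r_drop=0.0, A_drop=0.0, h=0.0, R_s=0.0)
    g = cap_g(theta)
    r = (3.0 * g * V / math.pi) ** (1.0 / 3.0)
    R_s = r / math.sin(theta)
    h = R_s * (1.0 - math.cos(theta))
    return SphericalCap(V=V, theta=theta, r_drop=r, A_drop=math.pi * r * r, h=h, R_s=R_s)


def contact_area(V: float, theta: float) -> float:
    """A_drop = pi^(1/3) (3 g(theta) V)^(2/3)."""
    if V == 0.0:
        return 0.0
    return math.pi ** (1.0 / 3.0) * (3.0 * cap_g(theta) * V) ** (2.0 / 3.0)


def theta0_from_area(A_drop_0: float, V_0: float) -> float:
    """Recover the initial contact angle from measured contact area and volume.

    Inverts A = pi^(1/3) (3 g(theta) V)^(2/3) by bracketed root finding on
    (0.01 deg, 179 deg); A is strictly decreasing in theta for fixed V.
    """
    if A_drop_0 <= 0 or V_0 <= 0:
        raise ValueError("area and volume must be positive")
    lo, hi = 0.01 * DEG, 179.0 * DEG

    def resid(t: float) -> float:
        return contact_area(V_0, t) - A_drop_0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_lo, r_hi = resid(lo), resid(hi)
        if r_lo < 0 or r_hi > 0:
            raise ValueError(
                f"no spherical cap with A={A_drop_0} m^2 at V={V_0} m^3")
        theta = brentq(resid, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return theta


def receding_angle(theta_0: float, fraction: float) -> float:
    """theta_rec = theta_0 (1 - fraction); fraction ~ 0.1264 experimentally."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    return theta_0 * (1.0 - fraction)


def receding_time(theta_0: float, theta_rec: float, r_drop_0: float,
                  Lambda: float) -> float:
    """Duration of the constant-contact-radius stage by quadrature.

    t_rec = int_{theta_rec}^{theta_0} r0^2 / [Lambda (1+cos t)^2 f(t)] dt —
    the closed-form of integrating the CCR contact-angle ODE.
    """
    if Lambda <= 0:
        return math.inf
    f = _f_spline()

    def integrand(t: float) -> float:
        return r_drop_0**2 / (Lambda * (1.0 + math.cos(t)) ** 2 * float(f(t)))

    val, _ = quad(integrand, theta_rec, theta_0, limit=200)
    return val


def cap_profile(V: float, theta: float, n: int = 181) -> np.ndarray:
    """(radius, height) cross-section pairs of the cap, for plotting/CSV.

    The cap is part of a sphere of radius R_s = r_drop/sin(theta) centered
    a distance R_s cos(theta) below the apex plane.
    """
    cap = cap_from_volume(V, theta)
    if cap.V == 0.0:
        return np.zeros((1, 2))
    phi = np.linspace(-theta, theta, n)
    x = cap.R_s * np.sin(phi)
    y = cap.R_s * (np.cos(phi) - math.cos(theta))
    return np.column_stack([x, y])
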