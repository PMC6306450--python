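"""Cuticle interior: swelling aqueous pores and porous diffusion.

The cuticle is a 1-D slab x in [0, b] crossed by tortuous water-filled
nanopores.  Water adsorbs to the pore walls as a Langmuir monolayer; the
adsorbed amount sets the pore radius, the radius sets the areal porosity,
and the porosity sets the effective diffusivities through a fractal
tortuosity power law.  Both the AI and water diffuse down gradients of
(eps * c); the water equation carries a sink for wall adsorption.

Discretization: node-centered uniform finite volumes, second-order central
differences for the diffusive fluxes with arithmetic averaging of the
diffusivity at cell faces, Dirichlet values imposed at the boundary faces
at half-cell distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import DerivedConstants, ModelParameters

__all__ = [
    "CuticleField", "pore_radius_from_gamma", "gamma_from_pore_radius",
    "porosity", "effective_diffusivity", "langmuir_gamma",
    "initialize_field", "transport_residuals",
]


# ----------------------------------------------------------------------
# pointwise physics

def pore_radius_from_gamma(Gamma, p: ModelParameters):
    """Pore radius from adsorbed water: r_p = r_H2O [1 + 1/sin(1/(Gamma r^2 N_A))].

    Strictly increasing in Gamma; equals r_p_max at the saturation value
    Gamma_S.  Valid while the monolayer argument 1/(Gamma r^2 N_A) stays
    below pi/2 (sparser coverage has no geometric inverse).
    """
    Gamma = np.asarray(Gamma, dtype=float)
    if np.any(Gamma <= 0):
        raise ValueError("Gamma must be positive")
    s = 1.0 / (Gamma * p.r_H2O**2 * p.N_A)
    if np.any(s >= math.pi / 2):
        raise ValueError("adsorbed water below the monolayer geometry limit")
    out = p.r_H2O * (1.0 + 1.0 / np.sin(s))
    return float(out) if out.ndim == 0 else out


def gamma_from_pore_radius(r_p, p: ModelParameters):
    """Inverse of :func:`pore_radius_from_gamma`:
    Gamma = 1 / (r_H2O^2 N_A arcsin(1/(r_p/r_H2O - 1)))."""
    r_p = np.asarray(r_p, dtype=float)
    ratio = r_p / p.r_H2O - 1.0
    if np.any(ratio <= 1.0):
        raise ValueError("pore radius too small: arcsin argument would reach 1")
    out = 1.0 / (p.r_H2O**2 * p.N_A * np.arcsin(1.0 / ratio))
    return float(out) if out.ndim == 0 else out


def porosity(r_p, p: ModelParameters):
    """Areal pore fraction eps = (n0 + 1) pi r_p^2 / L^2 with n0 = eta_pore L^2."""
    n0 = p.eta_pore * p.L**2
    eps = (n0 + 1.0) * math.pi * np.asarray(r_p, dtype=float) ** 2 / p.L**2
    if np.any(eps >= 1.0):
        raise ValueError("porosity >= 1: pore density times pore area exceeds the surface")
    return float(eps) if eps.ndim == 0 else eps


def effective_diffusivity(eps, D_bulk: float, F_s: float):
    """Fractal-tortuosity scaling D = D_bulk * eps^(F_s/(2-F_s)).

    At F_s -> 1 the exponent degenerates to 1 (classical porosity scaling);
    larger F_s (more tortuous pores) suppresses transport.
    """
    if not (1.0 <= F_s < 2.0):
        raise ValueError("F_s must lie in [1, 2)")
    expo = F_s / (2.0 - F_s)
    return D_bulk * np.asarray(eps, dtype=float) ** expo


def langmuir_gamma(c_H2O, beta: float, Gamma_S: float):
    """Langmuir monolayer adsorption Gamma = Gamma_S beta c / (1 + beta c)."""
    c = np.asarray(c_H2O, dtype=float)
    if np.any(c < 0):
        raise ValueError("water concentration must be non-negative")
    out = Gamma_S * beta * c / (1.0 + beta * c)
    return float(out) if out.ndim == 0 else out


def langmuir_dgamma_dc(c_H2O, beta: float, Gamma_S: float):
    """d Gamma / d c_H2O = Gamma_S beta / (1 + beta c)^2."""
    c = np.asarray(c_H2O, dtype=float)
    return Gamma_S * beta / (1.0 + beta * c) ** 2


# ----------------------------------------------------------------------
# field container

@dataclass
class CuticleField:
    """Node-centered finite-volume field over the cuticle thickness."""

    x: np.ndarray        # cell centers, m
    dx: float
    c_AI: np.ndarray     # mol/m^3
    c_H2O: np.ndarray    # mol/m^3
    Gamma: np.ndarray    # adsorbed water, mol/m^2
    r_p: np.ndarray      # pore radius, m
    eps: np.ndarray      # porosity
    D_AI: np.ndarray     # effective diffusivity, m^2/s
    D_H2O: np.ndarray


def field_from_state(c_AI: np.ndarray, c_H2O: np.ndarray, p: ModelParameters,
                     d: DerivedConstants) -> CuticleField:
    """Reconstruct all auxiliary pore fields from the two concentrations."""
    N = len(c_AI)
    dx = p.b / N
    x = (np.arange(N) + 0.5) * dx
    Gamma = langmuir_gamma(c_H2O, d.beta_H2O, d.Gamma_S)
    r_p = pore_radius_from_gamma(Gamma, p)
    eps = porosity(r_p, p)
    return CuticleField(
        x=x, dx=dx, c_AI=np.asarray(c_AI, float), c_H2O=np.asarray(c_H2O, float),
        Gamma=Gamma, r_p=r_p, eps=eps,
        D_AI=effective_diffusivity(eps, p.D_AI_bulk, p.F_s),
        D_H2O=effective_diffusivity(eps, p.D_H2O_bulk, p.F_s),
    )


def initialize_field(p: ModelParameters, d: DerivedConstants | None = None) -> CuticleField:
    """Initial cuticle state: AI-free pores at gamma * r_p_max, pure water.

    The surface water value (set by the droplet composition) enters through
    the boundary condition, not the cell averages, so all cells start at
    c_H2O_pure / zero AI and satisfy every field invariant.
    """
    from .params import derive_constants
    if d is None:
        d = derive_constants(p)
    c_AI = np.zeros(p.N_x)
    c_H2O = np.full(p.N_x, d.c_H2O_pure)
    return field_from_state(c_AI, c_H2O, p, d)


def surface_water_concentration(c_AI_surf: float, p: ModelParameters) -> float:
    """Volume-conservation boundary value c_H2O(0,t) = (1 - vbar_AI c_AI)/vbar_H2O.

    Clamped at zero: a drop concentrated beyond 1/vbar_AI holds no free
    water (only reachable transiently below the POD, where the solution
    would physically crystallize).
    """
    return max(0.0, (1.0 - p.v_bar_AI * c_AI_surf) / p.v_bar_H2O)


# ----------------------------------------------------------------------
# discrete operators

def _laplacian(w: np.ndarray, D: np.ndarray, dx: float,
               w_left, w_right, D_left, D_right,
               closed_left: bool = False, closed_right: bool = False) -> np.ndarray:
    """FV divergence of D * d(w)/dx with Dirichlet ghost values w_left/right.

    Face diffusivities are arithmetic means; the boundary faces use the
    adjacent cell value and a half-cell distance.  ``closed_*`` replaces a
    boundary by a zero-flux wall.
    """
    D_face = 0.5 * (D[:-1] + D[1:])
    flux = np.empty(len(w) + 1)               # flux_i = -D dw/dx at face i
    flux[1:-1] = -D_face * (w[1:] - w[:-1]) / dx
    flux[0] = 0.0 if closed_left else -D_left * (w[0] - w_left) / (dx / 2.0)
    flux[-1] = 0.0 if closed_right else -D_right * (w_right - w[-1]) / (dx / 2.0)
    return -(flux[1:] - flux[:-1]) / dx


def transport_rates(c_AI: np.ndarray, c_H2O: np.ndarray,
                    c_AI_surf: float | None, p: ModelParameters,
                    d: DerivedConstants, *, closed: bool = False):
    """Time derivatives of the cell concentrations plus boundary fluxes.

    Solves the chain-rule-coupled system pointwise: with w_i = eps c_i,
    the water equation  d(eps c_w)/dt = div flux - (2/r_p)(1-eps) dGamma/dt
    gives  [eps + c_w eps' + (2/r_p)(1-eps) Gamma'] dc_w/dt = L_w,  and the
    AI equation then yields dc_AI/dt = (L_AI - c_AI eps' dc_w/dt)/eps,
    where eps'(c_w) follows the Langmuir -> pore radius -> porosity chain.

    ``c_AI_surf = None`` marks the dried-out state: zero AI flux at x = 0
    and pure water held at the outer face.  ``closed = True`` walls off
    both ends of both species (conservation testing).

    Returns ``(dc_AI, dc_H2O, J_AI_0, J_AI_b, J_H2O_0)`` with the J's the
    one-sided boundary values of D * d(eps c)/dx.
    """
    N = len(c_AI)
    dx = p.b / N
    beta, G_S = d.beta_H2O, d.Gamma_S

    Gamma = langmuir_gamma(c_H2O, beta, G_S)
    s = 1.0 / (Gamma * p.r_H2O**2 * p.N_A)
    sin_s = np.sin(s)
    r_p = p.r_H2O * (1.0 + 1.0 / sin_s)
    n0p1 = p.eta_pore * p.L**2 + 1.0
    eps = n0p1 * math.pi * r_p**2 / p.L**2
    expo = p.F_s / (2.0 - p.F_s)
    eps_pow = eps**expo
    D_AI = p.D_AI_bulk * eps_pow
    D_w = p.D_H2O_bulk * eps_pow

    # derivative chain eps'(c_w)
    dG_dc = langmuir_dgamma_dc(c_H2O, beta, G_S)
    dr_dG = p.r_H2O * np.cos(s) / sin_s**2 * s / Gamma
    deps_dc = (2.0 * n0p1 * math.pi * r_p / p.L**2) * dr_dG * dG_dc

    w_AI = eps * c_AI
    w_w = eps * c_H2O

    if closed:
        L_AI = _laplacian(w_AI, D_AI, dx, 0, 0, 0, 0, True, True)
        L_w = _laplacian(w_w, D_w, dx, 0, 0, 0, 0, True, True)
        J_AI_0 = J_AI_b = J_w_0 = 0.0
    elif c_AI_surf is None:  # dry: no drop on the surface
        w_w0 = eps[0] * d.c_H2O_pure
        w_wb = eps[-1] * d.c_H2O_pure
        L_AI = _laplacian(w_AI, D_AI, dx, 0, 0.0, 0, D_AI[-1], True, False)
        L_w = _laplacian(w_w, D_w, dx, w_w0, w_wb, D_w[0], D_w[-1])
        J_AI_0 = 0.0
        J_AI_b = D_AI[-1] * (0.0 - w_AI[-1]) / (dx / 2.0)
        J_w_0 = D_w[0] * (w_w[0] - w_w0) / (dx / 2.0)
    else:
        c_w_surf = surface_water_concentration(c_AI_surf, p)
        w_AI0 = eps[0] * c_AI_surf
        w_w0 = eps[0] * c_w_surf
        w_wb = eps[-1] * d.c_H2O_pure
        L_AI = _laplacian(w_AI, D_AI, dx, w_AI0, 0.0, D_AI[0], D_AI[-1])
        L_w = _laplacian(w_w, D_w, dx, w_w0, w_wb, D_w[0], D_w[-1])
        J_AI_0 = D_AI[0] * (w_AI[0] - w_AI0) / (dx / 2.0)
        J_AI_b = D_AI[-1] * (0.0 - w_AI[-1]) / (dx / 2.0)
        J_w_0 = D_w[0] * (w_w[0] - w_w0) / (dx / 2.0)

    coeff_w = eps + c_H2O * deps_dc + (2.0 / r_p) * (1.0 - eps) * dG_dc
    dc_w = L_w / coeff_w
    dc_AI = (L_AI - c_AI * deps_dc * dc_w) / eps
    return dc_AI, dc_w, J_AI_0, J_AI_b, J_w_0


def transport_residuals(field: CuticleField, dc_AI: np.ndarray,
                        dc_H2O: np.ndarray, c_AI_surf: float | None,
                        p: ModelParameters, d: DerivedConstants,
                        *, closed: bool = False) -> np.ndarray:
    """Implicit residual F(y, y') of the finite-volume discretization.

    Zero iff the supplied time derivatives satisfy the discrete PDE system;
    the steady state with frozen gradients therefore has zero residual for
    the linear (eps c) profile.
    """
    rA, rW, *_ = transport_rates(field.c_AI, field.c_H2O, c_AI_surf, p, d,
                                 closed=closed)
    res = np.concatenate([np.asarray(dc_AI) - rA, np.asarray(dc_H2O) - rW])
    if not np.all(np.isfinite(res)):
        raise ArithmeticError("non-finite transport residual; state dump: "
                              f"c_AI={field.c_AI}, c_H2O={field.c_H2O}")
    return res
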