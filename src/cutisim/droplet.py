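"""Droplet-side ordinary differential equations.

The sessile drop evaporates in two stages: constant contact radius (CCR),
where the contact angle relaxes from theta_0 to the receding angle, then
constant contact angle (CCA), where the footprint shrinks.  Above the POD
the CCA rate carries a logistic deliquescence factor that throttles
evaporation as the water volume approaches the equilibrium deliquescent
volume V_Del, plus a cap keeping the drop concentration below c_POD; below
the POD the bare Popov rate applies.  The drop's AI content obeys a
surface balance with irreversible ion binding and diffusive exchange with
the cuticle surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .geometry import cap_g, popov_f_fast
from .params import DerivedConstants, ModelParameters

V_DEL_FLOOR = 1e-18  # m^3; smooth guard for V/V_Del as the AI runs out

__all__ = ["Mode", "DropletState", "ccr_rates", "cca_hygroscopic_rate",
           "cca_below_pod_rate", "surface_ai_balance"]


class Mode(Enum):
    CCR = "CCR"
    CCA = "CCA"
    DRY = "DRY"


@dataclass
class DropletState:
    """Instantaneous droplet state (one drop; SI units)."""

    V: float               # water volume, m^3
    theta: float           # contact angle, rad
    mode: Mode
    c_AI_surf: float       # AI concentration in the drop, mol/m^3
    m_bound: float         # cumulative ion-bound AI, mol
    r_drop: float
    A_drop: float
    V_Del: float           # current deliquescent volume, m^3


def ccr_rates(theta: float, V: float, r_drop_0: float,
              d: DerivedConstants) -> tuple[float, float]:
    """CCR-stage rates (dtheta/dt, dV/dt); both are non-positive.

    dtheta/dt = -Lambda (1+cos theta)^2 f(theta) / r0^2,
    dV/dt     = -pi Lambda r0 f(theta).
    """
    f = popov_f_fast(theta)
    dtheta = -d.Lambda * (1.0 + math.cos(theta)) ** 2 * f / r_drop_0**2
    dV = -math.pi * d.Lambda * r_drop_0 * f
    return dtheta, dV


def _popov_cca(V: float, theta_rec: float, d: DerivedConstants) -> float:
    """Bare Popov CCA evaporation rate -pi Lambda f (3 g V / pi)^(1/3) <= 0."""
    if V <= 0.0:
        return 0.0
    r = (3.0 * cap_g(theta_rec) * V / math.pi) ** (1.0 / 3.0)
    return -math.pi * d.Lambda * popov_f_fast(theta_rec) * r


def water_backflux_volume_rate(A_drop: float, J_H2O_0: float,
                               p: ModelParameters) -> float:
    """Volume gain from water diffusing cuticle -> drop, m^3/s.

    eta_pore A_Pi M_w,H2O A_drop / rho_H2O * [D_H2O d(eps c_H2O)/dx]|x=0.
    """
    return p.flux_prefactor * p.M_w_H2O * A_drop / p.rho_H2O * J_H2O_0


def cca_hygroscopic_rate(V: float, c_AI_surf: float, V_Del: float,
                         c_POD: float, A_drop: float, J_H2O_0: float,
                         p: ModelParameters, d: DerivedConstants) -> float:
    """CCA dV/dt above the POD: Popov rate x logistic deliquescence factor
    x (1 - c_AI/c_POD) cap, plus the cuticle water back-flux.

    The logistic factor chi_bar (V/V_0) (V/V_Del - 1) vanishes as V
    approaches V_Del from above and turns the rate into absorption when
    V < V_Del.  With no AI left (V_Del -> 0) the factor is floored so the
    limit is plain evaporation.
    """
    evap = _popov_cca(V, p.theta_rec_eff, d)
    logistic = d.chi_bar * (V / p.V_0) * (V / max(V_Del, V_DEL_FLOOR) - 1.0)
    cap = 1.0 - c_AI_surf / c_POD
    return evap * logistic * cap + water_backflux_volume_rate(A_drop, J_H2O_0, p)


def cca_below_pod_rate(V: float, A_drop: float, J_H2O_0: float,
                       p: ModelParameters, d: DerivedConstants) -> float:
    """CCA dV/dt below the POD (or with hygroscopic growth disabled)."""
    return (_popov_cca(V, p.theta_rec_eff, d)
            + water_backflux_volume_rate(A_drop, J_H2O_0, p))


def surface_ai_balance(c_AI_surf: float, A_drop: float, J_AI_0: float,
                       p: ModelParameters) -> tuple[float, float]:
    """Rates (d(V c_AI)/dt, dm_bound/dt) for the drop's AI content.

    d(V c)/dt = -k c + eta_pore A_drop A_Pi [D_AI d(eps c_AI)/dx]|x=0.
    The gradient term is negative while the drop feeds the cuticle, so AI
    moles flow drop -> cuticle; binding is irreversible and accumulates.
    """
    binding = p.k * c_AI_surf
    exchange = p.flux_prefactor * A_drop * J_AI_0
    return -binding + exchange, binding
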