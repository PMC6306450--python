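"""Deliquescence physics of the droplet solution.

A salt solution sitting above its point of deliquescence (POD) absorbs
water vapor instead of drying to crystals.  Two empirical fits against
published CaCl2 equilibrium data drive the model: the final solution weight
percent c_mass%(Phi) and the equilibrium water uptake per unit salt mass
m_inf(Phi), both functions of a shifted relative humidity Phi = H + xi
(the adjuvant shifts the POD by xi, and by the assumed one-to-one
correspondence shifts the humidity axis of the fits by the same amount).

Other salts/adjuvants can supply their own (c_mass%, m_inf, POD) triple via
:class:`HygroscopicMaterial`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import ModelParameters

PHI_MAX = 0.97  # fits are clamped at 97 %RH

__all__ = [
    "HygroscopicMaterial", "HygroState", "CACL2", "shifted_humidity",
    "mass_percent", "m_inf", "pod_concentration", "deliquescent_volume",
]


@dataclass(frozen=True)
class HygroscopicMaterial:
    """Two-exponential equilibrium fits and POD for a deliquescent solute.

    ``c_mass%(Phi) = a1 exp(b1 Phi) + a2 exp(b2 Phi)`` (percent) and
    ``m_inf(Phi) = m1 exp(n1 Phi) + m2 exp(n2 Phi)`` (g water / g solute).
    """

    name: str
    pod: float
    cmass_coeffs: tuple[float, float, float, float]
    minf_coeffs: tuple[float, float, float, float]

    def mass_percent(self, phi):
        _check_phi(phi)
        a1, b1, a2, b2 = self.cmass_coeffs
        return a1 * np.exp(b1 * phi) + a2 * np.exp(b2 * phi)

    def m_inf(self, phi):
        _check_phi(phi)
        m1, n1, m2, n2 = self.minf_coeffs
        return m1 * np.exp(n1 * phi) + m2 * np.exp(n2 * phi)


#: Calcium chloride at 20-25 C (POD 32 %RH).
CACL2 = HygroscopicMaterial(
    name="CaCl2",
    pod=0.32,
    cmass_coeffs=(-0.8307, 3.618, 55.44, -0.612),
    minf_coeffs=(0.307, 2.763, 1.218e-9, 24.0),
)


@dataclass(frozen=True)
class HygroState:
    """Humidity-derived quantities governing the droplet's CCA stage."""

    phi: float                     # shifted relative humidity, fraction
    above_pod: bool
    c_mass_pct: Optional[float]    # final solution weight percent of AI
    m_inf: Optional[float]         # g water absorbed per g AI
    c_POD: Optional[float]         # max AI concentration before crystallization, mol/m^3


def _check_phi(phi) -> None:
    if np.any(np.asarray(phi) < 0) or np.any(np.asarray(phi) > PHI_MAX + 1e-12):
        raise ValueError(f"Phi={phi} outside the fitted range [0, {PHI_MAX}]")


def shifted_humidity(H: float, xi: float, pod_ai: float) -> tuple[float, bool]:
    """Shifted humidity Phi = min(H + xi, 0.97) and the above-POD flag.

    Hygroscopic growth is active only when H + xi exceeds the solute POD;
    otherwise the droplet evaporates without water absorption.
    """
    for name, v in (("H", H), ("xi", xi), ("POD", pod_ai)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} must lie in [0, 1]")
    s = H + xi
    if s > pod_ai:
        return min(s, PHI_MAX), True
    return s, False


def mass_percent(phi, material: HygroscopicMaterial = CACL2):
    """Final solution weight percent of the AI at shifted humidity Phi."""
    return material.mass_percent(phi)


def m_inf(phi, material: HygroscopicMaterial = CACL2):
    """Equilibrium mass of water absorbed per mass of AI (g/g) at Phi."""
    return material.m_inf(phi)


def pod_concentration(phi: float, p: ModelParameters,
                      material: HygroscopicMaterial = CACL2) -> float:
    """Maximum AI concentration before crystallization, mol/m^3.

    c_POD = c_mass%(Phi) * rho_AI / (100 * M_w_AI).
    """
    return mass_percent(phi, material) * p.rho_AI / (100.0 * p.M_w_AI)


def deliquescent_volume(c_AI_surf: float, V: float, phi: float,
                        p: ModelParameters,
                        material: HygroscopicMaterial = CACL2) -> float:
    """Equilibrium (minimum) water volume for the current AI content, m^3.

    V_Del = m_inf(Phi) M_w,AI c_AI(0,t) V / rho_H2O.  Since c*V is the AI
    mole content of the drop, V_Del depends on the state only through it.
    """
    if c_AI_surf < 0 or V < 0:
        raise ValueError("concentration and volume must be non-negative")
    return m_inf(phi, material) * p.M_w_AI * c_AI_surf * V / p.rho_H2O


def hygro_state(p: ModelParameters, material: HygroscopicMaterial = CACL2,
                *, xi: Optional[float] = None) -> HygroState:
    """Evaluate the full humidity-dependent state for a parameter set."""
    xi_ = p.xi if xi is None else xi
    phi, above = shifted_humidity(p.H, xi_, material.pod)
    if not above:
        return HygroState(phi=phi, above_pod=False, c_mass_pct=None,
                          m_inf=None, c_POD=None)
    return HygroState(phi=phi, above_pod=True,
                      c_mass_pct=float(mass_percent(phi, material)),
                      m_inf=float(m_inf(phi, material)),
                      c_POD=pod_concentration(phi, p, material))
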