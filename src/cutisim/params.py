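"""Model parameters, derived constants and configuration loading.

Every physical constant of the cuticle-penetration model lives in
:class:`ModelParameters`; quantities that are fixed functions of those
constants (evaporation constant, Langmuir parameters, receding time, ...)
are computed once into :class:`DerivedConstants`.

Units are SI throughout the library: concentrations in mol/m^3, lengths in
m, time in s, angles in radians.  Degrees, hours and g/L appear only at I/O
boundaries (config files, CSV exports, presets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

DEG = math.pi / 180.0
HOUR = 3600.0

#: Measured initial droplet contact areas (m^2) for a 1 uL drop of CaCl2
#: solution on isolated tomato fruit cuticle, with and without the
#: ethoxylated rapeseed-oil surfactant RSO 5, keyed by (surfactant, g/L).
#: The contact angles (degrees) were back-calculated from area and volume
#: via spherical-cap geometry; the receding angle is 12.64 % below theta_0.
CONTACT_ANGLE_TABLE: dict[tuple[bool, float], tuple[float, float, float]] = {
    (False, 1.0): (0.49e-6, 141.00, 123.18),
    (False, 5.0): (0.84e-6, 126.58, 110.58),
    (False, 10.0): (0.86e-6, 125.82, 109.91),
    (False, 15.0): (0.57e-6, 137.50, 120.12),
    (False, 30.0): (0.55e-6, 138.36, 120.87),
    (True, 1.0): (1.99e-6, 87.91, 76.79),
    (True, 5.0): (2.15e-6, 83.32, 72.79),
    (True, 10.0): (2.15e-6, 83.32, 72.79),
    (True, 15.0): (2.10e-6, 84.73, 74.02),
    (True, 30.0): (2.18e-6, 82.48, 72.06),
}

#: Alternative fitted parameter set that improves the RSO 5 150 ug fit in
#: isolation (not retained for the joint CaCl2 / CaCl2+RSO 5 fit).
ALT_FIT = {"F_s": 1.138, "k": 3.74e-15, "eta_pore": 1.99e15, "chi": 0.0023}


class ConfigError(ValueError):
    """Raised for unknown keys or non-physical parameter values."""


@dataclass
class ModelParameters:
    """Physical constants, fitted parameters and run controls.

    Defaults are the CaCl2 + RSO 5 calibration on tomato fruit cuticle at
    20 C and 70 % relative humidity (1 g/L, five 1 uL drops per cuticle).
    """

    # cuticle / pore structure
    b: float = 1.87e-5                 # cuticle thickness, m
    r_H2O: float = 1.5e-10             # van der Waals radius of water, m
    r_p_max: float = 2.12e-9           # maximum aqueous pore radius, m
    gamma: float = 0.97                # initial pore-size reduction factor
    eta_pore: float = 2.18e15          # aqueous pore density, m^-2 (fitted)
    F_s: float = 1.203                 # fractal scaling dimension (fitted)
    L: float = 1.0                     # reference length, m

    # transport / binding
    D_AI_bulk: float = 7.93e-10        # bulk diffusivity of the AI (Ca2+), m^2/s
    D_H2O_bulk: float = 2.299e-9       # bulk self-diffusivity of water, m^2/s
    k: float = 8.68e-16                # ion-binding rate constant, m^3/s (fitted)

    # evaporation / environment
    D_evap: float = 2.4e-5             # diffusivity of water vapor in air, m^2/s
    H: float = 0.7                     # relative humidity, fraction
    T: float = 293.15                  # temperature, K
    P_v: float = 2338.8                # saturated water vapor pressure, Pa
    chi: float = 0.043                 # logistic decay constant, L^2/g^2 (fitted)
    xi: float = 0.05                   # POD shift from adjuvant, RH fraction
    POD_AI: float = 0.32               # point of deliquescence of the AI, RH fraction

    # physical constants and material data
    R: float = 8.3145                  # gas constant, Pa m^3/(K mol)
    N_A: float = 6.02214e23            # Avogadro constant, 1/mol
    M_w_AI: float = 110.98             # molar mass CaCl2, g/mol
    M_w_H2O: float = 18.015            # molar mass water, g/mol
    rho_AI: float = 2.16e6             # density CaCl2, g/m^3
    rho_H2O: float = 9.98207e5         # density water at 20 C, g/m^3
    v_bar_AI: float = 1.6e-5           # partial molar volume CaCl2, m^3/mol
    v_bar_H2O: float = 1.8047e-5       # partial molar volume water, m^3/mol

    # droplet / application
    V_0: float = 1e-9                  # initial drop volume, m^3 (1 uL)
    c_AI_0_gL: float = 1.0             # initial AI concentration, g/L
    theta_0: float = 87.91 * DEG       # initial contact angle, rad
    theta_rec: Optional[float] = None  # receding contact angle, rad (default from fraction)
    theta_rec_fraction: float = 0.1264 # relative reduction theta_0 -> theta_rec
    n_drops: int = 5                   # drops per cuticle
    A_Pi: Optional[float] = None       # control-volume area, m^2 (default 1/eta_pore)

    # overrides for quantities normally derived (None -> computed)
    beta_H2O: Optional[float] = None   # Langmuir equilibrium parameter, m^3/mol

    # run controls
    t_final: float = 48 * HOUR         # s
    N_x: int = 100                     # finite-volume cells across the cuticle
    rtol: float = 1e-8
    atol: float = 1e-12

    provenance: list = field(default_factory=list, compare=False, repr=False)

    # ------------------------------------------------------------------
    @property
    def c_AI_0_drop(self) -> float:
        """Initial AI concentration in the drop, mol/m^3."""
        return 1000.0 * self.c_AI_0_gL / self.M_w_AI

    @property
    def theta_rec_eff(self) -> float:
        """Receding contact angle, rad (explicit value or fractional reduction)."""
        if self.theta_rec is not None:
            return self.theta_rec
        return self.theta_0 * (1.0 - self.theta_rec_fraction)

    @property
    def A_Pi_eff(self) -> float:
        """Control-volume area, m^2.

        Defaults to L^2/(n0+1) ~= 1/eta_pore so that the flux prefactor
        eta_pore * A_drop * A_Pi in the droplet balances reduces to the
        drop footprint area A_drop.
        """
        if self.A_Pi is not None:
            return self.A_Pi
        return self.L**2 / (self.eta_pore * self.L**2 + 1.0)

    @property
    def flux_prefactor(self) -> float:
        """eta_pore * A_Pi — multiplies A_drop * [D d(eps c)/dx] everywhere."""
        return self.eta_pore * self.A_Pi_eff

    # ------------------------------------------------------------------
    def validate(self) -> "ModelParameters":
        """Check physical invariants; raise :class:`ConfigError` on breach."""
        errs = []
        if not (1.0 < self.F_s < 2.0):
            errs.append(f"F_s={self.F_s} must lie in (1, 2)")
        if not (0.0 <= self.H <= 1.0):
            errs.append(f"H={self.H} must lie in [0, 1]")
        if not (0.0 < self.gamma <= 1.0):
            errs.append(f"gamma={self.gamma} must lie in (0, 1]")
        if not (0.0 < self.theta_rec_eff < self.theta_0 < math.pi):
            errs.append("need 0 < theta_rec < theta_0 < pi")
        if self.V_0 <= 0:
            errs.append("V_0 must be positive")
        if self.r_H2O >= self.r_p_max:
            errs.append("r_H2O must be smaller than r_p_max")
        for name in ("rho_AI", "rho_H2O", "D_AI_bulk", "D_H2O_bulk", "D_evap",
                     "M_w_AI", "M_w_H2O", "b", "T", "P_v", "eta_pore"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be positive")
        if self.k < 0 or self.chi < 0 or self.xi < 0:
            errs.append("k, chi and xi must be non-negative")
        if self.c_AI_0_gL < 0:
            errs.append("c_AI_0_gL must be non-negative")
        if self.N_x < 10:
            errs.append("N_x must be at least 10")
        if errs:
            raise ConfigError("; ".join(errs))
        return self


@dataclass(frozen=True)
class DerivedConstants:
    """Constants derived once from :class:`ModelParameters`."""

    psi: float          # saturated vapor concentration deficit, g/m^3
    Lambda: float       # evaporation constant, m^2/s
    c_H2O_pure: float   # pure-water molar concentration, mol/m^3
    Gamma_S: float      # Langmuir saturation, mol/m^2
    beta_H2O: float     # Langmuir equilibrium parameter, m^3/mol
    chi_bar: float      # logistic decay term chi * c0[g/L]^2, dimensionless
    t_rec: float        # receding time from the contact-angle quadrature, s


def derive_constants(p: ModelParameters) -> DerivedConstants:
    """Compute :class:`DerivedConstants` for a validated parameter set.

    ``psi = M_w,H2O P_v (1-H)/(R T)`` and ``Lambda = D_evap psi / rho_H2O``
    set the Popov evaporation rate; ``Gamma_S`` comes from inverting the
    pore-radius/adsorption relation at ``r_p_max``; ``beta_H2O`` is chosen
    so the Langmuir isotherm evaluated at pure water reproduces the initial
    adsorbed amount of a pore at ``gamma * r_p_max`` (self-consistent
    initialization); ``chi_bar = chi * c0^2`` with c0 in g/L.
    """
    p.validate()
    from . import geometry, transport  # local import avoids cycles

    psi = p.M_w_H2O * p.P_v * (1.0 - p.H) / (p.R * p.T)
    Lam = p.D_evap * psi / p.rho_H2O
    c_pure = p.rho_H2O / p.M_w_H2O
    Gamma_S = transport.gamma_from_pore_radius(p.r_p_max, p)
    if p.beta_H2O is not None:
        beta = p.beta_H2O
    else:
        Gamma_0 = transport.gamma_from_pore_radius(p.gamma * p.r_p_max, p)
        beta = 1.0 / (c_pure * (Gamma_S / Gamma_0 - 1.0))
    chi_bar = p.chi * p.c_AI_0_gL**2
    r0 = geometry.cap_from_volume(p.V_0, p.theta_0).r_drop
    t_rec = geometry.receding_time(p.theta_0, p.theta_rec_eff, r0, Lam) if Lam > 0 else math.inf
    return DerivedConstants(psi=psi, Lambda=Lam, c_H2O_pure=c_pure,
                            Gamma_S=Gamma_S, beta_H2O=beta,
                            chi_bar=chi_bar, t_rec=t_rec)


# ----------------------------------------------------------------------
# configuration files

_PRESETS = {
    "cacl2": {"surfactant": False, "xi": 0.0},
    "cacl2_rso5": {"surfactant": True, "xi": 0.05},
    "cacl2_rso5_alt": {"surfactant": True, "xi": 0.05, **ALT_FIT},
}

_ANGLE_KEYS = {"theta_0", "theta_rec"}
_PARAM_KEYS = {f.name for f in fields(ModelParameters)} - {"provenance"}


def lookup_contact_angles(surfactant: bool, c0_gL: float):
    """Table-1 preset (area, theta_0 deg, theta_rec deg) or None."""
    return CONTACT_ANGLE_TABLE.get((bool(surfactant), float(c0_gL)))


def _parse_concentration(value, M_w_AI: float, log: list) -> float:
    """Return c0 in g/L from a number (g/L) or a string like '1 g/L' / '9 mol/m^3'."""
    if isinstance(value, str):
        txt = value.strip()
        parts = txt.split(None, 1)
        num = float(parts[0])
        unit = parts[1].replace(" ", "") if len(parts) > 1 else "g/L"
        if unit.lower() in ("g/l", "g/liter"):
            log.append(f"c_AI_0 = {num} g/L -> {1000*num/M_w_AI:.4f} mol/m^3")
            return num
        if unit.lower() in ("mol/m^3", "mol/m3"):
            gl = num * M_w_AI / 1000.0
            log.append(f"c_AI_0 = {num} mol/m^3 -> {gl:.4f} g/L")
            return gl
        raise ConfigError(f"unknown concentration unit in {value!r}")
    log.append(f"c_AI_0 = {value} g/L -> {1000*float(value)/M_w_AI:.4f} mol/m^3")
    return float(value)


def load_config(path) -> tuple[ModelParameters, "ExperimentConfig"]:
    """Load a YAML config into a validated parameter set and scenario.

    Keys are ASCII transliterations of the model symbols (``eta_pore``,
    ``F_s``, ``chi``, ``xi``, ...).  Missing keys fall back to the defaults;
    an empty file yields the RSO 5 preset at 1 g/L (theta_0 = 87.91 deg).
    Angles are degrees in files, radians internally; ``c_AI_0`` accepts
    "<x> g/L" or "<x> mol/m^3" strings.  Unit conversions are appended to
    ``ModelParameters.provenance``.
    """
    from .experiments import ExperimentConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    log: list[str] = []

    preset_name = raw.pop("preset", "cacl2_rso5")
    if preset_name not in _PRESETS:
        raise ConfigError(f"unknown preset {preset_name!r}; choose from {sorted(_PRESETS)}")
    preset = dict(_PRESETS[preset_name])
    surfactant = bool(raw.pop("surfactant", preset.pop("surfactant")))

    kwargs: dict = {k: v for k, v in preset.items()}
    if "c_AI_0" in raw or "c_AI_0_drop" in raw:
        val = raw.pop("c_AI_0", raw.pop("c_AI_0_drop", None))
        kwargs["c_AI_0_gL"] = _parse_concentration(val, ModelParameters.M_w_AI, log)
    label = raw.pop("label", preset_name)
    hygro = bool(raw.pop("hygroscopic_growth", True))

    for key, val in raw.items():
        if key not in _PARAM_KEYS:
            raise ConfigError(f"unknown config key {key!r}")
        if key in _ANGLE_KEYS:
            log.append(f"{key} = {val} deg -> {float(val)*DEG:.6f} rad")
            val = float(val) * DEG
        kwargs[key] = val

    c0 = float(kwargs.get("c_AI_0_gL", 1.0))
    if "theta_0" not in kwargs:
        row = lookup_contact_angles(surfactant, c0)
        if row is None:
            raise ConfigError(
                f"no contact-angle preset for surfactant={surfactant}, c0={c0} g/L; "
                "supply theta_0 explicitly")
        kwargs["theta_0"] = row[1] * DEG
    p = ModelParameters(**kwargs)
    p.provenance.extend(log)
    p.validate()
    exp = ExperimentConfig(label=label, surfactant=surfactant,
                           concentrations_gL=(c0,), hygroscopic_growth=hygro)
    return p, exp


def save_config(p: ModelParameters, path, *, surfactant: bool = True) -> None:
    """Write a YAML config that :func:`load_config` round-trips bit-identically."""
    data = {}
    for f_ in fields(ModelParameters):
        if f_.name in ("provenance",):
            continue
        v = getattr(p, f_.name)
        if v is None:
            continue
        if f_.name in _ANGLE_KEYS:
            v = v / DEG
        data[f_.name] = v
    data["surfactant"] = surfactant
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def with_overrides(p: ModelParameters, **overrides) -> ModelParameters:
    """Functional update preserving validation."""
    q = replace(p, **overrides)
    q.validate()
    return q
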