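"""Scenario layer: validation suites, sensitivity sweeps, fitting, fixtures.

The validation suites rerun the calibrated model over the five applied
CaCl2 concentrations (1, 5, 10, 15, 30 g/L; five 1 uL drops per cuticle)
with and without the RSO 5 surfactant, each run taking its measured initial
contact angle.  One-factor-at-a-time sensitivity perturbs a single
parameter around the 1 g/L + RSO 5 baseline and ranks parameters by three
standard measures.  Nelder-Mead fitting recovers the four fitted
parameters (F_s, k, eta_pore, chi) from penetration curves; a seeded
fixture generator supplies synthetic curves in the same CSV schema
(t_h, pct, sd) that user-digitized experimental data would use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .params import DEG, HOUR, ModelParameters, lookup_contact_angles, with_overrides
from .simulate import SimulationResult, run

__all__ = [
    "ExperimentConfig", "PenetrationDataset", "build_params",
    "validation_suite", "sensitivity_oat", "fit_parameters",
    "two_exponential_fit", "make_fixture",
]

CONCENTRATIONS_GL = (1.0, 5.0, 10.0, 15.0, 30.0)
ASSAY_TIMES_H = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0)


@dataclass
class ExperimentConfig:
    """Descriptor of a validation/sensitivity scenario."""

    label: str = "cacl2_rso5"
    surfactant: bool = True
    concentrations_gL: Sequence[float] = (1.0,)
    H: Optional[float] = None
    xi: Optional[float] = None
    theta_0_deg: Optional[float] = None     # explicit angle; else Table lookup
    hygroscopic_growth: bool = True
    overrides: dict = field(default_factory=dict)
    sweep: Optional[tuple[str, Sequence[float]]] = None

    def validate(self) -> "ExperimentConfig":
        for c in self.concentrations_gL:
            if self.theta_0_deg is None and lookup_contact_angles(self.surfactant, c) is None:
                raise ValueError(f"no contact-angle preset for c0={c} g/L "
                                 f"(surfactant={self.surfactant}); give theta_0_deg")
        return self


@dataclass
class PenetrationDataset:
    """Penetration curve samples: t (hours), percent, standard deviation."""

    t_h: np.ndarray
    pct: np.ndarray
    sd: np.ndarray
    c0_gL: float = 1.0
    surfactant: bool = True
    label: str = ""

    def __post_init__(self):
        self.t_h = np.asarray(self.t_h, float)
        self.pct = np.asarray(self.pct, float)
        self.sd = np.asarray(self.sd, float)
        if np.any(np.diff(self.t_h) <= 0) or np.any(self.t_h < 0):
            raise ValueError("times must be non-negative and increasing")
        if np.any((self.pct < 0) | (self.pct > 100)):
            raise ValueError("percent penetration must lie in [0, 100]")

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_h": self.t_h, "pct": self.pct, "sd": self.sd}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "PenetrationDataset":
        df = pd.read_csv(path)
        return cls(t_h=df["t_h"].to_numpy(), pct=df["pct"].to_numpy(),
                   sd=df.get("sd", pd.Series(np.zeros(len(df)))).to_numpy(), **meta)


# ----------------------------------------------------------------------

def build_params(base: ModelParameters, *, surfactant: bool, c0_gL: float,
                 theta_0_deg: Optional[float] = None,
                 **overrides) -> ModelParameters:
    """Parameter set for one scenario: concentration-matched contact angle,
    POD shift on/off with the surfactant, plus explicit overrides."""
    kw = dict(overrides)
    kw["c_AI_0_gL"] = c0_gL
    if theta_0_deg is not None:
        kw["theta_0"] = theta_0_deg * DEG
    else:
        row = lookup_contact_angles(surfactant, c0_gL)
        if row is None:
            raise ValueError(f"no preset contact angle for c0={c0_gL} g/L")
        kw["theta_0"] = row[1] * DEG
    kw.setdefault("xi", base.xi if surfactant else 0.0)
    return with_overrides(base, **kw)


def run_scenario(base: ModelParameters, exp: ExperimentConfig,
                 c0_gL: float) -> SimulationResult:
    kw = dict(exp.overrides)
    if exp.H is not None:
        kw["H"] = exp.H
    if exp.xi is not None:
        kw["xi"] = exp.xi
    p = build_params(base, surfactant=exp.surfactant, c0_gL=c0_gL,
                     theta_0_deg=exp.theta_0_deg, **kw)
    return run(p, exp)


def validation_suite(surfactant: bool, base: Optional[ModelParameters] = None,
                     concentrations: Sequence[float] = CONCENTRATIONS_GL,
                     **run_kwargs) -> dict:
    """Rerun the calibrated model over the applied-concentration series.

    All runs share the fitted (F_s, k, eta_pore, chi); only the initial
    concentration and its measured contact angle change.  Returns the
    per-concentration results and summary statistics of the final percent
    penetration at t_final.
    """
    base = base or ModelParameters()
    exp = ExperimentConfig(label="validation", surfactant=surfactant,
                           concentrations_gL=tuple(concentrations)).validate()
    results = {}
    for c0 in concentrations:
        results[c0] = run_scenario(base, exp, c0)
    finals = np.array([results[c].final_pct for c in concentrations])
    return {
        "results": results,
        "final_pct": dict(zip(concentrations, finals)),
        "mean_final_pct": float(finals.mean()),
        "sd_final_pct": float(finals.std(ddof=1)),
    }


# ----------------------------------------------------------------------
# one-factor-at-a-time sensitivity

def _common_grid_pct(res: SimulationResult, t_h: np.ndarray) -> np.ndarray:
    return np.interp(t_h, res.times / HOUR, res.pct_pen)


def sensitivity_oat(base: Optional[ModelParameters] = None,
                    sweeps: Optional[dict[str, Sequence[float]]] = None,
                    *, relative_steps: Sequence[float] = (-0.1, 0.1),
                    n_grid: int = 97) -> pd.DataFrame:
    """One-factor-at-a-time sensitivity around the 1 g/L + RSO 5 baseline.

    For each perturbed value the model is rerun and three measures are
    accumulated against the reference run: the percent relative sensitivity
    at t_final ``S_pct = |d(final)/final| / |dp/p|``, the residual sum of
    squares over a common time grid and its RMSE.  Parameters are ranked by
    each measure (1 = most sensitive); proportionality is the sign of the
    response to an increase of the parameter.
    """
    base = base or ModelParameters()
    if sweeps is None:
        sweeps = {name: [getattr(base, name) * (1.0 + s) for s in relative_steps]
                  for name in ("F_s", "r_p_max", "H", "eta_pore", "k", "b", "chi")}
    ref = run(base)
    t_h = np.linspace(0.0, base.t_final / HOUR, n_grid)
    pct_ref = _common_grid_pct(ref, t_h)
    final_ref = ref.final_pct

    rows = []
    for name, values in sweeps.items():
        p0 = getattr(base, name)
        s_pct, ss_res, rmse, signs = [], [], [], []
        for v in values:
            if v == p0:
                s_pct.append(0.0), ss_res.append(0.0), rmse.append(0.0)
                continue
            try:
                pert = run(with_overrides(base, **{name: v}))
            except ValueError as e:  # out-of-range perturbation
                import warnings
                warnings.warn(f"skipping {name}={v}: {e}")
                continue
            pct_v = _common_grid_pct(pert, t_h)
            dfin = pert.final_pct - final_ref
            rel_p = (v - p0) / p0 if p0 != 0 else math.nan
            s_pct.append(abs(dfin / final_ref) / abs(rel_p))
            ss_res.append(float(np.sum((pct_v - pct_ref) ** 2)))
            rmse.append(float(np.sqrt(np.mean((pct_v - pct_ref) ** 2))))
            signs.append(math.copysign(1.0, dfin * rel_p) if dfin != 0 else 0.0)
        if not s_pct:
            continue
        sgn = np.sign(np.sum(signs)) if signs else 0.0
        prop = {1.0: "direct", -1.0: "inverse", 0.0: "-"}[float(sgn)]
        rows.append({"parameter": name, "S_pct": float(np.mean(s_pct)),
                     "SS_res": float(np.mean(ss_res)),
                     "RMSE": float(np.mean(rmse)), "proportionality": prop})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    for col in ("S_pct", "SS_res", "RMSE"):
        df[f"rank_{col}"] = df[col].rank(ascending=False, method="min").astype(int)
    return df.sort_values("rank_S_pct").reset_index(drop=True)


# ----------------------------------------------------------------------
# parameter fitting

_FIT_BOUNDS = {"F_s": (1.0001, 1.9999), "k": (0.0, None),
               "eta_pore": (1e-12, None), "chi": (0.0, None)}


def _to_internal(name: str, v: float) -> float:
    if name == "F_s":       # logit over (1, 2)
        z = (v - 1.0)
        return math.log(z / (1.0 - z))
    return math.log(max(v, 1e-300))


def _from_internal(name: str, u: float) -> float:
    if name == "F_s":
        return 1.0 + 1.0 / (1.0 + math.exp(-u))
    return math.exp(u)


def fit_parameters(datasets: Sequence[PenetrationDataset],
                   free: Sequence[str] = ("F_s", "k", "eta_pore", "chi"),
                   base: Optional[ModelParameters] = None,
                   *, staged: bool = True, maxiter: int = 200,
                   xatol: float = 1e-3, fatol: float = 1e-4) -> dict:
    """Nelder-Mead fit of the free parameters to penetration curves.

    Residuals are model-minus-data percent penetration at the data time
    points, pooled over datasets; bounds are enforced through smooth
    reparameterizations (logit for F_s, log for the positive parameters).
    With ``staged=True`` the first dataset alone provides a warm start
    before the joint fit, mirroring the original calibration protocol.
    Returns estimates, the pooled residual sum of squares and per-dataset
    R^2 values; non-convergence is flagged, with the best point found.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    base = base or ModelParameters()
    unknown = set(free) - set(_FIT_BOUNDS)
    if unknown:
        raise ValueError(f"cannot fit {sorted(unknown)}; free parameters are "
                         f"{sorted(_FIT_BOUNDS)}")
    free = list(free)

    def model_pct(p: ModelParameters, ds: PenetrationDataset,
                  cache: dict) -> np.ndarray:
        key = (ds.surfactant, ds.c0_gL)
        if key not in cache:  # datasets sharing a scenario reuse one run
            q = build_params(p, surfactant=ds.surfactant, c0_gL=ds.c0_gL)
            cache[key] = run(q)
        return _common_grid_pct(cache[key], ds.t_h)

    def objective(u: np.ndarray, subset) -> float:
        vals = {n: _from_internal(n, ui) for n, ui in zip(free, u)}
        try:
            p = with_overrides(base, **vals)
        except ValueError:
            return 1e12
        sq = 0.0
        cache: dict = {}
        for ds in subset:
            r = model_pct(p, ds, cache) - ds.pct
            sq += float(r @ r)
        return sq

    u0 = np.array([_to_internal(n, getattr(base, n)) for n in free])
    converged = True
    if staged and len(datasets) > 1:
        warm = minimize(objective, u0, args=([datasets[0]],),
                        method="Nelder-Mead",
                        options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol})
        u0 = warm.x
    final = minimize(objective, u0, args=(list(datasets),), method="Nelder-Mead",
                     options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol})
    converged = bool(final.success)
    estimates = {n: _from_internal(n, ui) for n, ui in zip(free, final.x)}

    fitted = with_overrides(base, **estimates)
    r2 = []
    cache: dict = {}
    for ds in datasets:
        pred = model_pct(fitted, ds, cache)
        ss_res = float(np.sum((pred - ds.pct) ** 2))
        ss_tot = float(np.sum((ds.pct - ds.pct.mean()) ** 2))
        r2.append(1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan)
    return {"estimates": estimates, "ss_res": float(final.fun),
            "r_squared": r2, "converged": converged, "n_iter": final.nit}


# ----------------------------------------------------------------------
# curve characterization and fixtures

def two_exponential_fit(dataset: PenetrationDataset) -> dict:
    """Fit pct(t) = a1 (1 - e^(-t/tau1)) + a2 (1 - e^(-t/tau2)), tau1 < tau2.

    Two saturating exponentials expose the two timescales of cuticular
    penetration (fast droplet-driven uptake, slow late-time tail).
    Degenerate (near-constant) data falls back to a flagged
    single-exponential fit.
    """
    t, y = dataset.t_h, dataset.pct
    if len(t) < 5:
        raise ValueError("need at least 5 points")
    if np.ptp(y) < 1e-9:
        return {"a": (float(y.mean()), 0.0), "tau": (1.0, 10.0),
                "degenerate": True}

    def resid(q):
        a1, a2, lt1, lt2 = q
        tau1, tau2 = np.exp(lt1), np.exp(lt2)
        return (a1 * (1 - np.exp(-t / tau1)) + a2 * (1 - np.exp(-t / tau2))) - y

    span = max(t.max(), 1.0)
    q0 = np.array([0.5 * y.max(), 0.5 * y.max(),
                   math.log(0.05 * span), math.log(0.5 * span)])
    sol = least_squares(resid, q0, method="lm", max_nfev=20000)
    a1, a2, lt1, lt2 = sol.x
    tau1, tau2 = math.exp(lt1), math.exp(lt2)
    if tau1 > tau2:
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    out = {"a": (float(a1), float(a2)), "tau": (float(tau1), float(tau2)),
           "degenerate": False, "ss_res": float(2 * sol.cost)}
    if tau2 / max(tau1, 1e-12) < 1.5:   # timescales not separated
        def resid1(q):
            return q[0] * (1 - np.exp(-t / np.exp(q[1]))) - y
        s1 = least_squares(resid1, np.array([y.max(), math.log(0.2 * span)]),
                           method="lm")
        out = {"a": (float(s1.x[0]), 0.0), "tau": (float(np.exp(s1.x[1])), math.inf),
               "degenerate": True, "ss_res": float(2 * s1.cost)}
    return out


def make_fixture(p: Optional[ModelParameters] = None, noise_sd: float = 3.0,
                 seed: int = 0, times_h: Sequence[float] = ASSAY_TIMES_H,
                 *, surfactant: bool = True, result: Optional[SimulationResult] = None,
                 ) -> PenetrationDataset:
    """Synthetic penetration curve: model output plus seeded Gaussian noise.

    Samples the simulated percent penetration at the assay cadence, adds
    N(0, noise_sd^2) noise and clamps to [0, 100].  ``noise_sd = 0``
    reproduces the model curve exactly; a fixed seed is fully reproducible.
    """
    p = p or ModelParameters()
    if result is None:
        result = run(p)
    t_h = np.asarray(times_h, float)
    pct = _common_grid_pct(result, t_h)
    rng = np.random.default_rng(seed)
    noisy = np.clip(pct + rng.normal(0.0, noise_sd, size=len(t_h)), 0.0, 100.0) \
        if noise_sd > 0 else pct
    return PenetrationDataset(t_h=t_h, pct=noisy,
                              sd=np.full(len(t_h), float(noise_sd)),
                              c0_gL=p.c_AI_0_gL, surfactant=surfactant,
                              label=f"synthetic seed={seed}")
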