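"""Coupled droplet/cuticle simulation with staged events.

The full model couples the droplet ODEs (contact angle, water volume,
AI content with ion binding) to the finite-volume cuticle transport system
through the surface boundary values and fluxes.  The coupled system is
integrated monolithically with a stiff BDF method in three phases:

  CCR  (pinned contact line)  until theta reaches theta_rec,
  CCA  (receding contact line) until the drop's water or AI is exhausted,
  DRY  (no drop)               cuticle-only diffusion to t_final.

Mole bookkeeping uses flux-integral ledgers so that
applied = in-drop + bound + in-cuticle + in-bath holds to integrator
accuracy at every output time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from . import droplet as drp
from . import transport as tr
from .geometry import cap_from_volume
from .hygroscopics import CACL2, HygroscopicMaterial, deliquescent_volume, hygro_state
from .params import DerivedConstants, ModelParameters, derive_constants

__all__ = ["SimulationResult", "run", "penetration_mass", "penetration_percent"]

DRY_FRACTION = 1e-3  # relative water-volume / AI-mole threshold ending the drop


@dataclass
class SimulationResult:
    """Time series of the coupled simulation (single drop unless noted)."""

    p: ModelParameters
    d: DerivedConstants
    times: np.ndarray          # s
    theta: np.ndarray          # rad
    V: np.ndarray              # m^3
    r_drop: np.ndarray         # m
    A_drop: np.ndarray         # m^2
    c_AI_surf: np.ndarray      # mol/m^3
    V_Del: np.ndarray          # m^3
    mode: np.ndarray           # str codes CCR/CCA/DRY
    c_AI: np.ndarray           # (n_t, N_x) mol/m^3
    c_H2O: np.ndarray          # (n_t, N_x)
    n_drop: np.ndarray         # mol in drop
    m_bound: np.ndarray        # mol bound
    n_cut_in: np.ndarray       # mol pushed into the cuticle (net of bath), ledger
    n_bath: np.ndarray         # mol delivered to the bath
    m_pen_ug: np.ndarray       # cumulative penetration, ug (all drops)
    pct_pen: np.ndarray        # percent of applied AI mass
    events: list = field(default_factory=list)

    # ------------------------------------------------------------------
    @property
    def applied_mol(self) -> float:
        """AI moles applied per drop."""
        return self.p.c_AI_0_drop * self.p.V_0

    @property
    def audit(self) -> dict[str, np.ndarray]:
        """Mole ledger: applied = drop + bound + cuticle + bath."""
        return {
            "applied": np.full_like(self.times, self.applied_mol),
            "drop": self.n_drop,
            "bound": self.m_bound,
            "cuticle": self.n_cut_in - self.n_bath,
            "bath": self.n_bath,
        }

    def audit_error(self) -> np.ndarray:
        """Relative closure error of the mole ledger at each output time."""
        a = self.audit
        tot = a["drop"] + a["bound"] + a["cuticle"] + a["bath"]
        return np.abs(tot - a["applied"]) / a["applied"]

    def event_time(self, name: str) -> float | None:
        for n, t in self.events:
            if n == name:
                return t
        return None

    @property
    def drop_end_time(self) -> float | None:
        """Time the droplet stage ends (water depleted or AI exhausted), s."""
        for n, t in self.events:
            if n in ("dry_out", "ai_exhausted"):
                return t
        return None

    @property
    def final_pct(self) -> float:
        return float(self.pct_pen[-1])

    @property
    def bound_fraction(self) -> float:
        """Fraction of applied AI trapped by ion binding at t_final."""
        return float(self.m_bound[-1] / self.applied_mol)

    def droplet_frame(self):
        """Droplet trajectory as a pandas DataFrame (hours/degrees at I/O)."""
        import pandas as pd
        return pd.DataFrame({
            "t_h": self.times / 3600.0,
            "V_m3": self.V,
            "theta_deg": np.degrees(self.theta),
            "r_drop_m": self.r_drop,
            "A_drop_m2": self.A_drop,
            "c_AI_surf": self.c_AI_surf,
            "V_Del_m3": self.V_Del,
            "mode": self.mode,
        })

    def field_frame(self, t: float):
        """Cuticle profile snapshot nearest to time t (seconds)."""
        import pandas as pd
        i = int(np.argmin(np.abs(self.times - t)))
        N = self.c_AI.shape[1]
        dx = self.p.b / N
        x = (np.arange(N) + 0.5) * dx
        fld = tr.field_from_state(self.c_AI[i], self.c_H2O[i], self.p, self.d)
        return pd.DataFrame({"x_m": x, "c_AI": fld.c_AI, "c_H2O": fld.c_H2O,
                             "Gamma": fld.Gamma, "r_p": fld.r_p, "eps": fld.eps})


# ----------------------------------------------------------------------

class _System:
    """Packed right-hand side of the coupled system.

    State layout: [theta, V, n_drop, m_bound, n_cut_in, n_bath,
                   c_AI (N cells), c_H2O (N cells)].
    """

    def __init__(self, p: ModelParameters, d: DerivedConstants,
                 material: HygroscopicMaterial, hygroscopic_growth: bool):
        self.p, self.d = p, d
        self.material = material
        self.N = p.N_x
        cap0 = cap_from_volume(p.V_0, p.theta_0)
        self.r0, self.A0 = cap0.r_drop, cap0.A_drop
        self.theta_rec = p.theta_rec_eff
        hs = hygro_state(p, material)
        self.above_pod = hs.above_pod and hygroscopic_growth
        self.phi = hs.phi
        self.c_POD = hs.c_POD
        self.m_inf = hs.m_inf
        self.n0 = p.c_AI_0_drop * p.V_0

    # -- helpers -------------------------------------------------------
    def drop_geometry(self, mode: str, theta: float, V: float):
        if mode == "CCR":
            return self.r0, self.A0
        if V <= 0.0:
            return 0.0, 0.0
        cap = cap_from_volume(V, self.theta_rec)
        return cap.r_drop, cap.A_drop

    def c_surf(self, n: float, V: float) -> float:
        c = max(0.0, n) / max(V, 1e-16)
        if self.above_pod:
            # the POD cap keeps c below c_POD dynamically; bound the factor
            # when the solver probes past the dry-out event
            c = min(c, 5.0 * self.c_POD)
        return c

    def v_del(self, c_surf: float, V: float) -> float:
        if not self.above_pod:
            return 0.0
        return deliquescent_volume(c_surf, max(V, 0.0), self.phi, self.p,
                                   self.material)

    # -- RHS per mode --------------------------------------------------
    def rhs(self, t: float, y: np.ndarray, mode: str) -> np.ndarray:
        p, d, N = self.p, self.d, self.N
        cA = y[6:6 + N]
        cw = y[6 + N:]
        out = np.zeros_like(y)

        if mode == "DRY":
            dcA, dcw, *_ = tr.transport_rates(cA, cw, None, p, d)
            out[6:6 + N] = dcA
            out[6 + N:] = dcw
            return out

        theta = y[0] if mode == "CCR" else self.theta_rec
        V, n = y[1], y[2]
        c_surf = self.c_surf(n, V)
        r, A = self.drop_geometry(mode, theta, V)

        dcA, dcw, J_AI_0, J_AI_b, J_w_0 = tr.transport_rates(cA, cw, c_surf, p, d)

        dnc_dt, dbound_dt = drp.surface_ai_balance(c_surf, A, J_AI_0, p)

        if mode == "CCR":
            dtheta, dV = drp.ccr_rates(theta, V, self.r0, d)
            out[0] = dtheta
        else:
            if self.above_pod:
                dV = drp.cca_hygroscopic_rate(V, c_surf, self.v_del(c_surf, V),
                                              self.c_POD, A, J_w_0, p, d)
            else:
                dV = drp.cca_below_pod_rate(V, A, J_w_0, p, d)
        out[1] = dV
        out[2] = dnc_dt
        out[3] = dbound_dt
        out[4] = -p.flux_prefactor * A * J_AI_0   # into the cuticle
        out[5] = -p.flux_prefactor * A * J_AI_b   # into the bath
        out[6:6 + N] = dcA
        out[6 + N:] = dcw
        return out

    # -- events --------------------------------------------------------
    def make_events(self, mode: str):
        evs = []
        if mode == "CCR":
            def hit_receding(t, y, *args):
                return y[0] - self.theta_rec
            hit_receding.terminal = True
            hit_receding.direction = -1
            evs.append(("t_rec", hit_receding))
        if mode in ("CCR", "CCA"):
            def dry_out(t, y, *args):
                return y[1] - DRY_FRACTION * self.p.V_0
            dry_out.terminal = True
            dry_out.direction = -1
            evs.append(("dry_out", dry_out))

            def ai_exhausted(t, y, *args):
                return y[2] - DRY_FRACTION * self.n0
            ai_exhausted.terminal = True
            ai_exhausted.direction = -1
            evs.append(("ai_exhausted", ai_exhausted))
        return evs

    # -- sparsity ------------------------------------------------------
    def jac_sparsity(self):
        N = self.N
        m = 6 + 2 * N
        S = lil_matrix((m, m), dtype=np.int8)
        S[:6, :6] = 1
        for col in (6, 6 + N - 1, 6 + N, 6 + 2 * N - 1):
            S[:6, col] = 1
        for j in range(N):
            for row in (6 + j, 6 + N + j):
                for dj in (-1, 0, 1):
                    jj = j + dj
                    if 0 <= jj < N:
                        S[row, 6 + jj] = 1
                        S[row, 6 + N + jj] = 1
            if j == 0:
                S[6 + j, :3] = 1
                S[6 + N + j, :3] = 1
        return S.tocsr()


def _initial_state(sys_: _System) -> np.ndarray:
    p, d, N = sys_.p, sys_.d, sys_.N
    y0 = np.zeros(6 + 2 * N)
    y0[0] = p.theta_0
    y0[1] = p.V_0
    y0[2] = sys_.n0
    y0[6:6 + N] = 0.0
    y0[6 + N:] = d.c_H2O_pure
    return y0


def run(p: ModelParameters, exp=None, *, hygroscopic_growth: bool | None = None,
        material: HygroscopicMaterial = CACL2, strict: bool = False,
        n_output: int = 401) -> SimulationResult:
    """Integrate the coupled model from t = 0 to ``p.t_final``.

    ``exp`` (an :class:`~cutisim.experiments.ExperimentConfig`) may switch
    hygroscopic growth off, in which case the below-POD evaporation form is
    used throughout the CCA stage.  The forward model is deterministic.
    """
    p.validate()
    d = derive_constants(p)
    if hygroscopic_growth is None:
        hygroscopic_growth = getattr(exp, "hygroscopic_growth", True)
    sys_ = _System(p, d, material, hygroscopic_growth)
    sparsity = sys_.jac_sparsity()

    segments = []          # (mode, OdeSolution, t_start, t_end)
    events: list[tuple[str, float]] = []
    y = _initial_state(sys_)
    t = 0.0
    mode = "CCR"

    while t < p.t_final:
        ev_pairs = sys_.make_events(mode)
        sol = solve_ivp(sys_.rhs, (t, p.t_final), y, method="BDF",
                        args=(mode,), events=[f for _, f in ev_pairs] or None,
                        dense_output=True, rtol=p.rtol, atol=p.atol,
                        jac_sparsity=sparsity)
        if not sol.success:
            raise RuntimeError(f"integration failed in {mode} phase at "
                               f"t={sol.t[-1]:.3g} s: {sol.message}")
        t_end = sol.t[-1]
        segments.append((mode, sol.sol, t, t_end))
        y = sol.y[:, -1].copy()
        t = t_end

        fired = None
        for (name, _), te in zip(ev_pairs, sol.t_events or []):
            if len(te):
                fired = name
                break
        if fired is None:
            break
        events.append((fired, t))
        if fired == "t_rec":
            y[0] = sys_.theta_rec
            mode = "CCA"
        else:          # dry_out or ai_exhausted -> cuticle-only diffusion
            mode = "DRY"

    # ---- sample the solution ----------------------------------------
    t_grid = np.linspace(0.0, p.t_final, n_output)
    t_grid = np.unique(np.concatenate([t_grid, [te for _, te in events]]))
    t_grid = t_grid[t_grid <= segments[-1][3] + 1e-9]
    n_t = len(t_grid)
    N = p.N_x
    Y = np.empty((6 + 2 * N, n_t))
    modes = np.empty(n_t, dtype=object)
    for i, ti in enumerate(t_grid):
        for mname, interp, t0, t1 in segments:
            if ti <= t1 + 1e-9:
                Y[:, i] = interp(min(ti, t1))
                modes[i] = mname
                break

    theta = np.where(modes == "CCR", Y[0], sys_.theta_rec)
    dry = modes == "DRY"
    # n_drop stays at its raw ledger value after dry-out (surface residue),
    # keeping the mole audit closed; V is display-zeroed once the drop ends.
    n_drop = Y[2]
    V = np.where(dry, 0.0, np.clip(Y[1], 0.0, None))
    c_surf = np.array([sys_.c_surf(ni, vi) if not di else 0.0
                       for ni, vi, di in zip(n_drop, V, dry)])
    geom = [sys_.drop_geometry(m_, th, v_) for m_, th, v_ in zip(modes, theta, V)]
    r_drop = np.array([g[0] for g in geom])
    A_drop = np.array([g[1] for g in geom])
    V_Del = np.array([sys_.v_del(ci, vi) for ci, vi in zip(c_surf, V)])

    m_pen_ug = 1e6 * p.M_w_AI * p.n_drops * Y[5]
    pct = penetration_percent(m_pen_ug, p)

    res = SimulationResult(
        p=p, d=d, times=t_grid, theta=theta, V=V, r_drop=r_drop,
        A_drop=A_drop, c_AI_surf=c_surf, V_Del=V_Del, mode=modes,
        c_AI=Y[6:6 + N].T.copy(), c_H2O=Y[6 + N:].T.copy(),
        n_drop=n_drop, m_bound=Y[3], n_cut_in=Y[4], n_bath=Y[5],
        m_pen_ug=m_pen_ug, pct_pen=pct, events=events,
    )
    _check_invariants(res, strict=strict)
    return res


def _check_invariants(res: SimulationResult, strict: bool) -> None:
    msgs = []
    err = res.audit_error()
    if err.max() > 1e-6:
        msgs.append(f"mole audit closure {err.max():.2e} > 1e-6")
    if np.any(np.diff(res.pct_pen) < -1e-9):
        msgs.append("percent penetration decreased")
    if np.any(np.diff(res.m_bound) < -1e-12):
        msgs.append("bound AI decreased")
    Gmax = res.d.Gamma_S
    G = tr.langmuir_gamma(res.c_H2O, res.d.beta_H2O, Gmax)
    if np.any(G >= Gmax):
        msgs.append("adsorbed water reached the Langmuir saturation")
    for m in msgs:
        if strict:
            raise RuntimeError(m)
        warnings.warn(m, stacklevel=3)


# ----------------------------------------------------------------------

def penetration_mass(times: np.ndarray, A_drop: np.ndarray,
                     J_AI_b: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Cumulative penetration mass (ug) from the bath-face flux series.

    m(t) = -1e6 M_w,AI eta_pore A_Pi n_drops *
           cumulative_int A_drop [D_AI d(eps c_AI)/dx]|x=b dt.
    """
    from scipy.integrate import cumulative_trapezoid
    integrand = A_drop * J_AI_b
    integral = cumulative_trapezoid(integrand, times, initial=0.0)
    return -1e6 * p.M_w_AI * p.flux_prefactor * p.n_drops * integral


def bath_flux_series(res: SimulationResult) -> np.ndarray:
    """[D_AI d(eps c_AI)/dx]|x=b reconstructed at the output times."""
    N = res.c_AI.shape[1]
    dx = res.p.b / N
    out = np.empty(len(res.times))
    for i in range(len(res.times)):
        fld = tr.field_from_state(res.c_AI[i], res.c_H2O[i], res.p, res.d)
        out[i] = fld.D_AI[-1] * (0.0 - fld.eps[-1] * fld.c_AI[-1]) / (dx / 2.0)
    return out


def penetration_percent(m_ug: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Percent of the applied AI mass delivered to the bath.

    %pen = m / (1e9 c0[g/L] n_drops V_0) * 100.
    """
    applied_ug = 1e9 * p.c_AI_0_gL * p.n_drops * p.V_0
    if applied_ug <= 0:
        raise ValueError("zero applied AI mass: percent penetration undefined")
    return np.asarray(m_ug) / applied_ug * 100.0
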