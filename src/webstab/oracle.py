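"""Independent dynamical oracle: the Lotka–Volterra + detritus ODE system.

The community matrix built by :mod:`webstab.interaction` claims to be the
Jacobian of a generalized Lotka–Volterra system at the mass-balance
equilibrium.  This module reconstructs that system explicitly so the claim
can be checked by finite differences, with no shared code path:

* per-capita feeding coefficients recovered from equilibrium flows,
  a_ij = F*_ij / (X*_i · X*_j);
* intrinsic rates r_i solved so the supplied biomasses are an equilibrium
  of  dX_i/dt = X_i (r_i + e_i Σ_prey a_pi X_p − Σ_pred a_ij X_j);
* a detritus balance fed by egestion of all feeding (fraction 1−ac_j),
  carcasses of non-predation mortality (m_i X_i), a constant allochthonous
  import chosen to close the budget, and drained by detritivory.

Living-group self-limitation (the imposed diagonal −s·m_i) is *not* part
of the reconstructed dynamics — it is a matrix-level assumption, so the
finite-difference diagonal is excluded from comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .energetics import FlowMatrix, MortalityPartition, detritus_budget
from .webmodel import FoodWeb, WebValidationError

__all__ = ["OdeSystem", "assemble_ode", "numeric_jacobian", "simulate"]


@dataclass(frozen=True)
class OdeSystem:
    """Reconstructed dynamical system with the web's biomasses as an
    equilibrium (state ordering = web group ordering)."""

    names: tuple[str, ...]
    living: np.ndarray          # bool mask
    detritus_index: int
    a: np.ndarray               # per-capita feeding rates, prey × predator
    efficiency: np.ndarray      # e_j (0 for non-consumers)
    unassim: np.ndarray         # ac_j
    nonpred: np.ndarray         # m_i >= 0 (0 for detritus)
    r: np.ndarray               # intrinsic rates (0 for detritus)
    import_rate: float          # constant detritus input Rd
    equilibrium: np.ndarray     # X*

    def rhs(self, x: np.ndarray, selflim_s: float = 0.0) -> np.ndarray:
        """Time derivative of the state vector.

        ``selflim_s`` adds an explicit self-limitation
        −s·m_i·X_i·(X_i/X*_i − 1) to every living group: zero at the
        equilibrium, with Jacobian contribution exactly −s·m_i on the
        diagonal.  The base system (s = 0) carries no such term, because
        the imposed diagonal is a matrix-level assumption, not part of the
        reconstructed energetics.
        """
        x = np.asarray(x, dtype=float)
        d = self.detritus_index
        consumption = self.a * np.outer(x, x)  # flow prey i -> predator j
        gains = self.efficiency * consumption.sum(axis=0)
        losses = consumption.sum(axis=1)
        dx = np.where(self.living, x * self.r + gains - losses, 0.0)
        if selflim_s:
            dx -= np.where(
                self.living,
                selflim_s * self.nonpred * x * (x / self.equilibrium - 1.0),
                0.0,
            )
        egestion = float(((1.0 - self.unassim) * consumption.sum(axis=0)).sum())
        carcasses = float((self.nonpred * x)[self.living].sum())
        dx[d] = self.import_rate + egestion + carcasses - losses[d]
        return dx


def assemble_ode(
    web: FoodWeb, flows: FlowMatrix, mort: MortalityPartition
) -> OdeSystem:
    """Recover the ODE system whose equilibrium is the web's biomasses."""
    n = web.n
    x_star = np.array([g.biomass for g in web.groups])
    a = np.zeros((n, n))
    nz = flows.flows > 0
    a[nz] = flows.flows[nz] / np.outer(x_star, x_star)[nz]
    eff = np.array(
        [g.efficiency if g.role == "consumer" else 0.0 for g in web.groups]
    )
    ac = np.array(
        [g.unassim if g.role == "consumer" else 0.0 for g in web.groups]
    )
    m = np.where(np.isnan(mort.nonpred_rate), 0.0, mort.nonpred_rate)
    living = np.array([g.is_living for g in web.groups])

    # r_i so that each living group's per-capita growth is zero at X*
    gains = eff * (a * np.outer(x_star, x_star)).sum(axis=0) / x_star
    losses = (a * x_star[None, :]).sum(axis=1)
    r = np.where(living, losses - gains, 0.0)

    budget = detritus_budget(web, flows, mort)
    ode = OdeSystem(
        names=tuple(web.names),
        living=living,
        detritus_index=web.index(web.detritus.name),
        a=a,
        efficiency=eff,
        unassim=ac,
        nonpred=m,
        r=r,
        import_rate=budget.implied_import,
        equilibrium=x_star,
    )
    resid = np.max(np.abs(ode.rhs(x_star))) / np.max(x_star)
    if resid > 1e-9:
        raise WebValidationError(
            f"ODE assembly failed: equilibrium residual {resid:.3g} > 1e-9"
        )
    return ode


def numeric_jacobian(
    ode: OdeSystem,
    at: np.ndarray | None = None,
    rel_step: float = 1e-6,
    validate: bool = True,
    selflim_s: float = 0.0,
) -> np.ndarray:
    """Central finite-difference Jacobian of the right-hand side.

    With ``validate=True`` the result is recomputed at 10× the step and the
    two must agree (guards against a step in the truncation- or round-off-
    dominated regime).
    """
    x = ode.equilibrium if at is None else np.asarray(at, dtype=float)
    if np.any(x <= 0):
        raise ValueError("state must be strictly positive")

    def fd(h_rel: float) -> np.ndarray:
        n = x.size
        jac = np.empty((n, n))
        for j in range(n):
            h = h_rel * x[j]
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            jac[:, j] = (
                ode.rhs(xp, selflim_s) - ode.rhs(xm, selflim_s)
            ) / (2 * h)
        return jac

    jac = fd(rel_step)
    if validate:
        jac2 = fd(rel_step * 10)
        scale = np.max(np.abs(jac)) or 1.0
        if np.max(np.abs(jac - jac2)) > 1e-5 * scale * 10:
            raise ValueError(
                "finite-difference Jacobian is step-sensitive; "
                "choose a smaller relative step"
            )
    return jac


def simulate(
    ode: OdeSystem,
    x0: np.ndarray,
    horizon: float,
    steps: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    selflim_s: float = 0.0,
):
    """Integrate the system from ``x0`` over ``[0, horizon]`` (years).

    Uses a stiff-capable solver; states are clipped at zero inside the
    right-hand side (and any clip is reported in the returned record).
    Returns ``(t, trajectory, info)`` with trajectory of shape
    ``(steps, n)``.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    clipped = {"count": 0}

    def f(_t, x):
        if np.any(x < 0):
            clipped["count"] += 1
            x = np.maximum(x, 0.0)
        return ode.rhs(x, selflim_s)

    t_eval = np.linspace(0.0, horizon, steps)
    sol = solve_ivp(
        f, (0.0, horizon), x0, method="LSODA", t_eval=t_eval,
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t = {sol.t[-1] if sol.t.size else 0:.4g}: "
            f"{sol.message}"
        )
    info = {"clipped_evaluations": clipped["count"], "message": sol.message}
    return sol.t, sol.y.T, info
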