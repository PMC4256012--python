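"""Macroscopic utility functions derived from the microscopic SMDP.

A trial outcome of ``K`` (possibly fractional) reward cycles and ``L``
seconds of cumulative leisure constrains the per-cycle policy through the
consistency condition ``K * E_pi[tau] = L``.  Scoring the policy by its
per-cycle microscopic utilities plus the entropy bonus, and enforcing the
consistency condition with a Lagrange multiplier ``lambda``, the optimal
constrained policy is the softmax with ``lambda`` in the role of the reward
rate:

    pi_lambda(tau) ∝ exp(beta * (U_L(tau) - lambda * tau)),

with ``lambda`` root-found so that ``E[tau] = L / K``.  At the
budget-constrained optimum the multiplier — the shadow price of leisure
time — equals the SMDP's average reward rate ``rho``.

The derived macroscopic utility evaluated at that constrained optimum is

    W(K, L) = K * (R_I + E[U_L] + H(pi_lambda)/beta + f(L/K)),

where ``f`` is the correction enforcing the average-foregone-reward
accounting.  ``f`` is constructed numerically here: it solves the linear
ODE ``f(l) - (l + P) f'(l) = -H(pi_lambda(l)) / beta``, which is precisely
the condition under which the budget-line optimum of ``W`` coincides with
the micro fixed point when the reward rate contains only microscopic
utilities.  (If the entropy bonus is included in the rate —
``include_entropy_in_rate=True`` — no correction is needed and ``f = 0``.)
``f`` is determined up to a multiple of ``(l + P)``, i.e. of ``L + K*P``,
which is constant on every budget line and therefore immaterial to optima;
the quadrature is anchored at the lower end of the tabulated range.

Limits: with deterministic choice (``beta = inf``) each cycle takes leisure
``l = L/K`` exactly and ``W(K, L) = K * (R_I + U_L(L/K))``; for linear
``U_L`` this is the affine perfect-substitutes utility ``R_I K + C_L L`` of
labor supply theory, and the finite-beta form converges to it pointwise as
``beta`` grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
from scipy import optimize
from scipy.interpolate import CubicSpline

from .leisure_utility import LeisureUtility, UtilityForm
from .macro_behavior import MacroAllocation, time_allocation
from .smdp_core import (
    PolicySettings,
    TaskSpec,
    _gibbs_density,
    _policy_stats,
    deterministic_policy,
    solve,
)
from .classical_macro import BudgetConstraint

__all__ = [
    "DerivedMacroUtility",
    "InfeasibleLeisureError",
    "constrained_policy",
    "derive",
    "macro_optimum",
    "consistency_check",
]


class InfeasibleLeisureError(ValueError):
    """Requested per-cycle leisure mean is not achievable by any finite
    multiplier."""


@dataclass
class _GibbsPoint:
    lam: float
    density: np.ndarray
    lnZ: float
    mean: float
    mean_u: float
    entropy: float


def _gibbs_at(lam: float, grid: np.ndarray, u_vals: np.ndarray,
              beta: float) -> _GibbsPoint:
    density, lnZ = _gibbs_density(u_vals - lam * grid, beta, grid)
    mean, mean_u, entropy = _policy_stats(density, grid, u_vals)
    return _GibbsPoint(lam, density, lnZ, mean, mean_u, entropy)


def _lambda_for_mean(
    target: float,
    grid: np.ndarray,
    u_vals: np.ndarray,
    beta: float,
    guess: float = 0.0,
) -> _GibbsPoint:
    """Root-find the multiplier whose softmax mean equals ``target``.

    The mean is strictly decreasing in ``lambda``; brackets are expanded
    geometrically from ``guess``.
    """
    tau_max = grid[-1]
    if not 0.0 < target < tau_max:
        raise InfeasibleLeisureError(
            f"per-cycle leisure mean {target} outside (0, {tau_max})"
        )

    def resid(lam: float) -> float:
        return _gibbs_at(lam, grid, u_vals, beta).mean - target

    lo = hi = guess
    step = max(1.0, abs(guess)) * 0.5
    r0 = resid(guess)
    if r0 > 0:  # mean too large -> raise lambda
        for _ in range(200):
            hi = hi + step
            if resid(hi) <= 0:
                break
            step *= 2.0
        else:
            raise InfeasibleLeisureError("could not bracket the multiplier")
        lo = hi - step
    elif r0 < 0:
        for _ in range(200):
            lo = lo - step
            if resid(lo) >= 0:
                break
            step *= 2.0
        else:
            raise InfeasibleLeisureError("could not bracket the multiplier")
        hi = lo + step
    else:
        return _gibbs_at(guess, grid, u_vals, beta)
    lam = float(optimize.brentq(resid, lo, hi, xtol=1e-13, rtol=8.9e-16))
    return _gibbs_at(lam, grid, u_vals, beta)


def constrained_policy(
    u: LeisureUtility,
    beta: float,
    L_per_cycle: float,
    tau_max: float,
    grid_n: int = 2001,
    lam_guess: float = 0.0,
):
    """Softmax policy constrained to a given per-cycle leisure mean.

    Returns ``(grid, density, lam)`` with ``E[tau] = L_per_cycle`` to root
    tolerance.  Raises :class:`InfeasibleLeisureError` if the mean is
    outside the achievable open interval ``(0, tau_max)``.
    """
    if not 0.0 < beta < math.inf:
        raise ValueError("constrained_policy requires finite beta > 0")
    grid = np.linspace(0.0, tau_max, grid_n)
    pt = _lambda_for_mean(L_per_cycle, grid, u._values(grid), beta,
                          guess=lam_guess)
    return grid, pt.density, pt.lam


@dataclass
class DerivedMacroUtility:
    """Macroscopic utility induced by a microscopic utility of leisure.

    ``evaluator(K, L)`` is the derived utility; ``afr_correction`` the
    numerically constructed ``f``; ``lam`` holds the consistency
    multiplier at the most recent budget-line optimum (the shadow price,
    equal to the reward rate there).
    """

    u: LeisureUtility
    beta: float
    task: TaskSpec
    include_entropy_in_rate: bool = False
    grid_n: int = 2001
    lam: Optional[float] = None
    # tabulated construction (finite beta only)
    _ell: Optional[np.ndarray] = field(default=None, repr=False)
    _splines: Optional[Dict[str, CubicSpline]] = field(default=None,
                                                       repr=False)
    _grid: Optional[np.ndarray] = field(default=None, repr=False)
    _u_vals: Optional[np.ndarray] = field(default=None, repr=False)

    # -- pieces -----------------------------------------------------------

    def afr_correction(self, ell):
        """The AFR-enforcing correction ``f(l)`` (zero at beta = inf or
        with the entropy-consistent rate)."""
        if math.isinf(self.beta) or self.include_entropy_in_rate:
            return np.zeros_like(np.asarray(ell, dtype=float)) if np.ndim(ell) else 0.0
        f = self._splines["f"](ell)
        return f if np.ndim(ell) else float(f)

    def lambda_at(self, ell: float, refine: bool = False) -> float:
        """Consistency multiplier for per-cycle leisure ``ell``."""
        if math.isinf(self.beta):
            return float(self.u.marginal(max(ell, 1e-300)))
        lam = float(self._splines["lam"](ell))
        if refine:
            lam = _lambda_for_mean(ell, self._grid, self._u_vals, self.beta,
                                   guess=lam).lam
        return lam

    # -- evaluation -------------------------------------------------------

    def evaluator(self, K, L):
        """Derived macroscopic utility ``W(K, L)``.

        Finite for ``K > 0`` and per-cycle leisure ``L/K`` inside the
        tabulated range; vectorized over arrays.
        """
        K = np.asarray(K, dtype=float)
        L = np.asarray(L, dtype=float)
        scalar = not (K.ndim or L.ndim)
        K, L = np.broadcast_arrays(np.atleast_1d(K), np.atleast_1d(L))
        with np.errstate(divide="ignore", invalid="ignore"):
            ell = np.where(K > 0, L / np.maximum(K, 1e-300), np.inf)
        if math.isinf(self.beta):
            vals = np.asarray(self.u._values(np.maximum(ell, 0.0)))
            out = K * (self.task.R_I + vals)
            out = np.where(K == 0, 0.0, out)
        else:
            lo, hi = self._ell[0], self._ell[-1]
            if np.any((ell < lo) | (ell > hi)):
                raise ValueError(
                    "per-cycle leisure L/K outside the tabulated range "
                    f"[{lo:.4g}, {hi:.4g}]"
                )
            sp = self._splines
            per_cycle = (
                self.task.R_I
                + sp["mean_u"](ell)
                + sp["entropy"](ell) / self.beta
                + (0.0 if self.include_entropy_in_rate else sp["f"](ell))
            )
            # with the entropy-consistent rate the entropy term stays and
            # f vanishes; otherwise f repairs the AFR accounting
            out = K * per_cycle
        return float(out[0]) if scalar else out

    __call__ = evaluator


def derive(
    u: LeisureUtility,
    beta: float,
    task: TaskSpec,
    include_entropy_in_rate: bool = False,
    grid_n: int = 2001,
    n_ell: int = 257,
) -> DerivedMacroUtility:
    """Construct the macroscopic utility induced by ``U_L`` at inverse
    temperature ``beta`` for the given task.

    For finite ``beta`` the constrained-softmax statistics and the
    correction ``f`` are tabulated on a per-cycle-leisure grid and exposed
    through cubic splines; ``beta = inf`` uses the closed deterministic
    form ``K * (R_I + U_L(L/K))``.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    w = DerivedMacroUtility(
        u=u,
        beta=beta,
        task=task,
        include_entropy_in_rate=include_entropy_in_rate,
        grid_n=grid_n,
    )
    if math.isinf(beta):
        return w
    if beta == 0.0:
        raise ValueError(
            "beta = 0 admits only the uniform policy; no macroscopic "
            "utility over (K, L) can be derived from it"
        )
    grid = np.linspace(0.0, task.tau_max, grid_n)
    u_vals = u._values(grid)
    ell = np.linspace(1e-3 * task.tau_max, 0.995 * task.tau_max, n_ell)
    lam = np.empty(n_ell)
    mean_u = np.empty(n_ell)
    entropy = np.empty(n_ell)
    lnZ = np.empty(n_ell)
    guess = task.R_I / task.P
    for i, l in enumerate(ell):
        pt = _lambda_for_mean(l, grid, u_vals, beta, guess=guess)
        lam[i] = guess = pt.lam
        mean_u[i] = pt.mean_u
        entropy[i] = pt.entropy
        lnZ[i] = pt.lnZ
    P = task.P
    integrand = entropy / (beta * (ell + P) ** 2)
    F = CubicSpline(ell, integrand).antiderivative()
    f = (ell + P) * (F(ell) - F(ell[0]))
    w._ell = ell
    w._grid = grid
    w._u_vals = u_vals
    w._splines = {
        "lam": CubicSpline(ell, lam),
        "mean_u": CubicSpline(ell, mean_u),
        "entropy": CubicSpline(ell, entropy),
        "lnZ": CubicSpline(ell, lnZ),
        "f": CubicSpline(ell, f),
    }
    return w


def macro_optimum(w: DerivedMacroUtility, bc: BudgetConstraint) -> MacroAllocation:
    """Maximize the derived utility over the budget line ``K*P + L = T``.

    The line is parameterized by the per-cycle leisure ``l`` (so that
    ``K = T/(P+l)``, ``L = K*l``); for finite ``beta`` the interior
    stationarity condition of the evaluator,

        lambda(l) * P = R_I + lnZ(lambda)/beta - H(pi_lambda)/beta,

    (entropy term absent when it is included in the rate) is solved by
    bracketing, with a spline scan as fallback.  ``beta = inf`` maximizes
    ``T * (R_I + U_L(l)) / (P + l)`` directly, corners included.  The
    consistency multiplier at the optimum is stored on ``w.lam``.
    """
    if abs(bc.P - w.task.P) > 1e-12 * max(1.0, w.task.P):
        raise ValueError(
            "budget price must match the task the utility was derived for"
        )
    task = w.task
    T, P = bc.T, bc.P
    if math.isinf(w.beta):
        pol = deterministic_policy(task, w.u, grid_n=w.grid_n)
        ell_star = pol.mean_leisure
        w.lam = pol.rho
    else:
        grid, u_vals, beta = w._grid, w._u_vals, w.beta
        inc = w.include_entropy_in_rate

        def stationarity(l: float) -> float:
            pt = _lambda_for_mean(l, grid, u_vals, beta,
                                  guess=float(w._splines["lam"](l)))
            g = pt.lam * P - task.R_I - pt.lnZ / beta
            if not inc:
                g += pt.entropy / beta
            return g

        lo, hi = w._ell[0], w._ell[-1]
        glo, ghi = stationarity(lo), stationarity(hi)
        if glo * ghi <= 0:
            ell_star = float(
                optimize.brentq(stationarity, lo, hi, xtol=1e-11)
            )
        else:  # no interior stationary point in range: scan the evaluator
            ells = np.linspace(lo, hi, 2049)
            vals = w.evaluator(T / (P + ells), ells * T / (P + ells))
            ell_star = float(ells[int(np.argmax(vals))])
        w.lam = _lambda_for_mean(
            ell_star, grid, u_vals, beta,
            guess=float(w._splines["lam"](ell_star))
        ).lam
    K = T / (P + ell_star)
    W_total = K * P
    return MacroAllocation(K=K, W_total=W_total, L_total=T - W_total,
                           TA=W_total / T)


def consistency_check(
    u: LeisureUtility,
    beta: float,
    task: TaskSpec,
    bc: Optional[BudgetConstraint] = None,
    include_entropy_in_rate: bool = False,
    grid_n: int = 2001,
) -> Dict[str, float]:
    """Compare the budget-line optimum of the derived macroscopic utility
    with the microscopic SMDP's average allocation.

    Returns ``{TA_macro, TA_micro, delta_TA, lambda, rho, delta}``;
    discrepancies are reported, never raised.
    """
    bc = bc if bc is not None else BudgetConstraint(T=task.T, P=task.P)
    pol = solve(
        task,
        u,
        PolicySettings(
            beta=beta,
            grid_n=grid_n,
            include_entropy_in_rate=include_entropy_in_rate,
        ),
    )
    ta_micro = time_allocation(pol, task)
    w = derive(u, beta, task, include_entropy_in_rate=include_entropy_in_rate,
               grid_n=grid_n)
    alloc = macro_optimum(w, bc)
    return {
        "TA_macro": alloc.TA,
        "TA_micro": ta_micro,
        "delta_TA": abs(alloc.TA - ta_micro),
        "lambda": w.lam,
        "rho": pol.rho,
        "delta": abs(w.lam - pol.rho),
    }
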