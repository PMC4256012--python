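"""Traditional macroscopic accounts: CES labor supply and generalized
matching.

Labor supply theory scores a trial outcome of ``K`` rewards and ``L``
seconds of cumulative leisure with a constant-elasticity-of-substitution
aggregate

    U(K, L) = ((w_K K)^sigma + (w_L L)^sigma)^(1/sigma),   0 < sigma <= 1,

maximized on the time budget ``K P + L = T``.  ``sigma = 1`` (perfect
substitutes: straight-line indifference curves) yields all-or-none
allocation by the sign of the work/leisure return comparison; ``sigma < 1``
(imperfect substitutes) yields an interior tangency and partial allocation.

The generalized matching law instead posits that the odds of working equal
the payoff ratio raised to a matching exponent ``a``:

    TA / (1 - TA) = (q_w / q_l)^a,     q_w = R_I / P,

with the leisure payoff anchored at ``q_l = R_max / P_e`` so that
``TA(R_max, P_e) = 1/2``.  Over an (R_I, P) grid this traces the "mountain"
surface, whose iso-TA contours rise smoothly with reward intensity and fall
smoothly with price.  ``a > 1`` is over-matching (steeper TA), ``a < 1``
under-matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence

import numpy as np

from .macro_behavior import MacroAllocation, SweepResult, contours as _contours

__all__ = [
    "CESParams",
    "BudgetConstraint",
    "MountainParams",
    "ces_utility",
    "optimal_allocation",
    "indifference_curves",
    "matching_ta",
    "mountain_surface",
]


@dataclass(frozen=True)
class CESParams:
    """CES substitutability exponent and good weights.

    ``w_K`` is utility per reward (typically the reward intensity) and
    ``w_L`` utility per second of leisure (typically the linear marginal
    utility of leisure).
    """

    sigma: float
    w_K: float
    w_L: float

    def __post_init__(self) -> None:
        if not 0.0 < self.sigma <= 1.0:
            raise ValueError("sigma must lie in (0, 1]")
        if self.w_K < 0 or self.w_L < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class BudgetConstraint:
    """Feasible set {(K, L): K*P + L = T, K >= 0, L >= 0}."""

    T: float
    P: float

    def __post_init__(self) -> None:
        if self.T < 0 or self.P <= 0:
            raise ValueError("need T >= 0 and P > 0")


@dataclass(frozen=True)
class MountainParams:
    """Matching exponent ``a`` and the (P_e, R_max) half-allocation anchor."""

    a: float
    P_e: float
    R_max: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.P_e <= 0 or self.R_max <= 0:
            raise ValueError("all mountain parameters must be positive")


def ces_utility(K, L, p: CESParams):
    """Two-good CES aggregate of ``w_K*K`` and ``w_L*L``."""
    K = np.asarray(K, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(K < 0) or np.any(L < 0):
        raise ValueError("goods must be non-negative")
    a = p.w_K * K
    b = p.w_L * L
    if p.sigma == 1.0:
        out = a + b
    else:
        out = (a ** p.sigma + b ** p.sigma) ** (1.0 / p.sigma)
    return out if (np.ndim(K) or np.ndim(L)) else float(out)


def optimal_allocation(p: CESParams, bc: BudgetConstraint) -> MacroAllocation:
    """Maximize the CES utility on the budget line ``K*P + L = T``.

    ``sigma = 1``: corner solution by the return comparison
    (``w_K/P`` vs ``w_L``; ties go to work).  ``sigma < 1``: interior
    tangency, solved in closed form from the first-order condition
    ``(K/L)^(sigma-1) = P * w_L^sigma / w_K^sigma``.
    """
    T, P = bc.T, bc.P
    if T == 0:
        return MacroAllocation(K=0.0, W_total=0.0, L_total=0.0, TA=0.0)
    if p.w_K == 0 and p.w_L == 0:
        return MacroAllocation(K=0.0, W_total=0.0, L_total=T, TA=0.0)
    if p.sigma == 1.0 or p.w_L == 0 or p.w_K == 0:
        work = p.w_K / P >= p.w_L
        if p.w_K == 0:
            work = False
        if work:
            return MacroAllocation(K=T / P, W_total=T, L_total=0.0, TA=1.0)
        return MacroAllocation(K=0.0, W_total=0.0, L_total=T, TA=0.0)
    ratio = (P * p.w_L ** p.sigma / p.w_K ** p.sigma) ** (
        1.0 / (p.sigma - 1.0)
    )  # K per unit L at the tangency
    L = T / (1.0 + P * ratio)
    K = ratio * L
    W = K * P
    return MacroAllocation(K=K, W_total=W, L_total=L, TA=W / T)


def indifference_curves(
    utility: Callable[[np.ndarray, np.ndarray], np.ndarray],
    levels: Sequence[float],
    L_max: float,
    K_max: float,
    n: int = 201,
) -> Dict[float, List[np.ndarray]]:
    """Iso-utility polylines of ``utility(K, L)`` in the (L, K) plane.

    Returns ``{level: [(m, 2) arrays of (L, K) vertices, ...]}``.
    """
    from skimage import measure

    L_grid = np.linspace(0.0, L_max, n)
    K_grid = np.linspace(0.0, K_max, n)
    LL, KK = np.meshgrid(L_grid, K_grid)  # rows: K, cols: L
    U = np.asarray(utility(KK, LL), dtype=float)
    out: Dict[float, List[np.ndarray]] = {}
    for level in levels:
        polys = []
        for seg in measure.find_contours(U, level):
            K = np.interp(seg[:, 0], np.arange(n), K_grid)
            L = np.interp(seg[:, 1], np.arange(n), L_grid)
            polys.append(np.column_stack([L, K]))
        out[level] = polys
    return out


def matching_ta(R_I, P, m: MountainParams):
    """Generalized-matching time allocation.

    ``TA = q_w^a / (q_w^a + q_l^a)`` with work payoff ``q_w = R_I/P`` and
    leisure payoff ``q_l = R_max/P_e`` (the anchor at which TA = 1/2).
    """
    R_I = np.asarray(R_I, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(R_I <= 0) or np.any(P <= 0):
        raise ValueError("reward intensity and price must be positive")
    log_odds = m.a * (np.log(R_I / P) - np.log(m.R_max / m.P_e))
    out = 1.0 / (1.0 + np.exp(-log_odds))
    return out if (np.ndim(R_I) or np.ndim(P)) else float(out)


def mountain_surface(
    R_I_grid: Sequence[float], P_grid: Sequence[float], m: MountainParams
) -> SweepResult:
    """Matching-law TA surface over an (R_I, P) grid."""
    R_I_grid = np.asarray(R_I_grid, dtype=float)
    P_grid = np.asarray(P_grid, dtype=float)
    if np.any(np.diff(R_I_grid) <= 0) or np.any(np.diff(P_grid) <= 0):
        raise ValueError("grids must be sorted ascending")
    TA = matching_ta(R_I_grid[:, None], P_grid[None, :], m)
    return SweepResult(R_I_grid, P_grid, TA)


mountain_contours = _contours
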