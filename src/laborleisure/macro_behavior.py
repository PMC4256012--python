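"""Macroscopic observables of solved microscopic policies.

Time allocation (TA) is the proportion of trial time spent working.  For a
stationary cycle of one price-long work bout followed by a leisure bout of
mean length ``E[tau]``, ``TA = P / (P + E[tau])``; this per-cycle quantity
equals ``W_total / T`` when the trial holds whole cycles.  Finite-trial
(sampled) TA lives in :mod:`laborleisure.ethogram_sim`.

``sweep`` solves the SMDP over a grid of reward intensities and prices and
records TA, the reward rate, and the mean and mode of the leisure-duration
distribution — the microscopically derived analogue of the matching-law
"mountain".  ``contours`` extracts iso-TA polylines by marching squares
with linear interpolation and no smoothing (smoothing could manufacture or
hide the non-monotonic contour structure that concave leisure utility
produces at long prices).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .leisure_utility import LeisureUtility
from .smdp_core import PolicySettings, SolvedPolicy, TaskSpec, solve

__all__ = [
    "MacroAllocation",
    "SweepResult",
    "time_allocation",
    "allocation_from_policy",
    "sweep",
    "contours",
]


@dataclass(frozen=True)
class MacroAllocation:
    """Macroscopic allocation over one trial.

    ``K`` may be fractional; ``W_total = K * P`` and
    ``W_total + L_total = T`` (up to roundoff) when built from a trial.
    """

    K: float
    W_total: float
    L_total: float
    TA: float


@dataclass
class SweepResult:
    """TA / rate / leisure-moment surfaces over an (R_I, P) grid.

    Matrices are indexed ``[i_R, j_P]``.  Fields other than ``TA`` may be
    ``None`` for surfaces that do not define them (e.g. the matching-law
    mountain).
    """

    R_I_grid: np.ndarray
    P_grid: np.ndarray
    TA: np.ndarray
    rho: Optional[np.ndarray] = None
    mean_leisure: Optional[np.ndarray] = None
    mode_leisure: Optional[np.ndarray] = None
    converged: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns R_I, P_s, rho, mean_leisure_s,
        mode_leisure_s, TA, converged."""
        nR, nP = self.TA.shape
        R = np.repeat(self.R_I_grid, nP)
        P = np.tile(self.P_grid, nR)

        def flat(m, fill=np.nan):
            return m.ravel() if m is not None else np.full(nR * nP, fill)

        return pd.DataFrame(
            {
                "R_I": R,
                "P_s": P,
                "rho": flat(self.rho),
                "mean_leisure_s": flat(self.mean_leisure),
                "mode_leisure_s": flat(self.mode_leisure),
                "TA": self.TA.ravel(),
                "converged": flat(self.converged, True).astype(bool),
            }
        )


def time_allocation(policy: SolvedPolicy, task: Optional[TaskSpec] = None) -> float:
    """Per-cycle time allocation ``P / (P + E[tau])`` of a solved policy."""
    task = task if task is not None else policy.task
    return task.P / (task.P + policy.mean_leisure)


def allocation_from_policy(
    policy: SolvedPolicy, task: Optional[TaskSpec] = None
) -> MacroAllocation:
    """Fractional-cycle allocation of a whole trial of length ``T``."""
    task = task if task is not None else policy.task
    K = task.T / (task.P + policy.mean_leisure)
    W = K * task.P
    return MacroAllocation(K=K, W_total=W, L_total=task.T - W, TA=W / task.T)


def sweep(
    R_I_grid: Sequence[float],
    P_grid: Sequence[float],
    u: LeisureUtility,
    settings: PolicySettings = PolicySettings(),
    tau_max: Optional[float] = None,
) -> SweepResult:
    """Solve the SMDP at every (R_I, P) cell.

    ``tau_max=None`` uses each cell's default range ``20 * P`` (the
    admissible leisure range scales with the trial, whose length is a
    multiple of the price); pass a float to pin a common range.
    Non-converged cells are flagged, not raised.
    """
    R_I_grid = np.asarray(R_I_grid, dtype=float)
    P_grid = np.asarray(P_grid, dtype=float)
    if np.any(np.diff(R_I_grid) <= 0) or np.any(np.diff(P_grid) <= 0):
        raise ValueError("grids must be sorted ascending")
    if np.any(R_I_grid <= 0) or np.any(P_grid <= 0):
        raise ValueError("grids must be positive")
    shape = (R_I_grid.size, P_grid.size)
    TA = np.empty(shape)
    rho = np.empty(shape)
    mean = np.empty(shape)
    mode = np.empty(shape)
    conv = np.empty(shape, dtype=bool)
    for i, R in enumerate(R_I_grid):
        for j, P in enumerate(P_grid):
            task = TaskSpec(R_I=R, P=P, tau_max=tau_max)
            pol = solve(task, u, settings)
            TA[i, j] = time_allocation(pol, task)
            rho[i, j] = pol.rho
            mean[i, j] = pol.mean_leisure
            if pol.is_point:
                mode[i, j] = pol.atom
            else:
                mode[i, j] = pol.grid[int(np.argmax(pol.density))]
            conv[i, j] = pol.converged
    return SweepResult(R_I_grid, P_grid, TA, rho, mean, mode, conv)


def contours(
    result: SweepResult, levels: Sequence[float]
) -> Dict[float, List[np.ndarray]]:
    """Iso-TA polylines in (R_I, P) space by marching squares.

    Returns ``{level: [polyline, ...]}`` where each polyline is an
    ``(n, 2)`` array of (R_I, P) vertices.  An empty list means the level
    does not cross the surface.
    """
    out: Dict[float, List[np.ndarray]] = {}
    nR = result.R_I_grid.size
    nP = result.P_grid.size
    for level in levels:
        if not 0.0 < level < 1.0:
            raise ValueError("TA contour levels must lie in (0, 1)")
        polys = []
        for seg in measure.find_contours(result.TA, level):
            R = np.interp(seg[:, 0], np.arange(nR), result.R_I_grid)
            P = np.interp(seg[:, 1], np.arange(nP), result.P_grid)
            polys.append(np.column_stack([R, P]))
        out[level] = polys
    return out
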