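"""Two-state average-reward semi-Markov decision process for labor/leisure.

The subject cycles between a pre-reward state, in which it pre-commits to
working for the entire price ``P`` and then collects a reward of subjective
intensity ``R_I``, and a post-reward state, in which it chooses a leisure
duration ``tau`` from ``[0, tau_max]``.  A policy ``pi(tau)`` is scored by its
long-run average reward rate

    rho = (R_I + E_pi[U_L(tau)]) / (P + E_pi[tau]),

the ratio of the expected microscopic utility accumulated per cycle to the
expected cycle length.  The differential Q-value of a leisure bout is

    Q_post(tau) = U_L(tau) - rho * tau + V_pre,

where ``rho * tau`` is the average foregone reward (AFR): the mean return
sacrificed by committing to leisure for ``tau`` seconds.  Choices maximize
expected return plus an entropy bonus ``H(pi)/beta``, which yields the
softmax policy

    pi(tau) ∝ exp(beta * Q_post(tau))            on [0, tau_max].

``beta -> inf`` recovers deterministic, optimal choice; ``beta = 0`` gives
the uniform density over the admissible range.  The solver finds the joint
fixed point of the policy and the reward rate.

Durations are represented on a uniform grid with trapezoidal quadrature;
densities (utility per second of probability mass) are the canonical policy
representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Union

import numpy as np
from scipy import optimize, special

from .leisure_utility import LeisureUtility, UtilityForm

__all__ = [
    "TaskSpec",
    "PolicySettings",
    "SolvedPolicy",
    "LeisureDistribution",
    "DistributionFamily",
    "ClosedFormUnavailable",
    "q_leisure",
    "q_work",
    "softmax_policy",
    "reward_rate",
    "solve",
    "deterministic_policy",
    "closed_form_distribution",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskSpec:
    """The experimental contingency.

    Parameters
    ----------
    R_I
        Subjective reward intensity (utility units), > 0 in normal use.
    P
        Price: cumulative work time required per reward (seconds, > 0).
    tau_max
        Upper bound of the admissible leisure-duration range (seconds).
        Defaults to ``20 * P``, wide enough to dominate the mean leisure
        duration at the lowest payoffs explored.
    T
        Trial duration (seconds). Defaults to ``25 * P``.
    """

    R_I: float
    P: float
    tau_max: Optional[float] = None
    T: Optional[float] = None

    def __post_init__(self) -> None:
        if self.P <= 0:
            raise ValueError("price P must be positive")
        if self.tau_max is None:
            object.__setattr__(self, "tau_max", 20.0 * self.P)
        if self.T is None:
            object.__setattr__(self, "T", 25.0 * self.P)
        if self.tau_max <= 0:
            raise ValueError("tau_max must be positive")
        if self.T < self.P:
            raise ValueError("trial duration T must be at least one price")


@dataclass(frozen=True)
class PolicySettings:
    """Solver settings.

    ``beta`` is the inverse temperature (``math.inf`` allowed: deterministic
    choice); ``include_entropy_in_rate`` switches the reward rate to the
    entropy-consistent variant ``(R_I + E[U_L] + H/beta) / (P + E[tau])``.
    """

    beta: float = 1.0
    grid_n: int = 2001
    include_entropy_in_rate: bool = False
    solver: str = "iterate"  # "iterate" (damped) or "root" (bracketing)
    tol: float = 1e-10
    max_iter: int = 10000
    damping: float = 0.5

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.grid_n < 2:
            raise ValueError("grid_n must be >= 2")
        if self.solver not in ("iterate", "root"):
            raise ValueError("solver must be 'iterate' or 'root'")
        if self.include_entropy_in_rate and not (
            0.0 < self.beta < math.inf
        ):
            raise ValueError(
                "entropy term in the rate requires finite beta > 0"
            )


@dataclass
class SolvedPolicy:
    """A solved leisure-duration policy with its summary quantities.

    For stochastic policies ``density`` holds ``pi(tau)`` on ``grid`` and
    ``atom`` is ``None``; for deterministic (point) policies ``density`` is
    ``None`` and ``atom`` is the chosen duration.  ``V_post`` is anchored at
    0 (differential values are defined up to an additive constant) and
    ``V_pre = R_I - rho * P``.
    """

    grid: np.ndarray
    density: Optional[np.ndarray]
    atom: Optional[float]
    rho: float
    mean_leisure: float
    mean_U_L: float
    entropy: float
    V_pre: float
    V_post: float
    converged: bool
    iterations: int
    beta: float
    task: TaskSpec
    u: LeisureUtility

    @property
    def is_point(self) -> bool:
        return self.atom is not None


class DistributionFamily(str, Enum):
    TRUNCATED_EXPONENTIAL = "truncated_exponential"
    TRUNCATED_GAMMA = "truncated_gamma"
    POINT = "point"
    UNIFORM = "uniform"


class ClosedFormUnavailable(Exception):
    """No closed-form leisure-duration distribution for this utility."""


@dataclass(frozen=True)
class LeisureDistribution:
    """Closed-form leisure-duration distribution on ``[0, truncation]``.

    ``truncated_exponential``: density ∝ exp(-rate * tau); a negative rate
    is admissible and means the density increases toward the truncation
    point.  ``truncated_gamma``: density ∝ tau^(shape-1) exp(-rate * tau).
    """

    family: DistributionFamily
    truncation: float
    rate: Optional[float] = None
    shape: Optional[float] = None
    atom: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", DistributionFamily(self.family))
        if self.truncation <= 0:
            raise ValueError("truncation must be positive")
        fam = self.family
        if fam is DistributionFamily.TRUNCATED_EXPONENTIAL and self.rate is None:
            raise ValueError("truncated_exponential requires a rate")
        if fam is DistributionFamily.TRUNCATED_GAMMA:
            if self.rate is None or self.shape is None:
                raise ValueError("truncated_gamma requires shape and rate")
            if self.shape <= 0 or self.rate <= 0:
                raise ValueError("gamma shape and rate must be positive")
        if fam is DistributionFamily.POINT:
            if self.atom is None or not 0 <= self.atom <= self.truncation:
                raise ValueError("point family requires an atom in range")

    # -- shape on a grid --------------------------------------------------

    def _log_shape(self, tau: np.ndarray) -> np.ndarray:
        fam = self.family
        if fam is DistributionFamily.TRUNCATED_EXPONENTIAL:
            return -self.rate * tau
        if fam is DistributionFamily.TRUNCATED_GAMMA:
            with np.errstate(divide="ignore", invalid="ignore"):
                out = (self.shape - 1.0) * np.log(tau) - self.rate * tau
            if self.shape > 1.0:
                out = np.where(tau == 0, -np.inf, out)
            return out
        if fam is DistributionFamily.UNIFORM:
            return np.zeros_like(tau)
        raise ValueError("point distribution has no density")

    def pdf(self, grid: np.ndarray) -> np.ndarray:
        """Density on ``grid``, normalized by the trapezoid rule on that
        grid (the package-wide density contract)."""
        tau = np.asarray(grid, dtype=float)
        logp = self._log_shape(tau)
        logp = logp - np.max(logp[np.isfinite(logp)])
        p = np.exp(logp)
        return p / np.trapezoid(p, tau)

    def cdf(self, x) -> np.ndarray:
        """Exact (analytic) CDF of the truncated distribution."""
        x = np.asarray(x, dtype=float)
        tm = self.truncation
        xc = np.clip(x, 0.0, tm)
        fam = self.family
        if fam is DistributionFamily.UNIFORM:
            return xc / tm
        if fam is DistributionFamily.POINT:
            return (x >= self.atom).astype(float)
        if fam is DistributionFamily.TRUNCATED_EXPONENTIAL:
            r = self.rate
            if abs(r) < 1e-14:
                return xc / tm
            return np.expm1(-r * xc) / np.expm1(-r * tm)
        k, r = self.shape, self.rate
        return special.gammainc(k, r * xc) / special.gammainc(k, r * tm)

    def mean(self) -> float:
        """Analytic mean of the truncated distribution."""
        tm = self.truncation
        fam = self.family
        if fam is DistributionFamily.POINT:
            return float(self.atom)
        if fam is DistributionFamily.UNIFORM:
            return tm / 2.0
        if fam is DistributionFamily.TRUNCATED_EXPONENTIAL:
            return _trunc_exp_mean(self.rate, tm)
        k, r = self.shape, self.rate
        return (k / r) * special.gammainc(k + 1, r * tm) / special.gammainc(
            k, r * tm
        )

    def mode(self) -> float:
        """Mode of the truncated distribution (clipped to the range)."""
        tm = self.truncation
        fam = self.family
        if fam is DistributionFamily.POINT:
            return float(self.atom)
        if fam is DistributionFamily.UNIFORM:
            return math.nan
        if fam is DistributionFamily.TRUNCATED_EXPONENTIAL:
            return 0.0 if self.rate >= 0 else tm
        return float(np.clip((self.shape - 1.0) / self.rate, 0.0, tm))


def _trunc_exp_mean(rate: float, tau_max: float) -> float:
    """Mean of density ∝ exp(-rate*tau) on [0, tau_max]; any real rate."""
    x = rate * tau_max
    if abs(x) < 1e-8:
        # series around the uniform limit
        return tau_max / 2.0 * (1.0 - x / 6.0)
    with np.errstate(over="ignore"):
        em1 = math.expm1(x) if x < 700 else math.inf
    return 1.0 / rate - tau_max / em1


# ---------------------------------------------------------------------------
# Q-values
# ---------------------------------------------------------------------------


def q_leisure(tau, rho: float, u: LeisureUtility, V_pre: float = 0.0, *,
              tau_max: Optional[float] = None):
    """Differential Q-value of a leisure bout of duration ``tau``:
    ``U_L(tau) - rho*tau + V_pre``.  The subtracted term is the average
    foregone reward."""
    tau_arr = np.asarray(tau, dtype=float)
    if tau_max is not None and np.any(tau_arr > tau_max):
        raise ValueError("tau exceeds the admissible range")
    out = np.asarray(u.evaluate(tau_arr)) - rho * tau_arr + V_pre
    return out if np.ndim(tau) else float(out)


def q_work(rho: float, task: TaskSpec, V_post: float = 0.0) -> float:
    """Differential Q-value of working the full price:
    ``R_I - rho*P + V_post`` (pre-commitment to the entire price)."""
    if not math.isfinite(rho):
        raise ValueError("rho must be finite")
    return task.R_I - rho * task.P + V_post


# ---------------------------------------------------------------------------
# Softmax policy and reward rate
# ---------------------------------------------------------------------------


def softmax_policy(
    q: Union[Callable[[np.ndarray], np.ndarray], np.ndarray],
    beta: float,
    tau_max: float,
    grid_n: int = 2001,
):
    """Entropy-regularized (softmax) density over leisure durations.

    ``pi(tau) = exp(beta q(tau)) / ∫ exp(beta q)``, computed with
    max-subtraction for overflow safety; ``beta = 0`` returns the uniform
    density ``1/tau_max``.

    ``q`` may be a callable evaluated on the internal grid, or an array of
    Q-values already aligned with ``linspace(0, tau_max, grid_n)``.

    Returns ``(grid, density)``.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    grid = np.linspace(0.0, tau_max, grid_n)
    if callable(q):
        q_vals = np.asarray(q(grid), dtype=float)
    else:
        q_vals = np.asarray(q, dtype=float)
        if q_vals.shape != grid.shape:
            raise ValueError("q array must match the duration grid")
    if np.any(np.isnan(q_vals)) or np.any(q_vals == np.inf):
        raise FloatingPointError("non-finite Q-values on the grid")
    density = _gibbs_density(q_vals, beta, grid)[0]
    return grid, density


def _gibbs_density(q_vals: np.ndarray, beta: float, grid: np.ndarray):
    """Density ∝ exp(beta*q) with trapezoid normalization.

    Returns ``(density, logZ)`` where ``Z = ∫ exp(beta*q) dtau``.
    ``q_vals`` may contain ``-inf`` (zero density there).
    """
    if beta == 0.0:
        n = grid[-1] - grid[0]
        return np.full_like(grid, 1.0 / n), math.log(n)
    logits = beta * q_vals
    m = np.max(logits[np.isfinite(logits)])
    z = np.exp(logits - m)
    Z = np.trapezoid(z, grid)
    return z / Z, m + math.log(Z)


def _policy_stats(density: np.ndarray, grid: np.ndarray,
                  u_vals: np.ndarray):
    """(mean, E[U_L], differential entropy) of a gridded density."""
    mean = float(np.trapezoid(density * grid, grid))
    # mask -inf utility nodes, where the density vanishes
    u_masked = np.where(np.isfinite(u_vals), u_vals, 0.0)
    mean_u = float(np.trapezoid(density * u_masked, grid))
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(density > 0, density * np.log(density), 0.0)
    entropy = -float(np.trapezoid(plogp, grid))
    return mean, mean_u, entropy


def reward_rate(
    density: Optional[np.ndarray],
    grid: Optional[np.ndarray],
    u: LeisureUtility,
    task: TaskSpec,
    *,
    atom: Optional[float] = None,
    beta: Optional[float] = None,
    include_entropy: bool = False,
) -> float:
    """Average reward rate of a policy: expected utility accumulated per
    cycle over expected cycle length.

    By default only microscopic utilities enter the numerator; with
    ``include_entropy=True`` the per-cycle entropy bonus ``H(pi)/beta`` is
    added (requires ``beta``).
    """
    if atom is not None:
        return (task.R_I + u.evaluate(atom)) / (task.P + atom)
    total = float(np.trapezoid(density, grid))
    if abs(total - 1.0) > 1e-6:
        raise ValueError("density is not normalized on its grid")
    u_vals = u._values(np.asarray(grid, dtype=float))
    mean, mean_u, entropy = _policy_stats(density, grid, u_vals)
    numer = task.R_I + mean_u
    if include_entropy:
        if beta is None or not (0.0 < beta < math.inf):
            raise ValueError("entropy term requires finite beta > 0")
        numer += entropy / beta
    return numer / (task.P + mean)


# ---------------------------------------------------------------------------
# Fixed-point solver
# ---------------------------------------------------------------------------


def _rate_of_rho(
    rho: float,
    grid: np.ndarray,
    u_vals: np.ndarray,
    beta: float,
    task: TaskSpec,
    include_entropy: bool,
):
    """Reward rate of the softmax policy induced by candidate rate ``rho``."""
    q_vals = u_vals - rho * grid  # V_pre shift drops out of the softmax
    density, _ = _gibbs_density(q_vals, beta, grid)
    mean, mean_u, entropy = _policy_stats(density, grid, u_vals)
    numer = task.R_I + mean_u
    if include_entropy:
        numer += entropy / beta
    return numer / (task.P + mean), density, mean, mean_u, entropy


def _rho_bracket(task: TaskSpec, u: LeisureUtility) -> float:
    """Upper bound for the reward-rate bracket."""
    hi = task.R_I / task.P + 1.0
    if u.form is UtilityForm.LINEAR:
        hi += max(u.C_L, 0.0)
    else:
        hi += max(u.C_L, 0.0) * max(1.0, abs(math.log(task.tau_max))) / task.P
        hi += max(u.C_L, 0.0)
    return hi


def solve(
    task: TaskSpec,
    u: LeisureUtility,
    settings: PolicySettings = PolicySettings(),
) -> SolvedPolicy:
    """Solve the joint fixed point ``pi = softmax(beta * Q(.; rho))`` and
    ``rho = reward_rate(pi)``.

    ``beta = inf`` is routed to :func:`deterministic_policy`.  The default
    solver is damped iteration ``rho <- (1-eta) rho + eta rate(rho)``; if it
    fails to converge (or ``settings.solver == "root"``) a bracketing root
    finder on ``rate(rho) - rho`` is used.  Non-convergence is flagged on
    the returned policy, never silent.
    """
    beta = settings.beta
    if math.isinf(beta):
        return deterministic_policy(task, u, grid_n=settings.grid_n)

    grid = np.linspace(0.0, task.tau_max, settings.grid_n)
    u_vals = u._values(grid)
    inc = settings.include_entropy_in_rate

    def g(rho: float) -> float:
        return _rate_of_rho(rho, grid, u_vals, beta, task, inc)[0] - rho

    rho = task.R_I / (task.P + task.tau_max / 2.0)  # feasible mid-range rate
    iterations = 0
    converged = False
    if settings.solver == "iterate":
        eta = settings.damping
        for iterations in range(1, settings.max_iter + 1):
            rate = _rate_of_rho(rho, grid, u_vals, beta, task, inc)[0]
            if abs(rate - rho) <= settings.tol:  # fixed-point residual
                converged = True
                break
            rho = (1.0 - eta) * rho + eta * rate
    if not converged:
        lo, hi = 0.0, _rho_bracket(task, u)
        glo, ghi = g(lo), g(hi)
        tries = 0
        while glo * ghi > 0 and tries < 60:
            hi *= 2.0
            ghi = g(hi)
            tries += 1
        if glo * ghi <= 0:
            rho = float(optimize.brentq(g, lo, hi, xtol=1e-13, rtol=1e-15))
            converged = True

    rate, density, mean, mean_u, entropy = _rate_of_rho(
        rho, grid, u_vals, beta, task, inc
    )
    converged = converged and abs(rate - rho) <= 1e-8 * max(1.0, abs(rho))
    return SolvedPolicy(
        grid=grid,
        density=density,
        atom=None,
        rho=rho,
        mean_leisure=mean,
        mean_U_L=mean_u,
        entropy=entropy,
        V_pre=task.R_I - rho * task.P,
        V_post=0.0,
        converged=converged,
        iterations=iterations,
        beta=beta,
        task=task,
        u=u,
    )


def deterministic_policy(
    task: TaskSpec, u: LeisureUtility, grid_n: int = 2001
) -> SolvedPolicy:
    """Optimal (beta = inf) point policy.

    The self-consistent deterministic optimum maximizes the reward rate
    ``(R_I + U_L(tau)) / (P + tau)`` over ``[0, tau_max]``; equivalently it
    is the argmax of ``U_L(tau) - rho* tau`` at the optimal ``rho*``.  For
    concave utility an interior optimum satisfies the first-order condition
    ``U_L'(tau*) = rho*``.  Ties break toward the smallest duration.
    """
    grid = np.linspace(0.0, task.tau_max, grid_n)
    u_vals = u._values(grid)
    with np.errstate(invalid="ignore"):
        rate_vals = (task.R_I + u_vals) / (task.P + grid)
    rate_vals = np.where(np.isfinite(rate_vals), rate_vals, -np.inf)
    i = int(np.argmax(rate_vals))  # argmax returns the first (smallest tau)

    def neg_rate(tau: float) -> float:
        return -(task.R_I + u.evaluate(tau)) / (task.P + tau)

    tau_star = grid[i]
    if 0 < i < grid_n - 1:
        res = optimize.minimize_scalar(
            neg_rate,
            bounds=(grid[i - 1], grid[i + 1]),
            method="bounded",
            options={"xatol": 1e-12},
        )
        if -res.fun >= rate_vals[i]:
            tau_star = float(res.x)
    rho = (task.R_I + u.evaluate(tau_star)) / (task.P + tau_star)
    return SolvedPolicy(
        grid=grid,
        density=None,
        atom=float(tau_star),
        rho=float(rho),
        mean_leisure=float(tau_star),
        mean_U_L=float(u.evaluate(tau_star)),
        entropy=-math.inf,
        V_pre=task.R_I - rho * task.P,
        V_post=0.0,
        converged=True,
        iterations=0,
        beta=math.inf,
        task=task,
        u=u,
    )


def closed_form_distribution(
    u: LeisureUtility, beta: float, rho: float, tau_max: float
) -> LeisureDistribution:
    """Closed-form softmax leisure-duration distribution, when one exists.

    linear ``U_L``  -> truncated exponential with rate ``beta*(rho - C_L)``
    (a negative rate means the density rises toward ``tau_max``);
    log ``U_L``     -> truncated gamma, shape ``beta*C_L + 1``, rate
    ``beta*rho``.

    Raises :class:`ClosedFormUnavailable` for other forms (callers fall
    back to the numeric density).
    """
    if not (0.0 < beta < math.inf):
        raise ValueError("closed forms require finite beta > 0")
    if u.form is UtilityForm.LINEAR:
        return LeisureDistribution(
            DistributionFamily.TRUNCATED_EXPONENTIAL,
            truncation=tau_max,
            rate=beta * (rho - u.C_L),
        )
    if u.form is UtilityForm.LOG:
        return LeisureDistribution(
            DistributionFamily.TRUNCATED_GAMMA,
            truncation=tau_max,
            shape=beta * u.C_L + 1.0,
            rate=beta * rho,
        )
    raise ClosedFormUnavailable(
        f"no closed-form policy for utility form {u.form.value!r}"
    )
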