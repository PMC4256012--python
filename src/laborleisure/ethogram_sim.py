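"""Trial simulation: ethograms of alternating work and leisure bouts.

A trial of length ``T`` starts in the post-reward state (leisure first, the
cycle as the model draws it; ``leisure_first=False`` starts with work) and
alternates leisure bouts sampled from the solved policy with price-long work
bouts.  Each completed work bout ends with a reward event; the final bout is
truncated at ``T`` and counted pro-rata in the empirical time allocation.
Bouts tile ``[0, T]`` with no gaps or overlaps.

Leisure durations are drawn by inverse-CDF sampling on the policy's grid
(linear interpolation of the trapezoid CDF), which is fast, exact on the
gridded density, and reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .smdp_core import SolvedPolicy, TaskSpec

__all__ = ["Bout", "Ethogram", "sample_leisure", "simulate_trial",
           "simulate_trials", "empirical_ta", "bouts_frame", "rewards_frame"]

SeedLike = Union[int, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Bout:
    kind: str  # "work" | "leisure"
    onset: float  # seconds from trial start
    duration: float  # seconds


@dataclass
class Ethogram:
    """Timestamped work/leisure bouts and reward events for one trial."""

    trial_id: int
    bouts: List[Bout]
    reward_times: List[float]
    T: float

    def total_work(self) -> float:
        return sum(b.duration for b in self.bouts if b.kind == "work")


def sample_leisure(
    policy: SolvedPolicy, n: int, seed: SeedLike
) -> np.ndarray:
    """Draw ``n`` leisure durations from a solved policy.

    Point policies return their atom; gridded densities are sampled by
    inverse-CDF with linear interpolation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    if policy.is_point:
        rng.uniform(size=n)  # keep the stream position consistent
        return np.full(n, policy.atom)
    grid, density = policy.grid, policy.density
    total = float(np.trapezoid(density, grid))
    if abs(total - 1.0) > 1e-6:
        raise ValueError("policy density is not normalized")
    dx = np.diff(grid)
    cdf = np.concatenate(
        [[0.0], np.cumsum(0.5 * dx * (density[1:] + density[:-1]))]
    )
    cdf /= cdf[-1]
    # keep the CDF strictly increasing for interpolation
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    u = rng.uniform(size=n)
    return np.interp(u, cdf[keep], grid[keep])


def simulate_trial(
    task: TaskSpec,
    policy: SolvedPolicy,
    seed: SeedLike,
    trial_id: int = 0,
    leisure_first: bool = True,
) -> Ethogram:
    """Simulate one fixed-duration trial under a solved policy."""
    if task.T < task.P:
        raise ValueError("trial must be at least one price long")
    rng = _rng(seed)
    bouts: List[Bout] = []
    rewards: List[float] = []
    t = 0.0
    work_next = not leisure_first
    while t < task.T:
        remaining = task.T - t
        if work_next:
            dur = min(task.P, remaining)
            if bouts and bouts[-1].kind == "work":
                # zero-length leisure in between: one continuous work bout
                prev = bouts.pop()
                bouts.append(Bout("work", prev.onset, prev.duration + dur))
            else:
                bouts.append(Bout("work", t, dur))
            if dur == task.P:
                rewards.append(t + dur)
        else:
            tau = float(sample_leisure(policy, 1, rng)[0])
            dur = min(tau, remaining)
            if dur > 0.0:
                bouts.append(Bout("leisure", t, dur))
        t += dur
        work_next = not work_next
    return Ethogram(trial_id=trial_id, bouts=bouts, reward_times=rewards,
                    T=task.T)


def simulate_trials(
    task: TaskSpec,
    policy: SolvedPolicy,
    n_trials: int,
    seed: SeedLike,
    leisure_first: bool = True,
) -> List[Ethogram]:
    """Simulate ``n_trials`` independent trials from one seeded stream."""
    rng = _rng(seed)
    return [
        simulate_trial(task, policy, rng, trial_id=i,
                       leisure_first=leisure_first)
        for i in range(n_trials)
    ]


def empirical_ta(e: Ethogram) -> float:
    """Proportion of trial time spent working: total work time / T."""
    return e.total_work() / e.T


def bouts_frame(ethograms: Sequence[Ethogram]) -> pd.DataFrame:
    """Bout table: trial_id, bout_index, kind, onset_s, duration_s."""
    rows = [
        (e.trial_id, i, b.kind, b.onset, b.duration)
        for e in ethograms
        for i, b in enumerate(e.bouts)
    ]
    return pd.DataFrame(
        rows, columns=["trial_id", "bout_index", "kind", "onset_s",
                       "duration_s"]
    )


def rewards_frame(ethograms: Sequence[Ethogram]) -> pd.DataFrame:
    """Reward-event table: trial_id, time_s."""
    rows = [(e.trial_id, t) for e in ethograms for t in e.reward_times]
    return pd.DataFrame(rows, columns=["trial_id", "time_s"])
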