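"""Stochastic agent-based realisation of the pairwise-comparison process.

Simulates the same update rule as the exact chain by direct agent sampling:
each elementary step draws an ordered pair of distinct agents (role model k,
learner j) uniformly from the population and j adopts k's strategy with the
Fermi probability.  Fitness is the expected payoff over the game ecology at
the current composition (agents experience many interactions per lifetime, so
per-encounter payoff noise is averaged out).

Used to validate the absorbing-chain solver and to produce trajectories;
`estimate_fixation` runs many replicates in lock-step vectorised form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .dynamics import DynamicsParams, PopulationState, payoff_matrix

__all__ = ["TrajectoryRecord", "run_replicate", "estimate_fixation", "AbmEstimate"]

VERTEX = {0: "AA", 1: "AllC", 2: "AllD"}


@dataclass(frozen=True)
class TrajectoryRecord:
    step: int
    state: tuple[int, int, int]
    absorbed: bool
    vertex: str | None = None


def _payoffs(M: np.ndarray, n: np.ndarray, N: int) -> np.ndarray:
    return (M @ n - np.diag(M)) / (N - 1)


def run_replicate(initial: PopulationState, params: DynamicsParams, adaptive_kind: str,
                  max_steps: int = 10_000_000, seed: int = 0,
                  record_every: int = 1) -> list[TrajectoryRecord]:
    """Simulate one population until absorption or max_steps.

    Returns the recorded trajectory; the final record carries the absorbed
    flag (False if the run was truncated at max_steps).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    rng = np.random.default_rng(seed)
    M = payoff_matrix(params.stats, params.c, adaptive_kind)
    scale = params.scale
    N = initial.N
    n = np.array(initial.as_tuple(), dtype=float)
    records: list[TrajectoryRecord] = []

    def absorbed_at() -> int | None:
        hit = np.nonzero(n == N)[0]
        return int(hit[0]) if hit.size else None

    v = absorbed_at()
    records.append(TrajectoryRecord(0, tuple(int(x) for x in n), v is not None,
                                    VERTEX[v] if v is not None else None))
    if v is not None:
        return records
    for step in range(1, max_steps + 1):
        # role model k ~ composition; learner j ~ remaining N-1 agents
        r = rng.random() * N
        k = 0 if r < n[0] else (1 if r < n[0] + n[1] else 2)
        rem = n.copy()
        rem[k] -= 1
        r = rng.random() * (N - 1)
        j = 0 if r < rem[0] else (1 if r < rem[0] + rem[1] else 2)
        if j != k:
            pi = _payoffs(M, n, N)
            if rng.random() < expit(params.beta * (pi[k] - pi[j]) / scale):
                n[k] += 1
                n[j] -= 1
        v = absorbed_at()
        if v is not None or step % record_every == 0 or step == max_steps:
            records.append(TrajectoryRecord(step, tuple(int(x) for x in n), v is not None,
                                            VERTEX[v] if v is not None else None))
        if v is not None:
            break
    return records


@dataclass
class AbmEstimate:
    """Monte-Carlo fixation estimates with binomial standard errors."""

    phi_a: float
    phi_c: float
    phi_d: float
    se_a: float
    se_c: float
    se_d: float
    replicates: int
    truncated: int
    meta: dict = field(default_factory=dict)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.phi_a, self.phi_c, self.phi_d)


def estimate_fixation(initial: PopulationState, params: DynamicsParams, adaptive_kind: str,
                      replicates: int = 10_000, seed: int = 0,
                      max_steps: int = 10_000_000) -> AbmEstimate:
    """Empirical fixation frequencies from many lock-step replicates.

    All replicates advance together with vectorised numpy updates, which is
    statistically identical to running `run_replicate` independently.
    Replicates still polymorphic at max_steps are excluded from the phi
    estimates and reported in ``truncated``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    M = payoff_matrix(params.stats, params.c, adaptive_kind)
    scale = params.scale
    N = initial.N
    n = np.tile(np.array(initial.as_tuple(), dtype=float), (replicates, 1))
    absorbed_counts = np.zeros(3, dtype=int)
    active = np.arange(replicates)

    def harvest(states):
        done = states.max(axis=1) == N
        if done.any():
            which = states[done].argmax(axis=1)
            np.add.at(absorbed_counts, which, 1)
        return done

    done0 = harvest(n)
    n = n[~done0]
    step = 0
    while len(n) and step < max_steps:
        step += 1
        R = len(n)
        r = rng.random(R) * N
        k = (r >= n[:, 0]).astype(int) + (r >= n[:, 0] + n[:, 1]).astype(int)
        rem = n.copy()
        rem[np.arange(R), k] -= 1.0
        r = rng.random(R) * (N - 1)
        j = (r >= rem[:, 0]).astype(int) + (r >= rem[:, 0] + rem[:, 1]).astype(int)
        pi = (n @ M.T - np.diag(M)[None, :]) / (N - 1)
        dpi = pi[np.arange(R), k] - pi[np.arange(R), j]
        move = (j != k) & (rng.random(R) < expit(params.beta * dpi / scale))
        if move.any():
            idx = np.nonzero(move)[0]
            n[idx, k[idx]] += 1.0
            n[idx, j[idx]] -= 1.0
            done = n.max(axis=1) == N
            if done.any():
                harvest(n)
                n = n[~done]
    truncated = len(n)
    eff = replicates - truncated
    phi = absorbed_counts / eff if eff else np.zeros(3)
    se = np.sqrt(phi * (1.0 - phi) / eff) if eff else np.full(3, np.nan)
    return AbmEstimate(
        phi_a=float(phi[0]), phi_c=float(phi[1]), phi_d=float(phi[2]),
        se_a=float(se[0]), se_c=float(se[1]), se_d=float(se[2]),
        replicates=replicates, truncated=truncated,
        meta={"N": N, "beta": params.beta, "c": params.c, "scale": scale,
              "kind": adaptive_kind, "seed": seed, "steps_run": step},
    )
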