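"""Exact evolutionary dynamics of three strategies in a finite population.

A well-mixed population of N agents holds two fixed-behaviour strategies —
unconditional cooperators (AllC) and defectors (AllD) — and one adaptive
strategy (AA) that pays a per-interaction cost c to infer either the degree
of correspondence of interests (kind "doc", cooperate iff DoC >= 0) or the
type of game (kind "tog", cooperate iff cooperation is strictly dominant).

Fitness is the expected payoff over the whole game ecology, averaged over the
N-1 possible partners.  Evolution follows a pairwise-comparison (imitation)
process: at each step an ordered pair of distinct agents (k, j) is drawn
uniformly and j adopts k's strategy with the Fermi probability

    p = 1 / (1 + exp(-beta (pi_k - pi_j) / w)),

where beta is the selection intensity and w is a payoff scale.  By default
w is the ecology's payoff span (max(1, T_max) - min(0, S_min)), which keeps
the effective selection pressure comparable across ecologies with very
different payoff magnitudes; set ``payoff_scale=1`` for the raw-payoff rule.

The population state (X, Y, Z) = (#AA, #AllC, #AllD) performs a random walk
on the simplex with absorbing vertices; fixation probabilities are absorption
probabilities of that chain, obtained from the standard (I - Q) B = R sparse
linear solve over the (N+1)(N+2)/2 - 3 transient states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix, identity
from scipy.sparse.linalg import splu
from scipy.special import expit

from .ecology import EcologyStats

__all__ = [
    "STRATEGIES",
    "PopulationState",
    "DynamicsParams",
    "FixationResult",
    "payoff_matrix",
    "pairwise_game_payoff",
    "state_payoffs",
    "fermi_probability",
    "transition_probabilities",
    "fixation_probabilities",
    "cooperation_increase",
    "StateSpace",
]

#: Strategy order used everywhere: adaptive agent, cooperator, defector.
STRATEGIES = ("AA", "AllC", "AllD")
_IDX = {s: i for i, s in enumerate(STRATEGIES)}


@dataclass(frozen=True)
class PopulationState:
    """Counts (X, Y, Z) of (AA, AllC, AllD) agents; X + Y + Z = N."""

    X: int
    Y: int
    Z: int

    def __post_init__(self) -> None:
        if min(self.X, self.Y, self.Z) < 0:
            raise ValueError("counts must be non-negative")
        if self.N < 2:
            raise ValueError("population size must be >= 2")

    @property
    def N(self) -> int:
        return self.X + self.Y + self.Z

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.X, self.Y, self.Z)


@dataclass
class DynamicsParams:
    """Selection intensity, inference cost and the ecology statistics.

    payoff_scale None (default) normalises Fermi payoff differences by the
    ecology's payoff span (stats.payoff_span); a number fixes the scale
    explicitly (1.0 recovers the raw-payoff Fermi rule).
    """

    beta: float
    c: float
    stats: EcologyStats
    payoff_scale: float | None = None

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.c < 0:
            raise ValueError("c must be >= 0")

    @property
    def scale(self) -> float:
        if self.payoff_scale is not None:
            return float(self.payoff_scale)
        return float(self.stats.payoff_span)


@dataclass
class FixationResult:
    """Absorption probabilities of the three monomorphic states."""

    phi_a: float
    phi_c: float
    phi_d: float
    p_c: float  # cooperation level phi_C + alpha phi_A
    alpha: float
    meta: dict = field(default_factory=dict)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.phi_a, self.phi_c, self.phi_d)


def payoff_matrix(stats: EcologyStats, c: float, adaptive_kind: str) -> np.ndarray:
    """Ecology-averaged pairwise payoff table M[actor, partner].

    Rows/columns follow STRATEGIES = (AA, AllC, AllD).  For the DoC kind
    (alpha = alpha_plus, unconditional splits x+/x-):

        M = [[alpha - c,   alpha + t_minus - c,  s_plus - c],
             [alpha + s_minus,       1,          mean_s    ],
             [t_plus,             mean_t,        0         ]]

    and the ToG analogue replaces (alpha_plus, +/-) with (alpha_md, MD/non-MD).
    The adaptive agent pays c in every interaction.
    """
    st = stats
    if adaptive_kind == "doc":
        a, xp_s, xm_s, xp_t, xm_t = st.alpha_plus, st.splus, st.sminus, st.tplus, st.tminus
    elif adaptive_kind == "tog":
        a, xp_s, xm_s, xp_t, xm_t = st.alpha_md, st.s_md, st.s_nonmd, st.t_md, st.t_nonmd
    else:
        raise ValueError(f"unknown adaptive kind {adaptive_kind!r}")
    if a is None:
        raise ValueError(f"stats lack the {adaptive_kind!r} split")
    return np.array(
        [
            [a - c, a + xm_t - c, xp_s - c],
            [a + xm_s, 1.0, st.mean_s],
            [xp_t, st.mean_t, 0.0],
        ]
    )


def pairwise_game_payoff(actor: str, partner: str, stats: EcologyStats, c: float,
                         adaptive_kind: str = "doc") -> float:
    """Expected payoff of one strategy against another over the ecology."""
    try:
        i, j = _IDX[actor], _IDX[partner]
    except KeyError as e:
        raise ValueError(f"unknown strategy {e.args[0]!r}") from None
    return float(payoff_matrix(stats, c, adaptive_kind)[i, j])


def state_payoffs(state: PopulationState, params: DynamicsParams, adaptive_kind: str) -> dict:
    """Fitness of each *present* strategy: mean payoff over the N-1 partners.

    pi_A = [(X-1) M[A,A] + Y M[A,C] + Z M[A,D]] / (N-1), etc.  Strategies with
    zero count map to None (their payoff is undefined in this state).
    """
    M = payoff_matrix(params.stats, params.c, adaptive_kind)
    n = np.array(state.as_tuple(), dtype=float)
    N = state.N
    pi = (M @ n - np.diag(M)) / (N - 1)
    return {s: (float(pi[i]) if n[i] > 0 else None) for i, s in enumerate(_IDX)}


def fermi_probability(pi_k: float, pi_j: float, beta: float) -> float:
    """Probability that agent k replaces agent j: 1/(1 + e^{-beta (pi_k - pi_j)}).

    Numerically stable for large |beta (pi_k - pi_j)| via scipy's expit.
    """
    return float(expit(beta * (np.asarray(pi_k) - np.asarray(pi_j))))


class StateSpace:
    """Enumeration of the (N+1)(N+2)/2 simplex states and their moves.

    States are ordered lexicographically over (X, Y), Z = N - X - Y:
    index(X, Y) = X(N+1) - X(X-1)/2 + Y.  Constructed once per N and reused
    across payoff tables (grid sweeps re-solve on the same sparsity pattern).
    """

    #: ordered pairs (role model, learner): learner adopts the role model's strategy
    PAIRS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]

    def __init__(self, N: int):
        if N < 2:
            raise ValueError("N must be >= 2")
        self.N = N
        X, Y = [], []
        for x in range(N + 1):
            for y in range(N + 1 - x):
                X.append(x)
                Y.append(y)
        self.X = np.array(X)
        self.Y = np.array(Y)
        self.Z = N - self.X - self.Y
        self.n_states = len(X)
        self.counts = np.stack([self.X, self.Y, self.Z], axis=1).astype(float)
        self.targets, self.legal = [], []
        for a, b in self.PAIRS:
            d = np.zeros(3, dtype=int)
            d[a] += 1
            d[b] -= 1
            ok = (self.counts[:, a] > 0) & (self.counts[:, b] > 0)
            tx = np.clip(self.X + d[0], 0, N)
            ty = np.clip(self.Y + d[1], 0, N)
            self.targets.append(np.where(ok, self.index(tx, ty), 0))
            self.legal.append(ok)
        vertices = self.index(np.array([N, 0, 0]), np.array([0, N, 0]))  # AA, AllC, AllD
        self.absorbing = np.sort(vertices)
        self._vertex_order = np.argsort(np.argsort(vertices))
        transient = np.ones(self.n_states, dtype=bool)
        transient[self.absorbing] = False
        self.transient_idx = np.nonzero(transient)[0]
        self._pos = np.full(self.n_states, -1)
        self._pos[self.transient_idx] = np.arange(len(self.transient_idx))

    def index(self, x, y):
        return x * (self.N + 1) - (x * (x - 1)) // 2 + y

    def all_payoffs(self, M: np.ndarray) -> np.ndarray:
        """Per-state fitness of all three strategies (junk where count = 0)."""
        return (self.counts @ M.T - np.diag(M)[None, :]) / (self.N - 1)

    def move_probabilities(self, M: np.ndarray, beta: float, scale: float = 1.0):
        """Probability of each of the six neighbour moves from every state."""
        P = self.all_payoffs(M)
        N = self.N
        probs = []
        for (a, b), ok in zip(self.PAIRS, self.legal):
            na, nb = self.counts[:, a], self.counts[:, b]
            f = expit(beta * (P[:, a] - P[:, b]) / scale)
            probs.append(np.where(ok, na * nb / (N * (N - 1)) * f, 0.0))
        return probs

    def solve_absorption(self, M: np.ndarray, beta: float, scale: float = 1.0) -> np.ndarray:
        """Absorption probabilities into (AA, AllC, AllD) vertices, all states.

        Returns an (n_states, 3) array; vertex rows are unit vectors.
        """
        probs = self.move_probabilities(M, beta, scale)
        nt = len(self.transient_idx)
        rows, cols, vals = [], [], []
        R = np.zeros((nt, 3))
        for p, tgt in zip(probs, self.targets):
            nz = np.nonzero(p)[0]
            src, dst, val = self._pos[nz], tgt[nz], p[nz]
            dpos = self._pos[dst]
            tt = dpos >= 0
            rows.append(src[tt])
            cols.append(dpos[tt])
            vals.append(val[tt])
            ab = ~tt
            if ab.any():
                vcol = np.searchsorted(self.absorbing, dst[ab])
                np.add.at(R, (src[ab], vcol), val[ab])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        Q = csc_matrix((vals, (rows, cols)), shape=(nt, nt))
        # self-loops sit on the diagonal of Q; (I - Q) removes them exactly
        diag = csc_matrix((1.0 - np.asarray(Q.sum(axis=1)).ravel() - R.sum(axis=1),
                           (np.arange(nt), np.arange(nt))), shape=(nt, nt))
        B = splu((identity(nt, format="csc") - (Q + diag)).tocsc()).solve(R)
        out = np.zeros((self.n_states, 3))
        # B's columns follow sorted vertex indices; reorder to (AA, AllC, AllD)
        out[self.transient_idx] = B[:, self._vertex_order]
        out[self.index(self.N, 0), 0] = 1.0  # (N,0,0): AA fixed
        out[self.index(0, self.N), 1] = 1.0  # (0,N,0): AllC fixed
        out[self.index(0, 0), 2] = 1.0       # (0,0,N): AllD fixed
        return out


def transition_probabilities(state: PopulationState, params: DynamicsParams,
                             adaptive_kind: str) -> dict[tuple[int, int, int], float]:
    """One-step transition distribution from a single state (incl. self-loop)."""
    M = payoff_matrix(params.stats, params.c, adaptive_kind)
    n = list(state.as_tuple())
    N = state.N
    pi = (M @ np.array(n, dtype=float) - np.diag(M)) / (N - 1)
    out: dict[tuple[int, int, int], float] = {}
    total = 0.0
    for a, b in StateSpace.PAIRS:
        if n[a] == 0 or n[b] == 0:
            continue
        p = n[a] * n[b] / (N * (N - 1)) * float(expit(params.beta * (pi[a] - pi[b]) / params.scale))
        tgt = list(n)
        tgt[a] += 1
        tgt[b] -= 1
        out[tuple(tgt)] = out.get(tuple(tgt), 0.0) + p
        total += p
    out[tuple(n)] = out.get(tuple(n), 0.0) + (1.0 - total)
    return out


_SPACES: dict[int, StateSpace] = {}


def get_state_space(N: int) -> StateSpace:
    """Cached StateSpace per population size."""
    if N not in _SPACES:
        _SPACES[N] = StateSpace(N)
    return _SPACES[N]


def fixation_probabilities(initial: PopulationState, params: DynamicsParams,
                           adaptive_kind: str) -> FixationResult:
    """Exact fixation probabilities from the absorbing-chain linear solve."""
    space = get_state_space(initial.N)
    M = payoff_matrix(params.stats, params.c, adaptive_kind)
    B = space.solve_absorption(M, params.beta, params.scale)
    phi = B[space.index(initial.X, initial.Y)]
    resid = abs(float(phi.sum()) - 1.0)
    if resid > 1e-8:
        raise RuntimeError(f"absorption probabilities sum to 1 +/- {resid:.2e}")
    alpha = params.stats.alpha(adaptive_kind)
    return FixationResult(
        phi_a=float(phi[0]),
        phi_c=float(phi[1]),
        phi_d=float(phi[2]),
        p_c=float(phi[1] + alpha * phi[0]),
        alpha=alpha,
        meta={"N": initial.N, "beta": params.beta, "c": params.c,
              "scale": params.scale, "kind": adaptive_kind, "residual": resid},
    )


def cooperation_increase(initial: PopulationState, params: DynamicsParams,
                         adaptive_kind: str) -> float:
    """Cooperation gain of adding the adaptive strategy to the population.

    Compares the cooperation level P_c = phi_C + alpha phi_A of the
    three-strategy chain against a baseline population of fixed-behaviour
    agents only: an AllC/AllD chain of the same size started from the even
    split (N/2 cooperators), whose cooperation level is its phi_C.
    """
    res = fixation_probabilities(initial, params, adaptive_kind)
    N = initial.N
    y0 = N // 2
    base = fixation_probabilities(PopulationState(0, y0, N - y0), params, adaptive_kind)
    return res.p_c - base.phi_c
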