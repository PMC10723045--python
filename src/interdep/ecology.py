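"""Random ecologies of 2x2 games and their payoff statistics.

An ecology is a distribution over games: around an average game (S0, T0),
each interaction's payoffs are displaced by independent uniform noise on
[-delta/2, +delta/2] in both S and T.  The width ``delta`` controls the
heterogeneity of interdependence an agent experiences over its lifetime.

Because fitness is the expected payoff over the whole ecology, everything
the evolutionary dynamics needs reduces to a handful of summary statistics:
the frequency of games in which an adaptive agent cooperates (``alpha_plus``
for DoC inferrers, ``alpha_md`` for ToG inferrers) and the average S/T
contributions of those games.  The split statistics are *unconditional*
per-game averages, e.g. ``tplus = E[T * 1{DoC >= 0}]``, so that
``tplus + tminus = E[T]`` exactly; this normalization makes each entry of the
strategy payoff table an exact expectation over the ecology.

The MD-split statistics have closed forms (rectangle probabilities and
truncated-uniform means); the DoC split is estimated by Monte Carlo over a
seeded shared sample, with an optional tensor-quadrature backend for
validation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .games import GameMatrix, classify, degree_of_correspondence

__all__ = ["Ecology", "EcologyStats", "sample_games", "compute_stats", "doc_stats_grid"]

DEFAULT_SAMPLE_SIZE = 1_000_000


@dataclass(frozen=True)
class Ecology:
    """Uniform-box distribution of games centred on (s0, t0) with width delta.

    ``m`` is the Monte-Carlo sample size used for DoC-split statistics and
    ``seed`` makes the sample reproducible.  ``delta = 0`` is the degenerate
    single-game ecology.
    """

    s0: float
    t0: float
    delta: float = 0.0
    m: int = DEFAULT_SAMPLE_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def s_bounds(self) -> tuple[float, float]:
        h = self.delta / 2.0
        return (self.s0 - h, self.s0 + h)

    @property
    def t_bounds(self) -> tuple[float, float]:
        h = self.delta / 2.0
        return (self.t0 - h, self.t0 + h)

    @property
    def payoff_span(self) -> float:
        """Width of the payoff range realisable in this ecology.

        Spans all four payoffs: max(R, T_max) - min(P, S_min).  Used to put
        selection intensity on a scale comparable across ecologies.
        """
        return max(1.0, self.t_bounds[1]) - min(0.0, self.s_bounds[0])

    def sample(self, rng: np.random.Generator | None = None):
        """Draw the (S, T) arrays of m games; vectorised form of sample_games."""
        if rng is None:
            rng = np.random.default_rng(self.seed)
        h = self.delta / 2.0
        S = rng.uniform(self.s0 - h, self.s0 + h, self.m) if h > 0 else np.full(self.m, float(self.s0))
        T = rng.uniform(self.t0 - h, self.t0 + h, self.m) if h > 0 else np.full(self.m, float(self.t0))
        return S, T

    # --- serialisation -------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(
            {"S0": self.s0, "T0": self.t0, "delta": self.delta, "m": self.m, "seed": self.seed},
            sort_keys=False,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "Ecology":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            source = Path(source).read_text()
        d = yaml.safe_load(io.StringIO(source))
        return cls(s0=d["S0"], t0=d["T0"], delta=d.get("delta", 0.0),
                   m=d.get("m", DEFAULT_SAMPLE_SIZE), seed=d.get("seed", 0))


def sample_games(ecology: Ecology, rng: np.random.Generator | None = None) -> list[GameMatrix]:
    """Sample ``ecology.m`` games as GameMatrix objects (reproducible by seed)."""
    S, T = ecology.sample(rng)
    return [GameMatrix(s, t) for s, t in zip(S.tolist(), T.tolist())]


def games_to_csv(games: list[GameMatrix], path: str | Path) -> pd.DataFrame:
    """Export sampled games with their DoC index and class label."""
    df = pd.DataFrame(
        {
            "S": [g.S for g in games],
            "T": [g.T for g in games],
            "doc": [degree_of_correspondence(g) for g in games],
            "game_class": [classify(g).value for g in games],
        }
    )
    df.to_csv(path, index=False)
    return df


@dataclass
class EcologyStats:
    """Summary statistics of an ecology consumed by the dynamics and ESS maps.

    Split statistics are unconditional per-game averages:
    ``splus = E[S * 1{DoC(g) >= 0}]`` etc., so splus + sminus = mean_s and
    tplus + tminus = mean_t exactly; likewise for the MD/non-MD split.
    """

    mean_s: float
    mean_t: float
    payoff_span: float
    # DoC split (may be None when only ToG statistics were requested)
    alpha_plus: float | None = None
    splus: float | None = None
    sminus: float | None = None
    tplus: float | None = None
    tminus: float | None = None
    # MD split (closed form)
    alpha_md: float | None = None
    s_md: float | None = None
    s_nonmd: float | None = None
    t_md: float | None = None
    t_nonmd: float | None = None
    meta: dict = field(default_factory=dict)

    def alpha(self, kind: str) -> float:
        """Cooperation frequency of the adaptive agent of the given kind."""
        a = self.alpha_plus if kind == "doc" else self.alpha_md
        if a is None:
            raise ValueError(f"statistics for kind {kind!r} were not computed")
        return a

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("meta")
        return d


# ----------------------------------------------------------------------
# closed forms for the MD split (independent uniforms on a rectangle)

def _uniform_tail(lo: float, hi: float, thr: float, above: bool):
    """P and E[x*1] for x ~ U[lo, hi] restricted to x > thr (or x < thr)."""
    if hi <= lo:  # degenerate point mass at lo
        inside = lo > thr if above else lo < thr
        return (1.0, lo) if inside else (0.0, 0.0)
    a, b = (max(lo, thr), hi) if above else (lo, min(hi, thr))
    if b <= a:
        return 0.0, 0.0
    w = (b - a) / (hi - lo)
    contrib = (b * b - a * a) / (2.0 * (hi - lo))
    return w, contrib


def md_split_stats(ecology: Ecology) -> dict:
    """Exact MD-split statistics: alpha_md and the S/T contributions.

    Strict MD membership (S > 0 and T < 1); S and T are independent, so
    alpha_md = P(S > 0) P(T < 1) and e.g. t_md = E[T 1{T<1}] P(S > 0).
    """
    s_lo, s_hi = ecology.s_bounds
    t_lo, t_hi = ecology.t_bounds
    p_s, es_pos = _uniform_tail(s_lo, s_hi, 0.0, above=True)
    p_t, et_neg = _uniform_tail(t_lo, t_hi, 1.0, above=False)
    alpha_md = p_s * p_t
    s_md = es_pos * p_t
    t_md = et_neg * p_s
    return {
        "alpha_md": alpha_md,
        "s_md": s_md,
        "s_nonmd": ecology.s0 - s_md,
        "t_md": t_md,
        "t_nonmd": ecology.t0 - t_md,
    }


# ----------------------------------------------------------------------
# DoC split: Monte Carlo over a shared sample, or quadrature

def _doc_split_from_sample(S, T):
    ind = _doc_numerator_sign(S, T)
    alpha = float(ind.mean())
    splus = float((S * ind).mean())
    tplus = float((T * ind).mean())
    return alpha, splus, tplus


def _doc_numerator_sign(S, T):
    # DoC >= 0 iff its numerator is; the variance denominator is positive.
    mu = (1.0 + S + T) / 4.0
    return (1.0 + 2.0 * S * T) / 4.0 - mu * mu >= 0.0


def doc_split_stats(ecology: Ecology, backend: str = "mc", quad_order: int = 512) -> dict:
    """DoC-split statistics: alpha_plus and the S/T contributions.

    backend "mc" uses ecology.m seeded uniform draws; backend "quadrature"
    integrates the indicator on a Gauss-Legendre tensor grid (validation
    only — the indicator's discontinuity limits its accuracy to ~1/order).
    """
    if ecology.delta == 0.0:
        coop = bool(degree_of_correspondence(S=ecology.s0, T=ecology.t0) >= 0.0)
        a = 1.0 if coop else 0.0
        return {
            "alpha_plus": a,
            "splus": ecology.s0 * a,
            "sminus": ecology.s0 * (1.0 - a),
            "tplus": ecology.t0 * a,
            "tminus": ecology.t0 * (1.0 - a),
        }
    if backend == "mc":
        S, T = ecology.sample()
        alpha, splus, tplus = _doc_split_from_sample(S, T)
    elif backend == "quadrature":
        x, wx = np.polynomial.legendre.leggauss(quad_order)
        h = ecology.delta / 2.0
        S = ecology.s0 + h * x
        T = ecology.t0 + h * x
        W = np.outer(wx, wx) / 4.0  # weights normalised to the unit box
        ind = _doc_numerator_sign(S[:, None], T[None, :])
        alpha = float((W * ind).sum())
        splus = float((W * ind * S[:, None]).sum())
        tplus = float((W * ind * T[None, :]).sum())
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return {
        "alpha_plus": alpha,
        "splus": splus,
        "sminus": ecology.s0 - splus,
        "tplus": tplus,
        "tminus": ecology.t0 - tplus,
    }


def compute_stats(ecology: Ecology, agent_kind: str | None = None, backend: str = "mc") -> EcologyStats:
    """All ecology statistics needed for one adaptive kind (or both).

    agent_kind "doc" fills the DoC split, "tog" the MD split, None both.
    """
    stats = EcologyStats(
        mean_s=float(ecology.s0),
        mean_t=float(ecology.t0),
        payoff_span=ecology.payoff_span,
        meta={"m": ecology.m, "seed": ecology.seed, "delta": ecology.delta, "backend": backend},
    )
    if agent_kind in (None, "doc"):
        for k, v in doc_split_stats(ecology, backend=backend).items():
            setattr(stats, k, v)
    if agent_kind in (None, "tog"):
        for k, v in md_split_stats(ecology).items():
            setattr(stats, k, v)
    return stats


def doc_stats_grid(s0s, t0s, delta: float, m: int = DEFAULT_SAMPLE_SIZE, seed: int = 0):
    """DoC-split statistics on a (S0, T0) grid from one shared noise sample.

    The uniform noise is a location family: a single draw of displacements
    (u, v) on [-delta/2, delta/2]^2 serves every grid point as
    (S, T) = (S0 + u, T0 + v), so the whole grid uses common random numbers
    and differences across the grid carry no sampling noise.  The DoC >= 0
    indicator reduces to the sign of a quadratic whose sample-dependent parts
    (u, v, 6uv - u^2 - v^2) are precomputed once.

    Returns dict of arrays of shape (len(s0s), len(t0s)):
    alpha_plus, splus, sminus, tplus, tminus.
    """
    s0s = np.atleast_1d(np.asarray(s0s, dtype=float))
    t0s = np.atleast_1d(np.asarray(t0s, dtype=float))
    if delta == 0.0:
        S0, T0 = np.meshgrid(s0s, t0s, indexing="ij")
        ind = _doc_numerator_sign(S0, T0).astype(float)
        return {
            "alpha_plus": ind,
            "splus": S0 * ind,
            "sminus": S0 * (1.0 - ind),
            "tplus": T0 * ind,
            "tminus": T0 * (1.0 - ind),
        }
    rng = np.random.default_rng(seed)
    h = delta / 2.0
    u = rng.uniform(-h, h, m)
    v = rng.uniform(-h, h, m)
    w = 6.0 * u * v - u * u - v * v
    shape = (len(s0s), len(t0s))
    alpha = np.empty(shape)
    splus = np.empty(shape)
    tplus = np.empty(shape)
    for i, s0 in enumerate(s0s):
        for j, t0 in enumerate(t0s):
            # sign of the DoC numerator: 3 + 6 S T - S^2 - T^2 - 2S - 2T >= 0
            A = 3.0 + 6.0 * s0 * t0 - s0 * s0 - t0 * t0 - 2.0 * s0 - 2.0 * t0
            B = 6.0 * t0 - 2.0 * s0 - 2.0
            C = 6.0 * s0 - 2.0 * t0 - 2.0
            ind = A + B * u + C * v + w >= 0.0
            a = ind.mean()
            alpha[i, j] = a
            splus[i, j] = s0 * a + (u * ind).mean()
            tplus[i, j] = t0 * a + (v * ind).mean()
    S0 = s0s[:, None]
    T0 = t0s[None, :]
    return {
        "alpha_plus": alpha,
        "splus": splus,
        "sminus": S0 - splus,
        "tplus": tplus,
        "tminus": T0 - tplus,
    }


def stats_at(s0: float, t0: float, delta: float, *, m: int = DEFAULT_SAMPLE_SIZE,
             seed: int = 0, agent_kind: str | None = None, backend: str = "mc") -> EcologyStats:
    """Convenience wrapper: EcologyStats for one (s0, t0, delta) point."""
    return compute_stats(Ecology(s0, t0, delta, m=m, seed=seed), agent_kind=agent_kind, backend=backend)
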