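"""Configured computational experiments: sweeps, heatmaps and fixtures.

Each experiment is a pure function from an :class:`ExperimentConfig` to a
pandas DataFrame whose rows carry the full parameter set that produced them,
so any table can be reproduced from its own columns.  Study defaults follow
the finite-population analysis: N = 60, beta = 1, c = 0.1, equal initial
proportions (20, 20, 20), heterogeneity delta = 2 for the game-space maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ecology import Ecology, EcologyStats, compute_stats, doc_stats_grid, md_split_stats, games_to_csv, sample_games
from .dynamics import (DynamicsParams, PopulationState, cooperation_increase,
                       fixation_probabilities, get_state_space, payoff_matrix)
from .ess import ess_map

__all__ = [
    "ExperimentConfig",
    "sweep_heterogeneity",
    "sweep_cost",
    "grid_fixation",
    "rare_mutant_robustness",
    "make_fixtures",
]

#: the three reference average games of the heterogeneity/cost sweeps
REFERENCE_ECOLOGIES = {"SH": (-0.5, 0.5), "CH": (0.5, 1.5), "PD": (-0.5, 1.5)}


@dataclass
class ExperimentConfig:
    """Sweep grid plus fixed parameters of one experiment."""

    experiment: str
    grid: dict = field(default_factory=dict)
    n: int = 60
    beta: float = 1.0
    c: float = 0.1
    delta: float = 2.0
    m: int = 1_000_000
    seed: int = 0
    initial: tuple[int, int, int] = (20, 20, 20)
    agent_kinds: tuple[str, ...] = ("doc", "tog")
    payoff_scale: float | None = None

    def __post_init__(self) -> None:
        fixed = {"n", "beta", "c", "delta", "m", "seed", "initial"}
        dup = fixed & set(self.grid)
        if dup:
            raise ValueError(f"parameters {sorted(dup)} appear in both grid and fixed fields")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["initial"] = list(self.initial)
        d["agent_kinds"] = list(self.agent_kinds)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ExperimentConfig":
        if isinstance(source, Path) or Path(str(source)).exists():
            source = Path(source).read_text()
        d = json.loads(source)
        d["initial"] = tuple(d.get("initial", (20, 20, 20)))
        d["agent_kinds"] = tuple(d.get("agent_kinds", ("doc", "tog")))
        return cls(**d)


def _point_result(s0, t0, cfg: ExperimentConfig, kind: str, delta=None, c=None,
                  initial=None, stats: EcologyStats | None = None) -> dict:
    delta = cfg.delta if delta is None else delta
    c = cfg.c if c is None else c
    initial = cfg.initial if initial is None else initial
    if stats is None:
        stats = compute_stats(Ecology(s0, t0, delta, m=cfg.m, seed=cfg.seed), agent_kind=kind)
    params = DynamicsParams(beta=cfg.beta, c=c, stats=stats, payoff_scale=cfg.payoff_scale)
    state = PopulationState(*initial)
    res = fixation_probabilities(state, params, kind)
    return {
        "S0": s0, "T0": t0, "delta": delta, "c": c, "beta": cfg.beta, "N": cfg.n,
        "X0": initial[0], "Y0": initial[1], "Z0": initial[2], "agent_kind": kind,
        "phi_A": res.phi_a, "phi_C": res.phi_c, "phi_D": res.phi_d,
        "P_c": res.p_c, "alpha": res.alpha, "seed": cfg.seed, "m": cfg.m,
    }


def sweep_heterogeneity(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Fixation probability vs heterogeneity for the SH / CH / PD ecologies."""
    cfg = config or ExperimentConfig("sweep_heterogeneity")
    deltas = cfg.grid.get("deltas", [0.1, 0.25, 0.5, 1.0, 1.5, 2.0])
    rows = []
    for label, (s0, t0) in REFERENCE_ECOLOGIES.items():
        for d in deltas:
            for kind in cfg.agent_kinds:
                row = _point_result(s0, t0, cfg, kind, delta=d)
                row["ecology"] = label
                rows.append(row)
    return pd.DataFrame(rows)


def sweep_cost(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Fixation probability vs inference cost for the SH / CH / PD ecologies."""
    cfg = config or ExperimentConfig("sweep_cost")
    costs = cfg.grid.get("costs", [round(0.05 * i, 2) for i in range(11)])
    rows = []
    for label, (s0, t0) in REFERENCE_ECOLOGIES.items():
        for cost in costs:
            for kind in cfg.agent_kinds:
                row = _point_result(s0, t0, cfg, kind, c=cost)
                row["ecology"] = label
                rows.append(row)
    return pd.DataFrame(rows)


def _grid_axes(cfg: ExperimentConfig):
    g = cfg.grid
    ns = g.get("s0_points", 41)
    nt = g.get("t0_points", 41)
    s0s = np.linspace(*g.get("s0_range", (-1.0, 1.0)), ns)
    t0s = np.linspace(*g.get("t0_range", (0.0, 2.0)), nt)
    return s0s, t0s


def _grid_run(cfg: ExperimentConfig, initial, neutral: float) -> pd.DataFrame:
    """Shared driver for the game-space fixation heatmaps."""
    s0s, t0s = _grid_axes(cfg)
    rows = []
    get_state_space(cfg.n)  # build once up front
    for kind in cfg.agent_kinds:
        doc = doc_stats_grid(s0s, t0s, cfg.delta, m=cfg.m, seed=cfg.seed) if kind == "doc" else None
        for i, s0 in enumerate(s0s):
            for j, t0 in enumerate(t0s):
                eco = Ecology(s0, t0, cfg.delta, m=cfg.m, seed=cfg.seed)
                stats = EcologyStats(mean_s=s0, mean_t=t0, payoff_span=eco.payoff_span)
                if kind == "doc":
                    for k in ("alpha_plus", "splus", "sminus", "tplus", "tminus"):
                        setattr(stats, k, float(doc[k][i, j]))
                else:
                    for k, v in md_split_stats(eco).items():
                        setattr(stats, k, v)
                params = DynamicsParams(beta=cfg.beta, c=cfg.c, stats=stats,
                                        payoff_scale=cfg.payoff_scale)
                # one absorption solve covers every start: the initial state
                # and the fixed-behaviour baseline (0, N/2, N/2)
                space = get_state_space(cfg.n)
                B = space.solve_absorption(payoff_matrix(stats, cfg.c, kind),
                                           cfg.beta, params.scale)
                phi = B[space.index(initial[0], initial[1])]
                alpha = stats.alpha(kind)
                base_phi_c = B[space.index(0, cfg.n // 2), 1]
                rows.append({
                    "S0": s0, "T0": t0, "delta": cfg.delta, "c": cfg.c,
                    "beta": cfg.beta, "N": cfg.n, "X0": initial[0],
                    "Y0": initial[1], "Z0": initial[2], "agent_kind": kind,
                    "phi_A": phi[0], "phi_C": phi[1], "phi_D": phi[2],
                    "P_c": phi[1] + alpha * phi[0], "alpha": alpha,
                    "seed": cfg.seed, "m": cfg.m,
                    "coop_increase": phi[1] + alpha * phi[0] - base_phi_c,
                    "favored": phi[0] > neutral,
                })
    df = pd.DataFrame(rows)
    df.attrs["config"] = cfg.as_dict()
    df.attrs["neutral"] = neutral
    return df


def grid_fixation(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Fixation, cooperation level and cooperation increase over game space.

    Adds per-point ``favored`` (phi_A above the neutral expectation, 1/3 for
    equal initial proportions); the favored-area fraction per agent kind is
    ``df.groupby("agent_kind")["favored"].mean()``.
    """
    cfg = config or ExperimentConfig("grid_fixation")
    neutral = cfg.initial[0] / cfg.n
    return _grid_run(cfg, cfg.initial, neutral)


def rare_mutant_robustness(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Game-space map with the adaptive type starting as a rare minority.

    Initial state (2, N/2 - 1, N/2 - 1); the neutral reference for "favored"
    is the initial adaptive frequency 2/N.
    """
    cfg = config or ExperimentConfig("rare_mutant_robustness")
    initial = (2, cfg.n // 2 - 1, cfg.n // 2 - 1)
    return _grid_run(cfg, initial, initial[0] / cfg.n)


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> dict[str, Path]:
    """Write the small deterministic fixture files used by the test suite.

    * ``ecology_100games.csv`` — 100 sampled games with DoC and class labels,
    * ``chain_n6_reference.csv`` — N=6 fixation probabilities for both kinds,
    * ``ess_5points.csv`` — ESS verdicts at five representative ecologies.

    Byte-identical under the same seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    eco = Ecology(-0.25, 1.25, 2.0, m=100, seed=seed)
    paths["ecology"] = outdir / "ecology_100games.csv"
    games_to_csv(sample_games(eco), paths["ecology"])

    rows = []
    for kind in ("doc", "tog"):
        stats = compute_stats(Ecology(-0.5, 1.5, 2.0, m=10_000, seed=seed), agent_kind=kind)
        params = DynamicsParams(beta=1.0, c=0.1, stats=stats)
        res = fixation_probabilities(PopulationState(2, 2, 2), params, kind)
        rows.append({"N": 6, "agent_kind": kind, "phi_A": res.phi_a,
                     "phi_C": res.phi_c, "phi_D": res.phi_d, "P_c": res.p_c,
                     "seed": seed})
    paths["chain"] = outdir / "chain_n6_reference.csv"
    pd.DataFrame(rows).to_csv(paths["chain"], index=False, float_format="%.15g")

    pts = [(-0.5, 0.5), (0.5, 1.5), (-0.5, 1.5), (0.5, 0.5), (0.0, 1.0)]
    rows = []
    for kind in ("doc", "tog"):
        df, _ = ess_map([p[0] for p in pts], [p[1] for p in pts], delta=2.0,
                        c=0.1, adaptive_kind=kind, m=100_000, seed=seed)
        for (s0, t0) in pts:
            hit = df[(df.S0 == s0) & (df.T0 == t0)].iloc[0]
            rows.append({"S0": s0, "T0": t0, "agent_kind": kind,
                         "is_ess": bool(hit.is_ess), "condition": hit.binding_condition})
    paths["ess"] = outdir / "ess_5points.csv"
    pd.DataFrame(rows).to_csv(paths["ess"], index=False)
    return paths
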