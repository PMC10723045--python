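"""Evolutionary stability of adaptive inference in infinite populations.

A resident adaptive strategy (DoC or ToG inference) is evolutionarily stable
against an invader x in {AllC, AllD} if either the resident strictly
outperforms the invader in a resident world, or they tie and the resident
strictly outperforms the invader in the invader's world:

    pi(AA, AA) > pi(x, AA), or
    pi(AA, AA) = pi(x, AA) and pi(AA, x) > pi(x, x).

All payoffs are expectations over the game ecology; the resident payoff table
for DoC inference (alpha = alpha_plus, unconditional splits) is

    pi(AA, AA)   = alpha - c          pi(AA, AllC) = alpha + t_minus - c
    pi(AllC, AA) = alpha + s_minus    pi(AA, AllD) = s_plus - c
    pi(AllD, AA) = t_plus             pi(AllC, AllC) = 1,  pi(AllD, AllD) = 0

with the ToG analogue using alpha_md and the MD/non-MD splits.

Payoff ties between float Monte-Carlo estimates are declared with a relative
tolerance; the structurally exact ties (e.g. a cost-free inferrer in an
ecology where it always cooperates is payoff-identical to AllC) are thereby
detected rather than broken by sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecology import EcologyStats, doc_stats_grid, md_split_stats, Ecology
from .dynamics import payoff_matrix

__all__ = ["ESSVerdict", "ess_payoffs", "is_ess", "ess_map"]

#: relative tolerance for declaring two expected payoffs equal
EQUALITY_RTOL = 1e-9


@dataclass
class ESSVerdict:
    is_ess: bool
    binding_condition: str
    payoffs: dict = field(default_factory=dict)


def ess_payoffs(stats: EcologyStats, c: float, adaptive_kind: str) -> dict:
    """The six resident/invader payoffs of the ESS test, as a dict."""
    M = payoff_matrix(stats, c, adaptive_kind)
    return {
        "pi_aa_aa": M[0, 0],
        "pi_allc_aa": M[1, 0],
        "pi_alld_aa": M[2, 0],
        "pi_aa_allc": M[0, 1],
        "pi_aa_alld": M[0, 2],
        "pi_allc_allc": M[1, 1],
        "pi_alld_alld": M[2, 2],
    }


def _close(x: float, y: float) -> bool:
    return abs(x - y) <= EQUALITY_RTOL * max(1.0, abs(x), abs(y))


def is_ess(stats: EcologyStats, c: float, adaptive_kind: str) -> ESSVerdict:
    """Two-clause ESS test of the adaptive resident against AllC and AllD."""
    p = ess_payoffs(stats, c, adaptive_kind)
    resident = p["pi_aa_aa"]
    failures = []
    for inv, pi_inv_res, pi_res_inv, pi_inv_inv in (
        ("AllC", p["pi_allc_aa"], p["pi_aa_allc"], p["pi_allc_allc"]),
        ("AllD", p["pi_alld_aa"], p["pi_aa_alld"], p["pi_alld_alld"]),
    ):
        if _close(resident, pi_inv_res):
            if not (pi_res_inv > pi_inv_inv and not _close(pi_res_inv, pi_inv_inv)):
                failures.append(f"{inv} neutral invasion")
        elif pi_inv_res > resident:
            failures.append(f"{inv} invades")
    return ESSVerdict(
        is_ess=not failures,
        binding_condition="stable" if not failures else "; ".join(failures),
        payoffs=p,
    )


def ess_map(s0s, t0s, delta: float, c: float, adaptive_kind: str,
            m: int = 1_000_000, seed: int = 0) -> tuple[pd.DataFrame, float]:
    """ESS verdicts on a (S0, T0) grid; returns (table, ESS area fraction).

    For DoC inference, one shared noise sample translated across the grid
    supplies the statistics (common random numbers); the ToG statistics are
    exact closed forms.  The fraction is the share of grid points where the
    adaptive resident is an ESS.
    """
    s0s = np.atleast_1d(np.asarray(s0s, dtype=float))
    t0s = np.atleast_1d(np.asarray(t0s, dtype=float))
    rows = []
    if adaptive_kind == "doc":
        g = doc_stats_grid(s0s, t0s, delta, m=m, seed=seed)
    for i, s0 in enumerate(s0s):
        for j, t0 in enumerate(t0s):
            eco = Ecology(s0, t0, delta, m=m, seed=seed)
            stats = EcologyStats(mean_s=s0, mean_t=t0, payoff_span=eco.payoff_span)
            if adaptive_kind == "doc":
                stats.alpha_plus = float(g["alpha_plus"][i, j])
                stats.splus = float(g["splus"][i, j])
                stats.sminus = float(g["sminus"][i, j])
                stats.tplus = float(g["tplus"][i, j])
                stats.tminus = float(g["tminus"][i, j])
            else:
                for k, v in md_split_stats(eco).items():
                    setattr(stats, k, v)
            verdict = is_ess(stats, c, adaptive_kind)
            rows.append({"S0": s0, "T0": t0, "is_ess": verdict.is_ess,
                         "binding_condition": verdict.binding_condition})
    df = pd.DataFrame(rows)
    df.attrs["grid"] = {"s0": [float(s0s[0]), float(s0s[-1]), len(s0s)],
                        "t0": [float(t0s[0]), float(t0s[-1]), len(t0s)],
                        "delta": delta, "c": c, "kind": adaptive_kind,
                        "m": m, "seed": seed}
    return df, float(df["is_ess"].mean())
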