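"""Symmetric 2x2 games with fixed reward/punishment payoffs.

Every game in this package has reward for mutual cooperation ``R = 1`` and
punishment for mutual defection ``P = 0``; a game is therefore fully described
by the sucker's payoff ``S`` (cooperating against a defector) and the
temptation ``T`` (defecting against a cooperator).  Varying (S, T) spans the
four archetypal social games:

* MD (Maximizing Difference / Harmony): S > 0, T < 1 — cooperation dominant,
* CH (Chicken / Snowdrift): S > 0, T > 1 — anti-coordination,
* SH (Stag Hunt / Assurance): S < 0, T < 1 — coordination,
* PD (Prisoner's Dilemma): S < 0, T > 1 — defection dominant.

The degree of correspondence of interests (DoC) of a game is the Pearson
correlation between the two players' payoffs across the four outcomes — the
correspondence-of-outcomes index of interdependence theory.  It is +1 when
both players rank outcomes identically (S = T) and -1 under pure conflict.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "R",
    "P",
    "GameMatrix",
    "GameClass",
    "degree_of_correspondence",
    "classify",
    "is_cooperation_dominant",
]

#: Reward for mutual cooperation (fixed for every game).
R: float = 1.0
#: Punishment for mutual defection (fixed for every game).
P: float = 0.0


class GameClass(enum.Enum):
    """The four archetypal symmetric 2x2 games."""

    PD = "PD"
    SH = "SH"
    CH = "CH"
    MD = "MD"


@dataclass(frozen=True)
class GameMatrix:
    """A symmetric 2x2 game with payoffs (R, S, T, P) = (1, S, T, 0).

    Parameters
    ----------
    S : float
        Sucker's payoff of a cooperator meeting a defector.
    T : float
        Temptation payoff of a defector meeting a cooperator.
    """

    S: float
    T: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.S) and np.isfinite(self.T)):
            raise ValueError("S and T must be finite")

    @property
    def doc(self) -> float:
        """Degree of correspondence of interests of this game."""
        return degree_of_correspondence(self)

    @property
    def game_class(self) -> GameClass:
        return classify(self)


def _doc_numerator(S, T):
    # covariance (times 4) of the two payoff vectors (1,S,T,0) and (1,T,S,0)
    mu = (1.0 + S + T) / 4.0
    return (1.0 + 2.0 * S * T) / 4.0 - mu * mu


def degree_of_correspondence(game: GameMatrix | None = None, *, S=None, T=None):
    """Correlation between the two players' payoffs over the four outcomes.

    The actor's payoffs across (CC, CD, DC, DD) are (1, S, T, 0) and the
    partner's are (1, T, S, 0).  Their Pearson correlation is

        DoC = [(1 + 2ST)/4 - mu^2] / [(1 + S^2 + T^2)/4 - mu^2],

    with mu = (1 + S + T)/4.  The denominator is the (shared) variance of the
    four payoffs and is strictly positive because R = 1 != 0 = P, so the index
    is defined for every game.  Symmetric in (S, T); equals 1 iff S = T.

    Accepts either a :class:`GameMatrix` or ``S=, T=`` scalars/arrays.
    """
    if game is not None:
        S, T = game.S, game.T
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    mu = (1.0 + S + T) / 4.0
    num = (1.0 + 2.0 * S * T) / 4.0 - mu * mu
    den = (1.0 + S * S + T * T) / 4.0 - mu * mu
    out = num / den
    return float(out) if out.ndim == 0 else out


def classify(game: GameMatrix) -> GameClass:
    """Assign a game to PD / SH / CH / MD from the signs of S and T - 1.

    Boundary convention (measure zero whenever payoffs are sampled from a
    continuous distribution): S = 0 is grouped with S > 0 and T = 1 with
    T > 1, so e.g. the degenerate game (S=0, T=1) is labelled CH.
    """
    s_pos = game.S >= 0.0
    t_high = game.T >= 1.0
    if s_pos and t_high:
        return GameClass.CH
    if s_pos:
        return GameClass.MD
    if t_high:
        return GameClass.PD
    return GameClass.SH


def is_cooperation_dominant(game: GameMatrix) -> bool:
    """True iff cooperation strictly dominates defection (R > T and S > P).

    With R = 1 and P = 0 this is T < 1 and S > 0 — strict MD membership.
    This strict test is what a type-of-game inferrer acts on; unlike
    :func:`classify`, boundary games (S = 0 or T = 1) are *not* counted.
    """
    return game.T < 1.0 and game.S > 0.0
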