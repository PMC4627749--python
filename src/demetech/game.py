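"""The 2x2 coordination game played across each edge of the deme network.

Every individual plays one of two strategies, the established technology
(``OLD``) or an innovation (``NEW``).  Matching on OLD pays 1, matching on
NEW pays ``alpha > 1`` (the relative fitness benefit of the next rung of the
technology ladder), and miscoordination pays 0.  An individual's payoff in a
period is the *average* of the interaction payoffs over their network
neighbors, so it always lies in ``[0, alpha]``.

``alpha`` may in principle depend on the deme's current technology level
``tau``; :class:`TechSchedule` captures that mapping, with the constant
schedule (a single ``alpha`` for the whole run) as the common case.
"""

from __future__ import annotations

from enum import IntEnum
from typing import Iterable, Mapping, Sequence

from .network import Graph

__all__ = [
    "Strategy",
    "OLD",
    "NEW",
    "TechSchedule",
    "interaction_payoff",
    "individual_payoff",
    "coalition_payoffs",
]


class Strategy(IntEnum):
    OLD = 0
    NEW = 1


OLD = Strategy.OLD
NEW = Strategy.NEW


class TechSchedule:
    """Maps a technology level ``tau`` to the payoff ratio ``alpha_tau > 1``.

    Parameters
    ----------
    alpha : float | Mapping[int, float] | Callable[[int], float]
        A constant ratio, a ``{tau: alpha}`` mapping (missing levels fall
        back to the largest specified level at or below ``tau``), or an
        arbitrary callable.
    """

    def __init__(self, alpha) -> None:
        if callable(alpha):
            self._fn = alpha
        elif isinstance(alpha, Mapping):
            if not alpha:
                raise ValueError("empty alpha mapping")
            levels = sorted(alpha)
            if levels[0] != 0:
                raise ValueError("alpha mapping must define level 0")
            table = dict(alpha)

            def _fn(tau: int, _levels=levels, _table=table) -> float:
                key = max(l for l in _levels if l <= tau)
                return _table[key]

            self._fn = _fn
        else:
            a = float(alpha)
            if a <= 1.0:
                raise ValueError(f"alpha={a} must exceed 1")
            self._fn = lambda tau: a

    def alpha_for(self, tau: int) -> float:
        a = float(self._fn(tau))
        if a <= 1.0:
            raise ValueError(f"alpha_{tau}={a} must exceed 1")
        return a

    @classmethod
    def ensure(cls, alpha) -> "TechSchedule":
        return alpha if isinstance(alpha, TechSchedule) else cls(alpha)


def _check_alpha(alpha: float) -> None:
    if alpha <= 1.0:
        raise ValueError(f"alpha={alpha} must exceed 1")


def interaction_payoff(s_i: Strategy, s_j: Strategy, alpha: float) -> float:
    """Payoff to a player using ``s_i`` against a neighbor using ``s_j``.

    OLD/OLD pays 1, NEW/NEW pays ``alpha``, any mismatch pays 0.  Symmetric
    in its strategy arguments.
    """
    _check_alpha(alpha)
    if s_i != s_j:
        return 0.0
    return alpha if s_i == Strategy.NEW else 1.0


def individual_payoff(
    graph: Graph, strategies: Sequence[int], i: int, alpha: float
) -> float:
    """Degree-averaged payoff of individual ``i`` under a strategy profile.

    Equals the sum of interaction payoffs over ``i``'s neighbors divided by
    ``i``'s degree; requires degree >= 1.
    """
    _check_alpha(alpha)
    nbrs = graph.neighbors[i]
    deg = len(nbrs)
    if deg == 0:
        raise ValueError(f"node {i} has degree 0; payoff undefined")
    s_i = strategies[i]
    matches = sum(1 for j in nbrs if strategies[j] == s_i)
    return matches * (alpha if s_i == Strategy.NEW else 1.0) / deg


def coalition_payoffs(
    graph: Graph, strategies: Sequence[int], members: Iterable[int], alpha: float
) -> list[float]:
    """Payoffs of each coalition member under one profile (batched helper)."""
    return [individual_payoff(graph, strategies, i, alpha) for i in members]
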