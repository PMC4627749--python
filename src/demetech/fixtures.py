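"""Small worked-example demes with analytically known better responses.

Two hand-constructed configurations exhibit the *conservative* and
*reforming* effects of shared intentionality:

``path_fixture`` — a 4-node path ``a - i - j - b`` with ``a, b`` playing OLD
and the adjacent SI pair ``i, j`` playing NEW.  Alone, neither ``i`` nor
``j`` benefits from switching back (each currently earns ``alpha/2`` versus
``1/2`` after a lone switch), but the *pair* reverting jointly to (OLD, OLD)
earns each a payoff of 1, which beats ``alpha/2`` exactly when
``alpha <= 2``: low-alpha innovations are rolled back by collaborating
conservatives.

``reforming_fixture`` — a 6-node graph where the adjacent SI pair ``i, j``
plays OLD, each with one NEW and one OLD outside neighbor.  A lone switch to
NEW pays ``alpha/3`` against a current ``2/3``, profitable only for
``alpha > 2``; the joint switch to (NEW, NEW) pays each ``2*alpha/3``,
profitable for every ``alpha > 1``.  For ``1 < alpha < 2`` collaboration is
therefore the *only* route to the innovation.

These graphs are synthetic constructions chosen to make the two thresholds
exactly computable by exhaustive enumeration; helpers below emit them as
edge-list files together with enumerated better-response tables.
"""

from __future__ import annotations

from pathlib import Path

from .dynamics import DemeState, SI_TYPE, N_TYPE, better_response_profiles
from .game import NEW, OLD
from .network import Graph, write_edge_list

__all__ = [
    "path_fixture",
    "reforming_fixture",
    "enumerate_profiles_table",
    "write_fixture_files",
]


def path_fixture(alpha: float = 1.2) -> DemeState:
    """4-node path a(0)-i(1)-j(2)-b(3); i, j are SI and play NEW."""
    graph = Graph.from_edges(4, [(0, 1), (1, 2), (2, 3)])
    strategies = [int(OLD), int(NEW), int(NEW), int(OLD)]
    types = [SI_TYPE, SI_TYPE, SI_TYPE, SI_TYPE]
    return DemeState(graph, types, tau=0, strategies=strategies, alpha=alpha)


def reforming_fixture(alpha: float = 1.2) -> DemeState:
    """6-node graph: SI pair i(0)-j(1) plays OLD; i's outside neighbors are
    a(2, NEW) and b(3, OLD); j's are c(4, NEW) and d(5, OLD)."""
    graph = Graph.from_edges(6, [(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)])
    strategies = [int(OLD), int(OLD), int(NEW), int(OLD), int(NEW), int(OLD)]
    types = [SI_TYPE, SI_TYPE, N_TYPE, N_TYPE, N_TYPE, N_TYPE]
    return DemeState(graph, types, tau=0, strategies=strategies, alpha=alpha)


def enumerate_profiles_table(
    make_deme, coalition: tuple[int, ...], alphas
) -> list[str]:
    """Lines of an exhaustively enumerated better-response table."""
    lines = [f"coalition {coalition}"]
    for alpha in alphas:
        deme = make_deme(alpha)
        profiles = better_response_profiles(deme, coalition, alpha)
        current = tuple(deme.strategies[m] for m in sorted(coalition))
        names = {0: "old", 1: "new"}
        entries = ", ".join(
            "(" + ",".join(names[s] for s in a) + ")"
            + ("*" if a == current else "")
            for a in sorted(profiles)
        )
        lines.append(f"alpha={alpha}: {entries}")
    return lines


def write_fixture_files(outdir) -> list[Path]:
    """Emit both fixtures as edge lists plus enumerated threshold tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for name, make, coalition, note in [
        (
            "path",
            path_fixture,
            (1, 2),
            "pair reversion (new,new)->(old,old) is a better response iff alpha <= 2",
        ),
        (
            "reforming",
            reforming_fixture,
            (0, 1),
            "pair adoption (old,old)->(new,new) is a better response for all "
            "alpha > 1; no singleton switch improves for alpha < 2",
        ),
    ]:
        deme = make(1.2)
        edge_path = out / f"{name}_edges.txt"
        write_edge_list(deme.graph, edge_path)
        written.append(edge_path)
        table_path = out / f"{name}_better_responses.txt"
        lines = [f"# {note}", f"strategies {deme.strategies} (0=old, 1=new)"]
        lines += enumerate_profiles_table(
            make, coalition, [1.2, 1.5, 2.0, 2.2, 4.0]
        )
        table_path.write_text("\n".join(lines) + "\n")
        written.append(table_path)
    return written
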