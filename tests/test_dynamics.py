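import random
from collections import Counter

import pytest

from demetech.dynamics import (
    DemeState,
    Params,
    apply_mistakes,
    better_response_profiles,
    check_and_apply_adoption,
    run_generation,
    run_period,
    sample_update_coalition,
    select_profile,
    _propose_update,
    _apply_changes,
)
from demetech.game import individual_payoff
from demetech.network import Graph, generate_interaction_graph


def complete_deme(n, types, alpha=1.5):
    g = Graph.from_edges(n, [(u, v) for u in range(n) for v in range(u + 1, n)])
    return DemeState(g, types, alpha=alpha)


# ---------------------------------------------------------------------------
# coalition sampling


def test_all_n_deme_always_samples_uniform_singletons(rng):
    deme = complete_deme(6, [0] * 6)
    counts = Counter()
    for _ in range(6000):
        c = sample_update_coalition(deme, 2, rng)
        assert len(c) == 1
        counts[c[0]] += 1
    assert min(counts.values()) > 800  # roughly uniform over 6 individuals


def test_k1_caps_coalitions_at_singletons(rng):
    deme = complete_deme(6, [1] * 6)
    assert all(len(sample_update_coalition(deme, 1, rng)) == 1 for _ in range(500))


def test_all_si_complete_graph_mixes_singletons_and_pairs(rng):
    deme = complete_deme(6, [1] * 6)
    sizes = Counter(len(sample_update_coalition(deme, 2, rng)) for _ in range(4000))
    # pair attempts occur with probability 1/2
    assert 0.4 < sizes[2] / 4000 < 0.6
    assert sizes[1] + sizes[2] == 4000


@pytest.mark.parametrize("k", [2, 3, 4])
def test_multi_member_coalitions_are_connected_si_sets(k):
    r = random.Random(k)
    g = generate_interaction_graph(16, 4, r)
    types = [1 if r.random() < 0.6 else 0 for _ in range(16)]
    deme = DemeState(g, types, alpha=1.5)
    for _ in range(2000):
        c = sample_update_coalition(deme, k, r)
        assert 1 <= len(c) <= k
        if len(c) >= 2:
            assert all(types[m] == 1 for m in c)
            # connected induced subgraph: grow a reachable set within c
            seen = {c[0]}
            frontier = [c[0]]
            while frontier:
                u = frontier.pop()
                for w in g.neighbors[u]:
                    if w in c and w not in seen:
                        seen.add(w)
                        frontier.append(w)
            assert seen == set(c)


# ---------------------------------------------------------------------------
# better responses on the worked examples


def test_path_singleton_retains_new(path_deme):
    """A lone supported innovator keeps NEW: alpha/2 beats 1/2 for alpha>1."""
    deme = path_deme(1.2)
    profiles = better_response_profiles(deme, (1,), 1.2)
    assert set(profiles) == {(1,)}


def test_path_pair_reversion_depends_on_alpha(path_deme):
    # at alpha=1.2 the SI pair can revert to OLD for payoff 1 > 0.6 each
    deme = path_deme(1.2)
    profiles = better_response_profiles(deme, (1, 2), 1.2)
    assert (0, 0) in profiles and profiles[(0, 0)] == (1.0, 1.0)
    assert select_profile(profiles, (1, 1), random.Random(0)) == (0, 0)
    # at alpha=2.5 reversion is no longer feasible
    deme = path_deme(2.5)
    profiles = better_response_profiles(deme, (1, 2), 2.5)
    assert set(profiles) == {(1, 1)}


def test_reforming_pair_adopts_without_singleton_route(reforming_deme):
    deme = reforming_deme(1.2)
    # no singleton improvement at alpha=1.2 (alpha/3 < 2/3)
    for i in (0, 1):
        profiles = better_response_profiles(deme, (i,), 1.2)
        assert select_profile(profiles, (deme.strategies[i],), random.Random(0)) \
            == (deme.strategies[i],)
    # but the pair can jointly adopt: 2*alpha/3 = 0.8 > 2/3 each
    profiles = better_response_profiles(deme, (0, 1), 1.2)
    assert profiles[(1, 1)] == (pytest.approx(0.8), pytest.approx(0.8))
    assert select_profile(profiles, (0, 0), random.Random(0)) == (1, 1)


def test_profiles_always_contain_current_assignment(small_deme):
    deme, r = small_deme()
    for _ in range(200):
        c = sample_update_coalition(deme, 3, r)
        profiles = better_response_profiles(deme, c, 1.5)
        current = tuple(deme.strategies[m] for m in sorted(c))
        assert current in profiles
        changes = _propose_update(deme, 1.5, 3, 0.2, 0.5, r)
        _apply_changes(deme, changes, 1.5)


def test_select_profile_tie_break(rng):
    profiles = {(0,): (1.0,), (1,): (1.0,)}
    assert select_profile(profiles, (0,), rng) == (0,)  # no strict improvement
    profiles = {(0,): (1.0,), (1,): (2.0,)}
    assert select_profile(profiles, (0,), rng) == (1,)
    # two strict improvements split roughly evenly
    profiles = {(0, 0): (1.0, 1.0), (0, 1): (2.0, 1.0), (1, 0): (1.0, 2.0)}
    picks = Counter(select_profile(profiles, (0, 0), rng) for _ in range(2000))
    assert 800 < picks[(0, 1)] < 1200


# ---------------------------------------------------------------------------
# mistakes


def test_mistakes_identity_at_zero_epsilon(rng):
    assert apply_mistakes((0, 1, 0), 0.0, rng) == (0, 1, 0)


def test_forced_mistake_is_uniform(rng):
    flips = sum(apply_mistakes((0,), 1.0, rng)[0] for _ in range(4000))
    assert 1800 < flips < 2200


def test_small_epsilon_deviation_rate(rng):
    n = 20000
    dev = sum(apply_mistakes((0,), 0.05, rng)[0] for _ in range(n))
    # deviates from intended with probability eps/2 = 0.025
    assert 0.018 < dev / n < 0.032


# ---------------------------------------------------------------------------
# adoption rule


@pytest.mark.parametrize(
    "n,new_count,adopted",
    [(32, 28, False), (32, 29, True), (32, 32, True), (10, 8, False), (10, 9, True)],
)
def test_adoption_threshold_is_inclusive_90_percent(n, new_count, adopted):
    g = Graph.from_edges(n, [(i, (i + 1) % n) for i in range(n)])
    strategies = [1] * new_count + [0] * (n - new_count)
    deme = DemeState(g, [0] * n, strategies=strategies, alpha=1.5)
    assert check_and_apply_adoption(deme) is adopted
    if adopted:
        assert deme.tau == 1
        assert deme.strategies == [0] * n
        assert deme.cur_payoff == [1.0] * n
    else:
        assert deme.tau == 0
        assert deme.strategies == strategies


# ---------------------------------------------------------------------------
# period and generation loops


def test_all_old_deme_is_absorbing_without_mistakes():
    p = Params(m=1, n=16, d=4, alpha=1.5, T=5, epsilon=0.0, engine="python")
    g = generate_interaction_graph(16, 4, 3)
    deme = DemeState(g, [1] * 8 + [0] * 8, alpha=1.5)
    r = random.Random(0)
    for t in range(5):
        adopted = run_period(deme, p, r)
        assert not adopted
    assert deme.strategies == [0] * 16
    # every individual accrued payoff exactly 1 per period
    assert deme.cum_fitness == [5.0] * 16


def test_zero_period_generation_is_a_no_op():
    p = Params(m=1, n=16, d=4, alpha=1.5, T=0, engine="python")
    g = generate_interaction_graph(16, 4, 3)
    deme = DemeState(g, [0] * 16, alpha=1.5)
    stats = run_generation(deme, p, random.Random(0))
    assert stats.steps == 0
    assert stats.cum_fitness == [0.0] * 16


@pytest.mark.parametrize("engine", ["python", "numba"])
def test_generation_determinism_and_cache_coherence(engine):
    p = Params(m=1, n=32, d=6, alpha=2.2, T=50, engine=engine)
    g = generate_interaction_graph(32, 6, 1)
    results = []
    for _ in range(2):
        deme = DemeState(g, [1] * 16 + [0] * 16, alpha=2.2)
        stats = run_generation(deme, p, random.Random(11))
        results.append((deme.strategies[:], deme.tau, stats.steps,
                        deme.cum_fitness[:]))
        alpha_now = p.schedule.alpha_for(deme.tau)
        assert deme.payoff_cache_errors(alpha_now) == 0.0
        assert deme.types == [1] * 16 + [0] * 16  # types never change in-generation
    assert results[0] == results[1]


def test_run_generation_matches_run_period_composition():
    """The batched generation loop is the exact composition of run_period."""
    p = Params(m=1, n=16, d=4, alpha=1.5, T=40, epsilon=0.1, engine="python")
    g = generate_interaction_graph(16, 4, 5)
    d1 = DemeState(g, [1] * 8 + [0] * 8, alpha=1.5)
    d2 = DemeState(g, [1] * 8 + [0] * 8, alpha=1.5)
    stats = run_generation(d1, p, random.Random(42))
    r2 = random.Random(42)
    steps2 = sum(run_period(d2, p, r2) for _ in range(40))
    assert d1.strategies == d2.strategies
    assert d1.tau == d2.tau
    assert stats.steps == steps2
    assert d1.cum_fitness == pytest.approx(d2.cum_fitness, abs=1e-9)


def test_updates_never_hurt_members_without_mistakes(small_deme):
    """With eps=0 no updating member's payoff ever strictly decreases."""
    deme, r = small_deme(alpha=1.3)
    alpha = 1.3
    for _ in range(3000):
        before = list(deme.cur_payoff)
        changes = _propose_update(deme, alpha, 2, 0.0, 0.5, r)
        members = [i for i, _ in changes]
        _apply_changes(deme, changes, alpha)
        for m in members:
            assert deme.cur_payoff[m] >= before[m] - 1e-12


def test_cache_matches_full_recomputation_along_noisy_trajectory(small_deme):
    deme, r = small_deme(alpha=2.0)
    for _ in range(500):
        changes = _propose_update(deme, 2.0, 2, 0.2, 0.5, r)
        _apply_changes(deme, changes, 2.0)
    for i in range(deme.n):
        assert deme.cur_payoff[i] == pytest.approx(
            individual_payoff(deme.graph, deme.strategies, i, 2.0)
        )


def test_adoption_speed_increases_with_alpha():
    """All-N demes climb the ladder faster at alpha=4 than at alpha=1.2."""
    from conftest import single_deme_steps

    lo = sum(single_deme_steps(1.2, False, 100 + s, 1) for s in range(8))
    hi = sum(single_deme_steps(4.0, False, 100 + s, 1) for s in range(8))
    assert hi > lo
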