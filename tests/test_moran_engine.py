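"""The discrete modified-Moran engine: one-generation steps and genealogies."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mmcoal.measures import LambdaMeasure
from mmcoal.moran_engine import (
    AllocationScheme,
    InfeasibleAllocationError,
    ancestry_update,
    fixed_step,
    pairwise_coalescence_mc,
    resize_decline,
    resize_growth,
    simulate,
)
from mmcoal.offspring_laws import LawFamily, coalescence_prob, custom_law, falling_factorial
from mmcoal.size_profiles import SizeProfile, SizeTrajectory, discretize


def constant_traj(N, cN=None, horizon=50.0, n=2):
    cN = cN if cN is not None else 2 / (N * (N - 1))
    return discretize(SizeProfile.constant(), N, cN, horizon, n)


def test_fixed_step_offspring_multiset(rng):
    law = custom_law(6, {4: 1.0})
    a = fixed_step(6, law, rng)
    a.validate()
    assert sorted(a.offspring_counts().tolist()) == [0, 0, 0, 1, 1, 4]
    std = fixed_step(5, custom_law(5, {2: 1.0}), rng)
    assert sorted(std.offspring_counts().tolist()) == [0, 1, 1, 1, 2]


def test_fixed_step_exchangeable_multiplier(rng):
    """Each parent is the multiplier with frequency 1/N (chi-square, fixed seed)."""
    N, reps = 6, 10_000
    law = custom_law(N, {4: 1.0})
    counts = np.zeros(N)
    for _ in range(reps):
        counts[fixed_step(N, law, rng).multiplier_parent] += 1
    stat, p = stats.chisquare(counts)
    assert p > 0.01


def test_resize_decline_enumeration_probs(rng):
    """N_r=4, U=2, target=2: P(U_eff) = (1/6, 4/6, 1/6) for (2, 1, 0)."""
    reps = 30_000
    hits = {0: 0, 1: 0, 2: 0}
    for _ in range(reps):
        a = fixed_step(4, custom_law(4, {2: 1.0}), rng)
        hits[resize_decline(a, 2, rng).U_eff] += 1
    for u_eff, p in [(2, 1 / 6), (1, 4 / 6), (0, 1 / 6)]:
        se = math.sqrt(p * (1 - p) / reps)
        assert abs(hits[u_eff] / reps - p) <= 4 * se


def enumerate_decline_moment(N, U, target, a):
    """Oracle: E((U_eff)_a) by full enumeration of C(N, target) retained subsets."""
    slots = [1] * U + [0] * (N - U)  # 1 marks a multiplier offspring
    total = 0.0
    count = 0
    for keep in itertools.combinations(range(N), target):
        k = sum(slots[i] for i in keep)
        total += falling_factorial(float(k), a)
        count += 1
    return total / count


@pytest.mark.parametrize("N", [4, 6, 8])
def test_decline_preserves_merger_functional(N):
    """Hypergeometric subsampling: E((U_eff)_a)/(target)_a = (U)_a/(N)_a exactly."""
    for U in range(2, N + 1):
        for target in range(2, N):
            for a in (2, 3):
                if a > target:
                    continue  # (target)_a vanishes; the functional is undefined
                lhs = enumerate_decline_moment(N, U, target, a) / falling_factorial(
                    float(target), a
                )
                rhs = falling_factorial(float(U), a) / falling_factorial(float(N), a)
                assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)


def test_resize_growth_figure_example(rng):
    """N=6 with U=4, d=3 and A=1: multiplier ends with 5 of 9 offspring."""
    a = fixed_step(6, custom_law(6, {4: 1.0}), rng)
    grown = resize_growth(a, 3, AllocationScheme.PROPORTIONAL, rng, fixed_a=1)
    grown.validate()
    assert grown.U_eff == 5
    assert grown.N_offspring == 9
    assert sorted(grown.offspring_counts().tolist()) == [0, 1, 1, 1, 1, 5]


def test_resize_growth_identity_and_errors(rng):
    a = fixed_step(6, custom_law(6, {4: 1.0}), rng)
    assert resize_growth(a, 0, AllocationScheme.PROPORTIONAL, rng) is a
    with pytest.raises(InfeasibleAllocationError, match="min"):
        resize_growth(a, 5, AllocationScheme.TO_NONREPRODUCERS, rng)
    all_to_mult = resize_growth(a, 5, AllocationScheme.TO_MULTIPLIER, rng)
    assert all_to_mult.U_eff == 9


def test_proportional_allocation_law(rng):
    """A ~ Binomial(3, 4/6) for N=6, U=4, d=3 (no overflow here)."""
    reps = 10_000
    hits = np.zeros(4)
    for _ in range(reps):
        a = fixed_step(6, custom_law(6, {4: 1.0}), rng)
        grown = resize_growth(a, 3, AllocationScheme.PROPORTIONAL, rng)
        hits[grown.U_eff - 4] += 1
    pm = stats.binom(3, 4 / 6).pmf(np.arange(4))
    for obs, p in zip(hits / reps, pm):
        assert abs(obs - p) <= 4 * math.sqrt(p * (1 - p) / reps)


def test_ancestry_update_merging(rng):
    a = fixed_step(6, custom_law(6, {4: 1.0}), rng)
    mult_slots = np.flatnonzero(a.parents == a.multiplier_parent)
    single_slots = np.flatnonzero(a.parents != a.multiplier_parent)
    blocks = [frozenset({1}), frozenset({2}), frozenset({3})]
    # all three lineages in the multiplier's brood: one triple merger
    placement = {b: int(s) for b, s in zip(blocks, mult_slots[:3])}
    part, _ = ancestry_update(blocks, a, placement, rng)
    assert part == [frozenset({1, 2, 3})]
    # lineages in distinct single-offspring slots: partition unchanged
    std = fixed_step(5, custom_law(5, {2: 1.0}), rng)
    singles = np.flatnonzero(std.parents != std.multiplier_parent)
    placement = {b: int(s) for b, s in zip(blocks, singles[:3])}
    part, place = ancestry_update(blocks, std, placement, rng)
    assert sorted(part, key=min) == blocks
    assert len(set(place.values())) == 3


def test_standard_moran_mergers_are_binary(rng):
    traj = constant_traj(30, horizon=100.0)
    for _ in range(20):
        g = simulate(traj, LawFamily("standard"), AllocationScheme.PROPORTIONAL, 5, rng)
        assert all(len(ev.merged) == 2 for ev in g.events)
        assert g.mrca_generation is not None


def test_simulate_single_lineage(rng):
    traj = constant_traj(20)
    g = simulate(traj, LawFamily("standard"), AllocationScheme.PROPORTIONAL, 1, rng)
    assert g.mrca_generation == 0 and not g.events


def test_simulate_pairwise_mean_generations(rng):
    """Geometric waiting with success 2/(N(N-1)): mean N(N-1)/2 within 3 SE."""
    N, reps = 100, 2000
    traj = constant_traj(N)
    gens = np.array(
        [
            simulate(traj, LawFamily("standard"), AllocationScheme.PROPORTIONAL, 2, rng).mrca_generation
            for _ in range(reps)
        ],
        dtype=float,
    )
    mean_expected = N * (N - 1) / 2
    se = mean_expected / math.sqrt(reps)  # geometric SD ~ mean
    assert abs(gens.mean() - mean_expected) <= 3 * se


def test_star_measure_multi_mergers(rng):
    """Rarefied Dirac(1): activation merges every lineage in the brood."""
    fam = LawFamily("rarefied", measure=LambdaMeasure.point_mass(1.0), gamma=1.5)
    cN = coalescence_prob(fam.at(60))
    traj = discretize(SizeProfile.constant(), 60, cN, 200.0, 5)
    sizes = []
    for _ in range(50):
        g = simulate(traj, fam, AllocationScheme.PROPORTIONAL, 5, rng)
        sizes.extend(len(ev.merged) for ev in g.events)
    assert set(sizes) <= {2, 3, 4, 5}
    assert max(sizes) > 2  # multiple mergers do occur


def test_fast_and_slow_paths_agree(rng):
    """Constant-size geometric skipping matches per-generation stepping."""
    N, reps = 30, 600
    fam = LawFamily("uprime", measure=LambdaMeasure.point_mass(0.4))
    cN = coalescence_prob(fam.at(N))
    fast_traj = discretize(SizeProfile.constant(), N, cN, 200.0, 4)
    slow_traj = SizeTrajectory(np.full(int(200.0 / cN) + 1, N), cN, 4, profile=None)
    assert not slow_traj.is_constant() and fast_traj.is_constant()
    fast = [
        simulate(fast_traj, fam, AllocationScheme.PROPORTIONAL, 4, rng).mrca_generation
        for _ in range(reps)
    ]
    slow = [
        simulate(slow_traj, fam, AllocationScheme.PROPORTIONAL, 4, rng).mrca_generation
        for _ in range(reps)
    ]
    assert stats.ks_2samp(fast, slow).pvalue > 0.01


def test_pairwise_coalescence_mc_examples(rng):
    N = 50
    est, se = pairwise_coalescence_mc(
        LawFamily("standard"), constant_traj(N), 1, 100_000, rng
    )
    exact = 2 / (N * (N - 1))
    assert abs(est - exact) <= 4 * max(se, math.sqrt(exact * (1 - exact) / 100_000))

    star = LawFamily("uprime", measure=LambdaMeasure.point_mass(1.0))
    est, _ = pairwise_coalescence_mc(star, constant_traj(20, cN=0.5), 1, 1000, rng)
    assert est == 1.0  # U == N deterministically


def test_pairwise_coalescence_mc_decline(rng):
    """N_r=6 declining to 3 with U=2: matches enumeration E((U_eff)_2)/(3)_2."""
    traj = SizeTrajectory(np.array([3, 6]), 0.1, 2, profile=None)
    exact = enumerate_decline_moment(6, 2, 3, 2) / (3 * 2)
    est, se = pairwise_coalescence_mc(LawFamily("standard"), traj, 1, 100_000, rng)
    assert abs(est - exact) <= 4 * se


def test_simulate_growth_trajectory_reaches_mrca(rng):
    """Exponentially growing population (looking back: shrinking sizes)."""
    fam = LawFamily("standard")
    N = 80
    cN = 2 / (N * (N - 1))
    traj = discretize(SizeProfile.exponential(0.5), N, cN, 6.0, 3)
    g = simulate(traj, fam, AllocationScheme.TO_NONREPRODUCERS, 3, rng)
    assert g.mrca_generation is not None and not g.open


def test_mutation_overlay_mean(rng):
    """Per-generation lineage mutations: E(count) = 2 theta for a pair sample."""
    N, theta, reps = 40, 2.0, 3000
    cN = 2 / (N * (N - 1))
    traj = constant_traj(N)
    counts = [
        len(
            simulate(
                traj,
                LawFamily("standard"),
                AllocationScheme.PROPORTIONAL,
                2,
                rng,
                mutation_rate=theta * cN,
            ).mutations
        )
        for _ in range(reps)
    ]
    expected = 2 * theta  # 2 lineage-branches of mean length 1/cN generations
    assert abs(np.mean(counts) - expected) <= 5 * 4.5 / math.sqrt(reps)


def test_sample_size_validation(rng):
    traj = constant_traj(10)
    with pytest.raises(ValueError, match="below n|exceeds"):
        simulate(traj, LawFamily("standard"), AllocationScheme.PROPORTIONAL, 11, rng)
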