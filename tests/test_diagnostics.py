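"""Convergence diagnostics: Phi estimates, time scales, limit comparisons."""

import math

import numpy as np
import pytest
from scipy import stats

from mmcoal.diagnostics import (
    MoranGeneration,
    SchweinsbergGeneration,
    empirical_time_scale,
    estimate_phi,
    first_merger_chi2,
    genealogy_convergence_test,
    moehle_sagitov_check,
    remark5_demo,
)
from mmcoal.limit_coalescent import TimeChange, simulate_standard, time_change_G_inverse
from mmcoal.measures import LambdaMeasure
from mmcoal.moran_engine import AllocationScheme, pairwise_coalescence_mc, simulate
from mmcoal.offspring_laws import (
    LawFamily,
    coalescence_prob,
    effective_pmf,
    falling_factorial,
)
from mmcoal.schweinsberg_engine import HeavyTailLaw
from mmcoal.schweinsberg_engine import pairwise_coalescence_mc as schw_pairwise
from mmcoal.size_profiles import SizeProfile, discretize


def constant_traj(N, cN, horizon=50.0, n=2):
    return discretize(SizeProfile.constant(), N, cN, horizon, n)


def test_phi_pairwise_identity(rng):
    """Phi_1(2) is the pairwise coalescence probability."""
    fam = LawFamily("uprime", measure=LambdaMeasure.point_mass(0.4))
    N = 30
    cN = coalescence_prob(fam.at(N))
    traj = constant_traj(N, cN)
    est = estimate_phi(MoranGeneration(fam, traj), (2,), 40_000, rng)
    mc, se = pairwise_coalescence_mc(fam, traj, 1, 40_000, rng)
    assert abs(est.estimate - mc) <= 4 * math.hypot(est.se, se)
    assert abs(est.estimate - cN) <= 4 * est.se


def test_phi_two_sets_structurally_zero(rng):
    """A modified Moran model has one multiplying parent: Phi_2(2,2) = 0."""
    fam = LawFamily("uprime", measure=LambdaMeasure.point_mass(0.5))
    traj = constant_traj(20, coalescence_prob(fam.at(20)))
    est = estimate_phi(MoranGeneration(fam, traj), (2, 2), 3000, rng)
    assert est.estimate == 0.0


def test_phi_triple_matches_closed_form(rng):
    """Phi_1(3) = E((U_N)_3)/(N)_3 for the fixed-size model."""
    fam = LawFamily("uprime", measure=LambdaMeasure.point_mass(0.5))
    N = 30
    law = fam.at(N)
    support, pmf = effective_pmf(law)
    exact = float(np.sum(falling_factorial(support, 3) * pmf)) / (N * 29 * 28)
    traj = constant_traj(N, coalescence_prob(law))
    est = estimate_phi(MoranGeneration(fam, traj), (3,), 60_000, rng)
    assert abs(est.estimate - exact) <= 4 * est.se


def test_phi_schweinsberg_pairwise(rng):
    law = HeavyTailLaw(1.5)
    N = 50
    traj = constant_traj(N, 0.05)
    est = estimate_phi(SchweinsbergGeneration(law, traj), (2,), 20_000, rng)
    mc, se = schw_pairwise(law, N, 50_000, rng)
    assert abs(est.estimate - mc) <= 4 * math.hypot(est.se, se)


def test_phi_pattern_validation(rng):
    fam = LawFamily("standard")
    traj = constant_traj(10, 0.02)
    with pytest.raises(ValueError, match="exceeds"):
        estimate_phi(MoranGeneration(fam, traj), (6, 5), 10, rng)


def test_moehle_sagitov_exact_ratios():
    fam = LawFamily("uprime", measure=LambdaMeasure.beta(1, 1))
    table = moehle_sagitov_check(fam, [50, 200], [(3,), (4,), (2, 2)])
    uni = table[table.pattern == (3,)]
    assert np.allclose(uni.ratio, 0.5, atol=1e-10)  # E(X) of Beta(1,1)
    assert np.allclose(table[table.pattern == (2, 2)].ratio, 0.0)
    std = moehle_sagitov_check(LawFamily("standard"), [200], [(3,)])
    assert std.ratio.iloc[0] == 0.0  # E((2)_3) = 0: Kingman limit
    assert std.limit.iloc[0] == 0.0


def test_time_scale_constant_size():
    fam = LawFamily("standard")
    N = 40
    cN = 2 / (N * (N - 1))
    traj = constant_traj(N, cN, horizon=2.0)
    table = empirical_time_scale(fam, traj, 2.0)
    assert table.F_N(100.4) == pytest.approx(100 * cN, rel=1e-12)
    for t in (0.3, 1.0):
        assert table.G_N_inverse(t) == pytest.approx(math.ceil(t / cN) - 1, abs=1.0)


def test_time_scale_exponential_matches_limit_inverse():
    """Standard Moran under exponential growth: c_N G_N^-1 tracks G^-1 (gamma=2)."""
    N = 500
    cN = 2 / (N * (N - 1))
    traj = discretize(SizeProfile.exponential(1.0), N, cN, 1.05, 2)
    table = empirical_time_scale(
        fam := LawFamily("standard"), traj, 1.02, scheme=AllocationScheme.TO_NONREPRODUCERS
    )
    tc = TimeChange(SizeProfile.exponential(1.0), 2.0)
    for t in (0.2, 0.5, 1.0):
        assert table.rescaled_inverse(t) == pytest.approx(
            time_change_G_inverse(tc, t), rel=0.02
        )


def test_time_scale_mc_mode_agrees(rng):
    fam = LawFamily("standard")
    N = 30
    cN = 2 / (N * (N - 1))
    traj = constant_traj(N, cN, horizon=0.02)
    exact = empirical_time_scale(fam, traj, 0.02)
    mc = empirical_time_scale(fam, traj, 0.02, mode="mc", reps=40_000, rng=rng)
    assert mc.F[-1] == pytest.approx(exact.F[-1], rel=0.25)


def test_monotone_F_on_varying_trajectory():
    fam = LawFamily("standard")
    N = 100
    cN = 2 / (N * (N - 1))
    traj = discretize(SizeProfile.exponential(0.5), N, cN, 1.0, 2)
    table = empirical_time_scale(fam, traj, 1.0, scheme=AllocationScheme.TO_NONREPRODUCERS)
    assert np.all(np.diff(table.F) > 0)


def test_convergence_standard_moran_vs_kingman(rng):
    """Pairwise coalescence times match Exp(1) after rescaling by c_N."""
    N = 100
    fam = LawFamily("standard")
    cN = 2 / (N * (N - 1))
    traj = constant_traj(N, cN)
    kingman = LambdaMeasure.kingman()
    report = genealogy_convergence_test(
        lambda r: simulate(traj, fam, AllocationScheme.PROPORTIONAL, 2, r),
        lambda r: simulate_standard(kingman, 2, r),
        1000,
        rng,
    )
    assert report.ks_tmrca[1] > 0.01


def rarefied_first_merger_pmf(N, n, fam):
    """Finite-N oracle: P(first merger size = k) across one generation."""
    support, pmf = effective_pmf(fam.at(N))
    qs = np.zeros(n + 1)
    for u, pu in zip(support, pmf):
        pk = stats.hypergeom(N, int(u), n).pmf(np.arange(2, n + 1))
        qs[2:] += pu * pk
    return qs[2:] / qs[2:].sum()


def test_rarefied_engine_matches_finite_N_first_merger_law(rng):
    """The simulated first-merger sizes follow the exact finite-N mixture law.

    At N = 80 this law is far from the Dirac(0.5) limit jump chain (the
    Kingman remainder of c_N still carries ~half the merger mass), so the
    engine is validated against the finite-N law itself.
    """
    meas = LambdaMeasure.point_mass(0.5)
    fam = LawFamily("rarefied", measure=meas, gamma=1.5)
    N, n, reps = 80, 6, 500
    traj = discretize(SizeProfile.constant(), N, coalescence_prob(fam.at(N)), 50.0, n)
    sizes = []
    for _ in range(reps):
        g = simulate(traj, fam, AllocationScheme.PROPORTIONAL, n, rng)
        sizes.append(len(g.events[0].merged))
    sizes = np.array(sizes)
    probs = rarefied_first_merger_pmf(N, n, fam)
    observed = np.array([np.sum(sizes == k) for k in range(2, n + 1)], dtype=float)
    expected = reps * probs
    keep = expected >= 5
    observed = np.append(observed[keep][:-1], observed[~keep].sum() + observed[keep][-1])
    expected = np.append(expected[keep][:-1], expected[~keep].sum() + expected[keep][-1])
    assert stats.chisquare(observed, expected).pvalue > 0.01


def test_negative_control_rejects_wrong_limit(rng):
    """First-merger chi-square separates Dirac(0.5) from a Kingman hypothesis."""
    meas = LambdaMeasure.point_mass(0.5)
    fam = LawFamily("rarefied", measure=meas, gamma=1.5)
    N, n = 80, 6
    traj = discretize(SizeProfile.constant(), N, coalescence_prob(fam.at(N)), 50.0, n)
    sizes = []
    for _ in range(300):
        g = simulate(traj, fam, AllocationScheme.PROPORTIONAL, n, rng)
        sizes.append(len(g.events[0].merged))
    _, p_kingman, _ = first_merger_chi2(sizes, LambdaMeasure.kingman(), n)
    assert p_kingman < 0.01


def test_remark5_lower_bound(rng):
    bound, est, se = remark5_demo(100, 0.5, rng, reps=100_000)
    assert bound == pytest.approx(49**2 / (150 * 149), rel=1e-12)
    assert est >= bound - 4 * se
    for N in (50, 200):
        b, e, s = remark5_demo(N, 0.5, rng, reps=50_000)
        assert e >= b - 4 * s


def test_remark5_validation():
    with pytest.raises(ValueError):
        remark5_demo(100, 0.0, np.random.default_rng(0))
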