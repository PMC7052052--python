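"""Empirical verification of coalescent limits of the discrete models.

The convergence machinery rests on the transition functionals
Phi^(N)_l(r; a_1..a_l) -- the probability that specific disjoint sets of
a_1 >= ... >= a_l sampled individuals each find a common parent one
generation back, parents distinct across sets -- and on the time scale
F_N(s) = sum_{r<=s} c_{N,r} with its shifted pseudo-inverse.  The
discrete genealogies converge to a Lambda-n-coalescent iff
``c_N**-1 Phi^(N)_l -> phi_l = lambda_{sum a_i, a_1} 1{a_2=..=a_l=1}``;
this module estimates those quantities by Monte Carlo (or exactly, where
the modified Moran structure permits), and compares whole simulated
genealogy distributions against the limit by KS and chi-square tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mmcoal.measures import LambdaMeasure, merger_rate, merger_size_pmf
from mmcoal.moran_engine import (
    AllocationScheme,
    DiscreteGenealogy,
    InfeasibleAllocationError,
    fixed_step,
    pairwise_coalescence_mc,
    resize_decline,
    resize_growth,
)
from mmcoal.offspring_laws import (
    LawFamily,
    coalescence_prob,
    effective_pmf,
    falling_factorial,
)
from mmcoal.limit_coalescent import CoalescentTree
from mmcoal.schweinsberg_engine import HeavyTailLaw, assemble_generation, sample_offspring_counts
from mmcoal.size_profiles import SizeTrajectory

__all__ = [
    "PhiEstimate",
    "TimeScaleTable",
    "ConvergenceReport",
    "MoranGeneration",
    "SchweinsbergGeneration",
    "estimate_phi",
    "moehle_sagitov_check",
    "empirical_time_scale",
    "first_merger_chi2",
    "genealogy_convergence_test",
    "remark5_demo",
]


# ---------------------------------------------------------------------------
# single-generation models (engine-agnostic parent-label drawers)
# ---------------------------------------------------------------------------

@dataclass
class MoranGeneration:
    """One generation transition of the modified Moran model at index r."""

    law_family: LawFamily
    trajectory: SizeTrajectory
    r: int = 1
    scheme: AllocationScheme = AllocationScheme.PROPORTIONAL

    @property
    def offspring_count(self) -> int:
        return self.trajectory.size(self.r - 1)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        Nr = self.trajectory.size(self.r)
        Nprev = self.trajectory.size(self.r - 1)
        a = fixed_step(Nr, self.law_family.at(Nr), rng, r=self.r)
        if Nprev < Nr:
            a = resize_decline(a, Nprev, rng)
        elif Nprev > Nr:
            a = resize_growth(a, Nprev - Nr, self.scheme, rng)
        return a.parents


@dataclass
class SchweinsbergGeneration:
    """One generation transition of the heavy-tail Cannings model at index r."""

    law: HeavyTailLaw
    trajectory: SizeTrajectory
    r: int = 1

    @property
    def offspring_count(self) -> int:
        return self.trajectory.size(self.r - 1)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        counts, _ = sample_offspring_counts(self.trajectory.size(self.r), self.law, rng)
        return assemble_generation(counts, self.trajectory.size(self.r - 1), rng).parents


@dataclass(frozen=True)
class PhiEstimate:
    pattern: tuple[int, ...]
    r: int
    estimate: float
    se: float
    reps: int

    @property
    def l(self) -> int:
        return len(self.pattern)


def estimate_phi(model, pattern, reps: int, rng: np.random.Generator) -> PhiEstimate:
    """MC estimate of Phi^(N)_l(r; a_1..a_l).

    Per replicate, one generation transition is drawn, ``sum(a_i)``
    distinct offspring are sampled, and the event "each set shares one
    parent, parents pairwise distinct across sets" is scored.
    """
    pattern = tuple(int(a) for a in pattern)
    if any(a < 1 for a in pattern):
        raise ValueError("pattern entries must be >= 1")
    total = sum(pattern)
    if total > model.offspring_count:
        raise ValueError("pattern exceeds the offspring generation size")
    hits = 0
    for _ in range(int(reps)):
        parents = model.draw(rng)
        slots = rng.choice(parents.size, size=total, replace=False)
        pos = 0
        group_parents = []
        ok = True
        for a in pattern:
            p = parents[slots[pos : pos + a]]
            pos += a
            if not np.all(p == p[0]):
                ok = False
                break
            group_parents.append(int(p[0]))
        if ok and len(set(group_parents)) == len(group_parents):
            hits += 1
    est = hits / reps
    se = math.sqrt(max(est * (1.0 - est), 1e-300) / reps)
    return PhiEstimate(pattern=pattern, r=getattr(model, "r", 0), estimate=est, se=se, reps=int(reps))


def _limit_measure(law_family: LawFamily) -> LambdaMeasure:
    if law_family.kind == "standard":
        return LambdaMeasure.kingman()
    return law_family.measure


def moehle_sagitov_check(
    law_family: LawFamily,
    N_grid,
    patterns,
    reps: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Table of c_N**-1 Phi^(N)_l against the limit rates phi_l.

    For the modified Moran model the l = 1 functionals are exact:
    Phi_1(a) = E((U_N)_a) / (N)_a; patterns with a second set of size >= 2
    are structurally zero (a single multiplying parent).  For uprime laws
    the exact ratio equals E(X**(a-2)) at every N.  If ``reps`` is given,
    an MC estimate is reported alongside.
    """
    measure = _limit_measure(law_family)
    rows = []
    for N in N_grid:
        N = int(N)
        law = law_family.at(N)
        cN = coalescence_prob(law)
        support, pmf = effective_pmf(law)
        for pattern in patterns:
            pattern = tuple(int(a) for a in pattern)
            a1 = pattern[0]
            if len(pattern) == 1:
                phi = float(np.sum(falling_factorial(support, a1) * pmf))
                ratio = phi / (falling_factorial(float(N), a1) * cN)
            else:
                ratio = 0.0  # one multiplying parent: no simultaneous mergers
            limit = (
                merger_rate(measure, sum(pattern), a1) if len(pattern) == 1 else 0.0
            )
            row = {"N": N, "pattern": pattern, "ratio": ratio, "limit": limit}
            if reps is not None:
                traj = SizeTrajectory(np.full(2, N), cN, 2, profile=None)
                est = estimate_phi(MoranGeneration(law_family, traj), pattern, reps, rng)
                row["mc_ratio"] = est.estimate / cN
                row["mc_se"] = est.se / cN
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# time scale F_N and its shifted pseudo-inverse
# ---------------------------------------------------------------------------

@dataclass
class TimeScaleTable:
    """F_N(s) on the integer grid s = 1..R and G_N^-1(t) = inf{s: F_N(s) > t} - 1."""

    cN: float
    F: np.ndarray  # F[i] = F_N(i + 1)

    def F_N(self, s: float) -> float:
        i = int(math.floor(s))
        if i <= 0:
            return 0.0
        if i > self.F.size:
            raise ValueError("s beyond the tabulated horizon")
        return float(self.F[i - 1])

    def G_N_inverse(self, t: float) -> float:
        j = int(np.searchsorted(self.F, t, side="right"))  # F[j] > t first
        if j >= self.F.size:
            raise ValueError("t beyond the tabulated horizon of F_N")
        return float(j + 1 - 1)  # s* - 1 with s* = j + 1

    def rescaled_inverse(self, t: float) -> float:
        """c_N * G_N^-1(t), comparable to the limit inverse time change."""
        return self.cN * self.G_N_inverse(t)


def _exact_cNr(law_family: LawFamily, Nr: int, Nprev: int, scheme: AllocationScheme) -> float:
    """Exact coalescence probability of one generation transition.

    Decline is neutral (hypergeometric subsampling preserves the merger
    functional), so c_{N,r} = c_{N_r}.  Growth uses the scheme's
    conditional law of the allocation A.
    """
    law = law_family.at(Nr)
    d = Nprev - Nr
    if d <= 0:
        return coalescence_prob(law)
    support, pmf = effective_pmf(law)
    e2 = 0.0
    for u, pu in zip(support, pmf):
        if pu == 0.0:
            continue
        u = int(u)
        if scheme is AllocationScheme.TO_MULTIPLIER:
            aw = {d: 1.0}
        elif scheme is AllocationScheme.TO_NONREPRODUCERS:
            if d > u - 1:
                raise InfeasibleAllocationError(
                    f"d={d} > U-1={u - 1} (constraint d_{{N,r}} - A_{{N,r}} <= "
                    "min{i: P(U_{N_r}=i)>0} - 1)"
                )
            aw = {0: 1.0}
        else:
            ks = np.arange(0, d + 1)
            pk = stats.binom(d, u / Nr).pmf(ks)
            aw = {}
            for a, pa in zip(ks, pk):
                a_eff = int(a) if d - a <= u - 1 else d - (u - 1)
                aw[a_eff] = aw.get(a_eff, 0.0) + float(pa)
        for a, pa in aw.items():
            ue = u + a
            e2 += pu * pa * ue * (ue - 1.0)
    return e2 / (Nprev * (Nprev - 1.0))


def empirical_time_scale(
    law_family: LawFamily,
    trajectory: SizeTrajectory,
    horizon_t: float,
    scheme: AllocationScheme = AllocationScheme.PROPORTIONAL,
    mode: str = "exact",
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> TimeScaleTable:
    """F_N over ``ceil(horizon_t / cN)`` generations, exactly or by MC.

    ``mode="exact"`` uses the closed-form per-generation coalescence
    probabilities of the modified Moran model; ``mode="mc"`` estimates
    each c_{N,r} by :func:`mmcoal.moran_engine.pairwise_coalescence_mc`
    (only sensible for short horizons).
    """
    cN = trajectory.cN
    R = int(math.ceil(horizon_t / cN))
    c = np.empty(R)
    cache: dict[tuple[int, int], float] = {}
    for r in range(1, R + 1):
        Nr, Nprev = trajectory.size(r), trajectory.size(r - 1)
        if mode == "exact":
            key = (Nr, Nprev)
            if key not in cache:
                cache[key] = _exact_cNr(law_family, Nr, Nprev, scheme)
            c[r - 1] = cache[key]
        elif mode == "mc":
            est, _ = pairwise_coalescence_mc(law_family, trajectory, r, reps, rng, scheme)
            c[r - 1] = est
        else:
            raise ValueError("mode must be 'exact' or 'mc'")
    return TimeScaleTable(cN=cN, F=np.cumsum(c))


# ---------------------------------------------------------------------------
# genealogy-level distribution tests
# ---------------------------------------------------------------------------

def first_merger_chi2(
    sizes_observed,
    measure: LambdaMeasure,
    n: int,
) -> tuple[float, float, int]:
    """Chi-square test of observed first-merger sizes against the limit jump chain.

    Expected probabilities are C(n,k) lambda_{n,k} / lambda_n from the
    measures module; size bins with expected count < 5 are pooled into the
    largest-size bin.  Returns (statistic, p value, dof).
    """
    sizes_observed = np.asarray(sizes_observed, dtype=int)
    reps = sizes_observed.size
    ks, probs = merger_size_pmf(measure, n)
    observed = np.array([np.sum(sizes_observed == k) for k in ks], dtype=float)
    expected = reps * probs
    # a degenerate expectation (e.g. Kingman allows only binary mergers) with
    # observed mass outside its support is an automatic rejection
    if np.any((expected == 0.0) & (observed > 0.0)):
        return math.inf, 0.0, int(np.sum(expected > 0.0))
    keep = expected >= 5.0
    if keep.sum() < 1:
        raise ValueError("too few replicates for a chi-square test")
    # pool all low-expectation sizes together with the largest-size bin
    if not keep.all():
        pool_obs = observed[~keep].sum()
        pool_exp = expected[~keep].sum()
        observed = observed[keep]
        expected = expected[keep]
        observed[-1] += pool_obs
        expected[-1] += pool_exp
    stat, p = stats.chisquare(observed, expected)
    return float(stat), float(p), observed.size - 1


@dataclass
class ConvergenceReport:
    """Distribution tests of discrete genealogies against the limit coalescent."""

    reps: int
    ks_tmrca: tuple[float, float]
    chi2_first_merger: tuple[float, float, int] | None

    def to_frame(self, seed: int | None = None, alpha: float = 0.01) -> pd.DataFrame:
        rows = [
            {
                "check_id": "ks_tmrca",
                "statistic": self.ks_tmrca[0],
                "p_value": self.ks_tmrca[1],
                "n_reps": self.reps,
                "seed": seed,
                "pass": self.ks_tmrca[1] > alpha,
            }
        ]
        if self.chi2_first_merger is not None:
            rows.append(
                {
                    "check_id": "chi2_first_merger",
                    "statistic": self.chi2_first_merger[0],
                    "p_value": self.chi2_first_merger[1],
                    "n_reps": self.reps,
                    "seed": seed,
                    "pass": self.chi2_first_merger[1] > alpha,
                }
            )
        return pd.DataFrame(rows)


def genealogy_convergence_test(
    discrete_draw,
    limit_draw,
    reps: int,
    rng: np.random.Generator,
    measure: LambdaMeasure | None = None,
    n: int | None = None,
) -> ConvergenceReport:
    """Simulate both sides and compare their genealogy distributions.

    ``discrete_draw(rng) -> DiscreteGenealogy`` (with its cN set) and
    ``limit_draw(rng) -> CoalescentTree``.  TMRCAs are compared by
    two-sample KS (discrete times rescaled by cN); if ``measure`` and
    ``n`` are given, first-merger sizes are tested against the analytic
    limit jump-chain pmf by chi-square.
    """
    d_tmrca = np.empty(reps)
    d_first = np.empty(reps, dtype=int)
    l_tmrca = np.empty(reps)
    for i in range(int(reps)):
        g: DiscreteGenealogy = discrete_draw(rng)
        if g.open or g.mrca_generation is None:
            raise RuntimeError("discrete genealogy did not reach its MRCA")
        d_tmrca[i] = g.mrca_generation * g.cN
        d_first[i] = len(g.events[0].merged) if g.events else 0
        t: CoalescentTree = limit_draw(rng)
        l_tmrca[i] = t.tmrca
    ks = stats.ks_2samp(d_tmrca, l_tmrca)
    chi2 = None
    if measure is not None and n is not None and n >= 4:
        chi2 = first_merger_chi2(d_first, measure, n)
    return ConvergenceReport(reps=int(reps), ks_tmrca=(float(ks.statistic), float(ks.pvalue)), chi2_first_merger=chi2)


def remark5_demo(
    N: int, m: float, rng: np.random.Generator, reps: int = 100_000
) -> tuple[float, float, float]:
    """A one-generation expansion fed entirely to the multiplying parent.

    Adding d = floor(N m) individuals to the multiplier in a single
    generation keeps the pairwise coalescence probability of order one:
    it is bounded below by (N m - 1)**2 / ((N_{r-1}) (N_{r-1} - 1)), so
    no time-changed continuous-limit coalescent can describe such a jump.
    Returns (analytic lower bound, MC estimate, MC standard error), based
    on the standard Moran model.
    """
    if not 0.0 < m <= 1.0:
        raise ValueError("m must lie in (0, 1]")
    N = int(N)
    d = int(math.floor(N * m))
    if N * m < 2:
        raise ValueError("N m must be >= 2")
    Nprev = N + d
    bound = (N * m - 1.0) ** 2 / (Nprev * (Nprev - 1.0))
    law_family = LawFamily("standard")
    traj = SizeTrajectory(np.array([Nprev, N]), 2.0 / (N * (N - 1.0)), 2, profile=None)
    est, se = pairwise_coalescence_mc(
        law_family, traj, 1, reps, rng, scheme=AllocationScheme.TO_MULTIPLIER
    )
    return bound, est, se
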