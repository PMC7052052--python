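"""The heavy-tailed-offspring Cannings model of Schweinsberg, with variable sizes.

Every individual of generation r independently produces a number of
potential offspring X with tail ``P(X >= k) = k**(-alpha)``, k >= 1
(``1 <= alpha < 2``; the simplest law with the required tail asymptotics,
with tail constant C = 1 and mean ``mu = zeta(alpha) > 1`` for alpha > 1).
The next generation of size N_{r-1} is a uniform without-replacement
sample from the pool of potential offspring; if the pool falls short --
an exponentially unlikely event, see :func:`shortfall_bound` -- the
missing individuals are attached to independently uniform parents, which
preserves exchangeability.  For fixed size the sample genealogies
converge to the Beta(2-alpha, alpha)-n-coalescent; population size
changes of order N are absorbed into a deterministic time change with
exponent gamma = alpha - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from mmcoal.moran_engine import DiscreteGenealogy, MergerEvent, ParentAssignment
from mmcoal.size_profiles import SizeTrajectory

__all__ = [
    "HeavyTailLaw",
    "BoundUnavailableError",
    "sample_offspring_counts",
    "assemble_generation",
    "simulate",
    "shortfall_bound",
    "empirical_cN_exponent",
    "ExponentFit",
]

_DRAW_CAP = 10**12  # guard against pathological tail draws


class BoundUnavailableError(ValueError):
    """No Chernoff parameter with u**-(1+eps) f(u) < 1 exists for these inputs."""


@dataclass(frozen=True)
class HeavyTailLaw:
    """Offspring law with P(X >= k) = k**(-alpha) on {1, 2, ...}.

    ``alpha`` in [1, 2); the mean is zeta(alpha) for alpha > 1 and infinite
    at alpha = 1 (the Bolthausen-Sznitman regime, where sampling still
    works but moment-based operations refuse).
    """

    alpha: float

    def __post_init__(self) -> None:
        if not 1.0 <= self.alpha < 2.0:
            raise ValueError("alpha must lie in [1, 2)")

    @property
    def mean(self) -> float:
        return float(zeta(self.alpha)) if self.alpha > 1.0 else math.inf

    def tail(self, k) -> np.ndarray | float:
        """P(X >= k)."""
        k = np.asarray(k, dtype=float)
        out = np.where(k <= 1.0, 1.0, k ** (-self.alpha))
        return float(out) if out.shape == () else out

    def pmf(self, k) -> np.ndarray | float:
        """P(X = k) = k**(-alpha) - (k+1)**(-alpha)."""
        k = np.asarray(k, dtype=float)
        lo = np.where(k <= 1.0, 1.0, k ** (-self.alpha))
        out = lo - (k + 1.0) ** (-self.alpha)
        return float(out) if out.shape == () else out

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF draws: X = floor(U**(-1/alpha)), U uniform on (0, 1]."""
        u = 1.0 - rng.random(size)  # in (0, 1]
        x = np.floor(u ** (-1.0 / self.alpha))
        if np.any(x > _DRAW_CAP):
            raise RuntimeError(f"offspring draw exceeded cap {_DRAW_CAP}")
        return x.astype(np.int64)


def sample_offspring_counts(
    N_r: int, law: HeavyTailLaw, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """i.i.d. potential offspring counts X_1..X_{N_r} and the pool total S."""
    if N_r < 1:
        raise ValueError("N_r must be >= 1")
    counts = law.sample(int(N_r), rng)
    return counts, int(counts.sum())


def _realized_multiplicities(
    counts: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Offspring per parent after sampling ``target`` from the pool.

    S >= target: multivariate hypergeometric given the counts.  Shortfall:
    all S offspring are kept and each missing individual is attached to an
    independently uniform parent.
    """
    counts = np.asarray(counts, dtype=np.int64)
    S = int(counts.sum())
    if S >= target:
        return rng.multivariate_hypergeometric(counts, target).astype(np.int64)
    extras = rng.multinomial(target - S, np.full(counts.size, 1.0 / counts.size))
    return counts + extras.astype(np.int64)


def assemble_generation(
    counts: np.ndarray, target: int, rng: np.random.Generator
) -> ParentAssignment:
    """Parent assignment of the ``target`` realized offspring, slots permuted.

    Unlike the modified Moran model, several parents may have two or more
    realized offspring (simultaneous multiple mergers are possible);
    ``multiplier_parent``/``U_eff`` report the largest family.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    mult = _realized_multiplicities(counts, int(target), rng)
    parents = np.repeat(np.arange(mult.size, dtype=np.int64), mult)
    parents = parents[rng.permutation(parents.size)]
    top = int(np.argmax(mult))
    return ParentAssignment(
        r=0,
        N_parents=int(mult.size),
        N_offspring=int(target),
        multiplier_parent=top,
        parents=parents,
        U_eff=int(mult[top]),
    )


def simulate(
    trajectory: SizeTrajectory,
    law: HeavyTailLaw,
    n: int,
    rng: np.random.Generator,
    max_coal_time: float = 1000.0,
) -> DiscreteGenealogy:
    """Genealogy of an n-sample; simultaneous mergers recorded per generation.

    Lineages occupy uniformly random distinct offspring slots, so the
    numbers of lineages per parent are multivariate hypergeometric given
    the realized family sizes; every parent gathering >= 2 lineages causes
    a merger in that generation.
    """
    n = int(n)
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    if trajectory.min_size() < n:
        raise ValueError(f"trajectory dips to {trajectory.min_size()} individuals, below n={n}")
    gen = DiscreteGenealogy(n=n, cN=trajectory.cN)
    blocks = [frozenset({i}) for i in range(1, n + 1)]
    if n == 1:
        gen.mrca_generation = 0
        return gen
    max_gen = int(math.ceil(max_coal_time / trajectory.cN))
    r = 0
    while len(blocks) > 1 and r < max_gen:
        r += 1
        Nr = trajectory.size(r)
        Nprev = trajectory.size(r - 1)
        counts, _ = sample_offspring_counts(Nr, law, rng)
        mult = _realized_multiplicities(counts, Nprev, rng)
        per_parent = rng.multivariate_hypergeometric(mult, len(blocks))
        group_sizes = per_parent[per_parent > 0]
        if np.all(group_sizes < 2):
            continue
        order = rng.permutation(len(blocks))
        pos = 0
        new_blocks: list[frozenset] = []
        merger_groups: list[tuple[frozenset, ...]] = []
        for gsize in group_sizes:
            members = [blocks[i] for i in order[pos : pos + gsize]]
            pos += int(gsize)
            if gsize >= 2:
                merger_groups.append(tuple(sorted(members, key=min)))
                new_blocks.append(frozenset().union(*members))
            else:
                new_blocks.append(members[0])
        blocks = new_blocks
        count_after = len(blocks)
        for merged in merger_groups:
            gen.events.append(MergerEvent(r=r, merged=merged, block_count_after=count_after))
    if len(blocks) == 1:
        gen.mrca_generation = gen.events[-1].r if gen.events else 0
    else:
        gen.open = True
    return gen


def _pgf(law: HeavyTailLaw, u: float, kmax: int = 100_000) -> float:
    """f(u) = E(u^X), truncated series plus the exact tail bound u^{K+1} P(X > K)."""
    k = np.arange(1, kmax + 1)
    val = float(np.sum(law.pmf(k) * u**k))
    return val + u ** (kmax + 1) * float(law.tail(kmax + 1))


def shortfall_bound(
    law: HeavyTailLaw, eps: float, N: int, c_minus: float = 1.0
) -> float:
    """Chernoff bound on P(pool < N_{r-1}) when per-generation growth is <= eps.

    Minimizes ``A_1(u) = u**-(1+eps) f(u)`` over u in (0, 1) (f the
    probability generating function of X) and returns ``A_1 ** (N * c_minus)``,
    where ``c_minus`` is the lower bound on N_r / N along the horizon.
    """
    if law.alpha <= 1.0:
        raise ValueError("shortfall bound requires alpha > 1 (finite mean)")
    if not 0.0 <= eps < law.mean - 1.0:
        raise ValueError("need 0 <= eps < mean - 1")
    obj = lambda u: u ** (-(1.0 + eps)) * _pgf(law, u)
    res = minimize_scalar(obj, bounds=(1e-6, 1.0 - 1e-9), method="bounded")
    a1 = float(res.fun)
    if not a1 < 1.0:
        raise BoundUnavailableError(
            f"no Chernoff parameter gives a bound < 1 (min A_1 = {a1:.4f}); "
            "alpha too close to 1 or eps too large"
        )
    return a1 ** (N * c_minus)


def pairwise_coalescence_mc(
    law: HeavyTailLaw,
    N: int,
    reps: int,
    rng: np.random.Generator,
    target: int | None = None,
    chunk_elems: int = 16_000_000,
) -> tuple[float, float]:
    """MC estimate of c_N (two random distinct offspring share a parent), with SE.

    Replicates are vectorized in chunks; each replicate draws one
    generation's pool and performs one Bernoulli trial with the
    conditional pair probability ``sum_i X_i (X_i - 1) / (S (S - 1))``
    (for a uniformly subsampled generation, a uniform pair of survivors is
    a uniform pair of the pool).
    """
    N = int(N)
    target = N if target is None else int(target)
    reps = int(reps)
    hits = 0
    done = 0
    chunk = max(1, chunk_elems // N)
    while done < reps:
        m = min(chunk, reps - done)
        x = law.sample((m, N), rng).astype(float)
        s = x.sum(axis=1)
        p_same = np.zeros(m)
        ok = s >= target
        ss = s[ok]
        p_same[ok] = np.sum(x[ok] * (x[ok] - 1.0), axis=1) / (ss * (ss - 1.0))
        for i in np.flatnonzero(~ok):  # rare shortfall: assemble explicitly
            mult = _realized_multiplicities(x[i].astype(np.int64), target, rng).astype(float)
            p_same[i] = np.sum(mult * (mult - 1.0)) / (target * (target - 1.0))
        hits += int(np.sum(rng.random(m) < p_same))
        done += m
    est = hits / reps
    se = math.sqrt(max(est * (1.0 - est), 1e-300) / reps)
    return est, se


@dataclass(frozen=True)
class ExponentFit:
    """Weighted log-log regression of c_N on N."""

    slope: float
    slope_se: float
    intercept: float
    N_grid: tuple[int, ...]
    estimates: tuple[float, ...]
    ses: tuple[float, ...]

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.slope - 1.96 * self.slope_se, self.slope + 1.96 * self.slope_se)


def empirical_cN_exponent(
    law,
    N_grid,
    reps: int,
    rng: np.random.Generator,
    estimator=None,
) -> ExponentFit:
    """Slope of log c_N against log N over a grid of population sizes.

    For the heavy-tail law the asymptotic slope is 1 - alpha; plugging a
    different pairwise estimator (``estimator(N, reps, rng) -> (est, se)``)
    reuses the same regression, e.g. the standard Moran model gives -2.
    Weighted least squares with per-point binomial SEs propagated to the
    log scale.
    """
    N_grid = [int(N) for N in N_grid]
    if len(N_grid) < 3:
        raise ValueError("need at least 3 grid sizes")
    if estimator is None:
        if not isinstance(law, HeavyTailLaw):
            raise TypeError("pass a HeavyTailLaw or an explicit estimator")
        if law.alpha <= 1.0:
            raise ValueError("exponent regression requires alpha > 1")
        estimator = lambda N, reps_, rng_: pairwise_coalescence_mc(law, N, reps_, rng_)
    ests, ses = [], []
    for N in N_grid:
        est, se = estimator(N, reps, rng)
        if est <= 0.0:
            raise ValueError(f"pairwise estimate is zero at N={N}; increase reps")
        ests.append(est)
        ses.append(se)
    x = np.log(np.asarray(N_grid, dtype=float))
    y = np.log(np.asarray(ests))
    sig = np.asarray(ses) / np.asarray(ests)  # delta method on the log scale
    w = 1.0 / sig**2
    X = np.column_stack([x, np.ones_like(x)])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    return ExponentFit(
        slope=float(beta[0]),
        slope_se=float(math.sqrt(cov[0, 0])),
        intercept=float(beta[1]),
        N_grid=tuple(N_grid),
        estimates=tuple(ests),
        ses=tuple(ses),
    )
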