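"""Exact simulation of (time-changed) Lambda-n-coalescents.

From b blocks the coalescent waits Exp(lambda_b) and merges k blocks with
probability C(b,k) lambda_{b,k} / lambda_b, the k blocks uniform among all
subsets.  A deterministic population-size profile nu enters only through
the clock: the time-changed process is Pi_{G(t)} with

    G(t) = integral_0^t nu(s)**(-gamma) ds,

where the exponent gamma is a property of the discrete pre-limit model
(2 for the classic Moran model, alpha for the Beta(a, b)-matched modified
Moran models, alpha - 1 for the Schweinsberg model; gamma = 0 covers
models with logarithmic coalescence probability, whose limit genealogy
ignores size changes entirely).  The jump chain is unaffected by the
time change; only waiting times are transformed.  For exponential growth
``nu(t) = exp(-rho t)``, G has the closed form
``(rho gamma)**-1 (exp(rho gamma t) - 1)`` and waiting times are
Gompertz distributed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from mmcoal.measures import LambdaMeasure, merger_size_pmf, total_rate
from mmcoal.size_profiles import SizeProfile, evaluate

__all__ = [
    "TimeChange",
    "CoalescentTree",
    "time_change_G",
    "time_change_G_inverse",
    "simulate_standard",
    "simulate_time_changed",
    "gompertz_waiting_cdf",
    "scatter_mutations",
]

_QUAD_TOL = 1e-10
_ROOT_TOL = 1e-10


@dataclass(frozen=True)
class TimeChange:
    """The clock transformation G(t) = int_0^t nu(s)**(-gamma) ds.

    ``gamma = 0`` encodes the logarithmic-c_N case, for which G is the
    identity regardless of the profile.
    """

    profile: SizeProfile
    gamma: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    def G(self, t: float) -> float:
        return time_change_G(self, t)

    def G_inverse(self, y: float) -> float:
        return time_change_G_inverse(self, y)


def time_change_G(tc: TimeChange, t: float) -> float:
    """G(t); closed form for constant/exponential profiles, quadrature otherwise."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0.0:
        return 0.0
    g = tc.gamma
    if g == 0.0 or tc.profile.kind == "constant":
        return float(t)
    if tc.profile.kind == "exponential":
        rg = tc.profile.rho * g
        if rg == 0.0:
            return float(t)
        return (math.exp(rg * t) - 1.0) / rg
    val, _ = quad(lambda s: evaluate(tc.profile, s) ** (-g), 0.0, t, epsabs=_QUAD_TOL, limit=500)
    return float(val)


def time_change_G_inverse(tc: TimeChange, y: float) -> float:
    """t with G(t) = y; closed-form for exponential profiles, bracketed root otherwise."""
    if y < 0:
        raise ValueError("y must be >= 0")
    if y == 0.0:
        return 0.0
    g = tc.gamma
    if g == 0.0 or tc.profile.kind == "constant":
        return float(y)
    if tc.profile.kind == "exponential":
        rg = tc.profile.rho * g
        if rg == 0.0:
            return float(y)
        arg = 1.0 + rg * y
        if arg <= 0.0:
            raise ValueError("y beyond the range of G for this declining profile")
        return math.log(arg) / rg
    hi = max(y, 1e-6)
    for _ in range(200):
        if time_change_G(tc, hi) >= y:
            break
        hi *= 2.0
    else:
        raise ValueError("could not bracket G inverse; profile horizon too short")
    return float(brentq(lambda t: time_change_G(tc, t) - y, 0.0, hi, xtol=_ROOT_TOL))


@dataclass
class CoalescentTree:
    """Timed merger events of a Lambda-n-coalescent sample genealogy."""

    n: int
    events: list[tuple[float, tuple[frozenset, ...]]] = field(default_factory=list)

    @property
    def tmrca(self) -> float:
        return self.events[-1][0] if self.events else 0.0

    @property
    def first_merger_size(self) -> int | None:
        return len(self.events[0][1]) if self.events else None

    def branches(self) -> list[tuple[frozenset, float, float]]:
        """(block, birth time, merge time) for every non-root block."""
        birth = {frozenset({i}): 0.0 for i in range(1, self.n + 1)}
        out = []
        for t, merged in self.events:
            for b in merged:
                out.append((b, birth.pop(b), t))
            birth[frozenset().union(*merged)] = t
        return out

    @property
    def total_branch_length(self) -> float:
        return sum(t1 - t0 for _, t0, t1 in self.branches())

    def block_count_trajectory(self) -> list[tuple[float, int]]:
        counts = [(0.0, self.n)]
        b = self.n
        for t, merged in self.events:
            b -= len(merged) - 1
            counts.append((t, b))
        return counts


def _simulate(
    measure: LambdaMeasure,
    n: int,
    rng: np.random.Generator,
    tc: TimeChange | None,
) -> CoalescentTree:
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    tree = CoalescentTree(n=n)
    blocks = [frozenset({i}) for i in range(1, n + 1)]
    t = 0.0
    while len(blocks) > 1:
        b = len(blocks)
        lam_b = total_rate(measure, b)
        w = rng.exponential(1.0 / lam_b)  # internal (untransformed) waiting time
        if tc is None:
            t = t + w
        else:
            t = time_change_G_inverse(tc, time_change_G(tc, t) + w)
        sizes, probs = merger_size_pmf(measure, b)
        k = int(rng.choice(sizes, p=probs))
        idx = rng.choice(b, size=k, replace=False)
        chosen = set(idx.tolist())
        merged = tuple(sorted((blocks[i] for i in chosen), key=min))
        blocks = [blk for i, blk in enumerate(blocks) if i not in chosen]
        blocks.append(frozenset().union(*merged))
        tree.events.append((t, merged))
    return tree


def simulate_standard(measure: LambdaMeasure, n: int, rng: np.random.Generator) -> CoalescentTree:
    """A Lambda-n-coalescent tree on the untransformed coalescent clock."""
    return _simulate(measure, n, rng, tc=None)


def simulate_time_changed(
    measure: LambdaMeasure, tc: TimeChange, n: int, rng: np.random.Generator
) -> CoalescentTree:
    """A time-changed Lambda-n-coalescent: Exp(lambda_b) waits on the internal
    clock, mapped to external time by inverting G; the jump chain (and the
    generator's draw sequence) is identical to :func:`simulate_standard`."""
    return _simulate(measure, n, rng, tc=tc)


def gompertz_waiting_cdf(
    b: int,
    t0: float,
    rho: float,
    gamma: float,
    measure: LambdaMeasure,
    t: float,
) -> float:
    """P(next merger within t | b blocks at time t0) under exponential growth.

    The waiting time is Gompertz with parameters ``a = lambda_b exp(rho
    gamma t0)`` and ``b = rho gamma``:
    ``1 - exp(-lambda_b (rho gamma)^-1 e^{rho gamma t0} (e^{rho gamma t} - 1))``.
    """
    if b < 2:
        raise ValueError("b must be >= 2")
    if t0 < 0 or t < 0 or rho <= 0 or gamma <= 0:
        raise ValueError("need t0, t >= 0 and rho, gamma > 0")
    lam_b = total_rate(measure, b)
    rg = rho * gamma
    return 1.0 - math.exp(-lam_b / rg * math.exp(rg * t0) * (math.exp(rg * t) - 1.0))


def scatter_mutations(
    tree: CoalescentTree, theta: float, rng: np.random.Generator
) -> list[tuple[frozenset, float]]:
    """Poisson(theta * L) mutations, uniform on the branch-length measure.

    Each mutation is (carrier block, time); the block records which sample
    members inherit it.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    branches = tree.branches()
    lengths = np.array([t1 - t0 for _, t0, t1 in branches])
    L = float(lengths.sum())
    if L <= 0.0 or theta == 0.0:
        return []
    count = int(rng.poisson(theta * L))
    if count == 0:
        return []
    which = rng.choice(len(branches), size=count, p=lengths / L)
    out = []
    for i in which:
        blk, t0, t1 = branches[int(i)]
        out.append((blk, float(rng.uniform(t0, t1))))
    return out
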