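"""Offspring laws of fixed-size modified Moran models.

A modified Moran model of size N has, each generation, exactly one
randomly chosen parent with ``U_N`` offspring (``U_N`` in {2..N}), ``U_N - 1``
randomly chosen parents with none, and all others with exactly one.  The
law of ``U_N`` determines the genealogy: the model converges to the
Lambda-n-coalescent of a measure Lambda when ``U'_N`` is distributed like
the first merger size of the Lambda-N-coalescent,

    P(U'_N = j) = C(N, j) * E(X**(j-2) * (1-X)**(N-j)) / lambda_N,

with X ~ Lambda and lambda_N the total rate.  Its factorial moments obey
the closed form ``E((U'_N)_k) = (N)_k * E(X**(k-2)) / lambda_N``, which
makes the pairwise coalescence probability exactly ``c'_N = 1/lambda_N``.

The *rarefied* variant activates the sweepstake draw only on an
independent event ``A_N`` with ``P(A_N) = N**(-gamma) * lambda_N``
(and uses the standard Moran ``U = 2`` otherwise), which calibrates the
coalescence probability to ``N**-gamma`` exactly, ``1 < gamma < 2``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln

from mmcoal.measures import LambdaMeasure, measure_moment, total_rate

__all__ = [
    "ModifiedMoranLaw",
    "RarefiedLaw",
    "LawFamily",
    "InfeasibleRarefactionError",
    "uprime_pmf",
    "standard_law",
    "custom_law",
    "factorial_moment",
    "coalescence_prob",
    "rarefy",
    "sample_U",
    "effective_pmf",
    "falling_factorial",
]


class InfeasibleRarefactionError(ValueError):
    """N**(-gamma) * lambda_N exceeds 1, so no activation probability exists."""


def falling_factorial(x, k: int):
    """(x)_k = x (x-1) ... (x-k+1); vectorized, (x)_0 = 1.

    For nonnegative integer x < k the product contains the factor zero, so
    the result vanishes as required by factorial-moment identities.
    """
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    for i in range(int(k)):
        out = out * (x - i)
    return out if out.shape else float(out)


@dataclass(frozen=True, eq=False)
class ModifiedMoranLaw:
    """Distribution of the multiplying parent's offspring count on {2..N}."""

    N: int
    support: np.ndarray = field(repr=False)
    pmf: np.ndarray = field(repr=False)
    provenance: str = "custom"
    measure: LambdaMeasure | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        s = np.asarray(self.support)
        p = np.asarray(self.pmf)
        if s.shape != p.shape or np.any(p < 0):
            raise ValueError("support and pmf must align, pmf nonnegative")
        if np.any((s < 2) | (s > self.N)):
            raise ValueError("support must lie in {2..N}")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("pmf must sum to 1 within 1e-12")

    def mean(self) -> float:
        return float(np.sum(self.support * self.pmf))


@dataclass(frozen=True, eq=False)
class RarefiedLaw:
    """U_N = U'_N on an independent activation event A_N, else 2.

    ``p_activation = N**(-gamma) * lambda_N`` so that the pairwise
    coalescence probability equals ``N**(-gamma)`` plus the standard Moran
    remainder ``(1 - P(A_N)) * 2 / (N (N-1))``.
    """

    base: ModifiedMoranLaw
    gamma: float
    p_activation: float

    def __post_init__(self) -> None:
        if not 1.0 < self.gamma < 2.0:
            raise ValueError("gamma must lie in (1, 2)")
        if not 0.0 <= self.p_activation <= 1.0:
            raise ValueError("p_activation must lie in [0, 1]")

    @property
    def N(self) -> int:
        return self.base.N


def _uprime_log_weights(measure: LambdaMeasure, N: int) -> np.ndarray:
    """log of C(N,j) E(X^{j-2}(1-X)^{N-j}) on j = 2..N (up to normalization)."""
    j = np.arange(2, N + 1)
    logc = gammaln(N + 1) - gammaln(j + 1) - gammaln(N - j + 1)
    if measure.family == "beta":
        a, bp = measure.a, measure.b
        return logc + betaln(a + j - 2, bp + N - j) - betaln(a, bp)
    x = measure.psi
    # psi in (0,1); boundary point masses are handled by the caller
    return logc + (j - 2) * math.log(x) + (N - j) * math.log1p(-x)


def uprime_pmf(measure: LambdaMeasure, N: int) -> ModifiedMoranLaw:
    """Law of U'_N, the first-merger size of the Lambda-N-coalescent.

    Computed in log space and normalized at the end (the normalizer is
    lambda_N), so the pmf is stable for N well beyond 10**3.
    """
    N = int(N)
    if N < 2:
        raise ValueError("N must be >= 2")
    support = np.arange(2, N + 1)
    if measure.family == "point_mass" and measure.psi == 0.0:
        pmf = np.zeros(N - 1)
        pmf[0] = 1.0  # Kingman: always a pair merger, U' == 2
    elif measure.family == "point_mass" and measure.psi == 1.0:
        pmf = np.zeros(N - 1)
        pmf[-1] = 1.0  # star-like: the whole population, U' == N
    else:
        logw = _uprime_log_weights(measure, N)
        m = np.max(logw)
        w = np.exp(logw - m)
        pmf = w / w.sum()
    return ModifiedMoranLaw(N=N, support=support, pmf=pmf, provenance="uprime", measure=measure)


def standard_law(N: int) -> ModifiedMoranLaw:
    """The classic Moran model: the multiplying parent always has 2 offspring."""
    N = int(N)
    support = np.arange(2, N + 1)
    pmf = np.zeros(N - 1)
    pmf[0] = 1.0
    return ModifiedMoranLaw(N=N, support=support, pmf=pmf, provenance="standard")


def custom_law(N: int, pmf: dict[int, float]) -> ModifiedMoranLaw:
    """A user-specified law on {2..N} (e.g. the Eldon-Wakeley two-point model)."""
    N = int(N)
    support = np.arange(2, N + 1)
    p = np.zeros(N - 1)
    for j, pj in pmf.items():
        j = int(j)
        if not 2 <= j <= N:
            raise ValueError(f"support point {j} outside {{2..{N}}}")
        p[j - 2] = pj
    return ModifiedMoranLaw(N=N, support=support, pmf=p, provenance="custom")


def _prob_total_rate(measure: LambdaMeasure, N: int) -> float:
    """lambda_N of the underlying *probability* measure (rate_multiplier removed)."""
    return total_rate(measure, N) / measure.rate_multiplier


def factorial_moment(law: ModifiedMoranLaw | RarefiedLaw, k: int, method: str = "auto") -> float:
    """E((U_N)_k), the k-th falling-factorial moment of the offspring count.

    ``uprime`` laws use the closed form ``(N)_k E(X^{k-2}) / lambda_N`` for
    k >= 2 (``method="auto"`` or ``"closed_form"``); any law can be summed
    directly over its pmf (``method="direct"``).
    """
    k = int(k)
    if k < 1:
        raise ValueError("moment order k must be >= 1")
    if isinstance(law, RarefiedLaw):
        p = law.p_activation
        base = factorial_moment(law.base, k, method=method)
        return p * base + (1.0 - p) * falling_factorial(2.0, k)
    if k > law.N:
        return 0.0
    use_closed = (
        method == "closed_form"
        or (method == "auto" and law.provenance == "uprime" and law.measure is not None and k >= 2)
    )
    if use_closed:
        if law.provenance != "uprime" or law.measure is None or k < 2:
            raise ValueError("closed form requires a uprime law and k >= 2")
        lam = _prob_total_rate(law.measure, law.N)
        return falling_factorial(float(law.N), k) * measure_moment(law.measure, k - 2) / lam
    return float(np.sum(falling_factorial(law.support, k) * law.pmf))


def coalescence_prob(law: ModifiedMoranLaw | RarefiedLaw, N: int | None = None) -> float:
    """Pairwise coalescence probability c_N = E((U_N)_2) / (N (N-1)).

    For uprime laws this is exactly 1/lambda_N; for rarefied laws it is
    ``N**-gamma + (1 - P(A_N)) * 2 / (N (N-1))`` exactly, by construction.
    """
    if N is not None and int(N) != law.N:
        raise ValueError(f"law is defined for N={law.N}, not N={N}")
    n = law.N
    if isinstance(law, RarefiedLaw):
        return n ** (-law.gamma) + (1.0 - law.p_activation) * 2.0 / (n * (n - 1.0))
    return factorial_moment(law, 2) / (n * (n - 1.0))


def rarefy(measure: LambdaMeasure, N: int, gamma: float) -> RarefiedLaw:
    """Thin the sweepstake mechanism so that c'_N P(A_N) = N**-gamma exactly.

    Raises :class:`InfeasibleRarefactionError` when ``N**-gamma * lambda_N > 1``,
    reporting the smallest admissible N if one exists below 10**6.  The
    requirement that ``E((U'_N)_2)/(N-1) = N/lambda_N`` stays bounded away
    from zero is an asymptotic statement; it is checked heuristically on the
    grid {N, 2N, 4N} and only warned about.
    """
    N = int(N)
    base = uprime_pmf(measure, N)
    lam = _prob_total_rate(measure, N)
    p = N ** (-float(gamma)) * lam
    if p > 1.0:
        n_min = None
        for cand in range(N + 1, 1_000_001):
            if cand ** (-float(gamma)) * _prob_total_rate(measure, cand) <= 1.0:
                n_min = cand
                break
        msg = f"N**-gamma * lambda_N = {p:.3g} > 1 at N={N}"
        if n_min is not None:
            msg += f"; smallest admissible N is {n_min}"
        raise InfeasibleRarefactionError(msg)
    ratios = [m / _prob_total_rate(measure, m) for m in (N, 2 * N, 4 * N)]
    if ratios[0] > ratios[1] > ratios[2] and ratios[2] < 0.5 * ratios[0]:
        warnings.warn(
            "E((U'_N)_2)/(N-1) appears to vanish as N grows; the rarefied "
            "construction targets measures with a non-degenerate sweepstake "
            "component",
            stacklevel=2,
        )
    return RarefiedLaw(base=base, gamma=float(gamma), p_activation=p)


def effective_pmf(law: ModifiedMoranLaw | RarefiedLaw) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of the effective offspring count U_N on {2..N}."""
    if isinstance(law, RarefiedLaw):
        support = law.base.support
        pmf = law.p_activation * law.base.pmf.copy()
        pmf[0] += 1.0 - law.p_activation
        return support, pmf
    return law.support, law.pmf


def sample_U(law: ModifiedMoranLaw | RarefiedLaw, rng: np.random.Generator, size: int | None = None):
    """Draw from the (effective) law of U_N; reproducible given the generator state."""
    support, pmf = effective_pmf(law)
    if support.size == 1 or pmf.max() == 1.0:
        j = int(support[int(np.argmax(pmf))])
        return j if size is None else np.full(size, j, dtype=np.int64)
    draw = rng.choice(support, size=size, p=pmf)
    return int(draw) if size is None else draw.astype(np.int64)


@dataclass(frozen=True)
class LawFamily:
    """A recipe producing the modified-Moran offspring law at any population size.

    ``kind`` is one of ``"standard"`` (U == 2), ``"uprime"`` (Lambda-matched
    sweepstake law) or ``"rarefied"`` (uprime thinned to c_N ~ N**-gamma).
    Used by the engines, which need laws at every size along a trajectory.
    """

    kind: str
    measure: LambdaMeasure | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("standard", "uprime", "rarefied"):
            raise ValueError(f"unknown law kind {self.kind!r}")
        if self.kind in ("uprime", "rarefied") and self.measure is None:
            raise ValueError(f"{self.kind} laws require a measure")
        if self.kind == "rarefied" and self.gamma is None:
            raise ValueError("rarefied laws require gamma")

    def at(self, N: int) -> ModifiedMoranLaw | RarefiedLaw:
        key = int(N)
        cache = _LAW_CACHE.setdefault(self, {})
        if key not in cache:
            if self.kind == "standard":
                cache[key] = standard_law(key)
            elif self.kind == "uprime":
                cache[key] = uprime_pmf(self.measure, key)
            else:
                cache[key] = rarefy(self.measure, key, self.gamma)
        return cache[key]


_LAW_CACHE: dict[LawFamily, dict[int, ModifiedMoranLaw | RarefiedLaw]] = {}
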