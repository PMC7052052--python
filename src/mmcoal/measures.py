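"""Lambda-measures and the merger rates of Lambda-n-coalescents.

A Lambda-n-coalescent is parameterized by a finite measure ``Lambda`` on
[0, 1]; any k of b ancestral lineages merge at rate

    lambda_{b,k} = integral_0^1 x**(k-2) * (1-x)**(b-k) Lambda(dx).

Two families are supported: a point mass at ``psi`` (``psi = 0`` gives
Kingman's coalescent, ``psi = 1`` the star-like Dirac coalescent) and a
Beta(a, b) density (``Beta(1, 1)`` is the Bolthausen-Sznitman coalescent;
``Beta(2 - alpha, alpha)`` the Beta-coalescents of sweepstake reproduction).
The underlying measure is always a probability measure; ``rate_multiplier``
scales all rates uniformly, which corresponds to rescaling discrete time by
a constant factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import betaln, gammaln


class InvalidMeasureError(ValueError):
    """The requested measure parameters do not define a usable Lambda-measure."""


@dataclass(frozen=True)
class LambdaMeasure:
    """A finite measure on [0, 1], as ``rate_multiplier`` times a probability measure.

    Parameters
    ----------
    family:
        ``"point_mass"`` (Dirac at ``psi``) or ``"beta"`` (Beta(a, b) density).
    psi:
        Location of the point mass, in [0, 1].  Only for ``point_mass``.
    a, b:
        Positive shape parameters of the Beta density.  Only for ``beta``.
    rate_multiplier:
        Uniform scaling of all merger rates (default 1, i.e. Lambda is a
        probability measure).
    """

    family: str
    psi: float | None = None
    a: float | None = None
    b: float | None = None
    rate_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_multiplier <= 0:
            raise InvalidMeasureError("rate_multiplier must be > 0")
        if self.family == "point_mass":
            if self.psi is None or not 0.0 <= self.psi <= 1.0:
                raise InvalidMeasureError("point_mass requires psi in [0, 1]")
        elif self.family == "beta":
            if self.a is None or self.b is None or self.a <= 0 or self.b <= 0:
                raise InvalidMeasureError("beta requires shape parameters a, b > 0")
        else:
            raise InvalidMeasureError(f"unknown measure family {self.family!r}")

    # -- convenience constructors -------------------------------------------------
    @staticmethod
    def point_mass(psi: float, rate_multiplier: float = 1.0) -> "LambdaMeasure":
        return LambdaMeasure("point_mass", psi=psi, rate_multiplier=rate_multiplier)

    @staticmethod
    def beta(a: float, b: float, rate_multiplier: float = 1.0) -> "LambdaMeasure":
        return LambdaMeasure("beta", a=a, b=b, rate_multiplier=rate_multiplier)

    @staticmethod
    def kingman() -> "LambdaMeasure":
        return LambdaMeasure.point_mass(0.0)

    @staticmethod
    def bolthausen_sznitman() -> "LambdaMeasure":
        return LambdaMeasure.beta(1.0, 1.0)

    def is_kingman(self) -> bool:
        return self.family == "point_mass" and self.psi == 0.0


@dataclass(frozen=True)
class MergerRateTable:
    """All merger rates lambda_{b,k}, k = 2..b, of a Lambda-b-coalescent.

    ``total`` is the total transition rate
    ``lambda_b = sum_k C(b, k) * lambda_{b,k}``.
    """

    b: int
    rates: dict[int, float] = field(repr=False)
    total: float = 0.0

    def __post_init__(self) -> None:
        if self.b < 2:
            raise ValueError("block count b must be >= 2")


def _pow00(x: float, m: float) -> float:
    """x**m with the 0**0 = 1 convention used on the boundary of [0, 1]."""
    if m == 0:
        return 1.0
    return float(x) ** m


def merger_rate(measure: LambdaMeasure, b: int, k: int) -> float:
    """Rate lambda_{b,k} at which a specific set of k of b lineages merges.

    Point masses evaluate the integrand ``x**(k-2) (1-x)**(b-k)`` at psi
    (with 0**0 = 1); Beta measures use the closed form
    ``B(a + k - 2, b_shape + b - k) / B(a, b_shape)``, computed through
    log-Beta differences so large b cannot overflow.
    """
    b = int(b)
    k = int(k)
    if b < 2:
        raise ValueError("b must be >= 2")
    if k < 2 or k > b:
        raise ValueError(f"merger size k={k} outside [2, b={b}]")
    if measure.family == "point_mass":
        x = measure.psi
        val = _pow00(x, k - 2) * _pow00(1.0 - x, b - k)
    else:
        a, bp = measure.a, measure.b
        if a + k - 2 <= 0:
            raise InvalidMeasureError(
                "Beta merger rate diverges: a + k - 2 <= 0 (non-integrable at 0)"
            )
        val = math.exp(betaln(a + k - 2, bp + b - k) - betaln(a, bp))
    return measure.rate_multiplier * val


def _log_binom(b: int, k: np.ndarray) -> np.ndarray:
    return gammaln(b + 1) - gammaln(k + 1) - gammaln(b - k + 1)


def total_rate(measure: LambdaMeasure, b: int) -> float:
    """Total transition rate lambda_b = sum_{k=2}^b C(b,k) lambda_{b,k}."""
    b = int(b)
    if b < 2:
        raise ValueError("b must be >= 2")
    if measure.family == "point_mass":
        x = measure.psi
        if x == 0.0:
            return measure.rate_multiplier * (b * (b - 1) / 2.0)
        if x == 1.0:
            return measure.rate_multiplier * 1.0
        k = np.arange(2, b + 1)
        logterm = _log_binom(b, k) + (k - 2) * math.log(x) + (b - k) * math.log1p(-x)
    else:
        a, bp = measure.a, measure.b
        k = np.arange(2, b + 1)
        logterm = _log_binom(b, k) + betaln(a + k - 2, bp + b - k) - betaln(a, bp)
    # sum in log space: rates stay finite for b up to at least 10**6
    m = float(np.max(logterm))
    return measure.rate_multiplier * float(math.exp(m) * np.sum(np.exp(logterm - m)))


def rate_table(measure: LambdaMeasure, b: int) -> MergerRateTable:
    """The full table of merger rates of the Lambda-b-coalescent."""
    rates = {k: merger_rate(measure, b, k) for k in range(2, b + 1)}
    return MergerRateTable(b=b, rates=rates, total=total_rate(measure, b))


def measure_moment(measure: LambdaMeasure, m: int) -> float:
    """Moment E(X**m) of the underlying probability measure (rate_multiplier ignored)."""
    m = int(m)
    if m < 0:
        raise ValueError("moment order m must be >= 0")
    if m == 0:
        return 1.0
    if measure.family == "point_mass":
        return _pow00(measure.psi, m)
    a, bp = measure.a, measure.b
    return math.exp(betaln(a + m, bp) - betaln(a, bp))


@lru_cache(maxsize=4096)
def _merger_size_distribution(measure: LambdaMeasure, b: int) -> tuple[np.ndarray, np.ndarray]:
    """Jump-chain pmf of the merger size from b blocks: P(k) = C(b,k) lambda_{b,k} / lambda_b.

    Cached per (measure, b); the cache makes repeated coalescent simulation
    at the same block counts cheap.
    """
    k = np.arange(2, b + 1)
    w = np.array([merger_rate(measure, b, int(kk)) for kk in k])
    w = w * np.exp(_log_binom(b, k))
    tot = w.sum()
    if tot <= 0:
        raise InvalidMeasureError(f"total merger rate is zero for b={b}")
    return k, w / tot


def merger_size_pmf(measure: LambdaMeasure, b: int) -> tuple[np.ndarray, np.ndarray]:
    """Sizes (2..b) and probabilities of the next merger of a Lambda-b-coalescent."""
    k, p = _merger_size_distribution(measure, int(b))
    return k.copy(), p.copy()
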