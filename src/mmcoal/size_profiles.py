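"""Population-size profiles in coalescent time and their discrete trajectories.

A profile ``nu(t)`` gives the population size, relative to the reference
size N of the present generation, ``t`` coalescent time units into the
past; one coalescent unit corresponds to ``1/c_N`` generations.  Profiles
must stay positive and bounded on any finite horizon and satisfy
``nu(0) = 1``.  A discrete backward-indexed trajectory ``N_r`` (r = 0 the
sampling generation, r growing into the past) realizes the profile via
``N_r ~ N * nu(r * c_N)``; exponential profiles use the geometric
recursion ``N_r = floor(N * (1 - rho c_N)**r)`` so that per-generation
increments are at most one individual for large N.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SizeProfile",
    "SizeTrajectory",
    "ProfileRangeError",
    "evaluate",
    "discretize",
    "spread_instantaneous",
]


class ProfileRangeError(ValueError):
    """Evaluation outside a tabulated profile's time range."""


@dataclass(frozen=True)
class SizeProfile:
    """A population-size profile nu(t), t >= 0 in coalescent time.

    kinds: ``constant``, ``exponential`` (``nu(t) = exp(-rho t)``, rho > 0
    is growth forward in time), ``piecewise_constant`` (levels between
    breakpoints, first level 1), ``tabulated`` (linear interpolation
    through (times, values), times[0] = 0, values[0] = 1).
    """

    kind: str
    rho: float | None = None
    breakpoints: tuple[float, ...] = ()
    levels: tuple[float, ...] = ()
    times: tuple[float, ...] = ()
    values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "constant":
            pass
        elif self.kind == "exponential":
            if self.rho is None:
                raise ValueError("exponential profile requires rho")
        elif self.kind == "piecewise_constant":
            if len(self.levels) != len(self.breakpoints) + 1:
                raise ValueError("need len(levels) == len(breakpoints) + 1")
            if any(lv <= 0 for lv in self.levels):
                raise ValueError("levels must be positive")
            if self.levels[0] != 1.0:
                raise ValueError("present-day level must be 1 (nu(0) = 1)")
            if list(self.breakpoints) != sorted(self.breakpoints) or (
                self.breakpoints and self.breakpoints[0] <= 0
            ):
                raise ValueError("breakpoints must be positive and increasing")
        elif self.kind == "tabulated":
            t = np.asarray(self.times, dtype=float)
            v = np.asarray(self.values, dtype=float)
            if t.size < 2 or t.size != v.size:
                raise ValueError("tabulated profile needs matching times/values, >= 2 points")
            if t[0] != 0.0 or v[0] != 1.0:
                raise ValueError("tabulated profile must start at (0, 1)")
            if np.any(np.diff(t) <= 0) or np.any(v <= 0):
                raise ValueError("times must increase strictly; values must be positive")
        else:
            raise ValueError(f"unknown profile kind {self.kind!r}")

    # -- constructors ------------------------------------------------------
    @staticmethod
    def constant() -> "SizeProfile":
        return SizeProfile("constant")

    @staticmethod
    def exponential(rho: float) -> "SizeProfile":
        return SizeProfile("exponential", rho=float(rho))

    @staticmethod
    def piecewise(breakpoints, levels) -> "SizeProfile":
        return SizeProfile(
            "piecewise_constant", breakpoints=tuple(breakpoints), levels=tuple(levels)
        )

    @staticmethod
    def tabulated(times, values) -> "SizeProfile":
        return SizeProfile("tabulated", times=tuple(times), values=tuple(values))

    def __call__(self, t: float) -> float:
        return evaluate(self, t)


def evaluate(profile: SizeProfile, t: float) -> float:
    """nu(t) for t >= 0 (coalescent time into the past)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if profile.kind == "constant":
        return 1.0
    if profile.kind == "exponential":
        return math.exp(-profile.rho * t)
    if profile.kind == "piecewise_constant":
        idx = int(np.searchsorted(np.asarray(profile.breakpoints), t, side="right"))
        return float(profile.levels[idx])
    # tabulated
    times = np.asarray(profile.times)
    if t > times[-1]:
        raise ProfileRangeError(
            f"t={t} beyond the tabulated range [0, {times[-1]}]"
        )
    return float(np.interp(t, times, np.asarray(profile.values)))


class SizeTrajectory:
    """Backward-indexed generation sizes N_r realizing a profile.

    ``sizes[r]`` is the population size r generations before sampling;
    ``cN`` maps generations to coalescent time, t = r * cN.  The
    trajectory extends itself on demand by continuing the profile
    (constant extrapolation of the last tabulated value, with a warning).
    Increments are ``d(r) = N_{r-1} - N_r`` (> 0 means the population grew
    from generation r to r-1, forward in time).
    """

    def __init__(
        self,
        sizes: np.ndarray,
        cN: float,
        n_min: int,
        rule=None,
        profile: SizeProfile | None = None,
        horizon_R: int | None = None,
        min_size_hint: int | None = None,
    ) -> None:
        self._sizes = np.asarray(sizes, dtype=np.int64).copy()
        if self._sizes.size < 1:
            raise ValueError("trajectory needs at least the present generation")
        if np.any(self._sizes < max(2, n_min)):
            raise ValueError("trajectory dips below max(2, sample size)")
        self.cN = float(cN)
        self.n_min = int(n_min)
        self._rule = rule
        self.profile = profile
        self.horizon_R = self._sizes.size - 1 if horizon_R is None else int(horizon_R)
        self._min_size_hint = min_size_hint
        self._warned_extension = False

    @property
    def N0(self) -> int:
        return int(self._sizes[0])

    def __len__(self) -> int:
        return self._sizes.size

    @property
    def sizes(self) -> np.ndarray:
        return self._sizes.copy()

    def size(self, r: int) -> int:
        r = int(r)
        if r < 0:
            raise ValueError("generation index r must be >= 0")
        if r < self._sizes.size:
            return int(self._sizes[r])
        if self._rule is not None:
            if r > self.horizon_R and not self._warned_extension:
                warnings.warn(
                    "extending size trajectory beyond its horizon by continuing "
                    "the profile",
                    stacklevel=2,
                )
                self._warned_extension = True
            return int(self._rule(r))
        self._extend_to(r)
        return int(self._sizes[r])

    def min_size(self) -> int:
        """Smallest generation size over the horizon (validated at build time)."""
        m = int(self._sizes.min())
        if self._min_size_hint is not None:
            m = min(m, int(self._min_size_hint))
        return m

    def d(self, r: int) -> int:
        """Increment d_{N,r} = N_{r-1} - N_r (defined for r >= 1)."""
        if r < 1:
            raise ValueError("increments are defined for r >= 1")
        return self.size(r - 1) - self.size(r)

    def is_constant(self) -> bool:
        return self.profile is not None and self.profile.kind == "constant"

    def _extend_to(self, r: int) -> None:
        if not self._warned_extension:
            warnings.warn(
                "extending size trajectory beyond its horizon by continuing "
                "the profile",
                stacklevel=3,
            )
            self._warned_extension = True
        old = self._sizes.size
        new_len = max(r + 1, 2 * old)
        ext = np.empty(new_len, dtype=np.int64)
        ext[:old] = self._sizes
        if self._rule is not None:
            for rr in range(old, new_len):
                ext[rr] = self._rule(rr)
        else:
            ext[old:] = self._sizes[-1]
        self._sizes = ext

    def with_sizes(self, sizes: np.ndarray) -> "SizeTrajectory":
        return SizeTrajectory(sizes, self.cN, self.n_min, rule=None, profile=None)


def discretize(
    profile: SizeProfile,
    N: int,
    cN: float,
    horizon_t: float,
    n: int = 2,
) -> SizeTrajectory:
    """Discrete trajectory N_r covering ``ceil(horizon_t / cN)`` generations.

    Exponential profiles use the geometric recursion
    ``N_r = floor(N (1 - rho cN)**r)`` (the analogous factor > 1 covers
    decline, rho < 0); other profiles round ``N * nu(r cN)`` half-to-even.
    A profile that dips below ``max(2, n)`` individuals is a hard error;
    clamping caused purely by rounding is a warning.
    """
    N = int(N)
    if not 0.0 < cN < 1.0:
        raise ValueError("cN must lie in (0, 1)")
    if horizon_t <= 0:
        raise ValueError("horizon_t must be > 0")
    n_min = max(2, int(n))
    R = int(math.ceil(horizon_t / cN))

    if profile.kind == "exponential":
        rho = profile.rho
        factor = 1.0 - rho * cN
        if factor <= 0:
            raise ValueError("rho * cN >= 1: growth too fast for this time scale")

        def rule(r: int) -> int:
            return int(math.floor(N * factor**r))

    else:

        def rule(r: int) -> int:
            try:
                nu = evaluate(profile, r * cN)
            except ProfileRangeError:
                nu = float(profile.values[-1])  # constant extrapolation
            return int(np.rint(N * nu))

    # materialize up to a cap; beyond it sizes come from the rule on demand
    M = min(R, 1_000_000)
    r_arr = np.arange(M + 1)
    if profile.kind == "exponential":
        sizes = np.floor(N * (1.0 - profile.rho * cN) ** r_arr).astype(np.int64)
        exact = N * (1.0 - profile.rho * cN) ** r_arr
    elif profile.kind == "constant":
        sizes = np.full(M + 1, N, dtype=np.int64)
        exact = sizes.astype(float)
    else:
        nu_vals = np.array([evaluate(profile, float(t)) for t in r_arr * cN])
        exact = N * nu_vals
        sizes = np.rint(exact).astype(np.int64)
    # validate the whole horizon on a coarse coalescent-time grid
    t_grid = np.linspace(0.0, R * cN, 4001)
    if profile.kind == "exponential":
        coarse = N * np.exp(np.log1p(-profile.rho * cN) * np.floor(t_grid / cN))
    elif profile.kind == "constant":
        coarse = np.full(t_grid.size, float(N))
    else:
        coarse = np.array([N * evaluate(profile, min(float(t), R * cN)) for t in t_grid])
    low = np.concatenate([exact, coarse])
    if np.any(low < n_min):
        raise ValueError(
            f"profile dips below max(2, n)={n_min} individuals on the horizon; "
            "increase N or adjust the profile"
        )
    if np.any(sizes < n_min):
        warnings.warn(
            f"clamping {int(np.sum(sizes < n_min))} generation sizes up to {n_min}",
            stacklevel=2,
        )
        sizes = np.maximum(sizes, n_min)

    def clamped_rule(r: int) -> int:
        return max(rule(r), n_min)

    min_hint = max(n_min, int(math.floor(low.min())) - 1)
    return SizeTrajectory(
        sizes, cN, n_min, rule=clamped_rule, profile=profile, horizon_R=R, min_size_hint=min_hint
    )


def spread_instantaneous(trajectory: SizeTrajectory, m: float, at_t: float) -> SizeTrajectory:
    """Spread a single-generation size jump of ``floor(m N)`` over ``ceil(1/sqrt(cN))`` generations.

    An instantaneous (in coalescent time) change of size m*N realized in a
    single generation violates the vanishing-relative-increment condition;
    replacing it by ~1/sqrt(cN) consecutive generations each changing by
    ~ m N sqrt(cN) keeps per-generation relative increments vanishing as N
    grows while leaving the profile unchanged on the coalescent time
    scale.  The spread increments sum exactly to the original jump.
    """
    if m < 0:
        raise ValueError("jump fraction m must be >= 0")
    if m == 0:
        return trajectory
    cN = trajectory.cN
    N = trajectory.N0
    r0 = int(round(at_t / cN))
    if r0 < 1:
        raise ValueError("jump must occur at least one generation into the past")
    jump = trajectory.size(r0) - trajectory.size(r0 - 1)
    expected = int(math.floor(m * N))
    if abs(jump) != expected:
        raise ValueError(
            f"trajectory jump at r={r0} is {jump}, not +/-{expected} = floor(m N)"
        )
    G = int(math.ceil(1.0 / math.sqrt(cN)))
    needed = max(trajectory.sizes.size - 1, r0 + G + 1)
    old = np.array([trajectory.size(r) for r in range(needed + 1)], dtype=np.int64)

    sign = 1 if jump > 0 else -1
    base, rem = divmod(abs(jump), G)
    increments = np.full(G, base, dtype=np.int64)
    increments[:rem] += 1
    increments *= sign  # sums exactly to `jump`

    new = np.empty(old.size + G - 1, dtype=np.int64)
    new[:r0] = old[:r0]
    for i in range(G):
        new[r0 + i] = new[r0 + i - 1] + increments[i]
    new[r0 + G :] = old[r0 + 1 :]
    if np.any(new < trajectory.n_min):
        raise ValueError("spread jump drives the population below max(2, n)")
    return trajectory.with_sizes(new)
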