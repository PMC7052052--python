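"""Discrete genealogies of modified Moran models with variable population sizes.

Each generation r has N_r parents producing N_{r-1} offspring.  A fixed-size
step first assigns offspring within the size-N_r modified Moran model (one
multiplying parent with U offspring, U - 1 parents with none, the rest one
each); the population change d_{N,r} = N_{r-1} - N_r is then realized by

* decline (d < 0): retaining a uniform without-replacement subset of the
  N_r potential offspring, so the multiplier's surviving brood is
  hypergeometric -- this preserves all merger probabilities exactly;
* growth (d > 0): adding A individuals to the multiplier's brood and d - A
  as single offspring of previously non-reproducing parents, where A is
  set by the allocation scheme (all to the multiplier, none, or binomially
  with success probability U/N_r).

Sample genealogies are followed lineage-wise: because offspring order is
exchangeable, the <= n ancestral lineages occupy uniformly random distinct
offspring slots, so the number hitting the multiplier's brood is
hypergeometric and no population-sized array is ever materialized.  On
constant-size stretches merger-free generations are skipped geometrically,
which makes Kingman-scale horizons (~N^2 generations) cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.stats import hypergeom

from mmcoal.offspring_laws import (
    LawFamily,
    ModifiedMoranLaw,
    RarefiedLaw,
    effective_pmf,
    sample_U,
)
from mmcoal.size_profiles import SizeTrajectory

__all__ = [
    "AllocationScheme",
    "ParentAssignment",
    "MergerEvent",
    "DiscreteGenealogy",
    "InfeasibleAllocationError",
    "fixed_step",
    "resize_decline",
    "resize_growth",
    "ancestry_update",
    "simulate",
    "pairwise_coalescence_mc",
]


class AllocationScheme(str, Enum):
    """Where individuals added under population growth come from."""

    TO_MULTIPLIER = "to_multiplier"
    TO_NONREPRODUCERS = "to_nonreproducers"
    PROPORTIONAL = "proportional"


class InfeasibleAllocationError(ValueError):
    """The allocation scheme cannot place the added individuals.

    Growth allocated to non-reproducing parents is limited by the
    constraint d_{N,r} - A_{N,r} <= min{i : P(U_{N_r} = i) > 0} - 1.
    """


@dataclass
class ParentAssignment:
    """Offspring-slot -> parent map for one generation transition.

    ``parents[s]`` is the parent index (in 0..N_parents-1) of offspring
    slot s; slots are in exchangeable (uniformly permuted) order.
    ``U_eff`` counts the multiplier's surviving/augmented brood; after a
    decline it may degenerate to 0 or 1 (no multi-merger possible then).
    """

    r: int
    N_parents: int
    N_offspring: int
    multiplier_parent: int
    parents: np.ndarray = field(repr=False)
    U_eff: int = 0

    def offspring_counts(self) -> np.ndarray:
        return np.bincount(self.parents, minlength=self.N_parents)

    def validate(self) -> None:
        counts = np.bincount(self.parents, minlength=self.N_parents)
        if self.parents.size != self.N_offspring:
            raise AssertionError("slot count mismatch")
        big = np.flatnonzero(counts >= 2)
        if self.U_eff >= 2:
            if big.size != 1 or big[0] != self.multiplier_parent:
                raise AssertionError("exactly one parent may have >= 2 offspring")
            if counts[self.multiplier_parent] != self.U_eff:
                raise AssertionError("U_eff inconsistent with slot map")
        elif big.size != 0:
            raise AssertionError("degenerate assignment must have no multi-offspring parent")


@dataclass(frozen=True)
class MergerEvent:
    """A coalescence at generation r: ``merged`` blocks collapse into one."""

    r: int
    merged: tuple[frozenset, ...]
    block_count_after: int


@dataclass
class DiscreteGenealogy:
    """Partition-valued ancestry of an n-sample, with generation-stamped mergers."""

    n: int
    events: list[MergerEvent] = field(default_factory=list)
    mrca_generation: int | None = None
    open: bool = False
    cN: float | None = None
    mutations: list[tuple[int, frozenset]] = field(default_factory=list)

    def partition_at(self, r: int) -> list[frozenset]:
        """Partition of {1..n} after all mergers up to and including generation r."""
        blocks = {frozenset({i}) for i in range(1, self.n + 1)}
        for ev in self.events:
            if ev.r > r:
                break
            for b in ev.merged:
                blocks.discard(b)
            blocks.add(frozenset().union(*ev.merged))
        return sorted(blocks, key=min)

    @property
    def block_counts(self) -> list[int]:
        return [ev.block_count_after for ev in self.events]


# ---------------------------------------------------------------------------
# explicit single-generation operations (used at small N and by diagnostics)
# ---------------------------------------------------------------------------

def fixed_step(N: int, law: ModifiedMoranLaw | RarefiedLaw, rng: np.random.Generator, r: int = 0) -> ParentAssignment:
    """One generation of the fixed-size modified Moran model, slots permuted."""
    N = int(N)
    U = sample_U(law, rng)
    order = rng.permutation(N)
    multiplier = int(order[0])
    # order[1:U] are the U-1 non-reproducers; the rest have one offspring each
    single_parents = order[U:]
    parents = np.concatenate([np.full(U, multiplier, dtype=np.int64), single_parents])
    parents = parents[rng.permutation(N)]
    return ParentAssignment(
        r=r, N_parents=N, N_offspring=N, multiplier_parent=multiplier, parents=parents, U_eff=U
    )


def resize_decline(
    assignment: ParentAssignment, target: int, rng: np.random.Generator
) -> ParentAssignment:
    """Keep a uniform without-replacement subset of ``target`` offspring.

    The multiplier's surviving brood is hypergeometric given U, which
    leaves every merger functional Phi unchanged (subsampling neutrality).
    """
    target = int(target)
    if target < 2:
        raise ValueError("target population size must be >= 2")
    if target > assignment.N_offspring:
        raise ValueError("decline target exceeds current offspring count")
    if target == assignment.N_offspring:
        return assignment
    keep = rng.choice(assignment.N_offspring, size=target, replace=False)
    parents = assignment.parents[keep]
    u_eff = int(np.sum(parents == assignment.multiplier_parent))
    return ParentAssignment(
        r=assignment.r,
        N_parents=assignment.N_parents,
        N_offspring=target,
        multiplier_parent=assignment.multiplier_parent,
        parents=parents,
        U_eff=u_eff,
    )


def _draw_allocation(
    u: int, N: int, d: int, scheme: AllocationScheme, rng: np.random.Generator
) -> int:
    """Number A of added individuals given to the multiplying parent."""
    if scheme is AllocationScheme.TO_MULTIPLIER:
        return d
    if scheme is AllocationScheme.TO_NONREPRODUCERS:
        if d > u - 1:
            raise InfeasibleAllocationError(
                f"cannot add d={d} individuals to non-reproducers: only U-1={u - 1} "
                "slots (constraint d_{N,r} - A_{N,r} <= min{i: P(U_{N_r}=i)>0} - 1)"
            )
        return 0
    # proportional: each added individual goes to the multiplier w.p. U/N,
    # overflow beyond the U-1 non-reproducer slots is forced to the multiplier
    a = int(rng.binomial(d, u / N))
    if d - a > u - 1:
        a = d - (u - 1)
    return a


def resize_growth(
    assignment: ParentAssignment,
    d: int,
    scheme: AllocationScheme,
    rng: np.random.Generator,
    fixed_a: int | None = None,
) -> ParentAssignment:
    """Add d individuals: A to the multiplier's brood, d - A to non-reproducers.

    ``fixed_a`` overrides the scheme with a deterministic allocation (used
    in worked examples and diagnostics).
    """
    d = int(d)
    if d < 0:
        raise ValueError("d must be >= 0 for growth")
    if d == 0:
        return assignment
    u = assignment.U_eff
    if u < 2:
        raise ValueError("growth step requires a multiplying parent (U >= 2)")
    if fixed_a is not None:
        a = int(fixed_a)
        if a < 0 or d - a > u - 1:
            raise InfeasibleAllocationError(
                f"fixed allocation A={a} infeasible for d={d}, U={u} "
                "(constraint d_{N,r} - A_{N,r} <= min{i: P(U_{N_r}=i)>0} - 1)"
            )
    else:
        a = _draw_allocation(u, assignment.N_parents, d, scheme, rng)
    counts = assignment.offspring_counts()
    nonrep = np.flatnonzero(counts == 0)
    extra_single = rng.choice(nonrep, size=d - a, replace=False) if d - a > 0 else np.empty(0, dtype=np.int64)
    parents = np.concatenate(
        [
            assignment.parents,
            np.full(a, assignment.multiplier_parent, dtype=np.int64),
            extra_single.astype(np.int64),
        ]
    )
    parents = parents[rng.permutation(parents.size)]
    return ParentAssignment(
        r=assignment.r,
        N_parents=assignment.N_parents,
        N_offspring=assignment.N_offspring + d,
        multiplier_parent=assignment.multiplier_parent,
        parents=parents,
        U_eff=u + a,
    )


def ancestry_update(
    partition: list[frozenset],
    assignment: ParentAssignment,
    placement: dict[frozenset, int],
    rng: np.random.Generator,
) -> tuple[list[frozenset], dict[frozenset, int]]:
    """Follow each block's offspring slot to its parent; merge equal parents.

    ``placement`` maps each block to the offspring slot its lineage
    occupies (slots must be distinct).  The returned placement maps the new
    blocks to parent individuals; re-randomizing slots uniformly at the
    next generation is distributionally equivalent to tracking the
    permuted offspring order explicitly.
    """
    slots = [placement[b] for b in partition]
    if len(set(slots)) != len(slots):
        raise AssertionError("lineages must occupy distinct offspring slots")
    by_parent: dict[int, list[frozenset]] = {}
    for b in partition:
        by_parent.setdefault(int(assignment.parents[placement[b]]), []).append(b)
    new_partition: list[frozenset] = []
    new_placement: dict[frozenset, int] = {}
    for parent, group in by_parent.items():
        merged = frozenset().union(*group)
        new_partition.append(merged)
        new_placement[merged] = parent
    return new_partition, new_placement


# ---------------------------------------------------------------------------
# lineage-wise simulation
# ---------------------------------------------------------------------------

def _ratio_ff(N: int, u: np.ndarray, b: int) -> np.ndarray:
    """(N-u)_b / (N)_b computed as a product of ratios in [0, 1]."""
    out = np.ones_like(u, dtype=float)
    for i in range(b):
        out *= np.clip((N - u - i) / (N - i), 0.0, None)
    return out


_KERNEL_CACHE: dict[tuple, tuple] = {}


def _merger_kernel(law_family: LawFamily, N: int, b: int):
    """Constant-size merger kernel for b lineages at population size N.

    Returns (q, support, w, k_pmfs): q is the per-generation probability of
    any merger; w the conditional law of U given a merger; k_pmfs[u] the
    conditional pmf of the merger size K >= 2 given U = u.
    """
    key = (law_family, N, b)
    if key in _KERNEL_CACHE:
        return _KERNEL_CACHE[key]
    law = law_family.at(N)
    support, pmf = effective_pmf(law)
    mask = pmf > 0
    support, pmf = support[mask], pmf[mask]
    h0 = _ratio_ff(N, support, b)
    h1 = np.zeros_like(h0)
    if b >= 1:
        h1 = b * support / (N - b + 1) * _ratio_ff(N, support, b - 1)
    p_merge = np.clip(1.0 - h0 - h1, 0.0, 1.0)
    q = float(np.sum(pmf * p_merge))
    if q > 0:
        w = pmf * p_merge / q
    else:
        w = pmf
    k_pmfs = {}
    for u in support:
        kmax = min(b, int(u))
        ks = np.arange(2, kmax + 1)
        pk = hypergeom(N, int(u), b).pmf(ks)
        tot = pk.sum()
        k_pmfs[int(u)] = (ks, pk / tot if tot > 0 else pk)
    result = (q, support, w, k_pmfs)
    _KERNEL_CACHE[key] = result
    return result


def _u_effective(
    law_family: LawFamily,
    Nr: int,
    Nprev: int,
    scheme: AllocationScheme,
    rng: np.random.Generator,
) -> int:
    """Draw the multiplier's offspring count after the resize step."""
    u = sample_U(law_family.at(Nr), rng)
    d = Nprev - Nr
    if d < 0:
        return int(rng.hypergeometric(u, Nr - u, Nprev))
    if d > 0:
        return u + _draw_allocation(u, Nr, d, scheme, rng)
    return u


def simulate(
    trajectory: SizeTrajectory,
    law_family: LawFamily,
    scheme: AllocationScheme,
    n: int,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
    max_coal_time: float = 1000.0,
) -> DiscreteGenealogy:
    """Genealogy of an n-sample under the modified Moran model on a trajectory.

    Runs generations r = 1, 2, ... until one ancestral block remains; a run
    exceeding ``max_coal_time / cN`` generations is flagged open.  With
    ``mutation_rate`` > 0, each lineage mutates independently with that
    probability per generation (the discrete counterpart of a Poisson
    overlay with intensity theta = mutation_rate / cN).
    """
    n = int(n)
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    if n > trajectory.size(0):
        raise ValueError("sample size exceeds present population size")
    # validate reachable sizes against the sample before starting
    if trajectory.min_size() < n:
        raise ValueError(f"trajectory dips to {trajectory.min_size()} individuals, below n={n}")
    gen = DiscreteGenealogy(n=n, cN=trajectory.cN)
    blocks = [frozenset({i}) for i in range(1, n + 1)]
    if n == 1:
        gen.mrca_generation = 0
        return gen
    max_gen = int(math.ceil(max_coal_time / trajectory.cN))
    r = 0
    constant = trajectory.is_constant()
    while len(blocks) > 1 and r < max_gen:
        r += 1
        b = len(blocks)
        Nr = trajectory.size(r)
        Nprev = trajectory.size(r - 1)
        if constant:
            q, support, w, k_pmfs = _merger_kernel(law_family, Nr, b)
            if q <= 0.0:
                r = max_gen
                break
            g = int(rng.geometric(q))  # generation offset of the next merger
            if mutation_rate > 0.0:
                _scatter_discrete_mutations(gen, blocks, r, g, mutation_rate, rng)
            r += g - 1
            if r > max_gen:
                r = max_gen
                break
            u = int(rng.choice(support, p=w))
            ks, pk = k_pmfs[u]
            k = int(rng.choice(ks, p=pk))
        else:
            u_eff = _u_effective(law_family, Nr, Nprev, scheme, rng)
            if u_eff < 2:
                k = 0
            else:
                k = int(rng.hypergeometric(u_eff, Nprev - u_eff, b))
            if mutation_rate > 0.0:
                _scatter_discrete_mutations(gen, blocks, r, 1, mutation_rate, rng)
        if k >= 2:
            idx = rng.choice(b, size=k, replace=False)
            merged = tuple(blocks[i] for i in sorted(idx))
            survivors = [blocks[i] for i in range(b) if i not in set(idx.tolist())]
            survivors.append(frozenset().union(*merged))
            blocks = survivors
            gen.events.append(MergerEvent(r=r, merged=merged, block_count_after=len(blocks)))
    if len(blocks) == 1:
        gen.mrca_generation = gen.events[-1].r if gen.events else 0
    else:
        gen.open = True
    return gen


def _scatter_discrete_mutations(gen, blocks, r_start, span, mu, rng):
    b = len(blocks)
    count = int(rng.binomial(span * b, mu))
    for _ in range(count):
        gg = r_start + int(rng.integers(span))
        gen.mutations.append((gg, blocks[int(rng.integers(b))]))


def pairwise_coalescence_mc(
    law_family: LawFamily,
    trajectory: SizeTrajectory,
    r: int,
    reps: int,
    rng: np.random.Generator,
    scheme: AllocationScheme = AllocationScheme.PROPORTIONAL,
) -> tuple[float, float]:
    """Monte-Carlo estimate of c_{N,r} with its binomial standard error.

    Per replicate, the generation's offspring assignment is realized in
    distribution (U, then the resize step) and a Bernoulli trial marks two
    uniformly chosen distinct offspring sharing their parent.
    """
    reps = int(reps)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    Nr = trajectory.size(r)
    Nprev = trajectory.size(r - 1) if r >= 1 else trajectory.size(0)
    d = Nprev - Nr
    law = law_family.at(Nr)
    support, pmf = effective_pmf(law)
    if support.size == 1 or pmf.max() == 1.0:
        u = np.full(reps, int(support[int(np.argmax(pmf))]), dtype=np.int64)
    else:
        u = rng.choice(support, size=reps, p=pmf).astype(np.int64)
    if d < 0:
        u_eff = rng.hypergeometric(u, Nr - u, Nprev)
    elif d > 0:
        if scheme is AllocationScheme.TO_MULTIPLIER:
            u_eff = u + d
        elif scheme is AllocationScheme.TO_NONREPRODUCERS:
            if np.any(u - 1 < d):
                raise InfeasibleAllocationError(
                    f"cannot add d={d} to non-reproducers for some U "
                    "(constraint d_{N,r} - A_{N,r} <= min{i: P(U_{N_r}=i)>0} - 1)"
                )
            u_eff = u
        else:
            a = rng.binomial(d, u / Nr)
            a = np.maximum(a, d - (u - 1))
            u_eff = u + a
    else:
        u_eff = u
    p_same = u_eff * (u_eff - 1.0) / (Nprev * (Nprev - 1.0))
    hits = rng.random(reps) < p_same
    est = float(np.mean(hits))
    se = math.sqrt(max(est * (1.0 - est), 1e-300) / reps)
    return est, se
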