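"""Run configuration, serialization (Newick/TSV/JSON) and the top-level runner.

A :class:`RunConfig` fully describes one simulation: the Lambda-measure,
the population-size profile, the model family (``moran``,
``schweinsberg`` or ``limit``), sizes and seed.  ``run`` executes it
deterministically -- identical config and seed give byte-identical
outputs -- writing a Newick tree, a TSV event table with the schema
shared by all engines (generation, coal_time, merged_blocks,
block_count_after) and a JSON provenance record (config hash, seed,
version).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

import mmcoal
from mmcoal import limit_coalescent, moran_engine, schweinsberg_engine
from mmcoal.limit_coalescent import CoalescentTree, TimeChange
from mmcoal.measures import LambdaMeasure
from mmcoal.moran_engine import AllocationScheme, DiscreteGenealogy
from mmcoal.offspring_laws import LawFamily, coalescence_prob
from mmcoal.schweinsberg_engine import HeavyTailLaw
from mmcoal.size_profiles import SizeProfile, discretize

__all__ = ["MeasureConfig", "ProfileConfig", "RunConfig", "RunResult", "run", "write_newick"]


class MeasureConfig(BaseModel):
    family: Literal["point_mass", "beta"]
    psi: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None
    rate_multiplier: float = 1.0

    def build(self) -> LambdaMeasure:
        if self.family == "point_mass":
            return LambdaMeasure.point_mass(self.psi, self.rate_multiplier)
        return LambdaMeasure.beta(self.a, self.b, self.rate_multiplier)

    @model_validator(mode="after")
    def _check(self):
        self.build()  # delegates parameter validation
        return self


class ProfileConfig(BaseModel):
    kind: Literal["constant", "exponential", "piecewise_constant", "tabulated"] = "constant"
    rho: Optional[float] = None
    breakpoints: list[float] = []
    levels: list[float] = []
    times: list[float] = []
    values: list[float] = []

    def build(self) -> SizeProfile:
        if self.kind == "constant":
            return SizeProfile.constant()
        if self.kind == "exponential":
            return SizeProfile.exponential(self.rho)
        if self.kind == "piecewise_constant":
            return SizeProfile.piecewise(self.breakpoints, self.levels)
        return SizeProfile.tabulated(self.times, self.values)

    @model_validator(mode="after")
    def _check(self):
        self.build()
        return self


class RunConfig(BaseModel):
    """Validated cross-field configuration of a single simulation run."""

    model: Literal["moran", "schweinsberg", "limit"]
    n: int
    seed: int
    measure: Optional[MeasureConfig] = None
    profile: ProfileConfig = ProfileConfig()
    N: Optional[int] = None
    offspring: Literal["standard", "uprime", "rarefied"] = "uprime"
    gamma: Optional[float] = None
    scheme: Literal["to_multiplier", "to_nonreproducers", "proportional"] = "proportional"
    alpha: Optional[float] = None
    theta: float = 0.0
    horizon_t: float = 50.0
    units: Literal["coalescent", "generations"] = "coalescent"

    @model_validator(mode="after")
    def _cross_field(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.model == "limit":
            if self.gamma is None:
                raise ValueError("limit runs require 'gamma' (time-change exponent)")
            if self.measure is None:
                raise ValueError("limit runs require 'measure'")
        if self.model == "schweinsberg":
            if self.alpha is None:
                raise ValueError("schweinsberg runs require 'alpha'")
            if self.N is None:
                raise ValueError("schweinsberg runs require 'N'")
        if self.model == "moran":
            if self.N is None:
                raise ValueError("moran runs require 'N'")
            if self.offspring != "standard" and self.measure is None:
                raise ValueError("moran runs with uprime/rarefied offspring require 'measure'")
            if self.offspring == "rarefied" and self.gamma is None:
                raise ValueError("rarefied offspring require 'gamma'")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class RunResult(BaseModel, arbitrary_types_allowed=True):
    config: RunConfig
    newick: str
    events: pd.DataFrame
    cN: Optional[float] = None
    provenance: dict


def _newick_node(block, children, length, fmt) -> str:
    if children:
        inner = ",".join(children)
        return f"({inner}):{fmt(length)}"
    (label,) = block
    return f"{label}:{fmt(length)}"


def _tree_events(obj, units: str):
    """(time, merged-blocks) pairs of either container, in requested units."""
    if isinstance(obj, CoalescentTree):
        return [(t, merged) for t, merged in obj.events]
    scale = 1.0 if units == "generations" else obj.cN
    return [(ev.r * scale, ev.merged) for ev in obj.events]


def write_newick(obj: CoalescentTree | DiscreteGenealogy, units: str = "coalescent") -> str:
    """Newick text with native multifurcations; leaf labels "1".."n".

    Branch lengths are inter-event spans in the chosen units (discrete
    genealogies are converted by cN for ``units="coalescent"``).  An open
    genealogy (MRCA not reached) is exported as a forest, one line per
    remaining root, with a warning.
    """
    n = obj.n
    fmt = lambda x: format(float(x), ".10g")
    if n == 1:
        return "1:0.0;"
    events = _tree_events(obj, units)
    is_open = isinstance(obj, DiscreteGenealogy) and obj.open
    subtree: dict[frozenset, str] = {}
    birth: dict[frozenset, float] = {}
    for i in range(1, n + 1):
        blk = frozenset({i})
        birth[blk] = 0.0
    for t, merged in events:
        parts = []
        for b in sorted(merged, key=min):
            child = subtree.pop(b, None)
            text = (
                _newick_node(b, None, t - birth[b], fmt)
                if child is None
                else f"{child}:{fmt(t - birth[b])}"
            )
            parts.append(text)
        new = frozenset().union(*merged)
        subtree[new] = "(" + ",".join(parts) + ")"
        for b in merged:
            birth.pop(b, None)
        birth[new] = t
    roots = sorted(birth, key=min)
    if len(roots) > 1:
        if not is_open:
            raise ValueError("genealogy has several roots but is not flagged open")
        warnings.warn("open genealogy: exporting a forest, one tree per line", stacklevel=2)
    lines = []
    for root in roots:
        body = subtree.get(root)
        if body is None:  # singleton leaf that never merged (open forest)
            (label,) = root
            lines.append(f"{label}:0.0;")
        else:
            lines.append(body + ";")
    return "\n".join(lines)


def _events_frame(obj, units: str) -> pd.DataFrame:
    rows = []
    if isinstance(obj, CoalescentTree):
        for t, merged in obj.events:
            rows.append(
                {
                    "generation": pd.NA,
                    "coal_time": t,
                    "merged_blocks": "|".join(
                        ",".join(str(i) for i in sorted(b)) for b in sorted(merged, key=min)
                    ),
                    "block_count_after": None,
                }
            )
        # recompute block counts forward
        b = obj.n
        for row, (_, merged) in zip(rows, obj.events):
            b -= len(merged) - 1
            row["block_count_after"] = b
    else:
        for ev in obj.events:
            rows.append(
                {
                    "generation": ev.r,
                    "coal_time": ev.r * obj.cN,
                    "merged_blocks": "|".join(
                        ",".join(str(i) for i in sorted(b)) for b in sorted(ev.merged, key=min)
                    ),
                    "block_count_after": ev.block_count_after,
                }
            )
    return pd.DataFrame(rows, columns=["generation", "coal_time", "merged_blocks", "block_count_after"])


def run(
    config: RunConfig,
    out_tree: str | Path | None = None,
    out_events: str | Path | None = None,
) -> RunResult:
    """Execute a configured simulation; deterministic given (config, seed)."""
    root = np.random.default_rng(config.seed)
    sim_rng = root.spawn(1)[0]
    measure = config.measure.build() if config.measure is not None else None
    profile = config.profile.build()
    cN = None
    if config.model == "limit":
        tc = TimeChange(profile=profile, gamma=config.gamma)
        tree = limit_coalescent.simulate_time_changed(measure, tc, config.n, sim_rng)
        obj: CoalescentTree | DiscreteGenealogy = tree
    else:
        if config.model == "moran":
            kind = config.offspring
            law_family = LawFamily(
                kind, measure=measure if kind != "standard" else None, gamma=config.gamma
            )
            cN = coalescence_prob(law_family.at(config.N))
            traj = discretize(profile, config.N, cN, config.horizon_t, config.n)
            mu = config.theta * cN
            obj = moran_engine.simulate(
                traj,
                law_family,
                AllocationScheme(config.scheme),
                config.n,
                sim_rng,
                mutation_rate=mu,
            )
        else:
            law = HeavyTailLaw(config.alpha)
            est_rng = root.spawn(1)[0]
            cN, _ = schweinsberg_engine.pairwise_coalescence_mc(
                law, config.N, 100_000, est_rng
            )
            traj = discretize(profile, config.N, cN, config.horizon_t, config.n)
            obj = schweinsberg_engine.simulate(traj, law, config.n, sim_rng)
    newick = write_newick(obj, units=config.units)
    events = _events_frame(obj, config.units)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": mmcoal.__version__,
        "cN": cN,
        "n_events": len(events),
    }
    if out_tree is not None:
        Path(out_tree).write_text(newick + "\n")
        Path(str(out_tree) + ".provenance.json").write_text(
            json.dumps(provenance, indent=1, sort_keys=True) + "\n"
        )
    if out_events is not None:
        events.to_csv(out_events, sep="\t", index=False)
    return RunResult(config=config, newick=newick, events=events, cN=cN, provenance=provenance)
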