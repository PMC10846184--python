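"""Unique-uptake-compound analysis across model collections.

A compound is *consumable* by a species when, under the reference diet, the
minimal feasible flux through its exchange reaction is negative (uptake is
possible at steady state).  Within a community, a compound consumable by
exactly one member is that member's private metabolic niche; the fraction of
members owning at least one such compound is the community's unique-uptake
fraction.  Subsampling communities of increasing size from a model collection
shows how quickly niche overlap erodes these private compounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .fba_engine import max_uptake
from .model_core import TOL_ZERO, AbundanceTable, Diet, MetabolicNetwork, apply_diet


@dataclass(frozen=True)
class UptakeProfile:
    species_id: str
    consumable: frozenset


@dataclass(frozen=True)
class UniqueUptakeReport:
    community: frozenset
    unique_sets: Mapping[str, frozenset]
    fraction_unique: float


def profile_uptake(network: MetabolicNetwork, diet: Diet,
                   tol_zero: float = TOL_ZERO) -> UptakeProfile:
    """Determine which compounds a species can take up under a diet."""
    constrained = apply_diet(network, diet)
    consumable = set()
    for compound, ex_id in constrained.compound_exchanges().items():
        if max_uptake(constrained, ex_id) < -tol_zero:
            consumable.add(compound)
    return UptakeProfile(network.model_id, frozenset(consumable))


def filter_abundance(table: AbundanceTable, min_frac: float = 0.001) -> Set[str]:
    """Normalize abundances to sum 1 and drop species below ``min_frac``."""
    total = sum(table.abundance.values())
    if total <= 0:
        raise ValueError(f"sample {table.sample_id!r}: all abundances are zero")
    return {sp for sp, v in table.abundance.items() if v / total >= min_frac}


def unique_uptake(profiles: Mapping[str, UptakeProfile],
                  community: Iterable[str]) -> UniqueUptakeReport:
    """Per-species unique-uptake sets within one community."""
    community = frozenset(community)
    unknown = community - set(profiles)
    if unknown:
        raise ValueError(f"species without uptake profiles: {sorted(unknown)}")
    unique_sets: Dict[str, frozenset] = {}
    for sp in community:
        others: Set[str] = set()
        for other in community:
            if other != sp:
                others |= profiles[other].consumable
        unique_sets[sp] = frozenset(profiles[sp].consumable - others)
    if community:
        fraction = sum(1 for s in community if unique_sets[s]) / len(community)
    else:
        fraction = 0.0
    return UniqueUptakeReport(community, unique_sets, fraction)


def subsample_unique_curve(profiles: Mapping[str, UptakeProfile],
                           sizes: Sequence[int], iterations: int = 50,
                           seed: int = 0) -> pd.DataFrame:
    """Unique-uptake fraction over random communities of increasing size.

    For each size, ``iterations`` communities are drawn uniformly without
    replacement from the collection (seeded and bit-reproducible).  Returns a
    long table with columns ``size``, ``iteration``, ``fraction_unique``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    species = sorted(profiles)
    for size in sizes:
        if size > len(species):
            raise ValueError(
                f"community size {size} exceeds collection size {len(species)}"
            )
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for it in range(iterations):
            subset = rng.choice(species, size=size, replace=False)
            report = unique_uptake(profiles, subset)
            rows.append((size, it, report.fraction_unique))
    return pd.DataFrame(rows, columns=["size", "iteration", "fraction_unique"])


def write_profiles(profiles: Mapping[str, UptakeProfile], path) -> None:
    """Cache profiles as a ``species<TAB>compound`` table."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# species\tcompound\n")
        for sp in sorted(profiles):
            for cpd in sorted(profiles[sp].consumable):
                fh.write(f"{sp}\t{cpd}\n")


def read_profiles(path) -> Dict[str, UptakeProfile]:
    collected: Dict[str, Set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sp, cpd = line.split("\t")
            collected.setdefault(sp, set()).add(cpd)
    return {sp: UptakeProfile(sp, frozenset(c)) for sp, c in collected.items()}
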