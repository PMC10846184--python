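"""Community-FBA stage: compartmentalized merge and supplementation screen.

Member models are merged into one community model sharing a single
extracellular pool.  Each member keeps its own namespaced compartments; its
former exchange reactions become *shuttle* reactions moving compounds between
the member and the shared pool (open at +/-U_FREE), and new community exchange
reactions - the only reactions crossing the system boundary - carry the diet
bounds.  Community FBA maximizes the summed member biomass fluxes with a small
penalty on the total absolute flux, and member growth rates are normalized by
the community growth rate, because a supplement that helps everyone still
shifts no composition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, Mapping, Sequence, Set, Tuple

import pandas as pd

from ._util import relative_change, round6
from .fba_engine import OPTIMAL, PenalizedLP
from .model_core import (
    TOL_ZERO,
    U_FREE,
    Diet,
    Metabolite,
    MetabolicNetwork,
    Reaction,
)
from .results import ScreenResult

logger = logging.getLogger(__name__)

_POOL_COMPARTMENT = "pool"


@dataclass(frozen=True)
class CommunityModel:
    members: Tuple[str, ...]
    network: MetabolicNetwork
    community_exchange: Mapping[str, str]           # compound -> EXC reaction id
    member_biomass: Mapping[str, str]               # species -> biomass reaction id
    member_shuttle: Mapping[Tuple[str, str], str]   # (species, compound) -> shuttle id


@dataclass(frozen=True)
class CommunityGrowth:
    status: str
    community_growth: float
    member_growth: Mapping[str, float]
    member_relative: Mapping[str, float]


def merge_community(models: Sequence[MetabolicNetwork], diet: Diet,
                    u_free: float = U_FREE) -> CommunityModel:
    """Merge member models into one diet-bounded community model."""
    if len(models) < 2:
        raise ValueError("a community needs at least two member models")
    member_ids = [m.model_id for m in models]
    if len(set(member_ids)) != len(member_ids):
        raise ValueError(f"duplicate member model ids: {member_ids}")

    metabolites = []
    reactions = []
    seen_ids: Set[str] = set()
    pool_compounds: Set[str] = set()
    member_biomass: Dict[str, str] = {}
    member_shuttle: Dict[Tuple[str, str], str] = {}

    for net in models:
        sp = net.model_id
        prefix = f"{sp}__"
        for met in net.metabolites:
            metabolites.append(replace(met, id=prefix + met.id))
        exchanges = net.compound_exchanges()
        pool_compounds |= set(exchanges)
        for rxn in net.reactions:
            new_id = prefix + rxn.id
            if new_id in seen_ids:
                raise ValueError(f"reaction id collision after namespacing: {new_id!r}")
            seen_ids.add(new_id)
            stoich = {prefix + met_id: c for met_id, c in rxn.stoichiometry.items()}
            if rxn.id in net.exchange_ids:
                # exchange -> shuttle: member boundary metabolite <-> shared pool
                compound = net.exchange_compound(rxn.id)
                stoich[compound] = 1.0
                reactions.append(
                    Reaction(new_id, stoich, -u_free, u_free, 0.0)
                )
                member_shuttle[(sp, compound)] = new_id
            else:
                obj = rxn.objective_coefficient
                if rxn.id == net.biomass_id:
                    member_biomass[sp] = new_id
                    obj = 1.0
                reactions.append(
                    Reaction(new_id, stoich, rxn.lower_bound, rxn.upper_bound, obj)
                )

    community_exchange: Dict[str, str] = {}
    for compound in sorted(pool_compounds):
        metabolites.append(Metabolite(compound, compound, _POOL_COMPARTMENT))
        exc_id = f"EXC_{compound}"
        if compound in diet.unconstrained_compounds:
            lb = -u_free
        elif compound in diet.availability:
            lb = -float(diet.availability[compound])
        else:
            lb = 0.0
        reactions.append(Reaction(exc_id, {compound: -1.0}, lb, u_free, 0.0))
        community_exchange[compound] = exc_id

    network = MetabolicNetwork(
        model_id="community(" + "+".join(member_ids) + ")",
        metabolites=tuple(metabolites),
        reactions=tuple(reactions),
        exchange_ids=frozenset(community_exchange.values()),
        biomass_id=None,
        extracellular_compartment=_POOL_COMPARTMENT,
    ).validated(single_objective=False)

    return CommunityModel(
        members=tuple(member_ids),
        network=network,
        community_exchange=community_exchange,
        member_biomass=member_biomass,
        member_shuttle=member_shuttle,
    )


def community_fba(cm: CommunityModel, epsilon: float = 1e-6) -> CommunityGrowth:
    """Maximize summed member growth (flux-penalized); normalize member shares."""
    sol = PenalizedLP(cm.network, epsilon).solve()
    return _growth_from_solution(cm, sol)


def _growth_from_solution(cm: CommunityModel, sol) -> CommunityGrowth:
    if sol.status != OPTIMAL:
        zeros = {sp: 0.0 for sp in cm.members}
        return CommunityGrowth(sol.status, 0.0, zeros, dict(zeros))
    member_growth = {sp: sol.fluxes[cm.member_biomass[sp]] for sp in cm.members}
    community = sum(member_growth.values())
    if community > TOL_ZERO:
        member_relative = {sp: g / community for sp, g in member_growth.items()}
    else:
        member_relative = {sp: 0.0 for sp in cm.members}
    return CommunityGrowth(OPTIMAL, community, member_growth, member_relative)


def community_supplement_screen(cm: CommunityModel, diet: Diet,
                                compounds, target: str,
                                delta: float = 10.0, cutoff: float = 0.01,
                                epsilon: float = 1e-6) -> ScreenResult:
    """Screen supplements for selective enrichment of the target member.

    For each compound the community exchange lower bound is opened by
    ``delta`` mmol/L and community FBA re-run.  The per-member effect is the
    relative change of its *normalized* growth share, on 6-decimal-rounded
    values.  A compound is selected iff the target's effect exceeds ``cutoff``
    and strictly dominates every other member's effect.
    """
    if target not in cm.members:
        raise ValueError(f"target {target!r} is not a community member")
    baseline = community_fba(cm, epsilon)
    rows = []
    selected: Set[str] = set()
    for compound in sorted(compounds):
        exc_id = cm.community_exchange.get(compound)
        if exc_id is None:
            logger.warning("compound %s has no community exchange: not importable",
                           compound)
            for sp in cm.members:
                rows.append((compound, sp, round6(baseline.member_relative[sp]),
                             round6(baseline.member_relative[sp]), 0.0, False,
                             "not importable"))
            continue
        rxn = cm.network.reaction(exc_id)
        net2 = cm.network.with_bounds(
            {exc_id: (rxn.lower_bound - float(delta), rxn.upper_bound)}
        )
        suppl = _growth_from_solution(
            cm, PenalizedLP(net2, epsilon).solve()
        )
        effects = {
            sp: relative_change(baseline.member_relative[sp],
                                suppl.member_relative[sp])
            for sp in cm.members
        }
        is_selected = effects[target] > cutoff and all(
            effects[target] > effects[sp] for sp in cm.members if sp != target
        )
        if is_selected:
            selected.add(compound)
        for sp in cm.members:
            rows.append((compound, sp, round6(baseline.member_relative[sp]),
                         round6(suppl.member_relative[sp]), effects[sp],
                         is_selected, suppl.status))
    table = pd.DataFrame(
        rows,
        columns=["compound", "species", "baseline_rel", "suppl_rel",
                 "effect", "selected", "note"],
    )
    return ScreenResult(table, frozenset(selected))
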