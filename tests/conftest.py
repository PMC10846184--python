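"""Shared fixtures: hand-built toy networks and a random-network generator."""

from __future__ import annotations

import numpy as np
import pytest

from prebiotic_screen.model_core import (
    U_FREE,
    Diet,
    Metabolite,
    MetabolicNetwork,
    Reaction,
)


def build_network(model_id, metabolites, reactions, biomass_id="BIOMASS",
                  single_objective=True):
    """Compact network builder for tests.

    ``metabolites``: iterable of (id, compartment);
    ``reactions``: iterable of (id, stoich dict, lb, ub[, objective]).
    Exchanges are auto-detected (single metabolite, coefficient -1,
    extracellular).
    """
    mets = tuple(Metabolite(mid, mid, comp) for mid, comp in metabolites)
    met_index = {m.id: m for m in mets}
    rxns = []
    for rec in reactions:
        rid, stoich, lb, ub = rec[:4]
        obj = rec[4] if len(rec) > 4 else 0.0
        rxns.append(Reaction(rid, dict(stoich), float(lb), float(ub), float(obj)))
    exchange_ids = frozenset(
        r.id for r in rxns
        if len(r.stoichiometry) == 1
        and next(iter(r.stoichiometry.values())) == -1
        and met_index[next(iter(r.stoichiometry))].compartment == "e"
    )
    return MetabolicNetwork(
        model_id=model_id,
        metabolites=mets,
        reactions=tuple(rxns),
        exchange_ids=exchange_ids,
        biomass_id=biomass_id,
    ).validated(single_objective=single_objective)


@pytest.fixture
def chain_network():
    """EX_A -> transport -> biomass; growth limited by uptake bound 10."""
    return build_network(
        "chain",
        [("A", "e"), ("A_c", "c")],
        [
            ("EX_A", {"A": -1}, -10, U_FREE),
            ("T_A", {"A": -1, "A_c": 1}, 0, U_FREE),
            ("BIOMASS", {"A_c": -1}, 0, U_FREE, 1.0),
        ],
    )


@pytest.fixture
def branched_network():
    """Two substrates with biomass yields 1.0 (A) and 0.5 (B), 10 mmol/L each."""
    return build_network(
        "branched",
        [("A", "e"), ("B", "e"), ("P", "c")],
        [
            ("EX_A", {"A": -1}, -10, U_FREE),
            ("EX_B", {"B": -1}, -10, U_FREE),
            ("CAT_A", {"A": -1, "P": 1.0}, 0, U_FREE),
            ("CAT_B", {"B": -1, "P": 0.5}, 0, U_FREE),
            ("BIOMASS", {"P": -1}, 0, U_FREE, 1.0),
        ],
    )


@pytest.fixture
def futile_cycle_network():
    """Chain model plus a two-reaction futile cycle not touching biomass."""
    return build_network(
        "futile",
        [("A", "e"), ("A_c", "c"), ("M1", "c"), ("M2", "c")],
        [
            ("EX_A", {"A": -1}, -10, U_FREE),
            ("T_A", {"A": -1, "A_c": 1}, 0, U_FREE),
            ("BIOMASS", {"A_c": -1}, 0, U_FREE, 1.0),
            ("CYC_F", {"M1": -1, "M2": 1}, 0, U_FREE),
            ("CYC_R", {"M2": -1, "M1": 1}, 0, U_FREE),
        ],
    )


@pytest.fixture
def cosubstrate_network():
    """7-reaction network where D is consumable only when E is available:
    catabolism of D consumes one E per D."""
    return build_network(
        "cosub",
        [("D", "e"), ("E", "e"), ("D_c", "c"), ("E_c", "c"), ("P", "c")],
        [
            ("EX_D", {"D": -1}, -5, U_FREE),
            ("EX_E", {"E": -1}, -10, U_FREE),
            ("T_D", {"D": -1, "D_c": 1}, 0, U_FREE),
            ("T_E", {"E": -1, "E_c": 1}, 0, U_FREE),
            ("CAT_D", {"D_c": -1, "E_c": -1, "P": 1}, 0, U_FREE),
            ("CAT_E", {"E_c": -1, "P": 0.5}, 0, U_FREE),
            ("BIOMASS", {"P": -1}, 0, U_FREE, 1.0),
        ],
    )


def random_network(rng: np.random.Generator) -> MetabolicNetwork:
    """Random small valid network (<= 12 reactions), always feasible at v=0."""
    n_ex = int(rng.integers(1, 4))
    n_int_mets = int(rng.integers(1, 5))
    e_mets = [(f"E{i}", "e") for i in range(n_ex)]
    c_mets = [(f"C{i}", "c") for i in range(n_int_mets)]
    all_met_ids = [m[0] for m in e_mets + c_mets]
    reactions = []
    for i in range(n_ex):
        lb = -float(rng.uniform(0, 10)) if rng.random() < 0.8 else 0.0
        reactions.append((f"EX_{i}", {f"E{i}": -1}, lb, float(rng.uniform(0, 10))))
    n_internal = int(rng.integers(2, 12 - n_ex - 1 + 1))
    for i in range(n_internal):
        k_in = int(rng.integers(1, 3))
        k_out = int(rng.integers(0, 3))
        chosen = rng.choice(len(all_met_ids), size=min(k_in + k_out, len(all_met_ids)),
                            replace=False)
        stoich = {}
        for j, idx in enumerate(chosen):
            coeff = float(rng.integers(1, 3))
            stoich[all_met_ids[idx]] = -coeff if j < k_in else coeff
        lb = -float(rng.uniform(0, 5)) if rng.random() < 0.3 else 0.0
        reactions.append((f"R{i}", stoich, lb, float(rng.uniform(0, 10))))
    k_bio = int(rng.integers(1, min(2, n_int_mets) + 1))
    bio_mets = rng.choice(n_int_mets, size=k_bio, replace=False)
    reactions.append(
        ("BIOMASS", {f"C{i}": -1.0 for i in bio_mets}, 0.0,
         float(rng.uniform(1, 20)), 1.0)
    )
    return build_network(f"rand{rng.integers(1 << 30)}", e_mets + c_mets, reactions)


@pytest.fixture
def reference_diet():
    return Diet("ref", {"A": 10.0, "B": 10.0, "D": 10.0, "E": 10.0})
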