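"""Generators for toy model collections with planted ground truth.

The toy species architecture is deliberately simple: per consumable compound
one exchange, one transporter and one catabolic reaction feeding a common
biomass precursor at a compound- and species-specific yield (gDW per mmol),
plus a single biomass reaction consuming the precursor.  Growth under a diet
therefore has the closed form  mu = sum_c availability_c * yield(species, c),
which makes every downstream stage analytically checkable.

Planted structure:

* private compounds - consumable by exactly one species (unique-uptake truth);
* planted prebiotics - consumable by everyone, but with a higher yield for the
  target species (precision-prebiotic truth);
* a mild "competitor edge" on shared compounds, so that community FBA has a
  unique, non-degenerate optimum the way two real strains of unequal
  efficiency do;
* optional co-substrate pairs (d, e): catabolizing d consumes e
  stoichiometrically, so d is only consumable while e is in the diet.

Default yields are scaled so that 1000-fold-diluted arenas stay grid-sparse
over 12 iterations; concentrated media would let populations overgrow the
arena before nutrients deplete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .candidate_stats import BiologRecord
from .model_core import (
    U_FREE,
    AbundanceTable,
    Diet,
    Metabolite,
    MetabolicNetwork,
    Reaction,
    write_diet,
    write_model,
)

_PRECURSOR = "biomass_precursor"


@dataclass(frozen=True)
class SyntheticSpec:
    """Blueprint of a synthetic model collection with planted truth."""

    n_species: int = 2
    n_shared_compounds: int = 11
    n_private_per_species: int = 0
    default_yield: float = 0.002         # gDW per mmol
    competitor_edge: float = 1.2         # shared-compound yield gradient
    planted_yield_ratio: float = 4.0     # target vs others on planted compounds
    diet_concentration: float = 10.0     # mmol/L for every compound
    yields: Optional[Mapping[Tuple[str, str], float]] = None
    co_substrate_pairs: FrozenSet[Tuple[str, str]] = frozenset()
    planted_prebiotics: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_shared_compounds < 0 or self.n_private_per_species < 0:
            raise ValueError("compound counts must be non-negative")
        if self.default_yield < 0:
            raise ValueError("default_yield must be non-negative")
        species = set(self.species_ids)
        for cpd, target in self.planted_prebiotics.items():
            if target not in species:
                raise ValueError(
                    f"planted prebiotic {cpd!r} targets unknown species {target!r}"
                )
        if self.yields:
            for (sp, cpd), y in self.yields.items():
                if y < 0:
                    raise ValueError(f"negative yield for ({sp}, {cpd})")

    # ------------------------------------------------------------------ layout
    @property
    def species_ids(self) -> List[str]:
        return [f"S{i + 1}" for i in range(self.n_species)]

    @property
    def shared_compounds(self) -> List[str]:
        width = max(2, len(str(self.n_shared_compounds)))
        return [f"c{i + 1:0{width}d}" for i in range(self.n_shared_compounds)]

    def private_compounds(self, species_id: str) -> List[str]:
        return [f"p_{species_id}_{j + 1}" for j in range(self.n_private_per_species)]

    @property
    def all_compounds(self) -> List[str]:
        out = list(self.shared_compounds) + sorted(self.planted_prebiotics)
        for sp in self.species_ids:
            out += self.private_compounds(sp)
        return out

    def repertoire(self, species_id: str) -> List[str]:
        """Compounds the species can take up (by construction)."""
        return (
            self.shared_compounds
            + sorted(self.planted_prebiotics)
            + self.private_compounds(species_id)
        )

    def yield_for(self, species_id: str, compound: str) -> float:
        if self.yields and (species_id, compound) in self.yields:
            return float(self.yields[(species_id, compound)])
        if compound in self.planted_prebiotics:
            if self.planted_prebiotics[compound] == species_id:
                return self.default_yield * self.planted_yield_ratio
            return self.default_yield
        if compound in self.shared_compounds:
            i = self.species_ids.index(species_id)
            span = max(self.n_species - 1, 1)
            return self.default_yield * (1.0 + (self.competitor_edge - 1.0) * i / span)
        return self.default_yield  # private compound


def make_species_model(spec: SyntheticSpec, species_id: str) -> MetabolicNetwork:
    """Build one toy species network from the blueprint."""
    if species_id not in spec.species_ids:
        raise ValueError(f"unknown species {species_id!r}")
    consumable = spec.repertoire(species_id)
    mets = [Metabolite(_PRECURSOR, "biomass precursor", "c")]
    rxns = []
    cosub = dict(spec.co_substrate_pairs)  # dependent -> required co-substrate
    for cpd in consumable:
        mets.append(Metabolite(cpd, cpd, "e"))
        mets.append(Metabolite(f"{cpd}_c", f"{cpd} (cytosol)", "c"))
        rxns.append(Reaction(f"EX_{cpd}", {cpd: -1.0}, 0.0, U_FREE))
        rxns.append(Reaction(f"T_{cpd}", {cpd: -1.0, f"{cpd}_c": 1.0}, 0.0, U_FREE))
        y = spec.yield_for(species_id, cpd)
        stoich: Dict[str, float] = {f"{cpd}_c": -1.0}
        if y > 0:
            stoich[_PRECURSOR] = y
        partner = cosub.get(cpd)
        if partner is not None and partner in consumable:
            stoich[f"{partner}_c"] = stoich.get(f"{partner}_c", 0.0) - 1.0
        rxns.append(Reaction(f"CAT_{cpd}", stoich, 0.0, U_FREE))
    rxns.append(Reaction("BIOMASS", {_PRECURSOR: -1.0}, 0.0, U_FREE,
                         objective_coefficient=1.0))
    return MetabolicNetwork(
        model_id=species_id,
        metabolites=tuple(mets),
        reactions=tuple(rxns),
        exchange_ids=frozenset(f"EX_{c}" for c in consumable),
        biomass_id="BIOMASS",
    ).validated()


def make_collection(spec: SyntheticSpec) -> Tuple[List[MetabolicNetwork], Diet]:
    """All species models plus the reference diet covering every compound."""
    models = [make_species_model(spec, sp) for sp in spec.species_ids]
    diet = Diet("reference",
                {c: spec.diet_concentration for c in spec.all_compounds})
    return models, diet


def planted_pair_spec(seed: int = 0, n_neutral: int = 11,
                      n_private_per_species: int = 0) -> SyntheticSpec:
    """Two-species benchmark: one planted prebiotic (4:1 yield for the target
    S1) among ``n_neutral`` shared compounds on which the competitor S2 holds
    a 1.2x efficiency edge."""
    return SyntheticSpec(
        n_species=2,
        n_shared_compounds=n_neutral,
        n_private_per_species=n_private_per_species,
        planted_prebiotics={"preb1": "S1"},
        seed=seed,
    )


def make_biolog_table(spec: SyntheticSpec, noise_sd: float = 0.0,
                      seed: Optional[int] = None,
                      species: Optional[str] = None) -> List[BiologRecord]:
    """Emulated phenotypic-plate summaries for one species.

    Consumable compounds receive OD590 - OD750 margins of +0.1 above the 0.1
    growth threshold and non-consumable ones land exactly at 0 difference;
    ``noise_sd`` adds seeded Gaussian noise to the margins.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if species is None:
        targets = sorted(set(spec.planted_prebiotics.values()))
        species = targets[0] if targets else spec.species_ids[0]
    consumable = set(spec.repertoire(species))
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records = []
    for cpd in sorted(spec.all_compounds):
        diff = 0.2 if cpd in consumable else 0.0
        if noise_sd > 0:
            diff += float(rng.normal(0.0, noise_sd))
        records.append(BiologRecord(cpd, max(0.1 + diff, 0.0), 0.1))
    return records


def make_class_map(spec: SyntheticSpec) -> Dict[str, set]:
    """Toy metabolite-class annotation covering every generated compound."""
    cycle = ["sugar", "amino_acid", "fatty_acid"]
    mapping: Dict[str, set] = {}
    for i, cpd in enumerate(spec.shared_compounds):
        mapping[cpd] = {cycle[i % len(cycle)]}
    for cpd in spec.planted_prebiotics:
        mapping[cpd] = {"planted_prebiotic"}
    for sp in spec.species_ids:
        for cpd in spec.private_compounds(sp):
            mapping[cpd] = {"private_niche"}
    return mapping


def make_abundance_table(spec: SyntheticSpec, sample_id: str = "sample1",
                         seed: Optional[int] = None) -> AbundanceTable:
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    counts = {sp: float(rng.lognormal(mean=5.0, sigma=1.0))
              for sp in spec.species_ids}
    return AbundanceTable(sample_id, counts)


def make_cross_feeding_pair() -> Tuple[MetabolicNetwork, MetabolicNetwork, Diet]:
    """Hand-built producer/consumer pair: XF_A turns A into biomass and
    secretes B; XF_B grows only on B."""
    producer = MetabolicNetwork(
        model_id="XF_A",
        metabolites=(
            Metabolite("A", "substrate A", "e"),
            Metabolite("B", "byproduct B", "e"),
            Metabolite("A_c", "", "c"),
            Metabolite("B_c", "", "c"),
            Metabolite(_PRECURSOR, "", "c"),
        ),
        reactions=(
            Reaction("EX_A", {"A": -1.0}, 0.0, U_FREE),
            Reaction("T_A", {"A": -1.0, "A_c": 1.0}, 0.0, U_FREE),
            Reaction("CAT_A", {"A_c": -1.0, _PRECURSOR: 0.5, "B_c": 1.0}, 0.0, U_FREE),
            Reaction("T_B_out", {"B_c": -1.0, "B": 1.0}, 0.0, U_FREE),
            Reaction("EX_B", {"B": -1.0}, 0.0, U_FREE),
            Reaction("BIOMASS", {_PRECURSOR: -1.0}, 0.0, U_FREE, 1.0),
        ),
        exchange_ids=frozenset({"EX_A", "EX_B"}),
        biomass_id="BIOMASS",
    ).validated()
    consumer = MetabolicNetwork(
        model_id="XF_B",
        metabolites=(
            Metabolite("B", "byproduct B", "e"),
            Metabolite("B_c", "", "c"),
            Metabolite(_PRECURSOR, "", "c"),
        ),
        reactions=(
            Reaction("EX_B", {"B": -1.0}, 0.0, U_FREE),
            Reaction("T_B", {"B": -1.0, "B_c": 1.0}, 0.0, U_FREE),
            Reaction("CAT_B", {"B_c": -1.0, _PRECURSOR: 0.4}, 0.0, U_FREE),
            Reaction("BIOMASS", {_PRECURSOR: -1.0}, 0.0, U_FREE, 1.0),
        ),
        exchange_ids=frozenset({"EX_B"}),
        biomass_id="BIOMASS",
    ).validated()
    return producer, consumer, Diet("crossfeed", {"A": 10.0})


def write_dataset(spec: SyntheticSpec, outdir, noise_sd: float = 0.0) -> Dict:
    """Write models, diet, Biolog table, class map and truth manifest.

    Returns the ground-truth manifest (also written as ``truth.json``).
    """
    outdir = Path(outdir)
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    models, diet = make_collection(spec)
    for net in models:
        write_model(net, outdir / "models" / f"{net.model_id}.json")
    write_diet(diet, outdir / "diet.tsv")
    with open(outdir / "biolog.tsv", "w", encoding="utf-8") as fh:
        fh.write("# compound\tod590\tod750\n")
        for rec in make_biolog_table(spec, noise_sd=noise_sd):
            fh.write(f"{rec.compound}\t{rec.od590:g}\t{rec.od750:g}\n")
    with open(outdir / "classes.tsv", "w", encoding="utf-8") as fh:
        fh.write("# compound\tclass\n")
        for cpd, labels in sorted(make_class_map(spec).items()):
            for label in sorted(labels):
                fh.write(f"{cpd}\t{label}\n")
    manifest = {
        "seed": spec.seed,
        "species": spec.species_ids,
        "planted_prebiotics": dict(spec.planted_prebiotics),
        "repertoires": {sp: spec.repertoire(sp) for sp in spec.species_ids},
        "yields": {
            sp: {c: spec.yield_for(sp, c) for c in spec.repertoire(sp)}
            for sp in spec.species_ids
        },
        "diet_concentration": spec.diet_concentration,
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
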