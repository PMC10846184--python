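"""Core data structures for constraint-based metabolic models and growth media.

The package follows the standard exchange-reaction sign convention used across
constraint-based modeling tools: every exchange reaction consumes exactly one
extracellular metabolite with stoichiometric coefficient -1, so a *negative*
flux through an exchange corresponds to uptake of the compound and a positive
flux to its excretion.  A :class:`Diet` maps compound ids (the ids of the
extracellular metabolites) to availability magnitudes in mmol/L, which are
applied directly as (negated) lower bounds on the matching exchange reactions.

Model files use a small documented JSON dialect (see :func:`read_model`); a
subset of SBML Level-3 FBC (stoichiometry, bounds, objective) can optionally be
read through :mod:`cobra` when it is installed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

#: Default magnitude used for "non-limiting" bounds (mmol gDW^-1 h^-1).
U_FREE = 1000.0

#: Fluxes smaller in magnitude than this are treated as zero.
TOL_ZERO = 1e-6


class ModelError(ValueError):
    """Base class for model file / validation problems."""


class ModelParseError(ModelError):
    """A model or table file could not be parsed."""


class ModelValidationError(ModelError):
    """A structural invariant of a metabolic network is violated."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    objective_coefficient: float = 0.0


@dataclass(frozen=True)
class MetabolicNetwork:
    """A stoichiometric model with flux bounds and a biomass objective.

    ``exchange_ids`` are the boundary reactions (single extracellular
    metabolite, coefficient -1).  ``biomass_id`` is the reaction whose flux is
    the growth rate in h^-1; for merged community models (which carry one
    biomass per member) it may be ``None``.
    """

    model_id: str
    metabolites: Tuple[Metabolite, ...]
    reactions: Tuple[Reaction, ...]
    exchange_ids: frozenset
    biomass_id: Optional[str]
    extracellular_compartment: str = "e"

    # ------------------------------------------------------------------ lookups
    def _met_index(self) -> Dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> Dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r} in model {self.model_id!r}")

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index()[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r} in model {self.model_id!r}")

    def exchange_compound(self, rxn_id: str) -> str:
        """Return the compound id (extracellular metabolite) of an exchange."""
        if rxn_id not in self.exchange_ids:
            raise ValueError(f"{rxn_id!r} is not an exchange reaction of {self.model_id!r}")
        (met_id,) = self.reaction(rxn_id).stoichiometry.keys()
        return met_id

    def compound_exchanges(self) -> Dict[str, str]:
        """Map compound id -> exchange reaction id."""
        return {self.exchange_compound(rid): rid for rid in self.exchange_ids}

    # ------------------------------------------------------------------ editing
    def with_bounds(self, bounds: Mapping[str, Tuple[float, float]]) -> "MetabolicNetwork":
        """Return a copy with the given reactions' (lb, ub) replaced."""
        new_rxns = tuple(
            replace(r, lower_bound=bounds[r.id][0], upper_bound=bounds[r.id][1])
            if r.id in bounds
            else r
            for r in self.reactions
        )
        return replace(self, reactions=new_rxns)

    # ------------------------------------------------------------------ checks
    def validated(self, single_objective: bool = True) -> "MetabolicNetwork":
        """Check all structural invariants; return self or raise.

        ``single_objective=False`` relaxes the single-biomass rule for merged
        community models, where every member biomass carries objective 1.
        """
        mets = self._met_index()
        if len(mets) != len(self.metabolites):
            raise ModelValidationError(f"duplicate metabolite ids in model {self.model_id!r}")
        rxns = self._rxn_index()
        if len(rxns) != len(self.reactions):
            raise ModelValidationError(f"duplicate reaction ids in model {self.model_id!r}")
        for r in self.reactions:
            for met_id in r.stoichiometry:
                if met_id not in mets:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references undeclared metabolite {met_id!r}"
                    )
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
        for ex_id in self.exchange_ids:
            if ex_id not in rxns:
                raise ModelValidationError(f"exchange reaction {ex_id!r} not declared")
            stoich = rxns[ex_id].stoichiometry
            if len(stoich) != 1 or next(iter(stoich.values())) != -1:
                raise ModelValidationError(
                    f"exchange reaction {ex_id!r} must consume exactly one "
                    "metabolite with coefficient -1"
                )
            met = mets[next(iter(stoich))]
            if met.compartment != self.extracellular_compartment:
                raise ModelValidationError(
                    f"exchange reaction {ex_id!r}: metabolite {met.id!r} is not "
                    f"extracellular (compartment {met.compartment!r})"
                )
        if single_objective:
            if self.biomass_id is None or self.biomass_id not in rxns:
                raise ModelValidationError(
                    f"model {self.model_id!r}: biomass reaction "
                    f"{self.biomass_id!r} not declared"
                )
            if rxns[self.biomass_id].objective_coefficient <= 0:
                raise ModelValidationError(
                    f"biomass reaction {self.biomass_id!r} must have a positive "
                    "objective coefficient"
                )
            for r in self.reactions:
                if r.id != self.biomass_id and r.objective_coefficient != 0:
                    raise ModelValidationError(
                        f"reaction {r.id!r} has a nonzero objective coefficient "
                        "but is not the biomass reaction"
                    )
        return self


@dataclass(frozen=True)
class Diet:
    """Compound availabilities (mmol/L) applied to exchange lower bounds.

    ``unconstrained_compounds`` (micronutrients such as Fe/Cu cations) are
    opened to -U_FREE so they never limit growth.
    """

    name: str
    availability: Mapping[str, float]
    unconstrained_compounds: frozenset = frozenset()

    def __post_init__(self):
        for cpd, value in self.availability.items():
            if value < 0:
                raise ValueError(f"diet {self.name!r}: negative availability for {cpd!r}")


@dataclass(frozen=True)
class AbundanceTable:
    sample_id: str
    abundance: Mapping[str, float]

    def __post_init__(self):
        for sp, value in self.abundance.items():
            if value < 0:
                raise ValueError(f"sample {self.sample_id!r}: negative abundance for {sp!r}")


# ---------------------------------------------------------------------------
# diet operations
# ---------------------------------------------------------------------------

def apply_diet(network: MetabolicNetwork, diet: Diet, u_free: float = U_FREE) -> MetabolicNetwork:
    """Constrain exchange lower bounds by a diet.

    For the exchange of compound ``c``: lb = -availability[c] if the diet lists
    it, -``u_free`` if it is an unconstrained micronutrient, and 0 (no uptake)
    otherwise.  Upper bounds (excretion) are untouched.  Diet compounds without
    a matching exchange in the model are skipped with a logged warning.
    """
    exchanges = network.compound_exchanges()
    bounds: Dict[str, Tuple[float, float]] = {}
    for cpd, rxn_id in exchanges.items():
        ub = network.reaction(rxn_id).upper_bound
        if cpd in diet.unconstrained_compounds:
            bounds[rxn_id] = (-u_free, ub)
        elif cpd in diet.availability:
            bounds[rxn_id] = (-float(diet.availability[cpd]), ub)
        else:
            bounds[rxn_id] = (0.0, ub)
    missing = [c for c in diet.availability if c not in exchanges]
    missing += [c for c in diet.unconstrained_compounds if c not in exchanges]
    if missing:
        logger.warning(
            "diet %s: %d compound(s) not exchangeable by model %s (skipped): %s",
            diet.name, len(missing), network.model_id, ", ".join(sorted(missing)[:5]),
        )
    return network.with_bounds(bounds)


def supplement(diet: Diet, compound: str, delta: float) -> Diet:
    """Return a diet with ``delta`` mmol/L added to one compound's availability."""
    if delta < 0:
        raise ValueError(f"supplement delta must be non-negative, got {delta}")
    avail = dict(diet.availability)
    avail[compound] = avail.get(compound, 0.0) + float(delta)
    return replace(diet, availability=avail)


# ---------------------------------------------------------------------------
# model I/O: JSON dialect
# ---------------------------------------------------------------------------
#
# {
#   "id": "toy",
#   "extracellular_compartment": "e",            # optional, default "e"
#   "metabolites": [{"id": "A", "name": "...", "compartment": "e"}, ...],
#   "reactions": [{"id": "EX_A", "stoichiometry": {"A": -1},
#                  "lower_bound": -10, "upper_bound": 1000,
#                  "objective_coefficient": 0}, ...],
#   "exchanges": ["EX_A"],                        # optional, auto-detected
#   "biomass": "BIOMASS"
# }

def _detect_exchanges(reactions: Sequence[Reaction], mets: Mapping[str, Metabolite],
                      extracellular: str) -> frozenset:
    found = set()
    for r in reactions:
        if len(r.stoichiometry) == 1:
            met_id, coeff = next(iter(r.stoichiometry.items()))
            if coeff == -1 and met_id in mets and mets[met_id].compartment == extracellular:
                found.add(r.id)
    return frozenset(found)


def read_model(path, fmt: Optional[str] = None) -> MetabolicNetwork:
    """Read a metabolic model from the JSON dialect or an SBML-FBC subset.

    ``fmt`` is ``"json"`` or ``"sbml"``; by default it is inferred from the
    file suffix (``.xml``/``.sbml`` -> SBML, anything else -> JSON).
    """
    path = Path(path)
    if fmt is None:
        fmt = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if fmt == "sbml":
        return _read_sbml(path)
    if fmt != "json":
        raise ValueError(f"unknown model format {fmt!r}")

    try:
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: not valid JSON ({exc})") from exc

    for key in ("id", "metabolites", "reactions", "biomass"):
        if key not in raw:
            raise ModelParseError(f"{path}: missing mandatory key {key!r}")

    extracellular = raw.get("extracellular_compartment", "e")
    mets = []
    for rec in raw["metabolites"]:
        if "id" not in rec:
            raise ModelParseError(f"{path}: metabolite record without 'id': {rec!r}")
        mets.append(Metabolite(rec["id"], rec.get("name", ""), rec.get("compartment", "c")))
    rxns = []
    for rec in raw["reactions"]:
        try:
            rxns.append(
                Reaction(
                    id=rec["id"],
                    stoichiometry={str(k): float(v) for k, v in rec["stoichiometry"].items()},
                    lower_bound=float(rec["lower_bound"]),
                    upper_bound=float(rec["upper_bound"]),
                    objective_coefficient=float(rec.get("objective_coefficient", 0.0)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelParseError(
                f"{path}: malformed reaction record {rec.get('id', rec)!r} ({exc})"
            ) from exc

    met_index = {m.id: m for m in mets}
    if "exchanges" in raw:
        exchange_ids = frozenset(raw["exchanges"])
    else:
        exchange_ids = _detect_exchanges(rxns, met_index, extracellular)

    network = MetabolicNetwork(
        model_id=str(raw["id"]),
        metabolites=tuple(mets),
        reactions=tuple(rxns),
        exchange_ids=exchange_ids,
        biomass_id=str(raw["biomass"]),
        extracellular_compartment=extracellular,
    )
    return network.validated()


def write_model(network: MetabolicNetwork, path) -> None:
    """Write a network to the JSON dialect (lossless round-trip)."""
    doc = {
        "id": network.model_id,
        "extracellular_compartment": network.extracellular_compartment,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "objective_coefficient": r.objective_coefficient,
            }
            for r in network.reactions
        ],
        "exchanges": sorted(network.exchange_ids),
        "biomass": network.biomass_id,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _read_sbml(path: Path) -> MetabolicNetwork:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ModelParseError(
            "reading SBML requires the optional 'cobra' dependency"
        ) from exc
    model = cobra.io.read_sbml_model(str(path))
    mets = tuple(
        Metabolite(m.id, m.name or "", m.compartment or "c") for m in model.metabolites
    )
    rxns = []
    biomass_id = None
    for r in model.reactions:
        obj = float(r.objective_coefficient)
        if obj > 0:
            biomass_id = r.id
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                objective_coefficient=obj,
            )
        )
    exchange_ids = frozenset(r.id for r in model.exchanges)
    if exchange_ids:
        sample = model.reactions.get_by_id(next(iter(exchange_ids)))
        extracellular = next(iter(sample.metabolites)).compartment or "e"
    else:
        extracellular = "e"
    return MetabolicNetwork(
        model_id=model.id or path.stem,
        metabolites=mets,
        reactions=tuple(rxns),
        exchange_ids=exchange_ids,
        biomass_id=biomass_id,
        extracellular_compartment=extracellular,
    ).validated()


# ---------------------------------------------------------------------------
# table I/O (TSV, '#' comments allowed)
# ---------------------------------------------------------------------------

def _tsv_rows(path) -> Iterable[Sequence[str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_diet(path, name: Optional[str] = None,
              unconstrained: Iterable[str] = ()) -> Diet:
    """Read a 2-column ``compound<TAB>mmolPerL`` diet table."""
    path = Path(path)
    avail: Dict[str, float] = {}
    for lineno, fields in _tsv_rows(path):
        if len(fields) != 2:
            raise ModelParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        cpd, value = fields
        if cpd == "compound":  # tolerated header line
            continue
        try:
            avail[cpd] = float(value)
        except ValueError as exc:
            raise ModelParseError(f"{path}:{lineno}: bad availability {value!r}") from exc
    return Diet(name or path.stem, avail, frozenset(unconstrained))


def write_diet(diet: Diet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# compound\tmmolPerL\n")
        for cpd in sorted(diet.availability):
            fh.write(f"{cpd}\t{diet.availability[cpd]:g}\n")


def read_abundance(path, sample_id: Optional[str] = None) -> AbundanceTable:
    """Read a 2-column ``species<TAB>abundance`` table."""
    path = Path(path)
    counts: Dict[str, float] = {}
    for lineno, fields in _tsv_rows(path):
        if len(fields) != 2:
            raise ModelParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        sp, value = fields
        if sp == "species":
            continue
        try:
            counts[sp] = float(value)
        except ValueError as exc:
            raise ModelParseError(f"{path}:{lineno}: bad abundance {value!r}") from exc
    return AbundanceTable(sample_id or path.stem, counts)
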