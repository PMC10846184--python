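"""Candidate selection and statistics for the prebiotic screen.

Brings the three screens together: intersection of the selected compound
sets, cross-referencing against phenotypic (Biolog-style) growth calls,
metabolite-class enrichment by Fisher's exact test over the target species'
model metabolites, and the host-filtering expectation for in-vivo proportions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from ._util import relative_change, round6
from .fba_engine import fba
from .model_core import Diet, MetabolicNetwork, ModelParseError, apply_diet, supplement
from .results import ScreenResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiologRecord:
    """One phenotypic-microarray growth measurement for a compound."""

    compound: str
    od590: float
    od750: float

    def __post_init__(self):
        if self.od590 < 0 or self.od750 < 0:
            raise ValueError(f"negative OD for compound {self.compound!r}")


def fba_single_screen(network: MetabolicNetwork, diet: Diet, compounds,
                      delta: float = 10.0, cutoff: float = 0.01) -> ScreenResult:
    """Single-species FBA supplementation screen.

    Growth under the diet versus the diet with ``delta`` mmol/L more of each
    compound; both growth rates rounded to six decimals before the relative
    change; selected iff the change is strictly bigger than ``cutoff``.
    """
    baseline = fba(apply_diet(network, diet)).growth_rate
    rows = []
    selected: Set[str] = set()
    for compound in sorted(compounds):
        suppl_growth = fba(apply_diet(network, supplement(diet, compound, delta))).growth_rate
        change = relative_change(baseline, suppl_growth)
        is_selected = change > cutoff
        if is_selected:
            selected.add(compound)
        rows.append((compound, round6(baseline), round6(suppl_growth), change, is_selected))
    table = pd.DataFrame(
        rows, columns=["compound", "baseline_growth", "suppl_growth", "effect", "selected"]
    )
    return ScreenResult(table, frozenset(selected))


def intersect_screens(fba_selected: Iterable[str], community_selected: Iterable[str],
                      arena_selected: Iterable[str]) -> Set[str]:
    """Compounds selected by all three screens."""
    return set(fba_selected) & set(community_selected) & set(arena_selected)


def biolog_confirm(candidates: Iterable[str], records: Sequence[BiologRecord],
                   threshold: float = 0.1) -> Dict[str, str]:
    """Tri-state growth call per candidate: growth iff OD590 - OD750 > threshold."""
    by_compound: Dict[str, BiologRecord] = {}
    for rec in records:
        if rec.compound in by_compound:
            raise ValueError(f"duplicate Biolog record for compound {rec.compound!r}")
        by_compound[rec.compound] = rec
    calls = {}
    for compound in candidates:
        rec = by_compound.get(compound)
        if rec is None:
            calls[compound] = "untested"
        elif rec.od590 - rec.od750 > threshold:
            calls[compound] = "yes"
        else:
            calls[compound] = "no"
    return calls


def class_enrichment(candidates: Iterable[str], universe: Iterable[str],
                     class_map: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Per-class 2x2 Fisher's exact tests of candidates against the universe.

    The universe is the annotated metabolite background (typically the target
    species' model metabolites); unannotated universe members count toward the
    out-of-class cells.  Reports the two-sided p, the one-sided enrichment
    tail (hypergeometric survival), and BH-adjusted q over classes.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("enrichment universe is empty")
    candidates = set(candidates)
    if not candidates <= universe:
        raise ValueError(
            f"candidates outside the universe: {sorted(candidates - universe)}"
        )
    classes: Dict[str, Set[str]] = {}
    for compound, labels in class_map.items():
        if compound not in universe:
            continue
        for label in ([labels] if isinstance(labels, str) else labels):
            classes.setdefault(label, set()).add(compound)
    rows = []
    n_universe = len(universe)
    for label in sorted(classes):
        in_class = classes[label]
        a = len(candidates & in_class)
        b = len(candidates - in_class)
        c = len(in_class - candidates)
        d = n_universe - a - b - c
        odds, p_two = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        # one-sided enrichment tail: P(overlap >= a) under hypergeometric
        p_enrich = float(stats.hypergeom.sf(a - 1, n_universe, len(in_class),
                                            len(candidates)))
        rows.append((label, a, b, c, d, odds, p_two, p_enrich))
    table = pd.DataFrame(
        rows, columns=["class", "a", "b", "c", "d", "odds_ratio", "p", "p_enrich"]
    )
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table


def expected_host_proportion(prop_lawn_suppl: float, prop_worm_base: float,
                             prop_lawn_base: float) -> float:
    """Expected target proportion in the host after supplementation.

    The product of the target's proportion on the supplemented lawn and the
    host-filtering shift observed without supplementation (in-host over
    on-lawn baseline proportion).
    """
    for name, value in (("prop_lawn_suppl", prop_lawn_suppl),
                        ("prop_worm_base", prop_worm_base),
                        ("prop_lawn_base", prop_lawn_base)):
        if not 0 < value <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {value}")
    return prop_lawn_suppl * (prop_worm_base / prop_lawn_base)


def chisq_obs_vs_expected(obs_counts: Tuple[int, int],
                          expected_prop: float) -> Tuple[float, int, float]:
    """One-sample goodness-of-fit chi-squared against (p, 1-p), df = 1."""
    o1, o2 = obs_counts
    if o1 < 0 or o2 < 0 or o1 + o2 == 0:
        raise ValueError(f"invalid observed counts {obs_counts}")
    if not 0 < expected_prop < 1:
        raise ValueError(f"expected proportion must be in (0, 1), got {expected_prop}")
    total = o1 + o2
    statistic, p = stats.chisquare(
        [o1, o2], f_exp=[total * expected_prop, total * (1 - expected_prop)]
    )
    return float(statistic), 1, float(p)


def build_candidate_table(compounds: Iterable[str], fba_selected: Iterable[str],
                          community_selected: Iterable[str],
                          arena_selected: Iterable[str],
                          biolog_calls: Mapping[str, str],
                          strict_biolog: bool = True) -> pd.DataFrame:
    """Combine screen flags and Biolog calls into the final candidate table.

    ``final_candidate`` requires selection by all three screens and, in strict
    mode, a positive Biolog growth confirmation.
    """
    fba_selected = set(fba_selected)
    community_selected = set(community_selected)
    arena_selected = set(arena_selected)
    rows = []
    for compound in sorted(set(compounds)):
        f = compound in fba_selected
        c = compound in community_selected
        a = compound in arena_selected
        call = biolog_calls.get(compound, "untested")
        final = f and c and a and (call == "yes" or not strict_biolog)
        rows.append((compound, f, c, a, call, final))
    return pd.DataFrame(
        rows, columns=["compound", "selected_fba", "selected_community",
                       "selected_arena", "biolog_confirmed", "final_candidate"]
    )


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_biolog(path) -> list:
    """Read a ``compound<TAB>od590<TAB>od750`` table."""
    path = Path(path)
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ModelParseError(f"{path}:{lineno}: expected 3 columns")
            if fields[0] == "compound":
                continue
            try:
                records.append(BiologRecord(fields[0], float(fields[1]), float(fields[2])))
            except ValueError as exc:
                raise ModelParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def read_class_map(path) -> Dict[str, Set[str]]:
    """Read a ``compound<TAB>class`` table (one row per assignment)."""
    path = Path(path)
    mapping: Dict[str, Set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ModelParseError(f"{path}:{lineno}: expected 2 columns")
            if fields[0] == "compound":
                continue
            mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping
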