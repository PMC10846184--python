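"""End-to-end orchestration of the precision-prebiotic screen.

The pipeline funnels a compound list through three supplementation screens of
increasing cost - single-species FBA, community FBA, and the agent-based
spatial arena - intersects the selected sets, cross-references phenotypic
growth calls, and reports class enrichment of the final candidates.  All
stage tables, the candidate table and a reproducibility manifest are written
to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .arena_sim import ArenaConfig, arena_supplement_screen
from .candidate_stats import (
    biolog_confirm,
    build_candidate_table,
    class_enrichment,
    fba_single_screen,
    intersect_screens,
    read_biolog,
    read_class_map,
)
from .community_screen import community_supplement_screen, merge_community
from .model_core import Diet, read_diet, read_model
from .results import ScreenResult

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    model_paths: List[str]
    diet_path: str
    target: str
    outdir: str
    compounds: Optional[List[str]] = None      # default: every diet compound
    biolog_path: Optional[str] = None
    class_map_path: Optional[str] = None
    unconstrained_compounds: List[str] = field(default_factory=list)
    delta: float = 10.0
    cutoff: float = 0.01
    alpha: float = 0.05
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    arena_compounds: str = "intersection"      # or "all"
    arena_selection: str = "fdr"               # or "median"
    strict_biolog: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.arena_compounds not in ("intersection", "all"):
            raise ValueError(f"unknown arena_compounds mode {self.arena_compounds!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        arena_raw = raw.pop("arena", {})
        cfg = cls(arena=ArenaConfig(**arena_raw), **raw)
        if "seed" not in arena_raw:
            cfg.arena = dataclasses.replace(cfg.arena, seed=cfg.seed)
        return cfg


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return wrap


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run every stage; write artifacts; return the candidate table."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    models = {}
    for path in config.model_paths:
        net = _stage("read_models")(read_model, path)
        models[net.model_id] = net
    if config.target not in models:
        raise PipelineError(
            f"stage 'read_models' failed: target {config.target!r} not among "
            f"models {sorted(models)}"
        )
    diet = _stage("read_diet")(
        read_diet, config.diet_path, unconstrained=config.unconstrained_compounds
    )
    compounds = sorted(config.compounds or diet.availability)

    fba_res: ScreenResult = _stage("fba_screen")(
        fba_single_screen, models[config.target], diet, compounds,
        delta=config.delta, cutoff=config.cutoff,
    )
    fba_res.write_tsv(outdir / "fba_screen.tsv")

    cm = _stage("community_merge")(merge_community, list(models.values()), diet)
    community_res: ScreenResult = _stage("community_screen")(
        community_supplement_screen, cm, diet, compounds,
        target=config.target, delta=config.delta, cutoff=config.cutoff,
    )
    community_res.write_tsv(outdir / "community_screen.tsv")

    if config.arena_compounds == "intersection":
        arena_compounds = sorted(fba_res.selected & community_res.selected)
    else:
        arena_compounds = compounds
    arena_cfg = dataclasses.replace(config.arena, seed=config.seed)
    arena_res: ScreenResult = _stage("arena_screen")(
        arena_supplement_screen, models, diet, arena_cfg, arena_compounds,
        target=config.target, alpha=config.alpha,
        selection=config.arena_selection,
    )
    arena_res.write_tsv(outdir / "arena_screen.tsv")

    shared = intersect_screens(fba_res.selected, community_res.selected,
                               arena_res.selected)

    if config.biolog_path:
        records = _stage("biolog")(read_biolog, config.biolog_path)
    else:
        records = []
    calls = _stage("biolog")(biolog_confirm, compounds, records)

    candidates = build_candidate_table(
        compounds, fba_res.selected, community_res.selected, arena_res.selected,
        calls, strict_biolog=config.strict_biolog,
    )
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    final = set(candidates.loc[candidates["final_candidate"], "compound"])
    if config.class_map_path:
        class_map = _stage("enrichment")(read_class_map, config.class_map_path)
        universe = set(models[config.target].compound_exchanges())
        annotated = universe & set(class_map)
        dropped = len(universe) - len(annotated)
        if dropped:
            logger.info("enrichment: %d unannotated universe compounds dropped",
                        dropped)
        enrichable = final & annotated
        if annotated:
            enrichment = _stage("enrichment")(
                class_enrichment, enrichable, annotated, class_map
            )
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "target": config.target,
        "models": sorted(models),
        "n_compounds_screened": len(compounds),
        "parameters": {
            "delta": config.delta,
            "cutoff": config.cutoff,
            "alpha": config.alpha,
            "arena": dataclasses.asdict(arena_cfg),
            "arena_compounds": config.arena_compounds,
            "arena_selection": config.arena_selection,
            "strict_biolog": config.strict_biolog,
        },
        "selected": {
            "fba": sorted(fba_res.selected),
            "community": sorted(community_res.selected),
            "arena": sorted(arena_res.selected),
            "shared": sorted(shared),
            "final": sorted(final),
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return candidates
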