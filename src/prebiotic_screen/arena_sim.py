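"""Individual-based spatial simulation of a microbial community on a grid.

Each grid cell holds a local pool of compounds (in mmol); each individual is a
growing bacterium whose metabolism is solved per step by flux-sum-penalized
FBA, with exchange lower bounds tightened to what its cell currently offers:
lb = max(model lb, -amount / (biomass * dt)).  Individuals take up and excrete
compounds, grow, divide into free Moore neighbors once they double their mass,
move at random, and nutrients spread by a discrete 4-neighbor diffusion sweep
with reflecting boundaries.  The growth medium is the diet diluted 1000-fold
(otherwise populations overgrow the arena before nutrients deplete), and a
supplemented compound is added once, at inoculation, to every cell.

The supplementation screen compares, per replicate, the relative change of
each species' total biomass at the final time step between a supplemented run
and the unsupplemented run with the same derived seed, then tests target
against competitor changes with a two-sided Wilcoxon rank-sum test and
controls the FDR across compounds (Benjamini-Hochberg).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from ._stats import bh_adjust, rank_sum_test
from ._util import round6
from .fba_engine import OPTIMAL, PenalizedLP
from .model_core import TOL_ZERO, U_FREE, Diet, MetabolicNetwork, apply_diet
from .results import ScreenResult

logger = logging.getLogger(__name__)

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class ArenaConfig:
    """Study conditions of the spatial simulation (defaults follow the screen
    design: 30x30 grid, 20 founders per species, 12 iterations, 15 replicates,
    1000-fold diluted medium, 0.01 mM supplement added once)."""

    rows: int = 30
    cols: int = 30
    inoculum_per_species: int = 20
    steps: int = 12
    dt: float = 1.0                 # h
    dilution: float = 1000.0
    supplement_conc: float = 0.01   # mM
    replicates: int = 15
    cell_volume: float = 1e-9       # L
    init_mass: float = 1e-12        # gDW
    division_mass: float = 2e-12    # gDW
    move_prob: float = 0.5
    diffusion_rate: float = 0.1     # per step, 0 disables
    seed: int = 0
    growth_update: str = "linear"   # or "exponential"

    def __post_init__(self):
        positive = ("rows", "cols", "inoculum_per_species", "steps", "dt",
                    "dilution", "replicates", "cell_volume", "init_mass",
                    "division_mass")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"ArenaConfig.{name} must be positive")
        if self.supplement_conc < 0:
            raise ValueError("supplement_conc must be non-negative")
        if self.division_mass <= self.init_mass:
            raise ValueError("division_mass must exceed init_mass")
        if not 0 <= self.move_prob <= 1:
            raise ValueError("move_prob must be in [0, 1]")
        if not 0 <= self.diffusion_rate <= 0.25:
            raise ValueError("diffusion_rate must be in [0, 0.25] for stability")
        if self.growth_update not in ("linear", "exponential"):
            raise ValueError(f"unknown growth_update {self.growth_update!r}")


@dataclass
class Agent:
    species: str
    row: int
    col: int
    biomass: float


@dataclass
class ArenaState:
    step: int
    amounts: Dict[str, np.ndarray]   # compound -> (rows, cols) mmol
    agents: List[Agent]
    rng: np.random.Generator
    net_exchange: Dict[str, float] = field(default_factory=dict)

    def occupancy(self) -> Dict[Tuple[int, int], int]:
        occ: Dict[Tuple[int, int], int] = {}
        for i, a in enumerate(self.agents):
            key = (a.row, a.col)
            if key in occ:
                raise ValueError(f"two individuals share cell {key}")
            occ[key] = i
        return occ


class _SpeciesSolver:
    """Per-species penalized-FBA problem with caching and batched solves.

    Agents only ever exchange with their own cell (there is at most one
    individual per cell), so within a step every agent's LP is independent of
    the others.  All still-unsolved bound situations of a step are therefore
    stacked into one block-diagonal LP and solved in a single call; agents in
    identical nutrient situations share one block through the cache.
    """

    def __init__(self, network: MetabolicNetwork, epsilon: float = 1e-6):
        self.network = network
        self.lp = PenalizedLP(network, epsilon)
        self.exchange = sorted(
            (network.exchange_compound(rid), rid) for rid in network.exchange_ids
        )
        self.base_lb = {
            rid: network.reaction(rid).lower_bound for _, rid in self.exchange
        }
        closed = self.lp.solve({rid: 0.0 for _, rid in self.exchange})
        self.closed_growth = closed.growth_rate if closed.status == OPTIMAL else 0.0
        self.cache: Dict[Tuple[float, ...], Tuple[float, Dict[str, float]]] = {}
        # split-LP arrays mirrored from PenalizedLP for batched assembly
        self._n = self.lp._n
        self._split = self.lp._split
        self._c = self.lp._c
        self._c_obj = self.lp._c_obj
        self._S_split = self.lp._S_split
        self._rxn_pos = {rid: j for j, rid in enumerate(self.lp._rxn_ids)}
        self._ex_pos = [self._rxn_pos[rid] for _, rid in self.exchange]
        self._base_lb_vec = self.lp._lb
        self._ub_vec = self.lp._ub

    def solve(self, lbs: Tuple[float, ...]) -> Tuple[float, Dict[str, float]]:
        """Growth rate and per-compound exchange fluxes for tightened bounds."""
        hit = self.cache.get(lbs)
        if hit is None:
            self.solve_batch([lbs])
            hit = self.cache[lbs]
        return hit

    def _single(self, lbs: Tuple[float, ...]) -> Tuple[float, Dict[str, float]]:
        overrides = {rid: lb for (_, rid), lb in zip(self.exchange, lbs)}
        sol = self.lp.solve(overrides)
        if sol.status != OPTIMAL:
            logger.warning("agent solve %s on %s: mu set to 0",
                           sol.status, self.network.model_id)
            return (0.0, {})
        ex = {
            cpd: sol.fluxes[rid]
            for cpd, rid in self.exchange
            if abs(sol.fluxes[rid]) > 0.0
        }
        return (max(sol.growth_rate, 0.0), ex)

    def solve_batch(self, keys) -> None:
        """Solve every uncached bound situation; populate the cache."""
        from scipy import sparse
        from scipy.optimize import linprog

        from .fba_engine import _HIGHS_OPTIONS, _STATUS

        todo = []
        seen = set()
        for lbs in keys:
            if lbs in self.cache or lbs in seen:
                continue
            seen.add(lbs)
            if self.closed_growth <= TOL_ZERO and all(b > -TOL_ZERO for b in lbs):
                self.cache[lbs] = (0.0, {})
            else:
                todo.append(lbs)
        if not todo:
            return
        k = len(todo)
        n, nsplit = self._n, len(self._split)
        ncols = n + nsplit
        A = sparse.kron(sparse.identity(k, format="csr"), self._S_split, format="csc")
        c = np.tile(self._c, k)
        bounds = np.empty((k * ncols, 2))
        for i, lbs in enumerate(todo):
            lb = self._base_lb_vec.copy()
            lb[self._ex_pos] = lbs
            bounds[i * ncols:(i + 1) * ncols] = self.lp._bounds(lb, self._ub_vec)
        res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds,
                      method="highs", options=_HIGHS_OPTIONS)
        if _STATUS.get(res.status) != OPTIMAL:
            # fall back to individual solves (keeps unusual models working)
            for lbs in todo:
                self.cache[lbs] = self._single(lbs)
            return
        for i, lbs in enumerate(todo):
            x = res.x[i * ncols:(i + 1) * ncols]
            v = x[:n].copy()
            v[self._split] -= x[n:ncols]
            mu = float(self._c_obj @ v)
            ex = {
                cpd: float(v[pos])
                for (cpd, _), pos in zip(self.exchange, self._ex_pos)
                if v[pos] != 0.0
            }
            self.cache[lbs] = (max(mu, 0.0), ex)


def _diffuse(grid: np.ndarray, rate: float) -> np.ndarray:
    """One 4-neighbor diffusion sweep, reflecting boundaries, mass conserving."""
    if rate == 0:
        return grid
    flux = np.zeros_like(grid)
    d = grid[1:, :] - grid[:-1, :]
    flux[:-1, :] += rate * d
    flux[1:, :] -= rate * d
    d = grid[:, 1:] - grid[:, :-1]
    flux[:, :-1] += rate * d
    flux[:, 1:] -= rate * d
    return grid + flux


def init_arena(models: Mapping[str, MetabolicNetwork], diet: Diet,
               config: ArenaConfig, supplement: Optional[str] = None,
               rng: Optional[np.random.Generator] = None,
               u_free: float = U_FREE) -> ArenaState:
    """Fill the grid with diluted medium and place founders at random cells."""
    n_cells = config.rows * config.cols
    total_inoculum = config.inoculum_per_species * len(models)
    if total_inoculum > n_cells:
        raise ValueError(
            f"inoculum of {total_inoculum} exceeds the {n_cells}-cell grid"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    amounts: Dict[str, np.ndarray] = {}
    shape = (config.rows, config.cols)
    for cpd, conc in diet.availability.items():
        if conc > 0:
            amounts[cpd] = np.full(shape, conc / config.dilution * config.cell_volume)
    for cpd in diet.unconstrained_compounds:
        amounts[cpd] = np.full(shape, u_free / config.dilution * config.cell_volume)
    if supplement is not None:
        extra = config.supplement_conc * config.cell_volume
        if supplement in amounts:
            amounts[supplement] = amounts[supplement] + extra
        else:
            amounts[supplement] = np.full(shape, extra)
    cells = rng.choice(n_cells, size=total_inoculum, replace=False)
    agents = []
    for k, sp in enumerate(sorted(models)):
        for j in range(config.inoculum_per_species):
            flat = int(cells[k * config.inoculum_per_species + j])
            agents.append(Agent(sp, flat // config.cols, flat % config.cols,
                                config.init_mass))
    return ArenaState(step=1, amounts=amounts, agents=agents, rng=rng)


def _free_neighbors(row: int, col: int, occ, config: ArenaConfig):
    out = []
    for dr, dc in _MOORE:
        r, c = row + dr, col + dc
        if 0 <= r < config.rows and 0 <= c < config.cols and (r, c) not in occ:
            out.append((r, c))
    return out


def step_arena(state: ArenaState, models: Mapping[str, MetabolicNetwork],
               config: ArenaConfig,
               solvers: Optional[Mapping[str, _SpeciesSolver]] = None) -> ArenaState:
    """Advance the arena by one time step (state is updated in place).

    ``models`` must already carry the diet on their exchange bounds.  Agents
    act in seeded random order: metabolize (penalized FBA with locally
    tightened uptake bounds), grow, divide, move; then nutrients diffuse.
    """
    if solvers is None:
        solvers = {sp: _SpeciesSolver(net) for sp, net in models.items()}
    rng = state.rng
    occ = {(a.row, a.col) for a in state.agents}
    net_exchange: Dict[str, float] = {}
    daughters: List[Agent] = []
    order = rng.permutation(len(state.agents))
    # Pass 1: collect every agent's tightened bounds from the current grid.
    # Agents only exchange with their own (exclusively held) cell, so their
    # LPs are mutually independent and can be batch-solved up front.
    agent_lbs: Dict[int, Tuple[float, ...]] = {}
    batch: Dict[str, list] = {sp: [] for sp in solvers}
    for idx in order:
        agent = state.agents[idx]
        solver = solvers[agent.species]
        denom = agent.biomass * config.dt
        lbs = []
        for cpd, rid in solver.exchange:
            grid = state.amounts.get(cpd)
            local = float(grid[agent.row, agent.col]) if grid is not None else 0.0
            lbs.append(max(solver.base_lb[rid], -local / denom))
        agent_lbs[idx] = tuple(lbs)
        batch[agent.species].append(agent_lbs[idx])
    for sp, keys in batch.items():
        if keys:
            solvers[sp].solve_batch(keys)
    # Pass 2: apply metabolism, growth, division and movement in seeded order.
    for idx in order:
        agent = state.agents[idx]
        solver = solvers[agent.species]
        mu, ex_fluxes = solver.solve(agent_lbs[idx])
        pre_mass = agent.biomass
        for cpd, flux in ex_fluxes.items():
            delta = flux * pre_mass * config.dt
            grid = state.amounts.get(cpd)
            if grid is None:
                grid = np.zeros((config.rows, config.cols))
                state.amounts[cpd] = grid
            new_amount = grid[agent.row, agent.col] + delta
            grid[agent.row, agent.col] = new_amount if new_amount > 0 else 0.0
            net_exchange[cpd] = net_exchange.get(cpd, 0.0) + delta
        if config.growth_update == "linear":
            agent.biomass = pre_mass * (1.0 + mu * config.dt)
        else:
            agent.biomass = pre_mass * math.exp(mu * config.dt)
        if agent.biomass >= config.division_mass:
            free = _free_neighbors(agent.row, agent.col, occ, config)
            if free:  # otherwise division is deferred to a later step
                r, c = free[int(rng.integers(len(free)))]
                half = agent.biomass / 2.0
                agent.biomass = half
                daughters.append(Agent(agent.species, r, c, half))
                occ.add((r, c))
        if config.move_prob > 0 and rng.random() < config.move_prob:
            free = _free_neighbors(agent.row, agent.col, occ, config)
            if free:
                r, c = free[int(rng.integers(len(free)))]
                occ.discard((agent.row, agent.col))
                agent.row, agent.col = r, c
                occ.add((r, c))
    state.agents.extend(daughters)
    if config.diffusion_rate > 0:
        for cpd in state.amounts:
            state.amounts[cpd] = _diffuse(state.amounts[cpd], config.diffusion_rate)
    state.step += 1
    state.net_exchange = net_exchange
    return state


def _record(rows: list, replicate: int, step: int, agents: Iterable[Agent],
            species: Iterable[str]) -> None:
    totals: Dict[str, float] = {sp: 0.0 for sp in species}
    counts: Dict[str, int] = {sp: 0 for sp in species}
    for a in agents:
        totals[a.species] += a.biomass
        counts[a.species] += 1
    for sp in totals:
        rows.append((replicate, sp, step, totals[sp], counts[sp]))


def simulate(models: Mapping[str, MetabolicNetwork], diet: Diet,
             config: ArenaConfig, supplement: Optional[str] = None,
             _solvers: Optional[Mapping[str, _SpeciesSolver]] = None) -> pd.DataFrame:
    """Run all replicates; return growth curves.

    Columns: ``replicate``, ``species``, ``step`` (1..steps+1), ``biomass``
    (total gDW), ``count``.  Replicate r uses the derived seed (seed, r), so
    supplemented and unsupplemented runs of the same replicate are paired.
    """
    applied = {sp: apply_diet(net, diet) for sp, net in models.items()}
    solvers = _solvers if _solvers is not None else {
        sp: _SpeciesSolver(net) for sp, net in applied.items()
    }
    rows: list = []
    for rep in range(config.replicates):
        rng = np.random.default_rng((config.seed, rep))
        state = init_arena(applied, diet, config, supplement=supplement, rng=rng)
        _record(rows, rep, 1, state.agents, applied)
        for _ in range(config.steps):
            state = step_arena(state, applied, config, solvers=solvers)
            _record(rows, rep, state.step, state.agents, applied)
    return pd.DataFrame(rows, columns=["replicate", "species", "step", "biomass", "count"])


def make_solvers(models: Mapping[str, MetabolicNetwork], diet: Diet,
                 epsilon: float = 1e-6) -> Dict[str, _SpeciesSolver]:
    """Prebuild (and share) per-species solvers across several simulate calls."""
    return {sp: _SpeciesSolver(apply_diet(net, diet), epsilon)
            for sp, net in models.items()}


def arena_supplement_screen(models: Mapping[str, MetabolicNetwork], diet: Diet,
                            config: ArenaConfig, compounds, target: str,
                            alpha: float = 0.05,
                            selection: str = "fdr") -> ScreenResult:
    """Replicate-based spatial supplementation screen for two species.

    ``selection="fdr"`` requires median dominance of the target and q <= alpha;
    ``"median"`` requires median dominance only.
    """
    if config.replicates < 2:
        raise ValueError("the arena screen needs at least 2 replicates")
    if target not in models:
        raise ValueError(f"target {target!r} is not among the models")
    if len(models) != 2:
        raise ValueError("the pairwise arena screen supports exactly two species")
    if selection not in ("fdr", "median"):
        raise ValueError(f"unknown selection mode {selection!r}")
    competitor = next(sp for sp in models if sp != target)
    final_step = config.steps + 1
    solvers = make_solvers(models, diet)

    def final_biomass(curves: pd.DataFrame) -> pd.DataFrame:
        last = curves[curves["step"] == final_step]
        return last.pivot(index="replicate", columns="species", values="biomass")

    base = final_biomass(simulate(models, diet, config, None, _solvers=solvers))
    rows = []
    for compound in sorted(compounds):
        sup = final_biomass(
            simulate(models, diet, config, compound, _solvers=solvers)
        )
        changes = {
            sp: np.array([
                round6((sup.loc[rep, sp] - base.loc[rep, sp]) / base.loc[rep, sp])
                for rep in base.index
            ])
            for sp in (target, competitor)
        }
        w, p = rank_sum_test(changes[target], changes[competitor])
        rows.append((compound, float(np.median(changes[target])),
                     float(np.median(changes[competitor])), w, p))
    table = pd.DataFrame(
        rows, columns=["compound", "median_effect_target", "median_effect_other",
                       "W", "p"]
    )
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    dominant = table["median_effect_target"] > table["median_effect_other"]
    if selection == "fdr":
        table["selected"] = dominant & (table["q"] <= alpha)
    else:
        table["selected"] = dominant
    selected = frozenset(table.loc[table["selected"], "compound"])
    return ScreenResult(table, selected)
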