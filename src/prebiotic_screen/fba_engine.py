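"""Linear-programming core: FBA, flux-sum-penalized FBA, maximal-uptake queries.

Flux balance analysis maximizes the biomass objective c.v subject to the
steady-state constraint S.v = 0 and flux bounds lb <= v <= ub.  The penalized
variant maximizes c.v - epsilon * sum_r |v_r|, implemented by splitting every
reaction into forward and reverse non-negative parts (v = v+ - v-); the
penalty discourages futile cycles and makes alternate optima better behaved.
The reported objective of the penalized solve is the biomass term alone, with
the penalty stripped, so downstream relative changes compare growth rates.

All solves go through scipy's HiGHS interface with tightened feasibility
tolerances.  Only objective-level quantities (objective value, growth rate,
uptake minima) are solver-deterministic; individual fluxes of degenerate
alternate optima are not, and callers must not rely on them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_core import TOL_ZERO, MetabolicNetwork

logger = logging.getLogger(__name__)

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_HIGHS_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}

_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


@dataclass(frozen=True)
class FluxSolution:
    """Result of one LP solve over a metabolic network."""

    status: str
    objective_value: float
    fluxes: Mapping[str, float]
    growth_rate: float
    residual: float = 0.0  # max |S.v| at the optimum


class FBAError(RuntimeError):
    """The LP solver failed for a numerical (non-status) reason."""


def _lp_arrays(network: MetabolicNetwork):
    """Assemble (S, lb, ub, c, rxn_ids, met_index) for a network."""
    rxn_ids = [r.id for r in network.reactions]
    met_index = {m.id: i for i, m in enumerate(network.metabolites)}
    rows, cols, data = [], [], []
    for j, r in enumerate(network.reactions):
        for met_id, coeff in r.stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(float(coeff))
    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(network.metabolites), len(rxn_ids))
    )
    lb = np.array([r.lower_bound for r in network.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in network.reactions], dtype=float)
    c = np.array([r.objective_coefficient for r in network.reactions], dtype=float)
    return S, lb, ub, c, rxn_ids, met_index


def _solve(network: MetabolicNetwork, minimize_c: np.ndarray, S, lb, ub,
           rxn_ids) -> Tuple[str, Optional[np.ndarray], float]:
    res = linprog(
        minimize_c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_HIGHS_OPTIONS,
    )
    status = _STATUS.get(res.status)
    if status is None:
        raise FBAError(
            f"LP solve failed on model {network.model_id!r}: {res.message}"
        )
    logger.debug("LP %s: status=%s objective=%s", network.model_id, status, res.fun)
    if status != OPTIMAL:
        return status, None, math.nan
    return status, res.x, float(res.fun)


def _finish(network: MetabolicNetwork, S, rxn_ids, status, v, objective) -> FluxSolution:
    if status != OPTIMAL:
        return FluxSolution(status, math.nan, {}, math.nan, math.nan)
    residual = float(np.max(np.abs(S @ v))) if S.shape[0] else 0.0
    fluxes = dict(zip(rxn_ids, v.tolist()))
    if network.biomass_id is not None:
        growth = fluxes.get(network.biomass_id, 0.0)
    else:
        growth = objective
    return FluxSolution(OPTIMAL, objective, fluxes, growth, residual)


def fba(network: MetabolicNetwork) -> FluxSolution:
    """Plain flux balance analysis: maximize the biomass objective."""
    S, lb, ub, c, rxn_ids, _ = _lp_arrays(network)
    status, v, fun = _solve(network, -c, S, lb, ub, rxn_ids)
    objective = -fun if status == OPTIMAL else math.nan
    return _finish(network, S, rxn_ids, status, v, objective)


def max_uptake(network: MetabolicNetwork, exchange_id: str) -> float:
    """Minimum feasible flux through one exchange (most negative = max uptake).

    No biomass requirement is imposed: the query asks only whether mass can
    flow into the network at steady state.  A value below -TOL_ZERO means the
    compound can be taken up.
    """
    if exchange_id not in network.exchange_ids:
        raise ValueError(
            f"{exchange_id!r} is not an exchange reaction of {network.model_id!r}"
        )
    S, lb, ub, _, rxn_ids, _ = _lp_arrays(network)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(exchange_id)] = 1.0
    status, v, fun = _solve(network, c, S, lb, ub, rxn_ids)
    if status != OPTIMAL:
        raise FBAError(
            f"uptake query for {exchange_id!r} on {network.model_id!r} "
            f"returned status {status}"
        )
    return float(fun)


class PenalizedLP:
    """Reusable flux-sum-penalized FBA problem for one network.

    Splitting is applied only to reactions whose bounds allow negative flux;
    irreversible reactions keep a single column.  ``solve`` accepts per-call
    lower-bound overrides (used heavily by the spatial simulation, where local
    nutrient amounts tighten exchange bounds every step).
    """

    def __init__(self, network: MetabolicNetwork, epsilon: float = 1e-6):
        if epsilon < 0:
            raise ValueError(f"epsilon must be non-negative, got {epsilon}")
        self.network = network
        self.epsilon = float(epsilon)
        S, lb, ub, c_obj, rxn_ids, _ = _lp_arrays(network)
        self._S_orig = S
        self._lb, self._ub = lb, ub
        self._rxn_ids = rxn_ids
        n = len(rxn_ids)
        self._split = np.flatnonzero(lb < 0)  # reactions needing a reverse part
        m = len(self._split)
        # columns: [forward parts (n)] + [reverse parts (m)]
        S_neg = -S[:, self._split]
        self._S_split = sparse.hstack([S, S_neg], format="csc")
        self._c = np.concatenate([-c_obj + self.epsilon,
                                  c_obj[self._split] + self.epsilon])
        self._c_obj = c_obj
        self._n, self._m = n, m

    def _bounds(self, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
        pos_lb = np.maximum(lb, 0.0)
        pos_ub = np.maximum(ub, 0.0)
        neg_lb = np.maximum(-ub[self._split], 0.0)
        neg_ub = np.maximum(-lb[self._split], 0.0)
        return np.column_stack(
            [np.concatenate([pos_lb, neg_lb]), np.concatenate([pos_ub, neg_ub])]
        )

    def solve(self, lb_overrides: Optional[Mapping[str, float]] = None) -> FluxSolution:
        lb = self._lb
        if lb_overrides:
            lb = lb.copy()
            split_set = set(self._split.tolist())
            for rxn_id, value in lb_overrides.items():
                j = self._rxn_ids.index(rxn_id)
                if value < 0 and j not in split_set:
                    raise ValueError(
                        f"cannot open reaction {rxn_id!r} below zero: it was "
                        "irreversible when the problem was built"
                    )
                lb[j] = value
        res = linprog(
            self._c,
            A_eq=self._S_split,
            b_eq=np.zeros(self._S_split.shape[0]),
            bounds=self._bounds(lb, self._ub),
            method="highs",
            options=_HIGHS_OPTIONS,
        )
        status = _STATUS.get(res.status)
        if status is None:
            raise FBAError(
                f"penalized LP failed on {self.network.model_id!r}: {res.message}"
            )
        if status != OPTIMAL:
            return FluxSolution(status, math.nan, {}, math.nan, math.nan)
        v = res.x[: self._n].copy()
        v[self._split] -= res.x[self._n:]
        objective = float(self._c_obj @ v)  # biomass term alone, penalty stripped
        return _finish(self.network, self._S_orig, self._rxn_ids, OPTIMAL, v, objective)


def fba_flux_penalty(network: MetabolicNetwork, epsilon: float = 1e-6) -> FluxSolution:
    """FBA with an epsilon-weighted penalty on the total absolute flux."""
    return PenalizedLP(network, epsilon).solve()
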