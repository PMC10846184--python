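"""Spatial arena: initialization, stepping, conservation, screen behavior."""

import math

import numpy as np
import pandas as pd
import pytest

from prebiotic_screen.arena_sim import (
    ArenaConfig,
    _diffuse,
    arena_supplement_screen,
    init_arena,
    simulate,
    step_arena,
)
from prebiotic_screen.model_core import Diet, apply_diet
from prebiotic_screen.synthetic_data import (
    SyntheticSpec,
    make_collection,
    planted_pair_spec,
)

from conftest import build_network

SMALL = dict(rows=8, cols=8, inoculum_per_species=3, steps=3, replicates=2,
             seed=7)


def growth_model(model_id="mono", yield_=0.05):
    """Single-substrate species: mu = uptake * yield (0.5/h at lb -10)."""
    return build_network(
        model_id, [("A", "e"), ("A_c", "c"), ("P", "c")],
        [("EX_A", {"A": -1}, 0, 1000),
         ("T_A", {"A": -1, "A_c": 1}, 0, 1000),
         ("CAT_A", {"A_c": -1, "P": yield_}, 0, 1000),
         ("BIOMASS", {"P": -1}, 0, 1000, 1.0)],
    )


def total_amounts(state):
    return {cpd: float(grid.sum()) for cpd, grid in state.amounts.items()}


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(rows=0), dict(steps=0), dict(move_prob=1.5),
        dict(diffusion_rate=0.3), dict(division_mass=5e-13),
        dict(supplement_conc=-1.0), dict(growth_update="cubic"),
    ])
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ArenaConfig(**kwargs)


class TestInit:
    def test_dilution_arithmetic(self):
        cfg = ArenaConfig(**SMALL)
        models = {"m": growth_model()}
        state = init_arena(models, Diet("d", {"A": 10.0}), cfg)
        # 10 mM / 1000 * 1e-9 L = 1e-11 mmol per cell
        assert state.amounts["A"][0, 0] == pytest.approx(1e-11)

    def test_supplement_added_once_at_start(self):
        cfg = ArenaConfig(**SMALL)
        models = {"m": growth_model()}
        state = init_arena(models, Diet("d", {"A": 10.0}), cfg, supplement="A")
        assert state.amounts["A"][0, 0] == pytest.approx(2e-11)
        state2 = init_arena(models, Diet("d", {"A": 10.0}), cfg, supplement="B")
        assert state2.amounts["B"][3, 3] == pytest.approx(1e-11)

    def test_same_seed_same_placement(self):
        cfg = ArenaConfig(**SMALL)
        models = {"m": growth_model()}
        a = init_arena(models, Diet("d", {"A": 10.0}), cfg)
        b = init_arena(models, Diet("d", {"A": 10.0}), cfg)
        assert [(x.row, x.col) for x in a.agents] == [(x.row, x.col) for x in b.agents]

    def test_overfull_grid_rejected(self):
        cfg = ArenaConfig(rows=3, cols=3, inoculum_per_species=10)
        with pytest.raises(ValueError):
            init_arena({"m": growth_model()}, Diet("d", {}), cfg)

    def test_inoculum_row_of_growth_curve(self):
        cfg = ArenaConfig(**SMALL)
        models = {"m": growth_model()}
        curves = simulate(models, Diet("d", {"A": 10.0}), cfg)
        first = curves[(curves.step == 1) & (curves.replicate == 0)]
        assert int(first["count"].iloc[0]) == cfg.inoculum_per_species
        assert float(first["biomass"].iloc[0]) == pytest.approx(
            cfg.inoculum_per_species * cfg.init_mass
        )


class TestStep:
    def test_single_agent_growth_update(self):
        # non-limiting nutrients, mu* = 0.5: one step multiplies mass by 1.5
        cfg = ArenaConfig(rows=4, cols=4, inoculum_per_species=1, steps=1,
                          replicates=1, dilution=1e-6, division_mass=1.0, seed=3)
        diet = Diet("d", {"A": 10.0})
        models = {"m": apply_diet(growth_model(), diet)}
        state = init_arena(models, diet, cfg)
        step_arena(state, models, cfg)
        assert state.agents[0].biomass == pytest.approx(1.5e-12)

    def test_exponential_update_option(self):
        cfg = ArenaConfig(rows=4, cols=4, inoculum_per_species=1, steps=1,
                          replicates=1, dilution=1e-6, division_mass=1.0,
                          growth_update="exponential", seed=3)
        diet = Diet("d", {"A": 10.0})
        models = {"m": apply_diet(growth_model(), diet)}
        state = init_arena(models, diet, cfg)
        step_arena(state, models, cfg)
        assert state.agents[0].biomass == pytest.approx(math.exp(0.5) * 1e-12)

    def test_starved_agent_keeps_mass(self):
        cfg = ArenaConfig(**SMALL)
        diet = Diet("empty", {})
        models = {"m": apply_diet(growth_model(), diet)}
        state = init_arena(models, diet, cfg)
        step_arena(state, models, cfg)
        assert all(a.biomass == pytest.approx(1e-12) for a in state.agents)

    def test_mass_balance_every_step(self):
        # grid totals change exactly by the agents' net exchange; diffusion
        # moves mass around but conserves the totals
        spec = planted_pair_spec(seed=0, n_neutral=3)
        models_raw, diet = make_collection(spec)
        cfg = ArenaConfig(rows=10, cols=10, inoculum_per_species=5, steps=6,
                          replicates=1, seed=11)
        models = {m.model_id: apply_diet(m, diet) for m in models_raw}
        state = init_arena(models, diet, cfg)
        for _ in range(cfg.steps):
            before = total_amounts(state)
            step_arena(state, models, cfg)
            after = total_amounts(state)
            for cpd in before:
                expected = before[cpd] + state.net_exchange.get(cpd, 0.0)
                scale = max(abs(before[cpd]), 1e-30)
                assert abs(after.get(cpd, 0.0) - expected) <= 1e-12 * scale

    def test_occupancy_invariant_preserved(self):
        spec = planted_pair_spec(seed=0, n_neutral=3)
        models_raw, diet = make_collection(spec)
        cfg = ArenaConfig(rows=6, cols=6, inoculum_per_species=8, steps=5,
                          replicates=1, seed=2)
        models = {m.model_id: apply_diet(m, diet) for m in models_raw}
        state = init_arena(models, diet, cfg)
        for _ in range(cfg.steps):
            step_arena(state, models, cfg)
            state.occupancy()  # raises if two agents share a cell
            assert all(a.biomass > 0 for a in state.agents)
            assert all(g.min() >= 0.0 for g in state.amounts.values())


class TestDiffusion:
    def test_conserves_total_mass(self):
        rng = np.random.default_rng(5)
        grid = rng.uniform(0, 1e-10, size=(12, 9))
        out = _diffuse(grid, 0.1)
        assert out.sum() == pytest.approx(grid.sum(), rel=1e-13)

    def test_smooths_towards_uniform(self):
        grid = np.zeros((5, 5))
        grid[2, 2] = 1.0
        out = _diffuse(grid, 0.25)
        assert out[2, 2] < 1.0
        assert out[2, 1] == pytest.approx(0.25)

    def test_zero_rate_is_identity(self):
        grid = np.arange(6.0).reshape(2, 3)
        assert np.array_equal(_diffuse(grid, 0.0), grid)


class TestSimulate:
    def test_thirteen_time_points_for_twelve_iterations(self):
        cfg = ArenaConfig(rows=6, cols=6, inoculum_per_species=2, steps=12,
                          replicates=1, seed=1)
        models = {"m": growth_model()}
        curves = simulate(models, Diet("d", {"A": 10.0}), cfg)
        assert sorted(curves["step"].unique()) == list(range(1, 14))

    def test_bit_reproducible_for_fixed_seed(self):
        spec = planted_pair_spec(seed=0, n_neutral=3)
        models_raw, diet = make_collection(spec)
        models = {m.model_id: m for m in models_raw}
        cfg = ArenaConfig(**SMALL)
        a = simulate(models, diet, cfg)
        b = simulate(models, diet, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_nutrients_flat_curves(self):
        cfg = ArenaConfig(**SMALL)
        models = {"m": growth_model()}
        curves = simulate(models, Diet("empty", {}), cfg)
        assert curves["biomass"].nunique() == 1

    def test_exponential_trajectory_without_division(self):
        # division off, nutrients non-limiting: biomass = (1 + mu dt)^t exactly
        cfg = ArenaConfig(rows=5, cols=5, inoculum_per_species=1, steps=4,
                          replicates=1, dilution=1e-6, division_mass=1.0, seed=9)
        models = {"m": growth_model()}
        curves = simulate(models, Diet("d", {"A": 10.0}), cfg)
        for t in range(1, 6):
            biomass = float(curves[curves.step == t]["biomass"].iloc[0])
            assert biomass == pytest.approx(1e-12 * 1.5 ** (t - 1), rel=1e-9)


@pytest.fixture(scope="module")
def screen_setup():
    spec = planted_pair_spec(seed=0, n_neutral=4)
    models_raw, diet = make_collection(spec)
    models = {m.model_id: m for m in models_raw}
    cfg = ArenaConfig(rows=10, cols=10, inoculum_per_species=5, steps=6,
                      replicates=6, seed=5)
    return models, diet, cfg


class TestArenaScreen:

    def test_planted_compound_selected(self, screen_setup):
        models, diet, cfg = screen_setup
        res = arena_supplement_screen(models, diet, cfg, ["preb1"], target="S1")
        row = res.table.iloc[0]
        assert row["median_effect_target"] > row["median_effect_other"]
        assert "preb1" in res.selected

    def test_inert_compound_not_selected(self, screen_setup):
        models, diet, cfg = screen_setup
        inert_diet = Diet(diet.name, {**diet.availability, "inert": 10.0})
        res = arena_supplement_screen(models, inert_diet, cfg, ["inert"],
                                      target="S1")
        row = res.table.iloc[0]
        assert row["median_effect_target"] == 0.0
        assert row["median_effect_other"] == 0.0
        assert row["p"] == 1.0
        assert res.selected == frozenset()

    def test_symmetric_boost_not_selected(self):
        # identical species: no median dominance for the target
        spec = SyntheticSpec(n_species=2, n_shared_compounds=3,
                             competitor_edge=1.0, seed=0)
        models_raw, diet = make_collection(spec)
        models = {m.model_id: m for m in models_raw}
        cfg = ArenaConfig(rows=10, cols=10, inoculum_per_species=5, steps=5,
                          replicates=6, seed=13)
        res = arena_supplement_screen(models, diet, cfg, ["c01"], target="S1",
                                      selection="fdr")
        assert res.table.iloc[0]["q"] > 0.05 or not res.table.iloc[0]["selected"]
        assert res.selected == frozenset()

    def test_too_few_replicates_rejected(self, screen_setup):
        models, diet, _ = screen_setup
        cfg = ArenaConfig(replicates=1)
        with pytest.raises(ValueError):
            arena_supplement_screen(models, diet, cfg, ["preb1"], target="S1")

    def test_unknown_target_rejected(self, screen_setup):
        models, diet, cfg = screen_setup
        with pytest.raises(ValueError):
            arena_supplement_screen(models, diet, cfg, ["preb1"], target="S9")
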