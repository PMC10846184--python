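"""Single-FBA screen rules, intersection, Biolog calls, enrichment, host stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from prebiotic_screen.candidate_stats import (
    BiologRecord,
    biolog_confirm,
    build_candidate_table,
    chisq_obs_vs_expected,
    class_enrichment,
    expected_host_proportion,
    fba_single_screen,
    intersect_screens,
    read_biolog,
    read_class_map,
)
from prebiotic_screen.model_core import Diet
from prebiotic_screen.synthetic_data import make_collection, planted_pair_spec

from conftest import build_network


def linear_model(yield_=0.01):
    """Growth = availability * yield, unbounded machinery."""
    return build_network(
        "lin", [("A", "e"), ("P", "c")],
        [("EX_A", {"A": -1}, 0, 1e6),
         ("CAT_A", {"A": -1, "P": yield_}, 0, 1e6),
         ("BIOMASS", {"P": -1}, 0, 1e6, 1.0)],
    )


class TestFbaSingleScreen:
    def test_planted_limiting_substrate_selected(self):
        models, diet = make_collection(planted_pair_spec())
        res = fba_single_screen(models[0], diet, sorted(diet.availability))
        assert "preb1" in res.selected

    def test_non_limiting_compound_not_selected(self):
        # biomass machinery capped: more substrate changes nothing
        net = build_network(
            "capped", [("A", "e"), ("P", "c")],
            [("EX_A", {"A": -1}, 0, 1e6),
             ("CAT_A", {"A": -1, "P": 1.0}, 0, 1e6),
             ("BIOMASS", {"P": -1}, 0, 5.0, 1.0)],
        )
        res = fba_single_screen(net, Diet("d", {"A": 10.0}), ["A"])
        assert res.table.iloc[0]["effect"] == 0.0
        assert res.selected == frozenset()

    def test_change_of_exactly_cutoff_not_selected(self):
        # growth 1.0 -> 1.01: relative change exactly 0.01, strict rule rejects
        res = fba_single_screen(linear_model(0.01), Diet("d", {"A": 100.0}),
                                ["A"], delta=1.0)
        assert res.table.iloc[0]["effect"] == pytest.approx(0.01, abs=0)
        assert res.selected == frozenset()

    def test_change_just_above_cutoff_selected(self):
        res = fba_single_screen(linear_model(0.01), Diet("d", {"A": 100.0}),
                                ["A"], delta=1.2)
        assert res.selected == frozenset({"A"})


class TestIntersect:
    def test_three_way_intersection(self):
        assert intersect_screens({"a", "b", "c"}, {"b", "c"}, {"c", "d"}) == {"c"}

    def test_empty_input_gives_empty(self):
        assert intersect_screens(set(), {"a"}, {"a"}) == set()

    def test_idempotent_on_identical_inputs(self):
        s = {"x", "y"}
        assert intersect_screens(s, s, s) == s


class TestBiolog:
    def test_growth_call_rules(self):
        records = [
            BiologRecord("grow", 0.25, 0.10),      # diff 0.15 -> yes
            BiologRecord("boundary", 0.20, 0.10),  # diff 0.10 -> no (strict)
        ]
        calls = biolog_confirm(["grow", "boundary", "absent"], records)
        assert calls == {"grow": "yes", "boundary": "no", "absent": "untested"}

    def test_record_order_irrelevant(self):
        records = [BiologRecord("a", 0.5, 0.1), BiologRecord("b", 0.15, 0.1)]
        forward = biolog_confirm(["a", "b"], records)
        assert forward == biolog_confirm(["a", "b"], records[::-1])

    def test_duplicate_records_rejected(self):
        records = [BiologRecord("a", 0.5, 0.1), BiologRecord("a", 0.4, 0.1)]
        with pytest.raises(ValueError):
            biolog_confirm(["a"], records)

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            BiologRecord("a", -0.1, 0.0)

    def test_reader(self, tmp_path):
        path = tmp_path / "biolog.tsv"
        path.write_text("# compound\tod590\tod750\nser\t0.3\t0.1\n")
        records = read_biolog(path)
        assert records == [BiologRecord("ser", 0.3, 0.1)]


class TestEnrichment:
    def test_worked_hypergeometric_example(self):
        # universe 20, class 5, candidates 4, overlap 4:
        # P(X >= 4) = C(5,4) C(15,0) / C(20,4) = 5 / 4845
        universe = {f"m{i}" for i in range(20)}
        in_class = {f"m{i}" for i in range(5)}
        candidates = {f"m{i}" for i in range(4)}
        class_map = {c: {"acid"} for c in in_class}
        table = class_enrichment(candidates, universe, class_map)
        row = table[table["class"] == "acid"].iloc[0]
        assert row["p_enrich"] == pytest.approx(5 / 4845, rel=1e-9)
        assert (row["a"], row["b"], row["c"], row["d"]) == (4, 0, 1, 15)

    def test_class_covering_universe_is_uninformative(self):
        universe = {f"m{i}" for i in range(8)}
        class_map = {c: {"everything"} for c in universe}
        table = class_enrichment({"m0", "m1"}, universe, class_map)
        assert table.iloc[0]["p"] == pytest.approx(1.0)

    def test_empty_candidate_set_gives_p_one(self):
        universe = {"m0", "m1", "m2", "m3"}
        class_map = {"m0": {"k"}, "m1": {"k"}}
        table = class_enrichment(set(), universe, class_map)
        assert (table["p"] == 1.0).all()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            class_enrichment(set(), set(), {})

    def test_candidates_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            class_enrichment({"x"}, {"m"}, {"m": {"k"}})

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(5, 30), st.data())
    def test_fisher_p_matches_hypergeometric_tail_sum(self, n_universe, data):
        n_class = data.draw(st.integers(1, n_universe))
        n_cand = data.draw(st.integers(0, n_universe))
        universe = {f"m{i}" for i in range(n_universe)}
        in_class = {f"m{i}" for i in range(n_class)}
        candidates = {f"m{i}" for i in range(n_cand)}
        table = class_enrichment(candidates, universe,
                                 {c: {"k"} for c in in_class})
        row = table.iloc[0]
        a = len(candidates & in_class)
        # exhaustive two-sided tail: sum of all table probabilities <= observed
        rv = stats.hypergeom(n_universe, n_class, n_cand)
        p_obs = rv.pmf(a)
        support = np.arange(max(0, n_cand + n_class - n_universe),
                            min(n_cand, n_class) + 1)
        expected = float(rv.pmf(support)[rv.pmf(support) <= p_obs * (1 + 1e-9)].sum())
        assert row["p"] == pytest.approx(expected, rel=1e-7)
        assert row["p_enrich"] == pytest.approx(float(rv.sf(a - 1)), rel=1e-9)


class TestHostProportion:
    def test_worked_example(self):
        assert expected_host_proportion(0.75, 0.5, 0.6) == pytest.approx(0.625)

    def test_unchanged_lawn_returns_baseline_host_proportion(self):
        assert expected_host_proportion(0.6, 0.45, 0.6) == pytest.approx(0.45)

    def test_fixed_point(self):
        assert expected_host_proportion(0.9, 0.9, 0.9) == pytest.approx(0.9)

    def test_scale_consistency(self):
        a = expected_host_proportion(0.8, 0.5, 0.4)
        b = expected_host_proportion(0.8, 0.25, 0.2)
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("args", [(0.0, 0.5, 0.5), (0.5, 0.5, 0.0),
                                      (1.5, 0.5, 0.5)])
    def test_out_of_range_rejected(self, args):
        with pytest.raises(ValueError):
            expected_host_proportion(*args)


class TestChiSquared:
    def test_perfect_agreement(self):
        stat, df, p = chisq_obs_vs_expected((50, 50), 0.5)
        assert stat == pytest.approx(0.0)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_formula_evaluation(self):
        # E = (50, 50): sum (O-E)^2/E = 625/50 + 625/50 = 25
        stat, _, _ = chisq_obs_vs_expected((75, 25), 0.5)
        assert stat == pytest.approx(25.0)
        stat, _, _ = chisq_obs_vs_expected((0, 100), 0.5)
        assert stat == pytest.approx(100.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            chisq_obs_vs_expected((0, 0), 0.5)
        with pytest.raises(ValueError):
            chisq_obs_vs_expected((10, 10), 1.0)


class TestCandidateTable:
    def test_final_requires_all_screens_and_biolog(self):
        table = build_candidate_table(
            ["a", "b", "c"], {"a", "b"}, {"a", "b"}, {"a"},
            {"a": "yes", "b": "yes", "c": "no"},
        )
        final = set(table.loc[table["final_candidate"], "compound"])
        assert final == {"a"}

    def test_lenient_mode_ignores_missing_biolog(self):
        table = build_candidate_table(
            ["a"], {"a"}, {"a"}, {"a"}, {}, strict_biolog=False,
        )
        assert bool(table.iloc[0]["final_candidate"])

    def test_class_map_reader(self, tmp_path):
        path = tmp_path / "classes.tsv"
        path.write_text("# compound\tclass\nser\tamino_acid\nser\tpolar\n")
        assert read_class_map(path) == {"ser": {"amino_acid", "polar"}}
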