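"""Model I/O, FBA/pFBA, production envelopes, conditions and biomass lumping."""

import itertools

import numpy as np
import pytest

from cbmkit import (
    FluxDistribution,
    ModelValidationError,
    load_model,
    save_model,
    lump_equivalent_biomass,
    production_envelope,
    set_condition,
    solve_fba,
    solve_pfba,
)
from cbmkit.model import OPTIMAL

from conftest import build_model


def brute_force_vertex_optimum(model, sense="max"):
    """Independent FBA oracle: enumerate candidate vertices of the flux
    polytope by fixing subsets of variables at their bounds and solving the
    remaining equality system (exhaustive for <= ~6 free dimensions)."""
    n = model.n_reactions
    c = model.objective_vector()
    d = n - np.linalg.matrix_rank(model.S)
    best = None
    for fixed in itertools.combinations(range(n), d):
        free = [j for j in range(n) if j not in fixed]
        for choice in itertools.product(*[(model.lower_bound[j], model.upper_bound[j]) for j in fixed]):
            rhs = -model.S[:, list(fixed)] @ np.array(choice)
            A = model.S[:, free]
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.max(np.abs(A @ sol - rhs)) > 1e-8:
                continue
            v = np.zeros(n)
            v[list(fixed)] = choice
            v[free] = sol
            if np.all(v >= model.lower_bound - 1e-8) and np.all(v <= model.upper_bound + 1e-8):
                val = float(c @ v)
                if best is None or (val > best if sense == "max" else val < best):
                    best = val
    return best


class TestFBA:
    def test_bound_limited_chain(self, chain_world):
        sol = solve_fba(chain_world.model)
        assert sol.status == OPTIMAL
        assert sol.objective_value == pytest.approx(10.0)

    def test_closed_exchanges_zero_growth(self, chain_world):
        m = chain_world.model.copy()
        m.lower_bound[m.reaction_index("EX_glc_e")] = 0.0
        sol = solve_fba(m)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_mass_balance_of_optimum(self, respferm_world):
        m = respferm_world.model
        sol = solve_fba(m)
        v = sol.vector(m)
        assert np.max(np.abs(m.S @ v)) < 1e-6

    def test_against_vertex_enumeration_oracle(self):
        m = build_model(
            ["a", "b"],
            [
                ("up", {"a": 1}, 0.0, 7.0),
                ("r1", {"a": -1, "b": 1}, 0.0, 5.0),
                ("r2", {"a": -1, "b": 2}, 0.0, 3.0),
                ("out", {"b": -1}, 0.0, 100.0),
            ],
            {"out": 1.0},
        )
        sol = solve_fba(m)
        oracle = brute_force_vertex_optimum(m)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-8)

    def test_empty_objective_raises(self, chain_world):
        m = chain_world.model.copy()
        m.objective = {}
        with pytest.raises(ValueError):
            solve_fba(m)

    def test_agrees_with_cobrapy(self, respferm_world, tmp_path):
        cobra = pytest.importorskip("cobra")
        path = tmp_path / "m.json"
        save_model(respferm_world.model, path)
        cm = cobra.io.load_json_model(str(path))
        ours = solve_fba(respferm_world.model)
        theirs = cm.optimize()
        assert ours.objective_value == pytest.approx(theirs.objective_value, rel=1e-6)


class TestPFBA:
    def test_parallel_paths_take_the_short_route(self):
        # direct path vs a two-step detour: pFBA routes everything directly
        m = build_model(
            ["a", "b", "x"],
            [
                ("up", {"a": 1}, 0.0, 10.0),
                ("direct", {"a": -1, "b": 1}, 0.0, 100.0),
                ("det1", {"a": -1, "x": 1}, 0.0, 100.0),
                ("det2", {"x": -1, "b": 1}, 0.0, 100.0),
                ("out", {"b": -1}, 0.0, 100.0),
            ],
            {"out": 1.0},
        )
        sol = solve_pfba(m)
        assert sol.objective_value == pytest.approx(10.0)
        assert sol.values["direct"] == pytest.approx(10.0, abs=1e-6)
        assert sol.values["det1"] == pytest.approx(0.0, abs=1e-6)

    def test_growth_preserved_and_norm_reduced(self, respferm_world):
        fba = solve_fba(respferm_world.model)
        pfba = solve_pfba(respferm_world.model)
        assert abs(pfba.objective_value - fba.objective_value) < 1e-6
        total = lambda s: sum(abs(v) for v in s.values.values())
        assert total(pfba) <= total(fba) + 1e-6

    def test_unique_optimum_matches_fba(self, chain_world):
        fba = solve_fba(chain_world.model)
        pfba = solve_pfba(chain_world.model)
        for r in chain_world.model.reaction_ids:
            assert pfba.values[r] == pytest.approx(fba.values[r], abs=1e-6)


class TestEnvelope:
    def test_linear_tradeoff_endpoints(self, branched_world):
        m = branched_world.model
        env = production_envelope(m, "EX_c_e", 11)
        p0, g0min, g0max = env.grid[0]
        pN, gNmin, gNmax = env.grid[-1]
        assert (p0, g0max) == pytest.approx((0.0, 10.0), abs=1e-7)
        assert (pN, gNmax) == pytest.approx((10.0, 0.0), abs=1e-7)
        # interior: max growth decreases linearly with production
        for p, _gmin, gmax in env.grid:
            assert gmax == pytest.approx(10.0 - p, abs=1e-7)

    def test_two_points_only_extremes(self, branched_world):
        env = production_envelope(branched_world.model, "EX_c_e", 2)
        assert len(env.grid) == 2
        assert env.grid[0][0] == pytest.approx(0.0, abs=1e-9)
        assert env.grid[1][0] == pytest.approx(10.0, abs=1e-9)

    def test_growth_coupled_product(self):
        m = build_model(
            ["a", "b"],
            [
                ("up", {"a": 1}, 0.0, 10.0),
                ("bm", {"a": -1, "b": 1}, 0.0, 100.0),  # biomass co-produces b
                ("EX_b", {"b": -1}, 0.0, 100.0),
            ],
            {"bm": 1.0},
        )
        env = production_envelope(m, "EX_b", 5)
        p_max, g_min, _ = env.grid[-1]
        assert p_max == pytest.approx(10.0)
        assert g_min > 1e-6  # product coupled to growth

    def test_envelope_nesting_of_submodel(self, respferm_world):
        parent = respferm_world.model.copy()
        parent.lower_bound[parent.reaction_index("EX_glc_e")] = -10.0
        sub = parent.copy()
        j = sub.reaction_index("RESP")
        sub.lower_bound[j] = sub.upper_bound[j] = 0.0
        env = production_envelope(sub, "EX_ac_e", 6)
        for p, gmin, gmax in env.grid:
            work = parent.copy()
            k = work.reaction_index("EX_ac_e")
            work.lower_bound[k] = work.upper_bound[k] = p
            lo = solve_fba(work, sense="min")
            hi = solve_fba(work, sense="max")
            assert lo.objective_value <= gmin + 1e-6
            assert hi.objective_value >= gmax - 1e-6

    def test_bad_point_count(self, branched_world):
        with pytest.raises(ValueError):
            production_envelope(branched_world.model, "EX_c_e", 1)


class TestCondition:
    def test_anaerobic_blocks_oxygen_and_sets_maintenance(self, respferm_world):
        m = set_condition(
            respferm_world.model, "EX_glc_e", 10.0, aerobic=False,
            maintenance_bound=6.86, oxygen_exchange="EX_o2_e",
            maintenance_reaction="ATPM",
        )
        assert m.lower_bound[m.reaction_index("EX_glc_e")] == -10.0
        assert m.lower_bound[m.reaction_index("EX_o2_e")] == 0.0
        assert m.lower_bound[m.reaction_index("ATPM")] == 6.86

    def test_zero_uptake_zero_growth(self, chain_world):
        m = set_condition(
            chain_world.model, "EX_glc_e", 0.0, aerobic=True,
            maintenance_bound=0.0, oxygen_exchange=None, maintenance_reaction=None,
        )
        assert solve_fba(m).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_idempotent(self, respferm_world):
        kw = dict(carbon_exchange="EX_glc_e", uptake_bound=10.0, aerobic=False,
                  maintenance_bound=2.0, oxygen_exchange="EX_o2_e",
                  maintenance_reaction="ATPM")
        m1 = set_condition(respferm_world.model, **kw)
        m2 = set_condition(m1, **kw)
        assert np.array_equal(m1.lower_bound, m2.lower_bound)
        assert np.array_equal(m1.upper_bound, m2.upper_bound)

    def test_unknown_exchange_raises(self, chain_world):
        with pytest.raises(KeyError):
            set_condition(chain_world.model, "EX_nope", 10.0, True, 0.0,
                          oxygen_exchange=None, maintenance_reaction=None)


class TestIO:
    @pytest.mark.parametrize("fmt", ["json", "sbml"])
    def test_round_trip_preserves_stoichiometry(self, respferm_world, tmp_path, fmt):
        ext = "json" if fmt == "json" else "xml"
        path = tmp_path / f"m.{ext}"
        save_model(respferm_world.model, path)
        back = load_model(path)
        orig = respferm_world.model
        assert back.reaction_ids == orig.reaction_ids
        assert back.metabolite_ids == orig.metabolite_ids
        assert np.allclose(back.S, orig.S)
        assert np.allclose(back.lower_bound, orig.lower_bound)
        assert np.allclose(back.upper_bound, orig.upper_bound)
        assert back.objective == orig.objective

    def test_zero_stoichiometry_reaction_rejected(self, tmp_path):
        import json

        doc = {
            "metabolites": [{"id": "a_c", "compartment": "c"}],
            "reactions": [
                {"id": "empty", "metabolites": {}, "lower_bound": 0,
                 "upper_bound": 10, "gene_reaction_rule": ""},
            ],
            "genes": [],
            "id": "bad",
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError):
            load_model(path)

    def test_parse_failure_is_format_error(self, tmp_path):
        from cbmkit import FormatError

        path = tmp_path / "junk.json"
        path.write_text("{not json")
        with pytest.raises(FormatError):
            load_model(path)


class TestLumping:
    def test_single_path_bookkeeping(self):
        m = build_model(
            ["prec", "p"],
            [
                ("SRC", {"prec": 1}, 0.0, 10.0),
                ("PS", {"prec": -1, "p": 1}, 0.0, 100.0),
                ("BM", {"p": -2}, 0.0, 100.0),
            ],
            {"BM": 1.0},
        )
        ref = solve_fba(m)
        lump = lump_equivalent_biomass(m, ref, {"prec"})
        assert lump.stoichiometry == pytest.approx({"prec": -2.0})

    def test_retain_all_recovers_biomass_reaction(self, respferm_world):
        m = respferm_world.model
        ref = solve_pfba(m)
        lump = lump_equivalent_biomass(m, ref, set(m.metabolite_ids))
        j = m.reaction_index("BIOMASS")
        expected = {
            met: m.S[i, j] for i, met in enumerate(m.metabolite_ids) if m.S[i, j]
        }
        assert lump.stoichiometry == pytest.approx(expected)

    def test_two_pathway_reduction_preserves_growth(self):
        extended = build_model(
            ["x_e", "x_c", "p"],
            [
                ("EX_x", {"x_e": -1}, -10.0, 100.0),
                ("T", {"x_e": -1, "x_c": 1}, 0.0, 100.0),
                ("R1", {"x_c": -1, "p": 1}, 0.0, 100.0),
                ("R2", {"x_c": -1, "p": 2}, 0.0, 100.0),
                ("BM", {"p": -2}, 0.0, 100.0),
            ],
            {"BM": 1.0},
        )
        ref = solve_pfba(extended)
        lump = lump_equivalent_biomass(extended, ref, {"x_e", "x_c"})
        reduced = build_model(
            ["x_e", "x_c"],
            [
                ("EX_x", {"x_e": -1}, -10.0, 100.0),
                ("T", {"x_e": -1, "x_c": 1}, 0.0, 100.0),
                ("BM_eq", dict(lump.stoichiometry), 0.0, 100.0),
            ],
            {"BM_eq": 1.0},
        )
        g_red = solve_fba(reduced).objective_value
        assert g_red == pytest.approx(ref.objective_value, abs=1e-6)

    def test_zero_biomass_reference_rejected(self):
        m = build_model(
            ["prec", "p"],
            [
                ("SRC", {"prec": 1}, 0.0, 10.0),
                ("PS", {"prec": -1, "p": 1}, 0.0, 100.0),
                ("BM", {"p": -2}, 0.0, 100.0),
            ],
            {"BM": 1.0},
        )
        zero = FluxDistribution({r: 0.0 for r in m.reaction_ids}, 0.0, OPTIMAL)
        with pytest.raises(ValueError):
            lump_equivalent_biomass(m, zero, {"prec"})

    def test_unbalanced_reference_rejected(self):
        m = build_model(
            ["prec", "p"],
            [
                ("SRC", {"prec": 1}, 0.0, 10.0),
                ("PS", {"prec": -1, "p": 1}, 0.0, 100.0),
                ("BM", {"p": -2}, 0.0, 100.0),
            ],
            {"BM": 1.0},
        )
        bad = FluxDistribution({"SRC": 5.0, "PS": 1.0, "BM": 1.0}, 1.0, OPTIMAL)
        with pytest.raises(ValueError):
            lump_equivalent_biomass(m, bad, {"prec"})
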