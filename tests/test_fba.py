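import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemflux import toys
from gemflux.errors import InfeasibleModelError, ValidationError
from gemflux.fba import (
    SOLVERS,
    FluxSolution,
    block,
    fba,
    flux_spearman,
    fva,
    mass_balance_residual,
)
from gemflux.model import Reaction

from conftest import build_model


class TestFba:
    def test_toy_a_optimum(self, toy_a):
        model, _ = toy_a
        sol = fba(model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)

    def test_blocked_uptake_kills_growth(self, toy_a):
        model, _ = toy_a
        sol = fba(block(model, {"EX_A"}))
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_mass_balance_on_every_solve(self, toy_a, toy_d, toy_o2):
        for model, _ in (toy_a, toy_d, toy_o2):
            for tie in ("none", "parsimonious"):
                sol = fba(model, tie_break=tie)
                assert mass_balance_residual(model, sol) < 1e-6

    def test_fluxes_within_bounds(self, toy_o2):
        model, _ = toy_o2
        sol = fba(model, tie_break="parsimonious")
        for rxn in model.reactions:
            v = sol.fluxes[rxn.id]
            assert rxn.lower_bound - 1e-6 <= v <= rxn.upper_bound + 1e-6

    def test_infeasible_status(self):
        model = build_model(
            "stuck",
            [
                Reaction("FORCE", {"A_c": 1.0}, 5, 10),  # must produce A
                Reaction("BIOMASS", {"A_c": -1.0}, 0, 1),  # cannot drain enough
            ],
        )
        sol = fba(model)
        assert sol.status == "infeasible"
        assert sol.objective_value is None

    def test_unbounded_status(self):
        model = build_model(
            "free",
            [
                Reaction("IN", {"A_c": 1.0}, -np.inf, np.inf),
                Reaction("BIOMASS", {"A_c": -1.0}, 0, np.inf),
            ],
        )
        assert fba(model).status == "unbounded"

    def test_unknown_objective_rejected(self, toy_a):
        model, _ = toy_a
        with pytest.raises(ValidationError):
            fba(model, objective_id="NOPE")

    def test_parsimonious_prefers_short_path(self, toy_b):
        model, _ = toy_b
        sol = fba(model, tie_break="parsimonious")
        assert sol.fluxes["R1"] == pytest.approx(10.0, abs=1e-6)
        assert sol.fluxes["R2"] == pytest.approx(0.0, abs=1e-6)
        assert sol.fluxes["R3"] == pytest.approx(0.0, abs=1e-6)

    def test_parsimonious_deterministic(self, toy_a):
        model, _ = toy_a
        a = fba(model, tie_break="parsimonious")
        b = fba(model, tie_break="parsimonious")
        for rid in a.fluxes:
            assert a.fluxes[rid] == pytest.approx(b.fluxes[rid], abs=1e-6)

    @pytest.mark.parametrize("solver", SOLVERS)
    def test_solvers_agree(self, solver, toy_o2):
        model, _ = toy_o2
        sol = fba(model, solver=solver)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(
        st.sampled_from(["EX_A", "T_A", "R1", "R2", "R3"]),
        st.floats(min_value=0.0, max_value=10.0, allow_nan=False),
    )
    def test_tightening_never_increases_optimum(self, rid, cap):
        # monotonicity: shrinking any reaction's flux window cannot help
        model, _ = toys.make_fixture("TOY-A")
        base = fba(model).objective_value
        tightened = model.copy()
        rxn = tightened.reaction(rid)
        rxn.upper_bound = min(rxn.upper_bound, cap)
        rxn.lower_bound = max(rxn.lower_bound, -cap)
        sol = fba(tightened)
        tightened_opt = sol.objective_value if sol.optimal else 0.0
        assert tightened_opt <= base + 1e-6


class TestFva:
    def test_parallel_paths_interchange(self, toy_a):
        model, _ = toy_a
        ranges = fva(model, fraction=1.0)
        assert ranges["R1"] == (pytest.approx(0.0, abs=1e-6), pytest.approx(10.0, abs=1e-6))
        assert ranges["R2"] == (pytest.approx(0.0, abs=1e-6), pytest.approx(10.0, abs=1e-6))

    def test_objective_pinned_at_optimum(self, toy_a):
        model, _ = toy_a
        ranges = fva(model, fraction=1.0, reaction_ids=["BIOMASS"])
        lo, hi = ranges["BIOMASS"]
        assert lo == pytest.approx(10.0, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-6)

    def test_unique_path_forces_flux(self, toy_a):
        model, _ = toy_a
        ranges = fva(block(model, {"R2"}), fraction=1.0, reaction_ids=["R1"])
        lo, hi = ranges["R1"]
        assert lo == pytest.approx(10.0, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-6)

    def test_min_leq_max_everywhere(self, toy_o2):
        model, _ = toy_o2
        for lo, hi in fva(model, fraction=0.9).values():
            assert lo <= hi + 1e-9

    def test_contains_parsimonious_flux(self, toy_a, toy_d):
        for model, _ in (toy_a, toy_d):
            sol = fba(model, tie_break="parsimonious")
            ranges = fva(model, fraction=1.0)
            for rid, (lo, hi) in ranges.items():
                assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6

    def test_lower_fraction_nests(self, toy_a):
        model, _ = toy_a
        tight = fva(model, fraction=1.0)
        loose = fva(model, fraction=0.9)
        for rid in tight:
            assert loose[rid][0] <= tight[rid][0] + 1e-6
            assert loose[rid][1] >= tight[rid][1] - 1e-6

    def test_bad_fraction_rejected(self, toy_a):
        model, _ = toy_a
        with pytest.raises(ValidationError):
            fva(model, fraction=1.5)

    def test_infeasible_model_raises(self, toy_a):
        model, _ = toy_a
        dead = model.copy()
        dead.reaction("BIOMASS").lower_bound = 50.0  # unreachable demand
        with pytest.raises(InfeasibleModelError):
            fva(dead, fraction=1.0)

    @pytest.mark.parametrize("solver", SOLVERS)
    def test_solver_independent(self, solver, toy_a):
        model, _ = toy_a
        ranges = fva(model, fraction=0.9, solver=solver)
        assert ranges["BIOMASS"][0] == pytest.approx(9.0, abs=1e-6)
        assert ranges["BIOMASS"][1] == pytest.approx(10.0, abs=1e-6)


class TestBlock:
    def test_full_zeroes_both_bounds(self, toy_a):
        model, _ = toy_a
        out = block(model, {"R1"})
        assert out.reaction("R1").lower_bound == 0.0
        assert out.reaction("R1").upper_bound == 0.0

    def test_uptake_only_keeps_secretion(self, toy_a):
        model, _ = toy_a
        out = block(model, {"EX_A"}, mode="uptake_only")
        assert out.reaction("EX_A").lower_bound == 0.0
        assert out.reaction("EX_A").upper_bound == 1000.0
        assert fba(out).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_empty_block_is_identity(self, toy_a):
        model, _ = toy_a
        out = block(model, set())
        assert fba(out).objective_value == pytest.approx(10.0, abs=1e-6)

    def test_uptake_only_on_internal_reaction_rejected(self, toy_a):
        model, _ = toy_a
        with pytest.raises(ValidationError):
            block(model, {"R1"}, mode="uptake_only")

    def test_original_model_untouched(self, toy_a):
        model, _ = toy_a
        block(model, {"R1"})
        assert model.reaction("R1").upper_bound == 1000.0


class TestSpearman:
    def _sol(self, fluxes):
        return FluxSolution("optimal", 1.0, fluxes)

    def test_identical_solutions(self):
        fluxes = {"a": 1.0, "b": 2.0, "c": -3.0, "d": 0.5}
        rho, n = flux_spearman(self._sol(fluxes), self._sol(dict(fluxes)))
        assert rho == pytest.approx(1.0)
        assert n == 4

    def test_negated_solution(self):
        fluxes = {"a": 1.0, "b": 2.0, "c": -3.0, "d": 0.5}
        neg = {k: -v for k, v in fluxes.items()}
        rho, n = flux_spearman(self._sol(fluxes), self._sol(neg))
        assert rho == pytest.approx(-1.0)
        assert n == 4

    def test_null_fluxes_excluded(self):
        a = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 0.0}
        b = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 5.0}
        _, n = flux_spearman(self._sol(a), self._sol(b))
        assert n == 3

    def test_too_few_shared_raises(self):
        with pytest.raises(ValidationError):
            flux_spearman(self._sol({"a": 1.0, "b": 2.0}), self._sol({"a": 1.0, "b": 2.0}))

    def test_non_optimal_rejected(self):
        bad = FluxSolution("infeasible", None, {})
        with pytest.raises(ValidationError):
            flux_spearman(bad, bad)
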