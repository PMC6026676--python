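import numpy as np
import pytest

from gemflux.errors import InfeasibleModelError, ValidationError
from gemflux.model import MediumSpec
from gemflux.secretion import (
    build_interaction_matrix,
    classify_interaction,
    growth_coupled_exchange,
    max_growth,
    profile,
)

MEDIUM_A = MediumSpec(uptakes={"EX_A": 10.0})


class TestMaxGrowth:
    def test_toy_d_optimum(self, toy_d):
        model, _ = toy_d
        assert max_growth(model, MEDIUM_A) == pytest.approx(10.0, abs=1e-6)

    def test_empty_medium_raises(self, toy_d):
        model, _ = toy_d
        dead = model.copy()
        dead.reaction("BIOMASS").lower_bound = 1.0  # growth demanded, no food
        with pytest.raises(InfeasibleModelError, match="medium insufficient"):
            max_growth(dead, MediumSpec(uptakes={}))

    def test_anaerobic_medium_closes_oxygen(self, toy_o2):
        model, _ = toy_o2
        medium = MediumSpec(
            uptakes={"EX_A": 10, "EX_O2": 10, "EX_Fe2": 10, "EX_Fe3": 10},
            anaerobic=True,
        )
        # still grows: ferric iron is taken up directly
        assert max_growth(model, medium) == pytest.approx(10.0, abs=1e-6)


class TestGrowthCoupledExchange:
    def test_byproduct_fully_coupled_at_max_growth(self, toy_d):
        model, _ = toy_d
        production, consumption = growth_coupled_exchange(model, MEDIUM_A, 10.0, "EX_P")
        assert production == pytest.approx(10.0, abs=1e-6)
        assert consumption == pytest.approx(0.0, abs=1e-6)

    def test_substrate_uptake_saturated(self, toy_d):
        model, _ = toy_d
        production, consumption = growth_coupled_exchange(model, MEDIUM_A, 10.0, "EX_A")
        assert production == pytest.approx(0.0, abs=1e-6)
        assert consumption == pytest.approx(10.0, abs=1e-6)

    def test_zero_mu_fix_relaxes_to_unconstrained(self, toy_d):
        model, _ = toy_d
        production, _ = growth_coupled_exchange(model, MEDIUM_A, 0.0, "EX_P")
        assert production == pytest.approx(10.0, abs=1e-6)

    def test_envelope_non_increasing_in_mu_fix(self, toy_d):
        model, _ = toy_d
        grid = np.linspace(0.0, 10.0, 5)
        prods, cons = [], []
        for mu in grid:
            p, c = growth_coupled_exchange(model, MEDIUM_A, mu, "EX_P")
            prods.append(p)
            cons.append(c)
        assert all(a >= b - 1e-9 for a, b in zip(prods, prods[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(cons, cons[1:]))

    def test_non_exchange_rejected(self, toy_d):
        model, _ = toy_d
        with pytest.raises(ValidationError):
            growth_coupled_exchange(model, MEDIUM_A, 1.0, "R1")

    def test_infeasible_mu_raises(self, toy_d):
        model, _ = toy_d
        with pytest.raises(InfeasibleModelError):
            growth_coupled_exchange(model, MEDIUM_A, 50.0, "EX_P")


class TestProfile:
    def test_toy_d_roles(self, toy_d):
        model, _ = toy_d
        prof = profile(model, MEDIUM_A, organism="org1")
        frame = prof.to_frame().set_index("exchange_id")
        assert frame.loc["EX_P", "role"] == "producer"
        assert frame.loc["EX_A", "role"] == "consumer"
        assert prof.producers() == {"P_e"}
        assert prof.consumers() == {"A_e"}

    def test_anaerobic_never_consumes_oxygen(self, toy_o2):
        model, _ = toy_o2
        medium = MediumSpec(
            uptakes={"EX_A": 10, "EX_O2": 10, "EX_Fe2": 10, "EX_Fe3": 10},
            anaerobic=True,
        )
        prof = profile(model, medium)
        frame = prof.to_frame().set_index("exchange_id")
        assert frame.loc["EX_O2", "max_consumption"] == pytest.approx(0.0, abs=1e-9)
        assert prof.regime == "anaerobic"

    def test_inert_metabolite(self, toy_o2):
        # ferric iron neither forced nor producible when only Fe2/O2 route used
        model, _ = toy_o2
        medium = MediumSpec(uptakes={"EX_A": 10, "EX_O2": 10, "EX_Fe2": 10, "EX_Fe3": 10})
        prof = profile(model, medium)
        frame = prof.to_frame().set_index("exchange_id")
        for rid in frame.index:
            p = frame.loc[rid, "max_production"]
            c = frame.loc[rid, "max_consumption"]
            if frame.loc[rid, "role"] == "inert":
                assert p < 1e-6 and c < 1e-6


class TestInteractionMatrix:
    def test_commensal_pair(self, toy_d, p_consumer):
        model, _ = toy_d
        prod = profile(model, MEDIUM_A, organism="maker")
        cons = profile(p_consumer, MediumSpec(uptakes={"EX_P": 10.0}), organism="eater")
        matrix = build_interaction_matrix([prod, cons])
        assert matrix.entries["P_e"]["classification"] == "commensal"
        assert matrix.entries["P_e"]["producers"] == {"maker"}
        assert matrix.entries["P_e"]["consumers"] == {"eater"}

    def test_competitive_metabolite(self, toy_d):
        model, _ = toy_d
        a = profile(model, MEDIUM_A, organism="org_a")
        b = profile(model, MEDIUM_A, organism="org_b")
        matrix = build_interaction_matrix([a, b])
        assert matrix.entries["A_e"]["classification"] == "competitive"
        assert matrix.entries["P_e"]["classification"] == "shared-production"

    def test_permutation_invariance(self, toy_d, p_consumer):
        model, _ = toy_d
        prod = profile(model, MEDIUM_A, organism="maker")
        cons = profile(p_consumer, MediumSpec(uptakes={"EX_P": 10.0}), organism="eater")
        m1 = build_interaction_matrix([prod, cons])
        m2 = build_interaction_matrix([cons, prod])
        assert {k: v["classification"] for k, v in m1.entries.items()} == {
            k: v["classification"] for k, v in m2.entries.items()
        }

    def test_single_profile_rejected(self, toy_d):
        model, _ = toy_d
        with pytest.raises(ValidationError):
            build_interaction_matrix([profile(model, MEDIUM_A)])

    def test_mixed_regimes_rejected(self, toy_d):
        model, _ = toy_d
        aero = profile(model, MEDIUM_A, organism="a")
        anaero = profile(model, MediumSpec(uptakes={"EX_A": 10.0}, anaerobic=True), organism="b")
        with pytest.raises(ValidationError, match="regime"):
            build_interaction_matrix([aero, anaero])

    def test_code_matrix(self, toy_d, p_consumer):
        model, _ = toy_d
        prod = profile(model, MEDIUM_A, organism="maker")
        cons = profile(p_consumer, MediumSpec(uptakes={"EX_P": 10.0}), organism="eater")
        codes = build_interaction_matrix([prod, cons]).code_matrix(["maker", "eater"])
        assert codes.loc["P_e", "maker"] == "P"
        assert codes.loc["P_e", "eater"] == "C"

    @pytest.mark.parametrize(
        "producers,consumers,expected",
        [
            ({"a"}, {"b"}, "commensal"),
            ({"a"}, {"a", "b"}, "commensal"),
            (set(), {"a", "b"}, "competitive"),
            ({"a", "b"}, set(), "shared-production"),
            ({"a"}, {"a"}, "none"),
            (set(), set(), "none"),
        ],
    )
    def test_classification_rules(self, producers, consumers, expected):
        assert classify_interaction(producers, consumers) == expected
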