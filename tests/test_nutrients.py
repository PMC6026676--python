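import pytest

from gemflux.errors import ValidationError
from gemflux.model import Reaction
from gemflux.nutrients import base_state, growth_rate_table, search_combos

from conftest import build_model


def _grown(results):
    return {r.combo for r in results if r.grows}


class TestBaseState:
    def test_blocks_all_nonessential_uptakes(self, toy_c):
        model, _ = toy_c
        state = base_state(model, set())
        assert state.base_growth == pytest.approx(0.0, abs=1e-9)
        assert not state.vacuous
        for rid in ("EX_A", "EX_B", "EX_N"):
            assert state.model.reaction(rid).lower_bound == 0.0
            # secretion stays open
            assert state.model.reaction(rid).upper_bound == 1000.0

    def test_essential_exchanges_untouched(self, toy_o2):
        model, _ = toy_o2
        state = base_state(model, {"EX_Fe2"})
        assert state.model.reaction("EX_Fe2").lower_bound == -10.0
        assert "EX_Fe2" not in state.original_lower

    def test_vacuous_when_essentials_sustain_growth(self, toy_a):
        model, _ = toy_a
        state = base_state(model, {"EX_A"})  # the only exchange stays open
        assert state.vacuous
        assert state.base_growth == pytest.approx(10.0, abs=1e-6)

    def test_non_exchange_id_rejected(self, toy_c):
        model, _ = toy_c
        with pytest.raises(ValidationError):
            base_state(model, {"R1"})


class TestSearchCombos:
    def test_no_single_combo_grows(self, toy_c):
        model, _ = toy_c
        results = search_combos(base_state(model, set()), k_max=1)
        assert _grown(results) == set()

    def test_unique_minimal_pair(self, toy_c):
        model, truth = toy_c
        results = search_combos(base_state(model, set()), k_max=2)
        grown = _grown(results)
        assert grown == {frozenset(("EX_A", "EX_B"))}
        winner = next(r for r in results if r.grows)
        assert winner.growth == pytest.approx(10.0, abs=1e-6)
        assert winner.minimal
        assert grown == truth.minimal_combos

    def test_superset_monotonicity(self, toy_c):
        model, _ = toy_c
        results = {r.combo: r for r in search_combos(base_state(model, set()), k_max=3)}
        for combo, res in results.items():
            for other, other_res in results.items():
                if combo < other:
                    assert other_res.growth >= res.growth - 1e-9

    def test_nonminimal_supersets_retained_and_flagged(self, toy_c):
        model, _ = toy_c
        results = {r.combo: r for r in search_combos(base_state(model, set()), k_max=3)}
        sup = results[frozenset(("EX_A", "EX_B", "EX_N"))]
        assert sup.grows and not sup.minimal

    def test_enumeration_is_exhaustive(self, toy_c):
        model, _ = toy_c
        results = search_combos(base_state(model, set()), k_max=3)
        # C(3,1) + C(3,2) + C(3,3)
        assert len(results) == 3 + 3 + 1

    def test_grows_flag_flips_exactly_at_threshold(self):
        # tuned fixture: uptake bound set so max growth equals the threshold
        def tuned(bound):
            model = build_model(
                "tuned",
                [
                    Reaction("EX_A", {"A_e": -1.0}, -bound, 1000.0),
                    Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0),
                    Reaction("BIOMASS", {"A_c": -1.0}, 0.0, 1000.0),
                ],
            )
            state = base_state(model, set())
            (res,) = search_combos(state, k_max=1)
            return res

        assert tuned(1e-5).grows  # growth == threshold counts as growth
        assert tuned(2e-5).grows
        assert not tuned(0.5e-5).grows

    def test_combo_cap_enforced(self, toy_c):
        model, _ = toy_c
        with pytest.raises(ValidationError, match="cap"):
            search_combos(base_state(model, set()), k_max=3, combo_cap=2)

    def test_bad_k_rejected(self, toy_c):
        model, _ = toy_c
        with pytest.raises(ValidationError):
            search_combos(base_state(model, set()), k_max=4)


class TestRegimes:
    def test_anaerobic_forces_oxygen_closed(self, toy_o2):
        model, _ = toy_o2
        # essential exchanges open (EX_Fe2); EX_A, EX_O2, EX_Fe3 closed
        state = base_state(model, {"EX_Fe2"})
        results = search_combos(state, k_max=2, regime="anaerobic")
        grown = _grown(results)
        # without O2, iron oxidation is dead: need EX_A AND EX_Fe3
        assert grown == {frozenset(("EX_A", "EX_Fe3"))}

    def test_aerobic_opens_oxygen_at_model_bounds(self, toy_o2):
        model, _ = toy_o2
        state = base_state(model, {"EX_Fe2"})
        results = search_combos(state, k_max=1, regime="aerobic")
        grown = _grown(results)
        # with O2 open, ferric iron comes from oxidation: EX_A alone suffices
        assert grown == {frozenset(("EX_A",))}

    def test_unknown_regime_rejected(self, toy_c):
        model, _ = toy_c
        with pytest.raises(ValidationError):
            search_combos(base_state(model, set()), regime="microaerophilic")


class TestGrowthRateTable:
    def _results(self, toy_o2):
        model, _ = toy_o2
        state = base_state(model, {"EX_Fe2"})
        out = []
        for regime in ("aerobic", "anaerobic"):
            out += search_combos(state, k_max=2, regime=regime)
        return out

    def test_one_row_per_partner_pair(self, toy_o2):
        df = growth_rate_table(self._results(toy_o2), partner_ids={"EX_Fe3"})
        # pairs containing exactly one partner: (EX_A, EX_Fe3) per regime
        assert set(df.nutrient) == {"EX_A"}
        assert set(df.regime) == {"aerobic", "anaerobic"}

    def test_regime_indifferent_flag(self, toy_o2):
        # EX_A + EX_Fe3 gives the same growth with or without oxygen
        df = growth_rate_table(self._results(toy_o2), partner_ids={"EX_Fe3"})
        assert df.regime_indifferent.all()
        assert not df.aerobic_only.any()

    def test_non_growing_rows_retained(self, toy_c):
        model, _ = toy_c
        state = base_state(model, set())
        results = search_combos(state, k_max=2)
        df = growth_rate_table(results, partner_ids={"EX_N"})
        assert not df.empty
        assert not df.grows.any()

    def test_empty_input(self):
        df = growth_rate_table([])
        assert df.empty
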