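"""Minimal-sufficient-nutrient search.

Starting from a base state where every non-essential exchange has its uptake
closed (essential exchanges left untouched so growth failure is never caused
by missing obligate nutrients), combinations of 1..k non-essential uptakes
are re-opened and growth re-evaluated. Re-opening restores each exchange's
original lower bound, preserving per-nutrient uptake limits of the source
model. Growth counts from a biomass flux of 1e-5 upward.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import pandas as pd

from .errors import ValidationError
from .fba import fba
from .lethality import GROWTH_THRESHOLD
from .model import MetabolicModel, detect_exchanges, oxygen_exchange_ids


@dataclass
class BaseState:
    """Uptake-closed model plus the bookkeeping needed to re-open uptakes."""

    model: MetabolicModel
    original_lower: Dict[str, float]
    essential_exchanges: Set[str]
    nonessential_exchanges: List[str]  # sorted, enumeration order
    base_growth: float
    vacuous: bool  # essential exchanges alone already sustain growth


@dataclass
class NutrientComboResult:
    combo: FrozenSet[str]
    growth: float
    grows: bool
    regime: str
    k: int
    minimal: bool = False

    def sorted_members(self) -> Tuple[str, ...]:
        return tuple(sorted(self.combo))


def base_state(
    model: MetabolicModel,
    singles_exchange: Iterable[str],
    growth_threshold: float = GROWTH_THRESHOLD,
    solver: str = "highs",
) -> BaseState:
    """Close uptake of every non-essential exchange; keep essentials open."""
    exchanges = detect_exchanges(model)
    essential = set(singles_exchange)
    bad = essential - exchanges
    if bad:
        raise ValidationError(
            f"singles_exchange entries are not exchange reactions: {sorted(bad)}"
        )
    nonessential = sorted(exchanges - essential)
    out = model.copy()
    original_lower = {}
    for rid in nonessential:
        rxn = out.reaction(rid)
        original_lower[rid] = rxn.lower_bound
        rxn.lower_bound = max(0.0, rxn.lower_bound)
    sol = fba(out, solver=solver)
    base_growth = sol.objective_value if sol.optimal else 0.0
    return BaseState(
        model=out,
        original_lower=original_lower,
        essential_exchanges=essential,
        nonessential_exchanges=nonessential,
        base_growth=base_growth,
        vacuous=base_growth >= growth_threshold,
    )


def _apply_regime(model: MetabolicModel, regime: str) -> None:
    oxy = oxygen_exchange_ids(model)
    if regime == "anaerobic":
        for rid in oxy:
            rxn = model.reaction(rid)
            rxn.lower_bound = max(0.0, rxn.lower_bound)
    elif regime != "aerobic":
        raise ValidationError(f"unknown regime {regime!r}")


def search_combos(
    state: BaseState,
    k_max: int = 2,
    regime: str = "anaerobic",
    growth_threshold: float = GROWTH_THRESHOLD,
    combo_cap: int = 200_000,
    solver: str = "highs",
) -> List[NutrientComboResult]:
    """Enumerate all 1..k_max-subsets of closed non-essential uptakes.

    Under the aerobic regime the oxygen exchange is restored to its original
    model bounds before enumeration; under the anaerobic regime oxygen uptake
    is forced closed. Oxygen exchanges are therefore not themselves
    enumerated as combo members. Results are sorted by (k, growth desc, id).
    """
    if not (1 <= k_max <= 3):
        raise ValidationError(f"k_max must be in 1..3, got {k_max}")
    base = state.model.copy()
    oxy = set(oxygen_exchange_ids(base))
    if regime == "aerobic":
        for rid in oxy & set(state.original_lower):
            base.reaction(rid).lower_bound = state.original_lower[rid]
    else:
        _apply_regime(base, regime)
    candidates = [r for r in state.nonessential_exchanges if r not in oxy]

    n_combos = sum(
        len(list(itertools.combinations(range(len(candidates)), k)))
        for k in range(1, k_max + 1)
    )
    if n_combos > combo_cap:
        raise ValidationError(
            f"{n_combos} combinations exceed the cap ({combo_cap}); "
            "pre-filter the candidate exchanges or raise combo_cap"
        )

    results: List[NutrientComboResult] = []
    growing: List[FrozenSet[str]] = []
    for k in range(1, k_max + 1):
        for combo in itertools.combinations(candidates, k):
            trial = base.copy()
            for rid in combo:
                trial.reaction(rid).lower_bound = state.original_lower[rid]
            if regime == "anaerobic":
                _apply_regime(trial, regime)
            sol = fba(trial, solver=solver)
            growth = sol.objective_value if sol.optimal else 0.0
            fs = frozenset(combo)
            grows = growth >= growth_threshold
            results.append(
                NutrientComboResult(
                    combo=fs, growth=growth, grows=grows, regime=regime, k=k
                )
            )
            if grows:
                growing.append(fs)

    growing_set = set(growing)
    for res in results:
        if res.grows:
            res.minimal = not any(
                sub != res.combo and sub < res.combo for sub in growing_set
            )
    results.sort(key=lambda r: (r.k, -r.growth, tuple(sorted(r.combo))))
    return results


def growth_rate_table(
    results: Iterable[NutrientComboResult],
    partner_ids: Optional[Set[str]] = None,
    partner_patterns: Tuple[str, ...] = ("o2", "fe"),
) -> pd.DataFrame:
    """Per-nutrient growth achieved alongside a designated partner exchange.

    Pairs containing exactly one partner exchange (by explicit id set, or by
    id substring pattern, e.g. oxygen or iron exchanges) contribute one row:
    the non-partner member is the nutrient. Non-growing rows are retained.
    Flags: ``aerobic_only`` (grows aerobically, not anaerobically) and
    ``regime_indifferent`` (grows in both regimes at the same rate to 1e-6).
    """
    def is_partner(rid: str) -> bool:
        if partner_ids is not None:
            return rid in partner_ids
        low = rid.lower()
        return any(p in low for p in partner_patterns)

    rows = []
    for res in results:
        members = res.sorted_members()
        partners = [m for m in members if is_partner(m)]
        if res.k == 2 and len(partners) == 1:
            nutrient = next(m for m in members if m != partners[0])
            rows.append(
                {
                    "nutrient": nutrient,
                    "partner": partners[0],
                    "regime": res.regime,
                    "growth": res.growth,
                    "grows": res.grows,
                }
            )
    df = pd.DataFrame(rows, columns=["nutrient", "partner", "regime", "growth", "grows"])
    if df.empty:
        df["aerobic_only"] = pd.Series(dtype=bool)
        df["regime_indifferent"] = pd.Series(dtype=bool)
        return df

    by_nutrient = df.groupby("nutrient")
    flags = {}
    for nutrient, sub in by_nutrient:
        aero = sub[sub.regime == "aerobic"]
        anaero = sub[sub.regime == "anaerobic"]
        grows_aero = bool(aero.grows.any())
        grows_anaero = bool(anaero.grows.any())
        indifferent = False
        if grows_aero and grows_anaero:
            indifferent = abs(aero.growth.max() - anaero.growth.max()) < 1e-6
        flags[nutrient] = (grows_aero and not grows_anaero, indifferent)
    df["aerobic_only"] = df.nutrient.map(lambda n: flags[n][0])
    df["regime_indifferent"] = df.nutrient.map(lambda n: flags[n][1])
    return df.sort_values(["nutrient", "regime"]).reset_index(drop=True)
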