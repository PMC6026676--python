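"""Synthetic lethality: single-lethal reactions and double-lethal pairs.

Single lethals are found by exhaustive one-at-a-time full blocking (both
bounds to zero). Double lethals use a pruned pair search in the style of
Fast-SL: a pair (i, j) can only be lethal if j carries flux in every
above-threshold solution of the i-blocked model, so the support of one
parsimonious optimum of the i-blocked model is a valid candidate superset.
The pruning is exact -- results must (and do, see the test oracle) equal
brute-force enumeration over all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Set, Tuple

from .errors import InfeasibleModelError, ValidationError
from .fba import block, fba
from .model import MetabolicModel, detect_exchanges, oxygen_exchange_ids

#: biomass flux below this counts as "no growth".
GROWTH_THRESHOLD = 1e-5


@dataclass
class LethalityResult:
    single_lethals: Set[str]
    double_lethals: Set[FrozenSet[str]]
    wild_type_growth: float
    exchange_single_lethals: Set[str] = field(default_factory=set)
    pairs_with_exchange: Set[FrozenSet[str]] = field(default_factory=set)
    pairs_two_exchanges: Set[FrozenSet[str]] = field(default_factory=set)
    n_conditions_tested: int = 0

    def sorted_pairs(self) -> List[Tuple[str, str]]:
        """Pairs canonicalized to lexicographic order, globally sorted."""
        return sorted(tuple(sorted(p)) for p in self.double_lethals)


def _growth(model: MetabolicModel, solver: str) -> float:
    sol = fba(model, solver=solver)
    return sol.objective_value if sol.optimal else 0.0


def _cutoff(wild_type: float, threshold: float, cutoff_mode: str) -> float:
    if cutoff_mode == "absolute":
        return threshold
    if cutoff_mode == "fractional":
        return threshold * wild_type
    raise ValidationError(f"unknown cutoff_mode {cutoff_mode!r}")


def single_lethals(
    model: MetabolicModel,
    threshold: float = GROWTH_THRESHOLD,
    cutoff_mode: str = "absolute",
    solver: str = "highs",
) -> Set[str]:
    """Reactions whose individual full blocking abolishes growth."""
    wt = _growth(model, solver)
    if wt < threshold:
        raise InfeasibleModelError(
            f"model does not grow: wild-type biomass {wt:.3g} below threshold"
        )
    cut = _cutoff(wt, threshold, cutoff_mode)
    lethal = set()
    for rxn in model.reactions:
        if _growth(block(model, {rxn.id}), solver) < cut:
            lethal.add(rxn.id)
    return lethal


def double_lethals(
    model: MetabolicModel,
    singles: Optional[Set[str]] = None,
    threshold: float = GROWTH_THRESHOLD,
    cutoff_mode: str = "absolute",
    solver: str = "highs",
) -> Tuple[Set[FrozenSet[str]], int]:
    """Unordered pairs lethal jointly but not individually.

    Returns the pair set and the number of blocking conditions solved
    (candidate-generation solves plus pair tests).
    """
    if singles is None:
        singles = single_lethals(model, threshold, cutoff_mode, solver)
    wt = _growth(model, solver)
    cut = _cutoff(wt, threshold, cutoff_mode)

    n_tested = 0
    ref = fba(model, tie_break="parsimonious", solver=solver)
    support = {rid for rid in ref.support() if rid not in singles}

    pairs: Set[FrozenSet[str]] = set()
    tested: Set[FrozenSet[str]] = set()
    for i in sorted(support):
        blocked_i = block(model, {i})
        sol_i = fba(blocked_i, tie_break="parsimonious", solver=solver)
        n_tested += 1
        if not sol_i.optimal or sol_i.objective_value < cut:
            continue  # would be a single lethal; excluded by definition
        for j in sorted(sol_i.support()):
            if j == i or j in singles:
                continue
            pair = frozenset((i, j))
            if pair in tested:
                continue
            tested.add(pair)
            n_tested += 1
            if _growth(block(model, pair), solver) < cut:
                pairs.add(pair)
    return pairs, n_tested


def classify_lethals(result: LethalityResult, model: MetabolicModel) -> LethalityResult:
    """Fill the exchange/intracellular classification subsets in place."""
    exchanges = detect_exchanges(model)
    result.exchange_single_lethals = result.single_lethals & exchanges
    result.pairs_with_exchange = {
        p for p in result.double_lethals if any(r in exchanges for r in p)
    }
    result.pairs_two_exchanges = {
        p for p in result.double_lethals if all(r in exchanges for r in p)
    }
    return result


def analyze(
    model: MetabolicModel,
    threshold: float = GROWTH_THRESHOLD,
    cutoff_mode: str = "absolute",
    solver: str = "highs",
) -> LethalityResult:
    """Full lethality analysis: singles, pairs, classification."""
    wt = _growth(model, solver)
    singles = single_lethals(model, threshold, cutoff_mode, solver)
    pairs, n_pair_tests = double_lethals(model, singles, threshold, cutoff_mode, solver)
    result = LethalityResult(
        single_lethals=singles,
        double_lethals=pairs,
        wild_type_growth=wt,
        n_conditions_tested=len(model.reactions) + n_pair_tests,
    )
    return classify_lethals(result, model)


def anaerobic_variant(model: MetabolicModel) -> MetabolicModel:
    """Copy of the model with oxygen exchange reaction(s) deleted outright."""
    oxy = oxygen_exchange_ids(model)
    if not oxy:
        raise ValidationError(f"{model.id}: no oxygen exchange reaction found")
    return model.without_reactions(oxy)
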