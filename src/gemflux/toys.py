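"""Deterministic toy metabolic models with analytically known structure.

The hand-built fixtures (TOY-A .. TOY-O2) and the seeded random generator
emulate the conventions of published gut-microbe reconstructions: cytosolic
``c`` / extracellular ``e`` compartments, ``EX_``-prefixed boundary exchange
reactions with uptake as negative flux, a single biomass objective, and
per-reaction subsystem annotations. Each generated model ships with ground
truth (lethal sets, exchanges, wild-type growth) computed at generation time
by exhaustive brute-force knockout enumeration, independent of the pruned
lethality search.

Fixture motifs:
  TOY-A   parallel vs. serial paths: a unique uptake route plus two
          interchangeable internal routes (one 1-step, one 2-step).
  TOY-B   TOY-A with subsystem labels on the internal routes.
  TOY-C   two substrates both required for biomass plus a dead-end nutrient,
          for the minimal-nutrient-combination search.
  TOY-D   growth-coupled byproduct secretion.
  TOY-O2  oxygen/iron coupling: ferric iron is either taken up directly or
          produced from ferrous iron via an oxygen-dependent oxidation, so
          the oxygen and ferric-iron exchanges form a double-lethal pair
          while the ferrous-iron exchange is single-lethal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np

from .errors import ValidationError
from .fba import block, fba
from .lethality import GROWTH_THRESHOLD
from .model import MetabolicModel, Metabolite, Reaction, detect_exchanges
from .sbml import write_sbml  # re-exported: fixtures are written in SBML

FIXTURE_NAMES = ("TOY-A", "TOY-B", "TOY-C", "TOY-D", "TOY-O2")

MAX_BRUTE_FORCE_REACTIONS = 40


# ---------------------------------------------------------------------------
# brute-force oracle (independent of the pruned lethality search)
# ---------------------------------------------------------------------------


def exhaustive_single_lethals(
    model: MetabolicModel,
    threshold: float = GROWTH_THRESHOLD,
    solver: str = "highs",
) -> Set[str]:
    """One-at-a-time full knockout of every reaction."""
    lethal = set()
    for rxn in model.reactions:
        sol = fba(block(model, {rxn.id}), solver=solver)
        growth = sol.objective_value if sol.optimal else 0.0
        if growth < threshold:
            lethal.add(rxn.id)
    return lethal


def exhaustive_double_lethals(
    model: MetabolicModel,
    singles: Optional[Set[str]] = None,
    threshold: float = GROWTH_THRESHOLD,
    solver: str = "highs",
) -> Set[FrozenSet[str]]:
    """All C(n,2) joint knockouts over non-single-lethal reactions."""
    if len(model.reactions) > MAX_BRUTE_FORCE_REACTIONS:
        raise ValidationError(
            f"brute force capped at {MAX_BRUTE_FORCE_REACTIONS} reactions; "
            f"model has {len(model.reactions)}"
        )
    if singles is None:
        singles = exhaustive_single_lethals(model, threshold, solver)
    candidates = [r.id for r in model.reactions if r.id not in singles]
    pairs: Set[FrozenSet[str]] = set()
    for a, b in itertools.combinations(candidates, 2):
        sol = fba(block(model, {a, b}), solver=solver)
        growth = sol.objective_value if sol.optimal else 0.0
        if growth < threshold:
            pairs.add(frozenset((a, b)))
    return pairs


@dataclass
class KnownTruth:
    """Ground truth shipped with every generated model."""

    single_lethals: Set[str]
    double_lethals: Set[FrozenSet[str]]
    exchanges: Set[str]
    max_growth: float
    minimal_combos: Set[FrozenSet[str]] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        return {
            "single_lethals": sorted(self.single_lethals),
            "double_lethals": sorted(sorted(p) for p in self.double_lethals),
            "exchanges": sorted(self.exchanges),
            "max_growth": self.max_growth,
            "minimal_combos": sorted(sorted(c) for c in self.minimal_combos),
        }


def _truth(model: MetabolicModel, minimal_combos=()) -> KnownTruth:
    singles = exhaustive_single_lethals(model)
    return KnownTruth(
        single_lethals=singles,
        double_lethals=exhaustive_double_lethals(model, singles),
        exchanges=detect_exchanges(model),
        max_growth=fba(model).objective_value,
        minimal_combos=set(minimal_combos),
    )


# ---------------------------------------------------------------------------
# hand-built fixtures
# ---------------------------------------------------------------------------


def _met(mid: str) -> Metabolite:
    comp = "e" if mid.endswith("_e") else "c"
    return Metabolite(id=mid, name=mid, compartment=comp)


def _build(model_id: str, reactions: List[Reaction]) -> MetabolicModel:
    met_ids: List[str] = []
    for rxn in reactions:
        for mid in rxn.stoichiometry:
            if mid not in met_ids:
                met_ids.append(mid)
    return MetabolicModel(
        id=model_id,
        metabolites=[_met(m) for m in met_ids],
        reactions=reactions,
        objective_reaction_id="BIOMASS",
    )


def _toy_a_reactions(subsystems: bool = False) -> List[Reaction]:
    sub = {
        "R1": "Glycolysis" if subsystems else None,
        "R2": "Pentose phosphate pathway" if subsystems else None,
        "R3": "Pentose phosphate pathway" if subsystems else None,
    }
    return [
        Reaction("EX_A", {"A_e": -1.0}, -10.0, 1000.0),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0),
        Reaction("R1", {"A_c": -1.0, "P_c": 1.0}, 0.0, 1000.0, subsystem=sub["R1"]),
        Reaction("R2", {"A_c": -1.0, "X_c": 1.0}, 0.0, 1000.0, subsystem=sub["R2"]),
        Reaction("R3", {"X_c": -1.0, "P_c": 1.0}, 0.0, 1000.0, subsystem=sub["R3"]),
        Reaction("BIOMASS", {"P_c": -1.0}, 0.0, 1000.0),
    ]


def make_fixture(name: str) -> Tuple[MetabolicModel, KnownTruth]:
    if name == "TOY-A":
        model = _build("TOY_A", _toy_a_reactions())
        return model, _truth(model)
    if name == "TOY-B":
        model = _build("TOY_B", _toy_a_reactions(subsystems=True))
        return model, _truth(model)
    if name == "TOY-C":
        reactions = _toy_a_reactions()
        reactions[-1] = Reaction("BIOMASS", {"P_c": -1.0, "Q_c": -1.0}, 0.0, 1000.0)
        reactions += [
            Reaction("EX_B", {"B_e": -1.0}, -10.0, 1000.0),
            Reaction("T_B", {"B_e": -1.0, "B_c": 1.0}, 0.0, 1000.0),
            Reaction("R4", {"B_c": -1.0, "Q_c": 1.0}, 0.0, 1000.0),
            # dead-end nutrient: uptake possible in principle but unusable
            Reaction("EX_N", {"N_e": -1.0}, -10.0, 1000.0),
            Reaction("T_N", {"N_e": -1.0, "N_c": 1.0}, 0.0, 1000.0),
        ]
        model = _build("TOY_C", reactions)
        return model, _truth(model, minimal_combos=[frozenset(("EX_A", "EX_B"))])
    if name == "TOY-D":
        reactions = [
            Reaction("EX_A", {"A_e": -1.0}, -10.0, 1000.0),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0),
            Reaction("R1", {"A_c": -1.0, "B_c": 1.0, "P_c": 1.0}, 0.0, 1000.0),
            Reaction("R2", {"A_c": -1.0, "X_c": 1.0}, 0.0, 1000.0),
            Reaction("R3", {"X_c": -1.0, "B_c": 1.0}, 0.0, 1000.0),
            Reaction("T_P", {"P_c": -1.0, "P_e": 1.0}, 0.0, 1000.0),
            Reaction("EX_P", {"P_e": -1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"B_c": -1.0}, 0.0, 1000.0),
        ]
        model = _build("TOY_D", reactions)
        return model, _truth(model)
    if name == "TOY-O2":
        reactions = [
            Reaction("EX_A", {"A_e": -1.0}, -10.0, 1000.0),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0),
            Reaction("R1", {"A_c": -1.0, "P_c": 1.0}, 0.0, 1000.0),
            Reaction("EX_O2", {"O2_e": -1.0}, -10.0, 1000.0),
            Reaction("T_O2", {"O2_e": -1.0, "O2_c": 1.0}, 0.0, 1000.0),
            Reaction("EX_Fe2", {"Fe2_e": -1.0}, -10.0, 1000.0),
            Reaction("T_Fe2", {"Fe2_e": -1.0, "Fe2_c": 1.0}, 0.0, 1000.0),
            Reaction("EX_Fe3", {"Fe3_e": -1.0}, -10.0, 1000.0),
            Reaction("T_Fe3", {"Fe3_e": -1.0, "Fe3_c": 1.0}, 0.0, 1000.0),
            # ferrous -> ferric oxidation requires oxygen
            Reaction(
                "R_FEOX",
                {"Fe2_c": -4.0, "O2_c": -1.0, "Fe3_c": 4.0},
                0.0,
                1000.0,
            ),
            Reaction(
                "BIOMASS", {"P_c": -1.0, "Fe2_c": -0.1, "Fe3_c": -0.1}, 0.0, 1000.0
            ),
        ]
        model = _build("TOY_O2", reactions)
        return model, _truth(model)
    raise ValidationError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# seeded random generator
# ---------------------------------------------------------------------------


@dataclass
class ToySpec:
    n_substrates: int = 2
    n_parallel_paths: int = 2
    with_byproduct: bool = False
    with_oxygen_couple: bool = False
    subsystem_labels: Tuple[str, ...] = (
        "Glycolysis",
        "Pentose phosphate pathway",
        "Amino acid metabolism",
    )
    seed: int = 0


def make_random(spec: ToySpec, _retries: int = 5) -> Tuple[MetabolicModel, KnownTruth]:
    """Layered substrate -> precursor -> biomass network, pure in the seed."""
    for attempt in range(_retries):
        rng = np.random.default_rng(spec.seed + 1_000_003 * attempt)
        reactions: List[Reaction] = []
        biomass_stoich: Dict[str, float] = {}
        label_cycle = itertools.cycle(spec.subsystem_labels or (None,))

        for i in range(spec.n_substrates):
            s_e, s_c, p_c = f"S{i}_e", f"S{i}_c", f"P{i}_c"
            uptake = round(float(rng.uniform(5.0, 15.0)), 3)
            reactions.append(Reaction(f"EX_S{i}", {s_e: -1.0}, -uptake, 1000.0))
            reactions.append(Reaction(f"T_S{i}", {s_e: -1.0, s_c: 1.0}, 0.0, 1000.0))
            n_paths = int(rng.integers(1, spec.n_parallel_paths + 1))
            for j in range(n_paths):
                two_step = bool(rng.integers(0, 2))
                label = next(label_cycle)
                if two_step:
                    mid = f"M{i}_{j}_c"
                    reactions.append(
                        Reaction(f"R{i}_{j}a", {s_c: -1.0, mid: 1.0}, 0.0, 1000.0,
                                 subsystem=label)
                    )
                    reactions.append(
                        Reaction(f"R{i}_{j}b", {mid: -1.0, p_c: 1.0}, 0.0, 1000.0,
                                 subsystem=label)
                    )
                else:
                    reactions.append(
                        Reaction(f"R{i}_{j}", {s_c: -1.0, p_c: 1.0}, 0.0, 1000.0,
                                 subsystem=label)
                    )
            biomass_stoich[p_c] = -1.0

        if spec.with_byproduct:
            first_path = next(r for r in reactions if r.id.startswith("R0_0"))
            first_path.stoichiometry["W_c"] = 1.0
            reactions.append(Reaction("T_W", {"W_c": -1.0, "W_e": 1.0}, 0.0, 1000.0))
            reactions.append(Reaction("EX_W", {"W_e": -1.0}, 0.0, 1000.0))

        if spec.with_oxygen_couple:
            reactions += [
                Reaction("EX_O2", {"O2_e": -1.0}, -10.0, 1000.0),
                Reaction("T_O2", {"O2_e": -1.0, "O2_c": 1.0}, 0.0, 1000.0),
                Reaction("EX_Fe2", {"Fe2_e": -1.0}, -10.0, 1000.0),
                Reaction("T_Fe2", {"Fe2_e": -1.0, "Fe2_c": 1.0}, 0.0, 1000.0),
                Reaction("EX_Fe3", {"Fe3_e": -1.0}, -10.0, 1000.0),
                Reaction("T_Fe3", {"Fe3_e": -1.0, "Fe3_c": 1.0}, 0.0, 1000.0),
                Reaction("R_FEOX", {"Fe2_c": -4.0, "O2_c": -1.0, "Fe3_c": 4.0},
                         0.0, 1000.0),
            ]
            biomass_stoich["Fe2_c"] = -0.1
            biomass_stoich["Fe3_c"] = -0.1

        reactions.append(Reaction("BIOMASS", dict(biomass_stoich), 0.0, 1000.0))
        if len(reactions) > MAX_BRUTE_FORCE_REACTIONS:
            raise ValidationError(
                f"spec yields {len(reactions)} reactions, above the "
                f"{MAX_BRUTE_FORCE_REACTIONS}-reaction brute-force cap"
            )
        model = _build(f"RANDOM_{spec.seed}", reactions)
        sol = fba(model)
        if sol.optimal and sol.objective_value >= GROWTH_THRESHOLD:
            return model, _truth(model)
    raise ValidationError(f"could not generate a feasible model for seed {spec.seed}")
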