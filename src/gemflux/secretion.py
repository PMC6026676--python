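"""Growth-coupled extracellular production/consumption envelopes.

At the maximal growth rate permitted by a medium, each exchange flux is in
turn maximized (production) and minimized (consumption) with biomass pinned
from below, yielding per-metabolite envelopes. Overlaying envelopes across
organisms classifies each extracellular metabolite as commensal (produced by
one organism, consumed by a different one), competitive (multiple consumers,
no producer), shared-production, or none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import pandas as pd

from .errors import InfeasibleModelError, ValidationError
from .fba import fba
from .model import MediumSpec, MetabolicModel, apply_medium, detect_exchanges

ROLE_EPS = 1e-6


def max_growth(model: MetabolicModel, medium: MediumSpec, solver: str = "highs") -> float:
    """Biomass optimum of the model under the medium."""
    constrained = apply_medium(model, medium)
    sol = fba(constrained, solver=solver)
    if not sol.optimal:
        raise InfeasibleModelError(
            f"medium insufficient: biomass FBA is {sol.status} for {model.id}"
        )
    return sol.objective_value


def growth_coupled_exchange(
    model: MetabolicModel,
    medium: MediumSpec,
    mu_fix: float,
    metabolite_exchange_id: str,
    solver: str = "highs",
) -> Tuple[float, float]:
    """(max_production, max_consumption) of one exchange at biomass >= mu_fix.

    Production is the maximal exchange flux clipped at 0 from below;
    consumption is the magnitude of the most negative achievable flux,
    naturally bounded by the medium's uptake limit.
    """
    constrained = apply_medium(model, medium)
    if not constrained.has_reaction(metabolite_exchange_id):
        raise ValidationError(f"unknown reaction {metabolite_exchange_id!r}")
    if not constrained.reaction(metabolite_exchange_id).is_exchange:
        raise ValidationError(f"{metabolite_exchange_id!r} is not an exchange reaction")

    # pin biomass from below, backed off relatively to avoid vertex infeasibility
    floor = mu_fix - 1e-9 * max(1.0, abs(mu_fix))
    biomass = constrained.reaction(constrained.objective_reaction_id)
    biomass.lower_bound = max(biomass.lower_bound, floor)

    hi_sol = fba(constrained, objective_id=metabolite_exchange_id, direction="max", solver=solver)
    lo_sol = fba(constrained, objective_id=metabolite_exchange_id, direction="min", solver=solver)
    if not (hi_sol.optimal and lo_sol.optimal):
        raise InfeasibleModelError(
            f"infeasible at biomass >= {mu_fix:.6g} for {metabolite_exchange_id}"
        )
    production = max(0.0, hi_sol.objective_value)
    consumption = max(0.0, -lo_sol.objective_value)
    return production, consumption


@dataclass
class ExchangeProfile:
    """Per-organism, per-regime envelope over extracellular metabolites."""

    organism: str
    regime: str
    rows: List[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=[
                "organism", "regime", "exchange_id", "metabolite_id",
                "metabolite_name", "max_production", "max_consumption", "role",
            ],
        )

    def producers(self) -> Set[str]:
        return {r["metabolite_id"] for r in self.rows if r["role"] in ("producer", "both")}

    def consumers(self) -> Set[str]:
        return {r["metabolite_id"] for r in self.rows if r["role"] in ("consumer", "both")}

    def metabolite_ids(self) -> Set[str]:
        return {r["metabolite_id"] for r in self.rows}


def _role(production: float, consumption: float) -> str:
    producer = production > ROLE_EPS
    consumer = consumption > ROLE_EPS
    if producer and consumer:
        return "both"
    if producer:
        return "producer"
    if consumer:
        return "consumer"
    return "inert"


def profile(
    model: MetabolicModel,
    medium: MediumSpec,
    organism: Optional[str] = None,
    exchange_ids: Optional[Iterable[str]] = None,
    mu_fix: Optional[float] = None,
    solver: str = "highs",
) -> ExchangeProfile:
    """Envelope over all (or selected) exchanges at maximal medium growth."""
    organism = organism or model.id
    regime = "anaerobic" if medium.anaerobic else "aerobic"
    if mu_fix is None:
        mu_fix = max_growth(model, medium, solver)
    if exchange_ids is None:
        exchange_ids = sorted(detect_exchanges(model))
    prof = ExchangeProfile(organism=organism, regime=regime)
    for rid in exchange_ids:
        production, consumption = growth_coupled_exchange(
            model, medium, mu_fix, rid, solver
        )
        rxn = model.reaction(rid)
        met_id = next(m for m, c in rxn.stoichiometry.items() if c != 0)
        met = model.metabolite(met_id)
        prof.rows.append(
            {
                "organism": organism,
                "regime": regime,
                "exchange_id": rid,
                "metabolite_id": met_id,
                "metabolite_name": met.name,
                "max_production": production,
                "max_consumption": consumption,
                "role": _role(production, consumption),
            }
        )
    return prof


@dataclass
class InteractionMatrix:
    """Per-metabolite producer/consumer sets and classification."""

    regime: str
    entries: Dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metabolite_id": met,
                "producers": "|".join(sorted(e["producers"])),
                "consumers": "|".join(sorted(e["consumers"])),
                "classification": e["classification"],
            }
            for met, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["metabolite_id", "producers", "consumers", "classification"]
        )

    def code_matrix(self, organisms: List[str]) -> pd.DataFrame:
        """Metabolite x organism matrix with P/C/B/. codes."""
        data = {}
        for met, e in sorted(self.entries.items()):
            row = {}
            for org in organisms:
                p = org in e["producers"]
                c = org in e["consumers"]
                row[org] = "B" if (p and c) else "P" if p else "C" if c else "."
            data[met] = row
        return pd.DataFrame.from_dict(data, orient="index", columns=organisms)


def classify_interaction(producers: Set[str], consumers: Set[str]) -> str:
    """Pure classification of one metabolite from its producer/consumer sets."""
    if any(p != c for p in producers for c in consumers):
        return "commensal"
    if len(consumers) >= 2 and not producers:
        return "competitive"
    if len(producers) >= 2:
        return "shared-production"
    return "none"


def build_interaction_matrix(profiles: List[ExchangeProfile]) -> InteractionMatrix:
    """Overlay >= 2 organism envelopes into a cross-feeding matrix.

    Profiles must share a metabolite namespace; a profile with no metabolite
    ids in common with the others is reported as a namespace mismatch.
    """
    if len(profiles) < 2:
        raise ValidationError("need profiles for at least 2 organisms")
    regimes = {p.regime for p in profiles}
    if len(regimes) > 1:
        raise ValidationError(
            f"profiles mix regimes {sorted(regimes)}; stratify by regime first"
        )
    namespaces = [p.metabolite_ids() for p in profiles]
    union_others = [
        set().union(*(ns for j, ns in enumerate(namespaces) if j != i))
        for i in range(len(namespaces))
    ]
    for prof, ns, others in zip(profiles, namespaces, union_others):
        if ns and others and not (ns & others):
            raise ValidationError(
                f"metabolite namespace mismatch for {prof.organism}: "
                f"unmatched ids e.g. {sorted(ns)[:5]}"
            )

    matrix = InteractionMatrix(regime=regimes.pop())
    all_mets = sorted(set().union(*namespaces))
    for met in all_mets:
        producers = {p.organism for p in profiles if met in p.producers()}
        consumers = {p.organism for p in profiles if met in p.consumers()}
        matrix.entries[met] = {
            "producers": producers,
            "consumers": consumers,
            "classification": classify_interaction(producers, consumers),
        }
    return matrix
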