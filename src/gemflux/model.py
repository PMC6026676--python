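"""Core data model for constraint-based metabolic networks.

A :class:`MetabolicModel` is a stoichiometric network with flux bounds, a
biomass objective reaction, optional per-reaction subsystem (pathway)
annotations, and a designated boundary (extracellular) compartment.
Exchange reactions follow the COBRA/AGORA sign convention: a boundary
pseudo-reaction ``met_e <-> (nothing)`` where negative flux is uptake and
positive flux is secretion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from scipy import sparse

from .errors import ValidationError

#: Community-convention default flux bound magnitude (mmol/gDW/h).
DEFAULT_BOUND = 1000.0

#: Reaction-id prefixes identifying macromolecular pseudo-reactions that are
#: never classified as exchanges even if they touch a boundary metabolite.
PSEUDO_PREFIXES: Tuple[str, ...] = ("biomass", "dna", "rna", "protein")

_OXY_RXN = re.compile(r"^ex_o2[\[\(_]?e?[\]\)]?$", re.IGNORECASE)
_OXY_MET = re.compile(r"^o2([\[\(_]e[\]\)]?)?$", re.IGNORECASE)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    subsystem: Optional[str] = None
    is_exchange: bool = False


@dataclass
class MetabolicModel:
    id: str
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    objective_reaction_id: str
    boundary_compartment: str = "e"
    pseudo_prefixes: Tuple[str, ...] = PSEUDO_PREFIXES

    def __post_init__(self) -> None:
        self._reindex()
        self.validate()
        self._flag_exchanges()

    # -- indexing -----------------------------------------------------------

    def _reindex(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if len(self._met_index) != len(self.metabolites):
            raise ValidationError(f"{self.id}: duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ValidationError(f"{self.id}: duplicate reaction ids")
        for met in self.metabolites:
            if not met.compartment:
                raise ValidationError(f"metabolite {met.id}: empty compartment")
        for rxn in self.reactions:
            if rxn.lower_bound > rxn.upper_bound:
                raise ValidationError(
                    f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}"
                )
            if not rxn.stoichiometry:
                raise ValidationError(f"reaction {rxn.id}: empty stoichiometry")
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ValidationError(
                        f"reaction {rxn.id}: unknown metabolite {met_id!r}"
                    )
        if self.objective_reaction_id not in self._rxn_index:
            raise ValidationError(
                f"{self.id}: objective reaction {self.objective_reaction_id!r} "
                "not in model"
            )

    def _is_pseudo(self, rxn_id: str) -> bool:
        low = rxn_id.lower()
        return any(low.startswith(p) for p in self.pseudo_prefixes)

    def _flag_exchanges(self) -> None:
        for rxn in self.reactions:
            rxn.is_exchange = self._qualifies_as_exchange(rxn)

    def _qualifies_as_exchange(self, rxn: Reaction) -> bool:
        if rxn.id == self.objective_reaction_id or self._is_pseudo(rxn.id):
            return False
        nonzero = [m for m, c in rxn.stoichiometry.items() if c != 0]
        if len(nonzero) != 1:
            return False
        return self.metabolite(nonzero[0]).compartment == self.boundary_compartment

    # -- derived structures -------------------------------------------------

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S with metabolites as rows and reactions as columns."""
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                if coef != 0:
                    rows.append(self._met_index[met_id])
                    cols.append(j)
                    vals.append(float(coef))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # -- copying / editing --------------------------------------------------

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                Reaction(
                    id=r.id,
                    stoichiometry=dict(r.stoichiometry),
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    name=r.name,
                    subsystem=r.subsystem,
                )
                for r in self.reactions
            ],
            objective_reaction_id=self.objective_reaction_id,
            boundary_compartment=self.boundary_compartment,
            pseudo_prefixes=self.pseudo_prefixes,
        )

    def without_reactions(self, rxn_ids: Iterable[str]) -> "MetabolicModel":
        """Copy of the model with the given reactions deleted entirely."""
        drop = set(rxn_ids)
        missing = drop - set(self._rxn_index)
        if missing:
            raise ValidationError(f"cannot delete unknown reactions: {sorted(missing)}")
        if self.objective_reaction_id in drop:
            raise ValidationError("cannot delete the objective reaction")
        kept = [r for r in self.reactions if r.id not in drop]
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                Reaction(
                    id=r.id,
                    stoichiometry=dict(r.stoichiometry),
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    name=r.name,
                    subsystem=r.subsystem,
                )
                for r in kept
            ],
            objective_reaction_id=self.objective_reaction_id,
            boundary_compartment=self.boundary_compartment,
            pseudo_prefixes=self.pseudo_prefixes,
        )


def detect_exchanges(model: MetabolicModel) -> Set[str]:
    """Ids of boundary exchange reactions.

    A reaction qualifies when it carries exactly one metabolite with a nonzero
    coefficient and that metabolite lives in the boundary compartment; the
    objective and macromolecular pseudo-reactions (DNA/RNA/protein/biomass)
    are always treated as intracellular.
    """
    return {r.id for r in model.reactions if model._qualifies_as_exchange(r)}


def oxygen_exchange_ids(model: MetabolicModel) -> List[str]:
    """Exchange reactions moving molecular oxygen, by id convention."""
    found = []
    for rxn in model.reactions:
        if not rxn.is_exchange:
            continue
        met_id = next(m for m, c in rxn.stoichiometry.items() if c != 0)
        if _OXY_RXN.match(rxn.id) or _OXY_MET.match(met_id):
            found.append(rxn.id)
    return sorted(found)


# ---------------------------------------------------------------------------
# Medium handling
# ---------------------------------------------------------------------------


@dataclass
class MediumSpec:
    """Maximum uptake rates per exchange reaction.

    ``uptakes`` maps exchange reaction id to a non-negative maximal uptake
    rate (mmol/gDW/h), applied as ``lower_bound = -rate``. When ``anaerobic``
    is set, oxygen uptake is forced closed regardless of the uptake table.
    """

    uptakes: Dict[str, float] = field(default_factory=dict)
    anaerobic: bool = False

    def __post_init__(self) -> None:
        for rid, rate in self.uptakes.items():
            if rate < 0:
                raise ValidationError(f"medium rate for {rid} is negative: {rate}")


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of the model constrained to the medium.

    Every exchange reaction absent from the medium has uptake closed
    (``lower_bound = 0``; secretion untouched); exchanges in the medium get
    ``lower_bound = -rate`` clamped so no bound is ever widened beyond the
    model's declared bounds. Anaerobic media additionally close oxygen uptake.
    """
    exchanges = detect_exchanges(model)
    bad = set(medium.uptakes) - exchanges
    if bad:
        raise ValidationError(
            f"medium entries are not exchange reactions: {sorted(bad)}"
        )
    out = model.copy()
    for rid in exchanges:
        rxn = out.reaction(rid)
        if rid in medium.uptakes:
            rxn.lower_bound = max(-medium.uptakes[rid], rxn.lower_bound)
        else:
            rxn.lower_bound = max(0.0, rxn.lower_bound)
    if medium.anaerobic:
        for rid in oxygen_exchange_ids(out):
            rxn = out.reaction(rid)
            rxn.lower_bound = max(0.0, rxn.lower_bound)
    out._flag_exchanges()
    return out


def read_medium_tsv(path: str) -> MediumSpec:
    """Read a two-column (exchange_id, max_uptake) TSV medium file.

    A header comment line ``#anaerobic: true`` marks the medium anaerobic.
    """
    uptakes: Dict[str, float] = {}
    anaerobic = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*anaerobic\s*:\s*(\w+)", line, re.IGNORECASE)
                if m:
                    anaerobic = m.group(1).lower() in ("true", "1", "yes")
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"malformed medium line: {line!r}")
            uptakes[parts[0]] = float(parts[1])
    return MediumSpec(uptakes=uptakes, anaerobic=anaerobic)


def write_medium_tsv(medium: MediumSpec, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#anaerobic: {'true' if medium.anaerobic else 'false'}\n")
        for rid in sorted(medium.uptakes):
            fh.write(f"{rid}\t{medium.uptakes[rid]:.10g}\n")
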