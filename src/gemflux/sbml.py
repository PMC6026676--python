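"""SBML I/O for metabolic models.

Primary dialect is SBML Level 3 Version 1 with the ``fbc`` (flux bounds)
package, version 2 -- the form currently served for published gut-microbe
reconstructions. Level 2 documents with bounds stored as kinetic-law
parameters are accepted as a fallback with a warning.

Subsystem (pathway) annotations travel in reaction notes as a
``SUBSYSTEM: <name>`` line, matching the convention of the source models.
"""

from __future__ import annotations

import re
import warnings
from typing import Dict, List, Optional

import libsbml

from .errors import NoObjectiveError, SBMLParseError, ValidationError
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

_SUBSYSTEM_RE = re.compile(r"SUBSYSTEM:\s*([^<\n]+)")
_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str) -> str:
    """Sanitize an arbitrary id into a valid SBML SId."""
    out = _SID_BAD.sub("_", raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def read_sbml(path: str) -> MetabolicModel:
    """Parse an SBML file into a :class:`MetabolicModel`.

    The objective is taken from the active fbc objective when present,
    otherwise the unique reaction whose id contains ``biomass``
    (case-insensitive). Bounds default to +/-1000 (0 lower bound for
    irreversible reactions) when unspecified.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(f"{path}: {err.getMessage() if err else 'SBML errors'}")
    sb_model = doc.getModel()
    if sb_model is None:
        raise SBMLParseError(f"{path}: no model element")

    level = doc.getLevel()
    if level < 3:
        warnings.warn(
            f"{path}: SBML level {level} document; reading bounds from "
            "kinetic-law parameters",
            stacklevel=2,
        )

    metabolites = []
    compartments: Dict[str, str] = {}
    for i in range(sb_model.getNumCompartments()):
        comp = sb_model.getCompartment(i)
        compartments[comp.getId()] = comp.getId()
    for i in range(sb_model.getNumSpecies()):
        sp = sb_model.getSpecies(i)
        metabolites.append(
            Metabolite(
                id=sp.getId(), name=sp.getName() or "", compartment=sp.getCompartment()
            )
        )

    reactions: List[Reaction] = []
    for i in range(sb_model.getNumReactions()):
        rx = sb_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        if not stoich:
            raise SBMLParseError(f"{path}: reaction {rx.getId()} has no participants")

        lb, ub = _read_bounds(sb_model, rx)
        subsystem = _read_subsystem(rx)
        reactions.append(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=rx.getName() or "",
                subsystem=subsystem,
            )
        )

    objective_id = _read_objective(sb_model, reactions)
    boundary = _guess_boundary_compartment(metabolites)
    try:
        return MetabolicModel(
            id=sb_model.getId() or "model",
            metabolites=metabolites,
            reactions=reactions,
            objective_reaction_id=objective_id,
            boundary_compartment=boundary,
        )
    except ValidationError as exc:
        raise SBMLParseError(f"{path}: {exc}") from exc


def _read_bounds(sb_model, rx) -> tuple:
    fbc_rx = rx.getPlugin("fbc")
    if fbc_rx is not None and fbc_rx.isSetLowerFluxBound():
        lb_param = sb_model.getParameter(fbc_rx.getLowerFluxBound())
        ub_param = sb_model.getParameter(fbc_rx.getUpperFluxBound())
        if lb_param is None or ub_param is None:
            raise SBMLParseError(f"reaction {rx.getId()}: dangling flux-bound parameter")
        return lb_param.getValue(), ub_param.getValue()
    # Level 2 fallback: kinetic-law parameters
    kl = rx.getKineticLaw()
    lb = ub = None
    if kl is not None:
        for j in range(kl.getNumParameters()):
            p = kl.getParameter(j)
            if p.getId().upper() == "LOWER_BOUND":
                lb = p.getValue()
            elif p.getId().upper() == "UPPER_BOUND":
                ub = p.getValue()
    if lb is None:
        lb = -DEFAULT_BOUND if rx.getReversible() else 0.0
    if ub is None:
        ub = DEFAULT_BOUND
    return lb, ub


def _read_subsystem(rx) -> Optional[str]:
    notes = rx.getNotesString() if rx.isSetNotes() else ""
    m = _SUBSYSTEM_RE.search(notes)
    if m:
        value = m.group(1).strip()
        return value or None
    return None


def _read_objective(sb_model, reactions: List[Reaction]) -> str:
    fbc = sb_model.getPlugin("fbc")
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            return obj.getFluxObjective(0).getReaction()
    candidates = [r.id for r in reactions if "biomass" in r.id.lower()]
    if len(candidates) == 1:
        return candidates[0]
    raise NoObjectiveError(
        "no objective: model declares no fbc objective and "
        f"{len(candidates)} reactions match the biomass naming convention"
    )


def _guess_boundary_compartment(metabolites: List[Metabolite]) -> str:
    comps = {m.compartment for m in metabolites}
    for candidate in ("e", "e0", "extracellular", "Extracellular"):
        if candidate in comps:
            return candidate
    return "e"


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML Level 3 Version 1 with fbc v2.

    The serialization is deterministic for a given model, so identical
    in-memory models yield byte-identical files.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb_model = doc.createModel()
    sb_model.setId(_sid(model.id))
    fbc = sb_model.getPlugin("fbc")
    fbc.setStrict(True)

    comps = sorted({m.compartment for m in model.metabolites})
    for cid in comps:
        comp = sb_model.createCompartment()
        comp.setId(_sid(cid))
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sb_model.createSpecies()
        sp.setId(_sid(met.id))
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(_sid(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    # one shared parameter per distinct bound value, in first-use order
    bound_params: Dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sb_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        rx = sb_model.createReaction()
        rx.setId(_sid(rxn.id))
        if rxn.name:
            rx.setName(rxn.name)
        rx.setFast(False)
        rx.setReversible(rxn.lower_bound < 0)
        for met_id in sorted(rxn.stoichiometry):
            coef = rxn.stoichiometry[met_id]
            if coef == 0:
                continue
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(_sid(met_id))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        fbc_rx = rx.getPlugin("fbc")
        fbc_rx.setLowerFluxBound(_bound_param(float(rxn.lower_bound)))
        fbc_rx.setUpperFluxBound(_bound_param(float(rxn.upper_bound)))
        if rxn.subsystem:
            rx.setNotes(
                '<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )

    objective = fbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction(_sid(model.objective_reaction_id))
    flux_obj.setCoefficient(1.0)
    fbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SBMLParseError(f"failed to write SBML to {path}")


def sbml_string(model: MetabolicModel) -> str:
    """Serialize to an SBML string (used for determinism checks)."""
    import os
    import tempfile

    fd, tmp = tempfile.mkstemp(suffix=".xml")
    os.close(fd)
    try:
        write_sbml(model, tmp)
        with open(tmp) as fh:
            return fh.read()
    finally:
        os.unlink(tmp)
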