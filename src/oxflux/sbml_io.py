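"""SBML reading and writing via libSBML.

Reads SBML Level 2 (COBRA-style ``LOWER_BOUND``/``UPPER_BOUND``/
``OBJECTIVE_COEFFICIENT`` kinetic-law parameters) and Level 3 with the ``fbc``
package; writes Level 3 Version 1 with ``fbc`` version 2, which round-trips
through this module and is readable by cobrapy.

Bound resolution precedence per reaction: fbc flux-bound parameters, then
COBRA kinetic-law parameters, then defaults derived from reversibility
(``[-B, +B]`` if reversible else ``[0, +B]`` with the configured large bound
``B``), logged as a warning.  Boundary species are flagged from the SBML
``boundaryCondition`` attribute or membership in a compartment declared as
boundary (id ``b`` or ``boundary``).  Identifiers are case-sensitive and
never renamed; bounds are never rescaled.
"""

from __future__ import annotations

import logging
from os import PathLike

import libsbml

from .core import LARGE_BOUND, MetabolicModel, Metabolite, Reaction

logger = logging.getLogger(__name__)

_BOUNDARY_COMPARTMENTS = {"b", "boundary"}


class SBMLParseError(ValueError):
    """The file is not readable SBML; the message names the offending line."""


def _collect_errors(doc: libsbml.SBMLDocument) -> list[str]:
    msgs = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            msgs.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    return msgs


def _kinetic_parameter(rxn: libsbml.Reaction, name: str) -> float | None:
    kl = rxn.getKineticLaw()
    if kl is None:
        return None
    par = kl.getParameter(name)
    if par is None:
        par = kl.getLocalParameter(name)
    return par.getValue() if par is not None else None


def _fbc_bound(
    model: libsbml.Model, rxn: libsbml.Reaction, which: str
) -> float | None:
    plug = rxn.getPlugin("fbc")
    if plug is None:
        return None
    pid = plug.getLowerFluxBound() if which == "lower" else plug.getUpperFluxBound()
    if not pid:
        return None
    par = model.getParameter(pid)
    return par.getValue() if par is not None else None


def read_sbml(path: str | PathLike, large_bound: float = LARGE_BOUND) -> MetabolicModel:
    """Load a metabolic model from an SBML file.

    Species, stoichiometries, bounds and (when an fbc objective or COBRA
    ``OBJECTIVE_COEFFICIENT`` parameters are present) objective coefficients
    are loaded; reactions lacking explicit bounds fall back to
    reversibility-based defaults with a logged warning.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    errors = _collect_errors(doc)
    if errors:
        raise SBMLParseError(
            f"cannot parse {path}: " + "; ".join(errors[:5])
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError(f"cannot parse {path}: no model element")

    metabolites = []
    for sp in sbml_model.getListOfSpecies():
        is_boundary = bool(sp.getBoundaryCondition()) or (
            sp.getCompartment() in _BOUNDARY_COMPARTMENTS
        )
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "",
                is_boundary=is_boundary,
            )
        )

    reactions = []
    objective: dict[str, float] = {}
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}

        lower = _fbc_bound(sbml_model, rxn, "lower")
        upper = _fbc_bound(sbml_model, rxn, "upper")
        if lower is None:
            lower = _kinetic_parameter(rxn, "LOWER_BOUND")
        if upper is None:
            upper = _kinetic_parameter(rxn, "UPPER_BOUND")
        if lower is None or upper is None:
            default_lower = -large_bound if rxn.getReversible() else 0.0
            logger.warning(
                "reaction %s: missing explicit bounds, defaulting to [%g, %g]",
                rxn.getId(),
                default_lower if lower is None else lower,
                large_bound if upper is None else upper,
            )
            lower = default_lower if lower is None else lower
            upper = large_bound if upper is None else upper

        coeff = _kinetic_parameter(rxn, "OBJECTIVE_COEFFICIENT")
        if coeff:
            objective[rxn.getId()] = coeff
        reactions.append(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=lower,
                upper_bound=upper,
            )
        )

    fbc_plug = sbml_model.getPlugin("fbc")
    if fbc_plug is not None and fbc_plug.getNumObjectives() > 0:
        active = fbc_plug.getActiveObjective() or fbc_plug.getObjective(0)
        if active is not None:
            objective = {}
            for fo in active.getListOfFluxObjectives():
                objective[fo.getReaction()] = fo.getCoefficient()

    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
        notes=sbml_model.getName() or "",
    )


def write_sbml(model: MetabolicModel, path: str | PathLike) -> None:
    """Write a model as SBML Level 3 Version 1 with fbc version 2.

    Flux bounds become shared constant parameters; the objective (if any)
    becomes the active fbc maximization objective.  ``read_sbml`` recovers
    the model up to ordering.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId("model")
    if model.notes:
        sbml_model.setName(model.notes)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in model.compartments or ["default"]:
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    default_comp = (model.compartments or ["default"])[0]
    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment or default_comp)
        sp.setBoundaryCondition(met.is_boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    bound_params: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sr = sbml_model.createReaction()
        sr.setId(rxn.id)
        if rxn.name:
            sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_id(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_id(rxn.upper_bound))

    if model.objective:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rxn_id, coef in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(rxn_id)
            fo.setCoefficient(coef)
        mplug.setActiveObjectiveId("obj")

    ok = libsbml.writeSBMLToFile(doc, str(path))
    if not ok:
        raise IOError(f"cannot write SBML to {path}")
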