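"""SBML Level 3 + FBC import/export for MetabolicModel.

Round-trips stoichiometry, bounds, GPR rules, the objective and the ATP
maintenance annotation.  Elemental formulas with fractional atom counts
(averaged lipid species) cannot be encoded as FBC chemical formulas and are
dropped on export with integer-formula species kept.
"""

from __future__ import annotations

from typing import Dict

import libsbml

from .gpr import And, Gene, Or, parse_gpr
from .model import MetabolicModel, Metabolite, Reaction

_MAINT_NOTE = "fluxrecon:atp_maintenance"


def _gpr_infix(node, rename) -> str:
    if isinstance(node, Gene):
        return rename(node.id)
    joiner = " and " if isinstance(node, And) else " or "
    return "(" + joiner.join(_gpr_infix(n, rename) for n in node.operands) + ")"


def _check(obj, msg: str):
    if obj is None:
        raise RuntimeError(f"libsbml failure: {msg}")
    return obj


def _sid(raw: str) -> str:
    """SBML ids must match SId; map other characters to underscores."""
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def write_sbml_model(model: MetabolicModel, path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = _check(doc.createModel(), "create model")
    sbml_model.setId(_sid(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    comp = _check(sbml_model.createCompartment(), "compartment")
    comp.setId("c")
    comp.setConstant(True)

    id_map: Dict[str, str] = {}
    for met in model.metabolites:
        sp = _check(sbml_model.createSpecies(), f"species {met.id}")
        sid = "M_" + _sid(met.id)
        id_map[met.id] = sid
        sp.setId(sid)
        sp.setName(met.id)
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if met.formula and all(float(n).is_integer() for n in met.formula.values()):
            splug = sp.getPlugin("fbc")
            splug.setChemicalFormula(
                "".join(f"{el}{int(n)}" for el, n in sorted(met.formula.items()))
            )

    for gene in sorted(model.genes):
        gp = _check(mplug.createGeneProduct(), f"gene {gene}")
        gp.setId("G_" + _sid(gene))
        gp.setLabel(gene)

    for i, rxn in enumerate(model.reactions):
        for suffix, value in (("lb", rxn.lower_bound), ("ub", rxn.upper_bound)):
            par = _check(sbml_model.createParameter(), "bound parameter")
            par.setId(f"bnd_{i}_{suffix}")
            par.setValue(value)
            par.setConstant(True)

    rid_map: Dict[str, str] = {}
    for i, rxn in enumerate(model.reactions):
        rx = _check(sbml_model.createReaction(), f"reaction {rxn.id}")
        sid = "R_" + _sid(rxn.id)
        rid_map[rxn.id] = sid
        rx.setId(sid)
        rx.setName(rxn.id)
        rx.setFast(False)
        rx.setReversible(rxn.lower_bound < 0)
        for met, coef in rxn.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(id_map[met])
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(f"bnd_{i}_lb")
        rplug.setUpperFluxBound(f"bnd_{i}_ub")
        if rxn.gpr.strip():
            gpa = rplug.createGeneProductAssociation()
            infix = _gpr_infix(parse_gpr(rxn.gpr), lambda g: "G_" + _sid(g))
            if gpa.setAssociation(infix, True, False) != libsbml.LIBSBML_OPERATION_SUCCESS:
                raise RuntimeError(f"could not encode GPR for {rxn.id!r}: {rxn.gpr!r}")
        if rxn.id == model.atp_maintenance_reaction:
            rx.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'><p>{_MAINT_NOTE}</p></body>")

    obj = _check(mplug.createObjective(), "objective")
    obj.setId("obj")
    obj.setType("maximize")
    mplug.setActiveObjectiveId("obj")
    fo = _check(obj.createFluxObjective(), "flux objective")
    fo.setReaction(rid_map[model.objective_reaction])
    fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise RuntimeError(f"could not write SBML to {path}")


def _parse_formula(s: str) -> Dict[str, float]:
    import re

    out: Dict[str, float] = {}
    for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", s):
        if el:
            out[el] = out.get(el, 0.0) + (float(num) if num else 1.0)
    return out


def read_sbml_model(path) -> MetabolicModel:
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(f"SBML parse error in {path}: "
                         f"{doc.getErrorLog().toString()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"no model element in {path}")
    mplug = sbml_model.getPlugin("fbc")

    gene_labels: Dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    metabolites = []
    met_names: Dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        name = sp.getName() or sp.getId()
        met_names[sp.getId()] = name
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = _parse_formula(splug.getChemicalFormula())
        metabolites.append(Metabolite(name, formula))

    def _gpa_to_infix(assoc) -> str:
        if assoc is None:
            return ""
        if assoc.isGeneProductRef():
            return gene_labels.get(assoc.getGeneProduct(), assoc.getGeneProduct())
        parts = [
            _gpa_to_infix(assoc.getAssociation(j))
            for j in range(assoc.getNumAssociations())
        ]
        joiner = " and " if assoc.isFbcAnd() else " or "
        return "(" + joiner.join(parts) + ")"

    reactions = []
    maint_id = None
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        name = rx.getName() or rx.getId()
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            met = met_names[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            met = met_names[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        lb, ub = -1000.0, 1000.0
        gpr = ""
        rplug = rx.getPlugin("fbc")
        if rplug is not None:
            lb_par = sbml_model.getParameter(rplug.getLowerFluxBound())
            ub_par = sbml_model.getParameter(rplug.getUpperFluxBound())
            if lb_par is not None:
                lb = lb_par.getValue()
            if ub_par is not None:
                ub = ub_par.getValue()
            if rplug.isSetGeneProductAssociation():
                gpr = _gpa_to_infix(rplug.getGeneProductAssociation().getAssociation())
        if rx.isSetNotes() and _MAINT_NOTE in rx.getNotesString():
            maint_id = name
        reactions.append(Reaction(name, stoich, lb, ub, gpr))

    objective_reaction = reactions[0].id if reactions else ""
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId()) or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            target = obj.getFluxObjective(0).getReaction()
            rx = sbml_model.getReaction(target)
            if rx is not None:
                objective_reaction = rx.getName() or rx.getId()

    return MetabolicModel(
        reactions=reactions,
        metabolites=metabolites,
        objective_reaction=objective_reaction,
        atp_maintenance_reaction=maint_id,
        id=sbml_model.getId() or "model",
    )
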