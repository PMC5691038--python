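"""SBML Level 3 (fbc) import/export via python-libsbml.

Round-trip preserves metabolite/reaction/gene counts, stoichiometry, flux
bounds, objective coefficients and GPR structure.  Only SBML Level 3 is
accepted; other levels raise with the offending level named.
"""

from __future__ import annotations

from pathlib import Path

import libsbml

from .core import (DEFAULT_LB, DEFAULT_UB, MetabolicModel, Metabolite,
                   Reaction, parse_formula)
from .gpr import GprNode


class SBMLError(ValueError):
    pass


# COBRA community convention: SBML SIds are prefixed M_/R_/G_ (also
# keeping ids like "13dpg" legal, since SIds may not start with a digit)
_PREFIXES = {"species": "M_", "reaction": "R_", "gene": "G_"}


def _sid(kind: str, raw: str) -> str:
    sid = "".join(ch if ch.isalnum() or ch == "_" else "__" for ch in raw)
    return _PREFIXES[kind] + sid


def _strip_sid(kind: str, sid: str) -> str:
    prefix = _PREFIXES[kind]
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _gpr_from_association(assoc) -> GprNode | None:
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        return GprNode("gene", gene=_strip_sid("gene", assoc.getGeneProduct()))
    children = tuple(_gpr_from_association(assoc.getAssociation(i))
                     for i in range(assoc.getNumAssociations()))
    children = tuple(c for c in children if c is not None)
    if not children:
        return None
    if assoc.isFbcAnd():
        return GprNode("and", children=children)
    if assoc.isFbcOr():
        return GprNode("or", children=children)
    raise SBMLError("unsupported gene association node")


def _association_from_gpr(gpa, node: GprNode, parent=None):
    if parent is None:
        if node.kind == "gene":
            ref = gpa.createGeneProductRef()
            ref.setGeneProduct(_sid("gene", node.gene))
            return
        parent = gpa.createAnd() if node.kind == "and" else gpa.createOr()
        for c in node.children:
            _association_from_gpr(gpa, c, parent)
        return
    if node.kind == "gene":
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(_sid("gene", node.gene))
    else:
        sub = parent.createAnd() if node.kind == "and" else parent.createOr()
        for c in node.children:
            _association_from_gpr(gpa, c, sub)


def read_sbml(path: str | Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None:
        raise SBMLError(f"could not parse SBML file {path}")
    if doc.getLevel() != 3:
        raise SBMLError(f"unsupported SBML level {doc.getLevel()} "
                        f"(only Level 3 is supported)")
    sb = doc.getModel()
    fbc = sb.getPlugin("fbc")
    model = MetabolicModel(id=sb.getId() or "model")
    model.compartments = {sb.getCompartment(i).getId():
                          sb.getCompartment(i).getName() or sb.getCompartment(i).getId()
                          for i in range(sb.getNumCompartments())}
    if not model.compartments:
        model.compartments = {"c": "cytosol"}
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        sfbc = sp.getPlugin("fbc")
        formula = None
        charge = None
        if sfbc is not None:
            if sfbc.isSetChemicalFormula():
                formula = parse_formula(sfbc.getChemicalFormula())
            if sfbc.isSetCharge():
                charge = sfbc.getCharge()
        model.add_metabolite(Metabolite(id=_strip_sid("species", sp.getId()),
                                        name=sp.getName(),
                                        compartment=sp.getCompartment() or "c",
                                        formula=formula, charge=charge))
    # fbc v2 flux bounds live in global parameters
    params = {sb.getParameter(i).getId(): sb.getParameter(i).getValue()
              for i in range(sb.getNumParameters())}
    objective_coefs: dict[str, float] = {}
    if fbc is not None and fbc.getActiveObjective() is not None:
        active = fbc.getActiveObjective()
        for i in range(active.getNumFluxObjectives()):
            fo = active.getFluxObjective(i)
            objective_coefs[_strip_sid("reaction", fo.getReaction())] = \
                fo.getCoefficient()
    biomass_id = None
    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            met = _strip_sid("species", sr.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            met = _strip_sid("species", sr.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + sr.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        lb = ub = None
        gpr = None
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = params.get(rfbc.getLowerFluxBound())
            if rfbc.isSetUpperFluxBound():
                ub = params.get(rfbc.getUpperFluxBound())
            gpa = rfbc.getGeneProductAssociation()
            if gpa is not None:
                gpr = _gpr_from_association(gpa.getAssociation())
        reversible = rx.getReversible()
        if lb is None:
            lb = DEFAULT_LB if reversible else 0.0
        if ub is None:
            ub = DEFAULT_UB
        rid = _strip_sid("reaction", rx.getId())
        coef = objective_coefs.get(rid, 0.0)
        model.add_reaction(Reaction(id=rid, name=rx.getName(),
                                    stoichiometry=stoich, lower_bound=lb,
                                    upper_bound=ub, objective_coefficient=coef,
                                    gpr=gpr))
        if coef:
            biomass_id = rid
    model.biomass_reaction_id = biomass_id
    return model


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(model.id)
    fbc = sb.getPlugin("fbc")
    fbc.setStrict(True)
    for cid, cname in model.compartments.items():
        comp = sb.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)
    for m in model.metabolites:
        sp = sb.createSpecies()
        sp.setId(_sid("species", m.id))
        sp.setName(m.name or m.id)
        sp.setCompartment(m.compartment)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sfbc = sp.getPlugin("fbc")
        # fbc only admits integral formulas/charges; pseudo-species with
        # fractional composition stay formula-free in the export
        if m.formula is not None and all(
                float(n).is_integer() for n in m.formula.values()):
            sfbc.setChemicalFormula("".join(
                f"{e}{int(n)}" if n != 1 else e for e, n in m.formula.items()))
        if m.charge is not None and float(m.charge).is_integer():
            sfbc.setCharge(int(m.charge))
    # gene products
    for gene in sorted(model.genes):
        gp = fbc.createGeneProduct()
        gp.setId(_sid("gene", gene))
        gp.setLabel(gene)
    # parameters for every distinct bound
    bound_param: dict[float, str] = {}

    def param_for(value: float) -> str:
        if value not in bound_param:
            pid = f"fb_{len(bound_param)}"
            p = sb.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_param[value] = pid
        return bound_param[value]

    obj = fbc.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fbc.setActiveObjectiveId("obj")
    for r in model.reactions:
        rx = sb.createReaction()
        rx.setId(_sid("reaction", r.id))
        rx.setName(r.name or r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for met, coef in r.stoichiometry.items():
            sr = rx.createReactant() if coef < 0 else rx.createProduct()
            sr.setSpecies(_sid("species", met))
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(param_for(r.lower_bound))
        rfbc.setUpperFluxBound(param_for(r.upper_bound))
        if r.gpr is not None:
            gpa = rfbc.createGeneProductAssociation()
            _association_from_gpr(gpa, r.gpr)
        if r.objective_coefficient:
            fo = obj.createFluxObjective()
            fo.setReaction(_sid("reaction", r.id))
            fo.setCoefficient(r.objective_coefficient)
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:  # pragma: no cover
        raise SBMLError(f"failed to write SBML to {path}")
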