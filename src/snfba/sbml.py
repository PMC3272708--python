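"""SBML import/export built on python-libsbml.

Export writes SBML Level 3 Version 1 with the ``fbc`` (v2) package: flux
bounds as shared parameters, GPRs as ``fbc:geneProductAssociation`` trees and
the objective as an fbc maximisation objective. Reaction subsystem and kind
are kept in the notes body (``SUBSYSTEM:`` / ``KIND:`` lines).

Import accepts the same dialect and falls back to the legacy COBRA
conventions used by pre-fbc models (notes-encoded ``GENE_ASSOCIATION`` /
``SUBSYSTEM`` lines and ``LOWER_BOUND`` / ``UPPER_BOUND`` kinetic-law
parameters), so 2012-era published models load without modification.

Native metabolite ids carry ``[c]``/``[e]`` suffixes; SBML species store the
compartment as an attribute and the suffix is regenerated on import.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional

import libsbml

from .gpr import And, Gene, GprTree, Or, gpr_to_string, parse_gpr
from .model import (DEFAULT_BOUND, OBJECTIVE_ID_PREFIXES, Metabolite, Model,
                    Reaction, ReactionKind, assert_valid, validate_model)


class SbmlReadError(ValueError):
    pass


class SbmlWriteError(ValueError):
    pass


_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(text: str) -> str:
    out = _SID_BAD.sub("_", text)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def _split_suffix(met_id: str) -> (str, Optional[str]):
    m = re.match(r"^(.*)\[([a-zA-Z0-9]+)\]$", met_id)
    if m:
        return m.group(1), m.group(2)
    return met_id, None


# -- export ---------------------------------------------------------------

def _gpr_to_fbc(tree: GprTree, parent, fbc_rxn=None):
    if isinstance(tree, Gene):
        ref = (fbc_rxn.createGeneProductAssociation().createGeneProductRef()
               if fbc_rxn is not None else parent.createGeneProductRef())
        ref.setGeneProduct("G_" + _sid(tree.gene))
        return
    if fbc_rxn is not None:
        gpa = fbc_rxn.createGeneProductAssociation()
        node = (gpa.createAnd() if isinstance(tree, And) else gpa.createOr())
    else:
        node = (parent.createAnd() if isinstance(tree, And)
                else parent.createOr())
    for child in tree.children:
        if isinstance(child, Gene):
            ref = node.createGeneProductRef()
            ref.setGeneProduct("G_" + _sid(child.gene))
        else:
            _gpr_to_fbc(child, node)


def write_sbml(model: Model, path: str) -> None:
    """Write ``model`` as SBML L3V1+fbc. The model is validated first."""
    assert_valid(model)

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid(model.id))
    sm.setName(model.name)
    fbc_model = sm.getPlugin("fbc")
    fbc_model.setStrict(False)

    for comp_id in ("c", "e"):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setName({"c": "cytosol", "e": "extracellular"}[comp_id])
        comp.setConstant(True)

    for met in model.metabolites:
        base, suffix = _split_suffix(met.id)
        sp = sm.createSpecies()
        sp.setId("M_" + _sid(base) + "_" + met.compartment)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)

    # shared flux-bound parameters, one per distinct value
    bound_param: Dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_param:
            pid = f"FB_{len(bound_param)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_param[value] = pid
        return bound_param[value]

    for gene in model.genes:
        gp = fbc_model.createGeneProduct()
        gp.setId("G_" + _sid(gene))
        gp.setLabel(gene)

    met_sid = {m.id: "M_" + _sid(_split_suffix(m.id)[0]) + "_" + m.compartment
               for m in model.metabolites}

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId("R_" + _sid(rxn.id))
        sr.setName(rxn.name)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        for met_id, coef in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(met_sid[met_id])
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        fbc_rxn = sr.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(bound_id(rxn.lower_bound))
        fbc_rxn.setUpperFluxBound(bound_id(rxn.upper_bound))
        if rxn.gpr is not None:
            _gpr_to_fbc(rxn.gpr, None, fbc_rxn=fbc_rxn)
        notes = [f"KIND: {rxn.kind.value}"]
        if rxn.subsystem:
            notes.append(f"SUBSYSTEM: {rxn.subsystem}")
        body = "".join(f"<p>{n}</p>" for n in notes)
        sr.setNotes(
            f'<notes><body xmlns="http://www.w3.org/1999/xhtml">{body}'
            f"</body></notes>")

    objective = fbc_model.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fbc_model.setActiveObjectiveId("obj")
    for rid in model.objective_reaction_ids:
        fo = objective.createFluxObjective()
        fo.setReaction("R_" + _sid(rid))
        fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise SbmlWriteError(f"could not write SBML to {path!r}")


# -- import ---------------------------------------------------------------

def _notes_text(element) -> str:
    if not element.isSetNotes():
        return ""
    return element.getNotesString()


_NOTE_LINE = re.compile(r"([A-Z_]+)\s*:\s*([^<]*)")


def _parse_notes(element) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for key, value in _NOTE_LINE.findall(_notes_text(element)):
        out[key.strip()] = value.strip()
    return out


def _fbc_assoc_to_tree(assoc) -> Optional[GprTree]:
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gp = assoc.getGeneProduct()
        return Gene(_GENE_LABELS.get(gp, gp[2:] if gp.startswith("G_") else gp))
    children = [_fbc_assoc_to_tree(assoc.getAssociation(i))
                for i in range(assoc.getNumAssociations())]
    children = [c for c in children if c is not None]
    if len(children) == 1:
        return children[0]
    if assoc.isFbcAnd():
        return And(tuple(children))
    return Or(tuple(children))


_GENE_LABELS: Dict[str, str] = {}


def _species_to_native_id(sp) -> str:
    sid = sp.getId()
    comp = sp.getCompartment() or "c"
    base = sid
    if base.startswith("M_"):
        base = base[2:]
    if base.endswith("_" + comp):
        base = base[: -(len(comp) + 1)]
    return f"{base}[{comp}]"


def read_sbml(path: str) -> Model:
    """Read an SBML file (fbc or legacy notes dialect) into a :class:`Model`.

    Raises :class:`SbmlReadError` naming the first offending element on
    malformed XML, and a validation error listing dangling species ids.
    """
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise SbmlReadError(
                    f"SBML parse error in {path!r} (line {err.getLine()}): "
                    f"{err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise SbmlReadError(f"{path!r} contains no SBML model element")

    fbc_model = sm.getPlugin("fbc")
    model = Model(id=sm.getId() or "model", name=sm.getName() or "")

    known_species = set()
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        known_species.add(sp.getId())
        comp = sp.getCompartment() or "c"
        model.metabolites.append(Metabolite(
            id=_species_to_native_id(sp),
            name=sp.getName() or sp.getId(),
            compartment=comp if comp in ("c", "e") else "c",
            formula=(sp.getPlugin("fbc").getChemicalFormula() or None
                     if sp.getPlugin("fbc") is not None else None),
        ))
    native_of = {}
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        native_of[sp.getId()] = _species_to_native_id(sp)

    _GENE_LABELS.clear()
    genes: List[str] = []
    if fbc_model is not None:
        for i in range(fbc_model.getNumGeneProducts()):
            gp = fbc_model.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            if label.startswith("G_") and not gp.getLabel():
                label = label[2:]
            _GENE_LABELS[gp.getId()] = label
            genes.append(label)

    param_value = {}
    for i in range(sm.getNumParameters()):
        par = sm.getParameter(i)
        param_value[par.getId()] = par.getValue()

    objective_ids: List[str] = []
    if fbc_model is not None and fbc_model.getActiveObjective() is not None:
        obj = fbc_model.getActiveObjective()
        for i in range(obj.getNumFluxObjectives()):
            rid = obj.getFluxObjective(i).getReaction()
            objective_ids.append(rid[2:] if rid.startswith("R_") else rid)

    dangling: List[str] = []
    ecomp_singletons = set()
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = sr.getId()
        native_rid = rid[2:] if rid.startswith("R_") else rid
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            sid = ref.getSpecies()
            if sid not in known_species:
                dangling.append(sid)
                continue
            mid = native_of[sid]
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            sid = ref.getSpecies()
            if sid not in known_species:
                dangling.append(sid)
                continue
            mid = native_of[sid]
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()

        notes = _parse_notes(sr)
        gpr: Optional[GprTree] = None
        fbc_rxn = sr.getPlugin("fbc")
        if fbc_rxn is not None and fbc_rxn.isSetGeneProductAssociation():
            gpr = _fbc_assoc_to_tree(
                fbc_rxn.getGeneProductAssociation().getAssociation())
        elif "GENE_ASSOCIATION" in notes and notes["GENE_ASSOCIATION"]:
            gpr = parse_gpr(notes["GENE_ASSOCIATION"])

        lb = ub = None
        if fbc_rxn is not None and fbc_rxn.isSetLowerFluxBound():
            lb = param_value.get(fbc_rxn.getLowerFluxBound())
        if fbc_rxn is not None and fbc_rxn.isSetUpperFluxBound():
            ub = param_value.get(fbc_rxn.getUpperFluxBound())
        if (lb is None or ub is None) and sr.isSetKineticLaw():
            kl = sr.getKineticLaw()
            for j in range(kl.getNumParameters()):
                par = kl.getParameter(j)
                if par.getId() == "LOWER_BOUND":
                    lb = par.getValue()
                elif par.getId() == "UPPER_BOUND":
                    ub = par.getValue()
                elif par.getId() == "OBJECTIVE_COEFFICIENT" and \
                        par.getValue() not in (0, 0.0):
                    objective_ids.append(native_rid)
        if lb is None:
            lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
        if ub is None:
            ub = DEFAULT_BOUND

        comp_of = {m.id: m.compartment for m in model.metabolites}
        if "KIND" in notes:
            kind = ReactionKind(notes["KIND"])
        elif any(native_rid.startswith(p) for p in OBJECTIVE_ID_PREFIXES):
            kind = ReactionKind.OBJECTIVE_PSEUDO
        elif len(stoich) == 1 and \
                comp_of.get(next(iter(stoich), "")) == "e":
            kind = ReactionKind.EXCHANGE
        else:
            kind = ReactionKind.INTERNAL

        rxn = Reaction(
            id=native_rid, name=sr.getName() or native_rid,
            stoichiometry=stoich, lower_bound=float(lb), upper_bound=float(ub),
            gpr=gpr, subsystem=notes.get("SUBSYSTEM") or None, kind=kind)
        model.reactions.append(rxn)
        if kind is ReactionKind.EXCHANGE:
            ecomp_singletons.add(native_rid)

    if dangling:
        raise SbmlReadError(
            f"{path!r}: reactions reference undeclared species: "
            f"{sorted(set(dangling))}")

    for rxn in model.reactions:
        for g in sorted(rxn.genes):
            if g not in genes:
                genes.append(g)
    model.genes = genes
    model.objective_reaction_ids = list(dict.fromkeys(objective_ids))

    violations = validate_model(model)
    if violations:
        raise SbmlReadError(
            f"{path!r} read but failed validation:\n  "
            + "\n  ".join(violations))
    return model
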