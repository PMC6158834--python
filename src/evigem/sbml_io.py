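"""Reading and writing SBML Level 3 (+ flux-balance extension) models.

Uses libSBML. Flux bounds are fbc flux-bound parameters, the objective is
an fbc objective, GPRs are fbc gene-product associations, ChEBI accessions
travel as MIRIAM identifier URIs in RDF annotations. Evidence items, test
cases and subsystem labels are embedded in a model-level annotation in the
``urn:evigem:evidence:1`` namespace (see :mod:`evigem.evidence`) — extra
information the SBML standard tolerates without breaking validity.

Gene products: SBML SIds may not start with a digit, but strain transcript
ids (JGI Aspni7 numbers) must survive verbatim, so the fbc ``id`` is a
sanitized token and the verbatim gene id is stored in the fbc ``label``;
reading prefers the label.

Boundary reactions may be encoded one-sided (canonical write form, e.g.
``A ->``) or with an explicit external species flagged
``boundaryCondition=true``; the reader accepts both and records which was
seen on ``model.boundary_encoding_seen``.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Sequence, Tuple

import libsbml

from .evidence import (
    EvidenceItem,
    ParseReport,
    TestCase,
    parse_annotation,
    serialize_annotation,
)
from .gpr import GPR, BoolOp, GeneRef, GPRNode
from .model import Compartment, Gene, Metabolite, MetabolicModel, Reaction

__all__ = ["read_sbml", "write_sbml", "SBMLReadError", "models_equal"]

FBC_URI = "http://www.sbml.org/sbml/level3/version1/fbc/version2"
_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_CHEBI_URI_RE = re.compile(r"(CHEBI[:%3A]+\d+)", re.IGNORECASE)


class SBMLReadError(ValueError):
    """Malformed or non-conforming SBML input; message names the defect."""


def _check(value: int, what: str) -> None:
    if value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(f"libSBML call failed ({value}): {what}")


def _sanitize_gene_id(gene_id: str, taken: Dict[str, str]) -> str:
    base = "G_" + re.sub(r"[^A-Za-z0-9_]", "_", gene_id)
    candidate = base
    n = 1
    while candidate in taken and taken[candidate] != gene_id:
        n += 1
        candidate = f"{base}__{n}"
    taken[candidate] = gene_id
    return candidate


# ---------------------------------------------------------------------------
# writing


def _build_association(
    node: GPRNode, parent, gene_sid: Dict[str, str]
) -> None:
    if isinstance(node, GeneRef):
        ref = parent.createGeneProductRef()
        _check(ref.setGeneProduct(gene_sid[node.gene]), f"gene ref {node.gene}")
    elif isinstance(node, BoolOp):
        assoc = parent.createAnd() if node.op == "and" else parent.createOr()
        for child in node.children:
            _build_association(child, assoc, gene_sid)
    else:  # pragma: no cover - defensive
        raise TypeError(f"unknown GPR node {node!r}")


def write_sbml(
    model: MetabolicModel,
    path: str,
    evidences: Sequence[EvidenceItem] = (),
    tests: Sequence[TestCase] = (),
) -> None:
    """Write `model` (plus embedded evidence/tests) as SBML L3V1 + fbc v2.

    Refuses with a diagnostic if the model violates its invariants or if a
    metabolite/reaction id is not a valid SBML SId.
    """
    model.require_valid()
    for coll, kind in ((model.metabolites, "metabolite"), (model.reactions, "reaction"),
                       (model.compartments, "compartment")):
        for oid in coll:
            if not _SID_RE.match(oid):
                raise ValueError(
                    f"{kind} id {oid!r} is not a valid SBML SId; rename before writing"
                )

    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    _check(sm.setId(model.id or "model"), "model id")
    if model.name:
        sm.setName(model.name)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for c in model.compartments.values():
        sc = sm.createCompartment()
        _check(sc.setId(c.id), f"compartment {c.id}")
        sc.setName(c.name)
        sc.setConstant(True)

    for m in model.metabolites.values():
        sp = sm.createSpecies()
        _check(sp.setId(m.id), f"species {m.id}")
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(m.is_boundary_species)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if m.formula is not None:
            splug.setChemicalFormula(m.formula)
        if m.charge is not None:
            splug.setCharge(int(m.charge))
        if m.chebi is not None:
            sp.setMetaId(f"meta_{m.id}")
            cv = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
            cv.setBiologicalQualifierType(libsbml.BQB_IS)
            cv.addResource(f"http://identifiers.org/chebi/{m.chebi}")
            _check(sp.addCVTerm(cv), f"ChEBI annotation for {m.id}")

    gene_sid: Dict[str, str] = {}
    taken: Dict[str, str] = {}
    for g in model.genes.values():
        sid = _sanitize_gene_id(g.id, taken)
        gene_sid[g.id] = sid
        gp = mplug.createGeneProduct()
        _check(gp.setId(sid), f"gene product {g.id}")
        gp.setLabel(g.id)
        if g.name:
            gp.setName(g.name)

    for r in model.reactions.values():
        for tag, value in (("lower", r.lower_bound), ("upper", r.upper_bound)):
            p = sm.createParameter()
            _check(p.setId(f"{r.id}_{tag}_bound"), f"bound parameter for {r.id}")
            p.setValue(float(value))
            p.setConstant(True)
        sr = sm.createReaction()
        _check(sr.setId(r.id), f"reaction {r.id}")
        sr.setName(r.name)
        sr.setReversible(r.lower_bound < 0)
        sr.setFast(False)
        for met, coeff in r.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(f"{r.id}_lower_bound")
        rplug.setUpperFluxBound(f"{r.id}_upper_bound")
        if not r.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            _build_association(r.gpr.root, gpa, gene_sid)

    if model.objective:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType(model.objective_sense)
        for rid, weight in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(float(weight))
        mplug.setActiveObjectiveId("obj")

    subsystems = {
        r.id: r.subsystem for r in model.reactions.values() if r.subsystem is not None
    }
    if evidences or tests or subsystems:
        xml = serialize_annotation(evidences, tests, subsystems)
        _check(sm.appendAnnotation(xml), "evidence annotation")

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise IOError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# reading


def _parse_association(assoc, label_of: Dict[str, str]) -> GPRNode:
    if assoc.isGeneProductRef():
        sid = assoc.getGeneProduct()
        return GeneRef(label_of.get(sid, sid))
    op = "and" if assoc.isFbcAnd() else "or"
    children = tuple(
        _parse_association(assoc.getAssociation(i), label_of)
        for i in range(assoc.getNumAssociations())
    )
    if len(children) == 1:  # degenerate nesting some writers emit
        return children[0]
    return BoolOp(op, children)


def _species_chebi(sp) -> Optional[str]:
    for i in range(sp.getNumCVTerms()):
        term = sp.getCVTerm(i)
        for j in range(term.getNumResources()):
            m = _CHEBI_URI_RE.search(term.getResourceURI(j))
            if m:
                acc = m.group(1).upper().replace("%3A", ":")
                if not acc.startswith("CHEBI:"):
                    acc = "CHEBI:" + acc.split(":")[-1]
                return acc
    return None


def read_sbml(path: str) -> Tuple[MetabolicModel, List[EvidenceItem], List[TestCase], ParseReport]:
    """Read an SBML L3 + fbc file into a fully cross-referenced model.

    Returns ``(model, evidence items, test cases, parse report)``. Raises
    :class:`SBMLReadError` naming the line for malformed XML and listing
    offending ids for unresolved references.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLReadError(
                f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
            )
    sm = doc.getModel()
    if sm is None:
        raise SBMLReadError(f"no <model> element in {path}")
    if sm.getLevel() < 3:
        raise SBMLReadError(f"expected SBML Level 3, got Level {sm.getLevel()}")
    mplug = sm.getPlugin("fbc")
    if mplug is None:
        raise SBMLReadError("missing flux-balance (fbc) extension")

    model = MetabolicModel(id=sm.getId() or "model", name=sm.getName() or "")

    for i in range(sm.getNumCompartments()):
        sc = sm.getCompartment(i)
        model.compartments[sc.getId()] = Compartment(sc.getId(), sc.getName() or "")

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.metabolites[sp.getId()] = Metabolite(
            id=sp.getId(),
            compartment=sp.getCompartment(),
            name=sp.getName() or "",
            formula=formula,
            charge=charge,
            chebi=_species_chebi(sp),
            is_boundary_species=sp.getBoundaryCondition(),
        )

    label_of: Dict[str, str] = {}
    for i in range(mplug.getNumGeneProducts()):
        gp = mplug.getGeneProduct(i)
        verbatim = gp.getLabel() if gp.isSetLabel() and gp.getLabel() else gp.getId()
        label_of[gp.getId()] = verbatim
        model.genes[verbatim] = Gene(verbatim, gp.getName() or "")

    param_value = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    unresolved: List[str] = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        for met in stoich:
            if met not in model.metabolites:
                unresolved.append(f"reaction {sr.getId()!r} -> species {met!r}")
        rplug = sr.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = param_value.get(rplug.getLowerFluxBound(), lb)
        if rplug is not None and rplug.isSetUpperFluxBound():
            ub = param_value.get(rplug.getUpperFluxBound(), ub)
        gpr = GPR()
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gpr = GPR(_parse_association(assoc, label_of))
        model.reactions[sr.getId()] = Reaction(
            id=sr.getId(),
            name=sr.getName() or "",
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
        )
        for g in gpr.genes():
            if g not in model.genes:
                model.genes[g] = Gene(g)

    if unresolved:
        raise SBMLReadError("unresolved references:\n  " + "\n  ".join(unresolved))

    obj = mplug.getActiveObjective() if mplug.getNumObjectives() else None
    if obj is not None:
        model.objective_sense = (
            "maximize" if obj.getType() in ("maximize", "") else "minimize"
        )
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            if fo.getReaction() not in model.reactions:
                raise SBMLReadError(
                    f"objective references missing reaction {fo.getReaction()!r}"
                )
            model.objective[fo.getReaction()] = fo.getCoefficient()

    model.infer_boundary_flags()
    encodings = set()
    for r in model.boundary_reactions():
        if len(r.stoichiometry) == 1:
            encodings.add("one_sided")
        else:
            encodings.add("explicit_external")
    model.boundary_encoding_seen = (
        "mixed" if len(encodings) > 1 else (encodings.pop() if encodings else None)
    )

    evidences: List[EvidenceItem] = []
    tests: List[TestCase] = []
    report = ParseReport()
    ann = sm.getAnnotationString() if sm.isSetAnnotation() else ""
    if ann:
        try:
            evidences, tests, subsystems, report = parse_annotation(ann)
        except Exception as exc:  # annotation problems never abort a read
            report.malformed_blocks += 1
            report.warn(f"model annotation unparseable: {exc}")
            subsystems = {}
        for rid, label in subsystems.items():
            if rid in model.reactions:
                model.reactions[rid].subsystem = label
            else:
                report.warn(f"subsystem label for unknown reaction {rid!r}")
    return model, evidences, tests, report


# ---------------------------------------------------------------------------
# structural equality (round-trip checks)


def models_equal(a: MetabolicModel, b: MetabolicModel) -> List[str]:
    """Field-by-field comparison; returns a list of differences (empty = equal)."""
    diffs: List[str] = []
    for attr in ("compartments", "metabolites", "reactions", "genes"):
        ka, kb = set(getattr(a, attr)), set(getattr(b, attr))
        if ka != kb:
            diffs.append(f"{attr} ids differ: only-a={sorted(ka - kb)} only-b={sorted(kb - ka)}")
    for cid in set(a.compartments) & set(b.compartments):
        if a.compartments[cid].name != b.compartments[cid].name:
            diffs.append(f"compartment {cid}: name differs")
    for mid in set(a.metabolites) & set(b.metabolites):
        ma, mb = a.metabolites[mid], b.metabolites[mid]
        for f in ("name", "compartment", "formula", "charge", "chebi", "is_boundary_species"):
            if getattr(ma, f) != getattr(mb, f):
                diffs.append(f"metabolite {mid}: {f} {getattr(ma, f)!r} != {getattr(mb, f)!r}")
    for rid in set(a.reactions) & set(b.reactions):
        ra, rb = a.reactions[rid], b.reactions[rid]
        if ra.stoichiometry != rb.stoichiometry:
            diffs.append(f"reaction {rid}: stoichiometry differs")
        if (ra.lower_bound, ra.upper_bound) != (rb.lower_bound, rb.upper_bound):
            diffs.append(f"reaction {rid}: bounds differ")
        if ra.gpr != rb.gpr:
            diffs.append(f"reaction {rid}: GPR {ra.gpr.to_string()!r} != {rb.gpr.to_string()!r}")
        if ra.subsystem != rb.subsystem:
            diffs.append(f"reaction {rid}: subsystem differs")
        if ra.name != rb.name:
            diffs.append(f"reaction {rid}: name differs")
    if a.objective != b.objective or a.objective_sense != b.objective_sense:
        diffs.append("objective differs")
    return diffs
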