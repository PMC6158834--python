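"""Literature evidence items and phenotype test cases, and their SBML
annotation serialization.

The central idea is that curation data travels *inside* the model file: an
SBML annotation element (which the standard allows to carry arbitrary
namespaced XML without breaking format compliance) holds

* evidence items — referenced assertions about model structure: a gene
  catalyzes (or does not catalyze) a reaction, a reaction or metabolite is
  present/absent in the organism, a gene product localizes to a
  compartment — each tagged with an Evidence and Conclusion Ontology (ECO)
  accession and literature references;
* test cases — stored phenotype experiments: boundary-bound overrides
  describing the medium, a set of deleted genes, and flux-threshold
  outcomes the simulated model must satisfy.

The dialect lives in the namespace ``urn:evigem:evidence:1`` and is
documented element-by-element in docs/methods.md; serialization round-trips
exactly. Unknown assertion kinds and malformed blocks are preserved or
counted, never fatal: a model read must always succeed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from lxml import etree

__all__ = [
    "Reference",
    "EvidenceItem",
    "Outcome",
    "TestCase",
    "ParseReport",
    "ASSERTION_KINDS",
    "EVIDENCE_NS",
    "evidence_census",
    "serialize_annotation",
    "parse_annotation",
    "evidence_table",
]

EVIDENCE_NS = "urn:evigem:evidence:1"
_E = "{%s}" % EVIDENCE_NS

REFERENCE_KINDS = ("pubmed", "doi", "pmc", "patent", "url")

#: the seven supported assertion kinds
ASSERTION_KINDS = (
    "gene_catalyzes_reaction",
    "gene_not_catalyzes_reaction",
    "reaction_present",
    "reaction_absent",
    "metabolite_present",
    "metabolite_absent",
    "gene_localizes_to_compartment",
)

#: assertion kind -> census family (Table-2 style blocks)
ASSERTION_FAMILY = {
    "gene_catalyzes_reaction": "gene_reaction",
    "gene_not_catalyzes_reaction": "gene_reaction",
    "reaction_present": "reaction_presence",
    "reaction_absent": "reaction_presence",
    "metabolite_present": "metabolite_presence",
    "metabolite_absent": "metabolite_presence",
    "gene_localizes_to_compartment": "localization",
}

_ECO_RE = re.compile(r"^ECO:\d{7}$")

#: ECO codes that denote computational predictions and therefore do not
#: require a literature reference (match on these prefixes of meaning is
#: handled by the rank table in model_qc; here only the reference rule).
PREDICTION_ECO = frozenset({
    "ECO:0000255",  # match to sequence model
    "ECO:0000259",  # match to InterPro signature
    "ECO:0000266",  # sequence orthology
    "ECO:0000250",  # sequence similarity
    "ECO:0000031",  # BLAST evidence
    "ECO:0000044",  # sequence similarity evidence
    "ECO:0000053",  # computational combinatorial
    "ECO:0000501",  # inferred from electronic annotation
})


@dataclass(frozen=True)
class Reference:
    """A pointer to the literature source of an assertion."""

    kind: str
    value: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.kind or not self.value:
            raise ValueError("reference kind and value must be non-empty")
        if self.kind not in REFERENCE_KINDS:
            raise ValueError(f"unknown reference kind {self.kind!r}")


@dataclass(frozen=True)
class EvidenceItem:
    """One literature-backed assertion about model structure.

    `subject` is the gene/reaction/metabolite the assertion is about;
    `target` the reaction (for gene-reaction links) or compartment (for
    localization), empty otherwise.
    """

    id: str
    assertion: str
    subject: str
    target: str = ""
    eco_code: str = ""
    description: str = ""
    references: Tuple[Reference, ...] = ()

    def __post_init__(self) -> None:
        if self.assertion not in ASSERTION_KINDS:
            raise ValueError(f"unknown assertion kind {self.assertion!r}")
        if not self.subject:
            raise ValueError("evidence subject must be non-empty")
        needs_target = self.assertion in (
            "gene_catalyzes_reaction",
            "gene_not_catalyzes_reaction",
            "gene_localizes_to_compartment",
        )
        if needs_target and not self.target:
            raise ValueError(f"assertion {self.assertion!r} requires a target")
        if self.eco_code and not _ECO_RE.match(self.eco_code):
            raise ValueError(f"malformed ECO accession {self.eco_code!r}")
        if not self.references and self.eco_code not in PREDICTION_ECO:
            raise ValueError(
                f"evidence {self.id!r} needs at least one reference or a "
                f"prediction-type ECO code"
            )

    @property
    def family(self) -> str:
        return ASSERTION_FAMILY[self.assertion]


@dataclass(frozen=True)
class Outcome:
    """A flux-threshold check: reaction flux `cmp` (greater/less) `value`."""

    reaction: str
    cmp: str
    value: float

    def __post_init__(self) -> None:
        if self.cmp not in ("greater", "less"):
            raise ValueError(f"outcome comparator must be greater/less, got {self.cmp!r}")

    def holds(self, achieved: float) -> bool:
        return achieved > self.value if self.cmp == "greater" else achieved < self.value


@dataclass(frozen=True)
class TestCase:
    """A stored phenotype experiment.

    `settings` override boundary-reaction bounds (the medium); boundary
    reactions not listed are closed to uptake. `deleted_genes` are knocked
    out via the GPRs. All `outcomes` must hold for the test to pass.
    """

    __test__ = False  # not a pytest collection target

    id: str
    name: str = ""
    settings: Tuple[Tuple[str, float, float], ...] = ()
    deleted_genes: Tuple[str, ...] = ()
    outcomes: Tuple[Outcome, ...] = ()
    references: Tuple[Reference, ...] = ()
    method: Optional[str] = None  # per-test override: "fba" | "pfba"

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError(f"test case {self.id!r} needs at least one outcome")


@dataclass
class ParseReport:
    """Tally of annotation blocks that could not be fully interpreted."""

    unknown_assertion_kinds: int = 0
    malformed_blocks: int = 0
    messages: List[str] = field(default_factory=list)
    #: unknown-kind items preserved verbatim as (tag, attribute-dict)
    opaque_records: List[Tuple[str, Dict[str, str]]] = field(default_factory=list)

    def warn(self, msg: str) -> None:
        self.messages.append(msg)


# ---------------------------------------------------------------------------
# census


def evidence_census(items: Sequence[EvidenceItem]) -> Dict[str, int]:
    """Count items by assertion family; families sum to ``total``."""
    counts = {
        "gene_reaction": 0,
        "reaction_presence": 0,
        "metabolite_presence": 0,
        "localization": 0,
    }
    for item in items:
        counts[item.family] += 1
    counts["total"] = len(items)
    return counts


# ---------------------------------------------------------------------------
# XML serialization (the evigem dialect)


def _ref_el(parent: etree._Element, ref: Reference) -> None:
    etree.SubElement(
        parent,
        _E + "reference",
        kind=ref.kind,
        value=ref.value,
        description=ref.description,
    )


def serialize_annotation(
    evidences: Sequence[EvidenceItem],
    tests: Sequence[TestCase],
    subsystems: Optional[Dict[str, str]] = None,
) -> str:
    """Serialize evidence items and test cases to the dialect XML string.

    The returned element is suitable for embedding inside an SBML
    ``<annotation>``; `subsystems` optionally maps reaction id → pathway
    label (carried here so the SBML core stays untouched).
    """
    root = etree.Element(_E + "evidence", nsmap={"ev": EVIDENCE_NS})
    ev_list = etree.SubElement(root, _E + "listOfEvidenceItems")
    for item in evidences:
        el = etree.SubElement(
            ev_list,
            _E + "evidenceItem",
            id=item.id,
            assertion=item.assertion,
            subject=item.subject,
            target=item.target,
            eco=item.eco_code,
            description=item.description,
        )
        for ref in item.references:
            _ref_el(el, ref)
    tc_list = etree.SubElement(root, _E + "listOfTestCases")
    for test in tests:
        attrs = {"id": test.id, "name": test.name}
        if test.method:
            attrs["method"] = test.method
        el = etree.SubElement(tc_list, _E + "testCase", **attrs)
        for rid, lb, ub in test.settings:
            etree.SubElement(
                el, _E + "setting", reaction=rid, lowerBound=repr(lb), upperBound=repr(ub)
            )
        for g in test.deleted_genes:
            etree.SubElement(el, _E + "deletedGene", gene=g)
        for out in test.outcomes:
            etree.SubElement(
                el, _E + "outcome", reaction=out.reaction, cmp=out.cmp, value=repr(out.value)
            )
        for ref in test.references:
            _ref_el(el, ref)
    if subsystems:
        ss_list = etree.SubElement(root, _E + "listOfSubsystems")
        for rid, label in subsystems.items():
            etree.SubElement(ss_list, _E + "subsystem", reaction=rid, label=label)
    return etree.tostring(root, encoding="unicode", pretty_print=True)


def _parse_refs(el: etree._Element, report: ParseReport) -> Tuple[Reference, ...]:
    refs = []
    for r in el.findall(_E + "reference"):
        try:
            refs.append(
                Reference(
                    kind=r.get("kind", ""),
                    value=r.get("value", ""),
                    description=r.get("description", ""),
                )
            )
        except ValueError as exc:
            report.malformed_blocks += 1
            report.warn(f"bad reference skipped: {exc}")
    return tuple(refs)


def parse_annotation(
    xml_text: str,
) -> Tuple[List[EvidenceItem], List[TestCase], Dict[str, str], ParseReport]:
    """Parse the dialect from an annotation XML string.

    Returns (evidence items, test cases, reaction→subsystem map, report).
    Malformed blocks are recorded and skipped; this never raises for
    content errors, only for XML that does not parse at all.
    """
    report = ParseReport()
    root = etree.fromstring(xml_text.encode())
    # accept either the dialect root itself or a wrapper (e.g. <annotation>)
    if root.tag != _E + "evidence":
        found = root.find(".//" + _E + "evidence")
        if found is None:
            return [], [], {}, report
        root = found

    items: List[EvidenceItem] = []
    ev_list = root.find(_E + "listOfEvidenceItems")
    if ev_list is not None:
        for el in ev_list:
            if el.tag != _E + "evidenceItem":
                report.malformed_blocks += 1
                report.warn(f"unexpected element {el.tag!r} in evidence list")
                continue
            attrs = dict(el.attrib)
            if attrs.get("assertion") not in ASSERTION_KINDS:
                report.unknown_assertion_kinds += 1
                report.opaque_records.append((el.tag, attrs))
                report.warn(
                    f"unknown assertion kind {attrs.get('assertion')!r} preserved opaquely"
                )
                continue
            try:
                items.append(
                    EvidenceItem(
                        id=attrs.get("id", ""),
                        assertion=attrs["assertion"],
                        subject=attrs.get("subject", ""),
                        target=attrs.get("target", ""),
                        eco_code=attrs.get("eco", ""),
                        description=attrs.get("description", ""),
                        references=_parse_refs(el, report),
                    )
                )
            except ValueError as exc:
                report.malformed_blocks += 1
                report.warn(f"evidence item skipped: {exc}")

    tests: List[TestCase] = []
    tc_list = root.find(_E + "listOfTestCases")
    if tc_list is not None:
        for el in tc_list:
            if el.tag != _E + "testCase":
                report.malformed_blocks += 1
                report.warn(f"unexpected element {el.tag!r} in test-case list")
                continue
            try:
                settings = tuple(
                    (s.get("reaction"), float(s.get("lowerBound")), float(s.get("upperBound")))
                    for s in el.findall(_E + "setting")
                )
                outcomes = tuple(
                    Outcome(o.get("reaction"), o.get("cmp"), float(o.get("value")))
                    for o in el.findall(_E + "outcome")
                )
                tests.append(
                    TestCase(
                        id=el.get("id", ""),
                        name=el.get("name", ""),
                        settings=settings,
                        deleted_genes=tuple(
                            g.get("gene") for g in el.findall(_E + "deletedGene")
                        ),
                        outcomes=outcomes,
                        references=_parse_refs(el, report),
                        method=el.get("method"),
                    )
                )
            except (TypeError, ValueError) as exc:
                report.malformed_blocks += 1
                report.warn(f"test case {el.get('id')!r} skipped: {exc}")

    subsystems: Dict[str, str] = {}
    ss_list = root.find(_E + "listOfSubsystems")
    if ss_list is not None:
        for el in ss_list.findall(_E + "subsystem"):
            subsystems[el.get("reaction")] = el.get("label", "")

    return items, tests, subsystems, report


# ---------------------------------------------------------------------------
# tabular export


def evidence_table(items: Sequence[EvidenceItem]) -> pd.DataFrame:
    """Flatten evidence items to a delimited-table-ready DataFrame
    (one row per item; references joined with ``;``)."""
    rows = []
    for item in items:
        rows.append(
            {
                "id": item.id,
                "assertion": item.assertion,
                "family": item.family,
                "subject": item.subject,
                "target": item.target,
                "eco_code": item.eco_code,
                "description": item.description,
                "references": ";".join(
                    f"{r.kind}:{r.value}" for r in item.references
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "assertion", "family", "subject", "target",
            "eco_code", "description", "references",
        ],
    )
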