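"""Strain translation via reciprocal best hits (RBH).

Two genes in different strains that are each other's top-scoring sequence
match are taken as orthologs — the standard proxy — and the ortholog map
rewrites every GPR leaf, transferring reaction assignments and evidence
from the development strain to the target strain. Alignment itself is out
of scope: precomputed pairwise hit tables (the common 12-column tabular
alignment format) are consumed as data.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .evidence import EvidenceItem
from .gpr import GPR, BoolOp, GeneRef, GPRNode
from .model import Gene, MetabolicModel

__all__ = [
    "HitRecord",
    "OrthologMap",
    "TranslationReport",
    "read_hit_table",
    "reciprocal_best_hits",
    "translate_model",
]

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    pident: float
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.bitscore < 0 or self.evalue < 0:
            raise ValueError("bitscore and e-value must be non-negative")


@dataclass
class OrthologMap:
    """Bijective gene pairing between strain A and strain B."""

    pairs: Dict[str, str]
    unmapped_a: List[str] = field(default_factory=list)
    unmapped_b: List[str] = field(default_factory=list)

    def reverse(self) -> "OrthologMap":
        return OrthologMap(
            pairs={b: a for a, b in self.pairs.items()},
            unmapped_a=list(self.unmapped_b),
            unmapped_b=list(self.unmapped_a),
        )


def read_hit_table(path: str) -> List[HitRecord]:
    """Read a 12-column tabular alignment hit file."""
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#", dtype=str)
    return [
        HitRecord(
            query=row["query"],
            subject=row["subject"],
            pident=float(row["pident"]),
            bitscore=float(row["bitscore"]),
            evalue=float(row["evalue"]),
        )
        for _, row in df.iterrows()
    ]


def _best_hits(
    hits: Sequence[HitRecord],
    min_pident: float,
    max_evalue: Optional[float],
) -> Dict[str, HitRecord]:
    """Best subject per query: max bitscore, ties broken by min e-value,
    then lexicographically smallest subject id. Duplicate (query, subject)
    rows keep the best-scoring one (with a warning)."""
    dedup: Dict[Tuple[str, str], HitRecord] = {}
    dup_count = 0
    for h in hits:
        if max_evalue is not None and h.evalue > max_evalue:
            continue
        if h.pident < min_pident:
            continue
        key = (h.query, h.subject)
        prev = dedup.get(key)
        if prev is None:
            dedup[key] = h
        else:
            dup_count += 1
            if (-h.bitscore, h.evalue) < (-prev.bitscore, prev.evalue):
                dedup[key] = h
    if dup_count:
        warnings.warn(f"{dup_count} duplicate (query,subject) hit rows; kept best-scoring")
    best: Dict[str, HitRecord] = {}
    for h in dedup.values():
        prev = best.get(h.query)
        if prev is None or (-h.bitscore, h.evalue, h.subject) < (
            -prev.bitscore, prev.evalue, prev.subject
        ):
            best[h.query] = h
    return best


def reciprocal_best_hits(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    min_pident: float = 0.0,
    max_evalue: Optional[float] = None,
) -> OrthologMap:
    """Pair (a, b) iff b is a's best hit in B and a is b's best hit in A.

    No pre-filter is applied by default; `min_pident`/`max_evalue` are
    optional stringency knobs.
    """
    best_ab = _best_hits(hits_ab, min_pident, max_evalue)
    best_ba = _best_hits(hits_ba, min_pident, max_evalue)
    pairs: Dict[str, str] = {}
    for a, hit in best_ab.items():
        b = hit.subject
        back = best_ba.get(b)
        if back is not None and back.subject == a:
            pairs[a] = b
    unmapped_a = sorted(set(best_ab) - set(pairs))
    unmapped_b = sorted(set(best_ba) - set(pairs.values()))
    return OrthologMap(pairs=pairs, unmapped_a=unmapped_a, unmapped_b=unmapped_b)


# ---------------------------------------------------------------------------
# model translation


@dataclass
class TranslationReport:
    unmapped_genes: List[str] = field(default_factory=list)
    degraded_reactions: List[str] = field(default_factory=list)
    emptied_reactions: List[str] = field(default_factory=list)
    dropped_evidence: List[str] = field(default_factory=list)


def _translate_node(
    node: GPRNode, mapping: Dict[str, str], degraded: List[bool]
) -> Optional[GPRNode]:
    """Rewrite leaves via `mapping`; unmapped leaves are removed.

    Removal simplification: an OR losing members keeps the rest; an AND
    losing members keeps the rest but is flagged degraded (requiring fewer
    subunits silently would change knockout semantics); a node losing all
    children vanishes.
    """
    if isinstance(node, GeneRef):
        target = mapping.get(node.gene)
        return GeneRef(target) if target is not None else None
    translated = [_translate_node(c, mapping, degraded) for c in node.children]
    kept = [t for t in translated if t is not None]
    if node.op == "and" and len(kept) < len(node.children):
        degraded[0] = True
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return BoolOp(node.op, tuple(kept))


def translate_model(
    model: MetabolicModel,
    evidences: Sequence[EvidenceItem],
    ortholog_map: OrthologMap,
    direction: str = "forward",
) -> Tuple[MetabolicModel, List[EvidenceItem], TranslationReport]:
    """Produce a strain-specific model by rewriting the gene layer.

    Reaction and metabolite content is untouched; every GPR leaf is mapped
    through the ortholog pairs (direction "forward" uses A→B, "reverse"
    B→A). Reactions whose GPR empties out are kept, gene-less. Evidence
    items about genes are rewritten, or dropped with a log entry when the
    gene has no ortholog.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError(f"direction must be forward/reverse, got {direction!r}")
    mapping = ortholog_map.pairs if direction == "forward" else ortholog_map.reverse().pairs

    report = TranslationReport()
    out = copy.deepcopy(model)
    out.id = f"{model.id}_translated"
    out.genes = {}
    unmapped: Set[str] = set()

    for r in out.reactions.values():
        if r.gpr.is_empty:
            continue
        unmapped |= {g for g in r.gpr.genes() if g not in mapping}
        degraded = [False]
        root = _translate_node(r.gpr.root, mapping, degraded)
        r.gpr = GPR(root)
        if degraded[0]:
            report.degraded_reactions.append(r.id)
            r.annotations["translation"] = "degraded"
        if root is None:
            report.emptied_reactions.append(r.id)
        for g in r.gpr.genes():
            if g not in out.genes:
                out.genes[g] = Gene(g)

    # carry over explicitly declared genes that some GPR no longer covers
    for g in model.genes.values():
        target = mapping.get(g.id)
        if target is not None and target not in out.genes:
            out.genes[target] = Gene(target, g.name, dict(g.annotations))
        elif target is None:
            unmapped.add(g.id)
    report.unmapped_genes = sorted(unmapped)

    gene_assertions = (
        "gene_catalyzes_reaction",
        "gene_not_catalyzes_reaction",
        "gene_localizes_to_compartment",
    )
    out_evidence: List[EvidenceItem] = []
    for ev in evidences:
        if ev.assertion in gene_assertions:
            target = mapping.get(ev.subject)
            if target is None:
                report.dropped_evidence.append(ev.id)
                continue
            out_evidence.append(
                EvidenceItem(
                    id=ev.id,
                    assertion=ev.assertion,
                    subject=target,
                    target=ev.target,
                    eco_code=ev.eco_code,
                    description=ev.description,
                    references=ev.references,
                )
            )
        else:
            out_evidence.append(ev)
    return out, out_evidence, report
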