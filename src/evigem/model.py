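"""Core domain types for a constraint-based metabolic network.

A :class:`MetabolicModel` is the simulatable object: compartments,
metabolites, reactions with flux bounds and gene associations, genes, and
a linear objective. Bounds follow the usual mmol·gDW⁻¹·h⁻¹ convention.

Identifier policy: all ids are opaque strings, stored verbatim and never
normalized — strain translation relies on lossless gene identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .formula import FormulaError, parse_formula
from .gpr import GPR

__all__ = [
    "Compartment",
    "Metabolite",
    "Gene",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
]


class ModelValidationError(ValueError):
    """A model violates its structural invariants; message lists offenders."""


@dataclass
class Compartment:
    id: str
    name: str = ""


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    `formula` is Hill notation (optional); `chebi` an accession like
    ``CHEBI:17234``. `is_boundary_species` marks species that represent the
    system exterior; they are excluded from steady-state rows and from the
    dead-end census. The undissociated-form convention applies: formulas
    carry the protons, charge is optional bookkeeping.
    """

    id: str
    compartment: str
    name: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None
    chebi: Optional[str] = None
    is_boundary_species: bool = False

    def element_counts(self) -> Optional[Dict[str, int]]:
        """Parsed formula, or None when absent. Raises FormulaError if bad."""
        if self.formula is None:
            return None
        return parse_formula(self.formula)


@dataclass
class Gene:
    id: str
    name: str = ""
    annotations: Dict[str, str] = field(default_factory=dict)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a GPR.

    `stoichiometry` maps metabolite id → signed coefficient (negative =
    substrate, positive = product). A boundary (exchange/drain) reaction
    touches exactly one non-boundary metabolite: it connects the network to
    the exterior and its bounds define the medium.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    gpr: GPR = field(default_factory=GPR)
    subsystem: Optional[str] = None
    is_boundary: bool = False
    annotations: Dict[str, str] = field(default_factory=dict)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> set:
        return self.gpr.genes()


@dataclass
class MetabolicModel:
    id: str
    name: str = ""
    compartments: Dict[str, Compartment] = field(default_factory=dict)
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    genes: Dict[str, Gene] = field(default_factory=dict)
    #: reaction id -> weight of the (single, active) linear objective
    objective: Dict[str, float] = field(default_factory=dict)
    objective_sense: str = "maximize"
    notes: Dict[str, str] = field(default_factory=dict)
    #: how boundary reactions were encoded in the source file, if read:
    #: "one_sided", "explicit_external", "mixed" or None
    boundary_encoding_seen: Optional[str] = None

    # -- structural helpers -------------------------------------------------

    def add_compartment(self, c: Compartment) -> None:
        if c.id in self.compartments:
            raise ModelValidationError(f"duplicate compartment id {c.id!r}")
        self.compartments[c.id] = c

    def add_metabolite(self, m: Metabolite) -> None:
        if m.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
        self.metabolites[m.id] = m

    def add_gene(self, g: Gene) -> None:
        if g.id in self.genes:
            raise ModelValidationError(f"duplicate gene id {g.id!r}")
        self.genes[g.id] = g

    def add_reaction(self, r: Reaction, *, declare_genes: bool = True) -> None:
        if r.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {r.id!r}")
        if declare_genes:
            for g in sorted(r.gpr.genes()):
                if g not in self.genes:
                    self.genes[g] = Gene(g)
        self.reactions[r.id] = r

    def boundary_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_boundary]

    def infer_boundary_flags(self) -> None:
        """Set `is_boundary` from structure: exactly one non-boundary
        metabolite participates (one-sided drain/source form)."""
        for r in self.reactions.values():
            internal = [
                m for m in r.stoichiometry
                if m in self.metabolites and not self.metabolites[m].is_boundary_species
            ]
            sided = len(internal) == 1 and all(
                self.metabolites[m].is_boundary_species
                for m in r.stoichiometry if m not in internal
            )
            r.is_boundary = sided

    # -- validation ---------------------------------------------------------

    def validate(self) -> List[str]:
        """Return a list of invariant violations (empty = valid)."""
        problems: List[str] = []
        for m in self.metabolites.values():
            if m.compartment not in self.compartments:
                problems.append(
                    f"metabolite {m.id!r} references missing compartment {m.compartment!r}"
                )
            if m.formula is not None:
                try:
                    parse_formula(m.formula)
                except FormulaError as exc:
                    problems.append(f"metabolite {m.id!r}: {exc}")
        for r in self.reactions.values():
            if not r.stoichiometry:
                problems.append(f"reaction {r.id!r} has empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                problems.append(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} > upper bound {r.upper_bound}"
                )
            for met in r.stoichiometry:
                if met not in self.metabolites:
                    problems.append(
                        f"reaction {r.id!r} references missing metabolite {met!r}"
                    )
            for g in r.gpr.genes():
                if g not in self.genes:
                    problems.append(
                        f"reaction {r.id!r} GPR references undeclared gene {g!r}"
                    )
            if r.is_boundary:
                internal = [
                    m for m in r.stoichiometry
                    if m in self.metabolites
                    and not self.metabolites[m].is_boundary_species
                ]
                if len(internal) != 1:
                    problems.append(
                        f"reaction {r.id!r} flagged boundary but touches "
                        f"{len(internal)} internal metabolites"
                    )
        for rid in self.objective:
            if rid not in self.reactions:
                problems.append(f"objective references missing reaction {rid!r}")
        if self.objective_sense not in ("maximize", "minimize"):
            problems.append(f"invalid objective sense {self.objective_sense!r}")
        return problems

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise ModelValidationError(
                "model invariant violations:\n  " + "\n  ".join(problems)
            )

    # -- simulation support ---------------------------------------------------

    def copy_bounds(self) -> Dict[str, Tuple[float, float]]:
        return {r.id: (r.lower_bound, r.upper_bound) for r in self.reactions.values()}
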