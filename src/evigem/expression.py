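"""Contextualizing expression data on the model's pathways.

The model's subsystem labels group reactions, and the GPRs group the
associated genes, so a gene × condition expression matrix can be summarized
per pathway: for each member gene, the change of (log2-scale) expression in
a condition relative to a user-chosen reference condition. Distributions of
those per-gene changes are what pathway violin plots show.

Co-expression scoring supports candidate-gene assignment: a gene whose
profile correlates with the known members of a cluster across conditions is
a co-regulation candidate (how a transporter gene gets proposed as a
cluster member). Input is assumed pre-normalized log2 data; the reference
condition is a required argument, never defaulted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .model import MetabolicModel

__all__ = [
    "ExpressionMatrix",
    "PathwayProfile",
    "CoexpressionResult",
    "pathway_members",
    "pathway_change_profile",
    "coexpression_score",
]


@dataclass
class ExpressionMatrix:
    """Genes × conditions log2 expression values."""

    values: pd.DataFrame  # index: gene ids, columns: condition labels

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in expression matrix: {dups}")

    @classmethod
    def read_csv(cls, path: str, sep: str = "\t") -> "ExpressionMatrix":
        """Read a delimited matrix: genes in rows, condition-label header."""
        return cls(pd.read_csv(path, sep=sep, index_col=0))

    @property
    def conditions(self) -> List[str]:
        return list(self.values.columns)

    def profile(self, gene: str) -> pd.Series:
        return self.values.loc[gene]


@dataclass
class PathwayProfile:
    """Per-gene expression changes of one pathway in one condition."""

    pathway: str
    condition: str
    reference: str
    changes: Dict[str, float] = field(default_factory=dict)
    missing_genes: List[str] = field(default_factory=list)

    def median(self) -> float:
        return float(np.median(list(self.changes.values())))

    def as_frame(self) -> pd.DataFrame:
        """Tidy table (pathway, condition, gene, change) for plotting tools."""
        return pd.DataFrame(
            {
                "pathway": self.pathway,
                "condition": self.condition,
                "gene": list(self.changes),
                "log2_change": list(self.changes.values()),
            }
        )


def pathway_members(model: MetabolicModel, pathway: str) -> Set[str]:
    """Union of GPR leaves over reactions labelled with `pathway`."""
    labels = {r.subsystem for r in model.reactions.values() if r.subsystem}
    if pathway not in labels:
        raise KeyError(f"unknown pathway label {pathway!r}; known: {sorted(labels)}")
    members: Set[str] = set()
    for r in model.reactions.values():
        if r.subsystem == pathway:
            members |= r.gpr.genes()
    return members


def pathway_change_profile(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    pathway: str,
    condition: str,
    reference: str,
) -> PathwayProfile:
    """Per-gene change = log2(condition) − log2(reference) for the pathway's
    member genes. Genes absent from the matrix are reported as missing,
    never imputed as zero."""
    for label in (condition, reference):
        if label not in expr.values.columns:
            raise KeyError(f"condition {label!r} not in expression matrix")
    members = pathway_members(model, pathway)
    changes: Dict[str, float] = {}
    missing: List[str] = []
    for gene in sorted(members):
        if gene in expr.values.index:
            changes[gene] = float(
                expr.values.at[gene, condition] - expr.values.at[gene, reference]
            )
        else:
            missing.append(gene)
    return PathwayProfile(
        pathway=pathway,
        condition=condition,
        reference=reference,
        changes=changes,
        missing_genes=missing,
    )


@dataclass
class CoexpressionResult:
    candidate: str
    correlations: Dict[str, Optional[float]]  # member gene -> Pearson r (None: undefined)
    mean_correlation: Optional[float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate": self.candidate,
                "member": list(self.correlations),
                "pearson_r": [
                    float("nan") if r is None else r for r in self.correlations.values()
                ],
            }
        )


def _pearson(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return None  # zero-variance profile: correlation undefined
    return float(xc @ yc) / denom


def coexpression_score(
    candidate: pd.Series,
    members: Dict[str, pd.Series],
    candidate_name: str = "candidate",
) -> CoexpressionResult:
    """Pearson correlation of a candidate profile against each cluster
    member across conditions, plus the mean over defined correlations.

    Profiles are aligned on their condition labels; at least 3 shared
    conditions are required.
    """
    correlations: Dict[str, Optional[float]] = {}
    for name, profile in members.items():
        shared = candidate.index.intersection(profile.index)
        if len(shared) < 3:
            raise ValueError(
                f"need >=3 shared conditions with member {name!r}, got {len(shared)}"
            )
        correlations[name] = _pearson(
            candidate.loc[shared].to_numpy(dtype=float),
            profile.loc[shared].to_numpy(dtype=float),
        )
    defined = [r for r in correlations.values() if r is not None]
    mean = float(np.mean(defined)) if defined else None
    return CoexpressionResult(candidate_name, correlations, mean)
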