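"""Compound-target interaction filtering and gene-symbol mapping.

Interaction scores come from upstream ligand-target predictors (a random
forest and a support vector machine trained on chemogenomic data); this
module consumes the scored pairs, keeps those meeting both score
thresholds, and annotates retained targets with gene symbols through a
UniProt-style accession table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "InteractionRecord",
    "TargetRecord",
    "filter_interactions",
    "map_targets",
    "MappedEdges",
]

DEFAULT_SVM_MIN = 0.8
DEFAULT_RF_MIN = 0.7


@dataclass(frozen=True)
class InteractionRecord:
    """A scored compound-target pair."""

    compound_id: str
    target_uniprot: str
    svm_score: float
    rf_score: float

    def __post_init__(self) -> None:
        if not self.compound_id or not self.target_uniprot:
            raise ValidationError("compound_id and target_uniprot must be nonempty")
        for fname in ("svm_score", "rf_score"):
            v = getattr(self, fname)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValidationError(
                    f"interaction ({self.compound_id}, {self.target_uniprot}): "
                    f"{fname} must be finite"
                )


@dataclass(frozen=True)
class TargetRecord:
    """One protein target: UniProt accession, gene symbol, protein name."""

    uniprot_id: str
    gene_symbol: str
    protein_name: str = ""

    def __post_init__(self) -> None:
        if not self.uniprot_id:
            raise ValidationError("uniprot_id must be nonempty")
        if not self.gene_symbol:
            raise ValidationError(f"{self.uniprot_id}: gene_symbol must be nonempty")


def filter_interactions(
    records: list[InteractionRecord],
    svm_min: float = DEFAULT_SVM_MIN,
    rf_min: float = DEFAULT_RF_MIN,
) -> list[InteractionRecord]:
    """Keep interactions with svm_score >= svm_min AND rf_score >= rf_min.

    Both comparisons are inclusive; input order is preserved. Filtering is
    monotone: raising either threshold never grows the retained set.
    """
    return [r for r in records if r.svm_score >= svm_min and r.rf_score >= rf_min]


@dataclass(frozen=True)
class MappedEdge:
    compound_id: str
    target_uniprot: str
    gene_symbol: str


@dataclass
class MappedEdges:
    """Gene-annotated edge list plus the log of unmappable accessions."""

    edges: list[MappedEdge]
    unmapped: list[InteractionRecord]

    @property
    def unique_genes(self) -> set[str]:
        return {e.gene_symbol for e in self.edges}

    @property
    def unique_compounds(self) -> set[str]:
        return {e.compound_id for e in self.edges}


def build_target_map(mapping: list[TargetRecord]) -> dict[str, TargetRecord]:
    """Index target records by accession, rejecting duplicates."""
    out: dict[str, TargetRecord] = {}
    for t in mapping:
        if t.uniprot_id in out:
            raise ValidationError(f"duplicate accession in target mapping: {t.uniprot_id}")
        out[t.uniprot_id] = t
    return out


def map_targets(
    edges: list[InteractionRecord], mapping: list[TargetRecord]
) -> MappedEdges:
    """Annotate retained edges with gene symbols.

    Edges whose accession is absent from the mapping are diverted to the
    unmapped log, never silently dropped, so
    ``len(edges) == len(result.edges) + len(result.unmapped)``.
    """
    index = build_target_map(mapping)
    mapped: list[MappedEdge] = []
    unmapped: list[InteractionRecord] = []
    for e in edges:
        t = index.get(e.target_uniprot)
        if t is None:
            unmapped.append(e)
        else:
            mapped.append(MappedEdge(e.compound_id, e.target_uniprot, t.gene_symbol))
    return MappedEdges(edges=mapped, unmapped=unmapped)
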