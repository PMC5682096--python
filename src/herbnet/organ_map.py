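"""Tissue-expression organ-location mapping for target genes.

Given a genes x tissues mRNA intensity matrix (a GeneAtlas-style layout,
176 tissue columns by default) the procedure is:

1. obtain each query gene's expression profile across all tissues;
2. compute the per-gene mean intensity over tissues;
3. flag the tissues in which the gene exceeds its own mean (strictly);
4. aggregate the flags into named organ groups — a gene belongs to a
   group when it is above-average in at least one of that group's
   tissues.

Query genes absent from the matrix are reported as excluded, never
silently dropped. Groups may overlap (the same tissue can serve two
groups), so per-group counts need not sum to the mapped-gene count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ExpressionMatrix",
    "OrganGroupScheme",
    "GeneOrganResult",
    "OrganMapResult",
    "above_average_flags",
    "map_genes",
]


class ExpressionMatrix:
    """Genes x tissues intensity matrix with validation.

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene
    symbols and whose columns hold unique tissue labels; every cell must
    be a finite nonnegative intensity.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        if frame.empty:
            raise ValidationError("expression matrix must be nonempty")
        if frame.index.has_duplicates:
            raise ValidationError("gene symbols must be unique")
        if frame.columns.has_duplicates:
            raise ValidationError("tissue labels must be unique")
        values = frame.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("expression matrix has missing cells")
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValidationError("intensities must be finite and >= 0")
        self._frame = frame.astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def genes(self) -> list[str]:
        return list(self._frame.index)

    @property
    def tissues(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape


@dataclass(frozen=True)
class OrganGroupScheme:
    """Ordered mapping of organ-group name -> set of tissue labels.

    Tissue assignment is by exact label match; groups may overlap (for
    instance a pituitary group alongside a combined
    hypothalamus/pituitary group).
    """

    groups: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("organ scheme must define at least one group")
        for name, tissues in self.groups.items():
            if not tissues:
                raise ValidationError(f"organ group {name!r} has no tissues")

    def validate_against(self, m: ExpressionMatrix) -> None:
        known = set(m.tissues)
        for name, tissues in self.groups.items():
            missing = sorted(set(tissues) - known)
            if missing:
                raise ValidationError(
                    f"organ group {name!r} references unknown tissues: {missing}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.groups)


def above_average_flags(m: ExpressionMatrix) -> pd.DataFrame:
    """Boolean genes x tissues matrix: cell (g, t) is True iff gene g's
    intensity in tissue t strictly exceeds g's mean over all tissues.

    A constant gene flags no tissue; scaling a gene's row leaves its
    flags unchanged."""
    f = m.frame
    return f.gt(f.mean(axis=1), axis=0)


@dataclass(frozen=True)
class GeneOrganResult:
    gene: str
    mean_intensity: float
    above_average_tissues: tuple[str, ...]
    group_flags: dict[str, bool]

    @property
    def n_groups(self) -> int:
        return sum(self.group_flags.values())


@dataclass
class OrganMapResult:
    """Per-gene flags plus group-level summaries.

    ``pct_multi_group`` is the share of analyzed genes belonging to two
    or more organ groups, in percent to one decimal.
    """

    genes: list[GeneOrganResult] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)
    group_counts: dict[str, int] = field(default_factory=dict)
    all_group_genes: list[str] = field(default_factory=list)
    pct_multi_group: float = 0.0

    @property
    def n_analyzed(self) -> int:
        return len(self.genes)

    @property
    def n_mapped(self) -> int:
        """Genes above-average in at least one group."""
        return sum(1 for g in self.genes if g.n_groups >= 1)


def map_genes(
    query_genes: list[str],
    m: ExpressionMatrix,
    scheme: OrganGroupScheme,
) -> OrganMapResult:
    """Run the four-step organ-location mapping for a list of genes.

    Output ordering is deterministic: genes alphabetical, groups in
    scheme order. ``excluded`` lists query genes missing from the matrix;
    ``excluded`` plus analyzed genes always account for the whole query.
    """
    scheme.validate_against(m)
    present = sorted(set(query_genes) & set(m.genes))
    excluded = sorted(set(query_genes) - set(m.genes))
    if not present:
        return OrganMapResult(excluded=excluded,
                              group_counts={g: 0 for g in scheme.names})

    sub = ExpressionMatrix(m.frame.loc[present])
    flags = above_average_flags(sub)
    means = sub.frame.mean(axis=1)

    results: list[GeneOrganResult] = []
    group_counts = {g: 0 for g in scheme.names}
    all_group: list[str] = []
    n_multi = 0
    flag_values = flags.to_numpy()
    tissue_list = sub.tissues
    for gi, gene in enumerate(present):
        row = flag_values[gi]
        above = tuple(t for t, f in zip(tissue_list, row) if f)
        above_set = set(above)
        gflags = {
            name: bool(above_set & tissues)
            for name, tissues in scheme.groups.items()
        }
        for name, hit in gflags.items():
            group_counts[name] += int(hit)
        n_hit = sum(gflags.values())
        if n_hit == len(scheme.groups):
            all_group.append(gene)
        if n_hit >= 2:
            n_multi += 1
        results.append(
            GeneOrganResult(
                gene=gene,
                mean_intensity=float(means[gene]),
                above_average_tissues=above,
                group_flags=gflags,
            )
        )

    pct = round(100.0 * n_multi / len(present), 1)
    return OrganMapResult(
        genes=results,
        excluded=excluded,
        group_counts=group_counts,
        all_group_genes=all_group,
        pct_multi_group=pct,
    )
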