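"""Seeded generators for every input the pipeline consumes.

Each generator emulates one upstream data source — a TCMSP-like compound
database with ADME annotations, a scored compound-target interaction
table, GMT annotation collections, and a GeneAtlas-style genes x tissues
expression matrix — and returns the planted ground truth alongside the
data, so every stage of the pipeline can be checked against a known
answer without any download.

All generators are pure functions of their parameters: each draws from
an independent RNG stream derived from the master seed and a fixed
per-generator tag, so adding a new generator never perturbs existing
outputs, and the same seed always reproduces the same dataset.

The ADME sampling distributions are pragmatic fits to published compound
tables, not a chemical model: OB is lognormal clipped to the observed
0.31-149.03 percent range, DL is Beta(1.2, 6) on [0, 1] (most herbal
compounds are weakly drug-like), and Caco-2 is Normal(1.0, 0.9) allowing
the negative tail seen in polar compounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import GO_BP, AnnotationTerm
from .errors import ValidationError
from .organ_map import ExpressionMatrix, OrganGroupScheme
from .screening import CompoundRecord, ScreeningCriteria, normalize_name
from .target_fishing import InteractionRecord

__all__ = [
    "SynthParams",
    "DEFAULT_ORGAN_GROUPS",
    "default_tissue_labels",
    "generate_compound_db",
    "generate_interactions",
    "generate_annotations",
    "generate_expression",
]

# fixed stream tags: never renumber, or seeds stop reproducing old data
_TAG_COMPOUNDS = 11
_TAG_INTERACTIONS = 12
_TAG_ANNOTATIONS = 13
_TAG_EXPRESSION = 14

DEFAULT_ORGAN_GROUPS: dict[str, tuple[str, ...]] = {
    "uterus": ("uterus", "uterus corpus"),
    "placenta_fetus": ("placenta", "fetal brain", "fetal liver",
                       "fetal lung", "fetal thyroid"),
    "hypothalamus_pituitary": ("hypothalamus", "pituitary"),
    "smooth_muscle": ("smooth muscle",),
    "pituitary": ("pituitary",),
    "whole_blood": ("whole blood",),
}

_NAMED_TISSUES = tuple(dict.fromkeys(
    t for tissues in DEFAULT_ORGAN_GROUPS.values() for t in tissues
))


def default_tissue_labels(n_tissues: int) -> list[str]:
    """Tissue label list: the named organ-group tissues first, padded
    with generic labels up to ``n_tissues`` (176 by default, the size of
    the reference gene atlas)."""
    if n_tissues < len(_NAMED_TISSUES):
        raise ValidationError(
            f"n_tissues must be >= {len(_NAMED_TISSUES)} to host the organ groups"
        )
    filler = [f"tissue_{i:03d}" for i in range(1, n_tissues - len(_NAMED_TISSUES) + 1)]
    return list(_NAMED_TISSUES) + filler


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic study, one field per knob.

    ``seed`` is mandatory: there is no implicit randomness anywhere.
    """

    seed: int
    # compound database
    n_herbs: int = 2
    compounds_per_herb: int = 50
    duplicate_fraction: float = 0.1
    ob_lognorm_mean: float = 3.4  # log-scale; exp ~ 30 % OB
    ob_lognorm_sigma: float = 0.9
    ob_range: tuple[float, float] = (0.31, 149.03)
    dl_beta: tuple[float, float] = (1.2, 6.0)
    caco2_normal: tuple[float, float] = (1.0, 0.9)
    # interactions
    n_compounds: int = 65
    n_targets: int = 100
    interaction_density: float = 0.15
    # annotations
    n_terms: int = 100
    term_size_range: tuple[int, int] = (10, 80)
    universe_size: int = 1000
    query_size: int = 50
    planted_term_size: int = 50
    planted_term_odds: float = 8.0
    # expression
    n_genes: int = 200
    n_signal_genes: int = 20
    n_tissues: int = 176
    planted_group: str = "uterus"
    boost: float = 5.0
    baseline_log_mean: float = 4.6  # exp ~ 100 intensity units
    baseline_log_sigma: float = 0.3

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        for fname in ("n_herbs", "compounds_per_herb", "n_compounds", "n_targets",
                      "n_terms", "universe_size", "query_size", "planted_term_size",
                      "n_genes", "n_signal_genes", "n_tissues"):
            if getattr(self, fname) <= 0:
                raise ValidationError(f"{fname} must be positive")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ValidationError("duplicate_fraction must lie in [0, 1]")
        if not 0.0 <= self.interaction_density <= 1.0:
            raise ValidationError("interaction_density must lie in [0, 1]")
        if self.planted_term_odds < 1.0:
            raise ValidationError("planted_term_odds must be >= 1")
        if self.boost <= 0.0:
            raise ValidationError("boost must be > 0")
        if self.planted_group not in DEFAULT_ORGAN_GROUPS:
            raise ValidationError(f"unknown planted_group {self.planted_group!r}")


def _rng(p: SynthParams, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(p.seed, spawn_key=(tag,)))


# ---------------------------------------------------------------------------
# compound database
# ---------------------------------------------------------------------------


def generate_compound_db(
    p: SynthParams,
) -> tuple[list[CompoundRecord], dict]:
    """Per-herb compound table with sampled ADME values.

    A ``duplicate_fraction`` share of each non-first herb's compounds
    reuses names (and property values) from the first herb, emulating
    cross-herb shared phytochemicals. The ground-truth sidecar records,
    by normalized name, which compounds truly satisfy the default
    screening criteria — computed by direct comparison, independently of
    the screening assembly.
    """
    rng = _rng(p, _TAG_COMPOUNDS)
    crit = ScreeningCriteria()
    herbs = [f"H{i + 1}" for i in range(p.n_herbs)]
    m = p.compounds_per_herb
    n_dup = int(round(p.duplicate_fraction * m)) if p.n_herbs > 1 else 0
    n_dup = min(n_dup, m)

    def sample_adme(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ob = np.exp(rng.normal(p.ob_lognorm_mean, p.ob_lognorm_sigma, n))
        ob = np.clip(ob, *p.ob_range).round(2)
        dl = rng.beta(*p.dl_beta, n).round(2)
        caco2 = rng.normal(*p.caco2_normal, n).round(2)
        return ob, dl, caco2

    records: list[CompoundRecord] = []
    base_names: list[str] = []
    base_props: dict[str, tuple[float, float, float]] = {}
    serial = 0
    for hi, herb in enumerate(herbs):
        ob, dl, caco2 = sample_adme(m)
        for j in range(m):
            if hi > 0 and j < n_dup:
                # reuse a first-herb compound: same name, same properties
                name = base_names[j]
                o, d, c = base_props[name]
            else:
                serial += 1
                name = f"synthcpd {serial:04d}"
                o, d, c = float(ob[j]), float(dl[j]), float(caco2[j])
                if hi == 0:
                    base_names.append(name)
                    base_props[name] = (o, d, c)
            records.append(
                CompoundRecord(
                    compound_id=f"{herb}-{j + 1:04d}",
                    name=name,
                    herbs=frozenset({herb}),
                    ob=o,
                    caco2=c,
                    dl=d,
                )
            )

    passing = sorted({
        normalize_name(r.name)
        for r in records
        if r.ob >= crit.ob_min and r.dl >= crit.dl_min and r.caco2 >= crit.caco2_min
    })
    truth = {
        "pass_names": passing,
        "n_records": len(records),
        "n_unique_names": len({normalize_name(r.name) for r in records}),
    }
    return records, truth


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------


def generate_interactions(
    p: SynthParams,
    compound_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> tuple[list[InteractionRecord], dict]:
    """Scored compound-target pairs with uniform [0, 1] SVM/RF scores.

    Each of the ``n_compounds`` x ``n_targets`` pairs is included with
    probability ``interaction_density``; the ground truth labels the
    pairs meeting svm >= 0.8 and rf >= 0.7, by direct comparison.
    Identifier lists default to ``C1..`` / ``T0001..`` but can be
    supplied to match an existing compound table or target mapping.
    """
    rng = _rng(p, _TAG_INTERACTIONS)
    compounds = compound_ids or [f"C{i + 1}" for i in range(p.n_compounds)]
    targets = target_ids or [f"T{i + 1:04d}" for i in range(p.n_targets)]
    if len(compounds) != p.n_compounds or len(targets) != p.n_targets:
        raise ValidationError("identifier lists must match n_compounds/n_targets")
    records: list[InteractionRecord] = []
    retained: list[list[str]] = []
    mask = rng.random((p.n_compounds, p.n_targets)) < p.interaction_density
    svm = rng.random((p.n_compounds, p.n_targets)).round(4)
    rf = rng.random((p.n_compounds, p.n_targets)).round(4)
    for i, c in enumerate(compounds):
        for j, t in enumerate(targets):
            if not mask[i, j]:
                continue
            records.append(InteractionRecord(c, t, float(svm[i, j]), float(rf[i, j])))
            if svm[i, j] >= 0.8 and rf[i, j] >= 0.7:
                retained.append([c, t])
    truth = {"retained_pairs": retained, "n_records": len(records)}
    return records, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def generate_annotations(
    p: SynthParams, kind: str = GO_BP
) -> tuple[list[AnnotationTerm], set[str], set[str], dict]:
    """GMT-style annotation collection with one planted enriched term.

    Returns (terms, query, universe, truth). Decoy terms draw genes
    uniformly from the universe; the planted term draws its genes with
    query members weighted by ``planted_term_odds``, so at odds 1 it is
    indistinguishable from the decoys and at higher odds it is
    over-represented in the query by construction.
    """
    # one stream per annotation kind, so GO and pathway collections differ
    rng = np.random.default_rng(
        np.random.SeedSequence(p.seed, spawn_key=(_TAG_ANNOTATIONS,
                                                  0 if kind == GO_BP else 1))
    )
    if p.query_size > p.universe_size or p.planted_term_size > p.universe_size:
        raise ValidationError("query and planted term must fit inside the universe")
    universe = [f"G{i + 1:05d}" for i in range(p.universe_size)]
    query = set(rng.choice(universe, size=p.query_size, replace=False).tolist())

    weights = np.asarray(
        [p.planted_term_odds if g in query else 1.0 for g in universe], dtype=float
    )
    weights /= weights.sum()
    planted_genes = frozenset(
        rng.choice(universe, size=p.planted_term_size, replace=False,
                   p=weights).tolist()
    )
    prefix = "GO" if kind == GO_BP else "PW"
    terms = [
        AnnotationTerm(
            term_id=f"{prefix}:PLANTED", term_name="planted signal term",
            kind=kind, genes=planted_genes,
        )
    ]
    lo, hi = p.term_size_range
    sizes = rng.integers(lo, hi + 1, size=p.n_terms - 1)
    for i, size in enumerate(sizes):
        genes = frozenset(rng.choice(universe, size=int(size), replace=False).tolist())
        terms.append(
            AnnotationTerm(
                term_id=f"{prefix}:D{i + 1:04d}", term_name=f"decoy term {i + 1}",
                kind=kind, genes=genes,
            )
        )
    truth = {
        "planted_term_id": f"{prefix}:PLANTED",
        "planted_overlap": len(planted_genes & query),
    }
    return terms, query, set(universe), truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(
    p: SynthParams,
    genes: list[str] | None = None,
) -> tuple[ExpressionMatrix, OrganGroupScheme, dict]:
    """Genes x tissues matrix with a planted high-expression organ group.

    Baseline intensities are lognormal; the first ``n_signal_genes``
    genes have every tissue of ``planted_group`` multiplied by ``boost``.
    At boost 1 signal genes are null; at boost well above the noise
    scale they are above their own mean in every planted tissue.
    Gene labels default to ``SYN0001..`` but can be supplied.
    """
    rng = _rng(p, _TAG_EXPRESSION)
    tissues = default_tissue_labels(p.n_tissues)
    genes = genes or [f"SYN{i + 1:04d}" for i in range(p.n_genes)]
    if len(genes) != p.n_genes:
        raise ValidationError("gene list must have length n_genes")
    values = np.exp(
        rng.normal(p.baseline_log_mean, p.baseline_log_sigma,
                   (p.n_genes, p.n_tissues))
    )
    scheme = OrganGroupScheme(
        groups={k: frozenset(v) for k, v in DEFAULT_ORGAN_GROUPS.items()}
    )
    boosted_cols = [tissues.index(t) for t in sorted(scheme.groups[p.planted_group])]
    signal = genes[: p.n_signal_genes]
    values[: p.n_signal_genes, boosted_cols] *= p.boost
    frame = pd.DataFrame(np.round(values, 3), index=genes, columns=tissues)
    matrix = ExpressionMatrix(frame)
    truth = {"signal_genes": signal, "planted_group": p.planted_group}
    return matrix, scheme, truth
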