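"""Bundled example datasets: the two-herb formula worked example.

The package ships the published ADME inventory of the CG-DG herb pair
(65 active compounds, 8 shared between both herbs) and its 185-protein
target mapping, plus the sub-threshold whitelist that reproduces the
published screen. The compound-target edge list behind the published
network was never released, so :func:`synthetic_interaction_table`
builds a synthetic stand-in — 739 unique scored pairs covering all 65
compounds and 185 targets, generated deterministically — that matches
the published network's size and shape but not its (unknown) edges.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from . import io
from .organ_map import OrganGroupScheme
from .screening import CompoundRecord
from .target_fishing import InteractionRecord, TargetRecord

__all__ = [
    "bundled_compounds",
    "bundled_whitelist",
    "bundled_targets",
    "bundled_organ_scheme",
    "bundled_path",
    "split_by_herb",
    "synthetic_interaction_table",
    "SYNTHETIC_EDGE_COUNT",
]

SYNTHETIC_EDGE_COUNT = 739
_SYNTH_EDGE_SEED = 736_436  # fixed: the stand-in is one dataset, not a dial


def bundled_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(resources.files("herbnet.data") / name)


def bundled_compounds() -> list[CompoundRecord]:
    """The 65-compound ADME inventory of the CG-DG formula."""
    return io.load_compound_table(bundled_path("bss_compounds.tsv"))


def bundled_whitelist() -> set[str]:
    """Names of the sub-threshold compounds rescued on pharmacological
    grounds (every inventory compound failing the numeric screen)."""
    return io.load_whitelist(bundled_path("bss_whitelist.txt"))


def bundled_targets() -> list[TargetRecord]:
    """The 185-protein target mapping (accession, symbol, name)."""
    return io.load_target_table(bundled_path("bss_targets.tsv"))


def bundled_organ_scheme() -> OrganGroupScheme:
    """Default six-group organ scheme (pituitary appears both alone and
    within the combined hypothalamus/pituitary group)."""
    return io.load_organ_scheme(bundled_path("organ_groups.json"))


def split_by_herb(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Expand multi-herb records into one row per herb membership,
    emulating per-herb source inventories (the screening assembly merges
    them back by name). The first herb's row keeps the canonical id —
    it is the record that survives the merge — and later rows get
    herb-suffixed ids."""
    out: list[CompoundRecord] = []
    for r in records:
        if len(r.herbs) == 1:
            out.append(r)
            continue
        for i, herb in enumerate(sorted(r.herbs)):
            out.append(
                CompoundRecord(
                    compound_id=r.compound_id if i == 0 else f"{r.compound_id}-{herb}",
                    name=r.name,
                    herbs=frozenset({herb}),
                    ob=r.ob, caco2=r.caco2, dl=r.dl,
                    mw=r.mw, hdon=r.hdon, hacc=r.hacc, alogp=r.alogp,
                )
            )
    return out


def synthetic_interaction_table() -> list[InteractionRecord]:
    """SYNTHETIC stand-in for the unpublished compound-target edge list.

    Deterministically generates 739 unique (compound, target) pairs in
    which every bundled compound and every bundled target appears at
    least once; SVM scores are uniform on [0.8, 1] and RF scores on
    [0.7, 1], i.e. all pairs sit in the retained score region. Edge
    identities are arbitrary: only the counts (739 edges, 65 compounds,
    185 targets) mirror the published network.
    """
    rng = np.random.default_rng(_SYNTH_EDGE_SEED)
    compounds = [r.compound_id for r in bundled_compounds()]
    targets = [t.uniprot_id for t in bundled_targets()]
    pairs: set[tuple[str, str]] = set()
    # coverage first: every target once, every compound at least once
    for i, t in enumerate(targets):
        pairs.add((compounds[i % len(compounds)], t))
    for c in compounds:
        if not any(p[0] == c for p in pairs):
            pairs.add((c, targets[int(rng.integers(len(targets)))]))
    while len(pairs) < SYNTHETIC_EDGE_COUNT:
        c = compounds[int(rng.integers(len(compounds)))]
        t = targets[int(rng.integers(len(targets)))]
        pairs.add((c, t))
    svm = rng.uniform(0.8, 1.0, SYNTHETIC_EDGE_COUNT)
    rf = rng.uniform(0.7, 1.0, SYNTHETIC_EDGE_COUNT)
    return [
        InteractionRecord(c, t, round(float(s), 4), round(float(r), 4))
        for (c, t), s, r in zip(sorted(pairs), svm, rf)
    ]
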