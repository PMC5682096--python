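"""ADME-based active-compound screening for multi-herb formulas.

This module covers the first stage of the pipeline: a Tanimoto-type
drug-likeness score over molecular descriptor vectors, a multi-criterion
ADME screen (oral bioavailability, drug-likeness, Caco-2 permeability,
Lipinski fields), cross-herb duplicate merging, whitelist rescue of
pharmacologically motivated sub-threshold compounds, and full exclusion
bookkeeping so every input compound is accounted for exactly once.
"""

from __future__ import annotations

import logging
import math
import re
import unicodedata
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DimensionMismatchError,
    UndefinedSimilarityError,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "ScreeningCriteria",
    "CriteriaEvaluation",
    "ActiveCompound",
    "Exclusion",
    "ActiveCompoundSet",
    "tanimoto",
    "drug_likeness",
    "normalize_name",
    "evaluate_criteria",
    "screen_compounds",
]

# ---------------------------------------------------------------------------
# descriptor similarity
# ---------------------------------------------------------------------------


def tanimoto(a, b) -> float:
    """Continuous Tanimoto similarity between two descriptor vectors.

    F(A, B) = A·B / (|A|^2 + |B|^2 - A·B)

    where A and B are real-valued molecular parameter vectors of equal
    dimension. For nonnegative inputs the score lies in [0, 1], equals 1
    iff the vectors are identical (and nonzero), and is symmetric.

    Raises
    ------
    DimensionMismatchError
        If the vectors differ in length.
    UndefinedSimilarityError
        If both vectors are all-zero (the denominator vanishes).
    ValidationError
        If any entry is non-finite.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.ndim != 1 or bv.ndim != 1:
        raise ValidationError("descriptor vectors must be one-dimensional")
    if av.shape[0] != bv.shape[0]:
        raise DimensionMismatchError(
            f"descriptor dimensions differ: {av.shape[0]} vs {bv.shape[0]}"
        )
    if av.shape[0] == 0:
        raise ValidationError("descriptor vectors must have dimension >= 1")
    if not (np.isfinite(av).all() and np.isfinite(bv).all()):
        raise ValidationError("descriptor vectors must be finite")
    dot = float(av @ bv)
    denom = float(av @ av) + float(bv @ bv) - dot
    if denom == 0.0:
        # for real vectors |A|^2+|B|^2-A.B == 0 only when A == B == 0
        raise UndefinedSimilarityError("similarity undefined for two zero vectors")
    return dot / denom


def drug_likeness(descriptors, reference_mean) -> float:
    """Drug-likeness: Tanimoto similarity of a compound's molecular
    parameters to the average parameters of known drugs.

    The reference vector is typically the per-descriptor mean over a drug
    database. Curated compound tables carry database-supplied DL values
    which are consumed as-is; this function scores synthetic or otherwise
    unannotated compounds.
    """
    return tanimoto(descriptors, reference_mean)


# ---------------------------------------------------------------------------
# records and criteria
# ---------------------------------------------------------------------------

_NONWORD_RE = re.compile(r"[\W_]+", re.UNICODE)


def normalize_name(name: str) -> str:
    """Canonical merge key for a compound name.

    Case-folded, with all whitespace and punctuation removed, so that
    per-herb inventory spellings such as ``"Senkyunolide-C"`` and
    ``"senkyunolide C"`` collapse to one key. Idempotent.
    """
    if not isinstance(name, str) or not name.strip():
        raise ValidationError("compound name must be a nonempty string")
    folded = unicodedata.normalize("NFKC", name).casefold()
    return _NONWORD_RE.sub("", folded)


@dataclass(frozen=True)
class CompoundRecord:
    """One herb compound with its ADME annotations and herb membership.

    ``ob`` is oral bioavailability in percent, ``caco2`` the log-scale
    Caco-2 permeability (may be negative), ``dl`` the drug-likeness in
    [0, 1]. The Lipinski fields (``mw``, ``hdon``, ``hacc``, ``alogp``)
    and the raw descriptor vector are optional.
    """

    compound_id: str
    name: str
    herbs: frozenset[str]
    ob: float
    caco2: float
    dl: float
    mw: float | None = None
    hdon: int | None = None
    hacc: int | None = None
    alogp: float | None = None
    descriptors: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be nonempty")
        if not self.herbs:
            raise ValidationError(f"{self.compound_id}: herbs must be nonempty")
        for fname in ("ob", "caco2", "dl"):
            v = getattr(self, fname)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValidationError(f"{self.compound_id}: {fname} must be finite")
        if self.ob < 0:
            raise ValidationError(f"{self.compound_id}: ob must be >= 0")
        if not 0.0 <= self.dl <= 1.0:
            raise ValidationError(f"{self.compound_id}: dl must lie in [0, 1]")
        for fname in ("mw", "alogp"):
            v = getattr(self, fname)
            if v is not None and not math.isfinite(v):
                raise ValidationError(f"{self.compound_id}: {fname} must be finite")
        for fname in ("hdon", "hacc"):
            v = getattr(self, fname)
            if v is not None and (int(v) != v or v < 0):
                raise ValidationError(
                    f"{self.compound_id}: {fname} must be a nonnegative integer"
                )

    @property
    def norm_name(self) -> str:
        return normalize_name(self.name)


@dataclass(frozen=True)
class ScreeningCriteria:
    """Active-compound thresholds; comparisons are inclusive.

    Defaults follow the standard ADME screen for herbal formulas:
    OB >= 15 %, DL >= 0.08, Caco-2 >= -0.4, plus Lipinski's rule
    (MW <= 500 Da, H-bond donors <= 5, acceptors <= 10, AlogP <= 5).
    """

    ob_min: float = 15.0
    dl_min: float = 0.08
    caco2_min: float = -0.4
    mw_max: float = 500.0
    hdon_max: int = 5
    hacc_max: int = 10
    alogp_max: float = 5.0

    def __post_init__(self) -> None:
        for fname in (
            "ob_min", "dl_min", "caco2_min", "mw_max", "hdon_max",
            "hacc_max", "alogp_max",
        ):
            if not math.isfinite(getattr(self, fname)):
                raise ValidationError(f"threshold {fname} must be finite")


PASS = "pass"
FAIL = "fail"
NOT_EVALUATED = "not_evaluated"


@dataclass(frozen=True)
class CriteriaEvaluation:
    """Per-criterion outcome of one compound against one criteria set."""

    compound_id: str
    flags: dict[str, str]  # criterion -> pass | fail | not_evaluated
    overall: bool

    @property
    def failing(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.flags.items() if v == FAIL)


def evaluate_criteria(c: CompoundRecord, crit: ScreeningCriteria) -> CriteriaEvaluation:
    """Evaluate one compound against the screen, criterion by criterion.

    All comparisons are inclusive (>= for minima, <= for maxima). Optional
    Lipinski fields that are absent from the record are marked
    ``not_evaluated`` and pass vacuously; the overall verdict is the
    conjunction of the evaluated flags.
    """
    checks: list[tuple[str, float | int | None, float, bool]] = [
        ("ob", c.ob, crit.ob_min, True),
        ("dl", c.dl, crit.dl_min, True),
        ("caco2", c.caco2, crit.caco2_min, True),
        ("mw", c.mw, crit.mw_max, False),
        ("hdon", c.hdon, crit.hdon_max, False),
        ("hacc", c.hacc, crit.hacc_max, False),
        ("alogp", c.alogp, crit.alogp_max, False),
    ]
    flags: dict[str, str] = {}
    for name, value, threshold, is_min in checks:
        if value is None:
            flags[name] = NOT_EVALUATED
            continue
        if not math.isfinite(value):
            raise ValidationError(f"{c.compound_id}: non-finite value for {name}")
        ok = value >= threshold if is_min else value <= threshold
        flags[name] = PASS if ok else FAIL
    overall = all(v != FAIL for v in flags.values())
    return CriteriaEvaluation(compound_id=c.compound_id, flags=flags, overall=overall)


# ---------------------------------------------------------------------------
# screening assembly
# ---------------------------------------------------------------------------

THRESHOLD_PASS = "threshold_pass"
WHITELIST_RESCUED = "whitelist_rescued"


@dataclass(frozen=True)
class ActiveCompound:
    record: CompoundRecord
    provenance: str  # threshold_pass | whitelist_rescued


@dataclass(frozen=True)
class Exclusion:
    compound_id: str
    reason: str  # threshold_fail | no_target | duplicate_merged_into:<id>
    failing: tuple[str, ...] = ()


@dataclass
class ActiveCompoundSet:
    """Outcome of the screening assembly: retained compounds plus a full
    exclusion log. No compound appears on both sides."""

    compounds: list[ActiveCompound] = field(default_factory=list)
    exclusions: list[Exclusion] = field(default_factory=list)

    @property
    def active_ids(self) -> list[str]:
        return [a.record.compound_id for a in self.compounds]

    def __len__(self) -> int:
        return len(self.compounds)


def _merge_records(first: CompoundRecord, other: CompoundRecord) -> CompoundRecord:
    return replace(first, herbs=first.herbs | other.herbs)


def screen_compounds(
    db: list[CompoundRecord],
    crit: ScreeningCriteria | None = None,
    whitelist: set[str] | frozenset[str] | None = None,
    target_index: dict[str, set[str]] | None = None,
) -> ActiveCompoundSet:
    """Run the full active-compound screen on a compound database.

    Pipeline order:

    1. threshold evaluation of every record against ``crit``;
    2. union with the whitelist — compounds named there are rescued even
       if they fail the numeric screen, tagged ``whitelist_rescued``;
    3. cross-herb duplicate merge keyed on the normalized compound name,
       uniting herb memberships (the surviving record is the first seen
       in input order; later duplicates are logged as merged);
    4. compounds absent from ``target_index`` (when one is supplied) are
       dropped with reason ``no_target``.

    The result is deterministic for a fixed input ordering, and every
    input record lands either in the active list or in the exclusion log.
    """
    if not db:
        raise ValidationError("compound database must be nonempty")
    crit = crit or ScreeningCriteria()
    wl_keys = {normalize_name(w) for w in (whitelist or set())}

    seen_wl = {k for c in db for k in (c.norm_name,) if k in wl_keys}
    for missed in sorted(wl_keys - seen_wl):
        log.warning("whitelist entry %r matches no compound in the database", missed)

    # stages 1-2: threshold evaluation and whitelist union
    candidates: list[ActiveCompound] = []
    exclusions: list[Exclusion] = []
    for rec in db:
        ev = evaluate_criteria(rec, crit)
        if ev.overall:
            candidates.append(ActiveCompound(rec, THRESHOLD_PASS))
        elif rec.norm_name in wl_keys:
            candidates.append(ActiveCompound(rec, WHITELIST_RESCUED))
        else:
            exclusions.append(Exclusion(rec.compound_id, "threshold_fail", ev.failing))

    # stage 3: cross-herb duplicate merge by normalized name
    merged: dict[str, ActiveCompound] = {}
    order: list[str] = []
    for cand in candidates:
        key = cand.record.norm_name
        if key not in merged:
            merged[key] = cand
            order.append(key)
        else:
            keeper = merged[key]
            prov = (
                THRESHOLD_PASS
                if THRESHOLD_PASS in (keeper.provenance, cand.provenance)
                else WHITELIST_RESCUED
            )
            merged[key] = ActiveCompound(
                _merge_records(keeper.record, cand.record), prov
            )
            exclusions.append(
                Exclusion(
                    cand.record.compound_id,
                    f"duplicate_merged_into:{keeper.record.compound_id}",
                )
            )

    # stage 4: drop compounds with no known target
    actives: list[ActiveCompound] = []
    for key in order:
        cand = merged[key]
        if target_index is not None and not target_index.get(
            cand.record.compound_id
        ):
            exclusions.append(Exclusion(cand.record.compound_id, "no_target"))
        else:
            actives.append(cand)

    if not actives:
        log.warning("screen produced an empty active set")
    return ActiveCompoundSet(compounds=actives, exclusions=exclusions)
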