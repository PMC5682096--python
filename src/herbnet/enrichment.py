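"""Hypergeometric over-representation analysis with FDR control.

A local gene-set enrichment engine over flat annotation collections
(GO biological-process terms, pathways): for a query gene set drawn from
a finite universe, each term's overlap is scored with the upper tail of
the hypergeometric distribution and adjusted for multiple testing with
the Benjamini-Hochberg step-up procedure, applied separately within each
annotation kind (mirroring separate GO and pathway runs).

An optional EASE mode computes the more conservative tail at k-1,
matching the modified Fisher statistic some annotation servers use; it
is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationTerm",
    "EnrichmentResult",
    "hypergeometric_tail",
    "bh_adjust",
    "enrich",
    "select_terms",
]

GO_BP = "GO_BP"
PATHWAY = "pathway"
KINDS = (GO_BP, PATHWAY)


@dataclass(frozen=True)
class AnnotationTerm:
    """One flat gene set: a GO BP term or a pathway."""

    term_id: str
    term_name: str
    kind: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"{self.term_id}: kind must be one of {KINDS}")
        if not self.genes:
            raise ValidationError(f"{self.term_id}: gene set must be nonempty")


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap statistics for one term against one query.

    k: overlap size, K: term size within the universe, n: query size
    within the universe, N: universe size; p_raw is the hypergeometric
    upper-tail probability P(X >= k) and p_adj its BH-adjusted value.
    """

    term: AnnotationTerm
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float

    @property
    def overlap_genes(self) -> frozenset[str]:  # convenience for reports
        return self.term.genes


def _validate_counts(k: int, K: int, n: int, N: int) -> None:
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a nonnegative integer, got {v!r}")
    if N < 1:
        raise ValidationError("universe size N must be >= 1")
    if K > N or n > N:
        raise ValidationError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValidationError(f"overlap k={k} exceeds min(K={K}, n={n})")


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the number of marked elements (term genes in
    the universe), n the draw size (query genes in the universe) and k the
    observed overlap. Computed in log space by scipy's survival function,
    stable for universes up to at least 1e5 genes.
    """
    _validate_counts(k, K, n, N)
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, scale p_(i) by m/i, enforce monotonicity from the
    largest rank downwards, cap at 1, and restore the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return np.asarray(stats.false_discovery_control(p, method="bh"), dtype=float)


def enrich(
    query: set[str],
    terms: list[AnnotationTerm],
    universe: set[str],
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Over-representation test of a query gene set against a term list.

    Query genes outside the universe are logged and clipped; term gene
    sets are intersected with the universe. Terms with zero overlap are
    not tested; the BH family is the set of tested terms of the same
    kind. Results are sorted by (p_adj asc, k desc, term_id asc).

    With ``ease=True`` the tail is evaluated at k-1 (one fewer overlap
    gene), the conservative variant popularised by annotation servers.
    """
    if not universe:
        raise ValidationError("gene universe must be nonempty")
    stray = query - universe
    if stray:
        log.warning("%d query genes outside the universe were clipped", len(stray))
    q = query & universe
    if not q:
        log.warning("empty query after clipping to universe; no enrichment computed")
        return []
    N = len(universe)
    n = len(q)

    tested: list[tuple[AnnotationTerm, int, int]] = []
    for t in terms:
        genes = t.genes & universe
        k = len(genes & q)
        if k >= 1:
            tested.append((t, k, len(genes)))

    raw: dict[str, list[float]] = {kind: [] for kind in KINDS}
    rows_by_kind: dict[str, list[tuple[AnnotationTerm, int, int]]] = {
        kind: [] for kind in KINDS
    }
    for t, k, K in tested:
        k_eff = max(k - 1, 0) if ease else k
        raw[t.kind].append(hypergeometric_tail(k_eff, K, n, N))
        rows_by_kind[t.kind].append((t, k, K))

    results: list[EnrichmentResult] = []
    for kind in KINDS:
        if not rows_by_kind[kind]:
            continue
        adj = bh_adjust(raw[kind])
        for (t, k, K), p_raw, p_adj in zip(rows_by_kind[kind], raw[kind], adj):
            results.append(
                EnrichmentResult(term=t, k=k, K=K, n=n, N=N,
                                 p_raw=float(p_raw), p_adj=float(p_adj))
            )
    results.sort(key=lambda r: (r.p_adj, -r.k, r.term.term_id))
    return results


def select_terms(
    results: list[EnrichmentResult],
    p_max: float,
    top_n: int | None = None,
    rank_keys=None,
    use_adjusted: bool = True,
) -> list[EnrichmentResult]:
    """Significance cut plus deterministic top-N extraction.

    Keep results whose (adjusted, by default) p-value is strictly below
    ``p_max``, then take the ``top_n`` best under ``rank_keys`` — by
    default gene count descending, adjusted p ascending, then term id,
    so ties never depend on input order.
    """
    if top_n is not None and top_n < 0:
        raise ValidationError("top_n must be >= 0")
    if rank_keys is None:
        rank_keys = lambda r: (-r.k, r.p_adj, r.term.term_id)  # noqa: E731
    passing = [
        r for r in results if (r.p_adj if use_adjusted else r.p_raw) < p_max
    ]
    passing.sort(key=rank_keys)
    return passing if top_n is None else passing[:top_n]
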