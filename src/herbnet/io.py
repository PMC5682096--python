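"""Readers and writers for every file dialect the pipeline touches.

Loaders are strict: unknown columns warn, malformed rows raise with file
and line context. Writers are deterministic — stable row ordering and
fixed float formatting (ratios to 2 decimals, percentages to 1 decimal,
p-values in scientific notation with 3 significant digits) — so reruns
on identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .enrichment import KINDS, AnnotationTerm, EnrichmentResult
from .errors import LoaderError
from .organ_map import ExpressionMatrix, OrganGroupScheme, OrganMapResult
from .screening import ActiveCompoundSet, CompoundRecord
from .target_fishing import InteractionRecord, TargetRecord

log = logging.getLogger(__name__)

__all__ = [
    "load_compound_table", "write_compound_table",
    "load_whitelist", "write_whitelist",
    "load_target_table", "write_target_table",
    "load_interaction_table", "write_interaction_table",
    "load_gmt", "write_gmt",
    "load_expression", "write_expression",
    "load_organ_scheme", "write_organ_scheme",
    "write_screening_report", "write_enrichment_report", "write_organ_report",
    "write_json",
]

_COMPOUND_COLS = ("id", "name", "herb", "ob", "caco2", "dl")
_COMPOUND_OPT = ("mw", "hdon", "hacc", "alogp")


def _read_tsv(path: str | Path, required: tuple[str, ...],
              optional: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         encoding="utf-8")
    except Exception as exc:  # malformed shape / encoding
        raise LoaderError(f"cannot parse TSV: {exc}", path=str(path)) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoaderError(f"missing columns {missing}", path=str(path))
    unknown = [c for c in df.columns if c not in required + optional]
    if unknown:
        log.warning("%s: ignoring unknown columns %s", path, unknown)
    return df


def _num(raw: str, field: str, path: Path, line: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise LoaderError(f"non-numeric {field}={raw!r}", path=str(path),
                          line=line) from None


def load_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound TSV (columns id, name, herb, ob, caco2, dl and
    optional mw, hdon, hacc, alogp; multi-herb membership is a
    semicolon-separated herb field)."""
    path = Path(path)
    df = _read_tsv(path, _COMPOUND_COLS, _COMPOUND_OPT)
    records: list[CompoundRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        herbs = frozenset(h.strip() for h in row.herb.split(";") if h.strip())
        if not herbs:
            raise LoaderError("empty herb field", path=str(path), line=line)

        def opt(col: str, integer: bool = False):
            raw = getattr(row, col, "")
            if raw == "":
                return None
            v = _num(raw, col, path, line)
            return int(v) if integer else v

        try:
            records.append(
                CompoundRecord(
                    compound_id=row.id,
                    name=row.name,
                    herbs=herbs,
                    ob=_num(row.ob, "ob", path, line),
                    caco2=_num(row.caco2, "caco2", path, line),
                    dl=_num(row.dl, "dl", path, line),
                    mw=opt("mw"),
                    hdon=opt("hdon", integer=True),
                    hacc=opt("hacc", integer=True),
                    alogp=opt("alogp"),
                )
            )
        except LoaderError:
            raise
        except Exception as exc:
            raise LoaderError(str(exc), path=str(path), line=line) from exc
    return records


def write_compound_table(records: list[CompoundRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "id": r.compound_id, "name": r.name, "herb": ";".join(sorted(r.herbs)),
            "ob": f"{r.ob:g}", "caco2": f"{r.caco2:g}", "dl": f"{r.dl:g}",
            "mw": "" if r.mw is None else f"{r.mw:g}",
            "hdon": "" if r.hdon is None else str(r.hdon),
            "hacc": "" if r.hacc is None else str(r.hacc),
            "alogp": "" if r.alogp is None else f"{r.alogp:g}",
        })
    pd.DataFrame(rows, columns=list(_COMPOUND_COLS) + list(_COMPOUND_OPT)).to_csv(
        path, sep="\t", index=False, encoding="utf-8", lineterminator="\n"
    )


def load_whitelist(path: str | Path) -> set[str]:
    """One compound name per line; blank lines and '#' comments allowed."""
    names: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            names.add(entry)
    return names


def write_whitelist(names, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{n}\n" for n in sorted(names)), encoding="utf-8"
    )


def load_target_table(path: str | Path) -> list[TargetRecord]:
    """Read a target mapping TSV (uniprot, gene_symbol, protein_name)."""
    path = Path(path)
    df = _read_tsv(path, ("uniprot", "gene_symbol"), ("protein_name",))
    records: list[TargetRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(TargetRecord(row.uniprot, row.gene_symbol,
                                        getattr(row, "protein_name", "")))
        except Exception as exc:
            raise LoaderError(str(exc), path=str(path), line=i + 2) from exc
    return records


def write_target_table(records: list[TargetRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"uniprot": r.uniprot_id, "gene_symbol": r.gene_symbol,
          "protein_name": r.protein_name} for r in records],
        columns=["uniprot", "gene_symbol", "protein_name"],
    ).to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


def load_interaction_table(path: str | Path) -> list[InteractionRecord]:
    """Read a scored interaction TSV (compound_id, uniprot, svm, rf).

    Duplicate (compound, target) pairs are collapsed to the first
    occurrence with a warning, so downstream edge counts are over unique
    pairs."""
    path = Path(path)
    df = _read_tsv(path, ("compound_id", "uniprot", "svm", "rf"))
    records: list[InteractionRecord] = []
    seen: set[tuple[str, str]] = set()
    dups = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        key = (row.compound_id, row.uniprot)
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        try:
            records.append(
                InteractionRecord(row.compound_id, row.uniprot,
                                  _num(row.svm, "svm", path, line),
                                  _num(row.rf, "rf", path, line))
            )
        except LoaderError:
            raise
        except Exception as exc:
            raise LoaderError(str(exc), path=str(path), line=line) from exc
    if dups:
        log.warning("%s: collapsed %d duplicate compound-target pairs", path, dups)
    return records


def write_interaction_table(records: list[InteractionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"compound_id": r.compound_id, "uniprot": r.target_uniprot,
          "svm": f"{r.svm_score:.4f}", "rf": f"{r.rf_score:.4f}"}
         for r in records],
        columns=["compound_id", "uniprot", "svm", "rf"],
    ).to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


def load_gmt(path: str | Path, kind: str) -> list[AnnotationTerm]:
    """Read a GMT file (term_id <tab> description <tab> gene1 <tab> ...)."""
    if kind not in KINDS:
        raise LoaderError(f"unknown annotation kind {kind!r}")
    path = Path(path)
    terms: list[AnnotationTerm] = []
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise LoaderError("GMT line needs term, description and >= 1 gene",
                              path=str(path), line=i)
        term_id, name, *genes = parts
        genes = [g for g in genes if g]
        if not genes:
            raise LoaderError(f"term {term_id!r} has no genes",
                              path=str(path), line=i)
        terms.append(AnnotationTerm(term_id, name, kind, frozenset(genes)))
    return terms


def write_gmt(terms: list[AnnotationTerm], path: str | Path) -> None:
    lines = [
        t.term_id + "\t" + t.term_name + "\t" + "\t".join(sorted(t.genes)) + "\n"
        for t in sorted(terms, key=lambda t: t.term_id)
    ]
    Path(path).write_text("".join(lines), encoding="utf-8")


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x tissues TSV (first column gene symbol)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    except Exception as exc:
        raise LoaderError(f"cannot parse expression TSV: {exc}",
                          path=str(path)) from exc
    try:
        return ExpressionMatrix(df)
    except Exception as exc:
        raise LoaderError(str(exc), path=str(path)) from exc


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.frame.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", encoding="utf-8", float_format="%.3f",
               lineterminator="\n")


def load_organ_scheme(path: str | Path) -> OrganGroupScheme:
    """Read a JSON mapping of group name -> list of tissue labels."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except Exception as exc:
        raise LoaderError(f"cannot parse scheme JSON: {exc}",
                          path=str(path)) from exc
    if not isinstance(raw, dict):
        raise LoaderError("scheme must be a JSON object", path=str(path))
    try:
        return OrganGroupScheme(
            groups={k: frozenset(v) for k, v in raw.items()}
        )
    except Exception as exc:
        raise LoaderError(str(exc), path=str(path)) from exc


def write_organ_scheme(scheme: OrganGroupScheme, path: str | Path) -> None:
    payload = {k: sorted(v) for k, v in scheme.groups.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_screening_report(result: ActiveCompoundSet, db: list[CompoundRecord],
                           path: str | Path) -> None:
    """One row per input compound: retained compounds first (with
    provenance), then exclusions (with reason and failing criteria)."""
    by_id = {r.compound_id: r for r in db}
    rows = []
    for a in result.compounds:
        rows.append({
            "id": a.record.compound_id, "name": a.record.name,
            "herbs": ";".join(sorted(a.record.herbs)),
            "status": a.provenance, "failing": "",
        })
    for e in result.exclusions:
        rec = by_id.get(e.compound_id)
        rows.append({
            "id": e.compound_id, "name": rec.name if rec else "",
            "herbs": ";".join(sorted(rec.herbs)) if rec else "",
            "status": e.reason, "failing": ";".join(e.failing),
        })
    pd.DataFrame(rows, columns=["id", "name", "herbs", "status", "failing"]).to_csv(
        path, sep="\t", index=False, encoding="utf-8", lineterminator="\n"
    )


def _sci(p: float) -> str:
    return f"{p:.2e}"  # 3 significant digits


def write_enrichment_report(results: list[EnrichmentResult], path: str | Path) -> None:
    cols = ["term_id", "name", "kind", "k", "K", "n", "N", "p_raw", "p_adj"]
    pd.DataFrame(
        [{"term_id": r.term.term_id, "name": r.term.term_name, "kind": r.term.kind,
          "k": r.k, "K": r.K, "n": r.n, "N": r.N,
          "p_raw": _sci(r.p_raw), "p_adj": _sci(r.p_adj)}
         for r in results],
        columns=cols,
    ).to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


def write_organ_report(result: OrganMapResult, scheme: OrganGroupScheme,
                       tsv_path: str | Path, json_path: str | Path) -> None:
    rows = []
    for g in result.genes:
        row = {
            "gene": g.gene,
            "mean_intensity": f"{g.mean_intensity:.3f}",
            "n_above_average": len(g.above_average_tissues),
        }
        for name in scheme.names:
            row[name] = int(g.group_flags[name])
        rows.append(row)
    cols = ["gene", "mean_intensity", "n_above_average"] + scheme.names
    pd.DataFrame(rows, columns=cols).to_csv(
        tsv_path, sep="\t", index=False, encoding="utf-8", lineterminator="\n"
    )
    summary = {
        "n_query": result.n_analyzed + len(result.excluded),
        "n_analyzed": result.n_analyzed,
        "excluded": result.excluded,
        "group_counts": result.group_counts,
        "all_group_genes": result.all_group_genes,
        "pct_multi_group": result.pct_multi_group,
    }
    write_json(summary, json_path)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
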