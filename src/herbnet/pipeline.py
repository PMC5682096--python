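"""End-to-end orchestration of the five analysis stages.

screen -> fish -> enrich -> networks -> organ map, with per-stage
reports, Cytoscape exports and a machine-readable run summary (record
counts per stage, parameters, input checksums). Reruns on identical
inputs and configuration are byte-identical: nothing time- or
path-order-dependent is ever written.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

from pydantic import BaseModel, Field

from . import io
from .enrichment import GO_BP, PATHWAY, enrich, select_terms
from .errors import HerbnetError, ValidationError
from .networks import build_hct, build_tp, summarize, write_graphml, write_sif
from .organ_map import map_genes
from .screening import ScreeningCriteria, screen_compounds
from .target_fishing import filter_interactions, map_targets

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "simulate_study"]


class PipelineError(HerbnetError):
    """A stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(BaseModel):
    """Validated run configuration; all referenced inputs must exist."""

    compounds: Path
    targets: Path
    interactions: Path
    whitelist: Path | None = None
    go_gmt: Path | None = None
    pathway_gmt: Path | None = None
    expression: Path | None = None
    organ_scheme: Path | None = None
    outdir: Path = Path("herbnet_run")
    criteria: dict[str, float] = Field(default_factory=dict)
    svm_min: float = 0.8
    rf_min: float = 0.7
    p_max_go: float = 0.01
    p_max_pathway: float = 0.05
    top_n_go: int = 30
    top_n_pathway: int = 40
    use_adjusted: bool = True
    seed: int | None = None

    def validate_paths(self) -> None:
        for fname in ("compounds", "targets", "interactions", "whitelist",
                      "go_gmt", "pathway_gmt", "expression", "organ_scheme"):
            p = getattr(self, fname)
            if p is not None and not Path(p).is_file():
                raise ValidationError(f"config path {fname} does not exist: {p}")
        if not (0 < self.p_max_go <= 1 and 0 < self.p_max_pathway <= 1):
            raise ValidationError("p_max thresholds must lie in (0, 1]")
        if self.top_n_go < 0 or self.top_n_pathway < 0:
            raise ValidationError("top_n must be >= 0")

    def screening_criteria(self) -> ScreeningCriteria:
        return ScreeningCriteria(**self.criteria)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages in order; returns the run summary.

    Stages whose inputs are not configured (no GMT file, no expression
    matrix) are skipped and recorded as such. On any stage failure a
    FAILED marker naming the stage is left in the output directory and
    a :class:`PipelineError` is raised; partial outputs are retained.
    """
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": cfg.model_dump(mode="json"), "stages": {}}
    summary["inputs"] = {
        name: _sha256(Path(p))
        for name in ("compounds", "targets", "interactions", "whitelist",
                     "go_gmt", "pathway_gmt", "expression", "organ_scheme")
        if (p := getattr(cfg, name)) is not None
    }

    stage = "screen"
    try:
        db = io.load_compound_table(cfg.compounds)
        whitelist = io.load_whitelist(cfg.whitelist) if cfg.whitelist else set()
        raw_interactions = io.load_interaction_table(cfg.interactions)
        retained = filter_interactions(raw_interactions, cfg.svm_min, cfg.rf_min)
        target_index: dict[str, set[str]] = {}
        for r in retained:
            target_index.setdefault(r.compound_id, set()).add(r.target_uniprot)
        active = screen_compounds(db, cfg.screening_criteria(), whitelist,
                                  target_index)
        io.write_screening_report(active, db, outdir / "screening_report.tsv")
        summary["stages"][stage] = {
            "n_input_compounds": len(db),
            "n_active": len(active),
            "n_threshold_pass": sum(
                1 for a in active.compounds if a.provenance == "threshold_pass"
            ),
            "n_whitelist_rescued": sum(
                1 for a in active.compounds if a.provenance == "whitelist_rescued"
            ),
            "n_excluded": len(active.exclusions),
        }
    except Exception as exc:
        _fail(outdir, stage, exc)

    stage = "fish"
    try:
        active_ids = set(active.active_ids)
        edges = [r for r in retained if r.compound_id in active_ids]
        mapping = io.load_target_table(cfg.targets)
        mapped = map_targets(edges, mapping)
        io.write_interaction_table(edges, outdir / "retained_interactions.tsv")
        summary["stages"][stage] = {
            "n_scored": len(raw_interactions),
            "n_retained": len(retained),
            "n_active_edges": len(edges),
            "n_mapped": len(mapped.edges),
            "n_unmapped": len(mapped.unmapped),
            "n_unique_targets": len(mapped.unique_genes),
        }
    except Exception as exc:
        _fail(outdir, stage, exc)

    stage = "enrich"
    query = sorted(mapped.unique_genes)
    selected_pathways = []
    try:
        enrich_counts = {}
        for kind, path, p_max, top_n, out_name in (
            (GO_BP, cfg.go_gmt, cfg.p_max_go, cfg.top_n_go, "enrichment_go.tsv"),
            (PATHWAY, cfg.pathway_gmt, cfg.p_max_pathway, cfg.top_n_pathway,
             "enrichment_pathway.tsv"),
        ):
            if path is None:
                enrich_counts[kind] = None
                continue
            terms = io.load_gmt(path, kind)
            universe = {g for t in terms for g in t.genes}
            results = enrich(set(query), terms, universe)
            io.write_enrichment_report(results, outdir / out_name)
            picked = select_terms(results, p_max, top_n,
                                  use_adjusted=cfg.use_adjusted)
            if kind == PATHWAY:
                selected_pathways = picked
            enrich_counts[kind] = {
                "n_terms": len(terms), "n_tested": len(results),
                "n_selected": len(picked),
            }
        summary["stages"][stage] = enrich_counts
    except Exception as exc:
        _fail(outdir, stage, exc)

    stage = "network"
    try:
        membership: dict[str, list[str]] = {}
        for a in active.compounds:
            for herb in sorted(a.record.herbs):
                membership.setdefault(herb, []).append(a.record.compound_id)
        gene_of = {t.uniprot_id: t.gene_symbol for t in mapping}
        ct_edges = sorted({(e.compound_id, gene_of[e.target_uniprot])
                           for e in mapped.edges})
        hct = build_hct(membership, ct_edges)
        write_sif(hct, outdir / "hct.sif", outdir / "hct_nodes.tsv")
        write_graphml(hct, outdir / "hct.graphml")
        s = summarize(hct)
        net_summary = {
            "hct": {
                "n_nodes": hct.n_nodes, "n_edges": hct.n_edges,
                "ct_edge_count": s.ct_edge_count,
                "n_compounds": s.n_compounds, "n_targets": s.n_targets,
                "targets_per_compound": s.targets_per_compound,
                "mean_compound_degree": round(s.mean_compound_degree, 2),
                "pct_targets_multi_compound": s.pct_targets_multi_compound,
            }
        }
        if selected_pathways:
            qset = set(query)
            tp_edges = sorted({
                (g, r.term.term_id)
                for r in selected_pathways
                for g in (r.term.genes & qset)
            })
            tp = build_tp(tp_edges)
            write_sif(tp, outdir / "tp.sif", outdir / "tp_nodes.tsv")
            write_graphml(tp, outdir / "tp.graphml")
            net_summary["tp"] = {
                "n_nodes": tp.n_nodes, "n_edges": tp.n_edges,
                "n_pathways": len(tp.nodes("pathway")),
                "n_connected_targets": len(tp.nodes("target")),
            }
        summary["stages"][stage] = net_summary
    except Exception as exc:
        _fail(outdir, stage, exc)

    stage = "organmap"
    try:
        if cfg.expression is None:
            summary["stages"][stage] = None
        else:
            matrix = io.load_expression(cfg.expression)
            scheme = (io.load_organ_scheme(cfg.organ_scheme)
                      if cfg.organ_scheme else _default_scheme())
            result = map_genes(query, matrix, scheme)
            io.write_organ_report(result, scheme,
                                  outdir / "organ_map.tsv",
                                  outdir / "organ_summary.json")
            summary["stages"][stage] = {
                "n_query": len(query),
                "n_analyzed": result.n_analyzed,
                "n_excluded": len(result.excluded),
                "n_mapped": result.n_mapped,
                "group_counts": result.group_counts,
                "pct_multi_group": result.pct_multi_group,
            }
    except Exception as exc:
        _fail(outdir, stage, exc)

    io.write_json(summary, outdir / "run_summary.json")
    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()
    return summary


def simulate_study(params, outdir: str | Path) -> RunConfig:
    """Write a complete synthetic study to ``outdir`` and return a
    ready-to-run configuration for it.

    Emits the per-herb compound table, a synthetic target mapping whose
    accessions T0001.. map to gene symbols G00001.., a scored
    interaction table over the compound-table ids, GO-BP and pathway GMT
    collections with one planted term each, an expression matrix over
    the first ``n_genes`` universe genes, the organ scheme, one
    ground-truth sidecar JSON per dataset, and ``config.json``.
    """
    from dataclasses import replace as _replace

    from .synth import (
        generate_annotations,
        generate_compound_db,
        generate_expression,
        generate_interactions,
    )
    from .target_fishing import TargetRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, c_truth = generate_compound_db(params)
    io.write_compound_table(records, outdir / "compounds.tsv")
    io.write_json(c_truth, outdir / "compounds.truth.json")

    targets = [
        TargetRecord(f"T{i + 1:04d}", f"G{i + 1:05d}", f"synthetic protein {i + 1}")
        for i in range(params.n_targets)
    ]
    io.write_target_table(targets, outdir / "targets.tsv")

    compound_ids = [r.compound_id for r in records]
    p_edges = _replace(params, n_compounds=len(compound_ids))
    interactions, i_truth = generate_interactions(
        p_edges, compound_ids=compound_ids,
        target_ids=[t.uniprot_id for t in targets],
    )
    io.write_interaction_table(interactions, outdir / "interactions.tsv")
    io.write_json(i_truth, outdir / "interactions.truth.json")

    go_terms, go_query, _, go_truth = generate_annotations(params, GO_BP)
    pw_terms, pw_query, _, pw_truth = generate_annotations(params, PATHWAY)
    io.write_gmt(go_terms, outdir / "go_bp.gmt")
    io.write_gmt(pw_terms, outdir / "pathways.gmt")
    io.write_json({"GO_BP": {**go_truth, "query": sorted(go_query)},
                   "pathway": {**pw_truth, "query": sorted(pw_query)}},
                  outdir / "annotations.truth.json")

    genes = [f"G{i + 1:05d}" for i in range(params.n_genes)]
    matrix, scheme, e_truth = generate_expression(params, genes=genes)
    io.write_expression(matrix, outdir / "expression.tsv")
    io.write_organ_scheme(scheme, outdir / "organ_groups.json")
    io.write_json(e_truth, outdir / "expression.truth.json")

    cfg = RunConfig(
        compounds=outdir / "compounds.tsv",
        targets=outdir / "targets.tsv",
        interactions=outdir / "interactions.tsv",
        go_gmt=outdir / "go_bp.gmt",
        pathway_gmt=outdir / "pathways.gmt",
        expression=outdir / "expression.tsv",
        organ_scheme=outdir / "organ_groups.json",
        outdir=outdir / "run",
        seed=params.seed,
    )
    io.write_json(cfg.model_dump(mode="json"), outdir / "config.json")
    return cfg


def _default_scheme():
    from .datasets import bundled_organ_scheme

    return bundled_organ_scheme()


def _fail(outdir: Path, stage: str, exc: Exception) -> None:
    (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n",
                                   encoding="utf-8")
    raise PipelineError(stage, exc)
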