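"""End-to-end pipeline: ingest → merge → map → classify → benchmarks → reports.

The run is configured by a single JSON file (paths to the three sources, the
alias map, candidates, citations and the phenotype synonym config) and emits
diff-friendly TSV/JSON reports plus a manifest with row counts at every
stage.  All stages are deterministic; the seed in the config exists only to
be recorded and forwarded to synthetic generation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import benchmarks as bm
from . import core, ingest

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sources: list[dict]  # each: {path, dialect, id}
    aliases: str
    candidates: str
    citations: str
    synonyms: str
    output_dir: str
    genome_size: int = 20000
    citation_thresholds: tuple[int, ...] = (1, 5, 10, 15)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        cfg = json.loads(Path(path).read_text())
        return cls(
            sources=cfg["sources"],
            aliases=cfg["aliases"],
            candidates=cfg["candidates"],
            citations=cfg["citations"],
            synonyms=cfg["synonyms"],
            output_dir=cfg["output_dir"],
            genome_size=int(cfg.get("genome_size", 20000)),
            citation_thresholds=tuple(cfg.get("citation_thresholds", (1, 5, 10, 15))),
            seed=int(cfg.get("seed", 0)),
            log_level=cfg.get("log_level", "INFO"),
        )

    def validate(self) -> None:
        th = self.citation_thresholds
        if not th or any(t <= 0 for t in th) or list(th) != sorted(set(th)):
            raise ValueError("citation thresholds must be strictly increasing positive integers")
        for entry in self.sources:
            if entry["dialect"] not in ingest.DIALECTS:
                raise ValueError(f"unknown dialect {entry['dialect']!r}")
            if not Path(entry["path"]).exists():
                raise FileNotFoundError(f"source file not found: {entry['path']}")
        for name in ("aliases", "candidates", "citations", "synonyms"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


@dataclass
class ReportBundle:
    """Everything a run produces, in memory plus on disk under output_dir."""

    config: RunConfig
    unified: ingest.UnifiedDrugTable
    overlap: ingest.OverlapReport
    parse_reports: list[ingest.ParseReport]
    reports: list[core.PhenotypeTargetReport]
    calls: list[core.RepositioningCall]
    novel_drugs: dict[str, set[str]]  # phenotype -> repositionable drug keys
    confusion_by_phenotype: dict[str, list[bm.ConfusionMatrix]]
    roc_by_phenotype: dict[str, bm.RocCurve]
    citation_roc_by_phenotype: dict[str, bm.CitationBenchmarkResult]
    manifest: dict = field(default_factory=dict)

    @property
    def reports_by_phenotype(self) -> dict[str, core.PhenotypeTargetReport]:
        return {r.phenotype: r for r in self.reports}


def _stage(manifest: dict, name: str, **counts) -> None:
    manifest["stages"].append({"stage": name, **counts})
    logger.info("stage %s: %s", name, counts)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the whole workflow and write the report bundle to disk."""
    t0 = time.perf_counter()
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "inputs": {
            "sources": config.sources,
            "aliases": config.aliases,
            "candidates": config.candidates,
            "citations": config.citations,
            "synonyms": config.synonyms,
        },
        "seed": config.seed,
        "genome_size": config.genome_size,
        "stages": [],
    }

    # --- ingest -----------------------------------------------------------
    alias_map = ingest.load_alias_map(config.aliases)
    parsed = []
    for entry in config.sources:
        ps = ingest.parse_source(
            entry["path"], entry["dialect"], alias_map, source_id=entry.get("id")
        )
        parsed.append(ps)
        _stage(
            manifest,
            f"parse:{ps.source}",
            file_rows=ps.report.n_rows,
            rows_in=ps.report.n_units,
            rejected=ps.report.n_rejected,
            deduplicated=ps.report.n_duplicates,
            rows_out=ps.report.n_associations,
        )

    all_assoc = [a for ps in parsed for a in ps.associations]
    human = ingest.filter_human(all_assoc)
    _stage(
        manifest,
        "filter_human",
        rows_in=len(all_assoc),
        rejected=len(all_assoc) - len(human),
        deduplicated=0,
        rows_out=len(human),
    )
    unified = ingest.merge_sources(
        [(list(filter(lambda a: a.source == ps.source, human)), ps.drugs) for ps in parsed]
    )
    _stage(
        manifest,
        "merge_sources",
        rows_in=len(human),
        rejected=0,
        deduplicated=len(human) - len(unified.associations),
        rows_out=len(unified.associations),
    )
    overlap = ingest.overlap_stats(unified, config.genome_size)
    ingest.write_unified_table(unified, outdir / "unified_targets.tsv")
    (outdir / "overlap.json").write_text(json.dumps(overlap.to_dict(), indent=1, sort_keys=True))

    # --- phenotype mapping and classification -----------------------------
    synonyms = core.load_synonyms(config.synonyms)
    candidate_sets = core.read_candidates(config.candidates)
    citations = bm.read_citations(config.citations)
    phenotypes = sorted({cs.phenotype for cs in candidate_sets})
    unknown = [p for p in phenotypes if p not in synonyms]
    if unknown:
        raise ValueError(f"candidates reference phenotypes with no synonym entry: {unknown}")

    reports: list[core.PhenotypeTargetReport] = []
    all_calls: list[core.RepositioningCall] = []
    novel_drugs: dict[str, set[str]] = {}
    for code in phenotypes:
        ph = synonyms[code]
        cand_union = core.phenotype_candidate_union(candidate_sets, code)
        rep = core.build_phenotype_report(ph, cand_union, unified)
        reports.append(rep)
        for gene in sorted(rep.replicated_targets | rep.novel_targets):
            _, calls = core.classify_target(gene, ph, unified)
            all_calls.extend(calls)
        drugs, _ = core.enumerate_novel_drugs(rep.novel_targets, ph, unified)
        novel_drugs[code] = drugs
    core.assign_ranks(reports)
    _stage(
        manifest,
        "phenotype_reports",
        rows_in=len(candidate_sets),
        rejected=0,
        deduplicated=0,
        rows_out=len(reports),
    )

    # --- benchmark 1: search-space classification (WS tier) ---------------
    confusion: dict[str, list[bm.ConfusionMatrix]] = {}
    roc1: dict[str, bm.RocCurve] = {}
    known_by_pheno: dict[str, set[str]] = {}
    for code in phenotypes:
        ph = synonyms[code]
        known = core.replicated_target_set(ph, unified)
        known_by_pheno[code] = known
        spaces = sorted(
            (cs for cs in candidate_sets if cs.phenotype == code and cs.tier == "WS"),
            key=lambda cs: cs.search_space_id,
        )
        mats = [
            bm.build_confusion_matrix(
                cs.search_space_genes,
                cs.genes,
                known,
                unified.targets,
                search_space_id=cs.search_space_id,
                phenotype=code,
            )
            for cs in spaces
        ]
        confusion[code] = mats
        if mats:
            curve = bm.roc_from_search_spaces(mats)
            if curve.auc is not None and curve.n_pos and curve.n_neg:
                curve.p_value = bm.auc_significance(curve, curve.n_pos, curve.n_neg)
            roc1[code] = curve

    # --- benchmark 2: literature citations --------------------------------
    roc2: dict[str, bm.CitationBenchmarkResult] = {}
    for code in phenotypes:
        spaces = [
            cs for cs in candidate_sets if cs.phenotype == code and cs.tier == "WS"
        ]
        if not spaces:
            continue
        widest = max(spaces, key=lambda cs: len(cs.search_space_genes))
        predicted_targets = core.map_candidates_to_targets(
            core.phenotype_candidate_union(candidate_sets, code), unified
        )
        roc2[code] = bm.citation_benchmark(
            predicted_targets,
            widest.search_space_genes,
            citations.for_phenotype(code),
            thresholds=config.citation_thresholds,
            phenotype=code,
        )

    bundle = ReportBundle(
        config=config,
        unified=unified,
        overlap=overlap,
        parse_reports=[ps.report for ps in parsed],
        reports=reports,
        calls=all_calls,
        novel_drugs=novel_drugs,
        confusion_by_phenotype=confusion,
        roc_by_phenotype=roc1,
        citation_roc_by_phenotype=roc2,
        manifest=manifest,
    )
    _write_bundle(bundle, outdir)
    manifest["elapsed_seconds"] = round(time.perf_counter() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return bundle


def _write_bundle(bundle: ReportBundle, outdir: Path) -> None:
    core.reports_to_frame(bundle.reports).to_csv(
        outdir / "phenotype_report.tsv", sep="\t", index=False
    )
    calls = core.calls_to_frame(bundle.calls)
    calls[calls["verdict"] == "replicated"].to_csv(
        outdir / "replicated_calls.tsv", sep="\t", index=False
    )
    calls[calls["verdict"] == "novel"].to_csv(
        outdir / "novel_calls.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"phenotype": p, "n_novel_drugs": len(d), "drug_keys": "|".join(sorted(d))}
            for p, d in sorted(bundle.novel_drugs.items())
        ]
    ).to_csv(outdir / "novel_drugs.tsv", sep="\t", index=False)
    conf_rows = [
        {
            "phenotype": p,
            "search_space_id": m.search_space_id,
            "total": m.total,
            "TP": m.tp,
            "FP": m.fp,
            "FN": m.fn,
            "TN": m.tn,
        }
        for p, mats in sorted(bundle.confusion_by_phenotype.items())
        for m in mats
    ]
    pd.DataFrame(conf_rows).to_csv(outdir / "benchmark1_confusion.tsv", sep="\t", index=False)
    roc_payload = {
        "search_space_benchmark": {p: c.to_dict() for p, c in sorted(bundle.roc_by_phenotype.items())},
        "citation_benchmark": {
            p: r.curve.to_dict() for p, r in sorted(bundle.citation_roc_by_phenotype.items())
        },
    }
    (outdir / "roc_auc.json").write_text(json.dumps(roc_payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------


def summarize(bundle: ReportBundle) -> str:
    """Human-readable run summary; partial bundles mark missing sections."""
    lines: list[str] = []
    lines.append(
        f"unified table: {len(bundle.unified.associations)} associations, "
        f"{len(bundle.unified.targets)} targets, {len(bundle.unified.drugs)} drugs "
        f"({100 * bundle.overlap.genome_coverage:.1f}% of a {bundle.overlap.genome_size}-gene genome)"
    )
    header = f"{'PH':<6}{'cand':>6}{'TT':>5}{'TI':>6}{'RTT':>5}{'NTT':>6}{'NV':>6}{'AT':>5}{'CT':>5}"
    lines.append(header)
    for r in bundle.reports:
        ti = f"{r.TI.rounded:.2f}" if r.TI else "--"
        nv = f"{r.NV.rounded:.2f}" if r.NV else "--"
        lines.append(
            f"{r.phenotype:<6}{r.n_candidates:>6}{r.TT:>5}{ti:>6}{r.RTT:>5}{r.NTT:>6}"
            f"{nv:>6}{r.status.AT:>5}{r.status.CT:>5}"
        )
    uniq_targets = set().union(*(set(r.replicated_targets | r.novel_targets) for r in bundle.reports)) if bundle.reports else set()
    uniq_known = set().union(*(set(r.replicated_targets) for r in bundle.reports)) if bundle.reports else set()
    lines.append(
        f"unique targets across phenotypes: {len(uniq_targets)} "
        f"(column sum {sum(r.TT for r in bundle.reports)}); "
        f"unique known targets: {len(uniq_known)} (row sum {sum(r.RTT for r in bundle.reports)})"
    )
    if bundle.roc_by_phenotype:
        lines.append("benchmark 1 (search spaces):")
        for p, c in sorted(bundle.roc_by_phenotype.items()):
            if c.auc is None:
                lines.append(f"  {p}: undefined TPR (no known targets)")
            else:
                lines.append(f"  {p}: AUC={c.auc:.3f} p={c.p_value:.2g}")
    else:
        lines.append("benchmark 1 (search spaces): not run")
    if bundle.citation_roc_by_phenotype:
        lines.append("benchmark 2 (citations):")
        for p, r in sorted(bundle.citation_roc_by_phenotype.items()):
            c = r.curve
            if c.auc is None:
                lines.append(f"  {p}: undefined (no supported genes)")
            else:
                p_txt = f" p={c.p_value:.2g}" if c.p_value is not None else ""
                lines.append(f"  {p}: AUC={c.auc:.3f}{p_txt}")
    else:
        lines.append("benchmark 2 (citations): not run")
    return "\n".join(lines)
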