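"""End-to-end orchestration: filter -> cluster -> prioritise -> prune -> ORA.

Each stage writes its intermediate table as TSV into the output directory
and a plain-text manifest records the configuration, the seed, and the row
counts per stage, so a run can be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    annotate_catalog, annotation_concordance, load_annotation,
    prioritise_clusters, prioritised_report,
)
from .catalog_io import (
    Catalog, deduplicate, filter_catalog, merge_catalogs, read_catalog,
    read_regulome_scores, with_regulome_scores,
)
from .clustering import build_clusters, clusters_to_frame, select_cross_phenotype
from .enrichment import read_gmt, results_to_frame, run_grouped_ora
from .errors import ConfigurationError, StageError
from .ld_prune import prune_clusters, read_ld_table, removal_report, summarise_selection

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults are the published study's: association p-value
    strictly below 1e-5, MAF at least 1%, a 1-Mbp window, LD redundancy at
    r² above 0.7, and ORA significance at p below 0.01 with the BH q-value
    below 0.05 over sets overlapping the query in at least 2 genes.
    """

    catalogs: list[str] = field(default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)
    ld_file: str | None = None
    scores_file: str | None = None
    gmt_files: list[str] = field(default_factory=list)
    dialect: dict[str, str] = field(default_factory=dict)
    phenotype_map: dict[str, str] = field(default_factory=dict)
    anchor: str = "height"
    partners: list[str] = field(default_factory=lambda: ["breast_cancer", "colorectal_cancer"])
    window_bp: int = 1_000_000
    p_max: float = 1e-5
    maf_min: float = 0.01
    r2_min: float = 0.7
    min_overlap: int = 2
    p_cutoff: float = 0.01
    q_cutoff: float = 0.05
    #: "auto", an integer background size, or a path to a gene-list file
    universe: str | int = "auto"
    #: which annotation source supplies the ORA query genes
    query_source: str | None = None
    out_dir: str = "snpclust_out"
    seed: int = 0

    def __post_init__(self):
        if self.anchor in self.partners:
            raise ConfigurationError("anchor must not appear among partners")
        if not (0 < self.p_max <= 1 and 0 <= self.maf_min <= 0.5
                and 0 <= self.r2_min <= 1 and 0 < self.p_cutoff <= 1
                and 0 < self.q_cutoff <= 1 and self.window_bp > 0):
            raise ConfigurationError("a threshold is outside its valid range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    catalog: Catalog
    clusters: list
    prioritised: list
    pruned: list
    summary: pd.DataFrame
    concordance: tuple[int, int, float | None] | None
    enrichment: dict[str, list]
    manifest: dict


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def _config_hash(cfg: PipelineConfig) -> str:
    payload = yaml.safe_dump(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage, writing intermediates and a run manifest.

    Any stage failure raises :class:`StageError` carrying the stage name;
    tables written before the failure are left in place for inspection.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "snpclust_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
    }

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                logger.info("stage %s: done", name)
        return _Ctx()

    with stage("read"):
        if not cfg.catalogs:
            raise ConfigurationError("no catalog files configured")
        cats = [
            read_catalog(p, dialect=cfg.dialect or None,
                         phenotype_map=cfg.phenotype_map or None)
            for p in cfg.catalogs
        ]
        cat = merge_catalogs(cats)
        manifest["n_input_records"] = sum(len(c) for c in cats)
        manifest["n_rejected_rows"] = len(cat.rejects)
        if cat.rejects:
            _write(cat.rejects_frame(), out / "rejects.tsv")

    with stage("filter"):
        cat = filter_catalog(cat, p_max=cfg.p_max, maf_min=cfg.maf_min)
        cat = deduplicate(cat)
        manifest["n_after_filter"] = len(cat)
        for ph, n in sorted(cat.phenotype_counts.items()):
            manifest[f"n_{ph}"] = n

    with stage("annotate"):
        sources = [load_annotation(path, name) for name, path in cfg.annotations.items()]
        if cfg.scores_file:
            cat = with_regulome_scores(cat, read_regulome_scores(cfg.scores_file))
        cat = annotate_catalog(cat, sources)
        _write(cat.to_frame(), out / "catalog.tsv")
        if len(sources) == 2:
            concordance = annotation_concordance(cat, sources[0].name, sources[1].name)
            manifest["concordance_matching"] = concordance[0]
            manifest["concordance_available"] = concordance[1]
            manifest["concordance_pct"] = (
                round(concordance[2], 1) if concordance[2] is not None else "NA"
            )
        else:
            concordance = None

    with stage("cluster"):
        clusters = build_clusters(cat, cfg.window_bp)
        manifest["n_clusters"] = len(clusters)
        _write(clusters_to_frame(clusters), out / "clusters.tsv")

    with stage("select"):
        selected = select_cross_phenotype(clusters, cfg.anchor, set(cfg.partners))
        manifest["n_cross_phenotype_clusters"] = len(selected)
        manifest["n_cross_phenotype_snps"] = sum(len(c) for c in selected)

    with stage("prioritise"):
        flagged = prioritise_clusters(selected, cfg.anchor, set(cfg.partners))
        prioritised = [cl for cl in flagged if cl.prioritised]
        manifest["n_prioritised_clusters"] = len(prioritised)
        manifest["n_prioritised_snps"] = sum(len(c) for c in prioritised)
        _write(prioritised_report(prioritised), out / "prioritised.tsv")

    with stage("prune"):
        if cfg.ld_file:
            ld = read_ld_table(cfg.ld_file)
        else:
            from .ld_prune import LdTable
            ld = LdTable()
        pruned, groups = prune_clusters(
            prioritised, ld, cfg.anchor, set(cfg.partners), r2_min=cfg.r2_min
        )
        manifest["n_snps_removed"] = sum(len(g.removed) for g in groups)
        manifest["n_snps_retained"] = sum(len(c) for c in pruned)
        _write(removal_report(groups), out / "ld_removals.tsv")
        _write(clusters_to_frame(pruned), out / "pruned_clusters.tsv")

    with stage("summarise"):
        summary = summarise_selection(pruned, cfg.anchor, set(cfg.partners))
        _write(summary, out / "summary.tsv")

    with stage("enrich"):
        enrichment: dict[str, list] = {}
        if cfg.gmt_files:
            sets = []
            for path in cfg.gmt_files:
                sets.extend(read_gmt(path))
            universe = _resolve_universe_cfg(cfg.universe)
            queries = _build_queries(pruned, cfg)
            enrichment = run_grouped_ora(
                queries, sets, universe=universe,
                min_overlap=cfg.min_overlap,
                p_cutoff=cfg.p_cutoff, q_cutoff=cfg.q_cutoff,
            )
            for label, results in enrichment.items():
                _write(results_to_frame(results), out / f"enrichment_{label}.tsv")
                manifest[f"n_tested_sets_{label}"] = len(results)
                manifest[f"n_significant_{label}"] = sum(r.significant for r in results)

    with stage("manifest"):
        lines = [f"{k}: {v}" for k, v in manifest.items()]
        (out / "manifest.txt").write_text("\n".join(lines) + "\n")

    return PipelineResult(
        catalog=cat, clusters=clusters, prioritised=prioritised, pruned=pruned,
        summary=summary, concordance=concordance, enrichment=enrichment,
        manifest=manifest,
    )


def _resolve_universe_cfg(universe):
    """Config universe: "auto", an int, a digit string, or a gene-list path."""
    if universe == "auto" or isinstance(universe, int):
        return universe
    if isinstance(universe, str) and universe.isdigit():
        return int(universe)
    with open(universe) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def _build_queries(pruned, cfg: PipelineConfig) -> dict[str, frozenset[str]]:
    """Combined and per-partner gene queries from the pruned clusters."""
    source = cfg.query_source

    def genes_of(clusters) -> frozenset[str]:
        out: set[str] = set()
        for cl in clusters:
            for rec in cl.members:
                out |= rec.genes(source)
        return frozenset(out)

    queries = {"combined": genes_of(pruned)}
    for partner in sorted(cfg.partners):
        sub = [cl for cl in pruned if partner in cl.phenotypes]
        queries[partner] = genes_of(sub)
    return queries
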