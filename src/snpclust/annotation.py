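"""SNP-to-gene annotation overlay and shared-gene cluster prioritisation.

Two kinds of annotation feed the pipeline: a positional source (nearest /
containing gene from a genome map) and a functional source (literature- or
structure-informed assignment).  They frequently disagree, so clusters are
prioritised on the *union* of sources: a cluster is kept when some gene is
annotated to at least one anchor-phenotype SNP and at least one
partner-phenotype SNP, no matter which source contributed either side.
Cross-source concordance is quantified over SNPs annotated in both sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .catalog_io import Catalog, normalise_rsid
from .clustering import SnpCluster
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSource:
    """A named rsid -> gene-symbol mapping; multi-gene SNPs allowed."""

    name: str
    mapping: dict[str, frozenset[str]] = field(default_factory=dict)
    rejects: list[tuple[dict, str]] = field(default_factory=list)

    def genes_for(self, rsid: str) -> frozenset[str]:
        return self.mapping.get(rsid, frozenset())

    @property
    def distinct_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.mapping.values():
            out |= genes
        return frozenset(out)


def load_annotation(path, name: str) -> AnnotationSource:
    """Read an annotation TSV (columns ``rsid``, ``gene``) into a source.

    One row per (SNP, gene) pair; a SNP appearing on several rows maps to
    all of its genes.  Malformed rows go to the source's reject list.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    source = AnnotationSource(name=name)
    if frame.empty:
        logger.warning("%s: empty annotation file for source %r", path, name)
        return source
    if not {"rsid", "gene"} <= set(frame.columns):
        raise ConfigurationError(f"{path}: annotation file needs columns rsid, gene")
    mapping: dict[str, set[str]] = {}
    for row in frame.to_dict(orient="records"):
        rsid, gene = row.get("rsid"), row.get("gene")
        if pd.isna(rsid) or pd.isna(gene) or not str(gene).strip():
            source.rejects.append((row, "missing rsid or gene"))
            continue
        mapping.setdefault(normalise_rsid(rsid), set()).add(str(gene).strip())
    source.mapping = {k: frozenset(v) for k, v in mapping.items()}
    return source


def annotate_catalog(cat: Catalog, sources: list[AnnotationSource]) -> Catalog:
    """Attach every source's gene sets to every record.

    A SNP absent from a source carries an empty set for it (distinguishing
    "source consulted, nothing found" from "source never applied").
    """
    records = []
    unannotated = {s.name: 0 for s in sources}
    for rec in cat.records:
        ann = dict(rec.annotations)
        for src in sources:
            genes = src.genes_for(rec.rsid)
            ann[src.name] = genes
            if not genes:
                unannotated[src.name] += 1
        records.append(replace(rec, annotations=ann))
    for name, n in unannotated.items():
        logger.info("annotation source %r: %d/%d SNPs unannotated", name, n, len(records))
    return Catalog(records=records, provenance=dict(cat.provenance), rejects=list(cat.rejects))


def shared_genes(cluster: SnpCluster, anchor: str, partners: set[str]) -> frozenset[str]:
    """Genes annotated (any source) to both an anchor and a partner member."""
    anchor_genes: set[str] = set()
    partner_genes: set[str] = set()
    for rec in cluster.members:
        if rec.phenotype == anchor:
            anchor_genes |= rec.genes()
        elif rec.phenotype in partners:
            partner_genes |= rec.genes()
    return frozenset(anchor_genes & partner_genes)


def prioritise_clusters(
    clusters: list[SnpCluster],
    anchor: str,
    partners: set[str],
) -> list[SnpCluster]:
    """Flag clusters where anchor and partner SNPs share a gene annotation.

    All clusters are returned (order preserved); only the ``prioritised``
    flag and ``shared_genes`` are set.  The rule is monotone in the
    annotations: adding genes can only ever prioritise more clusters.
    """
    out = []
    for cl in clusters:
        genes = shared_genes(cl, anchor, set(partners))
        out.append(
            SnpCluster(
                cluster_id=cl.cluster_id, chrom=cl.chrom, members=list(cl.members),
                prioritised=bool(genes), shared_genes=genes,
            )
        )
    return out


def annotation_concordance(
    cat: Catalog,
    source_a: str,
    source_b: str,
    mode: str = "equal",
) -> tuple[int, int, float | None]:
    """Agreement between two annotation sources over doubly-annotated SNPs.

    Returns ``(matching, available, percentage)`` where *available* counts
    SNPs with a non-empty gene set in both sources and *matching* counts
    those whose two gene sets agree.  ``mode="equal"`` requires set
    equality; ``mode="overlap"`` accepts any common gene.  With no
    doubly-annotated SNP the percentage is ``None`` (undefined, reported
    as such rather than 0 or 100).
    """
    if mode not in ("equal", "overlap"):
        raise ConfigurationError(f"unknown concordance mode {mode!r}")
    names = {src for rec in cat.records for src in rec.annotations}
    missing = {source_a, source_b} - names
    if missing and cat.records:
        raise ConfigurationError(f"annotation source(s) {sorted(missing)} not attached")
    available = matching = 0
    for rec in cat.records:
        a, b = rec.genes(source_a), rec.genes(source_b)
        if a and b:
            available += 1
            if (a == b) if mode == "equal" else bool(a & b):
                matching += 1
    pct = 100.0 * matching / available if available else None
    return matching, available, pct


def prioritised_report(clusters: list[SnpCluster]) -> pd.DataFrame:
    """Per-member table of the prioritised clusters (TSV-ready)."""
    rows = []
    for cl in clusters:
        if not cl.prioritised:
            continue
        for rec in cl.members:
            row = {
                "cluster_id": cl.cluster_id,
                "shared_genes": ",".join(sorted(cl.shared_genes)),
                "rsid": rec.rsid,
                "phenotype": rec.phenotype,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "p_value": rec.p_value,
                "regulome_score": rec.regulome_score,
            }
            for source, genes in sorted(rec.annotations.items()):
                row[f"genes_{source}"] = ",".join(sorted(genes))
            rows.append(row)
    return pd.DataFrame(rows)
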