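"""Genomic sliding-window clustering of catalog SNPs.

SNPs associated with complex traits are not scattered uniformly along the
genome; they co-segregate in regions of low recombination.  To find regions
relevant to more than one phenotype we chain SNPs on each chromosome: after
sorting by position, a SNP joins the open cluster when its distance to the
*previous* member is at most the window size (single-linkage chaining), and
otherwise starts a new cluster.  A cluster can therefore span more than one
window length as long as no consecutive gap exceeds the window.  Clusters
containing an anchor phenotype (e.g. height) together with at least one
partner phenotype (e.g. breast or colorectal cancer risk) are the
cross-phenotype clusters the pipeline carries forward.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog_io import Catalog, SnpAssociation, chrom_sort_key
from .errors import ConfigurationError

#: Default window: 1 Mbp, wide enough for multi-phenotype loci in low
#: recombination regions; narrower windows split shared-gene clusters.
DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class WindowConfig:
    window_bp: int = DEFAULT_WINDOW_BP

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ConfigurationError(f"window_bp must be > 0, got {self.window_bp}")


@dataclass
class SnpCluster:
    """A maximal chain of same-chromosome SNPs with consecutive gaps <= window.

    ``prioritised``/``shared_genes`` are filled in by the annotation stage;
    they record whether an anchor-phenotype and a partner-phenotype member
    are annotated to the same gene (by any annotation source).
    """

    cluster_id: int
    chrom: str
    members: list[SnpAssociation]
    prioritised: bool = False
    shared_genes: frozenset[str] = frozenset()

    @property
    def span_start(self) -> int:
        return self.members[0].pos

    @property
    def span_end(self) -> int:
        return self.members[-1].pos

    @property
    def phenotypes(self) -> set[str]:
        return {m.phenotype for m in self.members}

    @property
    def rsids(self) -> list[str]:
        return [m.rsid for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


def build_clusters(cat: Catalog, w: WindowConfig | int = DEFAULT_WINDOW_BP) -> list[SnpCluster]:
    """Partition all catalog records into sliding-window clusters.

    Every record ends up in exactly one cluster (singletons included);
    clusters never cross chromosomes.  Cluster ids are assigned in genome
    order (chromosome, then leftmost position), so output is deterministic
    and independent of input row order.  Ties at identical positions are
    broken by rsid then phenotype for stable ordering.
    """
    if isinstance(w, int):
        w = WindowConfig(w)
    by_chrom: dict[str, list[SnpAssociation]] = {}
    for rec in cat.records:
        by_chrom.setdefault(rec.chrom, []).append(rec)

    clusters: list[SnpCluster] = []
    next_id = 1
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.pos, r.rsid, r.phenotype))
        open_members = [recs[0]]
        for rec in recs[1:]:
            if rec.pos - open_members[-1].pos <= w.window_bp:
                open_members.append(rec)
            else:
                clusters.append(SnpCluster(next_id, chrom, open_members))
                next_id += 1
                open_members = [rec]
        clusters.append(SnpCluster(next_id, chrom, open_members))
        next_id += 1
    return clusters


def select_cross_phenotype(
    clusters: list[SnpCluster],
    anchor: str,
    partners: set[str],
) -> list[SnpCluster]:
    """Keep clusters holding the anchor phenotype plus at least one partner.

    Raises :class:`ConfigurationError` when the anchor appears among the
    partners or a requested label occurs nowhere in the clusters (almost
    always a typo in the trait mapping).
    """
    partners = set(partners)
    if anchor in partners:
        raise ConfigurationError(f"anchor {anchor!r} must not be among partners")
    seen: set[str] = set()
    for cl in clusters:
        seen |= cl.phenotypes
    unknown = ({anchor} | partners) - seen
    if unknown and clusters:
        raise ConfigurationError(
            f"phenotype label(s) {sorted(unknown)} not present in any cluster "
            f"(known: {sorted(seen)})"
        )
    return [cl for cl in clusters if anchor in cl.phenotypes and cl.phenotypes & partners]


def window_sensitivity(
    cat: Catalog,
    windows: list[int],
    anchor: str | None = None,
    partners: set[str] | None = None,
) -> pd.DataFrame:
    """Re-cluster under several window sizes and summarise the effect.

    For each window size reports the cluster count, the cross-phenotype
    cluster count (when anchor/partners given), and how many clusters from
    the largest window split apart at this size.  Shrinking the window can
    only split clusters, never merge them, so each smaller-window cluster
    lies inside exactly one largest-window cluster.
    """
    if not windows:
        raise ConfigurationError("windows must be non-empty")
    windows = sorted(set(windows), reverse=True)
    ref = build_clusters(cat, windows[0])
    ref_of: dict[tuple[str, str], int] = {}
    for cl in ref:
        for rec in cl.members:
            ref_of[(rec.rsid, rec.phenotype)] = cl.cluster_id

    rows = []
    for w in windows:
        clusters = build_clusters(cat, w)
        id_of: dict[tuple[str, str], int] = {}
        for cl in clusters:
            for rec in cl.members:
                id_of[(rec.rsid, rec.phenotype)] = cl.cluster_id
        n_split = sum(
            1 for ref_cl in ref
            if len({id_of[(m.rsid, m.phenotype)] for m in ref_cl.members}) > 1
        )
        row = {
            "window_bp": w,
            "n_clusters": len(clusters),
            "n_split_vs_largest": n_split,
        }
        if anchor is not None and partners:
            row["n_cross_phenotype"] = len(select_cross_phenotype(clusters, anchor, partners))
        rows.append(row)
    return pd.DataFrame(rows)


def clusters_to_frame(clusters: list[SnpCluster]) -> pd.DataFrame:
    """One row per cluster: id, span, size, phenotypes, members (TSV-ready)."""
    rows = [
        {
            "cluster_id": cl.cluster_id,
            "chrom": cl.chrom,
            "span_start": cl.span_start,
            "span_end": cl.span_end,
            "n_snps": len(cl),
            "phenotypes": ",".join(sorted(cl.phenotypes)),
            "prioritised": int(cl.prioritised),
            "shared_genes": ",".join(sorted(cl.shared_genes)),
            "rsids": ",".join(cl.rsids),
        }
        for cl in clusters
    ]
    return pd.DataFrame(rows)


def replace_members(cluster: SnpCluster, members: list[SnpAssociation]) -> SnpCluster:
    """Copy of a cluster with a new member list (used by annotation/pruning)."""
    return SnpCluster(
        cluster_id=cluster.cluster_id,
        chrom=cluster.chrom,
        members=list(members),
        prioritised=cluster.prioritised,
        shared_genes=cluster.shared_genes,
    )
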