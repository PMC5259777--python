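"""LD-redundancy pruning within clusters, ranked by regulatory evidence.

SNPs in high pairwise linkage disequilibrium (r² above threshold, default
0.7 strict) within one cluster tag the same signal.  Such SNPs are grouped
by transitive closure (connected components of the r²-threshold graph) and
each group is collapsed to a single representative: the member with the
strongest regulatory-evidence grade (RegulomeDB-style ordinal, 1a strongest,
"ND"/score-0 weakest), ties broken by smallest association p-value, then by
rsid for determinism.  Pruning is constraint-preserving: if collapsing a
group would strip the cluster of its cross-phenotype membership or of its
shared-gene prioritisation, just enough pruned SNPs are restored (strongest
evidence first) for the cluster to keep satisfying both rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .annotation import shared_genes
from .catalog_io import SnpAssociation, normalise_rsid
from .clustering import SnpCluster, replace_members
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Evidence ordering, strongest first.  1a-1f are cis-eQTL grades, 2-3
#: protein/TF-binding grades, 4-6 minimal binding evidence; "ND" (no data,
#: score 0 in RegulomeDB exports) ranks below everything.
REGULOME_ORDER = (
    "1a", "1b", "1c", "1d", "1e", "1f",
    "2a", "2b", "2c", "3a", "3b", "4", "5", "6", "ND",
)
_ORDINAL = {tok: i for i, tok in enumerate(REGULOME_ORDER)}

#: Default redundancy threshold: pairs with r² strictly above this are LD-linked.
DEFAULT_R2_MIN = 0.7


def regulome_ordinal(token: str | None) -> int:
    """Integer rank of an evidence token (lower = stronger); None -> ND."""
    if token is None:
        token = "ND"
    if token not in _ORDINAL:
        raise ConfigurationError(f"unknown regulatory score token {token!r}")
    return _ORDINAL[token]


@dataclass
class LdTable:
    """Symmetric rsid-pair -> r² lookup; self-pairs are ignored."""

    pairs: dict[frozenset[str], float] = field(default_factory=dict)

    def add(self, a: str, b: str, r2: float) -> None:
        a, b = normalise_rsid(a), normalise_rsid(b)
        if a == b:
            return
        if not (0 <= r2 <= 1):
            raise ValueError(f"r² must be in [0,1], got {r2} for ({a},{b})")
        self.pairs[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float | None:
        return self.pairs.get(frozenset((normalise_rsid(a), normalise_rsid(b))))

    def __len__(self) -> int:
        return len(self.pairs)


def read_ld_table(path) -> LdTable:
    """Read a pairwise LD TSV with columns ``rsid_a``, ``rsid_b``, ``r2``."""
    frame = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str, "r2": float})
    table = LdTable()
    if frame.empty:
        logger.warning("%s: empty LD file", path)
        return table
    if not {"rsid_a", "rsid_b", "r2"} <= set(frame.columns):
        raise ConfigurationError(f"{path}: LD file needs columns rsid_a, rsid_b, r2")
    for row in frame.itertuples(index=False):
        table.add(row.rsid_a, row.rsid_b, float(row.r2))
    return table


@dataclass
class LdGroup:
    """A maximal set of same-cluster SNPs connected by r² above threshold."""

    cluster_id: int
    members: frozenset[str]
    kept: str | None = None
    removed: frozenset[str] = frozenset()
    #: per-removed-rsid reason: "score" | "p_tie" | "rsid_tie"; restored SNPs
    #: get "constraint_retained" and move back out of ``removed``.
    reasons: dict[str, str] = field(default_factory=dict)
    constraint_override: bool = False


def build_ld_groups(
    cluster: SnpCluster,
    ld: LdTable,
    r2_min: float = DEFAULT_R2_MIN,
) -> list[LdGroup]:
    """Connected components of the within-cluster high-LD graph.

    Edges are pairs with ``r² > r2_min`` (strict: a pair at exactly the
    threshold is *not* redundant).  Components of size one are not groups.
    LD pairs mentioning SNPs outside the cluster are ignored.
    """
    if not (0 <= r2_min <= 1):
        raise ConfigurationError(f"r2_min must be in [0,1], got {r2_min}")
    in_cluster = set(cluster.rsids)
    graph = nx.Graph()
    graph.add_nodes_from(in_cluster)
    for pair, r2 in ld.pairs.items():
        a, b = sorted(pair)
        if a not in in_cluster or b not in in_cluster:
            logger.debug("LD pair (%s,%s) outside cluster %d ignored", a, b, cluster.cluster_id)
            continue
        if r2 > r2_min:
            graph.add_edge(a, b)
    groups = [
        LdGroup(cluster_id=cluster.cluster_id, members=frozenset(comp))
        for comp in nx.connected_components(graph)
        if len(comp) > 1
    ]
    groups.sort(key=lambda g: min(g.members))
    return groups


def _evidence_key(rec: SnpAssociation) -> tuple[int, float, str]:
    return (regulome_ordinal(rec.regulome_score), rec.p_value, rec.rsid)


def choose_representative(group: LdGroup, records: list[SnpAssociation]) -> str:
    """The group member to keep: strongest evidence, then lowest p, then rsid."""
    members = [r for r in records if r.rsid in group.members]
    if not members:
        raise ValueError("group has no member records")
    return min(members, key=_evidence_key).rsid


def _removal_reason(kept: SnpAssociation, removed: SnpAssociation) -> str:
    if regulome_ordinal(removed.regulome_score) != regulome_ordinal(kept.regulome_score):
        return "score"
    if removed.p_value != kept.p_value:
        return "p_tie"
    return "rsid_tie"


def prune_cluster(
    cluster: SnpCluster,
    groups: list[LdGroup],
    anchor: str,
    partners: set[str],
) -> tuple[SnpCluster, list[LdGroup]]:
    """Collapse each LD group to its representative, preserving cluster rules.

    All non-representative group members are tentatively removed; if the
    cluster then fails the cross-phenotype rule or the shared-gene rule,
    removed SNPs are restored one at a time — strongest regulatory evidence
    first — until both rules hold again.  Restored SNPs are flagged
    ``constraint_retained`` on their group.  Returns the pruned cluster and
    the filled-in groups (kept / removed / reasons).
    """
    partners = set(partners)
    by_rsid = {rec.rsid: rec for rec in cluster.members}
    filled: list[LdGroup] = []
    removed_all: set[str] = set()
    for group in groups:
        kept = choose_representative(group, cluster.members)
        removed = group.members - {kept}
        reasons = {r: _removal_reason(by_rsid[kept], by_rsid[r]) for r in removed}
        filled.append(
            LdGroup(
                cluster_id=group.cluster_id, members=group.members,
                kept=kept, removed=frozenset(removed), reasons=reasons,
            )
        )
        removed_all |= removed

    def rules_hold(member_rsids: set[str]) -> bool:
        members = [by_rsid[r] for r in cluster.rsids if r in member_rsids]
        trial = replace_members(cluster, members)
        phen = trial.phenotypes
        if anchor not in phen or not (phen & partners):
            return False
        # shared-gene rule only binds on clusters that were prioritised
        if cluster.prioritised and not shared_genes(trial, anchor, partners):
            return False
        return True

    surviving = set(by_rsid) - removed_all
    # restore strongest-evidence SNPs until the cluster rules pass again
    while not rules_hold(surviving) and removed_all:
        back = min((by_rsid[r] for r in removed_all), key=_evidence_key).rsid
        removed_all.discard(back)
        surviving.add(back)
        for g in filled:
            if back in g.removed:
                g.removed = g.removed - {back}
                g.reasons[back] = "constraint_retained"
                g.constraint_override = True

    members = [rec for rec in cluster.members if rec.rsid in surviving]
    pruned = replace_members(cluster, members)
    if cluster.prioritised:
        pruned.shared_genes = shared_genes(pruned, anchor, partners)
    return pruned, filled


def prune_clusters(
    clusters: list[SnpCluster],
    ld: LdTable,
    anchor: str,
    partners: set[str],
    r2_min: float = DEFAULT_R2_MIN,
) -> tuple[list[SnpCluster], list[LdGroup]]:
    """Prune every cluster independently; convenience over the per-cluster ops."""
    pruned_list: list[SnpCluster] = []
    all_groups: list[LdGroup] = []
    for cl in clusters:
        groups = build_ld_groups(cl, ld, r2_min)
        pruned, filled = prune_cluster(cl, groups, anchor, partners)
        pruned_list.append(pruned)
        all_groups.extend(filled)
    return pruned_list, all_groups


def removal_report(groups: list[LdGroup]) -> pd.DataFrame:
    """TSV-ready report: one row per LD group with kept/removed members."""
    rows = []
    for g in groups:
        retained_extra = sorted(g.members - g.removed - {g.kept})
        rows.append(
            {
                "cluster_id": g.cluster_id,
                "group_members": ",".join(sorted(g.members)),
                "kept": g.kept,
                "removed": ",".join(sorted(g.removed)),
                "constraint_retained": ",".join(retained_extra),
                "reasons": ",".join(f"{r}:{g.reasons[r]}" for r in sorted(g.reasons)),
            }
        )
    return pd.DataFrame(rows)


def summarise_selection(
    clusters: list[SnpCluster],
    anchor: str,
    partners: set[str],
) -> pd.DataFrame:
    """Per-partner summary of the pruned selection.

    For each partner phenotype: number of clusters containing anchor + that
    partner, anchor-SNP and partner-SNP counts within them, and the number
    of distinct genes per annotation source over their members.
    """
    rows = []
    for partner in sorted(partners):
        selected = [
            cl for cl in clusters
            if anchor in cl.phenotypes and partner in cl.phenotypes
        ]
        n_anchor = sum(1 for cl in selected for m in cl.members if m.phenotype == anchor)
        n_partner = sum(1 for cl in selected for m in cl.members if m.phenotype == partner)
        source_names = sorted({
            src for cl in selected for m in cl.members for src in m.annotations
        })
        row = {
            "partner": partner,
            "n_clusters": len(selected),
            f"n_{anchor}_snps": n_anchor,
            "n_partner_snps": n_partner,
            "n_snps_total": sum(len(cl) for cl in selected),
        }
        for src in source_names:
            genes: set[str] = set()
            for cl in selected:
                for m in cl.members:
                    genes |= m.genes(src)
            row[f"n_genes_{src}"] = len(genes)
        rows.append(row)
    return pd.DataFrame(rows)
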