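"""LD grouping, representative choice, constraint-preserving pruning."""

import itertools

import pytest

from snpclust.annotation import prioritise_clusters, shared_genes
from snpclust.clustering import SnpCluster, build_clusters, replace_members
from snpclust.ld_prune import (
    LdGroup, LdTable, build_ld_groups, choose_representative, prune_cluster,
    prune_clusters, regulome_ordinal, summarise_selection,
)

from conftest import ANCHOR, PARTNERS, make_snp

MB = 1_000_000


def cluster_of(*records, prioritised=False):
    cl = SnpCluster(cluster_id=1, chrom=records[0].chrom, members=list(records))
    cl.prioritised = prioritised
    return cl


class TestRegulomeOrdering:
    def test_full_ordering_strongest_first(self):
        tokens = ["1a", "1b", "1c", "1d", "1e", "1f", "2a", "2b", "2c",
                  "3a", "3b", "4", "5", "6", "ND"]
        ordinals = [regulome_ordinal(t) for t in tokens]
        assert ordinals == sorted(ordinals)

    def test_missing_score_ranks_as_no_data(self):
        assert regulome_ordinal(None) == regulome_ordinal("ND")


class TestBuildLdGroups:
    def _cluster(self):
        return cluster_of(
            make_snp(rsid="rs101", pos=100), make_snp(rsid="rs102", pos=200),
            make_snp(rsid="rs103", pos=300),
        )

    def test_threshold_is_strict(self):
        ld = LdTable()
        ld.add("rs101", "rs102", 0.7)
        assert build_ld_groups(self._cluster(), ld, 0.7) == []

    def test_transitive_closure_forms_one_group(self):
        ld = LdTable()
        ld.add("rs101", "rs102", 0.9)
        ld.add("rs102", "rs103", 0.8)
        ld.add("rs101", "rs103", 0.1)
        groups = build_ld_groups(self._cluster(), ld, 0.7)
        assert len(groups) == 1
        assert groups[0].members == {"rs101", "rs102", "rs103"}

    def test_no_pairs_above_threshold_gives_no_groups(self):
        ld = LdTable()
        ld.add("rs101", "rs102", 0.5)
        assert build_ld_groups(self._cluster(), ld, 0.7) == []

    def test_pairs_outside_cluster_are_ignored(self):
        ld = LdTable()
        ld.add("rs101", "rs999", 0.99)
        assert build_ld_groups(self._cluster(), ld, 0.7) == []

    def test_self_pairs_never_stored(self):
        ld = LdTable()
        ld.add("rs101", "rs101", 0.99)
        assert len(ld) == 0


class TestChooseRepresentative:
    def test_strongest_evidence_wins(self):
        # mirrors the published cluster where 3a beats 6 and no-data
        records = [
            make_snp(rsid="rs967417", pos=1, regulome_score="6"),
            make_snp(rsid="rs2145270", pos=2, regulome_score="ND"),
            make_snp(rsid="rs2145272", pos=3, regulome_score="3a"),
        ]
        group = LdGroup(1, frozenset(r.rsid for r in records))
        assert choose_representative(group, records) == "rs2145272"

    def test_within_low_evidence_pool_4_beats_5(self):
        records = [
            make_snp(rsid="rs941873", pos=1, regulome_score="4"),
            make_snp(rsid="rs2145998", pos=2, regulome_score="5"),
        ]
        group = LdGroup(1, frozenset(r.rsid for r in records))
        assert choose_representative(group, records) == "rs941873"

    def test_score_tie_broken_by_p_value(self):
        records = [
            make_snp(rsid="rs201", pos=1, regulome_score="5", p=1e-6),
            make_snp(rsid="rs202", pos=2, regulome_score="5", p=1e-9),
        ]
        group = LdGroup(1, frozenset(r.rsid for r in records))
        assert choose_representative(group, records) == "rs202"

    def test_full_tie_broken_by_rsid(self):
        records = [
            make_snp(rsid="rs102", pos=1, regulome_score="5", p=1e-8),
            make_snp(rsid="rs101", pos=2, regulome_score="5", p=1e-8),
        ]
        group = LdGroup(1, frozenset(r.rsid for r in records))
        assert choose_representative(group, records) == "rs101"


class TestPruneCluster:
    def test_redundant_snps_removed_when_criteria_safe(self):
        h1 = make_snp(rsid="rs1", pos=100, phenotype=ANCHOR, regulome_score="1a",
                      annotations={"a": frozenset({"G"})})
        h2 = make_snp(rsid="rs2", pos=200, phenotype=ANCHOR, regulome_score="5",
                      annotations={"a": frozenset({"G"})})
        h3 = make_snp(rsid="rs3", pos=300, phenotype=ANCHOR, regulome_score="6",
                      annotations={"a": frozenset({"G"})})
        bc = make_snp(rsid="rs4", pos=400, phenotype="breast_cancer",
                      annotations={"a": frozenset({"G"})})
        cl = cluster_of(h1, h2, h3, bc, prioritised=True)
        cl.shared_genes = frozenset({"G"})
        groups = [LdGroup(1, frozenset({"rs1", "rs2", "rs3"}))]
        pruned, filled = prune_cluster(cl, groups, ANCHOR, PARTNERS)
        assert sorted(pruned.rsids) == ["rs1", "rs4"]
        assert filled[0].kept == "rs1"
        assert filled[0].removed == {"rs2", "rs3"}
        assert not filled[0].constraint_override

    def test_two_snp_cross_phenotype_cluster_is_protected(self):
        h = make_snp(rsid="rs1", pos=100, phenotype=ANCHOR, regulome_score="1a",
                     annotations={"a": frozenset({"G"})})
        bc = make_snp(rsid="rs2", pos=200, phenotype="breast_cancer",
                      regulome_score="6", annotations={"a": frozenset({"G"})})
        cl = cluster_of(h, bc, prioritised=True)
        cl.shared_genes = frozenset({"G"})
        groups = [LdGroup(1, frozenset({"rs1", "rs2"}))]
        pruned, filled = prune_cluster(cl, groups, ANCHOR, PARTNERS)
        assert sorted(pruned.rsids) == ["rs1", "rs2"]
        assert filled[0].constraint_override
        assert filled[0].reasons["rs2"] == "constraint_retained"

    def test_shared_gene_rule_protects_last_annotated_anchor(self):
        # the only shared-gene anchor SNP has the weakest evidence; removing
        # it would break prioritisation, so it must be restored
        h1 = make_snp(rsid="rs1", pos=100, phenotype=ANCHOR, regulome_score="1a",
                      annotations={"a": frozenset({"OTHER"})})
        h2 = make_snp(rsid="rs2", pos=200, phenotype=ANCHOR, regulome_score="6",
                      annotations={"a": frozenset({"G"})})
        bc = make_snp(rsid="rs3", pos=300, phenotype="breast_cancer",
                      annotations={"a": frozenset({"G"})})
        cl = cluster_of(h1, h2, bc, prioritised=True)
        cl.shared_genes = frozenset({"G"})
        groups = [LdGroup(1, frozenset({"rs1", "rs2"}))]
        pruned, filled = prune_cluster(cl, groups, ANCHOR, PARTNERS)
        assert sorted(pruned.rsids) == ["rs1", "rs2", "rs3"]
        assert filled[0].constraint_override


class TestFixturePruning:
    def _pruned(self, fx):
        clusters = build_clusters(fx.catalog, MB)
        prioritised = prioritise_clusters(clusters, ANCHOR, PARTNERS)
        return prune_clusters(prioritised, fx.ld, ANCHOR, PARTNERS)

    def test_eight_snps_removed_across_five_clusters(self, fx):
        pruned, groups = self._pruned(fx)
        removed = [r for g in groups for r in g.removed]
        assert len(removed) == 8
        assert len({g.cluster_id for g in groups if g.removed}) == 5
        assert sum(len(c) for c in pruned) == 48

    def test_kept_representatives_match_published_footnotes(self, fx):
        _, groups = self._pruned(fx)
        assert {g.kept for g in groups} == set(fx.kept_rsids)

    def test_ld_tagged_snps_match_published_tags(self, fx):
        _, groups = self._pruned(fx)
        tagged = set().union(*(g.members for g in groups))
        assert tagged == set(fx.ld_tagged)

    def test_pruned_clusters_still_satisfy_both_rules(self, fx):
        pruned, _ = self._pruned(fx)
        for cl in pruned:
            assert ANCHOR in cl.phenotypes and cl.phenotypes & PARTNERS
            assert shared_genes(cl, ANCHOR, PARTNERS)

    def test_no_retained_pair_in_high_ld_without_override(self, fx):
        pruned, groups = self._pruned(fx)
        overridden = set().union(*(g.members for g in groups if g.constraint_override),
                                 frozenset())
        for cl in pruned:
            for a, b in itertools.combinations(cl.rsids, 2):
                r2 = fx.ld.r2(a, b)
                if r2 is not None and r2 > 0.7:
                    assert a in overridden and b in overridden

    def test_counts_invariant_to_representative_choice(self, fx):
        # every published LD group is phenotype-homogeneous, so the summary
        # counts must not depend on which member the tie-break retains
        clusters = build_clusters(fx.catalog, MB)
        prioritised = prioritise_clusters(clusters, ANCHOR, PARTNERS)
        _, groups = prune_clusters(prioritised, fx.ld, ANCHOR, PARTNERS)
        choices = [sorted(g.members) for g in groups]
        for keep in itertools.product(*choices):
            removed = set()
            for g, k in zip(groups, keep):
                removed |= g.members - {k}
            trial = [
                replace_members(cl, [m for m in cl.members if m.rsid not in removed])
                for cl in prioritised
            ]
            for cl in trial:  # rules survive any representative choice
                assert ANCHOR in cl.phenotypes and cl.phenotypes & PARTNERS
                assert shared_genes(cl, ANCHOR, PARTNERS)
            summary = summarise_selection(trial, ANCHOR, PARTNERS).set_index("partner")
            assert summary.loc["breast_cancer", "n_clusters"] == 8
            assert summary.loc["breast_cancer", "n_height_snps"] == 19
            assert summary.loc["breast_cancer", "n_partner_snps"] == 14
            assert summary.loc["colorectal_cancer", "n_clusters"] == 4
            assert summary.loc["colorectal_cancer", "n_height_snps"] == 10
            assert summary.loc["colorectal_cancer", "n_partner_snps"] == 5
            assert sum(len(c) for c in trial) == 48


class TestSummarise:
    def test_fixture_summary_matches_published_counts(self, fx):
        clusters = build_clusters(fx.catalog, MB)
        prioritised = prioritise_clusters(clusters, ANCHOR, PARTNERS)
        pruned, _ = prune_clusters(prioritised, fx.ld, ANCHOR, PARTNERS)
        summary = summarise_selection(pruned, ANCHOR, PARTNERS).set_index("partner")
        assert summary.loc["breast_cancer",
                           ["n_clusters", "n_height_snps", "n_partner_snps"]].tolist() \
            == [8, 19, 14]
        assert summary.loc["colorectal_cancer",
                           ["n_clusters", "n_height_snps", "n_partner_snps"]].tolist() \
            == [4, 10, 5]

    def test_empty_cluster_list_gives_zero_summary(self):
        summary = summarise_selection([], ANCHOR, PARTNERS)
        assert (summary["n_clusters"] == 0).all()
        assert (summary["n_snps_total"] == 0).all()
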