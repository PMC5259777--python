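"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Two kinds of test data live here:

* Seeded generators (:func:`generate_catalog`, :func:`generate_ld`,
  :func:`generate_annotations_and_sets`, :func:`planted_ora_design`) that
  emulate multi-phenotype GWAS catalogs with planted cross-phenotype
  clusters, block LD, two partially concordant annotation sources, and gene
  sets with a planted enriched pathway.  Every generator is driven by a
  single integer seed through one named RNG and returns the ground truth it
  planted, so pipeline output can be compared against truth exactly.

* :func:`table1_fixture` — a verbatim transcription of the published table
  of 12 prioritised height-cancer SNP clusters (56 SNPs) with phenotypes,
  RegulomeDB scores, positional and functional gene annotations and LD-group
  tags.  Base-pair positions, association p-values and the exact intra-group
  LD pairings are NOT printed in that table; the fixture fills them with
  synthetic values chosen to be consistent with every printed count (spacing
  below the 1-Mbp window within a cluster, several Mbp between clusters on a
  shared chromosome, tie-break p-values under which the table's kept-SNP
  footnotes hold).  These synthetic fields are fixture assumptions; all
  count-level results are invariant to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationSource, annotate_catalog
from .catalog_io import REGULOME_TOKENS, Catalog, SnpAssociation, with_regulome_scores
from .enrichment import GeneSet
from .errors import ConfigurationError
from .ld_prune import LdTable

ANCHOR = "height"
PARTNERS = ("breast_cancer", "colorectal_cancer")


# --------------------------------------------------------------------------
# seeded generators
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    Defaults emulate the published working set: 514 height, 157 breast
    cancer and 50 colorectal cancer SNPs after filtering, a 1-Mbp window,
    and a cross-source annotation concordance of 64.7%.
    """

    seed: int = 0
    n_chromosomes: int = 22
    chrom_length_bp: int = 100_000_000
    phenotype_counts: dict[str, int] = field(
        default_factory=lambda: {ANCHOR: 514, PARTNERS[0]: 157, PARTNERS[1]: 50}
    )
    anchor: str = ANCHOR
    n_planted_clusters: int = 5
    cluster_span_bp: int = 500_000
    window_bp: int = 1_000_000
    #: probability that a same-cluster SNP pair is designated a high-LD pair
    ld_block_rate: float = 0.5
    #: probability that the two annotation sources agree on a SNP's gene
    annotation_concordance: float = 0.647
    n_genes: int = 1_000
    n_gene_sets: int = 100
    set_size_range: tuple[int, int] = (10, 30)
    planted_set_size: int = 50

    def __post_init__(self):
        if self.n_planted_clusters < 0 or min(self.phenotype_counts.values()) < 0:
            raise ConfigurationError("counts must be >= 0")
        for p in (self.ld_block_rate, self.annotation_concordance):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"probability {p} outside [0,1]")

    @property
    def partners(self) -> list[str]:
        return [p for p in self.phenotype_counts if p != self.anchor]


@dataclass
class PlantedCluster:
    chrom: str
    start: int
    gene: str
    members: dict[str, str]  # rsid -> phenotype


@dataclass
class SimTruth:
    """Ground truth of one synthetic study, filled in by the generators."""

    planted: list[PlantedCluster] = field(default_factory=list)
    background_rsids: list[str] = field(default_factory=list)
    #: rsid pairs designated high-LD (r² drawn above the threshold)
    ld_pairs: set[frozenset[str]] = field(default_factory=set)
    #: per planted-cluster index: LD groups (components of designated pairs)
    ld_groups: dict[int, list[frozenset[str]]] = field(default_factory=dict)
    planted_set_name: str | None = None


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_catalog(cfg: SimConfig) -> tuple[Catalog, SimTruth]:
    """Synthetic association catalog with planted cross-phenotype clusters.

    The genome is carved into slots spaced more than one window apart; each
    planted cluster occupies one slot (1-3 anchor SNPs plus 1-2 SNPs of one
    partner phenotype within ``cluster_span_bp``), and every leftover SNP is
    a background singleton in its own slot.  Re-clustering therefore
    recovers exactly the planted clusters, which is what the truth record
    asserts.  P-values are log-uniform in [1e-30, 1e-6], MAF uniform in
    [0.01, 0.5].
    """
    rng = _rng(cfg.seed)
    counts = dict(cfg.phenotype_counts)
    if cfg.anchor not in counts:
        raise ConfigurationError(f"anchor {cfg.anchor!r} missing from phenotype_counts")
    partners = cfg.partners
    if cfg.n_planted_clusters > 0 and not partners:
        raise ConfigurationError("planted clusters need at least one partner phenotype")

    # cluster compositions, drawn before placement so feasibility is checkable
    compositions: list[tuple[int, str, int]] = []  # (n_anchor, partner, n_partner)
    for _ in range(cfg.n_planted_clusters):
        n_anchor = int(rng.integers(1, 4))
        partner = partners[int(rng.integers(0, len(partners)))]
        n_partner = int(rng.integers(1, 3))
        compositions.append((n_anchor, partner, n_partner))
    need = {ph: 0 for ph in counts}
    for n_a, partner, n_p in compositions:
        need[cfg.anchor] += n_a
        need[partner] += n_p
    for ph, n in need.items():
        if n > counts[ph]:
            raise ConfigurationError(
                f"planted clusters need {n} {ph!r} SNPs but only {counts[ph]} configured"
            )

    background = {ph: counts[ph] - need[ph] for ph in counts}
    n_background = sum(background.values())

    pitch = cfg.window_bp + cfg.cluster_span_bp + 1
    slots_per_chrom = cfg.chrom_length_bp // pitch
    all_slots = [
        (str(c + 1), int(s * pitch) + 1)
        for c in range(cfg.n_chromosomes)
        for s in range(slots_per_chrom)
    ]
    n_slots_needed = cfg.n_planted_clusters + n_background
    if n_slots_needed > len(all_slots):
        raise ConfigurationError(
            f"cannot place {n_slots_needed} separated loci in "
            f"{len(all_slots)} available slots; lower the SNP counts or "
            f"raise chrom_length_bp"
        )
    slot_idx = rng.choice(len(all_slots), size=n_slots_needed, replace=False)

    truth = SimTruth()
    records: list[SnpAssociation] = []
    next_rs = 900_000_001

    def make_record(rsid: str, chrom: str, pos: int, phenotype: str) -> SnpAssociation:
        p = float(10.0 ** rng.uniform(-30.0, -6.0))
        maf = float(rng.uniform(0.01, 0.5))
        score = REGULOME_TOKENS[int(rng.integers(0, len(REGULOME_TOKENS)))]
        return SnpAssociation(rsid=rsid, chrom=chrom, pos=pos,
                              phenotype=phenotype, p_value=p, maf=maf,
                              regulome_score=score)

    for i, (n_a, partner, n_p) in enumerate(compositions):
        chrom, start = all_slots[slot_idx[i]]
        n_members = n_a + n_p
        offsets = np.sort(rng.choice(cfg.cluster_span_bp, size=n_members, replace=False))
        phenos = [cfg.anchor] * n_a + [partner] * n_p
        rng.shuffle(phenos)
        members: dict[str, str] = {}
        for off, ph in zip(offsets, phenos):
            rsid = f"rs{next_rs}"
            next_rs += 1
            records.append(make_record(rsid, chrom, start + int(off), ph))
            members[rsid] = ph
        truth.planted.append(
            PlantedCluster(chrom=chrom, start=start, gene=f"PGENE{i:03d}", members=members)
        )

    slot_cursor = cfg.n_planted_clusters
    for ph in sorted(background):
        for _ in range(background[ph]):
            chrom, start = all_slots[slot_idx[slot_cursor]]
            slot_cursor += 1
            rsid = f"rs{next_rs}"
            next_rs += 1
            pos = start + int(rng.integers(0, cfg.cluster_span_bp))
            records.append(make_record(rsid, chrom, pos, ph))
            truth.background_rsids.append(rsid)

    cat = Catalog(records=records, provenance={"synthetic": len(records)})
    return cat, truth


def generate_ld(catalog: Catalog, truth: SimTruth, cfg: SimConfig) -> LdTable:
    """Pairwise r² table with LD blocks inside the planted clusters.

    Within each planted cluster, every SNP pair is designated high-LD with
    probability ``ld_block_rate`` (r² ~ U(0.75, 1)); the remaining
    within-cluster pairs draw r² ~ U(0, 0.5).  Pairs spanning different
    clusters sit far beyond the window and carry no LD rows, matching how
    proxy-search tools only report nearby pairs.  The connected components
    of the designated pairs are recorded in ``truth.ld_groups``.
    """
    rng = _rng(cfg.seed + 1)
    table = LdTable()
    for idx, pl in enumerate(truth.planted):
        rsids = sorted(pl.members)
        designated: list[tuple[str, str]] = []
        for i in range(len(rsids)):
            for j in range(i + 1, len(rsids)):
                if rng.random() < cfg.ld_block_rate:
                    table.add(rsids[i], rsids[j], float(rng.uniform(0.75, 1.0)))
                    designated.append((rsids[i], rsids[j]))
                    truth.ld_pairs.add(frozenset((rsids[i], rsids[j])))
                else:
                    table.add(rsids[i], rsids[j], float(rng.uniform(0.0, 0.5)))
        # components of the designated-pair graph, by successive merging
        comps: list[set[str]] = []
        for a, b in designated:
            hit = [c for c in comps if a in c or b in c]
            merged = {a, b}.union(*hit) if hit else {a, b}
            comps = [c for c in comps if c not in hit] + [merged]
        truth.ld_groups[idx] = [frozenset(c) for c in comps]
    return table


def generate_annotations_and_sets(
    catalog: Catalog,
    truth: SimTruth,
    cfg: SimConfig,
) -> tuple[AnnotationSource, AnnotationSource, list[GeneSet]]:
    """Two partially concordant SNP->gene sources plus gene sets.

    The positional source annotates each planted cluster's members to the
    cluster gene and each background SNP to a random gene; the functional
    source copies the positional gene with probability
    ``annotation_concordance`` and otherwise picks a different gene.  One
    planted gene set collects the planted cluster genes (padded with random
    genes to ``planted_set_size``); the remaining sets are random decoys.
    """
    rng = _rng(cfg.seed + 2)
    genes = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    cluster_genes = {rsid: pl.gene for pl in truth.planted for rsid in pl.members}
    universe = genes + sorted({pl.gene for pl in truth.planted})

    positional: dict[str, frozenset[str]] = {}
    functional: dict[str, frozenset[str]] = {}
    for rec in catalog.records:
        gene = cluster_genes.get(rec.rsid)
        if gene is None:
            gene = genes[int(rng.integers(0, len(genes)))]
        positional[rec.rsid] = frozenset({gene})
        if rng.random() < cfg.annotation_concordance:
            functional[rec.rsid] = frozenset({gene})
        else:
            other = gene
            while other == gene:
                other = universe[int(rng.integers(0, len(universe)))]
            functional[rec.rsid] = frozenset({other})

    planted_genes = sorted({pl.gene for pl in truth.planted})
    pad = [g for g in genes if g not in planted_genes]
    n_pad = max(0, cfg.planted_set_size - len(planted_genes))
    pad_pick = list(rng.choice(len(pad), size=min(n_pad, len(pad)), replace=False))
    planted_set = GeneSet(
        name="PLANTED_SET", source_db="synthetic",
        genes=frozenset(planted_genes + [pad[i] for i in pad_pick]),
    )
    sets = [planted_set]
    lo, hi = cfg.set_size_range
    for i in range(cfg.n_gene_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        pick = rng.choice(len(universe), size=size, replace=False)
        sets.append(
            GeneSet(name=f"DECOY{i:03d}", source_db="synthetic",
                    genes=frozenset(universe[j] for j in pick))
        )
    truth.planted_set_name = planted_set.name
    return (
        AnnotationSource(name="positional", mapping=positional),
        AnnotationSource(name="functional", mapping=functional),
        sets,
    )


def planted_ora_design(
    seed: int,
    universe_size: int = 1_000,
    query_size: int = 20,
    set_size: int = 50,
    planted_overlap: int = 5,
    n_decoys: int = 99,
    decoy_size: int = 15,
) -> tuple[frozenset[str], list[GeneSet], frozenset[str], str]:
    """Standalone planted enrichment design for calibrating the ORA stage.

    Returns ``(query, sets, universe, planted_name)``: a universe of
    ``universe_size`` genes, a query of ``query_size`` genes, one planted
    set of ``set_size`` genes containing exactly ``planted_overlap`` query
    genes, and ``n_decoys`` random decoy sets of ``decoy_size`` genes each.
    The decoy size sits at a discreteness gap of the hypergeometric tail:
    with the default geometry a 15-gene decoy needs to overlap the query in
    four or more genes before its p-value undercuts the planted set's, so
    the planted signal is recoverable by design rather than by chance.
    """
    rng = _rng(seed)
    universe = [f"G{i:05d}" for i in range(universe_size)]
    q_idx = rng.choice(universe_size, size=query_size, replace=False)
    query = frozenset(universe[i] for i in q_idx)
    non_query = [g for g in universe if g not in query]
    in_q = rng.choice(query_size, size=planted_overlap, replace=False)
    out_q = rng.choice(len(non_query), size=set_size - planted_overlap, replace=False)
    planted = GeneSet(
        name="PLANTED", source_db="synthetic",
        genes=frozenset([universe[q_idx[i]] for i in in_q]
                        + [non_query[i] for i in out_q]),
    )
    sets = [planted]
    for i in range(n_decoys):
        pick = rng.choice(universe_size, size=decoy_size, replace=False)
        sets.append(
            GeneSet(name=f"DECOY{i:03d}", source_db="synthetic",
                    genes=frozenset(universe[j] for j in pick))
        )
    return query, sets, frozenset(universe), planted.name


# --------------------------------------------------------------------------
# published-table fixture
# --------------------------------------------------------------------------

# One row per SNP of the published prioritised-cluster table:
# (cluster label, rsid, phenotype, regulome score, positional gene,
#  functional gene, ld_tag, kept_flag, p_value).
# Phenotypes: H = height, BC = breast cancer, CRC = colorectal cancer.
# Score "ND" is the table's "0" (no data).  P-values are synthetic fixture
# assumptions (see module docstring); within tied-score LD groups they are
# ordered so the table's kept-SNP footnotes hold.
_TABLE1_ROWS: list[tuple[int, str, str, str, str | None, str | None, int, int, float]] = [
    (22, "rs13387042", "BC", "ND", "TNP1", "TNP1", 0, 0, 1.0e-29),
    (22, "rs2553026", "H", "ND", "TNP1", None, 0, 0, 3.0e-9),
    (22, "rs1351164", "H", "ND", "TNS1", None, 0, 0, 5.0e-10),
    (22, "rs16857609", "BC", "5", "TNS1", None, 0, 0, 1.0e-15),
    (22, "rs6435999", "H", "ND", "TNS1", "DIRC3", 0, 0, 2.0e-11),
    (22, "rs3791950", "H", "2b", "TNS1", "TNS1", 0, 0, 4.0e-9),
    (22, "rs10187066", "H", "1f", "ZNF142", "STK36", 0, 0, 6.0e-12),
    (22, "rs12470505", "H", "1f", "CCDC108", "IHH", 1, 1, 2.0e-13),
    (22, "rs1052483", "H", "1f", "NHEJ1", "IHH", 1, 0, 7.0e-11),
    (22, "rs6724465", "H", "1f", "SLC23A3", "IHH", 1, 0, 9.0e-9),
    (22, "rs16859517", "H", "5", "SLC23A3", "IHH", 0, 0, 3.0e-10),
    (27, "rs9790517", "BC", "ND", "TET2", "TET2", 0, 0, 4.6e-8),
    (27, "rs10010325", "H", "ND", "TET2", "TET2", 0, 0, 2.0e-10),
    (27, "rs6855629", "H", "6", "TET2", "EEF1AL7", 0, 0, 5.0e-9),
    (29, "rs526896", "H", "5", "PITX1", "PITX1", 1, 1, 1.0e-12),
    (29, "rs31198", "H", "5", "PITX1", "PITX1", 1, 0, 6.0e-10),
    (29, "rs647161", "CRC", "5", "PITX1", "PITX1", 0, 0, 3.0e-9),
    (32, "rs1047014", "H", "5", "ID4", "ID4", 0, 0, 2.0e-9),
    (32, "rs16882214", "BC", "ND", "ID4", None, 0, 0, 8.0e-8),
    (33, "rs2322633", "H", "6", "BCKDHB", "BCKDHB", 0, 0, 4.0e-8),
    (33, "rs310405", "H", "ND", "FAM46A", None, 0, 0, 9.0e-9),
    (33, "rs17530068", "BC", "ND", "FAM46A", "FAM46A", 0, 0, 2.0e-8),
    (34, "rs961764", "H", "ND", "VGLL2", "RFXDC1", 0, 0, 1.0e-8),
    (34, "rs2057314", "CRC", "4", "DCBLD1", "DCBLD1", 0, 0, 5.0e-8),
    (34, "rs9285425", "H", "5", "DCBLD1", "DCBLD1", 0, 0, 3.0e-10),
    (7, "rs3757318", "BC", "2c", "C6orf97", "C6orf97", 1, 1, 2.0e-24),
    (7, "rs3734805", "BC", "ND", "C6orf97", "C6orf97", 1, 0, 6.0e-16),
    (7, "rs2046210", "BC", "1f", "ESR1", "C6orf97", 0, 0, 1.0e-35),
    (7, "rs9383938", "BC", "5", "ESR1", "C6orf97", 0, 0, 4.0e-12),
    (7, "rs543650", "H", "ND", "ESR1", "ESR1", 0, 0, 7.0e-11),
    (7, "rs9383951", "BC", "4", "ESR1", "ESR1", 0, 0, 9.0e-8),
    (7, "rs2982712", "H", "ND", "ESR1", "ESR1", 0, 0, 2.0e-9),
    (39, "rs10114408", "CRC", "6", "BARX1", "BARX1", 0, 0, 6.0e-8),
    (39, "rs1257763", "H", "ND", "PTPDC1", "BARX1", 0, 0, 2.0e-7),
    (39, "rs16910061", "H", "5", "FBP2", "FBP1", 0, 0, 8.0e-9),
    (39, "rs473902", "H", "3a", "PTCH1", "PTCH1", 0, 0, 3.0e-11),
    (39, "rs10512248", "H", "6", "PTCH1", "PTCH1", 0, 0, 1.0e-13),
    (39, "rs2025151", "H", "1f", "ZNF367", "HABP4", 0, 0, 5.0e-10),
    (39, "rs10816533", "H", "1f", "ZNF510", "ZNF782", 0, 0, 7.0e-9),
    (5, "rs704010", "BC", "2b", "ZMIZ1", "ZMIZ1", 0, 0, 4.0e-13),
    (5, "rs7916441", "H", "5", "ZMIZ1", "ZMIZ1", 1, 1, 2.0e-14),
    (5, "rs780151", "H", "5", "ZMIZ1", "ZMIZ1", 1, 0, 1.0e-10),
    (5, "rs12355688", "BC", "4", "ZMIZ1", "ZMIZ1", 0, 0, 6.0e-9),
    (5, "rs2145998", "H", "5", "PPIF", "ZMIZ1", 1, 0, 3.0e-8),
    (5, "rs941873", "H", "4", "ZCCHC24", "ZMIZ1", 1, 1, 5.0e-11),
    (15, "rs2588809", "BC", "ND", "RAD51B", "RAD51B", 0, 0, 2.0e-9),
    (15, "rs1570106", "H", "ND", "RAD51B", "RAD51B", 0, 0, 8.0e-10),
    (15, "rs999737", "BC", "6", "RAD51B", "RAD51B", 0, 0, 1.0e-16),
    (23, "rs961253", "CRC", "5", "FERMT1", "FERMT1", 0, 0, 2.0e-10),
    (23, "rs967417", "H", "6", "BMP2", "BMP2", 1, 0, 4.0e-12),
    (23, "rs2145270", "H", "ND", "BMP2", "BMP2", 1, 0, 6.0e-9),
    (23, "rs2145272", "H", "3a", "BMP2", "BMP2", 1, 1, 1.0e-11),
    (23, "rs4813802", "CRC", "3a", "BMP2", "BMP2", 0, 0, 5.0e-9),
    (25, "rs139909", "H", "2b", "TNRC6B", "TNRC6B", 0, 0, 3.0e-12),
    (25, "rs5757949", "H", "5", "MKL1", "MCHR1", 0, 0, 7.0e-10),
    (25, "rs6001930", "BC", "5", "MKL1", "MCHR1", 0, 0, 2.0e-13),
]

#: Synthetic within-chromosome anchor position per cluster label; clusters
#: sharing a chromosome (label 32/33/34/7 on chr6) are several Mbp apart so
#: re-clustering at the 1-Mbp window keeps them separate.
_TABLE1_CLUSTER_LOCATION: dict[int, tuple[str, int]] = {
    22: ("2", 217_000_000),
    27: ("4", 105_000_000),
    29: ("5", 134_000_000),
    32: ("6", 19_800_000),
    33: ("6", 82_000_000),
    34: ("6", 117_800_000),
    7: ("6", 151_900_000),
    39: ("9", 96_000_000),
    5: ("10", 80_800_000),
    15: ("14", 68_300_000),
    23: ("20", 6_700_000),
    25: ("22", 40_000_000),
}

#: bp spacing between consecutive fixture SNPs of one cluster (< window).
_TABLE1_SPACING = 50_000

#: Intra-cluster high-LD pairings (r² > 0.7).  The published table only tags
#: which SNPs belong to *some* high-LD group; the pairings themselves are a
#: fixture assumption.  In the six-SNP cluster (label 5) the four tagged
#: SNPs form the two pairs below; all count-level results are invariant to
#: the pairing choice.
_TABLE1_LD_PAIRS: list[tuple[str, str, float]] = [
    ("rs12470505", "rs1052483", 0.92),
    ("rs1052483", "rs6724465", 0.88),
    ("rs12470505", "rs6724465", 0.85),
    ("rs526896", "rs31198", 0.95),
    ("rs3757318", "rs3734805", 0.83),
    ("rs7916441", "rs780151", 0.91),
    ("rs941873", "rs2145998", 0.78),
    ("rs967417", "rs2145270", 0.81),
    ("rs2145270", "rs2145272", 0.86),
    ("rs967417", "rs2145272", 0.74),
    # sub-threshold pairs, present so the strict r² > 0.7 cut is exercised
    ("rs704010", "rs12355688", 0.40),
    ("rs2553026", "rs1351164", 0.70),
]

_PHENOTYPE_CODE = {"H": ANCHOR, "BC": PARTNERS[0], "CRC": PARTNERS[1]}


@dataclass
class Table1Fixture:
    """The packaged transcription, ready to feed every pipeline stage."""

    catalog: Catalog                      # annotated, scores attached
    positional: AnnotationSource
    functional: AnnotationSource
    ld: LdTable
    scores: dict[str, str]
    cluster_labels: dict[int, list[str]]  # published label -> member rsids
    kept_rsids: frozenset[str]            # footnote-marked LD representatives
    ld_tagged: frozenset[str]             # SNPs with LD tag = 1
    frame: pd.DataFrame


def table1_fixture() -> Table1Fixture:
    """Build the published prioritised-cluster table as pipeline inputs."""
    records: list[SnpAssociation] = []
    positional: dict[str, frozenset[str]] = {}
    functional: dict[str, frozenset[str]] = {}
    scores: dict[str, str] = {}
    cluster_labels: dict[int, list[str]] = {}
    kept: set[str] = set()
    tagged: set[str] = set()
    offset_within: dict[int, int] = {}

    rows = []
    for label, rsid, code, score, pos_gene, fun_gene, ld_tag, kept_flag, p in _TABLE1_ROWS:
        chrom, base = _TABLE1_CLUSTER_LOCATION[label]
        i = offset_within.get(label, 0)
        offset_within[label] = i + 1
        pos = base + i * _TABLE1_SPACING
        # MAF is not printed; any value >= the 1% floor works for the counts
        maf = 0.05 + ((len(records) * 13) % 40) / 100.0
        records.append(
            SnpAssociation(
                rsid=rsid, chrom=chrom, pos=pos,
                phenotype=_PHENOTYPE_CODE[code], p_value=p, maf=maf,
            )
        )
        positional[rsid] = frozenset({pos_gene}) if pos_gene else frozenset()
        if fun_gene:
            functional[rsid] = frozenset({fun_gene})
        scores[rsid] = score
        cluster_labels.setdefault(label, []).append(rsid)
        if kept_flag:
            kept.add(rsid)
        if ld_tag:
            tagged.add(rsid)
        rows.append(
            {
                "cluster_label": label, "rsid": rsid, "phenotype": _PHENOTYPE_CODE[code],
                "chrom": chrom, "pos": pos, "p_value": p, "maf": maf,
                "regulome_score": score, "gene_positional": pos_gene or "",
                "gene_functional": fun_gene or "", "ld_tag": ld_tag, "kept": kept_flag,
            }
        )

    pos_src = AnnotationSource(name="positional",
                               mapping={k: v for k, v in positional.items() if v})
    fun_src = AnnotationSource(name="functional", mapping=functional)

    cat = Catalog(records=records, provenance={"table1_fixture": len(records)})
    cat = with_regulome_scores(cat, scores)
    cat = annotate_catalog(cat, [pos_src, fun_src])

    ld = LdTable()
    for a, b, r2 in _TABLE1_LD_PAIRS:
        ld.add(a, b, r2)

    return Table1Fixture(
        catalog=cat, positional=pos_src, functional=fun_src, ld=ld,
        scores=scores, cluster_labels=cluster_labels,
        kept_rsids=frozenset(kept), ld_tagged=frozenset(tagged),
        frame=pd.DataFrame(rows),
    )
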