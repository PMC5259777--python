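"""Reading, validating, filtering and merging GWAS-catalog-style association tables.

A catalog row is one SNP-phenotype association.  Tables from different
repositories use different column names and chromosome dialects, so ingestion
goes through a user-supplied column mapping and normalises chromosome labels
("chr2" -> "2") and phenotype labels (lower-cased, optionally recoded through
a trait-name mapping).  Rows whose required fields cannot be parsed are never
silently dropped: they are collected in a reject report alongside the loaded
records.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

_RSID_RE = re.compile(r"^rs[0-9]+$")

#: Required logical columns every catalog dialect must map.
REQUIRED_COLUMNS = ("rsid", "chrom", "pos", "phenotype", "p_value", "maf")
#: Optional logical columns picked up when mapped.
OPTIONAL_COLUMNS = ("risk_allele", "ancestry", "study", "regulome_score")

#: Valid RegulomeDB-style evidence tokens ("ND" = no data, exported as score 0).
REGULOME_TOKENS = (
    "1a", "1b", "1c", "1d", "1e", "1f",
    "2a", "2b", "2c", "3a", "3b", "4", "5", "6", "ND",
)


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP-phenotype association record.

    ``annotations`` maps an annotation-source name (e.g. ``"positional"``,
    ``"functional"``) to the set of gene symbols that source assigns to the
    SNP; an empty set means the source was consulted but had no annotation.
    """

    rsid: str
    chrom: str
    pos: int
    phenotype: str
    p_value: float
    maf: float
    risk_allele: str | None = None
    ancestry: str | None = None
    study: str | None = None
    regulome_score: str | None = None
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not _RSID_RE.match(self.rsid):
            raise ValueError(f"invalid rsid {self.rsid!r}")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.rsid}: p_value must be in (0,1], got {self.p_value}")
        if not (0 <= self.maf <= 0.5):
            raise ValueError(f"{self.rsid}: maf must be in [0,0.5], got {self.maf}")
        if not self.phenotype:
            raise ValueError(f"{self.rsid}: phenotype must be non-empty")
        if self.regulome_score is not None and self.regulome_score not in REGULOME_TOKENS:
            raise ValueError(
                f"{self.rsid}: unknown regulatory score token {self.regulome_score!r}"
            )

    def genes(self, source: str | None = None) -> frozenset[str]:
        """Gene symbols for one source, or the union over all sources."""
        if source is not None:
            return self.annotations.get(source, frozenset())
        out: set[str] = set()
        for genes in self.annotations.values():
            out |= genes
        return frozenset(out)


@dataclass
class Catalog:
    """An ordered collection of associations plus ingestion provenance.

    ``rejects`` keeps rows that failed validation, as (row-dict, reason)
    pairs, so a reject report can be written next to the loaded data.
    """

    records: list[SnpAssociation] = field(default_factory=list)
    provenance: dict[str, int] = field(default_factory=dict)
    rejects: list[tuple[dict, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def phenotype_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.phenotype] = counts.get(rec.phenotype, 0) + 1
        return counts

    @property
    def phenotypes(self) -> set[str]:
        return {rec.phenotype for rec in self.records}

    def to_frame(self) -> pd.DataFrame:
        """Flat table view (one row per record), for TSV output."""
        rows = []
        for r in self.records:
            row = {
                "rsid": r.rsid, "chrom": r.chrom, "pos": r.pos,
                "phenotype": r.phenotype, "p_value": r.p_value, "maf": r.maf,
                "risk_allele": r.risk_allele, "ancestry": r.ancestry,
                "study": r.study, "regulome_score": r.regulome_score,
            }
            for source, genes in sorted(r.annotations.items()):
                row[f"genes_{source}"] = ",".join(sorted(genes))
            rows.append(row)
        return pd.DataFrame(rows)

    def rejects_frame(self) -> pd.DataFrame:
        rows = [dict(row, reject_reason=reason) for row, reason in self.rejects]
        return pd.DataFrame(rows)


def normalise_chrom(raw: str) -> str:
    """Normalise a chromosome label: strip a "chr" prefix, upper-case X/Y/MT."""
    label = str(raw).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if label.upper() in ("X", "Y", "MT", "M"):
        return "MT" if label.upper() in ("MT", "M") else label.upper()
    return label


_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Genome order: 1..22, X, Y, MT, then anything else lexicographically."""
    return (_CHROM_ORDER.get(chrom, 99), chrom)


def normalise_rsid(raw: str) -> str:
    return str(raw).strip().lower()


def _parse_row(
    row: dict,
    dialect: dict[str, str],
    phenotype_map: dict[str, str] | None,
) -> SnpAssociation:
    """Build one record from a raw row; raises ValueError on unparseable fields."""

    def get(col: str):
        value = row.get(dialect[col])
        if value is None or (isinstance(value, float) and pd.isna(value)):
            raise ValueError(f"missing {col}")
        return value

    rsid = normalise_rsid(get("rsid"))
    chrom = normalise_chrom(get("chrom"))
    raw_pos = get("pos")
    try:
        pos = int(raw_pos)
    except (TypeError, ValueError):
        raise ValueError(f"unparseable pos {raw_pos!r}")
    phenotype = str(get("phenotype")).strip().lower()
    if phenotype_map is not None:
        phenotype = phenotype_map.get(phenotype, phenotype)
    try:
        p_value = float(get("p_value"))
        maf = float(get("maf"))
    except (TypeError, ValueError) as exc:
        raise ValueError(str(exc))

    optional: dict[str, str | None] = {}
    for col in OPTIONAL_COLUMNS:
        mapped = dialect.get(col)
        if mapped and mapped in row and not pd.isna(row[mapped]):
            optional[col] = str(row[mapped]).strip()
        else:
            optional[col] = None

    return SnpAssociation(
        rsid=rsid, chrom=chrom, pos=pos, phenotype=phenotype,
        p_value=p_value, maf=maf, **optional,
    )


def read_catalog(
    path,
    dialect: dict[str, str] | None = None,
    phenotype_map: dict[str, str] | None = None,
) -> Catalog:
    """Read a tab-separated association table into a :class:`Catalog`.

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        Mapping from logical column names (``rsid``, ``chrom``, ``pos``,
        ``phenotype``, ``p_value``, ``maf``, plus optional ones) to the
        file's actual column names.  Defaults to the identity mapping.
    phenotype_map
        Optional raw-trait-name -> controlled-label recoding, matched
        case-insensitively (keys must be lower case).

    Rows with unparseable required fields go to ``catalog.rejects`` with a
    reason; they are reported, never silently dropped.
    """
    dialect = dict(dialect or {})
    for col in REQUIRED_COLUMNS:
        dialect.setdefault(col, col)
    for col in OPTIONAL_COLUMNS:
        dialect.setdefault(col, col)

    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [dialect[c] for c in REQUIRED_COLUMNS if dialect[c] not in frame.columns]
    if len(frame.columns) and missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; present: {list(frame.columns)}"
        )

    cat = Catalog()
    if frame.empty:
        logger.warning("%s: empty catalog file", path)
        cat.provenance[str(path)] = 0
        return cat

    for row in frame.to_dict(orient="records"):
        try:
            cat.records.append(_parse_row(row, dialect, phenotype_map))
        except ValueError as exc:
            cat.rejects.append((row, str(exc)))
    cat.provenance[str(path)] = len(cat.records)
    if cat.rejects:
        logger.warning("%s: rejected %d row(s)", path, len(cat.rejects))
    return cat


def filter_catalog(cat: Catalog, p_max: float = 1e-5, maf_min: float = 0.01) -> Catalog:
    """Keep records with ``p_value < p_max`` (strict) and ``maf >= maf_min``.

    The p-value cut is deliberately strict-less-than while the MAF cut is
    inclusive: a record at exactly the p threshold is dropped, a record at
    exactly the MAF floor is kept.
    """
    if not (0 < p_max <= 1):
        raise ConfigurationError(f"p_max must be in (0,1], got {p_max}")
    if not (0 <= maf_min <= 0.5):
        raise ConfigurationError(f"maf_min must be in [0,0.5], got {maf_min}")
    kept, n_p, n_maf = [], 0, 0
    for rec in cat.records:
        if not rec.p_value < p_max:
            n_p += 1
        elif not rec.maf >= maf_min:
            n_maf += 1
        else:
            kept.append(rec)
    logger.info("filter: removed %d by p-value, %d by MAF; %d kept", n_p, n_maf, len(kept))
    return Catalog(records=kept, provenance=dict(cat.provenance), rejects=list(cat.rejects))


def deduplicate(cat: Catalog) -> Catalog:
    """Collapse to one record per (rsid, phenotype) pair.

    The same SNP reported for the same trait by several studies (or
    meta-analyses) is redundant; the record with the smallest p-value wins,
    ties going to the earliest record in input order.  The same rsid under
    *different* phenotypes is genuinely cross-phenotype information and all
    such records are kept.
    """
    best: dict[tuple[str, str], tuple[float, int]] = {}
    for i, rec in enumerate(cat.records):
        key = (rec.rsid, rec.phenotype)
        if key not in best or rec.p_value < best[key][0]:
            best[key] = (rec.p_value, i)
    keep_idx = sorted(i for _, i in best.values())
    kept = [cat.records[i] for i in keep_idx]
    return Catalog(records=kept, provenance=dict(cat.provenance), rejects=list(cat.rejects))


def merge_catalogs(cats: list[Catalog]) -> Catalog:
    """Concatenate catalogs from several repositories, then deduplicate."""
    if not cats:
        raise ConfigurationError("merge_catalogs requires at least one catalog")
    merged = Catalog()
    for cat in cats:
        merged.records.extend(cat.records)
        for src, n in cat.provenance.items():
            merged.provenance[src] = merged.provenance.get(src, 0) + n
        merged.rejects.extend(cat.rejects)
    return deduplicate(merged)


def with_regulome_scores(cat: Catalog, scores: dict[str, str]) -> Catalog:
    """Return a catalog whose records carry regulatory-evidence tokens.

    ``scores`` maps rsid -> RegulomeDB-style token; "0" (the database's
    no-data code) is accepted as an alias for "ND".  SNPs absent from the
    table keep score ``None`` (treated as no data downstream).
    """
    norm = {normalise_rsid(k): ("ND" if str(v).strip() in ("0", "ND") else str(v).strip())
            for k, v in scores.items()}
    records = [
        replace(rec, regulome_score=norm.get(rec.rsid, rec.regulome_score))
        for rec in cat.records
    ]
    return Catalog(records=records, provenance=dict(cat.provenance), rejects=list(cat.rejects))


def read_regulome_scores(path) -> dict[str, str]:
    """Read a two-column TSV (rsid, score) of regulatory-evidence tokens."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.empty:
        logger.warning("%s: empty score file", path)
        return {}
    cols = list(frame.columns[:2])
    return {
        normalise_rsid(r[cols[0]]): str(r[cols[1]]).strip()
        for r in frame.to_dict(orient="records")
    }
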