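"""Gene-set over-representation analysis by hypergeometric test with FDR control.

The annotated genes of the pruned clusters form a query list that is tested
against pathway / GO gene sets: for each set, the upper-tail hypergeometric
probability of drawing at least the observed overlap when sampling the query
from the background universe.  The universe defaults to the union of all
genes in the loaded sets (a pathway-database background) and can be
overridden by an explicit gene list or a plain integer size.  P-values are
adjusted by Benjamini-Hochberg within each family of tested sets; sets whose
overlap falls below ``min_overlap`` are skipped before testing and do not
count toward the correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 2
DEFAULT_P_CUTOFF = 0.01
DEFAULT_Q_CUTOFF = 0.05


@dataclass(frozen=True)
class GeneSet:
    """A named gene collection with its database-of-origin label."""

    name: str
    source_db: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested set: overlap, hypergeometric p and BH q."""

    set_name: str
    source_db: str
    m: int              # set size within universe
    n: int              # query size within universe
    k: int              # overlap
    overlap_genes: frozenset[str]
    N: int              # universe size
    p_value: float
    q_value: float
    significant: bool


def read_gmt(path, source_db: str = "") -> list[GeneSet]:
    """Parse a GMT file (name <tab> description <tab> gene...), order preserved.

    Duplicate genes within a line are collapsed; lines with fewer than three
    fields are reported and skipped.  When ``source_db`` is empty the
    description field is used as the database label.
    """
    sets: list[GeneSet] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: GMT line with <3 fields skipped", path, lineno)
                n_bad += 1
                continue
            name, desc, *genes = fields
            genes = frozenset(g.strip() for g in genes if g.strip())
            if not genes:
                logger.warning("%s:%d: GMT line with no genes skipped", path, lineno)
                n_bad += 1
                continue
            sets.append(GeneSet(name=name, source_db=source_db or desc, genes=genes))
    if not sets:
        logger.warning("%s: no gene sets loaded (%d bad lines)", path, n_bad)
    return sets


def hypergeometric_tail(k: int, n: int, m: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N total, m marked, n drawn).

    Exact (no normal approximation).  ``k = 0`` gives 1.0 by definition.
    """
    if not (0 <= k <= min(n, m)) or n > N or m > N or min(k, n, m, N) < 0:
        raise ConfigurationError(
            f"invalid hypergeometric arguments k={k}, n={n}, m={m}, N={N}"
        )
    # survival function at k-1 is exactly P(X >= k)
    return float(hypergeom.sf(k - 1, N, m, n))


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * T / j over the sorted p-values, capped at 1.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ConfigurationError("p-values must lie in (0,1]")
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    return q


def _resolve_universe(universe, sets: list[GeneSet]):
    """Return (universe_genes | None, N).  ``None`` genes means size-only mode."""
    if universe is None or (isinstance(universe, str) and universe == "auto"):
        genes: set[str] = set()
        for s in sets:
            genes |= s.genes
        return frozenset(genes), len(genes)
    if isinstance(universe, int):
        if universe <= 0:
            raise ConfigurationError("integer universe size must be positive")
        return None, universe
    genes = frozenset(universe)
    for s in sets:
        extra = s.genes - genes
        if extra:
            raise ConfigurationError(
                f"gene set {s.name!r} has {len(extra)} gene(s) outside the "
                f"explicit universe (e.g. {sorted(extra)[:3]})"
            )
    return genes, len(genes)


def run_ora(
    query,
    sets: list[GeneSet],
    universe="auto",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> list[EnrichmentResult]:
    """Over-representation analysis of one query gene list.

    The query and every set are intersected with the universe before
    testing; sets overlapping the query in fewer than ``min_overlap`` genes
    are skipped entirely (they neither appear in the output nor inflate the
    BH correction).  Results are sorted by ascending p-value (ties by set
    name, then database) and flagged significant when ``p < p_cutoff`` and
    ``q < q_cutoff``.  With an integer universe the query and sets are used
    as given (size-only background).
    """
    query = frozenset(query)
    if not query:
        raise ConfigurationError("query gene list is empty")
    uni_genes, N = _resolve_universe(universe, sets)
    if uni_genes is not None:
        query_u = query & uni_genes
        if not query_u:
            raise ConfigurationError(
                f"none of the {len(query)} query genes occur in the "
                f"{N}-gene universe; check symbol conventions"
            )
    else:
        query_u = query
    n = len(query_u)
    if n > N:
        raise ConfigurationError(f"query size {n} exceeds universe size {N}")

    tested: list[tuple[GeneSet, int, frozenset[str], int]] = []
    for s in sets:
        genes = s.genes & uni_genes if uni_genes is not None else s.genes
        overlap = genes & query_u
        if len(overlap) < min_overlap or not genes:
            continue
        tested.append((s, len(genes), overlap, len(overlap)))
    if not tested:
        return []

    pvals = [hypergeometric_tail(k, n, m, N) for (_, m, _, k) in tested]
    qvals = bh_qvalues(pvals)
    results = [
        EnrichmentResult(
            set_name=s.name, source_db=s.source_db, m=m, n=n, k=k,
            overlap_genes=overlap, N=N, p_value=p, q_value=float(q),
            significant=bool(p < p_cutoff and q < q_cutoff),
        )
        for (s, m, overlap, k), p, q in zip(tested, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name, r.source_db))
    return results


def run_grouped_ora(
    queries: dict[str, frozenset[str] | set[str]],
    sets: list[GeneSet],
    universe="auto",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> dict[str, list[EnrichmentResult]]:
    """Independent ORA per labelled query over a shared universe.

    Used for the combined gene list and per-cancer-site sub-analyses; the BH
    family is each label's own set of tested gene sets.  Labels whose query
    is empty yield an empty result list rather than an error.
    """
    if not queries:
        raise ConfigurationError("at least one labelled query is required")
    out: dict[str, list[EnrichmentResult]] = {}
    for label, query in queries.items():
        if not query:
            logger.warning("grouped ORA: query %r is empty, skipped", label)
            out[label] = []
            continue
        out[label] = run_ora(
            query, sets, universe=universe, min_overlap=min_overlap,
            p_cutoff=p_cutoff, q_cutoff=q_cutoff,
        )
    return out


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """TSV-ready table mirroring the usual pathway-report columns."""
    rows = [
        {
            "set_name": r.set_name,
            "source_db": r.source_db,
            "set_size": r.m,
            "overlap": r.k,
            "overlap_genes": ",".join(sorted(r.overlap_genes)),
            "query_size": r.n,
            "universe_size": r.N,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "significant": int(r.significant),
        }
        for r in results
    ]
    return pd.DataFrame(rows)
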