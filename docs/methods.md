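# Methods

## Model and assumptions

The pipeline rests on one empirical regularity: SNPs associated with
complex traits cluster in regions of low recombination, so hits for two
biologically linked phenotypes can co-locate within a megabase even when no
single SNP is associated with both. The method never tests a SNP against
two phenotypes jointly; it only asks whether *separately discovered* hits
fall in the same window-chained region and share a gene annotation. All
genomic reasoning is in base pairs on a single build; no liftover and no
recombination-map (cM) distances are used.

### Window chaining

"Clustering with a sliding window of *w*" is implemented as single-linkage
chaining: per chromosome, SNPs are sorted by position and a SNP joins the
open cluster iff its distance to the previous member is ≤ *w* (inclusive
boundary). Equivalently, clusters are the connected components of the graph
joining every SNP pair at distance ≤ *w* — the all-pairs formulation is
kept as an independent test oracle. Consequences worth knowing:

* a cluster can span several times *w* (each link, not the span, is
  bounded), which is intended — some prioritised regions exceed 1 Mbp;
* shrinking *w* can only split clusters, never merge them (monotone
  refinement), which `window_sensitivity` quantifies;
* clusters never cross chromosome boundaries, and output is invariant to
  input row order (ties at one position break by rsID, then phenotype).

### Shared-gene prioritisation

A cross-phenotype cluster (anchor phenotype + ≥ 1 partner phenotype) is
prioritised when some gene is annotated to at least one anchor SNP and at
least one partner SNP, taking each SNP's annotation as the *union* over
sources. The union deliberately allows same-source, cross-source and mixed
matches. Gene symbols are compared as trimmed, case-sensitive strings; no
alias resolution is attempted (annotations are inputs, not computed here).

Cross-source concordance is reported over SNPs annotated in *both* sources;
"same" means set equality of the two gene sets. With multi-gene
annotations set equality is the stricter reading; an any-overlap mode is
available (`mode="overlap"`) for sensitivity analysis. With zero doubly
annotated SNPs the percentage is undefined and reported as `None`, never
coerced to 0 or 100.

### LD pruning with regulatory-evidence ranking

Within one cluster, SNP pairs with r² strictly above the threshold
(default 0.7) are redundant; redundancy groups are the connected components
of that graph (transitive closure — a deliberate choice, since "two or
more SNPs in high pairwise LD" underdetermines grouping). Each group keeps
one representative:

1. strongest regulatory evidence, ordinal
   `1a<1b<1c<1d<1e<1f<2a<2b<2c<3a<3b<4<5<6<ND` (cis-eQTL grades first,
   then protein-binding grades, then minimal-evidence grades; "ND" is the
   no-data code, also written "0" in RegulomeDB exports, and a missing
   score is treated as ND);
2. ties by smallest association p-value;
3. remaining ties by lexicographic rsID (pure determinism).

Within the minimal-evidence pool the order 4 < 5 < 6 < ND is imposed for
determinism even though that pool is sometimes treated as one grade.

Pruning is constraint-preserving: all non-representatives are removed
tentatively, then — if the cluster no longer holds an anchor and a partner
SNP, or (for prioritised clusters) no longer passes the shared-gene rule —
removed SNPs are restored strongest-evidence-first until both rules hold.
Restored SNPs are flagged `constraint_retained`; a report row records every
group with kept/removed members and reasons (`score`, `p_tie`, `rsid_tie`,
`constraint_retained`). Restoration always terminates because the original
cluster satisfied the rules. All within-cluster pairs are evaluated
regardless of phenotype; phenotype balance is protected by the constraint
override, not by restricting which pairs may form groups.

### Over-representation analysis

For a query gene list against a gene-set collection: exact hypergeometric
upper tail P(X ≥ k), X ~ Hypergeom(N, m, n) (scipy's survival function at
k−1; no normal approximation), BH step-up q-values within the family of
*tested* sets, significance at p < `p_cutoff` (0.01) and q < `q_cutoff`
(0.05). Sets overlapping the query in fewer than `min_overlap` (2) genes
are skipped before testing and do not inflate the correction. The
background universe defaults to the union of all genes in the loaded sets
and can be overridden by an explicit gene list or a plain integer size —
printed p-values from any specific pathway server are only reproducible
with that server's background, which is why the knob exists. Grouped
analyses (combined plus per-partner queries) share the universe but apply
BH within each label's own family.

## Parameters

| parameter | default | unit | why |
|---|---|---|---|
| `p_max` | 1e-5 | — | liberal cut keeping sub-genome-wide hits that may act jointly; strict `<` |
| `maf_min` | 0.01 | frequency | exclude rare variants; inclusive `≥` |
| `window_bp` | 1,000,000 | bp | wide enough for multi-phenotype loci; regulatory contacts span >250 kbp |
| `r2_min` | 0.7 | r² | redundancy threshold, strict `>` |
| `min_overlap` | 2 | genes | a single-gene overlap is not set-level evidence |
| `p_cutoff`, `q_cutoff` | 0.01, 0.05 | — | ORA significance |
| `universe` | `"auto"` | — | union of loaded sets; override with list or integer |

## Synthetic data: what it emulates, what it does not

`generate_catalog` carves the genome into slots spaced more than one
window apart and places each planted cluster (1–3 anchor + 1–2 partner
SNPs within 0.5 Mbp) and each background singleton in its own slot, so the
planted partition is exactly recoverable and recorded as truth. P-values
are log-uniform in [1e-30, 1e-6], MAF uniform in [0.01, 0.5], regulatory
scores uniform over the 15 tokens. Defaults mirror the motivating study's
working set (514 height / 157 breast-cancer / 50 colorectal SNPs).
`generate_ld` draws r² ~ U(0.75, 1) for designated within-cluster pairs
(each pair designated with probability `ld_block_rate`) and U(0, 0.5)
otherwise; pairs across clusters carry no rows, as proxy-search LD tables
only list nearby pairs. `generate_annotations_and_sets` gives every SNP
one gene per source, the two sources agreeing with probability
`annotation_concordance` (default 0.647).

Not emulated: genotypes or haplotypes, realistic LD decay with distance,
overlapping or nested clusters, multi-gene annotations, genome-build
artefacts, trait-name noise. Passing planted-truth tests therefore shows
the *algorithms* implement their definitions, not that the thresholds are
optimal for real catalogs — on real data clusters can merge by chance and
annotation sources disagree in structured, not Bernoulli, ways.

The packaged fixture transcribes the published table of 12 prioritised
clusters verbatim in its printed columns (rsIDs, phenotypes, scores, two
gene columns, LD tags, kept-SNP footnotes). Three fields the table does not
print are synthetic, documented fixture assumptions: base-pair positions
(cytogenetic bands only are printed; members are spaced 50 kbp apart and
same-chromosome clusters several Mbp apart so re-clustering reproduces the
printed memberships), association p-values (chosen so the printed kept-SNP
footnotes win the tie-breaks), and the exact intra-group LD pairings in
the six-SNP cluster (two pairs; every count-level result is invariant to
the pairing, which the test suite checks by exhausting all representative
choices).

### Planted-enrichment design

The ORA power check plants one 50-gene set containing exactly 5 genes of a
20-gene query in a 1,000-gene universe, plus 99 random decoys. The planted
tail probability is then fixed at P(X ≥ 5) = 2.24×10⁻³. Decoys are
fixed-size 15-gene sets: a closed-form discreteness analysis of the
hypergeometric tail shows a 15-gene decoy must overlap the query in ≥ 4
genes (probability 1.4×10⁻⁴) before its p-value undercuts the planted
set's, giving a rank-1 probability of ≈ 0.986 across the 99 decoys, while
the expected BH family stays small enough (~4–5 tested sets) for the
planted q-value to clear 0.05. Broader decoy-size mixtures (e.g. uniform
10–30) put substantial mass on sizes whose k = 3 or k = 4 tails fall just
below the planted p, degrading rank-1 recovery to ~90% and making the
check a coin flip about decoy geometry rather than about the ORA code.

## Numerical and design choices

* Strict vs inclusive boundaries follow the stated rules exactly:
  p-value `<`, MAF `≥`, window `≤`, r² `>`. Each has a boundary test.
* Deduplication keeps the smallest p per (rsID, phenotype), ties to first
  input occurrence; the same rsID under different phenotypes is
  cross-phenotype information and is never collapsed. SNPs at identical
  positions under different rsIDs stay distinct records.
* BH q-values delegate to `statsmodels.multipletests(method="fdr_bh")`
  behind the `bh_qvalues` surface; tests verify it against an independent
  quadratic-time suffix-minimum oracle. The hypergeometric tail delegates
  to `scipy.stats.hypergeom.sf`; tests verify it against brute-force
  enumeration of all draws for universes up to 12 genes.
* Degenerate inputs: empty catalog files load as empty catalogs with a
  warning; rows with unparseable required fields go to a reject report,
  never silently dropped; an empty LD table makes pruning a no-op; a query
  disjoint from all sets yields an empty (not erroneous) result; an
  undefined concordance is reported as undefined.
* Determinism: one named `numpy.random.default_rng` per generator, seeded
  from a single integer (sub-generators offset by +1/+2); cluster IDs
  assigned in genome order; all output tables sorted deterministically;
  pipeline reruns are byte-identical.
* Check problem sizes (the package's own choice of simulation scale):
  planted-cluster recovery over 100 seeds of 5–20 planted clusters in a
  225-SNP catalog; clustering-oracle agreement over 1,000 random 500-SNP
  instances; pruning safety over 1,000 random clusters of 4–12 SNPs;
  enrichment power over 200 replicates; null calibration of the ORA
  type-I rate over 1,000 random queries.

## Known limitations

* Annotations, LD and regulatory scores are consumed as files; nothing is
  fetched, recomputed from genotype panels, or alias-resolved.
* GO terms are flat gene sets; no hierarchy propagation or level filtering.
* Phenotype labels are free strings recoded through a user mapping;
  haplotype entries or merged rsIDs in source catalogs are treated as
  independent rows.
* The cluster-ID numbering is this package's genome-order numbering; the
  fixture carries the published labels separately for cross-reference.
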