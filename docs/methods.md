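# Methods

## Scope and model of the data

`gutdiverge` operates on the artifacts a single-library comparative
tissue-transcriptome experiment produces: per-species tables of raw read
counts (and optionally FPKM) for one tissue library and one
whole-organism library, a strictly one-to-one ortholog map between the
two species, many-to-many gene→protein-domain and gene→term annotations,
and named gene sets (plain lists or GMT).  Reads, alignments and
annotation pipelines are out of scope; the package starts where the
count matrix ends.

All expression is expressed as FPKM = count · 10⁹ / (length_bp ·
library_size).  Library sizes are explicit metadata rather than column
sums, since multi-mapping makes column sums unreliable.

## Exact overlap statistics

The package's one statistical primitive is the hypergeometric tail.  For
an overlap of `k` between sets of size `K` and `n` in a universe of `N`:

- enrichment: `p = P(X ≥ k)`, depletion: `p = P(X ≤ k)` with
  `X ~ Hypergeom(N, K, n)`;
- enrichment fold `k/(K·n/N)`, reported as 0 when `k = 0` and flagged
  undefined when the expectation is 0.

Numerics: the pmf at the observed `k` is evaluated through log-gamma;
subsequent terms follow the ratio recurrence
`pmf(j+1)/pmf(j) = (K−j)(n−j)/((j+1)(N−K−n+j+1))` accumulated with
log-add-exp.  Summation stops once the geometric-series bound on the
remaining tail falls below 10⁻¹⁷ of the running sum, so truncation never
dominates floating-point error.  Because the distribution is symmetric
in `(K, n)`, arguments are canonicalised so that overlap tests are
*exactly* swap-invariant.  The lower tail reuses the same code through
the reflection `P(X ≤ k) = P(n − X ≥ n − k)` with `n − X ~
Hypergeom(N, N−K, n)`.  Against exact integer enumeration the routine is
accurate to ~10⁻¹³ relative error for every universe up to N = 60; at
genome-scale arguments accuracy is bounded by log-gamma differencing at
~10⁻⁸ relative, far below any decision threshold in use.

Membership outside a stated universe is dropped (and logged), not an
error: published gene sets routinely contain retired identifiers.

Multiple testing uses Benjamini–Hochberg step-up (via statsmodels).
Genome-wide screens (per-gene enrichment calling, term enrichment)
default to BH; the family-level screen defaults to the unadjusted
`p < 0.01` convention common for domain-enrichment reporting, with a BH
mode behind a flag.

## Tissue-enrichment calling

With one library per condition there is no replicate variance to
estimate, so differential expression is defined as the one-sided exact
test on the 2×2 table of raw counts against library totals
(`count_tissue` of `lib_tissue` vs `count_whole` of `lib_whole`).  A gene
is called tissue-enriched when `q ≤ α` (default 0.05), its tissue FPKM
exceeds its whole-organism FPKM, and the displayed
`log2((fpkm_t + c)/(fpkm_w + c))` (pseudocount `c = 1` FPKM, display
only) clears an optional floor (default 0).

This test treats biological variability as zero — the single-library
design admits nothing else — so its p-values quantify sequencing-depth
noise only.  Deeper sequencing monotonically increases power and can
only add calls, never remove them (asserted in tests).  Adding all-zero
genes enlarges the BH denominator and can shrink the called set; this is
a property of FDR control, documented and asserted rather than patched.

## Conservation analyses

The cross-species universe is the one-to-one ortholog core only.  A
whole-genome universe is deliberately not offered: genes without
one-to-one orthologs cannot be shared, and counting them would inflate
the fold.  The conserved-overlap test takes `N` = core size, `K`/`n` =
per-species enriched genes inside the core, `k` = pairs enriched on both
sides, upper-tail p.

Expression-category distributions bin FPKM at [0,1), [1,10), [10,100),
[100,∞); only the `< 1` boundary carries meaning (the conventional
"lowly expressed" threshold), the rest are display conventions.  The
low-expression depletion test is the lower hypergeometric tail of
below-threshold membership in the gene set versus the background; the
background defaults to the ortholog core in the pipeline's conservation
stage (the natural comparison population there) and to all genes of the
table when called directly, both exposed as arguments.

## Family-level analyses

A family is the set of genes carrying a protein domain.  Cumulative
share = (Σ member FPKM)/(Σ all genes' FPKM) per library; a multi-domain
gene contributes fully to each of its families, so shares are not a
partition (they sum to 1 only when annotation is single-domain —
asserted as a property).  The abundant-family filter keeps families with
tissue share > 1% that also exceed their whole-organism share.  Family
enrichment is the overlap test of family members against the
tissue-enriched set in the universe of all genes with calls; families
with fewer than 2 members in the universe are skipped; unannotated genes
stay in the universe by default (annotated-only behind a flag).

## Set-level comparisons

The cross-study matrix is row-normalised (`value[i][j]` = % of set *i*
found in set *j*) and therefore intentionally asymmetric.  Term
enrichment is flat — annotations are used as given, no ontology
propagation (pre-propagated annotations are accepted as input).  The
pathogen-response table prints, per `<pathogen>/<up|down>` set, the
common-gene count, fold and exact p, with the display convention
`n.s.` at p ≥ 0.05, plain numbers down to 0.01 and power-of-ten ceilings
(`<10^-12`) below; exact p-values always remain in the machine-readable
column.

## The synthetic generator

The generator emulates the study conditions the pipeline is built for,
at full scale by default: catalogs of 20 000 and 24 000 genes, a
5985-pair one-to-one core, enriched fractions 724/20000 and 464/24000,
single libraries of 4 × 10⁷ mapped reads, mean transcript length 1500 bp.
A single `size_factor` scales catalog, core, library and annotation
sizes down uniformly; tests and the desk-scale examples use 0.25 (and
0.1 for smoke tests) so the suite runs in seconds.

Model choices, and why:

- **Baseline expression** log₁₀ FPKM ~ Normal(0.7, 0.8), shared across
  ortholog pairs with per-species jitter (sd 0.15).  This yields a
  median around 5 FPKM, ~20% of genes below 1 FPKM, and the high
  tissue/whole and cross-species correlations seen in real library
  pairs, without modelling correlation explicitly.
- **Counts** are Poisson with mean FPKM·length·library/10⁹.  Each
  condition is a single library, so there is no replicate dispersion for
  a negative binomial to represent; an NB dispersion knob exists for
  robustness experiments.  Reported FPKM columns are recomputed from the
  sampled counts, so tables carry genuine measurement noise.
- **Planted enrichment** multiplies tissue-library expectation by
  2^effect (default 8-fold) for a fraction of genes drawn only from
  baselines ≥ 1 FPKM.  Real tissue-enriched sets are strongly depleted
  of lowly expressed genes, and a planted effect on a silent gene is
  undetectable at any depth; restricting eligibility reproduces that
  depletion structure.
- **Conservation probability** ρ (default 0.105): a core gene enriched
  in species A makes its partner enriched in B with probability ρ; the
  rest of B's quota is drawn uniformly from eligible genes.  The default
  makes the expected shared-core overlap ≈ 15 of a 5985-pair core with
  124/107 enriched per side.  `expected_conserved_overlap()` returns the
  analytic expectation of (K, n, k, fold) under this law, handling
  partner eligibility through the bivariate-normal orthant probability
  implied by the shared baseline; parameter-recovery tests compare
  simulated folds against it.
- **Families**: ~1200 domain families with Zipf(1.8) weights, 1–3
  families per gene, hard size cap 400.  Five families are planted as
  enriched in both species (plus 8/6 private ones) by adding a dozen
  tissue-enriched member genes each; the family-conservation stage must
  recover exactly the shared five.
- **Response sets**: 4 pathogens × up/down per species, 100 genes each;
  a member comes from the planted enriched pool with probability
  `coupling` (A: 0.35, B: 0.0), otherwise uniformly from the catalog, so
  coupling 0 gives fold ≈ 1.  The defaults reproduce the designed
  asymmetry: ≥ 6/8 highly significant rows in A, none in B.
- **Study variants**: 5 replicates of the species-A enriched set with
  40% of members swapped for random genes, giving the 35–60% pairwise
  sharing typical of independently derived tissue gene sets.

Everything is deterministic under (config, seed): identical inputs give
byte-identical bundles.

What the generator does *not* emulate — and what passing tests therefore
do not show: isoform structure, mappability and GC bias, correlated
count overdispersion across genes, realistic domain co-occurrence
architecture, ontology structure among terms, and biological coupling
between expression level and family membership.  Recovery rates measured
here are upper bounds for data with those complications.

## Numerical and degenerate-input conventions

Thresholds live in one config object (`α_de = 0.05`, `α_family = 0.01`,
`α_term = 0.05`, min share 1%, FPKM floor 1.0, `n.s.` at 0.05).  Empty
gene sets are read errors; an empty ortholog map is valid on read but a
hard error for the conservation stage; sets fully outside a universe are
errors for response tables (they indicate a species mix-up) but silent
drops elsewhere.  Report writers sort rows by primary key and format
floats at 6 significant digits so reruns are byte-identical.

## Known limitations

- The enrichment caller's p-values ignore biological replication by
  design; they should be read as depth-limited evidence, not population
  inference.
- One-to-one orthologs only; paralog families are handled at the
  domain-family level, not by homology-aware mapping.
- Flat term analysis can both over- and under-count agreement relative
  to DAG-aware enrichment.
- The two-sided overlap mode is a minimum-likelihood exact test and is
  conservative; all default screens are one-sided by design.
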