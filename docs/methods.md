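# Methods

## Scope and model

`pleioband` operationalizes a cross-phenotype locus-sharing analysis: given a
GWAS-catalog-style table of SNP–trait associations, it asks which cytobands
carry significant associations for several clinical phenotype groups at once,
and then triages the SNPs and genes in those bands. The unit of intersection
is the cytoband *label* (string equality). This is deliberately coarse: it
needs no LD reference or coordinate liftover, and it matches how the source
region column is reported. Sub-bands (11p11.2) are never merged with parent
bands (11p11); two catalogs disagreeing on band nomenclature will not
intersect.

### Phenotype grouping

A `TraitQuery` is a named list of trait strings. The default five groups
(diabetes combining T1D and T2D; obesity/BMI; dyslipidemia; sleep apnea;
hypertension) carry the UAEDIAB study's trait vocabularies verbatim. Matching
is exact after case-folding and whitespace normalization; substring matching
is opt-in because it silently broadens groups (e.g. "diabetes" would capture
nephropathy traits). An association may belong to several groups; one
matching no group is returned under the reserved `unassigned` key and takes
no further part.

The significance filter keeps records with reported p-value strictly below α
(default 0.05). The catalog's p-values are per-study association p-values; no
re-adjustment is applied, since no well-defined adjustment exists across
heterogeneous studies. Records with a missing p-value are dropped and tallied
as a warning count rather than an error.

### Exclusive Venn partition

Each region is assigned to the cell of exactly the groups whose region sets
contain it; cells are disjoint and cover the input union (asserted at run
time). Shared-region selection takes the union of cells with ≥ k groups
(default 4) that include a required anchor group (default the diabetes
group, so every reported combination is diabetes-anchored; pass
`required_group=None` to disable).

**Known discrepancy in the bundled membership table.** The published table of
region–phenotype memberships prints the bands 11p15.4 and 11p15.5 each in two
cells (one multi-phenotype cell and the diabetes-only list). Reconstructing
per-phenotype sets takes the union of the implied memberships, so an
exclusive re-partition places each band once, in its larger cell, and the
diabetes-only cell therefore holds 87 bands while the published list prints
89 entries. All other cell sizes reproduce the published counts exactly. The
duplication is preserved verbatim in `pleioband.refdata` rather than edited
away, and the recomputed 87 is reported as computed.

**Median-threshold selection prints more genes than the narrative names.**
With the bundled two-patient counts, the pooled median after excluding counts
≤ 1 is 4, and six genes (ASAH1, LRP4, FES, HSD17B12, HNF1B, SH2B3) reach 4 in
both patients, although the narrative highlights only the first four.
`select_candidate_genes` returns all qualifying genes; callers wanting the
narrower set must raise the threshold themselves.

### Enrichment

Defaults: hypergeometric upper tail (one-sided, enrichment only), z-score
with the finite-population variance nK/N·(N−K)/N·(N−n)/(N−1) so that z and p
share a null, Benjamini–Hochberg FDR across the terms of one call (the
adjustment is unnamed upstream; BH is the field default). The binomial
method approximates with success probability K/N; Fisher's one-sided exact
test equals the hypergeometric tail on the same 2×2 table (tested). The
background universe is an explicit required input — results are only
interpretable relative to it, and no default exists that is defensible for
every catalog snapshot. Degenerate terms (K = 0, or variance 0) report p = 1,
z = 0 and a `degenerate` flag instead of NaNs.

### Ontology similarity

Annotations propagate to all ancestors (true-path rule) before anything else;
IC(t) = −log₁₀(propagated frequency). The root always has IC 0 and IC is
monotone from parent to child. Terms left with zero propagated annotations
get IC = +∞ as an explicit "no evidence" marker; any Lin score through them
is 0. Term similarity is Lin-normalized at the MICA — chosen over raw Resnik
because the downstream partner-count threshold lives on a fixed [0, 1] scale;
raw Resnik is available via `normalize=False`.

The three profile combiners operate on the directional best matches (each
term's best partner in the other profile, both directions):
*best-match-average* is their mean, *maximum* is the matrix maximum, and
*complete* is their minimum — the most conservative summary, demanding that
every annotated term find a good match. "Complete" has no single canonical
definition in the literature, so this one is documented and tested rather
than assumed; by construction complete ≤ best-match-average ≤ maximum.
Partner counting uses strict inequality at the threshold (default > 0.5) and
counts only *other* entities.

### Variant burden

Counting is site-based: a passing record contributes once regardless of
genotype or how many ALT alleles it lists. The SNV rule requires a 1-bp REF
and at least one 1-bp ACGT ALT; indels are excluded by default
(`include_indels=True` to change). FILTER must be PASS or "." unless
`pass_only=False`. Intervals are 1-based with both ends inclusive (BED input
is converted on read and this is the only place half-open coordinates
appear). Chromosome naming is not silently normalized: a `chr1`-vs-`1`
mismatch raises with a hint, because silent stripping can mask a wrong
reference build.

The candidate threshold pools every per-gene, per-sample count, drops counts
≤ `exclusion_max` (default 1 — genes with at most one SNV in a sample carry
no clustering signal), and takes the median with midpoint interpolation. The
pooled median is used rather than per-sample medians because per-sample
medians are unstable at small gene panels and do not reproduce the reference
threshold of 4 on the bundled counts (the pooled version does; tested).
Candidates must reach the threshold in **every** sample, and are ordered by
descending minimum count.

### Expression comparison

Analysis runs on log₂(FPKM+1) by default (raw scale available); the +1
offset keeps zeros finite and the log tames the right skew of FPKM. The
D'Agostino–Pearson gate needs its skewness and kurtosis components to be
meaningful, so it is applied only when both groups have ≥ 8 samples; smaller
groups go straight to Mann–Whitney. Both branches are two-sided. No
multiple-testing correction is applied by default (single-gene follow-up
comparisons are reported raw); `adjust_fdr=True` applies BH across the tested
genes. The mean-expression ranking uses the nondiabetic group only, so a
disease effect cannot reorder the baseline ranking, with alphabetical
tie-breaks.

## Synthetic data: what it emulates and what it does not

`synthdata` serves two roles. The **fixture** generators materialize the
bundled reference tables: the catalog fixture emits the 46 shared-region SNP
rows with trait strings chosen to realize each region's full phenotype
combination, one association per remaining region–phenotype membership, and
decoy rows (non-matching traits; a mix of significant, non-significant and
missing p-values). Regions whose combination has more phenotypes than SNPs
(one band: 3 SNPs, 4 phenotypes) get extra rows reusing an existing rsID with
a different trait — exactly how the real catalog represents one SNP with
several trait associations — so distinct-SNP counts are preserved.

The **simulators** plant known truths: regions shared by exactly k
phenotypes (truth = the membership map); a random rooted DAG whose IC and
pairwise similarities are recomputed by an independent closure-enumeration
oracle inside the generator; VCFs with planted per-gene SNV counts plus
decoy indels, out-of-interval SNVs and filter-failing records; and a
log-normal FPKM matrix (default 63 vs 12 samples, matching the islet cohort)
with planted per-gene log₂ shifts — by default HSD17B12 one unit *down* in
T2D, following the detailed differential-expression result (p = 0.03,
reduced in diabetic islets) rather than the contradictory "upregulated"
summary phrasing; the comparison reports signed direction either way.

None of this emulates LD structure, allele frequencies, annotation-ontology
realism, or count-level RNA-seq noise. Passing tests therefore demonstrate
that the *procedures* are implemented correctly against enumerable ground
truth, not that the published snapshot-dependent values (enrichment z/p/FDR
tables, partner counts, the islet p = 0.03) are recoverable — those depend on
the 2019 catalog and annotation snapshots and are out of scope.

## Numerical and testing choices

- Hypergeometric tails come from `scipy.stats.hypergeom.sf(x−1, …)` and are
  tested to 1e−12 against exhaustive enumeration of all C(N, n) draws for
  N ≤ 12; the Venn partition is tested against the exhaustive 2^G
  combination oracle; IC/MICA/combiners against the enumeration oracle over
  100 simulated DAGs.
- Type-I calibration: on ~1000 null genes at 63-vs-12, the gated procedure's
  rejection rate at α = 0.05 must fall within two binomial standard
  deviations of 0.05; power at a planted 2-SD shift must be ≥ 90% over 500
  genes. Problem sizes (catalog of ~420 rows, 12–15-term DAGs, 1000 null
  genes) keep the whole suite in the tens of seconds while leaving the
  statistical tolerances meaningful.
- Determinism: every generator takes a seed (`numpy.random.default_rng`),
  writes it into a header comment, and is byte-identical across runs;
  orderings everywhere are explicit (regions by chromosome then band string,
  genes by region then symbol, candidates by descending minimum count then
  symbol) so golden-file comparisons are stable.
- Degenerate inputs fail loudly and early: empty trait lists, duplicate group
  names, cyclic or multi-rooted DAGs, unannotated entities, empty median
  pools, sub-2-sample groups and unknown YAML keys are all fatal with the
  offending name in the message.

## Limitations

- Band-label granularity inherits every quirk of the catalog's region column
  (see the band/position warning report for chromosome-level disagreements;
  finer disagreements are undetectable without a cytoband coordinate track).
- The enrichment universe and the gene panel for variant counting are
  explicit inputs by design; the package does not guess them.
- The similarity module is entity-type-agnostic (SNPs or genes); whether the
  annotation frequency underlying IC should count SNPs or genes is a modeling
  choice left to the caller's annotation file.
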