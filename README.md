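# pleioband

Cross-phenotype mining of GWAS-catalog associations at cytoband resolution.

Clinically linked phenotypes — diabetes, obesity/BMI, dyslipidemia,
obstructive sleep apnea and hypertension (the UAEDIAB phenotype groups) —
often share risk loci. `pleioband` is a library for geneticists and
bioinformaticians who want to find those shared loci from a GWAS-catalog-style
association table and carry them through the downstream triage steps:
annotation enrichment, ontology-based SNP relatedness, per-patient variant
burden, and a two-group expression comparison in pancreatic islets.

## The method

1. **Phenotype grouping and filtering.** Each association row (one record per
   SNP after splitting multi-SNP rows) is assigned to every phenotype group
   whose trait vocabulary matches its trait string (exact, case-insensitive
   matching by default) and kept if its reported p-value is < α (default
   0.05, strict).
2. **Exclusive Venn partition.** For each group *g*, let *R(g)* be the set of
   cytobands holding at least one of its filtered SNPs. Every band *r* is
   assigned to the cell *C(r) = {g : r ∈ R(g)}*, so cells are pairwise
   disjoint and cover every band. Shared regions are the union of cells with
   |C| ≥ k (default k = 4) that contain a required anchor group (default the
   diabetes group). Each shared region's SNPs form a **SNP-cluster**; the
   distinct reported genes across clusters (alias-merged, e.g. TCF2 → HNF1B)
   are the candidate gene list.
3. **Enrichment.** For a query of *n* SNPs in a universe of *N*, a term
   annotating *K* SNPs with *x* overlapping gets the upper-tail
   hypergeometric p-value P(X ≥ x) (binomial and Fisher's exact variants
   available), the finite-population z-score
   (x − nK/N)/√(nK/N·(N−K)/N·(N−n)/(N−1)), and Benjamini–Hochberg FDR.
4. **Semantic similarity.** Over an annotation DAG, IC(t) = −log₁₀(fraction
   of entities annotated at or below *t*); term pairs score
   2·IC(MICA)/(IC(t₁)+IC(t₂)) at the most informative common ancestor;
   entity pairs combine the cross-profile matrix by best-match average,
   maximum, or complete linkage. The partner-count summary counts, per SNP,
   the other SNPs scoring above a threshold (default > 0.5).
5. **Variant burden.** SNVs (1-bp REF/ALT, PASS filter) are counted per gene
   interval per sample VCF; the candidate threshold is the pooled median of
   counts after dropping counts ≤ 1, and candidates must reach it in *every*
   sample.
6. **Islet expression.** Per gene, nondiabetic (n = 63) vs T2D (n = 12)
   groups are compared on log₂(FPKM+1) by Student's t-test when both groups
   pass the D'Agostino–Pearson normality gate, otherwise Mann–Whitney;
   candidates are also ranked by mean nondiabetic expression against the
   β-cell marker KCNJ11.

All inputs needed to run the full pipeline are bundled or simulated by
`pleioband.synthdata`, so nothing is downloaded.

## Worked example

`examples/01_shared_regions.py` runs the intersection on the bundled
reference catalog (46 shared-region SNP associations plus one association per
region–phenotype membership and 10 decoy rows):

```
associations parsed: 418 (decoys land in 'unassigned')
regions shared by >=4 phenotypes incl. diabetes: ['11p11.2', '12q24.13', '15q26.1', '17q12', '1q32.3', '6q21', '7p15.2', '8p22']
     1q32.3: 4 SNPs
       6q21: 5 SNPs
     7p15.2: 6 SNPs
       8p22: 7 SNPs
    11p11.2: 8 SNPs
   12q24.13: 3 SNPs
    15q26.1: 8 SNPs
      17q12: 5 SNPs
total distinct SNPs: 46
distinct reported genes (TCF2 merged into HNF1B): 34
```

Eight cytobands are associated with at least four of the five phenotype
groups (always including diabetes); they contain 46 distinct SNPs whose
reported genes collapse to 34 symbols. The other examples
(`02_enrichment.py` … `05_expression.py`) exercise the downstream stages the
same way; `examples/04_variant_rank.py` recovers the pooled-median threshold
of 4 and the genes reaching it in both patients, and `05_expression.py`
detects the planted HSD17B12 down-shift in T2D islets while ranking ASAH1 and
HSD17B12 above the KCNJ11 marker.

A thin CLI wraps the same library calls
(`pleioband intersect|enrich|similarity|rank-variants|expression|simulate|run-all`).

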