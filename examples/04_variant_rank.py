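"""Rank genes by per-patient SNV burden with the median-threshold rule.

Simulates two patients' VCFs carrying the bundled per-gene SNV counts
(plus decoy indels, out-of-interval SNVs and filter-failing records that the
counter must ignore), recounts from the VCFs, derives the pooled-median
threshold, and selects genes reaching it in every patient.
"""

import tempfile

from pleioband import count_snps_per_gene, median_threshold, select_candidate_genes
from pleioband.synthdata import SimConfig, simulate_vcf

with tempfile.TemporaryDirectory() as tmp:
    vcfs, intervals, truth = simulate_vcf(SimConfig(seed=7), tmp)
    counts = count_snps_per_gene(vcfs, intervals)

print(counts.to_frame().to_string())
threshold = median_threshold(counts, exclusion_max=1)
print(f"\npooled median of counts > 1: {threshold}")
candidates = select_candidate_genes(counts, threshold)
print(f"genes with >= {threshold:g} SNVs in every patient: {candidates}")
# The threshold is the median SNV count after dropping genes with at most
# one SNV in a sample; candidates carry a high SNV rate in all patients.
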