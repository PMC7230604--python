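"""Per-gene SNV counting from VCFs and median-threshold candidate selection.

Counts single-nucleotide substitutions per gene interval per sample, then
nominates candidate genes carrying at least the pooled-median SNV count
(counts of one or less excluded from the median pool) in EVERY sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GeneInterval:
    """1-based, both-ends-inclusive gene interval."""

    gene: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene}: coordinates are 1-based, got start {self.start}")


@dataclass
class SampleVariantCounts:
    """Per-sample, per-gene SNV counts; every sample maps every gene."""

    counts: dict[str, dict[str, int]]

    @property
    def samples(self) -> list[str]:
        return list(self.counts)

    @property
    def genes(self) -> list[str]:
        first = next(iter(self.counts.values()), {})
        return list(first)

    def to_frame(self) -> pd.DataFrame:
        """Gene x sample count table."""
        return pd.DataFrame(self.counts).rename_axis("gene")


def _is_snv(ref: str, alts: Sequence[str] | None) -> bool:
    if alts is None or len(ref) != 1 or ref.upper() not in _BASES:
        return False
    return any(len(a) == 1 and a.upper() in _BASES for a in alts)


def count_snps_per_gene(
    vcf_paths: Mapping[str, str | Path],
    intervals: Sequence[GeneInterval],
    pass_only: bool = True,
    include_indels: bool = False,
) -> SampleVariantCounts:
    """Count passing variant sites per gene interval for each sample's VCF.

    Only single-nucleotide substitutions count by default (REF and at least
    one ALT of length 1, no symbolic alleles); ``include_indels=True`` also
    counts length-changing alleles. A multi-allelic record counts once.
    Records with FILTER other than PASS/"." are skipped when ``pass_only``.
    Interval ends are inclusive; genes may have several intervals (summed).
    """
    genes = sorted({iv.gene for iv in intervals})
    interval_chroms = {iv.chromosome for iv in intervals}
    counts: dict[str, dict[str, int]] = {}
    for sample, path in vcf_paths.items():
        per_gene = {g: 0 for g in genes}
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                chrom = rec.chrom
                if chrom not in interval_chroms:
                    stripped = chrom.removeprefix("chr")
                    prefixed = f"chr{chrom}"
                    if stripped in interval_chroms or prefixed in interval_chroms:
                        raise ValueError(
                            f"{path}: chromosome naming mismatch ({chrom!r} in VCF vs "
                            f"intervals); normalize the 'chr' prefix on one side"
                        )
                    continue
                if pass_only:
                    filters = list(rec.filter.keys())
                    if filters and filters != ["PASS"]:
                        continue
                if rec.ref is None:
                    continue
                alts = rec.alts
                if not include_indels and not _is_snv(rec.ref, alts):
                    continue
                if include_indels and alts is None:
                    continue
                pos = rec.pos  # 1-based
                for iv in intervals:
                    if iv.chromosome == chrom and iv.start <= pos <= iv.end:
                        per_gene[iv.gene] += 1
                        break
        counts[sample] = per_gene
    return SampleVariantCounts(counts)


def median_threshold(counts: SampleVariantCounts, exclusion_max: int = 1) -> float:
    """Pooled median of per-gene counts across samples, excluding low counts.

    Counts <= ``exclusion_max`` (default 1: genes with at most a single SNV
    in a sample) are dropped before taking the median; even-sized pools use
    midpoint interpolation.
    """
    pool = [
        c
        for per_gene in counts.counts.values()
        for c in per_gene.values()
        if c > exclusion_max
    ]
    if not pool:
        raise ValueError("no informative genes: every count is at or below the exclusion cap")
    return float(np.median(pool))


def select_candidate_genes(
    counts: SampleVariantCounts, threshold: float
) -> list[str]:
    """Genes reaching ``threshold`` SNVs in EVERY sample.

    Sorted by descending minimum count across samples, then symbol.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    per_sample = list(counts.counts.values())
    if not per_sample:
        return []
    genes = counts.genes
    min_counts = {
        g: min(sample_counts.get(g, 0) for sample_counts in per_sample) for g in genes
    }
    selected = [g for g in genes if min_counts[g] >= threshold]
    return sorted(selected, key=lambda g: (-min_counts[g], g))


def read_intervals(path: str | Path, bed: bool | None = None) -> list[GeneInterval]:
    """Read gene intervals from TSV (1-based inclusive) or BED (0-based
    half-open, converted to 1-based inclusive).

    TSV columns: gene, chromosome, start, end (header required).
    BED columns: chrom, start, end, gene (no header; set ``bed=True`` or use
    a ``.bed`` suffix).
    """
    path = Path(path)
    if bed is None:
        bed = path.suffix.lower() == ".bed"
    out = []
    if bed:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        for chrom, start, end, gene in df.iloc[:, :4].itertuples(index=False):
            out.append(GeneInterval(str(gene), str(chrom), int(start) + 1, int(end)))
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        for row in df.itertuples(index=False):
            out.append(
                GeneInterval(str(row.gene), str(row.chromosome), int(row.start), int(row.end))
            )
    return out


def write_counts(counts: SampleVariantCounts, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t")
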