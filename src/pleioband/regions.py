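"""Cytoband clustering, exclusive Venn partition and SNP-cluster extraction.

The unit of intersection is the cytoband label (string equality; sub-bands
are never merged with parent bands). Each region is assigned to the Venn
cell of exactly the phenotype groups whose region set contains it, so cells
are pairwise disjoint and cover every region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import CatalogAssociation, UNASSIGNED
from .refdata import DEFAULT_GENE_ALIASES, DIABETES

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}
_BAND_RE = re.compile(r"^(\d+|X|Y|MT|M)([pq].*)?$", re.IGNORECASE)


def band_sort_key(band: str) -> tuple[int, str]:
    """Sort key: chromosome number first, then the band string."""
    m = _BAND_RE.match(band.strip())
    if m:
        chrom = _CHROM_ORDER.get(m.group(1).upper(), 99)
    else:
        chrom = 99
    return (chrom, band)


@dataclass(frozen=True)
class RegionSet:
    """The set of cytobands holding >=1 filtered association of one group."""

    group_name: str
    regions: frozenset[str]

    def __post_init__(self) -> None:
        if any(not r for r in self.regions):
            raise ValueError(f"group {self.group_name!r}: empty region label")


@dataclass(frozen=True)
class VennPartition:
    """Exclusive partition of regions over phenotype combinations."""

    cells: dict[frozenset[str], frozenset[str]]

    @property
    def groups(self) -> frozenset[str]:
        out: set[str] = set()
        for combo in self.cells:
            out.update(combo)
        return frozenset(out)

    def cell(self, combo: Iterable[str]) -> frozenset[str]:
        return self.cells.get(frozenset(combo), frozenset())

    def all_regions(self) -> frozenset[str]:
        out: set[str] = set()
        for regions in self.cells.values():
            out.update(regions)
        return frozenset(out)


@dataclass(frozen=True)
class SnpCluster:
    """All catalog SNPs falling in one shared cytoband."""

    region: str
    snps: frozenset[str]
    mapped_genes: frozenset[str]
    reported_genes: frozenset[str]


def regions_per_phenotype(
    grouped: Mapping[str, Sequence[CatalogAssociation]]
) -> list[RegionSet]:
    """One RegionSet per phenotype group (the reserved unassigned key is ignored)."""
    out = []
    for group, assocs in grouped.items():
        if group == UNASSIGNED:
            continue
        out.append(RegionSet(group, frozenset(a.cytoband for a in assocs)))
    return out


def venn_partition(region_sets: Sequence[RegionSet]) -> VennPartition:
    """Assign every region to the cell of exactly the groups containing it."""
    if not region_sets:
        raise ValueError("at least one RegionSet required")
    names = [rs.group_name for rs in region_sets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate group names: {names}")
    cells: dict[frozenset[str], set[str]] = {}
    all_regions = set().union(*(rs.regions for rs in region_sets))
    for region in all_regions:
        combo = frozenset(rs.group_name for rs in region_sets if region in rs.regions)
        cells.setdefault(combo, set()).add(region)
    part = VennPartition({c: frozenset(r) for c, r in cells.items()})
    # conservation check: disjoint cells covering every input region
    assert sum(len(r) for r in part.cells.values()) == len(part.all_regions())
    assert part.all_regions() == frozenset(all_regions)
    return part


def select_shared_regions(
    partition: VennPartition,
    min_phenotypes: int = 4,
    required_group: str | None = DIABETES,
) -> frozenset[str]:
    """Union of cells shared by >= ``min_phenotypes`` groups.

    If ``required_group`` is given, only cells whose combination contains it
    contribute (the diabetes-anchored selection by default).
    """
    if min_phenotypes < 1:
        raise ValueError("min_phenotypes must be >= 1")
    if required_group is not None and required_group not in partition.groups:
        raise ValueError(
            f"required group {required_group!r} not among partition groups "
            f"{sorted(partition.groups)}"
        )
    selected: set[str] = set()
    for combo, regions in partition.cells.items():
        if len(combo) < min_phenotypes:
            continue
        if required_group is not None and required_group not in combo:
            continue
        selected.update(regions)
    return frozenset(selected)


def extract_snp_clusters(
    regions: Iterable[str], associations: Sequence[CatalogAssociation]
) -> list[SnpCluster]:
    """One cluster per selected region; SNPs deduplicated by rsID.

    Regions with no association in the input are omitted. Output is ordered
    by chromosome then band label.
    """
    by_region: dict[str, list[CatalogAssociation]] = {}
    wanted = set(regions)
    for a in associations:
        if a.cytoband in wanted:
            by_region.setdefault(a.cytoband, []).append(a)
    clusters = []
    for region in sorted(by_region, key=band_sort_key):
        assocs = by_region[region]
        clusters.append(
            SnpCluster(
                region=region,
                snps=frozenset(a.snp_id for a in assocs),
                mapped_genes=frozenset(g for a in assocs for g in a.mapped_genes),
                reported_genes=frozenset(g for a in assocs for g in a.reported_genes),
            )
        )
    return clusters


def collect_genes(
    clusters: Sequence[SnpCluster],
    alias_map: Mapping[str, str] | None = None,
) -> list[str]:
    """Distinct canonicalized reported-gene symbols across clusters.

    ``alias_map`` maps alias symbols to their canonical form; the default
    merges the legacy symbol TCF2 into HNF1B. Order is deterministic:
    clusters by region, symbols alphabetically, first occurrence kept.
    """
    if alias_map is None:
        alias_map = DEFAULT_GENE_ALIASES
    seen: list[str] = []
    for cluster in sorted(clusters, key=lambda c: band_sort_key(c.region)):
        for gene in sorted(cluster.reported_genes):
            canon = alias_map.get(gene, gene)
            if canon not in seen:
                seen.append(canon)
    return seen


def band_position_warnings(
    associations: Sequence[CatalogAssociation],
) -> list[str]:
    """rsIDs whose band label names a different chromosome than the position.

    The band column is trusted for clustering; disagreements are reported,
    not resolved. Only chromosome-level mismatches are detectable without an
    external cytoband coordinate track.
    """
    out = []
    for a in associations:
        m = _BAND_RE.match(a.cytoband)
        if m and a.chromosome and m.group(1).upper() != a.chromosome.upper():
            out.append(a.snp_id)
    return out


def write_shared_region_report(
    partition: VennPartition,
    clusters: Sequence[SnpCluster],
    path: str | Path,
) -> None:
    """Shared-region report: region, phenotype combination, SNP count."""
    combo_of = {r: c for c, rs in partition.cells.items() for r in rs}
    rows = [
        {
            "region": cl.region,
            "phenotypes": "|".join(sorted(combo_of.get(cl.region, frozenset()))),
            "n_snps": len(cl.snps),
        }
        for cl in clusters
    ]
    pd.DataFrame(rows, columns=["region", "phenotypes", "n_snps"]).to_csv(
        path, sep="\t", index=False
    )


def write_cluster_table(clusters: Sequence[SnpCluster], path: str | Path) -> None:
    rows = [
        {
            "region": cl.region,
            "snp_id": snp,
            "mapped_genes": ";".join(sorted(cl.mapped_genes)),
            "reported_genes": ";".join(sorted(cl.reported_genes)),
        }
        for cl in clusters
        for snp in sorted(cl.snps)
    ]
    pd.DataFrame(
        rows, columns=["region", "snp_id", "mapped_genes", "reported_genes"]
    ).to_csv(path, sep="\t", index=False)
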