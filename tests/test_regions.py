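"""Venn partitioning, shared-region selection and SNP-cluster extraction."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pleioband.catalog import CatalogAssociation
from pleioband.refdata import (
    DIABETES,
    DYSLIPIDEMIA,
    HYPERTENSION,
    OBESITY,
    REGION_CELLS,
    SLEEP_APNEA,
)
from pleioband.regions import (
    RegionSet,
    band_position_warnings,
    band_sort_key,
    collect_genes,
    extract_snp_clusters,
    regions_per_phenotype,
    select_shared_regions,
    venn_partition,
)


def assoc(snp, region, reported=(), mapped=(), chrom="1"):
    return CatalogAssociation(
        snp_id=snp, chromosome=chrom, position=1000, cytoband=region,
        mapped_genes=tuple(mapped), reported_genes=tuple(reported),
        trait="t", p_value=1e-8, source_row=0,
    )


def brute_force_partition(region_sets):
    """Exhaustive oracle: test every nonempty group combination per region."""
    groups = [rs.group_name for rs in region_sets]
    by_group = {rs.group_name: rs.regions for rs in region_sets}
    cells = {}
    all_regions = set().union(*(rs.regions for rs in region_sets))
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            members = {
                region for region in all_regions
                if all(region in by_group[g] for g in combo)
                and all(region not in by_group[g] for g in groups if g not in combo)
            }
            if members:
                cells[frozenset(combo)] = frozenset(members)
    return cells


def test_regions_per_phenotype_deduplicates_bands():
    grouped = {
        "diabetes": [assoc("rs1", "11p11.2"), assoc("rs2", "11p11.2")],
        "obesity": [assoc("rs3", "9q34.2")],
    }
    sets = {rs.group_name: rs.regions for rs in regions_per_phenotype(grouped)}
    assert sets["diabetes"] == {"11p11.2"}
    assert sets["obesity"] == {"9q34.2"}


def test_unassigned_key_is_excluded():
    grouped = {"g": [assoc("rs1", "1p1")], "unassigned": [assoc("rs2", "2p2")]}
    assert {rs.group_name for rs in regions_per_phenotype(grouped)} == {"g"}


def test_single_region_set_gives_one_cell():
    part = venn_partition([RegionSet("g", frozenset({"1p1", "2q2"}))])
    assert part.cells == {frozenset({"g"}): frozenset({"1p1", "2q2"})}


def test_duplicate_group_names_fatal():
    rs = RegionSet("g", frozenset({"1p1"}))
    with pytest.raises(ValueError, match="duplicate"):
        venn_partition([rs, rs])


@given(
    data=st.lists(
        st.frozensets(st.sampled_from([f"r{i}" for i in range(10)]), min_size=1),
        min_size=1, max_size=6,
    )
)
def test_partition_matches_exhaustive_combination_oracle(data):
    region_sets = [RegionSet(f"g{i}", regions) for i, regions in enumerate(data)]
    part = venn_partition(region_sets)
    assert part.cells == brute_force_partition(region_sets)
    # conservation: disjoint cells covering the input union
    union = set().union(*(rs.regions for rs in region_sets))
    assert part.all_regions() == union
    assert sum(len(c) for c in part.cells.values()) == len(union)


@given(
    data=st.lists(
        st.frozensets(st.sampled_from([f"r{i}" for i in range(8)]), min_size=1),
        min_size=1, max_size=5,
    )
)
def test_select_shared_regions_is_monotone(data):
    part = venn_partition([RegionSet(f"g{i}", r) for i, r in enumerate(data)])
    previous = None
    for k in range(1, 7):
        selected = select_shared_regions(part, k, required_group=None)
        if previous is not None:
            assert selected <= previous
        previous = selected


class TestReferencePartition:
    """Re-partitioning the published per-phenotype cytoband sets."""

    def test_cell_sizes(self, fixture_partition):
        part = fixture_partition
        assert len(part.cell({OBESITY, DYSLIPIDEMIA, HYPERTENSION, DIABETES})) == 4
        assert part.cell({OBESITY, DYSLIPIDEMIA, HYPERTENSION, DIABETES}) == {
            "8p22", "1q32.3", "12q24.13", "7p15.2"}
        assert len(part.cell({OBESITY, DYSLIPIDEMIA, SLEEP_APNEA, DIABETES})) == 3
        assert len(part.cell({OBESITY, HYPERTENSION, SLEEP_APNEA, DIABETES})) == 1
        assert len(part.cell({OBESITY, DYSLIPIDEMIA, DIABETES})) == 34
        assert len(part.cell({DYSLIPIDEMIA, HYPERTENSION, DIABETES})) == 5
        assert len(part.cell({OBESITY, HYPERTENSION, DIABETES})) == 2
        assert len(part.cell({OBESITY, SLEEP_APNEA, DIABETES})) == 3
        assert len(part.cell({DYSLIPIDEMIA, DIABETES})) == 17
        assert len(part.cell({OBESITY, DIABETES})) == 47
        assert len(part.cell({HYPERTENSION, DIABETES})) == 6
        assert len(part.cell({SLEEP_APNEA, DIABETES})) == 1

    def test_duplicated_bands_fold_into_their_larger_cell(self, fixture_partition):
        # 11p15.4 and 11p15.5 are printed both in a multi-phenotype cell and
        # in the diabetes-only list; an exclusive partition keeps each band
        # once, in the cell of its full membership, so the diabetes-only
        # cell holds 87 bands (89 printed entries minus the two duplicates).
        part = fixture_partition
        assert "11p15.4" in part.cell({OBESITY, DYSLIPIDEMIA, DIABETES})
        assert "11p15.5" in part.cell({OBESITY, DIABETES})
        assert len(part.cell({DIABETES})) == 87

    def test_shared_region_selection(self, fixture_partition):
        shared = select_shared_regions(fixture_partition, 4, DIABETES)
        assert shared == {"8p22", "1q32.3", "12q24.13", "7p15.2",
                          "11p11.2", "6q21", "17q12", "15q26.1"}
        assert select_shared_regions(fixture_partition, 5, DIABETES) == frozenset()
        assert select_shared_regions(fixture_partition, 1, None) == \
            fixture_partition.all_regions()

    def test_unknown_required_group_fatal(self, fixture_partition):
        with pytest.raises(ValueError, match="nosuch"):
            select_shared_regions(fixture_partition, 4, "nosuch")


class TestSnpClusters:
    def test_dedup_and_conservation(self):
        assocs = [
            assoc("rs1", "1p1"), assoc("rs1", "1p1"),  # same SNP, two traits
            assoc("rs2", "1p1"), assoc("rs3", "2q2"), assoc("rs4", "3q3"),
        ]
        clusters = extract_snp_clusters({"1p1", "2q2", "9q9"}, assocs)
        by_region = {c.region: c for c in clusters}
        assert set(by_region) == {"1p1", "2q2"}  # absent region omitted
        assert by_region["1p1"].snps == {"rs1", "rs2"}
        # every filtered association in a selected region lands in exactly one cluster
        selected = [a for a in assocs if a.cytoband in {"1p1", "2q2", "9q9"}]
        assert {a.snp_id for a in selected} == {s for c in clusters for s in c.snps}

    def test_fixture_cluster_sizes(self, fixture_grouped):
        all_filtered = [a for assocs in fixture_grouped.values() for a in assocs]
        clusters = extract_snp_clusters(
            {"8p22", "1q32.3", "12q24.13", "7p15.2", "11p11.2", "6q21", "17q12", "15q26.1"},
            all_filtered,
        )
        total = {s for c in clusters for s in c.snps}
        assert len(total) == 46
        sizes = {c.region: len(c.snps) for c in clusters}
        assert sizes["15q26.1"] == 8


class TestCollectGenes:
    def test_alias_merge_yields_34_vs_35(self, fixture_grouped):
        all_filtered = [a for assocs in fixture_grouped.values() for a in assocs]
        part_regions = {"8p22", "1q32.3", "12q24.13", "7p15.2",
                        "11p11.2", "6q21", "17q12", "15q26.1"}
        clusters = extract_snp_clusters(part_regions, all_filtered)
        assert len(collect_genes(clusters, {"TCF2": "HNF1B"})) == 34
        assert len(collect_genes(clusters, {})) == 35
        assert len(collect_genes(clusters)) == 34  # default alias map

    def test_multi_gene_cell_contributes_each_symbol(self):
        clusters = extract_snp_clusters(
            {"15q26.1"}, [assoc("rs2521501", "15q26.1", reported=("FURIN", "FES"))])
        genes = collect_genes(clusters, {})
        assert genes == ["FES", "FURIN"]

    def test_order_deterministic_by_region_then_symbol(self):
        assocs = [
            assoc("rs1", "2q1", reported=("ZZZ", "AAA"), chrom="2"),
            assoc("rs2", "1p1", reported=("MMM",)),
        ]
        clusters = extract_snp_clusters({"1p1", "2q1"}, assocs)
        assert collect_genes(clusters, {}) == ["MMM", "AAA", "ZZZ"]


def test_band_sort_key_orders_chromosomes_numerically():
    bands = ["11p11.2", "2q37.3", "X q28".replace(" ", ""), "1p36.1"]
    assert sorted(bands, key=band_sort_key) == ["1p36.1", "2q37.3", "11p11.2", "Xq28"]


def test_band_position_chromosome_mismatch_warning():
    ok = assoc("rs1", "6q21", chrom="6")
    bad = assoc("rs2", "6q21", chrom="7")
    assert band_position_warnings([ok, bad]) == ["rs2"]
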