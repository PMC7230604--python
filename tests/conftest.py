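import hypothesis
import pytest

from pleioband.catalog import assign_phenotype_groups, filter_significant, parse_catalog
from pleioband.regions import regions_per_phenotype, venn_partition
from pleioband.synthdata import fixture_catalog, fixture_queries, write_catalog

hypothesis.settings.register_profile(
    "stable", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("stable")


@pytest.fixture(scope="session")
def fixture_catalog_path(tmp_path_factory):
    """The bundled reference catalog (with decoys) written to disk."""
    path = tmp_path_factory.mktemp("catalog") / "catalog.tsv"
    write_catalog(fixture_catalog(n_decoys=9, seed=0), path, seed=0)
    return path


@pytest.fixture(scope="session")
def fixture_grouped(fixture_catalog_path):
    """Parsed, phenotype-assigned, significance-filtered fixture associations."""
    parsed = parse_catalog(fixture_catalog_path)
    grouped = assign_phenotype_groups(parsed.associations, fixture_queries())
    return {
        group: filter_significant(assocs).associations
        for group, assocs in grouped.items()
        if group != "unassigned"
    }


@pytest.fixture(scope="session")
def fixture_partition(fixture_grouped):
    return venn_partition(regions_per_phenotype(fixture_grouped))
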