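import pytest

from methyloscan import pipeline, simulate
from methyloscan.catalog import default_catalog, load_chem_table


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def chem_table():
    return load_chem_table()


@pytest.fixture(scope="session")
def community():
    """The standard 30-MAG labeled community (seed 1)."""
    design = simulate.default_community_design(seed=1)
    return simulate.build_community(design)


@pytest.fixture(scope="session")
def genotype_result(community, catalog):
    """Screen -> assign -> classify over the standard community.

    Session-scoped: the alignment screen is the slow step and every
    round-trip check can share its output.
    """
    return pipeline.run_genotype_pipeline(
        community.proteomes,
        community.annotations,
        community.taxonomy,
        community.gff_text,
        community.cds,
        catalog=catalog,
    )
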