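import pytest

from compoundmap import (
    FixtureSpec,
    demo_fixture_dir,
    generate_fixture,
    load_compound_db,
    parse_disease_map,
    run_build,
)


@pytest.fixture(scope="session")
def demo_dir():
    return demo_fixture_dir()


@pytest.fixture(scope="session")
def demo_collection(demo_dir):
    return load_compound_db(demo_dir / "compounds.csv")


@pytest.fixture(scope="session")
def demo_entities(demo_dir):
    return parse_disease_map(demo_dir / "map.xml")


@pytest.fixture(scope="session")
def demo_build(demo_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("demo_index")
    link, summary = run_build(
        demo_dir / "compounds.csv",
        demo_dir / "map.xml",
        ctd_paths=[demo_dir / "ctd.tsv"],
        chembl_paths=[demo_dir / "chembl.tsv"],
        out_dir=out,
        timestamp="2024-01-01T00:00:00Z",
    )
    return link, summary, out


@pytest.fixture()
def small_fixture(tmp_path):
    spec = FixtureSpec(
        n_compounds=12,
        n_genes=8,
        interaction_density=0.5,
        offmap_gene_fraction=0.25,
        duplicate_source_fraction=0.3,
        seed=42,
    )
    return generate_fixture(spec, tmp_path / "fx"), spec
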