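import pytest

from keggdraft.fixtures import (
    TABLE1_ORGANISMS,
    TABLE1_REACTIONS,
    FixtureSpec,
    generate_fixture,
    table1_fixture,
)
from keggdraft.kegg_io import (
    CompoundRecord,
    KeggSource,
    ReactionRecord,
    fetch_ec_reaction_links,
    fetch_gene_ec_links,
)
from keggdraft.linkage import build_or_matrix


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default synthetic local source (seed 7) plus its ground-truth manifest."""
    out = tmp_path_factory.mktemp("minikegg")
    manifest = generate_fixture(FixtureSpec(seed=7), out)
    return out, manifest


@pytest.fixture
def local_source(fixture_dir):
    out, _ = fixture_dir
    return KeggSource(mode="local", root=out)


@pytest.fixture(scope="session")
def table1_matrices(tmp_path_factory):
    """OR/ORG matrices rebuilt from the published five-strain gene lists."""
    out = tmp_path_factory.mktemp("table1")
    table1_fixture(out)
    src = KeggSource(mode="local", root=out)
    gene_ec = {org: fetch_gene_ec_links(src, org) for org in TABLE1_ORGANISMS}
    ecs = {f"9.8.7.{i + 1}" for i in range(len(TABLE1_REACTIONS))}
    ec_rxn = fetch_ec_reaction_links(src, ecs)
    return build_or_matrix(gene_ec, ec_rxn)


def glycan_showcase_records():
    """Reaction/compound records encoding the published glycan worked examples.

    A glycan hydrolysis whose two glycans cross-reference ordinary compound
    IDs (so an all-compound twin reaction exists), and one whose glycans
    have no compound equivalents at all.
    """
    water = CompoundRecord(id="C00001", name="H2O", formula="H2O", exact_mass=18.0106, mol_weight=18.0153)
    acetate = CompoundRecord(id="C00124", name="D-Galactose", formula="C6H12O6", exact_mass=180.0634, mol_weight=180.1559)
    c06136 = CompoundRecord(id="C06136", name="generic glycolipid", formula="C45H79N2O23R")
    c06135 = CompoundRecord(id="C06135", name="glycolipid product", formula="C39H69N2O18R")
    g00124 = CompoundRecord(id="G00124", mass=1040.0, same_as="C06136")
    g00123 = CompoundRecord(id="G00123", mass=878.0, same_as="C06135")
    g01977 = CompoundRecord(id="G01977", mass=2000.0)
    g13073 = CompoundRecord(id="G13073", mass=1838.0)
    compounds = {
        c.id: c
        for c in [water, acetate, c06136, c06135, g00124, g00123, g01977, g13073]
    }
    r05994 = ReactionRecord(
        id="R05994",
        equation_text="G00124 + C00001 <=> G00123 + C00124",
        substrates={"G00124": 1.0, "C00001": 1.0},
        products={"G00123": 1.0, "C00124": 1.0},
    )
    r05112 = ReactionRecord(
        id="R05112",
        equation_text="C06136 + C00001 <=> C06135 + C00124",
        substrates={"C06136": 1.0, "C00001": 1.0},
        products={"C06135": 1.0, "C00124": 1.0},
    )
    r07807 = ReactionRecord(
        id="R07807",
        equation_text="G01977 + C00001 <=> G13073 + C00124",
        substrates={"G01977": 1.0, "C00001": 1.0},
        products={"G13073": 1.0, "C00124": 1.0},
    )
    return {"R05994": r05994, "R05112": r05112, "R07807": r07807}, compounds


@pytest.fixture
def glycan_showcase():
    return glycan_showcase_records()
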