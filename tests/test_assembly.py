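"""Model assembly: consolidated/single/community builds, GPRs, serialization."""

import numpy as np
import pytest

from keggdraft.assembly import (
    DraftModel,
    build_community,
    build_consolidated,
    build_single,
    split_community,
)
from keggdraft.filtering import apply_filters
from keggdraft.fixtures import TABLE1_ORGANISMS
from keggdraft.kegg_io import CompoundRecord, KeggSource, ReactionRecord, fetch_records
from keggdraft.linkage import reaction_universe
from keggdraft import ids


def _table1_records(matrices):
    """Trivial clean equations for the five-strain reaction universe."""
    records = {}
    compounds = {}
    for i, rxn in enumerate(reaction_universe(matrices)):
        a, b = f"C9{2 * i:04d}", f"C9{2 * i + 1:04d}"
        for cid in (a, b):
            compounds[cid] = CompoundRecord(id=cid, exact_mass=100.0 + i)
        records[rxn] = ReactionRecord(
            id=rxn,
            equation_text=f"{a} <=> {b}",
            substrates={a: 1.0},
            products={b: 1.0},
        )
    return records, compounds


@pytest.fixture
def table1_models(table1_matrices):
    records, compounds = _table1_records(table1_matrices)
    report = apply_filters(records.values(), compounds)
    consolidated = build_consolidated(report, records, table1_matrices, compounds)
    return consolidated, report, records, compounds


@pytest.fixture
def fixture_models(fixture_dir):
    out, manifest = fixture_dir
    src = KeggSource(mode="local", root=out)
    from keggdraft.kegg_io import fetch_ec_reaction_links, fetch_gene_ec_links
    from keggdraft.linkage import build_or_matrix

    gene_ec = {o: fetch_gene_ec_links(src, o) for o in manifest["organisms"]}
    ecs = {ec for t in gene_ec.values() for _, ec in t.pairs}
    ec_rxn = fetch_ec_reaction_links(src, ecs)
    matrices = build_or_matrix(gene_ec, ec_rxn)
    records = {
        r.id: r for r in fetch_records(src, reaction_universe(matrices)).records
    }
    cids = sorted({p for r in records.values() for p in r.participants})
    compounds = {c.id: c for c in fetch_records(src, cids).records}
    report = apply_filters(records.values(), compounds)
    consolidated = build_consolidated(report, records, matrices, compounds)
    singles = {
        org: build_single(consolidated, matrices, org)
        for org in matrices.organisms
    }
    return consolidated, singles, matrices, report


class TestConsolidated:
    def test_shared_reaction_appears_once_with_union_gpr(self, table1_models, table1_matrices):
        consolidated, *_ = table1_models
        rxn = consolidated.reactions["R00013"]
        assert sorted(ids.gene_organism(g) for g in rxn.genes) == sorted(TABLE1_ORGANISMS)

    def test_published_gene_union_count(self, table1_models):
        """Per-strain gene counts (6,6,4,6,6) OR-join to 28 genes."""
        consolidated, *_ = table1_models
        rxn = consolidated.reactions["R00014"]
        assert len(rxn.genes) == 28
        assert " or " in rxn.gpr

    def test_metabolites_in_cytosol_with_annotations(self, table1_models):
        consolidated, *_ = table1_models
        assert consolidated.compartments == {"c": "cytosol"}
        for met in consolidated.metabolites.values():
            assert met.compartment == "c"
            assert met.annotations["kegg_id"] == met.kegg_id
        for rxn in consolidated.reactions.values():
            assert rxn.annotations["kegg_id"] == rxn.kegg_id
            assert rxn.reversible
            assert rxn.bounds[0] == -rxn.bounds[1] < 0

    def test_equals_union_of_singles(self, fixture_models):
        consolidated, singles, *_ = fixture_models
        union = set().union(*(set(s.reactions) for s in singles.values()))
        assert set(consolidated.reactions) == union

    def test_stoichiometry_signs(self, fixture_models):
        consolidated, *_ = fixture_models
        for rxn in consolidated.reactions.values():
            coeffs = list(rxn.stoichiometry.values())
            assert any(c < 0 for c in coeffs) and any(c > 0 for c in coeffs)

    def test_missing_compound_is_hard_error(self, table1_matrices):
        records = {
            "R00013": ReactionRecord(
                id="R00013", substrates={"C90000": 1.0}, products={"C90001": 1.0}
            )
        }
        compounds = {
            "C90000": CompoundRecord(id="C90000", exact_mass=1.0),
            "C90001": CompoundRecord(id="C90001", exact_mass=1.0),
        }
        report = apply_filters(records.values(), compounds)
        del compounds["C90001"]
        # filtering would normally have omitted it; force the inconsistency
        report.verdicts[0].substrates = {"C90000": 1.0}
        report.verdicts[0].products = {"C99999": 1.0}
        with pytest.raises(KeyError, match="C99999"):
            build_consolidated(report, records, table1_matrices, compounds)


class TestSingle:
    def test_restriction_oracle(self, fixture_models):
        consolidated, singles, matrices, _ = fixture_models
        for org, single in singles.items():
            oi = matrices.organism_index[org]
            for rxn_id, rxn in consolidated.reactions.items():
                expected = any(
                    src in matrices.reaction_index
                    and matrices.or_matrix[oi, matrices.reaction_index[src]]
                    for src in rxn.annotations["source_reactions"]
                )
                assert (rxn_id in single.reactions) == expected

    def test_gprs_restricted_to_organism(self, fixture_models):
        _, singles, matrices, _ = fixture_models
        for org, single in singles.items():
            for rxn in single.reactions.values():
                for gene in rxn.genes:
                    assert ids.gene_organism(gene) == org

    def test_no_orphan_metabolites(self, fixture_models):
        _, singles, *_ = fixture_models
        for single in singles.values():
            used = set().union(*(r.stoichiometry for r in single.reactions.values()))
            assert set(single.metabolites) == used

    def test_unknown_organism(self, fixture_models):
        consolidated, _, matrices, _ = fixture_models
        with pytest.raises(KeyError, match="zzz"):
            build_single(consolidated, matrices, "zzz")


class TestCommunity:
    def test_disjoint_union_counts(self, fixture_models):
        _, singles, *_ = fixture_models
        community = build_community(list(singles.values()))
        assert len(community.reactions) == sum(len(s.reactions) for s in singles.values())
        assert len(community.metabolites) == sum(
            len(s.metabolites) for s in singles.values()
        )
        assert set(community.compartments) == set(singles)

    def test_no_edges_between_compartments(self, fixture_models):
        _, singles, *_ = fixture_models
        community = build_community(list(singles.values()))
        for rxn in community.reactions.values():
            orgs = {
                community.metabolites[mid].compartment for mid in rxn.stoichiometry
            }
            assert len(orgs) == 1

    def test_suffix_round_trip(self, fixture_models):
        _, singles, *_ = fixture_models
        community = build_community(list(singles.values()))
        recovered = split_community(community)
        for org, single in singles.items():
            assert set(recovered[org].reactions) == set(single.reactions)
            assert set(recovered[org].metabolites) == set(single.metabolites)
            for rid, rxn in single.reactions.items():
                assert recovered[org].reactions[rid].stoichiometry == rxn.stoichiometry
                assert recovered[org].reactions[rid].gpr == rxn.gpr

    def test_duplicate_organisms_rejected(self, fixture_models):
        _, singles, *_ = fixture_models
        one = next(iter(singles.values()))
        with pytest.raises(ValueError, match="duplicate"):
            build_community([one, one])


class TestGprSoundness:
    def test_every_gpr_gene_in_org_matrix(self, fixture_models):
        consolidated, _, matrices, _ = fixture_models
        for rxn in consolidated.reactions.values():
            allowed = set()
            for src in rxn.annotations["source_reactions"]:
                for org in matrices.organisms:
                    allowed.update(matrices.genes(org, src))
            assert set(rxn.genes) <= allowed


class TestSerialization:
    def test_json_round_trip_lossless(self, fixture_models, tmp_path):
        consolidated, singles, *_ = fixture_models
        for model in [consolidated, *singles.values()]:
            path = tmp_path / f"{model.model_id}.json"
            model.to_json(path)
            again = DraftModel.from_json(path)
            assert again == model

    def test_s_matrix_matches_stoichiometry(self, fixture_models):
        consolidated, *_ = fixture_models
        s_matrix, met_ids, rxn_ids = consolidated.stoichiometric_matrix()
        met_index = {m: i for i, m in enumerate(met_ids)}
        for j, rid in enumerate(rxn_ids):
            col = s_matrix.getcol(j).toarray().ravel()
            expected = np.zeros(len(met_ids))
            for met, coeff in consolidated.reactions[rid].stoichiometry.items():
                expected[met_index[met]] = coeff
            assert np.array_equal(col, expected)

    def test_sbml_write_read(self, fixture_models, tmp_path):
        import cobra
        from cobra.io.sbml import validate_sbml_model

        consolidated, *_ = fixture_models
        path = tmp_path / "consolidated.xml"
        consolidated.write_sbml(path)
        _, errors = validate_sbml_model(str(path))
        assert errors["SBML_FATAL"] == []
        assert errors["SBML_ERROR"] == []
        assert errors["SBML_SCHEMA_ERROR"] == []
        model = cobra.io.read_sbml_model(str(path))
        assert len(model.reactions) == len(consolidated.reactions)
        assert len(model.metabolites) == len(consolidated.metabolites)
        for rxn in model.reactions:
            assert rxn.lower_bound == -1000 and rxn.upper_bound == 1000
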