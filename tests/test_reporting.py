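"""Network statistics against brute-force oracles, and the omission accounting."""

from collections import deque

import numpy as np
import pytest

from keggdraft.assembly import DraftModel, Metabolite, Reaction
from keggdraft.reporting import (
    blocked_and_same_sign,
    connected_components,
    disconnected_reactions,
    gene_histograms,
    mean_degree,
    mean_shortest_path,
    network_stats,
    omission_accounting,
)


def model_from_stoich(stoich: dict[str, dict[str, float]]) -> DraftModel:
    """Build a bare model from {reaction: {metabolite: coefficient}}."""
    model = DraftModel(model_id="toy", kind="consolidated", compartments={"c": "cytosol"})
    mets = sorted({m for s in stoich.values() for m in s})
    for met in mets:
        model.metabolites[met] = Metabolite(model_id=met, kegg_id=met)
    for rid, s in sorted(stoich.items()):
        model.reactions[rid] = Reaction(model_id=rid, kegg_id=rid, stoichiometry=dict(s))
    return model


def random_model(rng, n_mets=10, n_rxns=8, density=0.25) -> DraftModel:
    stoich = {}
    for j in range(n_rxns):
        col = {}
        for i in range(n_mets):
            if rng.random() < density:
                col[f"m{i}"] = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
        if not col:  # keep every reaction attached to the graph
            col[f"m{int(rng.integers(n_mets))}"] = -1.0
        stoich[f"r{j}"] = col
    return model_from_stoich(stoich)


def bfs_components(model) -> list[set[str]]:
    """Independent breadth-first-search component oracle."""
    adj: dict[str, set[str]] = {n: set() for n in (*model.metabolites, *model.reactions)}
    for rid, rxn in model.reactions.items():
        for met, coeff in rxn.stoichiometry.items():
            if coeff != 0:
                adj[rid].add(met)
                adj[met].add(rid)
    seen: set[str] = set()
    comps = []
    for node in adj:
        if node in seen:
            continue
        comp = {node}
        queue = deque([node])
        while queue:
            cur = queue.popleft()
            for nxt in adj[cur] - comp:
                comp.add(nxt)
                queue.append(nxt)
        seen |= comp
        comps.append(comp)
    return comps


def bfs_all_pairs_mean(model) -> float:
    adj: dict[str, set[str]] = {n: set() for n in (*model.metabolites, *model.reactions)}
    for rid, rxn in model.reactions.items():
        for met, coeff in rxn.stoichiometry.items():
            if coeff != 0:
                adj[rid].add(met)
                adj[met].add(rid)
    total, n_pairs = 0, 0
    nodes = sorted(adj)
    for source in nodes:
        dist = {source: 0}
        queue = deque([source])
        while queue:
            cur = queue.popleft()
            for nxt in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + 1
                    queue.append(nxt)
        for target, d in dist.items():
            if source < target:
                total += d
                n_pairs += 1
    return total / n_pairs if n_pairs else 0.0


class TestComponents:
    def test_two_disjoint_chains(self):
        model = model_from_stoich(
            {
                "r1": {"a": -1, "b": 1},
                "r2": {"b": -1, "c": 1},
                "r3": {"x": -1, "y": 1},
                "r4": {"y": -1, "z": 1},
            }
        )
        comps = connected_components(model)
        assert len(comps) == 2
        assert all(sum(1 for n in c if n.startswith("r")) == 2 for c in comps)

    def test_star_is_one_component(self):
        model = model_from_stoich(
            {f"r{i}": {"hub": -1, f"leaf{i}": 1} for i in range(5)}
        )
        stats = network_stats(model)
        assert len(stats.component_sizes) == 1
        assert stats.giant_reaction_fraction == 100.0

    @pytest.mark.parametrize("seed", range(8))
    def test_agreement_with_bfs_oracle(self, seed):
        model = random_model(np.random.default_rng(seed))
        ours = {frozenset(c) for c in connected_components(model)}
        oracle = {frozenset(c) for c in bfs_components(model)}
        assert ours == oracle

    def test_disconnected_reactions_outside_giant(self):
        model = model_from_stoich(
            {
                "r1": {"a": -1, "b": 1},
                "r2": {"b": -1, "c": 1},
                "r3": {"x": -1, "y": 1},
            }
        )
        assert disconnected_reactions(model) == ["r3"]

    def test_empty_model(self):
        model = DraftModel(model_id="e", kind="consolidated")
        assert connected_components(model) == []


class TestDegreeAndPaths:
    def test_single_reaction_mean_degree(self):
        model = model_from_stoich({"r1": {"a": -1, "b": 1}})
        assert mean_degree(model) == pytest.approx(4 / 3)

    def test_coefficient_two_is_one_edge(self):
        model = model_from_stoich({"r1": {"a": -2, "b": 2}})
        assert mean_degree(model) == pytest.approx(4 / 3)

    @pytest.mark.parametrize("seed", range(8))
    def test_mean_degree_equals_per_node_average(self, seed):
        model = random_model(np.random.default_rng(100 + seed))
        degrees = {n: 0 for n in (*model.metabolites, *model.reactions)}
        for rid, rxn in model.reactions.items():
            for met, coeff in rxn.stoichiometry.items():
                if coeff != 0:
                    degrees[rid] += 1
                    degrees[met] += 1
        assert mean_degree(model) == pytest.approx(np.mean(list(degrees.values())))

    def test_path_graph(self):
        model = model_from_stoich({"r1": {"m1": -1, "m2": 1}})
        # pairs: (m1,r1)=1, (r1,m2)=1, (m1,m2)=2 -> mean 4/3
        assert mean_shortest_path(model) == pytest.approx(4 / 3)

    def test_two_isolated_dyads(self):
        model = model_from_stoich({"r1": {"a": -1}, "r2": {"b": -1}})
        assert mean_shortest_path(model) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_against_all_pairs_bfs(self, seed):
        model = random_model(np.random.default_rng(200 + seed), n_mets=12, n_rxns=10)
        assert mean_shortest_path(model) == pytest.approx(bfs_all_pairs_mean(model))


class TestBlockedAndSameSign:
    def test_trivial_cases(self):
        model = model_from_stoich(
            {
                "r1": {"only_r1": -1, "shared_neg": -1, "balanced": 1},
                "r2": {"shared_neg": -2, "balanced": -1, "sink": 1},
            }
        )
        blocked, same_sign = blocked_and_same_sign(model)
        # only_r1 and sink occur once; shared_neg is consumed twice;
        # balanced is produced once and consumed once
        assert blocked == 2
        assert same_sign == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_oracle(self, seed):
        model = random_model(np.random.default_rng(300 + seed))
        occurrence: dict[str, list[float]] = {m: [] for m in model.metabolites}
        for rxn in model.reactions.values():
            for met, coeff in rxn.stoichiometry.items():
                if coeff != 0:
                    occurrence[met].append(coeff)
        expected_blocked = sum(1 for v in occurrence.values() if len(v) == 1)
        expected_same = sum(
            1
            for v in occurrence.values()
            if len(v) == 2 and np.sign(v[0]) == np.sign(v[1])
        )
        assert blocked_and_same_sign(model) == (expected_blocked, expected_same)

    def test_removing_reaction_bound_on_blocked(self):
        rng = np.random.default_rng(9)
        model = random_model(rng)
        blocked_before, _ = blocked_and_same_sign(model)
        victim = next(iter(model.reactions))
        participants = len(model.reactions[victim].stoichiometry)
        del model.reactions[victim]
        blocked_after, _ = blocked_and_same_sign(model)
        assert blocked_before - blocked_after <= participants


class TestGeneHistograms:
    def test_five_strain_fragment(self, table1_matrices):
        """One strain's seven gene-bearing rows give counts {1,5,1,2,2,1,6}."""
        hists = gene_histograms(table1_matrices)
        eco = hists["eco"]
        assert eco["n_reactions"] == 7
        assert eco["genes_per_reaction"] == {1: 3, 2: 2, 5: 1, 6: 1}
        assert sum(eco["genes_per_reaction"].values()) == eco["n_reactions"]

    def test_empty_organism(self, table1_matrices):
        from keggdraft.kegg_io import LinkTable
        from keggdraft.linkage import build_or_matrix

        gene_ec = {"emp": LinkTable(pairs=(), kind="gene-ec")}
        ec_rxn = LinkTable(pairs=(("9.9.9.1", "R90001"),), kind="ec-reaction")
        with pytest.warns(UserWarning):
            m = build_or_matrix(gene_ec, ec_rxn)
        assert gene_histograms(m)["emp"] == {
            "n_reactions": 0,
            "n_genes": 0,
            "genes_per_reaction": {},
        }


class TestOmissionAccounting:
    def test_reaction_filter_percentage(self):
        acct = omission_accounting(1745, 141, 1626, 390, 378)
        assert acct["filter_percent"] == 8.08
        assert acct["remaining_after_reaction_filters"] == 1604
        assert acct["generic_compound_percent"] == 23.98
        assert acct["total_omitted"] == 519
        assert acct["omitted_percent"] == 29.74
        assert acct["total_kept"] == 1226

    def test_zero_omissions(self):
        acct = omission_accounting(50, 0, 40, 0, 0)
        assert acct["filter_percent"] == 0.0
        assert acct["generic_compound_percent"] == 0.0
        assert acct["omitted_percent"] == 0.0
        assert acct["total_kept"] == 50
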