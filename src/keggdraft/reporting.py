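"""Network statistics and run reports.

All graph metrics are computed on the bipartite metabolite-reaction graph:
one node per metabolite, one per reaction, an edge wherever the S-matrix has
a nonzero entry. This is the natural graph of a stoichiometric model before
any projection, and the one the incidence-matrix framing of the pipeline
describes.

Two curation-oriented metabolite counts summarize potential dead ends once
transport reactions are absent: a *blocked* metabolite occurs in exactly one
reaction; a *same-sign* metabolite occurs in exactly two reactions with
equal-signed stoichiometric entries (it is only ever produced, or only ever
consumed, so it cannot balance at steady state).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .assembly import DraftModel
from .filtering import OmissionReport, round2
from .linkage import OrgMatrices


@dataclass
class NetworkStats:
    n_reactions: int
    n_metabolites: int
    component_sizes: list[tuple[int, int]]  # (metabolites, reactions), descending
    giant_reaction_count: int
    giant_reaction_fraction: float  # percent
    mean_degree: float
    mean_shortest_path: float
    blocked_metabolites: int
    same_sign_metabolites: int


def bipartite_graph(model: DraftModel) -> nx.Graph:
    """Metabolite-reaction graph: edge wherever S has a nonzero entry."""
    graph = nx.Graph()
    graph.add_nodes_from(model.metabolites, bipartite=0)
    graph.add_nodes_from(model.reactions, bipartite=1)
    for rxn_id, rxn in model.reactions.items():
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff != 0:
                graph.add_edge(met_id, rxn_id)
    return graph


def connected_components(model: DraftModel) -> list[set[str]]:
    """Components of the bipartite graph, giant first.

    Ordering: most reactions, then most metabolites, then lexicographically
    smallest member (deterministic tie-break).
    """
    if not model.reactions and not model.metabolites:
        return []
    graph = bipartite_graph(model)
    comps = list(nx.connected_components(graph))

    def key(comp: set[str]):
        n_rxn = sum(1 for n in comp if n in model.reactions)
        n_met = len(comp) - n_rxn
        return (-n_rxn, -n_met, min(comp))

    return sorted(comps, key=key)


def mean_degree(model: DraftModel) -> float:
    """2|E| / (n_metabolites + n_reactions) over the bipartite graph.

    |E| counts nonzero S entries; coefficient magnitude is irrelevant.
    """
    graph = bipartite_graph(model)
    n = graph.number_of_nodes()
    return 2 * graph.number_of_edges() / n if n else 0.0


def mean_shortest_path(model: DraftModel) -> float:
    """Average geodesic length over unordered same-component node pairs.

    Cross-component pairs (infinite distance) are excluded from the average,
    so the statistic is defined for disconnected draft networks too.
    """
    graph = bipartite_graph(model)
    total = 0
    n_pairs = 0
    for source, lengths in nx.all_pairs_shortest_path_length(graph):
        for target, dist in lengths.items():
            if source < target:
                total += dist
                n_pairs += 1
    return total / n_pairs if n_pairs else 0.0


def blocked_and_same_sign(model: DraftModel) -> tuple[int, int]:
    """(blocked, same-sign) metabolite counts from the S-matrix."""
    s_matrix, met_ids, _ = model.stoichiometric_matrix()
    blocked = 0
    same_sign = 0
    for i in range(len(met_ids)):
        row = s_matrix.getrow(i)
        entries = row.data[row.data != 0]
        if len(entries) == 1:
            blocked += 1
        elif len(entries) == 2 and np.sign(entries[0]) == np.sign(entries[1]):
            same_sign += 1
    return blocked, same_sign


def network_stats(model: DraftModel) -> NetworkStats:
    comps = connected_components(model)
    sizes = []
    for comp in comps:
        n_rxn = sum(1 for n in comp if n in model.reactions)
        sizes.append((len(comp) - n_rxn, n_rxn))
    giant_rxn = sizes[0][1] if sizes else 0
    n_rxn = len(model.reactions)
    blocked, same_sign = blocked_and_same_sign(model)
    return NetworkStats(
        n_reactions=n_rxn,
        n_metabolites=len(model.metabolites),
        component_sizes=sizes,
        giant_reaction_count=giant_rxn,
        giant_reaction_fraction=round2(100 * giant_rxn / n_rxn) if n_rxn else 0.0,
        mean_degree=mean_degree(model),
        mean_shortest_path=mean_shortest_path(model),
        blocked_metabolites=blocked,
        same_sign_metabolites=same_sign,
    )


def disconnected_reactions(model: DraftModel) -> list[str]:
    """Reactions outside the giant component, sorted by component size
    (largest first) then reaction ID."""
    comps = connected_components(model)
    out = []
    for comp in comps[1:]:
        out.extend(sorted(r for r in comp if r in model.reactions))
    return out


# ---------------------------------------------------------------------------
# gene histograms
# ---------------------------------------------------------------------------


def gene_histograms(matrices: OrgMatrices) -> dict[str, dict]:
    """Per-organism reaction/gene counts and the genes-per-reaction histogram.

    Histogram bins are gene counts; values are numbers of reactions with
    that many genes, so bin values sum to the organism's reaction count.
    """
    out: dict[str, dict] = {}
    for org in matrices.organisms:
        counts = []
        genes: set[str] = set()
        for rxn in matrices.reactions:
            cell = matrices.genes(org, rxn)
            if cell:
                counts.append(len(cell))
                genes.update(cell)
        histogram: dict[int, int] = {}
        for c in counts:
            histogram[c] = histogram.get(c, 0) + 1
        out[org] = {
            "n_reactions": len(counts),
            "n_genes": len(genes),
            "genes_per_reaction": dict(sorted(histogram.items())),
        }
    return out


# ---------------------------------------------------------------------------
# omission accounting
# ---------------------------------------------------------------------------


def omission_accounting(
    total_input: int,
    reaction_filter_omitted: int,
    compounds_evaluated: int,
    generic_compounds: int,
    massless_reactions: int,
) -> dict:
    """Derived totals and percentage renderings of the omission bookkeeping.

    ``remaining`` reactions survive the reaction-level filters; the
    compound-mass screen then removes ``massless_reactions`` more, leaving
    the final kept count. Percentages are rounded half-up to two decimals.
    """
    remaining = total_input - reaction_filter_omitted
    total_omitted = reaction_filter_omitted + massless_reactions
    kept = total_input - total_omitted
    return {
        "total_input": total_input,
        "reaction_filter_omitted": reaction_filter_omitted,
        "remaining_after_reaction_filters": remaining,
        "compounds_evaluated": compounds_evaluated,
        "generic_compounds": generic_compounds,
        "massless_reactions": massless_reactions,
        "total_omitted": total_omitted,
        "total_kept": kept,
        "filter_percent": round2(100 * reaction_filter_omitted / total_input)
        if total_input
        else 0.0,
        "generic_compound_percent": round2(100 * generic_compounds / compounds_evaluated)
        if compounds_evaluated
        else 0.0,
        "omitted_percent": round2(100 * total_omitted / total_input)
        if total_input
        else 0.0,
    }


def omission_summary(report: OmissionReport) -> dict:
    """Render an OmissionReport as the standard accounting dictionary."""
    counts = report.category_counts
    massless = counts.get("massless_compound", 0)
    reaction_filter = report.total_omitted - massless
    acct = omission_accounting(
        total_input=report.total_input,
        reaction_filter_omitted=reaction_filter,
        compounds_evaluated=report.n_compounds_evaluated,
        generic_compounds=len(report.generic_compounds),
        massless_reactions=massless,
    )
    acct["category_counts"] = dict(sorted(counts.items()))
    return acct


def write_omission_report(report: OmissionReport, out_dir: str | Path) -> None:
    """JSON per-verdict dump plus a TSV summary under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "summary": omission_summary(report),
        "generic_compounds": report.generic_compounds,
        "unresolved_compounds": report.unresolved_compounds,
        "verdicts": [
            {
                "reaction": v.reaction,
                "status": v.status,
                "category": v.category,
                "attention_text": v.attention_text,
                "replacement": v.replacement,
            }
            for v in report.verdicts
        ],
    }
    (out_dir / "omitted_data.json").write_text(json.dumps(payload, indent=1))
    lines = ["reaction\tstatus\tcategory\treplacement\tattention"]
    for v in report.verdicts:
        lines.append(
            f"{v.reaction}\t{v.status}\t{v.category}\t"
            f"{v.replacement or ''}\t{v.attention_text}"
        )
    (out_dir / "omitted_data.tsv").write_text("\n".join(lines) + "\n")


def write_network_stats(stats: NetworkStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(stats), indent=1))
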