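"""Organism-reaction linkage matrices.

Genes reach reactions through EC numbers: a gene annotated with an EC is
linked to every reaction that EC catalyzes. Composing the per-organism
gene->EC table with the EC->reaction table yields the binary
Organisms-Reactions (OR) incidence matrix — the reactome of each query
organism as a bipartite graph — and its gene-bearing extension, the
Organisms-Reactions-Genes (ORG) matrix, whose per-row summaries (Sum /
Total / Genes) support comparative analysis across strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ids
from .kegg_io import LinkTable


@dataclass
class OrgMatrices:
    """OR matrix plus gene lists per (organism, reaction) cell.

    ``reactions`` is the full reaction universe known to the run (every
    reaction the EC->reaction table mentions), so the ORG report can show
    empty rows for reactions absent from all query organisms.
    """

    organisms: list[str]
    reactions: list[str]
    or_matrix: np.ndarray  # binary, organisms x reactions
    org_genes: dict[tuple[str, str], list[str]]
    ec_numbers: list[str] = field(default_factory=list)
    ec_reaction_matrix: np.ndarray | None = None

    def __post_init__(self):
        self.organism_index = {o: i for i, o in enumerate(self.organisms)}
        self.reaction_index = {r: j for j, r in enumerate(self.reactions)}

    def genes(self, organism: str, reaction: str) -> list[str]:
        return self.org_genes.get((organism, reaction), [])


@dataclass(frozen=True)
class OrgRow:
    """One rendered ORG-report row."""

    reaction: str
    genes_by_organism: dict[str, list[str]]
    sum: int          # organisms whose metabolism contains the reaction
    total: float      # fraction of query organisms containing it
    genes_summary: str  # distinct per-organism gene counts, ascending, ";"-joined


def build_or_matrix(
    gene_ec: dict[str, LinkTable], ec_rxn: LinkTable
) -> OrgMatrices:
    """Compose per-organism gene->EC links with EC->reaction links.

    ``or_matrix[o, r] = 1`` iff some gene of organism ``o`` maps to an EC
    that maps to reaction ``r``; the cell's gene list is the sorted set of
    genes reaching ``r`` through any EC. An organism with no gene->EC links
    yields an all-zero row (warning, not an error).
    """
    organisms = list(gene_ec)
    reactions = sorted(ec_rxn.targets())
    ecs = sorted(ec_rxn.sources())
    ec_index = {e: i for i, e in enumerate(ecs)}
    rxn_index = {r: j for j, r in enumerate(reactions)}

    ec_rxn_mat = np.zeros((len(ecs), len(reactions)), dtype=np.int8)
    rxns_by_ec: dict[str, list[str]] = {}
    for ec, rxn in ec_rxn.pairs:
        ec_rxn_mat[ec_index[ec], rxn_index[rxn]] = 1
        rxns_by_ec.setdefault(ec, []).append(rxn)

    or_matrix = np.zeros((len(organisms), len(reactions)), dtype=np.int8)
    org_genes: dict[tuple[str, str], list[str]] = {}
    for oi, org in enumerate(organisms):
        table = gene_ec[org]
        if not table.pairs:
            import warnings

            warnings.warn(f"organism {org!r} has no gene-EC links", stacklevel=2)
        cell: dict[str, set[str]] = {}
        for gene, ec in table.pairs:
            if ids.gene_organism(gene) != org:
                raise ValueError(
                    f"gene {gene!r} does not belong to organism {org!r}"
                )
            for rxn in rxns_by_ec.get(ec, ()):
                cell.setdefault(rxn, set()).add(gene)
        for rxn, genes in cell.items():
            or_matrix[oi, rxn_index[rxn]] = 1
            org_genes[(org, rxn)] = sorted(genes)
    return OrgMatrices(
        organisms=organisms,
        reactions=reactions,
        or_matrix=or_matrix,
        org_genes=org_genes,
        ec_numbers=ecs,
        ec_reaction_matrix=ec_rxn_mat,
    )


def summarize_row(matrices: OrgMatrices, reaction: str) -> OrgRow:
    """Sum / Total / Genes summary for one reaction across the query organisms.

    ``Genes`` reports the distinct per-organism gene counts in ascending
    order joined by ";" (gene counts (6,6,4,6,6) print as "4;6"), or "0"
    when no organism carries the reaction.
    """
    if reaction not in matrices.reaction_index:
        raise KeyError(f"unknown reaction ID: {reaction!r}")
    genes_by_org = {
        org: matrices.genes(org, reaction) for org in matrices.organisms
    }
    counts = [len(g) for g in genes_by_org.values() if g]
    n_present = len(counts)
    summary = ";".join(str(c) for c in sorted(set(counts))) if counts else "0"
    return OrgRow(
        reaction=reaction,
        genes_by_organism=genes_by_org,
        sum=n_present,
        total=n_present / len(matrices.organisms) if matrices.organisms else 0.0,
        genes_summary=summary,
    )


def reaction_universe(matrices: OrgMatrices) -> list[str]:
    """Reactions present in at least one query organism, sorted by KEGG ID.

    Downstream record downloads iterate only this list; the full known
    reaction list is kept for ORG-report rendering.
    """
    present = matrices.or_matrix.sum(axis=0) > 0
    return [r for r, keep in zip(matrices.reactions, present) if keep]


def org_report(matrices: OrgMatrices) -> pd.DataFrame:
    """ORG report: one row per known reaction, gene cells per organism,
    then Sum / Total / Genes. Empty rows render as 0 / 0 / "0"."""
    rows = []
    for rxn in matrices.reactions:
        row = summarize_row(matrices, rxn)
        rec = {"KEGG ID": rxn}
        for org in matrices.organisms:
            rec[org] = ", ".join(row.genes_by_organism[org])
        rec["Sum"] = row.sum
        rec["Total"] = row.total
        rec["Genes"] = row.genes_summary
        rows.append(rec)
    return pd.DataFrame(rows)


def write_org_report(matrices: OrgMatrices, path: str | Path) -> None:
    org_report(matrices).to_csv(path, sep="\t", index=False)
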