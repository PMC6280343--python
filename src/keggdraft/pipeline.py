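"""End-to-end reconstruction runs.

The stages mirror the data flow: gene->EC links per organism, EC->reaction
links, OR/ORG matrices, reaction+compound record download restricted to the
query organisms' reaction universe, filtering, model assembly, reports.
Flags control which stages execute — the matrix-only outputs (ORG report,
gene histograms) skip record downloads entirely, which is the expensive
stage against the live service.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import ids
from .assembly import DraftModel, build_community, build_consolidated, build_single
from .filtering import OmissionReport, apply_filters
from .kegg_io import (
    CompoundRecord,
    KeggSource,
    ReactionRecord,
    fetch_ec_reaction_links,
    fetch_gene_ec_links,
    fetch_records,
)
from .linkage import OrgMatrices, build_or_matrix, reaction_universe, write_org_report
from .reporting import (
    disconnected_reactions,
    gene_histograms,
    network_stats,
    write_network_stats,
    write_omission_report,
)

BUILD_FLAGS = {"consolidated", "single", "community"}
MATRIX_FLAGS = {"org_rxn_gen", "gene_plot", "histogram"}
ALL_FLAGS = BUILD_FLAGS | MATRIX_FLAGS | {"omitted_data", "disconnected_reactions"}


@dataclass
class RunConfig:
    organisms: list[str]
    flags: set[str] = field(default_factory=set)
    source: KeggSource = field(default_factory=KeggSource)
    out_dir: Path = Path("keggdraft_run")

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        unknown = self.flags - ALL_FLAGS
        if unknown:
            raise ValueError(f"unknown flags: {sorted(unknown)}")
        if not self.organisms:
            raise ValueError("at least one organism is required")
        for org in self.organisms:
            if not ids.is_organism_code(org):
                raise ValueError(f"invalid organism code: {org!r}")

    @property
    def effective_flags(self) -> set[str]:
        # a bare invocation builds the consolidated model (the default)
        return self.flags or {"consolidated"}

    @property
    def needs_records(self) -> bool:
        return bool(
            self.effective_flags & (BUILD_FLAGS | {"omitted_data", "disconnected_reactions"})
        )


@dataclass
class RunResult:
    config: RunConfig
    matrices: OrgMatrices
    report: OmissionReport | None = None
    consolidated: DraftModel | None = None
    singles: dict[str, DraftModel] = field(default_factory=dict)
    community: DraftModel | None = None
    outputs: dict[str, Path] = field(default_factory=dict)


def collect_records(
    source: KeggSource, universe: list[str]
) -> tuple[dict[str, ReactionRecord], dict[str, CompoundRecord], list[str]]:
    """Fetch reaction records for the universe, then every participant
    compound/glycan record plus any "Same as" cross-reference targets."""
    result = fetch_records(source, universe)
    missing = list(result.missing)
    records = {r.id: r for r in result.records}
    participant_ids = sorted({p for r in records.values() for p in r.participants})
    cres = fetch_records(source, participant_ids)
    missing += cres.missing
    compounds = {c.id: c for c in cres.records}
    targets = sorted(
        {
            c.same_as
            for c in compounds.values()
            if c.same_as and c.same_as not in compounds
        }
    )
    if targets:
        tres = fetch_records(source, targets)
        missing += tres.missing
        compounds.update({c.id: c for c in tres.records})
    return records, compounds, missing


def run(config: RunConfig) -> RunResult:
    """Execute the stages ``config.flags`` require and write all outputs."""
    flags = config.effective_flags
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    gene_ec = {
        org: fetch_gene_ec_links(config.source, org) for org in config.organisms
    }
    all_ecs = {ec for table in gene_ec.values() for _, ec in table.pairs}
    ec_rxn = fetch_ec_reaction_links(config.source, all_ecs or {"-.-.-.-"})
    matrices = build_or_matrix(gene_ec, ec_rxn)
    result = RunResult(config=config, matrices=matrices)

    if "org_rxn_gen" in flags:
        path = out_dir / "org_rxn_gen.tsv"
        write_org_report(matrices, path)
        result.outputs["org_rxn_gen"] = path
    if flags & {"gene_plot", "histogram"}:
        path = out_dir / "gene_histograms.json"
        path.write_text(json.dumps(gene_histograms(matrices), indent=1))
        result.outputs["gene_histograms"] = path

    if not config.needs_records:
        _write_manifest(result)
        return result

    universe = reaction_universe(matrices)
    records, compounds, missing = collect_records(config.source, universe)
    report = apply_filters(records.values(), compounds)
    result.report = report
    if "omitted_data" in flags:
        write_omission_report(report, out_dir)
        result.outputs["omitted_data"] = out_dir / "omitted_data.json"

    if flags & (BUILD_FLAGS | {"disconnected_reactions"}):
        consolidated = build_consolidated(report, records, matrices, compounds)
        result.consolidated = consolidated
        if "consolidated" in flags or not config.flags:
            sbml = out_dir / "consolidated.xml"
            consolidated.write_sbml(sbml)
            consolidated.to_json(out_dir / "consolidated.json")
            result.outputs["consolidated"] = sbml
        if flags & {"single", "community"}:
            for org in config.organisms:
                result.singles[org] = build_single(consolidated, matrices, org)
        if "single" in flags:
            for org, model in result.singles.items():
                sbml = out_dir / f"single_{org}.xml"
                model.write_sbml(sbml)
                result.outputs[f"single_{org}"] = sbml
        if "community" in flags:
            community = build_community(list(result.singles.values()))
            result.community = community
            sbml = out_dir / "community.xml"
            community.write_sbml(sbml)
            result.outputs["community"] = sbml
        if "disconnected_reactions" in flags:
            path = out_dir / "disconnected_reactions.json"
            path.write_text(json.dumps(disconnected_reactions(consolidated), indent=1))
            result.outputs["disconnected_reactions"] = path
            stats_path = out_dir / "network_stats.json"
            write_network_stats(network_stats(consolidated), stats_path)
            result.outputs["network_stats"] = stats_path

    _write_manifest(result, missing)
    return result


def _write_manifest(result: RunResult, missing: list[str] | None = None) -> None:
    manifest = {
        "organisms": result.config.organisms,
        "flags": sorted(result.config.effective_flags),
        "source_mode": result.config.source.mode,
        "outputs": {k: str(v) for k, v in result.outputs.items()},
        "missing_ids": missing or [],
        "n_reactions_known": len(result.matrices.reactions),
    }
    (result.config.out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1)
    )
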