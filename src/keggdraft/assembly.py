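"""Draft-model assembly.

Three reconstruction flavors share one container:

* **consolidated** — the union of every query organism's kept reactions,
  all in one "cytosol" compartment, with gene associations OR-joined across
  organisms (KEGG never specifies how gene products interact, so no AND
  complexes are inferred).
* **single** — the consolidated model restricted to one organism's
  reactions, with GPRs restricted to that organism's genes.
* **community** — the disjoint union of single models, each organism in its
  own compartment (IDs suffixed ``_<org>``); without transport reactions the
  compartments stay unconnected by construction.

All reactions are reversible with symmetric default bounds: KEGG carries no
directionality annotation, and assigning directions is curation work, not
reconstruction. No biomass, ATP-maintenance, transport or exchange reactions
are created.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence
from xml.sax.saxutils import escape as xml_escape

import numpy as np
from scipy import sparse

from . import ids
from .filtering import OmissionReport
from .kegg_io import CompoundRecord, ReactionRecord

DEFAULT_BOUND = 1000.0
CYTOSOL = ("c", "cytosol")


@dataclass
class Metabolite:
    model_id: str
    kegg_id: str
    name: str = ""
    formula: str = ""
    compartment: str = "c"
    annotations: dict = field(default_factory=dict)


@dataclass
class Reaction:
    model_id: str
    kegg_id: str
    name: str = ""
    # metabolite model_id -> signed coefficient (negative = consumed)
    stoichiometry: dict[str, float] = field(default_factory=dict)
    reversible: bool = True
    bounds: tuple[float, float] = (-DEFAULT_BOUND, DEFAULT_BOUND)
    gpr: str = ""
    rxn_attention: str | None = None
    annotations: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return [g for g in self.gpr.split(" or ") if g]


@dataclass
class DraftModel:
    model_id: str
    kind: str  # single | consolidated | community
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    compartments: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    # -- stoichiometric matrix --------------------------------------------

    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """S-matrix (metabolites x reactions) plus its row/column ID orders."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        mat = sparse.dok_matrix((len(met_ids), len(rxn_ids)), dtype=float)
        for j, rxn_id in enumerate(rxn_ids):
            for met_id, coeff in self.reactions[rxn_id].stoichiometry.items():
                mat[met_index[met_id], j] = coeff
        return mat.tocsr(), met_ids, rxn_ids

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "kind": self.kind,
            "compartments": self.compartments,
            "provenance": self.provenance,
            "metabolites": [vars(m) for m in self.metabolites.values()],
            "reactions": [
                {**vars(r), "bounds": list(r.bounds)} for r in self.reactions.values()
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "DraftModel":
        model = cls(
            model_id=data["model_id"],
            kind=data["kind"],
            compartments=dict(data["compartments"]),
            provenance=dict(data["provenance"]),
        )
        for m in data["metabolites"]:
            model.metabolites[m["model_id"]] = Metabolite(**m)
        for r in data["reactions"]:
            r = dict(r)
            r["bounds"] = tuple(r["bounds"])
            model.reactions[r["model_id"]] = Reaction(**r)
        return model

    @classmethod
    def from_json(cls, source: str | Path) -> "DraftModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls.from_dict(json.loads(text))

    # -- SBML via cobrapy --------------------------------------------------

    def to_cobra(self):
        import cobra

        model = cobra.Model(_sid(self.model_id))
        model.compartments = dict(self.compartments)
        mets = {}
        for m in self.metabolites.values():
            met = cobra.Metabolite(
                _sid(m.model_id),
                name=m.name,
                formula=m.formula or None,
                compartment=m.compartment,
            )
            met.annotation["kegg.compound"] = m.kegg_id
            mets[m.model_id] = met
        for r in self.reactions.values():
            rxn = cobra.Reaction(
                _sid(r.model_id),
                name=r.name,
                lower_bound=r.bounds[0],
                upper_bound=r.bounds[1],
            )
            model.add_reactions([rxn])
            rxn.add_metabolites(
                {mets[mid]: coeff for mid, coeff in r.stoichiometry.items()}
            )
            if r.gpr:
                rxn.gene_reaction_rule = " or ".join(_sid(g) for g in r.genes)
            rxn.annotation["kegg.reaction"] = r.kegg_id
            notes = {}
            if r.rxn_attention:
                notes["rxnAttention"] = r.rxn_attention
            for key in ("genes", "ec_numbers", "equation", "source_reactions"):
                value = r.annotations.get(key)
                if isinstance(value, (list, tuple)):
                    value = ", ".join(map(str, value))
                if value:
                    notes[key] = str(value)
            # libsbml rejects raw "<" (e.g. the "<=>" arrow) inside XHTML notes
            rxn.notes.update({k: xml_escape(v) for k, v in notes.items() if v})
        return model

    def write_sbml(self, path: str | Path) -> None:
        """SBML Level 3 Version 1 with the fbc extension (cobrapy writer).

        A draft reconstruction has no biomass reaction, hence nothing to
        optimize; the empty flux objective cobrapy always emits would be an
        fbc consistency error, so it is stripped from the document.
        """
        import cobra
        import libsbml

        cobra.io.write_sbml_model(self.to_cobra(), str(path))
        doc = libsbml.readSBMLFromFile(str(path))
        plugin = doc.getModel().getPlugin("fbc")
        if plugin is not None and plugin.getNumObjectives() > 0:
            obj = plugin.getObjective(0)
            if obj.getNumFluxObjectives() == 0:
                plugin.getListOfObjectives().clear()
                plugin.unsetActiveObjectiveId()
        libsbml.writeSBMLToFile(doc, str(path))


def _sid(identifier: str) -> str:
    # SBML SIds forbid ":" (gene IDs are "org:locus"); verbatim forms stay
    # in the annotations
    return identifier.replace(":", "_")


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _gpr_for(matrices, source_reactions: Sequence[str], organisms: Sequence[str]) -> list[str]:
    genes: set[str] = set()
    for org in organisms:
        for rxn in source_reactions:
            genes.update(matrices.genes(org, rxn))
    return sorted(genes)


def build_consolidated(
    report: OmissionReport,
    records: Mapping[str, ReactionRecord],
    matrices,
    compounds: Mapping[str, CompoundRecord],
    model_id: str = "consolidated",
) -> DraftModel:
    """Union model over all query organisms from the kept filter verdicts.

    Glycan reactions with a compound-ID alternative enter as that
    alternative (merging gene associations if the alternative is itself in
    the kept set); everything else enters under its own ID. Metabolites all
    live in the cytosol compartment and carry their KEGG name and formula.
    """
    model = DraftModel(
        model_id=model_id,
        kind="consolidated",
        compartments={CYTOSOL[0]: CYTOSOL[1]},
        provenance={"organisms": list(matrices.organisms)},
    )
    # final reaction id -> (sides, contributing source reaction ids, attention)
    merged: dict[str, dict] = {}
    for verdict in report.kept_verdicts():
        final_id = verdict.replacement or verdict.reaction
        entry = merged.setdefault(
            final_id,
            {
                "substrates": dict(verdict.substrates),
                "products": dict(verdict.products),
                "sources": [],
                "attention": [],
            },
        )
        entry["sources"].append(verdict.reaction)
        if verdict.attention_text:
            entry["attention"].append(verdict.attention_text)

    for final_id in sorted(merged):
        entry = merged[final_id]
        genes = _gpr_for(matrices, sorted(set(entry["sources"])), matrices.organisms)
        record = records.get(final_id)
        stoich: dict[str, float] = {}
        for met, coeff in entry["substrates"].items():
            stoich[met] = stoich.get(met, 0.0) - float(coeff)
        for met, coeff in entry["products"].items():
            stoich[met] = stoich.get(met, 0.0) + float(coeff)
        for met_id in stoich:
            if met_id not in compounds and not ids.is_glycan_id(met_id):
                raise KeyError(
                    f"reaction {final_id} references unknown compound {met_id}"
                )
            _ensure_metabolite(model, met_id, compounds, CYTOSOL[0])
        rxn = Reaction(
            model_id=final_id,
            kegg_id=final_id,
            name=record.name if record else "",
            stoichiometry=dict(sorted(stoich.items())),
            gpr=" or ".join(genes),
            rxn_attention="; ".join(entry["attention"]) or None,
            annotations={
                "kegg_id": final_id,
                "source_reactions": sorted(set(entry["sources"])),
                "ec_numbers": list(record.ec_numbers) if record else [],
                "equation": record.equation_text if record else "",
                "genes": genes,
                "raw_text": record.raw_text if record else "",
            },
        )
        model.reactions[final_id] = rxn
    model.metabolites = dict(sorted(model.metabolites.items()))
    model.reactions = dict(sorted(model.reactions.items()))
    return model


def _ensure_metabolite(model, kegg_id, compounds, compartment, suffix=""):
    model_id = kegg_id + suffix
    if model_id in model.metabolites:
        return
    rec = compounds.get(kegg_id)
    model.metabolites[model_id] = Metabolite(
        model_id=model_id,
        kegg_id=kegg_id,
        name=rec.name if rec else "",
        formula=rec.formula if rec else "",
        compartment=compartment,
        annotations={"kegg_id": kegg_id, "name": rec.name if rec else ""},
    )


def build_single(consolidated: DraftModel, matrices, organism: str) -> DraftModel:
    """Copy of the consolidated model restricted to one organism.

    A reaction stays if any of its source reactions is present in the
    organism's row of the OR matrix; its GPR keeps only that organism's
    genes. Metabolites no longer used by any reaction are dropped.
    """
    if organism not in matrices.organism_index:
        raise KeyError(f"organism {organism!r} not in query list")
    oi = matrices.organism_index[organism]
    model = DraftModel(
        model_id=organism,
        kind="single",
        compartments=dict(consolidated.compartments),
        provenance={"organisms": [organism]},
    )
    for rxn in consolidated.reactions.values():
        sources = rxn.annotations.get("source_reactions", [rxn.kegg_id])
        present = any(
            src in matrices.reaction_index
            and matrices.or_matrix[oi, matrices.reaction_index[src]]
            for src in sources
        )
        if not present:
            continue
        genes = sorted(
            g for g in rxn.genes if ids.gene_organism(g) == organism
        )
        new = Reaction(
            model_id=rxn.model_id,
            kegg_id=rxn.kegg_id,
            name=rxn.name,
            stoichiometry=dict(rxn.stoichiometry),
            bounds=rxn.bounds,
            gpr=" or ".join(genes),
            rxn_attention=rxn.rxn_attention,
            annotations={**rxn.annotations, "genes": genes},
        )
        model.reactions[new.model_id] = new
        for met_id in new.stoichiometry:
            model.metabolites[met_id] = consolidated.metabolites[met_id]
    if not model.reactions:
        import warnings

        warnings.warn(f"organism {organism!r} owns no kept reactions", stacklevel=2)
    model.metabolites = dict(sorted(model.metabolites.items()))
    model.reactions = dict(sorted(model.reactions.items()))
    return model


def build_community(singles: Sequence[DraftModel], model_id: str = "community") -> DraftModel:
    """Disjoint union of single models, one compartment per organism.

    Every metabolite and reaction ID is suffixed ``_<org>``; no transport
    reactions are created, so compartments share nothing. Stripping the
    suffix recovers each single model exactly.
    """
    if len(singles) < 2:
        raise ValueError("a community model needs at least two single models")
    organisms = [m.model_id for m in singles]
    if len(set(organisms)) != len(organisms):
        raise ValueError(f"duplicate organism IDs in community query: {organisms}")
    model = DraftModel(
        model_id=model_id,
        kind="community",
        compartments={org: org for org in organisms},
        provenance={"organisms": organisms},
    )
    for single in singles:
        org = single.model_id
        for met in single.metabolites.values():
            new_id = f"{met.model_id}_{org}"
            model.metabolites[new_id] = Metabolite(
                model_id=new_id,
                kegg_id=met.kegg_id,
                name=met.name,
                formula=met.formula,
                compartment=org,
                annotations=dict(met.annotations),
            )
        for rxn in single.reactions.values():
            new_id = f"{rxn.model_id}_{org}"
            model.reactions[new_id] = Reaction(
                model_id=new_id,
                kegg_id=rxn.kegg_id,
                name=rxn.name,
                stoichiometry={
                    f"{met_id}_{org}": coeff
                    for met_id, coeff in rxn.stoichiometry.items()
                },
                bounds=rxn.bounds,
                gpr=rxn.gpr,
                rxn_attention=rxn.rxn_attention,
                annotations=dict(rxn.annotations),
            )
    return model


def split_community(community: DraftModel) -> dict[str, DraftModel]:
    """Invert ``build_community``: strip the ``_<org>`` suffixes."""
    singles: dict[str, DraftModel] = {}
    for org in community.provenance["organisms"]:
        single = DraftModel(
            model_id=org,
            kind="single",
            compartments={CYTOSOL[0]: CYTOSOL[1]},
            provenance={"organisms": [org]},
        )
        suffix = f"_{org}"
        for met in community.metabolites.values():
            if met.compartment == org:
                base = met.model_id[: -len(suffix)]
                single.metabolites[base] = Metabolite(
                    model_id=base,
                    kegg_id=met.kegg_id,
                    name=met.name,
                    formula=met.formula,
                    compartment=CYTOSOL[0],
                    annotations=dict(met.annotations),
                )
        for rxn in community.reactions.values():
            if rxn.model_id.endswith(suffix):
                base = rxn.model_id[: -len(suffix)]
                single.reactions[base] = Reaction(
                    model_id=base,
                    kegg_id=rxn.kegg_id,
                    name=rxn.name,
                    stoichiometry={
                        met_id[: -len(suffix)]: coeff
                        for met_id, coeff in rxn.stoichiometry.items()
                    },
                    bounds=rxn.bounds,
                    gpr=rxn.gpr,
                    rxn_attention=rxn.rxn_attention,
                    annotations=dict(rxn.annotations),
                )
        singles[org] = single
    return singles
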