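"""Deterministic synthetic mini-KEGG sources.

Two generators back the offline test harness:

* :func:`generate_fixture` writes a randomized local-source directory
  (link tables + flat-file records) whose reactions are constructed to hit
  every filter branch — generic comments, symbolic polymer equations,
  comment-declared polymerization, pure-glycan equations, glycan reactions
  with and without compound-ID alternatives, ill-defined equations, and
  reactions containing massless compounds — together with a ground-truth
  manifest, so every omission count and every OR/ORG cell can be asserted
  exactly.
* :func:`table1_fixture` encodes a published five-strain ORG-report
  fragment (*E. coli* K-12 strains eco/ecj/ecd/ebw/ecok, reactions
  R00001-R00017) as link tables, so the Sum/Total/Genes rendering can be
  checked against known cells.

Synthetic IDs use high number ranges (R9xxxx, C9xxxx, G9xxxx, EC 9.x.x.x)
to avoid colliding with real KEGG entries in shared cache directories. The
fixture is a correctness harness, not a biological simulator: degree
distributions, pathway structure and compound chemistry are not realistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .kegg_io import CompoundRecord, ReactionRecord, serialize_record


@dataclass
class FixtureSpec:
    """Composition of a synthetic source.

    Category fractions must sum to <= 1; the remainder becomes clean
    reactions. The same seed always produces a byte-identical directory.
    """

    seed: int = 0
    n_organisms: int = 3
    n_reactions: int = 40
    n_compounds: int = 30
    frac_generic_comment: float = 0.1
    frac_polymer: float = 0.05
    frac_possible_polymer: float = 0.05
    frac_pure_glycan: float = 0.05
    frac_glycan_with_alternative: float = 0.1
    frac_glycan_no_alternative: float = 0.05
    frac_ill_defined: float = 0.05
    frac_massless: float = 0.1
    genes_per_reaction: tuple[int, int] = (1, 4)
    organism_overlap: float = 0.6  # P(an organism carries a given reaction)

    def fractions(self) -> dict[str, float]:
        return {
            "generic_comment": self.frac_generic_comment,
            "polymer": self.frac_polymer,
            "possible_polymer": self.frac_possible_polymer,
            "pure_glycan": self.frac_pure_glycan,
            "glycan_with_alternative": self.frac_glycan_with_alternative,
            "glycan_no_alternative": self.frac_glycan_no_alternative,
            "ill_defined": self.frac_ill_defined,
            "massless": self.frac_massless,
        }

    def __post_init__(self):
        if sum(self.fractions().values()) > 1 + 1e-9:
            raise ValueError("filter-category fractions must sum to <= 1")


def _organisms(n: int) -> list[str]:
    if n > 26:
        raise ValueError("at most 26 synthetic organisms supported")
    return [f"ts{chr(ord('a') + i)}" for i in range(n)]


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write a local-source directory and return its ground-truth manifest.

    Layout matches what the I/O layer expects: ``links/<org>_ec.tsv``,
    ``links/ec_rxn.tsv`` and ``records/<ID>.txt``. The manifest maps every
    reaction to its intended filter category ("clean" or
    "glycan_alternative_target" for keepers), lists the generic compounds,
    and records the per-organism reaction and gene assignments.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    (out_dir / "links").mkdir(parents=True, exist_ok=True)
    (out_dir / "records").mkdir(parents=True, exist_ok=True)

    # -- compounds ---------------------------------------------------------
    compounds: dict[str, CompoundRecord] = {}
    n_generic = max(1, int(round(spec.n_compounds * 0.15)))
    compound_ids = [f"C9{i:04d}" for i in range(spec.n_compounds)]
    generic_ids = compound_ids[:n_generic]
    clean_ids = compound_ids[n_generic:]
    if len(clean_ids) < 4:
        raise ValueError("n_compounds too small for equation construction")
    for cid in compound_ids:
        generic = cid in generic_ids
        compounds[cid] = CompoundRecord(
            id=cid,
            name=f"synthetic compound {cid}",
            formula="C6H12O6R" if generic else "C6H12O6",
            exact_mass=None if generic else float(np.round(rng.uniform(50, 500), 4)),
            mol_weight=None if generic else float(np.round(rng.uniform(50, 500), 4)),
        )

    glycans: dict[str, CompoundRecord] = {}

    def new_glycan(idx: int, same_as: str | None) -> str:
        gid = f"G9{idx:04d}"
        glycans[gid] = CompoundRecord(
            id=gid,
            name=f"synthetic glycan {gid}",
            mass=float(np.round(rng.uniform(200, 2000), 2)),
            same_as=same_as,
        )
        return gid

    # -- reaction category plan -------------------------------------------
    plan: list[str] = []
    for cat, frac in spec.fractions().items():
        plan.extend([cat] * int(round(spec.n_reactions * frac)))
    if len(plan) > spec.n_reactions:
        plan = plan[: spec.n_reactions]
    plan.extend(["clean"] * (spec.n_reactions - len(plan)))

    def pick(ids_pool, k):
        return [ids_pool[i] for i in rng.choice(len(ids_pool), size=k, replace=False)]

    reactions: dict[str, ReactionRecord] = {}
    manifest_categories: dict[str, str] = {}
    glycan_counter = 0
    extra_counter = 0

    def reaction_id() -> str:
        return f"R9{len(reactions):04d}"

    def add(rid, subs, prods, category, comment="", remark=""):
        reactions[rid] = ReactionRecord(
            id=rid,
            name=f"synthetic reaction {rid}",
            equation_text="",  # filled on serialization round trip
            substrates=subs,
            products=prods,
            is_symbolic=any(
                isinstance(c, str) for c in (*subs.values(), *prods.values())
            ),
            ec_numbers=(),
            comment=comment,
            remark=remark,
        )
        manifest_categories[rid] = category

    for category in plan:
        rid = reaction_id()
        a, b, c, d = pick(clean_ids, 4)
        if category == "generic_comment":
            add(rid, {a: 1.0}, {b: 1.0}, category, remark="General reaction")
        elif category == "polymer":
            add(rid, {a: "(n+1)", b: 1.0}, {c: "n", d: 1.0}, category)
        elif category == "possible_polymer":
            add(
                rid, {a: 2.0}, {b: 1.0}, category,
                comment="acts in polymerization of synthetic units",
            )
        elif category == "pure_glycan":
            g1 = new_glycan(glycan_counter, None)
            g2 = new_glycan(glycan_counter + 1, None)
            glycan_counter += 2
            add(rid, {g1: 1.0}, {g2: 1.0}, category)
        elif category == "glycan_with_alternative":
            g1 = new_glycan(glycan_counter, a)
            g2 = new_glycan(glycan_counter + 1, b)
            glycan_counter += 2
            add(rid, {g1: 1.0, c: 1.0}, {g2: 1.0, d: 1.0}, category)
            alt_id = f"R8{extra_counter:04d}"
            extra_counter += 1
            reactions[alt_id] = ReactionRecord(
                id=alt_id,
                name=f"synthetic reaction {alt_id}",
                equation_text="",
                substrates={a: 1.0, c: 1.0},
                products={b: 1.0, d: 1.0},
            )
            manifest_categories[alt_id] = "glycan_alternative_target"
        elif category == "glycan_no_alternative":
            g1 = new_glycan(glycan_counter, None)
            glycan_counter += 1
            add(rid, {g1: 1.0, a: 1.0}, {b: 1.0, c: 1.0}, category)
        elif category == "ill_defined":
            add(rid, {a: 1.0, b: 1.0}, {b: 1.0, c: 1.0}, category)
        elif category == "massless":
            g = generic_ids[int(rng.integers(len(generic_ids)))]
            add(rid, {a: 1.0, g: 1.0}, {b: 1.0}, category)
        else:  # clean
            k = int(rng.integers(1, 3))
            subs = {x: 1.0 for x in pick(clean_ids, k)}
            prods = {x: 1.0 for x in pick([i for i in clean_ids if i not in subs], k)}
            add(rid, subs, prods, category)

    # -- organisms, genes, ECs --------------------------------------------
    organisms = _organisms(spec.n_organisms)
    all_rids = sorted(reactions)
    ec_of = {rid: f"9.9.{1 + i // 100}.{1 + i % 100}" for i, rid in enumerate(all_rids)}
    org_reactions: dict[str, list[str]] = {o: [] for o in organisms}
    org_genes: dict[str, dict[str, list[str]]] = {o: {} for o in organisms}
    gene_counter = 0
    for rid in all_rids:
        carriers = [o for o in organisms if rng.random() < spec.organism_overlap]
        if not carriers:  # every reaction belongs somewhere
            carriers = [organisms[int(rng.integers(len(organisms)))]]
        for org in carriers:
            k = int(rng.integers(spec.genes_per_reaction[0], spec.genes_per_reaction[1] + 1))
            genes = [f"{org}:g{gene_counter + i:05d}" for i in range(k)]
            gene_counter += k
            org_reactions[org].append(rid)
            org_genes[org][rid] = genes

    # -- write the source --------------------------------------------------
    for org in organisms:
        lines = []
        for rid in sorted(org_genes[org]):
            for gene in org_genes[org][rid]:
                lines.append(f"{gene}\t{ec_of[rid]}")
        (out_dir / "links" / f"{org}_ec.tsv").write_text(
            "\n".join(sorted(lines)) + ("\n" if lines else "")
        )
    ec_lines = sorted(f"{ec_of[rid]}\t{rid}" for rid in all_rids)
    (out_dir / "links" / "ec_rxn.tsv").write_text("\n".join(ec_lines) + "\n")
    for rid in all_rids:
        (out_dir / "records" / f"{rid}.txt").write_text(
            serialize_record(reactions[rid])
        )
    for cid in sorted({**compounds, **glycans}):
        rec = compounds.get(cid) or glycans[cid]
        (out_dir / "records" / f"{cid}.txt").write_text(serialize_record(rec))

    manifest = {
        "spec": {**asdict(spec), "genes_per_reaction": list(spec.genes_per_reaction)},
        "organisms": organisms,
        "categories": manifest_categories,
        "generic_compounds": generic_ids,
        "org_reactions": {o: sorted(set(r)) for o, r in org_reactions.items()},
        "org_genes": org_genes,
        "ec_of": ec_of,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# published five-strain ORG fragment
# ---------------------------------------------------------------------------

# Gene cells of the published ORG-report fragment for the five E. coli K-12
# strains; rows absent from the mapping carry no genes in any strain.
_TABLE1_GENES: dict[str, dict[str, list[str]]] = {
    "R00004": {
        "eco": ["b4226"],
        "ecj": ["JW4185"],
        "ecd": ["ECDH10B_4421"],
        "ebw": ["BWG_3936"],
        "ecok": ["ECMDS42_3668"],
    },
    "R00006": {
        "eco": ["b0078", "b3670", "b0077", "b3671", "b3769"],
        "ecj": ["JW0077", "JW3645", "JW0076", "JW3646", "JW3742"],
        "ecd": ["ECDH10B_3853", "ECDH10B_3958", "ECDH10B_3854"],
        "ebw": ["BWG_0073", "BWG_0074", "BWG_3454", "BWG_3361", "BWG_3362"],
        "ecok": ["ECMDS42_3207", "ECMDS42_0071", "ECMDS42_0072", "ECMDS42_3105", "ECMDS42_3106"],
    },
    "R00009": {
        "eco": ["b1732", "b3942"],
        "ecj": ["JW1721", "JW3914"],
        "ecd": ["ECDH10B_1870", "ECDH10B_4131"],
        "ebw": ["BWG_1545", "BWG_3611"],
        "ecok": ["ECMDS42_1407", "ECMDS42_3380"],
    },
    "R00010": {
        "eco": ["b1197", "b3519"],
        "ecj": ["JW3487", "JW1186"],
        "ecd": ["ECDH10B_3696", "ECDH10B_1250"],
        "ebw": ["BWG_3208", "BWG_1022"],
        "ecok": ["ECMDS42_2954", "ECMDS42_0984"],
    },
    "R00013": {
        "eco": ["b0507"],
        "ecj": ["JW0495"],
        "ecd": ["ECDH10B_0463"],
        "ebw": ["BWG_0384"],
        "ecok": ["ECMDS42_0400"],
    },
    "R00014": {
        "eco": ["b0114", "b0078", "b3670", "b0077", "b3671", "b3769"],
        "ecj": ["JW0110", "JW0077", "JW3645", "JW0076", "JW3646", "JW3742"],
        "ecd": ["ECDH10B_0094", "ECDH10B_3853", "ECDH10B_3958", "ECDH10B_3854"],
        "ebw": ["BWG_0073", "BWG_0074", "BWG_3454", "BWG_3361", "BWG_3362", "BWG_0107"],
        "ecok": ["ECMDS42_3207", "ECMDS42_0071", "ECMDS42_0072", "ECMDS42_0105", "ECMDS42_3105", "ECMDS42_3106"],
    },
    "R00017": {
        "eco": ["b3518"],
        "ecj": ["JW3486"],
        "ecd": ["ECDH10B_3695"],
        "ebw": ["BWG_3207"],
        "ecok": ["ECMDS42_2953"],
    },
}

TABLE1_ORGANISMS = ["eco", "ecj", "ecd", "ebw", "ecok"]
TABLE1_REACTIONS = [
    "R00001", "R00002", "R00004", "R00005", "R00006", "R00008", "R00009",
    "R00010", "R00011", "R00012", "R00013", "R00014", "R00015", "R00017",
]


def table1_fixture(out_dir: str | Path) -> Path:
    """Write the five-strain ORG fragment as a local source directory.

    Each reaction gets one synthetic EC; gene->EC links reproduce the
    published gene cells. Reactions with no genes in any strain are linked
    from an EC no organism carries, so they appear as empty report rows.
    """
    out_dir = Path(out_dir)
    (out_dir / "links").mkdir(parents=True, exist_ok=True)
    (out_dir / "records").mkdir(parents=True, exist_ok=True)
    ec_of = {rid: f"9.8.7.{i + 1}" for i, rid in enumerate(TABLE1_REACTIONS)}
    for org in TABLE1_ORGANISMS:
        lines = []
        for rid, cells in _TABLE1_GENES.items():
            for locus in cells.get(org, []):
                lines.append(f"{org}:{locus}\t{ec_of[rid]}")
        (out_dir / "links" / f"{org}_ec.tsv").write_text("\n".join(sorted(lines)) + "\n")
    ec_lines = sorted(f"{ec_of[rid]}\t{rid}" for rid in TABLE1_REACTIONS)
    (out_dir / "links" / "ec_rxn.tsv").write_text("\n".join(ec_lines) + "\n")
    return out_dir
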