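"""Reaction and compound exclusion rules.

A first-draft reconstruction should contain only well-defined, mass-balanced
reactions, so reactions are screened before model assembly:

* **generic_comment** — the KEGG REMARK/COMMENT text declares the reaction
  generic ("Generic", "General", "General reaction").
* **polymer** — the equation carries symbolic ``n``/``m`` coefficients;
  steady-state modeling has no consensus treatment of polymerization.
* **possible_polymer** — the comment text announces polymerization even
  though the coefficients are numeric.
* **glycan handling** — glycan (``G``) participants are translated to their
  compound (``C``) equivalents via the "Same as" cross-reference when
  possible; if an equivalent all-compound reaction exists in the reaction
  universe it replaces the glycan reaction, otherwise the reaction is kept
  but flagged for curator attention. Reactions consisting solely of glycans
  are dropped even without an alternative.
* **ill_defined** — the same compound appears on both sides of the equation.
* **massless_compound** — a surviving reaction contains a generic compound
  (every mass field absent or 0), which would break mass balance.

Every reaction receives exactly one verdict; nothing is silently dropped.
Kept-but-suspect reactions carry an ``rxn_attention`` explanation that is
propagated into the model annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_DOWN, Decimal
from typing import Iterable, Mapping

from . import ids
from .kegg_io import CompoundRecord, ReactionRecord

GENERIC_TRIGGERS = ("generic", "general reaction", "general")
POLYMER_TRIGGERS = ("polymerization", "polymerisation", "polymer")

OMITTED_CATEGORIES = frozenset(
    {
        "generic_comment",
        "polymer",
        "possible_polymer",
        "glycan_only_omitted",
        "ill_defined",
        "massless_compound",
    }
)
# categories counted as "reaction filtering" (structure/annotation based),
# as opposed to the later compound-mass screen
REACTION_FILTER_CATEGORIES = frozenset(
    {"generic_comment", "polymer", "possible_polymer", "glycan_only_omitted", "ill_defined"}
)

MASSLESS_ATTENTION = (
    "This reaction contains a generic compound or a compound without mass in KEGG"
)


@dataclass
class FilterVerdict:
    reaction: str
    status: str  # kept | kept_with_attention | omitted
    category: str  # none | generic_comment | polymer | possible_polymer |
    #                glycan_replaced | glycan_only_omitted |
    #                glycan_kept_no_alternative | ill_defined | massless_compound
    attention_text: str = ""
    replacement: str | None = None
    # effective participant maps (translated for glycan_replaced)
    substrates: Mapping[str, float] = field(default_factory=dict)
    products: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if (self.status == "omitted") != (self.category in OMITTED_CATEGORIES):
            raise ValueError(
                f"{self.reaction}: status {self.status!r} inconsistent with "
                f"category {self.category!r}"
            )
        if self.status != "kept" and not self.attention_text:
            raise ValueError(f"{self.reaction}: non-kept verdict needs attention_text")
        if (self.replacement is not None) != (self.category == "glycan_replaced"):
            raise ValueError(f"{self.reaction}: replacement/category mismatch")


@dataclass
class OmissionReport:
    """Bookkeeping for every excluded reaction and generic compound."""

    verdicts: list[FilterVerdict]
    category_counts: dict[str, int]
    total_input: int
    total_omitted: int
    total_kept: int
    generic_compounds: list[str]
    unresolved_compounds: list[str]
    n_compounds_evaluated: int
    filter_percent: float          # reaction-level omissions / total input
    generic_compound_percent: float  # generic compounds / compounds evaluated
    omitted_percent: float         # all omissions / total input

    def kept_verdicts(self) -> list[FilterVerdict]:
        return [v for v in self.verdicts if v.status != "omitted"]


def round2(value: float) -> float:
    """Truncate to two decimals (the percentage rendering convention:
    390/1626 prints as 23.98, not 23.99)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_DOWN))


# ---------------------------------------------------------------------------
# individual detectors
# ---------------------------------------------------------------------------


def is_generic_comment(record: ReactionRecord) -> bool:
    """Generic/general reaction declared in the REMARK or COMMENT text."""
    text = f"{record.remark} {record.comment}".lower()
    return any(trigger in text for trigger in GENERIC_TRIGGERS)


def is_polymer(record: ReactionRecord) -> bool:
    """Symbolic n/m stoichiometry in the equation."""
    return record.is_symbolic


def is_possible_polymer(record: ReactionRecord) -> bool:
    """Comment text announces polymerization without symbolic coefficients."""
    text = f"{record.comment} {record.remark}".lower()
    return any(trigger in text for trigger in POLYMER_TRIGGERS)


def is_ill_defined(record: ReactionRecord) -> bool:
    """Same participant on both sides of the equation."""
    return bool(set(record.substrates) & set(record.products))


def is_generic_compound(record: CompoundRecord) -> bool:
    """True when every mass field is absent or 0.

    A mass of 0 is KEGG's marker for a generic (R-group) structure. Glycans
    that carry only the ``mass`` field — no ``exact_mass``/``mol_weight`` —
    are *not* generic as long as that mass is positive.
    """
    masses = (record.exact_mass, record.mol_weight, record.mass)
    return not any(m is not None and m > 0 for m in masses)


# ---------------------------------------------------------------------------
# glycan translation
# ---------------------------------------------------------------------------


def _translated_sides(
    record: ReactionRecord, compounds: Mapping[str, CompoundRecord]
) -> tuple[dict, dict] | None:
    """Both equation sides with every glycan replaced by its compound
    cross-reference, or None if any glycan lacks one."""

    def translate(side: Mapping[str, float]) -> dict | None:
        out: dict[str, float] = {}
        for part, coeff in side.items():
            if ids.is_glycan_id(part):
                rec = compounds.get(part)
                if rec is None or rec.same_as is None or not ids.is_compound_id(rec.same_as):
                    return None
                part = rec.same_as
            out[part] = out.get(part, 0) + coeff
        return out

    subs = translate(record.substrates)
    prods = translate(record.products)
    if subs is None or prods is None:
        return None
    return subs, prods


def translate_glycan_reaction(
    record: ReactionRecord,
    compounds: Mapping[str, CompoundRecord],
    universe: Iterable[ReactionRecord],
) -> FilterVerdict:
    """Decide the fate of a reaction with glycan participants.

    If every glycan translates through a "Same as" cross-reference and an
    all-compound reaction with the translated equation exists in the
    reaction universe, that reaction replaces this one. A reaction made
    solely of glycans is omitted outright. Otherwise the glycan reaction is
    kept, flagged for curator attention.
    """
    glycans = record.glycan_participants
    if not glycans:
        raise ValueError(f"{record.id} has no glycan participants")
    pure_glycan = all(ids.is_glycan_id(p) for p in record.participants)
    translated = _translated_sides(record, compounds)

    if translated is not None:
        subs, prods = translated
        for alt in universe:
            if alt.id == record.id or alt.is_symbolic:
                continue
            same = (dict(alt.substrates), dict(alt.products))
            if (subs, prods) in (same, (same[1], same[0])):
                return FilterVerdict(
                    reaction=record.id,
                    status="kept_with_attention",
                    category="glycan_replaced",
                    attention_text=(
                        f"Glycan reaction replaced by the compound-ID "
                        f"alternative {alt.id}"
                    ),
                    replacement=alt.id,
                    substrates=subs,
                    products=prods,
                )
        translated_generic = any(
            (c in compounds and is_generic_compound(compounds[c]))
            for c in {*subs, *prods}
        )
        if pure_glycan or translated_generic:
            return FilterVerdict(
                reaction=record.id,
                status="omitted",
                category="glycan_only_omitted",
                attention_text=(
                    "Glycan reaction without a usable compound-ID alternative"
                ),
                substrates=dict(record.substrates),
                products=dict(record.products),
            )
        return FilterVerdict(
            reaction=record.id,
            status="kept_with_attention",
            category="glycan_kept_no_alternative",
            attention_text=(
                "Reaction contains glycan compounds and no alternative "
                "reaction exists in KEGG"
            ),
            substrates=dict(record.substrates),
            products=dict(record.products),
        )

    if pure_glycan:
        return FilterVerdict(
            reaction=record.id,
            status="omitted",
            category="glycan_only_omitted",
            attention_text="Reaction contains only glycan compounds",
            substrates=dict(record.substrates),
            products=dict(record.products),
        )
    return FilterVerdict(
        reaction=record.id,
        status="kept_with_attention",
        category="glycan_kept_no_alternative",
        attention_text=(
            "Reaction contains glycan compounds and no alternative "
            "reaction exists in KEGG"
        ),
        substrates=dict(record.substrates),
        products=dict(record.products),
    )


# ---------------------------------------------------------------------------
# the full screen
# ---------------------------------------------------------------------------


def apply_filters(
    records: Iterable[ReactionRecord],
    compounds: Mapping[str, CompoundRecord],
) -> OmissionReport:
    """Run every exclusion rule over ``records`` (first match wins).

    Rule order: generic comment -> polymer -> possible polymer -> glycan
    handling -> ill-defined; the compound-mass screen then runs over the
    participants of the reactions that survived. Participants missing from
    the compound map are treated as massless (conservative omission) and
    listed separately. Verdicts are sorted by reaction ID, so the outcome is
    independent of input order.
    """
    records = sorted(records, key=lambda r: r.id)
    verdicts: list[FilterVerdict] = []
    for rec in records:
        sides = dict(substrates=dict(rec.substrates), products=dict(rec.products))
        if is_generic_comment(rec):
            verdicts.append(
                FilterVerdict(
                    rec.id, "omitted", "generic_comment",
                    "Reaction is marked generic/general in KEGG", **sides,
                )
            )
        elif is_polymer(rec):
            verdicts.append(
                FilterVerdict(
                    rec.id, "omitted", "polymer",
                    "Polymerization reaction (symbolic n/m stoichiometry)", **sides,
                )
            )
        elif is_possible_polymer(rec):
            verdicts.append(
                FilterVerdict(
                    rec.id, "omitted", "possible_polymer",
                    "Comment indicates a possible polymerization reaction", **sides,
                )
            )
        elif rec.glycan_participants:
            verdicts.append(translate_glycan_reaction(rec, compounds, records))
        elif is_ill_defined(rec):
            verdicts.append(
                FilterVerdict(
                    rec.id, "omitted", "ill_defined",
                    "Ill-defined: same compound on both sides of the equation",
                    **sides,
                )
            )
        else:
            verdicts.append(FilterVerdict(rec.id, "kept", "none", **sides))

    # compound-mass screen over the survivors' (effective) participants
    evaluated: set[str] = set()
    for v in verdicts:
        if v.status != "omitted":
            evaluated |= {*v.substrates, *v.products}
    generic = sorted(
        c for c in evaluated if c in compounds and is_generic_compound(compounds[c])
    )
    unresolved = sorted(c for c in evaluated if c not in compounds)
    bad = set(generic) | set(unresolved)
    for i, v in enumerate(verdicts):
        if v.status == "omitted":
            continue
        hit = bad & {*v.substrates, *v.products}
        if hit:
            verdicts[i] = FilterVerdict(
                v.reaction, "omitted", "massless_compound",
                MASSLESS_ATTENTION + f" ({', '.join(sorted(hit))})",
                substrates=dict(v.substrates), products=dict(v.products),
            )

    counts: dict[str, int] = {}
    for v in verdicts:
        if v.status == "omitted":
            counts[v.category] = counts.get(v.category, 0) + 1
    total_input = len(verdicts)
    total_omitted = sum(counts.values())
    reaction_filter = sum(
        n for cat, n in counts.items() if cat in REACTION_FILTER_CATEGORIES
    )
    n_eval = len(evaluated)
    return OmissionReport(
        verdicts=verdicts,
        category_counts=counts,
        total_input=total_input,
        total_omitted=total_omitted,
        total_kept=total_input - total_omitted,
        generic_compounds=generic,
        unresolved_compounds=unresolved,
        n_compounds_evaluated=n_eval,
        filter_percent=round2(100 * reaction_filter / total_input) if total_input else 0.0,
        generic_compound_percent=round2(100 * len(generic) / n_eval) if n_eval else 0.0,
        omitted_percent=round2(100 * total_omitted / total_input) if total_input else 0.0,
    )
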