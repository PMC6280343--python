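"""KEGG identifier syntax.

Every KEGG entity class has a distinct identifier grammar, so the category of
an ID is decidable from its text alone:

* reactions ``R`` + 5 digits, compounds ``C`` + 5 digits, glycans ``G`` + 5 digits
* organism codes: 2-4 lowercase letters (``eco``, ``ecj``)
* EC numbers: ``a.b.c.d`` where trailing levels may be ``-`` (partial ECs)
* genes: ``<org>:<locus>``
"""

from __future__ import annotations

import re

_RE_REACTION = re.compile(r"^R\d{5}$")
_RE_COMPOUND = re.compile(r"^C\d{5}$")
_RE_GLYCAN = re.compile(r"^G\d{5}$")
_RE_ORGANISM = re.compile(r"^[a-z]{2,4}$")
_RE_EC = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")
_RE_GENE = re.compile(r"^[a-z]{2,4}:\S+$")


class InvalidKeggId(ValueError):
    """Raised when an identifier does not match any known KEGG grammar."""


def is_reaction_id(value: str) -> bool:
    return bool(_RE_REACTION.match(value))


def is_compound_id(value: str) -> bool:
    return bool(_RE_COMPOUND.match(value))


def is_glycan_id(value: str) -> bool:
    return bool(_RE_GLYCAN.match(value))


def is_participant_id(value: str) -> bool:
    """True for anything allowed in a reaction equation (compound or glycan)."""
    return is_compound_id(value) or is_glycan_id(value)


def is_organism_code(value: str) -> bool:
    return bool(_RE_ORGANISM.match(value))


def is_ec_number(value: str) -> bool:
    return bool(_RE_EC.match(value))


def is_gene_id(value: str) -> bool:
    return bool(_RE_GENE.match(value))


def category(value: str) -> str:
    """Classify an ID by syntax alone.

    Returns one of ``reaction``, ``compound``, ``glycan``, ``ec``, ``gene``,
    ``organism``. Order matters only for organism vs gene, which cannot
    collide (genes contain a colon).
    """
    if is_reaction_id(value):
        return "reaction"
    if is_compound_id(value):
        return "compound"
    if is_glycan_id(value):
        return "glycan"
    if is_ec_number(value):
        return "ec"
    if is_gene_id(value):
        return "gene"
    if is_organism_code(value):
        return "organism"
    raise InvalidKeggId(f"not a recognizable KEGG identifier: {value!r}")


def gene_organism(gene_id: str) -> str:
    """Organism code prefix of a gene ID (``eco:b0507`` -> ``eco``)."""
    if not is_gene_id(gene_id):
        raise InvalidKeggId(f"not a gene identifier: {gene_id!r}")
    return gene_id.split(":", 1)[0]
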