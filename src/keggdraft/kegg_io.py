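"""Acquisition and parsing of KEGG annotation data.

Two interchangeable sources are supported: the live KEGG REST service
(``link``/``get`` verbs) and a local directory of flat files in the same
text format, used both for cached downloads and for offline fixtures. Every
fetched record is written to a plain-text cache (one file per ID) before it
is returned, so a run can be replayed byte-identically without network
access.

KEGG flat-file records are line oriented: a 12-column keyword field followed
by the value, with continuation lines indented; ``///`` terminates a record.
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import ids

ARROWS = ("<=>", "⇔")  # both reversible-arrow dialects KEGG prints

_PARTICIPANT_RE = re.compile(r"[CG]\d{5}")
_NUMERIC_COEFF_RE = re.compile(r"^\d+(\.\d+)?$")
_SAME_AS_RE = re.compile(r"Same as:\s*([CG]\d{5})")


class KeggIOError(RuntimeError):
    pass


class OrganismNotFound(KeggIOError):
    def __init__(self, organism: str):
        super().__init__(f"organism-not-found: {organism!r}")
        self.organism = organism


class SourceUnavailable(KeggIOError):
    pass


class EquationParseError(KeggIOError):
    def __init__(self, message: str, fragment: str):
        super().__init__(f"equation-parse-error: {message}: {fragment!r}")
        self.fragment = fragment


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionRecord:
    """One parsed KEGG reaction entry.

    ``substrates``/``products`` map participant IDs to coefficients. A
    coefficient is a positive float for plain stoichiometry, or the verbatim
    symbolic expression (``"n"``, ``"(n+1)"``, ...) for polymer equations;
    ``is_symbolic`` is set when any coefficient is symbolic.
    """

    id: str
    name: str = ""
    equation_text: str = ""
    substrates: Mapping[str, float | str] = field(default_factory=dict)
    products: Mapping[str, float | str] = field(default_factory=dict)
    is_symbolic: bool = False
    ec_numbers: tuple[str, ...] = ()
    comment: str = ""
    remark: str = ""
    raw_text: str = ""

    @property
    def participants(self) -> set[str]:
        return set(self.substrates) | set(self.products)

    @property
    def glycan_participants(self) -> set[str]:
        return {p for p in self.participants if ids.is_glycan_id(p)}


@dataclass(frozen=True)
class CompoundRecord:
    """One parsed KEGG compound or glycan entry.

    Compounds carry ``exact_mass``/``mol_weight``; glycans carry only
    ``mass``. A mass stored as 0 is preserved — it encodes a generic
    (R-group) structure. ``same_as`` holds the glycan<->compound
    cross-reference taken from the REMARK line, when present.
    """

    id: str
    name: str = ""
    formula: str = ""
    exact_mass: float | None = None
    mol_weight: float | None = None
    mass: float | None = None
    same_as: str | None = None
    raw_text: str = ""

    @property
    def is_glycan(self) -> bool:
        return ids.is_glycan_id(self.id)


@dataclass(frozen=True)
class LinkTable:
    """Deduplicated, ordered (source, target) ID pairs of one link kind."""

    pairs: tuple[tuple[str, str], ...]
    kind: str  # "gene-ec" or "ec-reaction"

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(sorted(set(self.pairs))))

    def sources(self) -> set[str]:
        return {s for s, _ in self.pairs}

    def targets(self) -> set[str]:
        return {t for _, t in self.pairs}


@dataclass
class FetchResult:
    """Records in input-ID order plus the IDs the source could not resolve."""

    records: list[ReactionRecord | CompoundRecord]
    missing: list[str]


# ---------------------------------------------------------------------------
# equation grammar
# ---------------------------------------------------------------------------


def parse_equation(equation_text: str) -> tuple[dict, dict, bool]:
    """Split a KEGG reaction equation into substrate and product maps.

    The grammar is ``side <=> side`` with terms joined by `` + ``; each term
    is ``[coefficient] ID`` where an omitted coefficient means 1. Integer and
    decimal coefficients parse numerically; anything containing the polymer
    symbols ``n``/``m`` (``n``, ``(n+1)``, ``2n``, ``(m)``) is kept verbatim
    and flips ``is_symbolic``.
    """
    arrow = None
    for cand in ARROWS:
        if cand in equation_text:
            arrow = cand
            break
    if arrow is None:
        raise EquationParseError("missing reversible arrow", equation_text)
    left, _, right = equation_text.partition(arrow)
    if arrow in right:
        raise EquationParseError("multiple arrows", equation_text)

    def parse_side(side: str) -> dict:
        out: dict[str, float | str] = {}
        terms = [t.strip() for t in side.split(" + ")]
        for term in terms:
            if not term:
                raise EquationParseError("empty term", side)
            out.update([_parse_term(term)])
        return out

    substrates = parse_side(left)
    products = parse_side(right)
    symbolic = any(
        isinstance(c, str) for c in (*substrates.values(), *products.values())
    )
    return substrates, products, symbolic


def _parse_term(term: str) -> tuple[str, float | str]:
    parts = term.split()
    if len(parts) == 1:
        coeff: float | str = 1.0
        ident = parts[0]
    elif len(parts) == 2:
        raw, ident = parts
        if _NUMERIC_COEFF_RE.match(raw):
            coeff = float(raw)
            if coeff <= 0:
                raise EquationParseError("non-positive coefficient", term)
        elif re.search(r"[nm]", raw):
            coeff = raw
        else:
            raise EquationParseError("unparseable coefficient", term)
    else:
        raise EquationParseError("malformed term", term)
    if not ids.is_participant_id(ident):
        raise EquationParseError("not a compound/glycan ID", term)
    return ident, coeff


# ---------------------------------------------------------------------------
# flat-file record parsing
# ---------------------------------------------------------------------------


def _split_fields(text: str) -> dict[str, list[str]]:
    fields: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        if line.startswith("///"):
            break
        if not line.strip():
            continue
        if line[:1].isspace():
            if current is not None:
                fields[current].append(line.strip())
            continue
        key = line[:12].strip()
        value = line[12:].strip()
        current = key
        fields.setdefault(key, []).append(value)
    return fields


def _first(fields: dict[str, list[str]], key: str) -> str:
    return fields.get(key, [""])[0]


def _joined(fields: dict[str, list[str]], key: str) -> str:
    return " ".join(fields.get(key, []))


def parse_record(text: str) -> ReactionRecord | CompoundRecord:
    """Parse a single KEGG flat-file record, dispatching on the ENTRY line."""
    fields = _split_fields(text)
    entry = _first(fields, "ENTRY").split()
    if not entry:
        raise KeggIOError("record has no ENTRY line")
    entry_id = entry[0]
    if ids.is_reaction_id(entry_id):
        return _parse_reaction(entry_id, fields, text)
    if ids.is_participant_id(entry_id):
        return _parse_compound(entry_id, fields, text)
    raise KeggIOError(f"unsupported record type for entry {entry_id!r}")


def _parse_reaction(entry_id, fields, text) -> ReactionRecord:
    equation = _joined(fields, "EQUATION")
    substrates, products, symbolic = parse_equation(equation)
    if not substrates or not products:
        raise EquationParseError("empty equation side", equation)
    enzymes = tuple(_joined(fields, "ENZYME").split())
    name = _name(fields)
    return ReactionRecord(
        id=entry_id,
        name=name,
        equation_text=equation,
        substrates=substrates,
        products=products,
        is_symbolic=symbolic,
        ec_numbers=enzymes,
        comment=_joined(fields, "COMMENT"),
        remark=_joined(fields, "REMARK"),
        raw_text=text,
    )


def _name(fields) -> str:
    # NAME continuation lines end in ";" in KEGG text; normalize to "; "-joined
    return "; ".join(l.rstrip(";").strip() for l in fields.get("NAME", []))


def _parse_mass(fields, key) -> float | None:
    raw = _first(fields, key)
    if not raw:
        return None
    try:
        return float(raw.split()[0])
    except ValueError:
        return None


def _parse_compound(entry_id, fields, text) -> CompoundRecord:
    remark = _joined(fields, "REMARK")
    same_as = None
    m = _SAME_AS_RE.search(remark)
    if m:
        same_as = m.group(1)
    return CompoundRecord(
        id=entry_id,
        name=_name(fields),
        formula=_first(fields, "FORMULA"),
        exact_mass=_parse_mass(fields, "EXACT_MASS"),
        mol_weight=_parse_mass(fields, "MOL_WEIGHT"),
        mass=_parse_mass(fields, "MASS"),
        same_as=same_as,
        raw_text=text,
    )


def _fmt_coeff(coeff: float | str) -> str:
    if isinstance(coeff, str):
        return f"{coeff} "
    if coeff == 1:
        return ""
    if float(coeff).is_integer():
        return f"{int(coeff)} "
    return f"{coeff} "


def serialize_record(record: ReactionRecord | CompoundRecord) -> str:
    """Render a record back to KEGG flat-file text (parse/serialize round-trips)."""
    lines = []

    def add(key: str, value: str):
        if value:
            lines.append(f"{key:<12}{value}")

    if isinstance(record, ReactionRecord):
        add("ENTRY", f"{record.id:<27} Reaction")
        add("NAME", record.name)
        side = lambda terms: " + ".join(
            f"{_fmt_coeff(c)}{i}" for i, c in terms.items()
        )
        add("EQUATION", f"{side(record.substrates)} <=> {side(record.products)}")
        add("COMMENT", record.comment)
        add("REMARK", record.remark)
        add("ENZYME", " ".join(record.ec_numbers))
    else:
        kind = "Glycan" if record.is_glycan else "Compound"
        add("ENTRY", f"{record.id:<27} {kind}")
        add("NAME", record.name)
        add("FORMULA", record.formula)
        if record.exact_mass is not None:
            add("EXACT_MASS", repr(record.exact_mass))
        if record.mol_weight is not None:
            add("MOL_WEIGHT", repr(record.mol_weight))
        if record.mass is not None:
            add("MASS", repr(record.mass))
        if record.same_as:
            add("REMARK", f"Same as: {record.same_as}")
    lines.append("///")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sources
# ---------------------------------------------------------------------------


@dataclass
class KeggSource:
    """Where KEGG data comes from and how it is cached.

    ``mode="local"`` reads a directory laid out as::

        links/<org>_ec.tsv   gene<TAB>ec pairs for one organism
        links/ec_rxn.tsv     ec<TAB>reaction pairs
        records/<ID>.txt     one flat-file record per entry

    and never touches the network. ``mode="rest"`` talks to the KEGG REST
    API (``link`` and ``get`` verbs, at most ``batch_size`` IDs per ``get``)
    with bounded retries, writing every response into ``cache_dir`` in the
    local layout before returning it, so a populated cache directory is
    itself a valid local source.
    """

    mode: str = "local"
    root: str | Path = "https://rest.kegg.jp"
    cache_dir: Path | None = None
    batch_size: int = 10
    max_attempts: int = 3
    backoff_seconds: float = 1.0

    def __post_init__(self):
        if self.mode not in ("rest", "local"):
            raise ValueError(f"unknown source mode {self.mode!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.cache_dir is not None:
            self.cache_dir = Path(self.cache_dir)
        self.records_fetched = 0  # record lookups served (stage-skipping audits)

    # -- internals ---------------------------------------------------------

    def _local_root(self) -> Path:
        return Path(self.root)

    def _cache_record_path(self, entry_id: str) -> Path | None:
        if self.cache_dir is None:
            return None
        return self.cache_dir / "records" / f"{entry_id}.txt"

    def _http_get(self, path: str) -> str:
        import requests

        url = f"{str(self.root).rstrip('/')}/{path}"
        last_exc: Exception | None = None
        for attempt in range(self.max_attempts):
            try:
                resp = requests.get(url, timeout=60)
                if resp.status_code == 404:
                    raise OrganismNotFound(path.rsplit("/", 1)[-1])
                resp.raise_for_status()
                return resp.text
            except OrganismNotFound:
                raise
            except Exception as exc:  # noqa: BLE001 - retried, then wrapped
                last_exc = exc
                time.sleep(self.backoff_seconds * (attempt + 1))
        raise SourceUnavailable(f"source-unavailable: {url}: {last_exc}")

    def _read_record_text(self, entry_id: str) -> str | None:
        cache_path = self._cache_record_path(entry_id)
        if cache_path is not None and cache_path.exists():
            return cache_path.read_text()
        if self.mode == "local":
            path = self._local_root() / "records" / f"{entry_id}.txt"
            if not path.exists():
                return None
            text = path.read_text()
            self._write_cache(entry_id, text)
            return text
        return None  # rest mode fetches in batches elsewhere

    def _write_cache(self, entry_id: str, text: str):
        cache_path = self._cache_record_path(entry_id)
        if cache_path is not None:
            cache_path.parent.mkdir(parents=True, exist_ok=True)
            cache_path.write_text(text)


def _strip_prefix(token: str) -> str:
    return token.split(":", 1)[1] if token.split(":", 1)[0] in (
        "ec",
        "rn",
        "cpd",
        "gl",
    ) else token


def fetch_gene_ec_links(source: KeggSource, organism: str) -> LinkTable:
    """All (gene, EC) pairs KEGG holds for one organism, sorted by gene then EC.

    Partial EC numbers (trailing ``-``) are kept and linked like full ECs.
    """
    if not ids.is_organism_code(organism):
        raise OrganismNotFound(organism)
    if source.mode == "local":
        path = source._local_root() / "links" / f"{organism}_ec.tsv"
        if not path.exists():
            raise OrganismNotFound(organism)
        text = path.read_text()
    else:
        text = source._http_get(f"link/enzyme/{organism}")
        if source.cache_dir is not None:
            out = source.cache_dir / "links" / f"{organism}_ec.tsv"
            out.parent.mkdir(parents=True, exist_ok=True)
            out.write_text(text)
    pairs = []
    for line in text.splitlines():
        if not line.strip():
            continue
        gene, ec = line.split("\t")[:2]
        pairs.append((_strip_prefix(gene), _strip_prefix(ec)))
    return LinkTable(pairs=tuple(pairs), kind="gene-ec")


def fetch_ec_reaction_links(source: KeggSource, ec_numbers: Iterable[str]) -> LinkTable:
    """(EC, reaction) pairs restricted to the query ECs.

    ECs with no reaction links simply contribute no pairs. Duplicate query
    ECs behave as if deduplicated.
    """
    query = set(ec_numbers)
    if not query:
        raise ValueError("ec_numbers must be non-empty")
    if source.mode == "local":
        path = source._local_root() / "links" / "ec_rxn.tsv"
        if not path.exists():
            raise SourceUnavailable(f"source-unavailable: {path}")
        text = path.read_text()
    else:
        text = source._http_get("link/reaction/enzyme")
        if source.cache_dir is not None:
            out = source.cache_dir / "links" / "ec_rxn.tsv"
            out.parent.mkdir(parents=True, exist_ok=True)
            out.write_text(text)
    pairs = []
    for line in text.splitlines():
        if not line.strip():
            continue
        ec, rxn = line.split("\t")[:2]
        ec, rxn = _strip_prefix(ec), _strip_prefix(rxn)
        if ec in query:
            pairs.append((ec, rxn))
    return LinkTable(pairs=tuple(pairs), kind="ec-reaction")


def fetch_records(source: KeggSource, entry_ids: Sequence[str]) -> FetchResult:
    """Fetch and parse records for ``entry_ids``, preserving input order.

    Cache hits bypass the source entirely; in rest mode cache misses are
    requested in batches of at most ``source.batch_size`` IDs per ``get``
    call. IDs the source cannot resolve are returned in ``missing`` rather
    than silently dropped.
    """
    for entry_id in entry_ids:
        if not (ids.is_reaction_id(entry_id) or ids.is_participant_id(entry_id)):
            raise KeggIOError(f"not a fetchable record ID: {entry_id!r}")
    texts: dict[str, str] = {}
    missing: list[str] = []
    unresolved: list[str] = []
    for entry_id in dict.fromkeys(entry_ids):
        source.records_fetched += 1
        text = source._read_record_text(entry_id)
        if text is not None:
            texts[entry_id] = text
        elif source.mode == "rest":
            unresolved.append(entry_id)
        else:
            missing.append(entry_id)
    for start in range(0, len(unresolved), source.batch_size):
        batch = unresolved[start : start + source.batch_size]
        raw = source._http_get("get/" + "+".join(batch))
        for chunk in raw.split("///\n"):
            if not chunk.strip():
                continue
            chunk_text = chunk + "///\n"
            entry = chunk_text.split(None, 2)
            if len(entry) < 2:
                continue
            texts[entry[1]] = chunk_text
            source._write_cache(entry[1], chunk_text)
        for entry_id in batch:
            if entry_id not in texts:
                missing.append(entry_id)
    records = [
        parse_record(texts[entry_id])
        for entry_id in dict.fromkeys(entry_ids)
        if entry_id in texts
    ]
    return FetchResult(records=records, missing=missing)
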