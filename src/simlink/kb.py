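"""Target knowledge base: concept gazetteers and alias merging.

The linking target space is defined by a flat gazetteer file mapping concept
codes (e.g. SNOMED CT identifiers) to surface terms.  Each concept keeps one
canonical (preferred) name plus a set of aliases with free-form language tags.
Additional alias sources (e.g. UMLS-style term tables) can be merged in, but
they never extend the set of target codes: the gazetteer alone defines which
concepts exist.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "Concept",
    "KnowledgeBase",
    "GazetteerSchemaError",
    "UnknownCodeError",
    "DEFAULT_COLUMN_MAP",
    "load_gazetteer",
    "merge_aliases",
    "canonical_name",
    "save_kb_json",
    "load_kb_json",
]


class GazetteerSchemaError(ValueError):
    """Raised when a gazetteer file does not match the expected schema."""


class UnknownCodeError(KeyError):
    """Raised when a concept code is not present in the knowledge base."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep message readable
        return self.args[0] if self.args else ""


#: Default column names for gazetteer / alias-table TSV files.  ``language``
#: and ``canonical`` are optional in the file; ``code`` and ``term`` are not.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "code": "code",
    "term": "term",
    "language": "language",
    "canonical": "mainterm",
}

_TRUTHY = {"1", "true", "yes", "y", "t"}


@dataclass(frozen=True)
class Concept:
    """A single target concept: a code, a preferred name and its aliases.

    ``aliases`` is a frozenset of ``(term, language)`` pairs; the canonical
    name is always a member of the alias set.
    """

    code: str
    canonical_name: str
    aliases: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("concept code must be non-empty")
        if not self.canonical_name.strip():
            raise ValueError(f"canonical name for {self.code!r} is empty")
        if not self.aliases:
            raise ValueError(f"concept {self.code!r} has no aliases")
        if not any(term == self.canonical_name for term, _ in self.aliases):
            raise ValueError(
                f"canonical name {self.canonical_name!r} of {self.code!r} "
                "is not among its aliases"
            )
        for term, _ in self.aliases:
            if not term.strip():
                raise ValueError(f"concept {self.code!r} has an empty alias")

    @property
    def alias_terms(self) -> list[str]:
        """Distinct alias surface strings, sorted."""
        return sorted({term for term, _ in self.aliases})


@dataclass
class KnowledgeBase:
    """Immutable-by-convention container of concepts, keyed by code.

    Iteration order is deterministic (sorted by code).
    """

    concepts: dict[str, Concept] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concepts = {code: self.concepts[code] for code in sorted(self.concepts)}

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, code: object) -> bool:
        return code in self.concepts

    def __getitem__(self, code: str) -> Concept:
        try:
            return self.concepts[code]
        except KeyError:
            raise UnknownCodeError(f"unknown concept code {code!r}") from None

    def __iter__(self) -> Iterator[Concept]:
        return iter(self.concepts.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return self.concepts == other.concepts

    @property
    def languages(self) -> set[str]:
        return {lang for c in self for _, lang in c.aliases}

    @property
    def n_aliases(self) -> int:
        """Total number of distinct (code, term, language) triples."""
        return sum(len(c.aliases) for c in self)

    def iter_aliases(self) -> Iterator[tuple[str, str, str]]:
        """Yield (code, term, language) triples in deterministic order."""
        for concept in self:
            for term, lang in sorted(concept.aliases):
                yield concept.code, term, lang

    def canonical_name(self, code: str) -> str:
        return self[code].canonical_name


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gazetteer file not found: {path}")
    frame = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    if frame.shape[0] == 0:
        raise GazetteerSchemaError(f"{path} contains a header but no data rows")
    return frame


def load_gazetteer(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> KnowledgeBase:
    """Load a tab-separated gazetteer into a :class:`KnowledgeBase`.

    Parameters
    ----------
    path:
        UTF-8 TSV file with a header row.
    column_map:
        Maps the roles ``code``, ``term``, ``language``, ``canonical`` to
        column names in the file.  ``code`` and ``term`` must resolve to
        existing columns; ``language`` and ``canonical`` may be absent from
        the file, in which case the language tag defaults to ``""`` and the
        first-seen term per code becomes the canonical name.

    Notes
    -----
    Terms are trimmed of surrounding whitespace but otherwise stored
    losslessly (case folding happens inside retrieval, not here).  Duplicate
    (code, term, language) rows are deduplicated; rows whose term is empty
    after trimming are dropped.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    frame = _read_table(path)

    for role in ("code", "term"):
        if cmap[role] not in frame.columns:
            raise GazetteerSchemaError(
                f"required column {cmap[role]!r} (role: {role}) missing from {path}"
            )
    has_lang = cmap.get("language") in frame.columns
    has_flag = cmap.get("canonical") in frame.columns

    flagged_canonical: dict[str, str] = {}
    first_seen: dict[str, str] = {}
    aliases: dict[str, set[tuple[str, str]]] = {}
    for record in frame.to_dict("records"):
        code = str(record[cmap["code"]]).strip()
        term = str(record[cmap["term"]]).strip()
        if not code or not term:
            continue
        lang = str(record[cmap["language"]]).strip() if has_lang else ""
        aliases.setdefault(code, set()).add((term, lang))
        first_seen.setdefault(code, term)
        if has_flag and str(record[cmap["canonical"]]).strip().casefold() in _TRUTHY:
            flagged_canonical.setdefault(code, term)

    if not aliases:
        raise GazetteerSchemaError(f"{path} contains no usable rows")

    concepts = {
        code: Concept(
            code=code,
            canonical_name=flagged_canonical.get(code, first_seen[code]),
            aliases=frozenset(pairs),
        )
        for code, pairs in aliases.items()
    }
    return KnowledgeBase(concepts)


def merge_aliases(
    kb: KnowledgeBase,
    alias_table: Iterable[tuple[str, str, str]],
) -> KnowledgeBase:
    """Return a new KB with extra (code, term, language) aliases merged in.

    Codes absent from ``kb`` are skipped: the gazetteer defines the target
    space.  Canonical names and the concept count never change, and alias
    sets only grow.
    """
    extra: dict[str, set[tuple[str, str]]] = {}
    for code, term, lang in alias_table:
        code, term = str(code).strip(), str(term).strip()
        if not term or code not in kb:
            continue
        extra.setdefault(code, set()).add((term, str(lang).strip()))
    if not extra:
        return KnowledgeBase(dict(kb.concepts))

    concepts = dict(kb.concepts)
    for code, pairs in extra.items():
        old = concepts[code]
        concepts[code] = Concept(
            code=old.code,
            canonical_name=old.canonical_name,
            aliases=old.aliases | frozenset(pairs),
        )
    return KnowledgeBase(concepts)


def load_alias_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[tuple[str, str, str]]:
    """Read a UMLS-style alias-extension TSV as (code, term, language) rows."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    frame = _read_table(path)
    for role in ("code", "term"):
        if cmap[role] not in frame.columns:
            raise GazetteerSchemaError(
                f"required column {cmap[role]!r} (role: {role}) missing from {path}"
            )
    has_lang = cmap.get("language") in frame.columns
    rows = []
    for record in frame.to_dict("records"):
        lang = str(record[cmap["language"]]).strip() if has_lang else ""
        rows.append((str(record[cmap["code"]]).strip(), str(record[cmap["term"]]).strip(), lang))
    return rows


def canonical_name(kb: KnowledgeBase, code: str) -> str:
    """Preferred term of ``code``; raises :class:`UnknownCodeError` if absent."""
    return kb.canonical_name(code)


def save_kb_json(kb: KnowledgeBase, path: str | Path) -> None:
    """Serialize a KB to a single JSON file for fast reload."""
    payload = {
        c.code: {
            "canonical": c.canonical_name,
            "aliases": [{"term": t, "lang": l} for t, l in sorted(c.aliases)],
        }
        for c in kb
    }
    Path(path).write_text(json.dumps(payload, ensure_ascii=False), encoding="utf-8")


def load_kb_json(path: str | Path) -> KnowledgeBase:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    concepts = {
        code: Concept(
            code=code,
            canonical_name=entry["canonical"],
            aliases=frozenset((a["term"], a["lang"]) for a in entry["aliases"]),
        )
        for code, entry in payload.items()
    }
    return KnowledgeBase(concepts)
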