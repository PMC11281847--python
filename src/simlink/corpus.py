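"""Mention-annotated corpora: standoff TSV reading, filtering, splitting.

Annotations follow the shared-task exchange dialect: a UTF-8 TSV with header
columns ``filename``, ``label``, ``start_span``, ``end_span``, ``text``,
``code``.  Offsets are 0-based character positions with an exclusive end.
Document texts, when available, live in a directory of ``<doc_id>.txt`` files
and are used to verify span/text consistency.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Mention",
    "Corpus",
    "LengthStats",
    "CorpusValidationError",
    "read_corpus",
    "filter_composites",
    "split_corpus",
    "corpus_stats",
    "write_predictions",
]

COLUMNS = ["filename", "label", "start_span", "end_span", "text", "code"]

#: Code values treated as "no code assigned".
_MISSING_CODES = {"", "NO_CODE", "NOCODE", "NIL"}


class CorpusValidationError(ValueError):
    """Raised for malformed rows or span/text mismatches."""


@dataclass(frozen=True)
class Mention:
    """One annotated span: where it is, what it says, what it links to."""

    doc_id: str
    start: int
    end: int
    text: str
    gold_code: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CorpusValidationError(
                f"mention in {self.doc_id!r} has end {self.end} <= start {self.start}"
            )
        if not self.text:
            raise CorpusValidationError(f"empty mention text in {self.doc_id!r}")

    @property
    def n_tokens(self) -> int:
        """Whitespace-token count (any Unicode whitespace run delimits)."""
        return len(self.text.split())

    def sort_key(self) -> tuple[str, int, int]:
        return (self.doc_id, self.start, self.end)


@dataclass
class Corpus:
    """An ordered sequence of mentions, optionally backed by document texts."""

    mentions: list[Mention]
    documents: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.mentions = sorted(self.mentions, key=Mention.sort_key)
        if self.documents is not None:
            missing = {m.doc_id for m in self.mentions} - set(self.documents)
            if missing:
                raise CorpusValidationError(
                    f"mentions reference documents without text: {sorted(missing)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.mentions)

    def __iter__(self) -> Iterator[Mention]:
        return iter(self.mentions)

    @property
    def doc_ids(self) -> list[str]:
        return sorted({m.doc_id for m in self.mentions})

    def subset(self, doc_ids: Iterable[str]) -> "Corpus":
        keep = set(doc_ids)
        docs = (
            {d: t for d, t in self.documents.items() if d in keep}
            if self.documents is not None
            else None
        )
        return Corpus([m for m in self.mentions if m.doc_id in keep], docs)


@dataclass(frozen=True)
class LengthStats:
    """Mention-length summary in whitespace tokens."""

    n_mentions: int
    mean_len: float
    median_len: float
    max_len: int


def read_corpus(
    annotations_path: str | Path,
    documents_dir: str | Path | None = None,
) -> Corpus:
    """Read a standoff annotation TSV (and optionally its document texts).

    When ``documents_dir`` is given, every mention's span is checked against
    ``document[start:end]``; a mismatch raises :class:`CorpusValidationError`
    naming the document and offsets.
    """
    annotations_path = Path(annotations_path)
    if not annotations_path.exists():
        raise FileNotFoundError(f"annotation file not found: {annotations_path}")
    frame = pd.read_csv(
        annotations_path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    missing_cols = [c for c in COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CorpusValidationError(
            f"{annotations_path} is missing columns {missing_cols}"
        )

    mentions: list[Mention] = []
    for i, record in enumerate(frame.to_dict("records")):
        line_no = i + 2  # header is line 1
        try:
            start = int(record["start_span"])
            end = int(record["end_span"])
        except ValueError as exc:
            raise CorpusValidationError(
                f"{annotations_path}:{line_no}: non-integer span offsets"
            ) from exc
        code = str(record["code"]).strip()
        try:
            mentions.append(
                Mention(
                    doc_id=str(record["filename"]).strip(),
                    start=start,
                    end=end,
                    text=str(record["text"]),
                    gold_code=None if code in _MISSING_CODES else code,
                    label=str(record["label"]).strip(),
                )
            )
        except CorpusValidationError as exc:
            raise CorpusValidationError(f"{annotations_path}:{line_no}: {exc}") from None

    documents = None
    if documents_dir is not None:
        documents_dir = Path(documents_dir)
        documents = {
            p.stem: p.read_text(encoding="utf-8")
            for p in sorted(documents_dir.glob("*.txt"))
        }
        for m in mentions:
            doc = documents.get(m.doc_id)
            if doc is None:
                raise CorpusValidationError(f"no document text for {m.doc_id!r}")
            if doc[m.start : m.end] != m.text:
                raise CorpusValidationError(
                    f"span mismatch in {m.doc_id!r} at ({m.start},{m.end}): "
                    f"document has {doc[m.start:m.end]!r}, annotation says {m.text!r}"
                )
    return Corpus(mentions, documents)


def filter_composites(corpus: Corpus) -> Corpus:
    """Drop composite mentions (multiple codes per span) and unlinked mentions.

    A composite mention carries several concept codes joined by ``+`` in its
    code field; these (and mentions with no code at all) are excluded from
    single-code linking evaluation.  Order is preserved and the operation is
    idempotent.
    """
    kept = [
        m
        for m in corpus.mentions
        if m.gold_code is not None and "+" not in m.gold_code
    ]
    return Corpus(kept, corpus.documents)


def split_corpus(
    corpus: Corpus, val_fraction: float, seed: int
) -> tuple[Corpus, Corpus]:
    """Document-level train/validation split.

    All mentions of a document land on the same side; the validation side
    receives ``round(val_fraction * n_documents)`` documents.  Deterministic
    given ``seed``.
    """
    if not 0 < val_fraction < 1:
        raise ValueError(f"val_fraction must be in (0, 1), got {val_fraction}")
    docs = corpus.doc_ids
    if len(docs) < 2:
        raise ValueError(f"cannot split a corpus with {len(docs)} document(s)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(docs))
    n_val = int(np.floor(val_fraction * len(docs) + 0.5))
    val_docs = {docs[i] for i in order[:n_val]}
    train_docs = [d for d in docs if d not in val_docs]
    return corpus.subset(train_docs), corpus.subset(val_docs)


def corpus_stats(corpus: Corpus) -> LengthStats:
    """Mention-length statistics in whitespace-separated tokens."""
    if len(corpus) == 0:
        raise ValueError("cannot compute statistics of an empty corpus")
    lengths = [m.n_tokens for m in corpus]
    return LengthStats(
        n_mentions=len(lengths),
        mean_len=float(np.mean(lengths)),
        median_len=float(statistics.median(lengths)),
        max_len=int(max(lengths)),
    )


def write_predictions(
    predictions: Sequence[tuple[Mention, str]], path: str | Path
) -> None:
    """Write (mention, predicted code) pairs in the standoff TSV dialect.

    Every mention must carry exactly one non-empty predicted code (no NIL);
    ``read_corpus`` of the written file round-trips the mentions with the
    predictions in the ``code`` column.
    """
    for mention, code in predictions:
        if not code or not str(code).strip():
            raise ValueError(
                f"missing prediction for mention {mention.text!r} in "
                f"{mention.doc_id!r}; NIL predictions are not allowed"
            )
    rows = sorted(predictions, key=lambda p: p[0].sort_key())
    frame = pd.DataFrame(
        [
            {
                "filename": m.doc_id,
                "label": m.label,
                "start_span": m.start,
                "end_span": m.end,
                "text": m.text,
                "code": str(code).strip(),
            }
            for m, code in rows
        ],
        columns=COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")
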