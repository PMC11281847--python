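"""Candidate generation: character n-gram TF-IDF retrieval over KB aliases.

Candidate concepts for a mention are found by cosine k-nearest-neighbour
search between the mention vector and alias vectors.  The sparse retriever
vectorizes text with raw term frequencies of character 3-grams, a smoothed
inverse document frequency ln((1+A)/(1+df)) + 1 over the A indexed aliases,
and L2 row normalization — so a mention that exactly matches an alias scores
a cosine of 1.0 (a "direct lookup").  A concept's score is the maximum cosine
over its aliases.

The dense side of the ensemble is a contract (:class:`Retriever`); this
module ships a deterministic hashed-character embedder as a lightweight
implementation, with the same interface an external sentence encoder adapter
would use.  Score fusion takes the maximum per-retriever score, so a direct
lookup keeps its 1.0 confidence through the ensemble.
"""

from __future__ import annotations

import json
import zlib
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from functools import partial
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.base import BaseEstimator
from sklearn.feature_extraction.text import TfidfVectorizer

from .kb import KnowledgeBase, UnknownCodeError

__all__ = [
    "char_ngrams",
    "Candidate",
    "CandidateList",
    "Retriever",
    "SparseNgramRetriever",
    "HashedCharRetriever",
    "build_sparse_index",
    "retrieve_sparse",
    "score_pair",
    "ensemble_retrieve",
    "save_index",
    "load_index",
    "write_candidates_jsonl",
    "read_candidates_jsonl",
]

DEFAULT_K = 64
_SCORE_TOL = 1e-9


def char_ngrams(text: str, n: int = 3) -> list[str]:
    """Case-folded character n-grams, with multiplicity.

    Windows are contiguous substrings of length ``n`` and cross token
    boundaries (internal whitespace is kept).  Text shorter than ``n`` yields
    the whole folded string as a single gram; the empty string yields nothing.
    """
    if n < 1:
        raise ValueError(f"n-gram length must be >= 1, got {n}")
    folded = text.casefold()
    if not folded:
        return []
    if len(folded) < n:
        return [folded]
    return [folded[i : i + n] for i in range(len(folded) - n + 1)]


@dataclass(frozen=True)
class Candidate:
    """A scored candidate concept for one mention."""

    code: str
    score: float
    source: str = "sparse"  # sparse | dense | fused
    best_alias: str = ""

    def __post_init__(self) -> None:
        if not -_SCORE_TOL <= self.score <= 1.0 + _SCORE_TOL:
            raise ValueError(f"candidate score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class CandidateList:
    """A ranked candidate shortlist for one mention (length <= k).

    Scores are non-increasing; ties are broken by higher sparse score, then
    lexicographically smaller code, making the order total and reproducible.
    """

    mention_text: str
    candidates: tuple[Candidate, ...]
    k: int = DEFAULT_K
    #: retrieval output is score-sorted; reranked permutations are not
    require_sorted: bool = True

    def __post_init__(self) -> None:
        scores = [c.score for c in self.candidates]
        if self.require_sorted and any(
            a < b - _SCORE_TOL for a, b in zip(scores, scores[1:])
        ):
            raise ValueError("candidate scores must be non-increasing")
        codes = [c.code for c in self.candidates]
        if len(set(codes)) != len(codes):
            raise ValueError("candidate codes must be unique within a list")
        if len(self.candidates) > self.k:
            raise ValueError(f"{len(self.candidates)} candidates exceed k={self.k}")

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self) -> Iterator[Candidate]:
        return iter(self.candidates)

    @property
    def codes(self) -> list[str]:
        return [c.code for c in self.candidates]

    @property
    def top(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None

    def rank_of(self, code: str) -> int | None:
        """1-based rank of ``code`` in the list, or None if absent."""
        for i, c in enumerate(self.candidates, start=1):
            if c.code == code:
                return i
        return None


class Retriever(ABC):
    """Contract for candidate generators.

    ``score_pair(q, c)`` must equal the score ``retrieve`` would assign to
    concept ``c`` whenever ``c`` is retrieved, and must be defined for every
    (query, code) pair over the indexed KB.
    """

    @abstractmethod
    def retrieve(self, query: str, k: int = DEFAULT_K) -> CandidateList: ...

    @abstractmethod
    def score_pair(self, query: str, code: str) -> float: ...


class _AliasScoringRetriever(Retriever):
    """Shared ranking logic for retrievers that score every indexed alias.

    Subclasses provide ``_alias_sims(query) -> per-alias cosine array`` and the
    fitted attributes ``alias_codes_``, ``alias_terms_``, ``codes_``,
    ``owner_idx_``, ``code_rows_`` and ``source``.
    """

    source = "sparse"

    def _alias_sims(self, query: str) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def _finalize_owner_tables(self) -> None:
        self.codes_, self.owner_idx_ = np.unique(self.alias_codes_, return_inverse=True)
        order = np.argsort(self.owner_idx_, kind="stable")
        bounds = np.searchsorted(self.owner_idx_[order], np.arange(len(self.codes_) + 1))
        self.code_rows_ = {
            str(code): order[bounds[i] : bounds[i + 1]]
            for i, code in enumerate(self.codes_)
        }

    def retrieve(self, query: str, k: int = DEFAULT_K) -> CandidateList:
        if k < 1:
            raise ValueError(f"retrieval depth k must be >= 1, got {k}")
        sims = self._alias_sims(query)
        if sims is None or not np.any(sims > 0):
            return CandidateList(query, (), k=k)
        concept_scores = np.zeros(len(self.codes_))
        np.maximum.at(concept_scores, self.owner_idx_, sims)
        nz = np.flatnonzero(concept_scores > 0)
        # rank by (-score, code); codes_ is sorted so lexsort's secondary key works
        order = nz[np.lexsort((self.codes_[nz], -concept_scores[nz]))][:k]
        candidates = []
        for ci in order:
            rows = self.code_rows_[self.codes_[ci]]
            row_sims = sims[rows]
            best = row_sims.max()
            best_aliases = [self.alias_terms_[r] for r in rows[row_sims >= best - _SCORE_TOL]]
            candidates.append(
                Candidate(
                    code=str(self.codes_[ci]),
                    score=float(min(concept_scores[ci], 1.0)),
                    source=self.source,
                    best_alias=min(best_aliases),
                )
            )
        return CandidateList(query, tuple(candidates), k=k)

    def score_pair(self, query: str, code: str) -> float:
        rows = self.code_rows_.get(code)
        if rows is None:
            raise UnknownCodeError(f"unknown concept code {code!r}")
        sims = self._alias_sims(query)
        if sims is None:
            return 0.0
        return float(min(sims[rows].max(), 1.0))


class SparseNgramRetriever(BaseEstimator, _AliasScoringRetriever):
    """TF-IDF character n-gram retriever over knowledge-base aliases.

    Parameters
    ----------
    n:
        Character n-gram length (default 3).

    Attributes (after :meth:`fit`)
    ------------------------------
    vectorizer_ : TfidfVectorizer
        Raw-tf, smooth-idf, L2-normalized vectorizer over character n-grams.
    matrix_ : scipy.sparse.csr_matrix
        One L2-normalized row per indexed alias.
    alias_codes_, alias_terms_ : per-row owner code and alias surface text.
    codes_ : sorted array of indexed concept codes.
    """

    source = "sparse"

    def __init__(self, n: int = 3):
        self.n = n

    def fit(self, kb: KnowledgeBase, y: None = None) -> "SparseNgramRetriever":
        if len(kb) == 0:
            raise ValueError("cannot index an empty knowledge base")
        owners = [(code, term) for code, term, _ in kb.iter_aliases()]
        # language variants of the same surface form collapse to one row
        owners = sorted({(code, term) for code, term in owners})
        if not owners:
            raise ValueError("knowledge base has no aliases to index")
        self.alias_codes_ = np.array([c for c, _ in owners], dtype=object)
        self.alias_terms_ = [t for _, t in owners]
        self.vectorizer_ = TfidfVectorizer(
            analyzer=partial(char_ngrams, n=self.n),
            norm="l2",
            smooth_idf=True,
            sublinear_tf=False,
        )
        self.matrix_ = sp.csr_matrix(self.vectorizer_.fit_transform(self.alias_terms_))
        self._finalize_owner_tables()
        return self

    def _alias_sims(self, query: str) -> np.ndarray | None:
        q = self.vectorizer_.transform([query])
        if q.nnz == 0:
            return None
        return np.asarray((self.matrix_ @ q.T).todense()).ravel()


class HashedCharRetriever(BaseEstimator, _AliasScoringRetriever):
    """Deterministic dense retriever: hashed character n-gram embeddings.

    Character n-gram counts are hashed (CRC32) into ``dim`` buckets and L2
    normalized, giving non-negative embeddings whose cosines lie in [0, 1].
    It fulfils the dense-retriever contract with full determinism and no
    pretrained weights; an external sentence-encoder adapter can implement
    the same :class:`Retriever` interface.
    """

    source = "dense"

    def __init__(self, dim: int = 256, n: int = 3):
        self.dim = dim
        self.n = n

    def _embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        for gram in char_ngrams(text, self.n):
            vec[zlib.crc32(gram.encode("utf-8")) % self.dim] += 1.0
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def fit(self, kb: KnowledgeBase, y: None = None) -> "HashedCharRetriever":
        if len(kb) == 0:
            raise ValueError("cannot index an empty knowledge base")
        owners = sorted({(code, term) for code, term, _ in kb.iter_aliases()})
        self.alias_codes_ = np.array([c for c, _ in owners], dtype=object)
        self.alias_terms_ = [t for _, t in owners]
        self.matrix_ = np.vstack([self._embed(t) for t in self.alias_terms_])
        self._finalize_owner_tables()
        return self

    def _alias_sims(self, query: str) -> np.ndarray | None:
        q = self._embed(query)
        if not np.any(q):
            return None
        return self.matrix_ @ q


def build_sparse_index(kb: KnowledgeBase, n: int = 3) -> SparseNgramRetriever:
    """Fit a :class:`SparseNgramRetriever` over all KB aliases."""
    return SparseNgramRetriever(n=n).fit(kb)


def retrieve_sparse(
    index: SparseNgramRetriever, query: str, k: int = DEFAULT_K
) -> CandidateList:
    """Top-k concepts for ``query`` by max-over-aliases cosine."""
    return index.retrieve(query, k)


def score_pair(index: Retriever, query: str, code: str) -> float:
    """Cosine between ``query`` and the best alias of ``code``."""
    return index.score_pair(query, code)


def ensemble_retrieve(
    retrievers: Sequence[Retriever], query: str, k: int = DEFAULT_K
) -> CandidateList:
    """Max-fusion of several retrievers' shortlists.

    The union of each retriever's top-k is rescored: every retriever
    contributes ``score_pair(query, code)`` for every union member, and the
    fused score is the per-code maximum, so no retriever's score is ever
    decreased by fusion and a direct lookup keeps confidence 1.0.  Ties break
    by the first retriever's score (the sparse one, by convention), then by
    code.
    """
    if not retrievers:
        raise ValueError("ensemble requires at least one retriever")
    lists = [r.retrieve(query, k) for r in retrievers]
    if len(retrievers) == 1:
        return lists[0]

    union: dict[str, dict[int, Candidate]] = {}
    for ri, clist in enumerate(lists):
        for cand in clist:
            union.setdefault(cand.code, {})[ri] = cand

    fused: list[tuple[float, float, str, Candidate]] = []
    for code, found in union.items():
        scores = []
        for ri, retriever in enumerate(retrievers):
            if ri in found:
                scores.append(found[ri].score)
            else:
                scores.append(retriever.score_pair(query, code))
        best_ri = int(np.argmax(scores))
        best_alias = (
            found[best_ri].best_alias
            if best_ri in found
            else next(iter(found.values())).best_alias
        )
        fused.append(
            (
                float(min(max(scores), 1.0)),
                float(scores[0]),  # sparse tie-break score
                code,
                Candidate(code=code, score=float(min(max(scores), 1.0)),
                          source="fused", best_alias=best_alias),
            )
        )
    fused.sort(key=lambda row: (-row[0], -row[1], row[2]))
    return CandidateList(query, tuple(row[3] for row in fused[:k]), k=k)


def save_index(index: SparseNgramRetriever, directory: str | Path) -> None:
    """Persist a fitted sparse index as text files (JSON + MatrixMarket + TSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "vectorizer.json").write_text(
        json.dumps(
            {
                "n": index.n,
                "vocabulary": {g: int(i) for g, i in index.vectorizer_.vocabulary_.items()},
                "idf": index.vectorizer_.idf_.tolist(),
            },
            ensure_ascii=False,
        ),
        encoding="utf-8",
    )
    mmwrite(str(directory / "alias_matrix.mtx"), index.matrix_)
    with open(directory / "alias_owner.tsv", "w", encoding="utf-8") as fh:
        fh.write("code\tterm\n")
        for code, term in zip(index.alias_codes_, index.alias_terms_):
            fh.write(f"{code}\t{term}\n")


def load_index(directory: str | Path) -> SparseNgramRetriever:
    """Reload an index persisted by :func:`save_index`."""
    directory = Path(directory)
    meta = json.loads((directory / "vectorizer.json").read_text(encoding="utf-8"))
    index = SparseNgramRetriever(n=int(meta["n"]))
    vectorizer = TfidfVectorizer(
        analyzer=partial(char_ngrams, n=index.n),
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
        vocabulary={g: int(i) for g, i in meta["vocabulary"].items()},
    )
    vectorizer._validate_vocabulary()
    vectorizer.idf_ = np.asarray(meta["idf"], dtype=float)
    index.vectorizer_ = vectorizer
    index.matrix_ = sp.csr_matrix(mmread(str(directory / "alias_matrix.mtx")))
    codes, terms = [], []
    with open(directory / "alias_owner.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            code, term = line.rstrip("\n").split("\t")
            codes.append(code)
            terms.append(term)
    index.alias_codes_ = np.array(codes, dtype=object)
    index.alias_terms_ = terms
    index._finalize_owner_tables()
    return index


def write_candidates_jsonl(
    records: Sequence[tuple[str, CandidateList]], path: str | Path
) -> None:
    """Serialize per-mention candidate lists as JSON Lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for mention_id, clist in records:
            fh.write(
                json.dumps(
                    {
                        "mention_id": mention_id,
                        "mention_text": clist.mention_text,
                        "k": clist.k,
                        "candidates": [
                            {
                                "code": c.code,
                                "score": c.score,
                                "source": c.source,
                                "best_alias": c.best_alias,
                            }
                            for c in clist
                        ],
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_candidates_jsonl(path: str | Path) -> list[tuple[str, CandidateList]]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            obj = json.loads(line)
            clist = CandidateList(
                obj["mention_text"],
                tuple(Candidate(**c) for c in obj["candidates"]),
                k=obj["k"],
            )
            records.append((obj["mention_id"], clist))
    return records
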