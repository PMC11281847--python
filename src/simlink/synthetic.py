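"""Synthetic knowledge bases, corpora and oracle simplifiers.

The generator emulates the statistical structure that confidence-gated
mention simplification assumes, at desk scale and with full determinism:

* a KB of concepts with globally unique, pronounceable pseudo-word aliases
  (so the exact-match ⇒ cosine 1.0 property is unambiguous);
* a corpus mixing *simple* mentions — an alias verbatim, optionally with
  per-character noise — and *complex* mentions — verbose spans that wrap a
  partially or fully paraphrased form of the concept's canonical name in
  filler tokens.  Filler tokens come from a consonant alphabet disjoint from
  the alias alphabet, so they never collide with alias tokens and reliably
  depress retrieval confidence.  Fully paraphrased cores share almost no
  character 3-grams with any alias, reproducing the situation where the
  candidate generator misses the gold concept entirely;
* an oracle map from each complex mention to the canonical name of its gold
  concept, from which a deterministic oracle simplifier is built.  An
  adversarial variant additionally maps a fraction of *simple* mentions to a
  wrong concept's canonical name, modelling over-eager generalization — the
  failure mode that makes simplifying high-confidence mentions harmful.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Corpus, Mention
from .kb import Concept, KnowledgeBase
from .simplify import Simplifier, extract_query_mention

__all__ = [
    "SynthParams",
    "OracleMap",
    "OracleSimplifier",
    "generate_kb",
    "generate_corpus",
    "oracle_simplifier",
    "make_adversarial_map",
    "write_dataset",
]

_ALIAS_CONSONANTS = list("bcdfglmnprst")
_FILLER_CONSONANTS = list("jkqvxz")
_VOWELS = list("aeiou")


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration.

    ``p_complex`` is the proportion of verbose mentions; ``p_full_paraphrase``
    is, among complex mentions, the probability that *every* canonical token
    is paraphrased (near-zero alias overlap) rather than only some.
    ``char_noise`` corrupts simple mentions per character; ``oracle_failure``
    is the probability the oracle echoes its input instead of simplifying.
    """

    n_concepts: int = 1000
    aliases_per_concept: tuple[int, int] = (1, 3)
    n_mentions: int = 5000
    p_complex: float = 0.5
    n_filler: int = 50
    char_noise: float = 0.0
    oracle_failure: float = 0.0
    p_full_paraphrase: float = 0.5
    mentions_per_doc: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_complex", "char_noise", "oracle_failure", "p_full_paraphrase"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value}")
        if self.n_concepts < 2:
            raise ValueError("need at least 2 concepts")
        lo, hi = self.aliases_per_concept
        if not 1 <= lo <= hi:
            raise ValueError("aliases_per_concept must be a range with 1 <= lo <= hi")


#: mention text -> canonical name of its gold concept
OracleMap = dict[str, str]


def _syllable(rng: np.random.Generator, consonants: Sequence[str]) -> str:
    return consonants[rng.integers(len(consonants))] + _VOWELS[rng.integers(5)]


def _token(rng: np.random.Generator, consonants: Sequence[str]) -> str:
    return "".join(_syllable(rng, consonants) for _ in range(rng.integers(2, 5)))


def _unique_tokens(
    rng: np.random.Generator, count: int, consonants: Sequence[str], taken: set[str]
) -> list[str]:
    tokens: list[str] = []
    attempts = 0
    while len(tokens) < count:
        token = _token(rng, consonants)
        attempts += 1
        if attempts > 50 * count + 1000:
            raise RuntimeError(
                "token vocabulary exhausted; requested aliases exceed the "
                "collision-free vocabulary"
            )
        if token not in taken:
            taken.add(token)
            tokens.append(token)
    return tokens


def generate_kb(params: SynthParams) -> KnowledgeBase:
    """Generate a KB of pseudo-word concepts.

    Each concept owns a private pool of globally unique tokens; its canonical
    name uses 1–3 of them and further aliases are distinct combinations of
    the same pool, so alias strings are globally unique across concepts.

    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    taken: set[str] = set()
    concepts: dict[str, Concept] = {}
    lo, hi = params.aliases_per_concept
    for i in range(params.n_concepts):
        code = f"C{i + 1:06d}"
        pool = _unique_tokens(rng, 4, _ALIAS_CONSONANTS, taken)
        n_canonical = int(rng.integers(1, 4))
        canonical = " ".join(pool[:n_canonical])
        aliases = {(canonical, "xx")}
        n_aliases = int(rng.integers(lo, hi + 1))
        while len(aliases) < n_aliases:
            size = int(rng.integers(1, len(pool) + 1))
            combo = list(rng.permutation(pool)[:size])
            aliases.add((" ".join(combo), "xx"))
        concepts[code] = Concept(
            code=code, canonical_name=canonical, aliases=frozenset(aliases)
        )
    return KnowledgeBase(concepts)


def _noisy(rng: np.random.Generator, text: str, rate: float) -> str:
    if rate <= 0:
        return text
    letters = "abcdefghijklmnopqrstuvwxyz"
    chars = [
        letters[rng.integers(26)] if c != " " and rng.random() < rate else c
        for c in text
    ]
    return "".join(chars)


def _paraphrase_token(rng: np.random.Generator, token: str) -> str:
    """Rewrite a token so it shares almost no character 3-grams with the original."""
    n_syllables = max(2, len(token) // 2)
    return "".join(_syllable(rng, _ALIAS_CONSONANTS) for _ in range(n_syllables))


def generate_corpus(
    kb: KnowledgeBase, params: SynthParams
) -> tuple[Corpus, OracleMap]:
    """Generate a mention corpus over ``kb`` plus its simplification oracle.

    Simple mentions copy a random alias of the concept (with per-character
    noise at ``char_noise``).  Complex mentions wrap a partially-to-fully
    paraphrased form of the canonical name in 2–6 filler tokens, guaranteeing
    at least 2 extra tokens over the core, and are recorded in the oracle map
    pointing at the canonical name.  Mentions are packed into documents with
    exact character offsets.
    """
    rng = np.random.default_rng(params.seed + 1)
    filler_vocab = _unique_tokens(rng, params.n_filler, _FILLER_CONSONANTS, set())
    codes = [c.code for c in kb]

    mention_rows: list[tuple[str, str]] = []  # (text, gold code)
    oracle: OracleMap = {}
    for _ in range(params.n_mentions):
        code = codes[rng.integers(len(codes))]
        concept = kb[code]
        if rng.random() >= params.p_complex:
            alias = concept.alias_terms[rng.integers(len(concept.alias_terms))]
            text = _noisy(rng, alias, params.char_noise)
            if not text.strip():
                text = alias
            mention_rows.append((text, code))
            continue
        core_tokens = concept.canonical_name.split()
        if rng.random() < params.p_full_paraphrase:
            n_keep = 0
        else:
            n_keep = int(rng.integers(1, len(core_tokens) + 1))
        keep = set(rng.permutation(len(core_tokens))[:n_keep])
        core = [
            tok if j in keep else _paraphrase_token(rng, tok)
            for j, tok in enumerate(core_tokens)
        ]
        n_filler_tokens = int(rng.integers(2, 7))
        fillers = [
            filler_vocab[rng.integers(len(filler_vocab))]
            for _ in range(n_filler_tokens)
        ]
        cut = int(rng.integers(0, n_filler_tokens + 1))
        text = " ".join(fillers[:cut] + core + fillers[cut:])
        oracle[text] = concept.canonical_name
        mention_rows.append((text, code))

    # pack mentions into documents with exact offsets
    mentions: list[Mention] = []
    documents: dict[str, str] = {}
    per_doc = max(1, params.mentions_per_doc)
    for doc_index in range(0, len(mention_rows), per_doc):
        doc_id = f"doc{doc_index // per_doc + 1:05d}"
        parts: list[str] = []
        cursor = 0
        for text, code in mention_rows[doc_index : doc_index + per_doc]:
            prefix = f"{filler_vocab[rng.integers(len(filler_vocab))]} "
            parts.append(prefix)
            cursor += len(prefix)
            mentions.append(
                Mention(
                    doc_id=doc_id,
                    start=cursor,
                    end=cursor + len(text),
                    text=text,
                    gold_code=code,
                    label="SYMPTOM",
                )
            )
            parts.append(text + ". ")
            cursor += len(text) + 2
        documents[doc_id] = "".join(parts)
    return Corpus(mentions, documents), oracle


class OracleSimplifier(Simplifier):
    """Deterministic stand-in for a generative rewriting model.

    Mapped inputs return their target rewriting; unmapped inputs are echoed.
    With ``failure > 0`` a per-mention deterministic coin (seeded, hash
    based, order-invariant) makes the oracle echo mapped inputs too.
    """

    backend_id = "oracle"

    def __init__(self, mapping: OracleMap, failure: float = 0.0, seed: int = 0):
        if not 0.0 <= failure <= 1.0:
            raise ValueError(f"failure must be a probability, got {failure}")
        self.mapping = dict(mapping)
        self.failure = failure
        self.seed = seed

    def _fails_on(self, mention: str) -> bool:
        if self.failure <= 0.0:
            return False
        if self.failure >= 1.0:
            return True
        # stable per-mention coin: CRC32 is process-independent, unlike hash()
        digest = np.random.default_rng(
            [self.seed, zlib.crc32(mention.encode("utf-8"))]
        ).random()
        return digest < self.failure

    def simplify(self, prompt: str) -> str:
        mention = extract_query_mention(prompt)
        target = self.mapping.get(mention)
        if target is None or self._fails_on(mention):
            return mention
        return target


def oracle_simplifier(
    mapping: OracleMap, failure: float = 0.0, seed: int = 0
) -> OracleSimplifier:
    """Build the oracle backend over a recorded mention → canonical-name map."""
    return OracleSimplifier(mapping, failure=failure, seed=seed)


def make_adversarial_map(
    kb: KnowledgeBase,
    corpus: Corpus,
    oracle: OracleMap,
    fraction: float = 0.5,
    seed: int = 0,
) -> OracleMap:
    """Extend an oracle map with harmful rewrites of simple mentions.

    A ``fraction`` of the mentions *not* covered by the oracle map (the
    simple, high-confidence ones) are mapped to the canonical name of a
    different, random concept — emulating a rewriter that over-generalizes
    already-linkable mentions to the wrong granularity.  Gating every mention
    (threshold 1.0) under this map degrades recall@1, while a lower selected
    threshold leaves those mentions untouched.
    """
    rng = np.random.default_rng(seed)
    codes = [c.code for c in kb]
    adversarial = dict(oracle)
    simple = sorted(
        {m.text for m in corpus if m.text not in oracle},
    )
    texts_by_mention = {m.text: m.gold_code for m in corpus}
    chosen = [simple[i] for i in rng.permutation(len(simple))[: int(fraction * len(simple))]]
    for text in chosen:
        gold = texts_by_mention[text]
        wrong = codes[rng.integers(len(codes))]
        while wrong == gold:
            wrong = codes[rng.integers(len(codes))]
        adversarial[text] = kb.canonical_name(wrong)
    return adversarial


def write_dataset(
    directory: str | Path,
    kb: KnowledgeBase,
    corpus: Corpus,
    oracle: OracleMap,
) -> None:
    """Write a generated dataset in the on-disk dialects the loaders read.

    Produces ``gazetteer.tsv``, ``mentions.tsv``, ``docs/<doc_id>.txt`` and
    ``oracle_map.tsv`` under ``directory``.
    """
    directory = Path(directory)
    (directory / "docs").mkdir(parents=True, exist_ok=True)
    with open(directory / "gazetteer.tsv", "w", encoding="utf-8") as fh:
        fh.write("code\tterm\tlanguage\tmainterm\n")
        for concept in kb:
            fh.write(f"{concept.code}\t{concept.canonical_name}\txx\t1\n")
            for term, lang in sorted(concept.aliases):
                if term != concept.canonical_name:
                    fh.write(f"{concept.code}\t{term}\t{lang}\t0\n")
    with open(directory / "mentions.tsv", "w", encoding="utf-8") as fh:
        fh.write("filename\tlabel\tstart_span\tend_span\ttext\tcode\n")
        for m in corpus:
            fh.write(
                f"{m.doc_id}\t{m.label}\t{m.start}\t{m.end}\t{m.text}\t{m.gold_code or ''}\n"
            )
    if corpus.documents:
        for doc_id, text in sorted(corpus.documents.items()):
            (directory / "docs" / f"{doc_id}.txt").write_text(text, encoding="utf-8")
    with open(directory / "oracle_map.tsv", "w", encoding="utf-8") as fh:
        fh.write("mention\tcanonical\n")
        for mention, canonical in sorted(oracle.items()):
            fh.write(f"{mention}\t{canonical}\n")
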