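"""Mention simplification: few-shot prompting, pluggable backends, caching.

Complex mentions — long, descriptive spans with little lexical overlap with
any dictionary alias — are rewritten into shorter, more canonical phrasings
before retrieval is repeated.  The rewriter is a generative model behind a
minimal contract (:class:`Simplifier`): it receives a few-shot prompt whose
in-context examples pair a training mention with the canonical name of its
gold concept, and returns a single rewritten mention.  A deterministic
oracle backend (see :mod:`simlink.synthetic`) and an identity backend allow
the full pipeline to run without any external model; a generic chat
completion adapter covers hosted models.

All backend calls are cached in an append-only JSON Lines store keyed by
(backend id, prompt-template hash, mention text), so repeated runs over the
same corpus never re-invoke the backend.
"""

from __future__ import annotations

import hashlib
import json
import os
import re
import time
import urllib.request
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .kb import KnowledgeBase
from .retrieve import CandidateList

__all__ = [
    "FewShotExample",
    "PromptTemplate",
    "SimplificationRecord",
    "Simplifier",
    "IdentitySimplifier",
    "CallableSimplifier",
    "ChatSimplifier",
    "SimplifierBackendError",
    "JsonlCache",
    "SimplifierPipeline",
    "select_few_shot_examples",
    "build_prompt",
    "simplify_mention",
    "extract_query_mention",
]

DEFAULT_INSTRUCTION = (
    "Simplify the following symptom mention so it can be matched to a medical "
    "terminology; keep the original language; return only the simplified mention."
)

#: Default manually curated example demonstrating that an easily linkable
#: mention should be returned unchanged.
IDENTITY_EXAMPLE_TEXT = "disnea"


class SimplifierBackendError(RuntimeError):
    """A backend failed after the configured number of retries."""


@dataclass(frozen=True)
class FewShotExample:
    """An in-context pair: a training mention and its target rewriting."""

    mention_text: str
    target_text: str

    def __post_init__(self) -> None:
        if not self.mention_text or not self.target_text:
            raise ValueError("few-shot example texts must be non-empty")


@dataclass(frozen=True)
class PromptTemplate:
    """Few-shot prompt layout: an instruction plus fenced example blocks.

    Each in-context example renders as an input/output pair delimited by
    triple backticks; the query mention renders as a final fenced input with
    an open output slot, so a rendered prompt contains exactly
    ``2 * n_examples + 1`` fenced segments.
    """

    instruction: str = DEFAULT_INSTRUCTION
    n_examples: int = 4

    def render(self, examples: Sequence[FewShotExample], mention: str) -> str:
        if len(examples) != self.n_examples:
            raise ValueError(
                f"template expects {self.n_examples} examples, got {len(examples)}"
            )
        if not mention.strip():
            raise ValueError("mention must be non-empty")
        blocks = [self.instruction, ""]
        for ex in examples:
            blocks.append(f"Input: ```{ex.mention_text}```")
            blocks.append(f"Output: ```{ex.target_text}```")
            blocks.append("")
        blocks.append(f"Input: ```{mention}```")
        blocks.append("Output:")
        return "\n".join(blocks)

    def fingerprint(self, examples: Sequence[FewShotExample]) -> str:
        """Stable hash of the template with its examples (cache component)."""
        payload = json.dumps(
            {
                "instruction": self.instruction,
                "examples": [[e.mention_text, e.target_text] for e in examples],
            },
            ensure_ascii=False,
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


@dataclass(frozen=True)
class SimplificationRecord:
    """Audit record of one simplification attempt."""

    original: str
    simplified: str
    changed: bool
    backend_id: str
    cached: bool = False

    def __post_init__(self) -> None:
        if not self.simplified:
            raise ValueError("simplified text must be non-empty (fallback to original)")
        if self.changed != (self.original.strip() != self.simplified.strip()):
            raise ValueError("changed flag inconsistent with texts")


class Simplifier(ABC):
    """Backend contract: a pure function from prompt text to output text.

    Failures must surface as :class:`SimplifierBackendError`, never as silent
    empty output; postprocessing and fallback live in the caller.
    """

    backend_id: str = "abstract"

    @abstractmethod
    def simplify(self, prompt: str) -> str: ...


class IdentitySimplifier(Simplifier):
    """Echoes the query mention back; the do-nothing baseline backend."""

    backend_id = "identity"

    def simplify(self, prompt: str) -> str:
        return extract_query_mention(prompt)


class CallableSimplifier(Simplifier):
    """Wraps any ``mention -> text`` function as a backend (testing hook)."""

    def __init__(self, fn, backend_id: str = "callable"):
        self._fn = fn
        self.backend_id = backend_id

    def simplify(self, prompt: str) -> str:
        return self._fn(extract_query_mention(prompt))


class ChatSimplifier(Simplifier):
    """Generic HTTP chat-completion adapter (OpenAI-style JSON schema).

    The endpoint URL, model label and token limit come from configuration;
    the API key is read from the environment variable named by ``key_env``.
    Temperature is fixed to 0 for determinism.  Transport errors are retried
    ``retries`` times, then raised as :class:`SimplifierBackendError`.
    """

    def __init__(
        self,
        endpoint: str,
        model: str,
        max_tokens: int = 64,
        retries: int = 2,
        key_env: str = "SIMLINK_API_KEY",
        timeout: float = 30.0,
    ):
        self.endpoint = endpoint
        self.model = model
        self.max_tokens = max_tokens
        self.retries = retries
        self.key_env = key_env
        self.timeout = timeout
        self.backend_id = f"chat:{model}"

    def simplify(self, prompt: str) -> str:
        payload = json.dumps(
            {
                "model": self.model,
                "messages": [{"role": "user", "content": prompt}],
                "temperature": 0,
                "max_tokens": self.max_tokens,
            }
        ).encode("utf-8")
        headers = {"Content-Type": "application/json"}
        key = os.environ.get(self.key_env)
        if key:
            headers["Authorization"] = f"Bearer {key}"
        last_error: Exception | None = None
        for _ in range(self.retries + 1):
            try:
                request = urllib.request.Request(
                    self.endpoint, data=payload, headers=headers
                )
                with urllib.request.urlopen(request, timeout=self.timeout) as resp:
                    body = json.loads(resp.read().decode("utf-8"))
                return body["choices"][0]["message"]["content"]
            except Exception as exc:  # transport or schema failure
                last_error = exc
        raise SimplifierBackendError(
            f"backend {self.backend_id!r} failed after {self.retries + 1} attempts: "
            f"{last_error}"
        )


_FENCE_RE = re.compile(r"```([^`]*)```", re.DOTALL)


def extract_query_mention(prompt: str) -> str:
    """Return the query mention (last fenced segment) of a rendered prompt."""
    fenced = _FENCE_RE.findall(prompt)
    if not fenced:
        raise ValueError("prompt contains no fenced segments")
    return fenced[-1]


def select_few_shot_examples(
    train_results: Sequence[tuple[str, CandidateList, str]],
    kb: KnowledgeBase,
    n_sampled: int = 3,
    seed: int = 0,
) -> list[FewShotExample]:
    """Sample in-context examples from candidate-generation failures.

    The failure set contains training mentions whose gold concept is absent
    from their retrieved top-k.  ``n_sampled`` mentions are drawn without
    replacement (all of them if fewer exist), each paired with the canonical
    name of its gold concept.  Sampling happens over the sorted, deduplicated
    mention texts, so the selection is deterministic given ``seed`` and
    invariant to the order of ``train_results``.

    Parameters
    ----------
    train_results:
        ``(mention_text, candidate_list, gold_code)`` triples.
    """
    if not train_results:
        raise ValueError("train_results must be non-empty")
    failures: dict[str, str] = {}
    for mention_text, clist, gold_code in train_results:
        if gold_code not in clist.codes:
            failures.setdefault(mention_text, kb.canonical_name(gold_code))
    if not failures:
        raise ValueError(
            "no retrieval failures to sample from; supply manual examples instead"
        )
    texts = sorted(failures)
    rng = np.random.default_rng(seed)
    picked = [texts[i] for i in rng.permutation(len(texts))[:n_sampled]]
    return [FewShotExample(t, failures[t]) for t in picked]


def build_prompt(
    template: PromptTemplate, examples: Sequence[FewShotExample], mention: str
) -> str:
    """Render the few-shot prompt for one mention (injective in the mention)."""
    return template.render(examples, mention)


class JsonlCache:
    """Append-only JSON Lines cache of simplification results."""

    def __init__(self, path: str | Path | None):
        self.path = Path(path) if path is not None else None
        self._store: dict[str, str] = {}
        if self.path is not None and self.path.exists():
            with open(self.path, encoding="utf-8") as fh:
                for line in fh:
                    if line.strip():
                        obj = json.loads(line)
                        self._store[obj["key"]] = obj["simplified"]

    def __len__(self) -> int:
        return len(self._store)

    def get(self, key: str) -> str | None:
        return self._store.get(key)

    def put(self, key: str, original: str, simplified: str, backend_id: str) -> None:
        if key in self._store:
            return
        self._store[key] = simplified
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(
                    json.dumps(
                        {
                            "key": key,
                            "original": original,
                            "simplified": simplified,
                            "backend_id": backend_id,
                            "timestamp": time.time(),
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )


def _postprocess(output: str) -> str:
    """Strip whitespace and any backtick fences from backend output."""
    text = output.strip()
    match = _FENCE_RE.search(text)
    if match:
        text = match.group(1)
    return text.strip().strip("`").strip()


def simplify_mention(
    backend: Simplifier,
    prompt: str,
    cache: JsonlCache | None = None,
    *,
    original: str | None = None,
    cache_key: str | None = None,
) -> SimplificationRecord:
    """Run one mention through a backend, with cache short-circuiting.

    Empty or whitespace-only backend output falls back to the original
    mention with ``changed=False``; backend errors propagate as
    :class:`SimplifierBackendError`.
    """
    if original is None:
        original = extract_query_mention(prompt)
    key = cache_key or hashlib.sha256(
        f"{backend.backend_id}\x1f{prompt}".encode("utf-8")
    ).hexdigest()
    cached_value = cache.get(key) if cache is not None else None
    if cached_value is not None:
        simplified = cached_value
        was_cached = True
    else:
        simplified = _postprocess(backend.simplify(prompt))
        was_cached = False
        if cache is not None:
            cache.put(key, original, simplified or original, backend.backend_id)
    if not simplified.strip():
        simplified = original
    return SimplificationRecord(
        original=original,
        simplified=simplified,
        changed=original.strip() != simplified.strip(),
        backend_id=backend.backend_id,
        cached=was_cached,
    )


@dataclass
class SimplifierPipeline:
    """Prompt template + examples + backend + cache, applied per mention.

    The cache key hashes the backend id, the template fingerprint (which
    covers the instruction and the in-context examples) and the mention text,
    so any prompt-altering change invalidates the cache.
    """

    backend: Simplifier
    template: PromptTemplate = field(default_factory=PromptTemplate)
    examples: tuple[FewShotExample, ...] = ()
    cache: JsonlCache | None = None
    n_backend_calls: int = 0
    n_cache_hits: int = 0

    def __post_init__(self) -> None:
        if not self.examples:
            # minimal built-in examples: template demands n_examples blocks
            base = [
                FewShotExample(
                    "aumento de densidad en lóbulo inferior", "lesión de pulmón"
                ),
                FewShotExample("afebril", "temperature corporal normal"),  # sic
                FewShotExample(
                    "pérdida de fuerza en miembro inferior izquierdo",
                    "disminución de fuerza",
                ),
            ]
            identity = FewShotExample(IDENTITY_EXAMPLE_TEXT, IDENTITY_EXAMPLE_TEXT)
            self.examples = tuple(base[: self.template.n_examples - 1]) + (identity,)

    def cache_key(self, mention: str) -> str:
        fingerprint = self.template.fingerprint(self.examples)
        return hashlib.sha256(
            f"{self.backend.backend_id}\x1f{fingerprint}\x1f{mention}".encode("utf-8")
        ).hexdigest()

    def __call__(self, mention: str) -> SimplificationRecord:
        prompt = build_prompt(self.template, self.examples, mention)
        record = simplify_mention(
            self.backend,
            prompt,
            self.cache,
            original=mention,
            cache_key=self.cache_key(mention),
        )
        if record.cached:
            self.n_cache_hits += 1
        else:
            self.n_backend_calls += 1
        return record
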