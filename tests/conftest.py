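"""Shared fixtures: hand-built KBs and small generated datasets."""

import pytest

from simlink.kb import Concept, KnowledgeBase
from simlink.retrieve import build_sparse_index
from simlink.synthetic import SynthParams, generate_corpus, generate_kb


def make_kb(entries: dict[str, list[str]]) -> KnowledgeBase:
    """KB from {code: [alias, ...]}; the first alias is canonical."""
    return KnowledgeBase(
        {
            code: Concept(
                code=code,
                canonical_name=aliases[0],
                aliases=frozenset((a, "es") for a in aliases),
            )
            for code, aliases in entries.items()
        }
    )


@pytest.fixture
def tiny_kb() -> KnowledgeBase:
    return make_kb(
        {
            "C1": ["fiebre", "pirexia"],
            "C2": ["disnea"],
            "C3": ["dolor de cabeza", "cefalea"],
            "C4": ["tos"],
        }
    )


@pytest.fixture(scope="session")
def synth_small():
    """A 60-concept / 200-mention dataset shared across tests (read-only)."""
    params = SynthParams(n_concepts=60, n_mentions=200, seed=11)
    kb = generate_kb(params)
    corpus, oracle = generate_corpus(kb, params)
    return params, kb, corpus, oracle


@pytest.fixture(scope="session")
def synth_small_index(synth_small):
    _, kb, _, _ = synth_small
    return build_sparse_index(kb)
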