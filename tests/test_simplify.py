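"""Few-shot prompting, example selection, backend caching and fallback."""

import re

import pytest

from simlink.kb import Concept, KnowledgeBase
from simlink.retrieve import Candidate, CandidateList
from simlink.simplify import (
    CallableSimplifier,
    FewShotExample,
    IdentitySimplifier,
    JsonlCache,
    PromptTemplate,
    SimplifierBackendError,
    SimplifierPipeline,
    build_prompt,
    extract_query_mention,
    select_few_shot_examples,
    simplify_mention,
)

FENCED = re.compile(r"```[^`]*```", re.DOTALL)


def four_examples():
    return [FewShotExample(f"mention {i}", f"target {i}") for i in range(4)]


class TestBuildPrompt:
    def test_contains_nine_fenced_segments(self):
        prompt = build_prompt(PromptTemplate(), four_examples(), "disnea")
        assert len(FENCED.findall(prompt)) == 9  # 4 examples x 2 + 1 query

    def test_example_pair_renders_verbatim(self):
        examples = four_examples()[:3] + [
            FewShotExample("afebril", "temperature corporal normal")
        ]
        prompt = build_prompt(PromptTemplate(), examples, "disnea")
        assert "```afebril```" in prompt
        assert "```temperature corporal normal```" in prompt

    def test_query_is_last_fenced_segment(self):
        prompt = build_prompt(PromptTemplate(), four_examples(), "dolor toracico")
        assert extract_query_mention(prompt) == "dolor toracico"

    def test_injective_in_mention(self):
        template, examples = PromptTemplate(), four_examples()
        assert build_prompt(template, examples, "a") != build_prompt(template, examples, "b")

    def test_wrong_example_count_raises(self):
        with pytest.raises(ValueError, match="4"):
            build_prompt(PromptTemplate(), four_examples()[:2], "disnea")

    def test_empty_mention_raises(self):
        with pytest.raises(ValueError):
            build_prompt(PromptTemplate(), four_examples(), "   ")


def results_with_failures(kb):
    """(text, candidate list, gold) triples where three mentions miss gold."""
    hit = CandidateList("ok", (Candidate("C1", 0.9, "sparse", "fiebre"),), k=4)
    triples = [("mención acertada", hit, "C1")]
    for i, text in enumerate(["frase compleja una", "frase compleja dos", "otra frase"]):
        wrong = CandidateList(text, (Candidate("C1", 0.4, "sparse", "fiebre"),), k=4)
        triples.append((text, wrong, f"C{i + 2}"))
    return triples


@pytest.fixture
def small_kb():
    return KnowledgeBase(
        {
            f"C{i}": Concept(f"C{i}", name, frozenset([(name, "es")]))
            for i, name in enumerate(
                ["fiebre", "cefalea", "disnea", "tos"], start=1
            )
        }
    )


class TestSelectFewShotExamples:
    def test_exhaustive_when_failures_equal_request(self, small_kb):
        picked = select_few_shot_examples(results_with_failures(small_kb), small_kb, 3, seed=0)
        assert {e.mention_text for e in picked} == {
            "frase compleja una", "frase compleja dos", "otra frase"
        }

    def test_targets_are_canonical_names(self, small_kb):
        picked = select_few_shot_examples(results_with_failures(small_kb), small_kb, 3, seed=0)
        by_text = {e.mention_text: e.target_text for e in picked}
        assert by_text["frase compleja una"] == "cefalea"

    def test_deterministic_and_order_invariant(self, small_kb):
        triples = results_with_failures(small_kb)
        a = select_few_shot_examples(triples, small_kb, 2, seed=9)
        b = select_few_shot_examples(list(reversed(triples)), small_kb, 2, seed=9)
        assert a == b

    def test_rank_beyond_k_is_a_failure(self, small_kb):
        # gold present in KB but absent from the shortlist => failure set member
        clist = CandidateList("m", tuple(
            Candidate(f"C{j}", 0.5 - j * 0.01, "sparse", "x") for j in range(1, 4)
        ), k=3)
        picked = select_few_shot_examples([("m", clist, "C4")], small_kb, 1, seed=0)
        assert picked[0].mention_text == "m"

    def test_empty_failure_set_raises(self, small_kb):
        hit = CandidateList("ok", (Candidate("C1", 1.0, "sparse", "fiebre"),), k=4)
        with pytest.raises(ValueError, match="manual"):
            select_few_shot_examples([("ok", hit, "C1")], small_kb, 3, seed=0)


class TestSimplifyMention:
    def test_oracle_style_backend_changes_text(self):
        backend = CallableSimplifier(
            lambda m: "lesión de pulmón", backend_id="stub"
        )
        prompt = build_prompt(
            PromptTemplate(), four_examples(), "aumento de densidad en lóbulo inferior"
        )
        record = simplify_mention(backend, prompt)
        assert record.simplified == "lesión de pulmón"
        assert record.changed

    def test_echoing_backend_is_unchanged(self):
        prompt = build_prompt(PromptTemplate(), four_examples(), "disnea")
        record = simplify_mention(IdentitySimplifier(), prompt)
        assert not record.changed
        assert record.simplified == "disnea"

    def test_empty_output_falls_back_to_original(self):
        backend = CallableSimplifier(lambda m: "   ", backend_id="empty")
        prompt = build_prompt(PromptTemplate(), four_examples(), "disnea")
        record = simplify_mention(backend, prompt)
        assert record.simplified == "disnea"
        assert not record.changed

    def test_fenced_output_is_unwrapped(self):
        backend = CallableSimplifier(lambda m: "```tos```", backend_id="fency")
        prompt = build_prompt(PromptTemplate(), four_examples(), "tos persistente")
        assert simplify_mention(backend, prompt).simplified == "tos"

    def test_backend_error_propagates(self):
        class Broken(IdentitySimplifier):
            def simplify(self, prompt):
                raise SimplifierBackendError("down")

        prompt = build_prompt(PromptTemplate(), four_examples(), "disnea")
        with pytest.raises(SimplifierBackendError):
            simplify_mention(Broken(), prompt)


class TestChatAdapter:
    def make_fake_urlopen(self, replies, calls):
        import contextlib, io, json

        @contextlib.contextmanager
        def fake_urlopen(request, timeout=None):
            calls.append(json.loads(request.data.decode("utf-8")))
            reply = replies.pop(0)
            if isinstance(reply, Exception):
                raise reply
            yield io.BytesIO(json.dumps(
                {"choices": [{"message": {"content": reply}}]}
            ).encode("utf-8"))

        return fake_urlopen

    def test_posts_prompt_and_returns_content(self, monkeypatch):
        from simlink.simplify import ChatSimplifier
        import urllib.request

        calls = []
        monkeypatch.setattr(
            urllib.request, "urlopen", self.make_fake_urlopen(["tos"], calls)
        )
        backend = ChatSimplifier("http://localhost/v1/chat", model="m0")
        prompt = build_prompt(PromptTemplate(), four_examples(), "tos persistente")
        assert backend.simplify(prompt) == "tos"
        assert calls[0]["temperature"] == 0
        assert calls[0]["messages"][0]["content"] == prompt

    def test_retries_then_raises_typed_error(self, monkeypatch):
        from simlink.simplify import ChatSimplifier
        import urllib.request

        calls = []
        monkeypatch.setattr(
            urllib.request,
            "urlopen",
            self.make_fake_urlopen([OSError("down")] * 3, calls),
        )
        backend = ChatSimplifier("http://localhost/v1/chat", model="m0", retries=2)
        prompt = build_prompt(PromptTemplate(), four_examples(), "tos")
        with pytest.raises(SimplifierBackendError, match="3 attempts"):
            backend.simplify(prompt)
        assert len(calls) == 3


class TestCaching:
    def test_second_call_hits_cache_without_backend(self, tmp_path):
        calls = []

        def backend_fn(mention):
            calls.append(mention)
            return "simplificado"

        pipeline = SimplifierPipeline(
            CallableSimplifier(backend_fn, backend_id="b1"),
            cache=JsonlCache(tmp_path / "cache.jsonl"),
        )
        first = pipeline("mención compleja")
        second = pipeline("mención compleja")
        assert first.simplified == second.simplified == "simplificado"
        assert not first.cached and second.cached
        assert calls == ["mención compleja"]

    def test_cache_persists_across_pipelines(self, tmp_path):
        path = tmp_path / "cache.jsonl"
        calls = []
        make = lambda: SimplifierPipeline(
            CallableSimplifier(lambda m: calls.append(m) or "x", backend_id="b1"),
            cache=JsonlCache(path),
        )
        make()("frase")
        record = make()("frase")
        assert record.cached
        assert calls == ["frase"]

    def test_different_backend_id_invalidates(self, tmp_path):
        path = tmp_path / "cache.jsonl"
        for backend_id in ("b1", "b2"):
            pipeline = SimplifierPipeline(
                CallableSimplifier(lambda m: f"via {backend_id}", backend_id=backend_id),
                cache=JsonlCache(path),
            )
            record = pipeline("frase")
            assert not record.cached

    def test_template_change_invalidates(self, tmp_path):
        path = tmp_path / "cache.jsonl"
        outputs = []
        for instruction in ("Simplifica.", "Resume."):
            pipeline = SimplifierPipeline(
                CallableSimplifier(lambda m: "y", backend_id="b"),
                template=PromptTemplate(instruction=instruction),
                cache=JsonlCache(path),
            )
            outputs.append(pipeline("frase").cached)
        assert outputs == [False, False]
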