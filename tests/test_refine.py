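"""Word-level and LLM refinement: Jaccard properties, oracle equivalence,
subset/k-bound invariants, prompt construction and response parsing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vaxmap as vm
from vaxmap.errors import ValidationError
from vaxmap.refine import MockLlmClient

from conftest import make_graph

token_sets = st.frozensets(
    st.sampled_from(["a", "b", "c", "d", "e", "f", "g"]), max_size=7
)


class TestJaccard:
    def test_reference_five_sixths_example(self):
        a = frozenset({"4", "type", "oral", "adenovirus", "live"})
        b = frozenset({"product", "4", "type", "oral", "adenovirus", "live"})
        assert vm.jaccard(a, b) == pytest.approx(5 / 6)
        assert vm.jaccard(a, b) == pytest.approx(0.833, abs=5e-4)

    def test_identical_and_disjoint_sets(self):
        s = frozenset({"x", "y"})
        assert vm.jaccard(s, s) == 1.0
        assert vm.jaccard(s, frozenset({"p", "q"})) == 0.0
        assert vm.jaccard(frozenset(), frozenset()) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(token_sets, token_sets)
    def test_symmetric_bounded_and_one_iff_equal(self, a, b):
        j = vm.jaccard(a, b)
        assert j == vm.jaccard(b, a)
        assert 0.0 <= j <= 1.0
        if a or b:
            assert (j == 1.0) == (a == b)


def _refine_graph():
    return make_graph(
        {
            "R": ("vaccine",),
            "VO_0000020": ("adenovirus type 4 vaccine live oral product", [], ["R"]),
            "VO_0000021": ("adenovirus type 7 vaccine", [], ["R"]),
            "VO_0000022": ("cholera vaccine", ["cholera oral inactivated vaccine"], ["R"]),
            "VO_0000023": ("typhoid conjugate vaccine", [], ["R"]),
        }
    )


def _as_candidates(graph, score=0.9):
    return [
        vm.ScoredCandidate(object_id=tid, score=score, method="embedding")
        for tid in sorted(graph.terms)
        if tid != graph.root
    ]


class TestJaccardRefine:
    def test_token_identical_candidate_kept_at_rank_one(self, stopwords):
        graph = _refine_graph()
        source = vm.SourceTerm(code="54", full_name="adenovirus vaccine, type 4, live, oral")
        out = vm.jaccard_refine(
            source, _as_candidates(graph), graph, vm.MatchConfig(), None, stopwords
        )
        assert out[0].object_id == "VO_0000020"
        assert out[0].score == pytest.approx(5 / 6)
        assert all(c.method == "jaccard" for c in out)

    def test_all_below_threshold_means_unmappable(self, stopwords):
        graph = _refine_graph()
        source = vm.SourceTerm(code="99", full_name="rabies purified chick embryo")
        out = vm.jaccard_refine(
            source, _as_candidates(graph), graph, vm.MatchConfig(), None, stopwords
        )
        assert out == []

    def test_candidate_synonym_can_carry_the_match(self, stopwords):
        graph = _refine_graph()
        source = vm.SourceTerm(code="26", full_name="cholera vaccine, oral, inactivated")
        out = vm.jaccard_refine(
            source, _as_candidates(graph), graph, vm.MatchConfig(), None, stopwords
        )
        assert out[0].object_id == "VO_0000022"
        assert out[0].score == 1.0
        assert out[0].best_synonym_index == 1

    def test_unknown_candidate_id_rejected(self, stopwords):
        graph = _refine_graph()
        source = vm.SourceTerm(code="1", full_name="cholera vaccine")
        bogus = [vm.ScoredCandidate(object_id="VO_9999999", score=0.9, method="embedding")]
        with pytest.raises(ValidationError):
            vm.jaccard_refine(source, bogus, graph, vm.MatchConfig(), None, stopwords)

    def test_input_larger_than_k_initial_rejected(self, stopwords):
        graph = _refine_graph()
        source = vm.SourceTerm(code="1", full_name="cholera vaccine")
        cands = _as_candidates(graph) * 8  # 32 > k_initial=20
        with pytest.raises(ValidationError):
            vm.jaccard_refine(source, cands, graph, vm.MatchConfig(), None, stopwords)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed, encoder, stopwords):
        import io

        from vaxmap.fixtures import FixtureSpec, generate_fixture

        bundle = generate_fixture(
            FixtureSpec(seed=seed, n_source_terms=8, n_ontology_terms=20)
        )
        sources = vm.read_source_table(io.StringIO(bundle.source_table))
        graph = vm.read_ontology(io.StringIO(bundle.ontology), root=bundle.vaccine_root)
        table = vm.AbbreviationTable.from_file(io.StringIO(bundle.abbreviations))
        config = vm.MatchConfig()
        for source in sources[:4]:
            top = vm.top_k(source, graph, encoder, config.k_initial, table, stopwords)
            got = vm.jaccard_refine(source, top, graph, config, table, stopwords)
            # oracle: rescore, filter, sort, truncate — straight from the rules
            src_tokens = vm.tokenize(vm.normalize_text(source.full_name, table), stopwords)
            scored = []
            for cand in top:
                variants = graph[cand.object_id].variants
                best = max(
                    vm.jaccard(
                        src_tokens,
                        vm.tokenize(vm.normalize_text(v, table), stopwords),
                    )
                    for v in variants
                )
                if best >= config.jaccard_threshold:
                    scored.append((cand.object_id, best))
            scored.sort(key=lambda p: (-p[1], p[0]))
            assert [(c.object_id, c.score) for c in got] == scored[: config.k_final]
            # invariants: subset of input, bounded by k_final
            assert {c.object_id for c in got} <= {c.object_id for c in top}
            assert len(got) <= config.k_final


class TestPrompting:
    def test_prompt_lists_every_candidate_once_and_source_verbatim(self):
        graph = _refine_graph()
        source = vm.SourceTerm(code="54", full_name="adenovirus vaccine, type 4, live, oral")
        cands = _as_candidates(graph)
        prompt = vm.build_llm_prompt(source, cands, graph)
        assert source.full_name in prompt
        for cand in cands:
            assert prompt.count(cand.object_id) == 1
        # byte-identical across runs
        assert prompt == vm.build_llm_prompt(source, cands, graph)

    def test_template_placeholders_are_validated(self):
        with pytest.raises(ValidationError):
            vm.PromptTemplate("only {source_term} here")
        with pytest.raises(ValidationError):
            vm.PromptTemplate("{source_term} {candidates} {candidates}")

    def test_parse_keeps_order_drops_hallucinations_and_truncates(self):
        allowed = [f"VO_{i:07d}" for i in range(1, 6)]
        text = "Best: VO_0000003, then VO_0000001; maybe VO_9999999 and VO_0000003."
        assert vm.parse_llm_response(text, allowed) == ["VO_0000003", "VO_0000001"]
        assert vm.parse_llm_response("NONE", allowed) == []
        assert vm.parse_llm_response("", allowed) == []
        many = " ".join(allowed)
        assert vm.parse_llm_response(many, allowed, k_final=2) == allowed[:2]

    def test_id_prefix_of_another_id_is_not_misparsed(self):
        allowed = ["VO_1", "VO_12"]
        assert vm.parse_llm_response("pick VO_12", allowed) == ["VO_12"]


class TestLlmRefine:
    def _setup(self):
        graph = _refine_graph()
        source = vm.SourceTerm(code="54", full_name="adenovirus vaccine, type 4, live, oral")
        return graph, source, _as_candidates(graph)

    def test_mock_first_two_ids(self, stopwords):
        graph, source, cands = self._setup()
        out = vm.llm_refine(source, cands, graph, MockLlmClient(strategy="first_k", k=2))
        assert [c.object_id for c in out] == [c.object_id for c in cands[:2]]
        assert all(c.method == "llm" for c in out)
        # embedding-stage scores are carried over
        assert [c.score for c in out] == [c.score for c in cands[:2]]

    def test_mock_declining_everything_means_unmappable(self):
        graph, source, cands = self._setup()
        out = vm.llm_refine(source, cands, graph, MockLlmClient(strategy="none"))
        assert out == []

    def test_response_order_is_preserved(self):
        graph, source, cands = self._setup()
        out = vm.llm_refine(source, cands, graph, MockLlmClient(strategy="reverse", k=4))
        assert [c.object_id for c in out] == [c.object_id for c in cands[:4]][::-1]

    def test_client_failure_names_the_term(self):
        graph, source, cands = self._setup()

        class Boom:
            name = "boom"

            def complete(self, prompt):
                raise RuntimeError("offline")

        with pytest.raises(ValidationError, match="54"):
            vm.llm_refine(source, cands, graph, Boom())
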