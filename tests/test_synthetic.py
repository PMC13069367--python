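"""Synthetic corpus / ratings generator: determinism, validity, diversity dials."""

import numpy as np
import pytest

from summdiv import (
    CRITERIA,
    ValidationError,
    self_rouge,
    semantic_diversity,
    write_corpus,
)
from summdiv.synthetic import (
    CorpusSpec,
    RatingsSpec,
    SystemProfile,
    default_ratings_spec,
    default_study_profiles,
    generate_corpus,
    generate_ratings,
)
from summdiv.vocab import MAX_TEMPLATE_POOL, PERSONAL_TOKENS, TEMPLATES


def spec_for(profiles, n=8, seed=0):
    return CorpusSpec(profiles=tuple(profiles), n_timelines=n, seed=seed)


class TestSpecValidation:
    def test_pool_exceeding_templates_rejected(self):
        with pytest.raises(ValidationError, match="templates"):
            SystemProfile("s", template_pool_size=MAX_TEMPLATE_POOL + 1)

    def test_rates_bounded(self):
        with pytest.raises(ValidationError):
            SystemProfile("s", synonym_rate=1.2)
        with pytest.raises(ValidationError):
            SystemProfile("s", personal_token_rate=-0.1)

    def test_needs_two_timelines(self):
        with pytest.raises(ValidationError):
            spec_for([SystemProfile("s")], n=1)

    def test_duplicate_profile_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            spec_for([SystemProfile("s"), SystemProfile("s")])


class TestGenerateCorpus:
    def test_output_passes_corpus_validation_and_pairing(self):
        corpus = generate_corpus(
            spec_for(default_study_profiles(), n=6, seed=3)
        )
        assert len(corpus) == 6 * 4
        for a in corpus.systems:
            for b in corpus.systems:
                if a < b:
                    assert len(corpus.paired_timelines(a, b)) == 6
        doc = corpus.documents[0]
        assert doc.aspects is not None and len(doc.aspects) == 3

    def test_byte_identical_for_fixed_seed(self, tmp_path):
        spec = spec_for(default_study_profiles(), n=5, seed=11)
        for name in ("a.jsonl", "b.jsonl"):
            write_corpus(generate_corpus(spec), tmp_path / name)
        assert (tmp_path / "a.jsonl").read_bytes() == (
            tmp_path / "b.jsonl"
        ).read_bytes()

    def test_adding_profile_does_not_perturb_existing_systems(self):
        base = spec_for([SystemProfile("x"), SystemProfile("y")], n=5, seed=2)
        extended = spec_for(
            [SystemProfile("x"), SystemProfile("y"), SystemProfile("z")],
            n=5,
            seed=2,
        )
        c1, c2 = generate_corpus(base), generate_corpus(extended)
        for t in c1.timelines:
            for s in ("x", "y"):
                assert c1.document(t, s).text == c2.document(t, s).text

    def test_degenerate_profile_identical_summaries(self):
        corpus = generate_corpus(
            spec_for(
                [
                    SystemProfile(
                        "degenerate",
                        template_pool_size=1,
                        synonym_rate=0.0,
                        personal_token_rate=0.0,
                    )
                ],
                n=4,
            )
        )
        texts = {d.text for d in corpus}
        assert len(texts) == 1
        assert self_rouge(corpus, "degenerate", "rouge1").value == 1.0

    def test_personal_tokens_are_timeline_specific(self):
        corpus = generate_corpus(
            spec_for(
                [SystemProfile("p", personal_token_rate=1.0)], n=6, seed=0
            )
        )
        for i, t in enumerate(corpus.timelines):
            assert PERSONAL_TOKENS[i] in corpus.document(t, "p").text

    def test_synonym_substitution_monotone_in_expectation(self):
        """Raising synonym_rate lowers rouge1 self-ROUGE across seeds."""
        lower = 0
        for seed in range(10):
            spec = spec_for(
                [
                    SystemProfile("plain", synonym_rate=0.0),
                    SystemProfile("syn", synonym_rate=0.5),
                ],
                n=10,
                seed=seed,
            )
            corpus = generate_corpus(spec)
            lower += (
                self_rouge(corpus, "syn", "rouge1").value
                < self_rouge(corpus, "plain", "rouge1").value
            )
        assert lower >= 9

    def test_template_pool_monotone_in_expectation(self):
        lower = 0
        for seed in range(10):
            spec = spec_for(
                [
                    SystemProfile("narrow", template_pool_size=1),
                    SystemProfile("wide", template_pool_size=20),
                ],
                n=10,
                seed=seed,
            )
            corpus = generate_corpus(spec)
            lower += (
                self_rouge(corpus, "wide", "rouge1").value
                < self_rouge(corpus, "narrow", "rouge1").value
            )
        assert lower >= 9

    def test_personal_rate_does_not_raise_semantic_similarity(self):
        lo, hi = [], []
        for seed in range(10):
            spec = spec_for(
                [
                    SystemProfile("generic", personal_token_rate=0.0),
                    SystemProfile("personal", personal_token_rate=1.0),
                ],
                n=10,
                seed=seed,
            )
            corpus = generate_corpus(spec)
            lo.append(semantic_diversity(corpus, "generic").value)
            hi.append(semantic_diversity(corpus, "personal").value)
        assert np.mean(hi) <= np.mean(lo)

    def test_word_lists_contain_no_markup_or_duplicates(self):
        for aspect, templates in TEMPLATES.items():
            assert len(set(templates)) == len(templates)
            for t in templates:
                assert t == t.lower().strip()
        assert len(set(PERSONAL_TOKENS)) == len(PERSONAL_TOKENS)


class TestGenerateRatings:
    def test_sd_zero_gives_exact_scores(self):
        corpus = generate_corpus(spec_for([SystemProfile("s")], n=4))
        spec = RatingsSpec(
            means={"s": {c: (4.0, 0.0) for c in CRITERIA}}, seed=0
        )
        table = generate_ratings(corpus, spec)
        assert {r.score for r in table.rows} == {4}
        assert len(table) == 4 * len(CRITERIA)

    def test_clamping_to_scale(self):
        corpus = generate_corpus(spec_for([SystemProfile("s")], n=10))
        spec = RatingsSpec(
            means={"s": {c: (5.0, 2.0) for c in CRITERIA}}, seed=1
        )
        scores = [r.score for r in generate_ratings(corpus, spec).rows]
        assert max(scores) <= 5 and min(scores) >= 1

    def test_uncovered_system_rejected(self):
        corpus = generate_corpus(
            spec_for([SystemProfile("s"), SystemProfile("u")], n=4)
        )
        spec = RatingsSpec(means={"s": {c: (3.0, 1.0) for c in CRITERIA}})
        with pytest.raises(ValidationError, match="'u'"):
            generate_ratings(corpus, spec)

    def test_empirical_mean_close_to_target(self):
        corpus = generate_corpus(spec_for([SystemProfile("s")], n=30))
        hits = 0
        for seed in range(20):
            spec = RatingsSpec(
                means={"s": {c: (3.5, 1.0) for c in CRITERIA}},
                n_raters=3,
                seed=seed,
            )
            scores = np.array(
                [r.score for r in generate_ratings(corpus, spec).rows]
            )
            hits += abs(scores.mean() - 3.5) <= 0.2
        assert hits >= 19

    def test_default_study_ratings_preserve_ordering(self):
        corpus = generate_corpus(
            spec_for(default_study_profiles(), n=30, seed=0)
        )
        table = generate_ratings(corpus, default_ratings_spec(seed=0, n_raters=3))
        frame = table.to_frame()
        by = frame.groupby(["system_id", "criterion"])["score"].mean()
        assert by["human", "factual_consistency"] > by["llama", "factual_consistency"]
        assert (
            by["naive-llama", "changes_over_time"]
            < by["th-vae", "changes_over_time"]
        )
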