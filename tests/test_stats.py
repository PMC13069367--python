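"""Permutation tests, Cohen d, comparison grids, ratings aggregation."""

import math

import numpy as np
import pytest

from summdiv import (
    PairingError,
    RatingRow,
    RatingsTable,
    UndefinedEffectError,
    ValidationError,
    cohen_d,
    compare_diversity,
    paired_permutation_test,
    summarize_ratings,
)

from conftest import make_corpus


def scored_stat(scores):
    """Group statistic: mean of a fixed per-summary score table."""

    def stat_fn(docs):
        return float(np.mean([scores[d.key] for d in docs]))

    return stat_fn


def paired_corpus(n, systems=("a", "b")):
    return make_corpus(
        [(f"t{i}", s, f"text {s} {i}") for i in range(n) for s in systems]
    )


class TestCohenD:
    def test_identical_lists_zero(self):
        assert cohen_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_value(self):
        assert cohen_d([2, 4], [1, 3]) == pytest.approx(1 / math.sqrt(2))

    def test_antisymmetric(self):
        a, b = [1.0, 2.0, 4.0], [0.5, 2.5, 3.0]
        assert cohen_d(a, b) == pytest.approx(-cohen_d(b, a))

    def test_zero_pooled_variance_undefined(self):
        with pytest.raises(UndefinedEffectError):
            cohen_d([3.0, 3.0], [1.0, 1.0])

    def test_needs_two_values_per_group(self):
        with pytest.raises(ValidationError):
            cohen_d([1.0], [2.0, 3.0])


class TestPairedPermutationTest:
    def test_identical_groups_p_one_exhaustive(self):
        corpus = make_corpus(
            [(f"t{i}", s, f"same text {i}") for i in range(4) for s in ("a", "b")]
        )
        scores = {d.key: hash(d.timeline_id) % 7 / 7 for d in corpus}
        # same per-timeline score for both systems -> exchangeable identity
        for t in corpus.timelines:
            scores[(t, "b")] = scores[(t, "a")]
        res = paired_permutation_test(
            corpus, "a", "b", scored_stat(scores), mode="exhaustive"
        )
        assert res.observed_diff == 0.0
        assert res.p_value == 1.0

    def test_constant_shift_exhaustive_p_is_two_over_2n(self):
        n = 5
        corpus = paired_corpus(n)
        rng = np.random.default_rng(0)
        base = rng.normal(size=n)
        scores = {}
        for i in range(n):
            scores[(f"t{i}", "a")] = base[i] + 10.0
            scores[(f"t{i}", "b")] = base[i]
        res = paired_permutation_test(
            corpus, "a", "b", scored_stat(scores), mode="exhaustive"
        )
        assert res.observed_diff == pytest.approx(10.0)
        assert res.p_value == pytest.approx(2 / 2**n)

    def test_monte_carlo_close_to_exhaustive(self):
        n, B = 6, 4000
        corpus = paired_corpus(n)
        rng = np.random.default_rng(42)
        scores = {d.key: float(rng.normal()) for d in corpus}
        stat = scored_stat(scores)
        exact = paired_permutation_test(corpus, "a", "b", stat, mode="exhaustive")
        mc = paired_permutation_test(
            corpus, "a", "b", stat, B=B, seed=11, mode="monte_carlo"
        )
        tol = 3 * math.sqrt(exact.p_value * (1 - exact.p_value) / B) + 1 / (B + 1)
        assert abs(mc.p_value - exact.p_value) <= tol

    def test_monte_carlo_p_floor_and_seed_reproducibility(self):
        corpus = paired_corpus(8)
        rng = np.random.default_rng(1)
        scores = {d.key: float(rng.normal()) for d in corpus}
        r1 = paired_permutation_test(
            corpus, "a", "b", scored_stat(scores), B=99, seed=5
        )
        r2 = paired_permutation_test(
            corpus, "a", "b", scored_stat(scores), B=99, seed=5
        )
        assert r1.p_value == r2.p_value
        assert r1.observed_diff == r2.observed_diff
        assert math.isnan(r1.cohen_d)  # no effect values supplied
        assert r1.p_value >= 1 / 100

    def test_relabeling_swaps_sign_keeps_p(self):
        corpus = paired_corpus(6)
        rng = np.random.default_rng(9)
        scores = {d.key: float(rng.normal()) for d in corpus}
        stat = scored_stat(scores)
        ab = paired_permutation_test(corpus, "a", "b", stat, mode="exhaustive")
        ba = paired_permutation_test(corpus, "b", "a", stat, mode="exhaustive")
        assert ab.p_value == ba.p_value
        assert ab.observed_diff == pytest.approx(-ba.observed_diff)

    def test_non_paired_corpus_rejected(self):
        corpus = make_corpus(
            [("t1", "a", "x"), ("t1", "b", "y"), ("t2", "a", "z")]
        )
        with pytest.raises(PairingError):
            paired_permutation_test(corpus, "a", "b", lambda docs: 0.0)

    def test_exhaustive_refused_beyond_limit(self):
        corpus = paired_corpus(21)
        with pytest.raises(ValidationError, match="monte_carlo"):
            paired_permutation_test(
                corpus, "a", "b", lambda docs: 0.0, mode="exhaustive"
            )


class TestCompareDiversity:
    def test_grid_shape_all_pairs_all_metrics(self):
        corpus = make_corpus(
            [
                (f"t{i}", s, f"summary {s} number {i} with shared words")
                for i in range(3)
                for s in ("h", "m1", "m2", "m3")
            ]
        )
        grid = compare_diversity(corpus, B=20, seed=1)
        # 6 pairs x (6 rouge variants + 1 embedder)
        assert len(grid) == 6 * 7
        assert set(grid["mode"]) == {"monte_carlo"}

    def test_missing_pair_rejected(self, two_system_corpus):
        with pytest.raises(PairingError):
            compare_diversity(
                two_system_corpus, system_pairs=[("human", "nosuch")], B=10
            )

    def test_grid_matches_direct_statistics(self, two_system_corpus):
        from summdiv import self_rouge, semantic_diversity

        grid = compare_diversity(
            two_system_corpus,
            system_pairs=[("human", "model")],
            variants=["rouge1"],
            B=50,
            seed=2,
        )
        r1 = grid[grid.metric == "self_rouge:rouge1"].iloc[0]
        assert r1.value_a == pytest.approx(
            self_rouge(two_system_corpus, "human", "rouge1").value
        )
        assert r1.value_b == pytest.approx(
            self_rouge(two_system_corpus, "model", "rouge1").value
        )
        sem = grid[grid.metric == "semantic:reference"].iloc[0]
        assert sem.value_a == pytest.approx(
            semantic_diversity(two_system_corpus, "human").value
        )

    def test_cohen_d_uses_per_summary_links(self, two_system_corpus):
        from summdiv import self_rouge

        grid = compare_diversity(
            two_system_corpus,
            system_pairs=[("human", "model")],
            variants=["rouge1"],
            embedders=(),
            B=10,
            seed=0,
        )
        links_h = list(
            self_rouge(two_system_corpus, "human", "rouge1").per_summary_link.values()
        )
        links_m = list(
            self_rouge(two_system_corpus, "model", "rouge1").per_summary_link.values()
        )
        assert grid.iloc[0].cohen_d == pytest.approx(cohen_d(links_h, links_m))


class TestSummarizeRatings:
    @staticmethod
    def full_table(score_fn, timelines, systems, raters=("r1",)):
        from summdiv import CRITERIA

        return RatingsTable(
            tuple(
                RatingRow(t, s, c, r, score_fn(t, s, c, r))
                for t in timelines
                for s in systems
                for c in CRITERIA
                for r in raters
            )
        )

    def test_all_threes_degenerate(self):
        table = self.full_table(
            lambda *a: 3, [f"t{i}" for i in range(4)], ["a", "b"]
        )
        means, tests = summarize_ratings(table, B=50, seed=0)
        assert (means["mean_score"] == 3.0).all()
        assert (tests["cohen_d"] == 0.0).all()
        assert tests["degenerate_effect"].all()

    def test_single_timeline_exhaustive_p_one(self):
        table = self.full_table(
            lambda t, s, c, r: 5 if s == "a" else 1, ["t1"], ["a", "b"]
        )
        means, tests = summarize_ratings(table, mode="exhaustive", seed=0)
        row = tests.iloc[0]
        assert row["diff"] == pytest.approx(4.0)
        assert row["p_value"] == 1.0  # both of the 2 assignments reach |4|

    def test_raters_averaged_before_testing(self):
        # two raters disagreeing 2/4 average to 3 -> identical to the other
        # system's constant 3 -> zero observed difference
        def score(t, s, c, r):
            if s == "a":
                return 2 if r == "r1" else 4
            return 3

        table = self.full_table(
            score, ["t1", "t2", "t3"], ["a", "b"], raters=("r1", "r2")
        )
        _, tests = summarize_ratings(table, mode="exhaustive", seed=0)
        assert (tests["diff"] == 0.0).all()
        assert (tests["p_value"] == 1.0).all()

    def test_unpaired_timeline_named(self):
        from summdiv import CRITERIA

        rows = [
            RatingRow("t1", "a", c, "r1", 3) for c in CRITERIA
        ] + [
            RatingRow("t1", "b", c, "r1", 3) for c in CRITERIA
        ] + [
            RatingRow("t2", "a", c, "r1", 3) for c in CRITERIA
        ]
        with pytest.raises(PairingError, match="t2"):
            summarize_ratings(RatingsTable(tuple(rows)), B=10, seed=0)

    def test_known_gap_recovered(self):
        """Parameter recovery: a 0.5-point Likert gap at SD 1 and n = 30 with
        3 raters is recovered within 0.25 in >= 90% of seeds."""
        from summdiv import CRITERIA
        from summdiv.synthetic import RatingsSpec, generate_ratings
        from summdiv.corpus import SummaryDocument, SummaryCorpus

        corpus = SummaryCorpus(
            SummaryDocument(f"t{i:02d}", s, "placeholder text")
            for i in range(30)
            for s in ("a", "b")
        )
        hits = total = 0
        for seed in range(30):
            spec = RatingsSpec(
                means={
                    "a": {c: (3.25, 1.0) for c in CRITERIA},
                    "b": {c: (2.75, 1.0) for c in CRITERIA},
                },
                n_raters=3,
                seed=seed,
            )
            table = generate_ratings(corpus, spec)
            means, _ = summarize_ratings(table, B=10, seed=seed)
            by_system = means.groupby("system_id")["mean_score"].mean()
            gap = by_system["a"] - by_system["b"]
            hits += abs(gap - 0.5) <= 0.25
            total += 1
        assert hits / total >= 0.90
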