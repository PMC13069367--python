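"""Paired permutation tests, Cohen d, and the system-comparison grids.

The test design follows the paired structure of the data: each timeline
contributes exactly one summary per system, so under the null hypothesis the
two system labels are exchangeable *within* a timeline. A permutation swaps
the two summaries of each timeline independently with probability 1/2
(Monte-Carlo mode) or enumerates all 2^n sign assignments (exhaustive mode),
recomputes the group statistic on both permuted groups, and compares the
permuted difference to the observed one.

Conventions (recorded in every result):

* two-sided comparison on |difference|;
* Monte-Carlo p uses add-one smoothing, p = (r + 1) / (B + 1) where r counts
  permutations with |perm diff| >= |observed diff|, so p is never 0 and is at
  least 1/(B+1); exhaustive mode reports the raw proportion over all 2^n
  assignments (the identity assignment guarantees p > 0);
* Cohen d uses the pooled-SD formula with sample (n-1) variances, computed
  over per-summary unit scores (per-summary link scores for self-ROUGE,
  per-summary centroid similarities for semantic diversity, per-timeline
  rater-mean scores for ratings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import CRITERIA, RatingsTable, SummaryCorpus, SummaryDocument
from .errors import PairingError, UndefinedEffectError, ValidationError
from .semantic import Embedder, embed_texts, get_embedder
from .surface import VARIANTS, rouge_pair, tokenize

__all__ = [
    "PermutationResult",
    "cohen_d",
    "paired_permutation_test",
    "compare_diversity",
    "summarize_ratings",
    "derive_seed",
    "EXHAUSTIVE_LIMIT",
]

#: Exhaustive mode enumerates 2^n assignments; refuse beyond this.
EXHAUSTIVE_LIMIT = 20

#: Default number of Monte-Carlo permutations.
DEFAULT_B = 1000

REPORT_COLUMNS = [
    "pair",
    "metric",
    "value_a",
    "value_b",
    "diff",
    "p_value",
    "cohen_d",
    "B",
    "seed",
    "mode",
]


def derive_seed(*parts: int | str) -> int:
    """Stable sub-seed (< 2^31) from a root seed and string/int labels.

    Hash-derived so that adding pairs or metrics to a report does not perturb
    the seeds of existing rows.
    """
    import hashlib

    h = hashlib.blake2b(digest_size=4)
    for part in parts:
        h.update(repr(part).encode("utf-8"))
        h.update(b"\x00")
    return int.from_bytes(h.digest(), "big") % (2**31)


@dataclass(frozen=True)
class PermutationResult:
    statistic_id: str
    system_a: str
    system_b: str
    observed_diff: float
    p_value: float
    n_permutations: int
    cohen_d: float
    seed: int
    mode: str
    degenerate_effect: bool = False


def cohen_d(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD.

    Pooled SD uses sample (n-1) variances. Raises
    :class:`UndefinedEffectError` when the pooled variance is zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError(
            f"cohen_d needs >= 2 values per group, got {a.size} and {b.size}"
        )
    n_a, n_b = a.size, b.size
    pooled_var = (
        (n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)
    ) / (n_a + n_b - 2)
    if pooled_var <= 0:
        raise UndefinedEffectError(
            "pooled variance is zero; Cohen d is undefined"
        )
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def _permutation_pvalue(
    diff_fn: Callable[[np.ndarray], float],
    n: int,
    B: int,
    seed: int,
    mode: str,
) -> tuple[float, float, int]:
    """Shared engine: returns (observed_diff, p_value, n_permutations).

    ``diff_fn(mask)`` evaluates the group difference after swapping the pair
    members at every index where ``mask`` is True.
    """
    observed = diff_fn(np.zeros(n, dtype=bool))
    if mode == "exhaustive":
        if n > EXHAUSTIVE_LIMIT:
            raise ValidationError(
                f"exhaustive mode enumerates 2^{n} assignments; refuse for "
                f"n > {EXHAUSTIVE_LIMIT}. Use mode='monte_carlo' instead."
            )
        total = 2**n
        count = 0
        for bits in range(total):
            mask = (bits >> np.arange(n)) & 1
            if abs(diff_fn(mask.astype(bool))) >= abs(observed):
                count += 1
        return observed, count / total, total
    if mode != "monte_carlo":
        raise ValueError(
            f"unknown mode {mode!r}; expected 'monte_carlo' or 'exhaustive'"
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        mask = rng.random(n) < 0.5
        if abs(diff_fn(mask)) >= abs(observed):
            count += 1
    return observed, (count + 1) / (B + 1), B


def paired_permutation_test(
    corpus: SummaryCorpus,
    system_a: str,
    system_b: str,
    stat_fn: Callable[[Sequence[SummaryDocument]], float],
    B: int = DEFAULT_B,
    seed: int = 0,
    mode: str = "monte_carlo",
    statistic_id: str = "custom",
    effect_values: tuple[Sequence[float], Sequence[float]] | None = None,
) -> PermutationResult:
    """Paired permutation test of ``stat_fn`` between two systems.

    ``stat_fn`` maps a group of summaries (one per timeline) to a real
    statistic; the observed difference is ``stat_fn(group A) - stat_fn(group
    B)``. Each permutation swaps the two summaries of each timeline with
    probability 1/2 and recomputes both group statistics. Requires the corpus
    to be paired-complete for the two systems.

    ``effect_values``, when given as per-summary unit scores (aligned lists
    for the observed groups), feeds the Cohen d reported on the result;
    otherwise d is NaN.
    """
    timelines = corpus.paired_timelines(system_a, system_b)
    docs_a = [corpus.document(t, system_a) for t in timelines]
    docs_b = [corpus.document(t, system_b) for t in timelines]
    n = len(timelines)

    def diff_fn(mask: np.ndarray) -> float:
        group_a = [b if m else a for a, b, m in zip(docs_a, docs_b, mask)]
        group_b = [a if m else b for a, b, m in zip(docs_a, docs_b, mask)]
        return stat_fn(group_a) - stat_fn(group_b)

    observed, p_value, n_perm = _permutation_pvalue(diff_fn, n, B, seed, mode)
    d = float("nan")
    degenerate = False
    if effect_values is not None:
        try:
            d = cohen_d(*effect_values)
        except UndefinedEffectError:
            d, degenerate = 0.0, True
    return PermutationResult(
        statistic_id=statistic_id,
        system_a=system_a,
        system_b=system_b,
        observed_diff=observed,
        p_value=p_value,
        n_permutations=n_perm,
        cohen_d=d,
        seed=seed,
        mode=mode,
        degenerate_effect=degenerate,
    )


# ---------------------------------------------------------------------------
# memoized group statistics for the diversity grid


class _PairwiseRougeStat:
    """Mean pairwise ROUGE F over a group, backed by a lazily filled matrix
    over the union of both systems' summaries, so that 1000 permutations cost
    1000 submatrix means instead of 1000 full self-ROUGE recomputations."""

    def __init__(
        self,
        docs: Sequence[SummaryDocument],
        variant: str,
    ):
        from .surface import _clipped_overlap, _gram_counts, _prf

        self._index = {d.key: i for i, d in enumerate(docs)}
        tokens = [tokenize(d.text) for d in docs]
        m = len(docs)
        self._matrix = np.zeros((m, m))
        if variant == "rougeL":
            for i, j in combinations(range(m), 2):
                score = rouge_pair(tokens[i], tokens[j], variant).fmeasure
                self._matrix[i, j] = self._matrix[j, i] = score
        else:
            grams = [_gram_counts(t, variant) for t in tokens]
            totals = [sum(g.values()) for g in grams]
            for i, j in combinations(range(m), 2):
                score = _prf(
                    float(_clipped_overlap(grams[i], grams[j])),
                    totals[i],
                    totals[j],
                    variant,
                ).fmeasure
                self._matrix[i, j] = self._matrix[j, i] = score

    def __call__(self, group: Sequence[SummaryDocument]) -> float:
        idx = [self._index[d.key] for d in group]
        m = len(idx)
        sub = self._matrix[np.ix_(idx, idx)]
        return float(sub.sum() / (m * (m - 1)))  # diagonal is zero

    def link_scores(self, group: Sequence[SummaryDocument]) -> list[float]:
        idx = [self._index[d.key] for d in group]
        sub = self._matrix[np.ix_(idx, idx)]
        return list(sub.sum(axis=1) / (len(idx) - 1))


class _CentroidSimStat:
    """Mean cosine-to-centroid over a group, with embeddings computed once."""

    def __init__(self, docs: Sequence[SummaryDocument], embedder: Embedder):
        self._index = {d.key: i for i, d in enumerate(docs)}
        vectors = embed_texts([d.text for d in docs], embedder)
        norms = np.linalg.norm(vectors, axis=1)
        if (norms == 0).any():
            bad = docs[int(np.where(norms == 0)[0][0])]
            from .errors import DegenerateGeometryError

            raise DegenerateGeometryError(
                f"zero-norm embedding for timeline {bad.timeline_id!r}"
            )
        self._unit = vectors / norms[:, None]

    def _sims(self, idx: Sequence[int]) -> np.ndarray:
        sub = self._unit[list(idx)]
        centroid = sub.mean(axis=0)
        c_norm = np.linalg.norm(centroid)
        if c_norm == 0:
            from .errors import DegenerateGeometryError

            raise DegenerateGeometryError(
                "centroid of the group embeddings is the zero vector"
            )
        return sub @ centroid / c_norm

    def __call__(self, group: Sequence[SummaryDocument]) -> float:
        return float(self._sims([self._index[d.key] for d in group]).mean())

    def sim_scores(self, group: Sequence[SummaryDocument]) -> list[float]:
        return list(self._sims([self._index[d.key] for d in group]))


def compare_diversity(
    corpus: SummaryCorpus,
    system_pairs: Sequence[tuple[str, str]] | None = None,
    variants: Sequence[str] = VARIANTS,
    embedders: Sequence[str | Embedder] = ("reference",),
    B: int = DEFAULT_B,
    seed: int = 0,
    mode: str = "monte_carlo",
) -> pd.DataFrame:
    """Full diversity-comparison grid: one row per (system pair, metric).

    Surface metrics are self-ROUGE under each requested variant; semantic
    metrics are mean centroid similarity under each requested embedder. Each
    row carries the two systems' observed values, the paired permutation p,
    and Cohen d over per-summary unit scores. Per-row seeds are derived from
    ``seed`` and the row labels, so the grid is reproducible row-by-row.
    """
    if system_pairs is None:
        system_pairs = list(combinations(corpus.systems, 2))
    for variant in variants:
        if variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {variant!r}; expected one of {VARIANTS}"
            )
    rows = []
    for system_a, system_b in system_pairs:
        timelines = corpus.paired_timelines(system_a, system_b)
        union = [corpus.document(t, s) for t in timelines for s in (system_a, system_b)]
        group_a = [corpus.document(t, system_a) for t in timelines]
        group_b = [corpus.document(t, system_b) for t in timelines]
        metrics: list[tuple[str, object]] = [
            (f"self_rouge:{v}", _PairwiseRougeStat(union, v)) for v in variants
        ]
        for emb in embedders:
            emb = get_embedder(emb)
            metrics.append((f"semantic:{emb.id}", _CentroidSimStat(union, emb)))
        for metric_id, stat in metrics:
            if isinstance(stat, _PairwiseRougeStat):
                eff = (stat.link_scores(group_a), stat.link_scores(group_b))
            else:
                eff = (stat.sim_scores(group_a), stat.sim_scores(group_b))  # type: ignore[attr-defined]
            row_seed = derive_seed(seed, system_a, system_b, metric_id)
            res = paired_permutation_test(
                corpus,
                system_a,
                system_b,
                stat,  # type: ignore[arg-type]
                B=B,
                seed=row_seed,
                mode=mode,
                statistic_id=metric_id,
                effect_values=eff,
            )
            value_a = stat(group_a)  # type: ignore[operator]
            value_b = stat(group_b)  # type: ignore[operator]
            rows.append(
                {
                    "pair": f"{system_a} vs {system_b}",
                    "metric": metric_id,
                    "value_a": value_a,
                    "value_b": value_b,
                    "diff": res.observed_diff,
                    "p_value": res.p_value,
                    "cohen_d": res.cohen_d,
                    "B": res.n_permutations,
                    "seed": res.seed,
                    "mode": res.mode,
                    "degenerate_effect": res.degenerate_effect,
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS + ["degenerate_effect"])


# ---------------------------------------------------------------------------
# ratings


def _per_timeline_means(ratings: RatingsTable) -> pd.DataFrame:
    """Raters averaged within (timeline, system, criterion)."""
    frame = ratings.to_frame()
    return (
        frame.groupby(["timeline_id", "system_id", "criterion"], sort=True)[
            "score"
        ]
        .mean()
        .reset_index()
    )


def summarize_ratings(
    ratings: RatingsTable,
    B: int = DEFAULT_B,
    seed: int = 0,
    mode: str = "monte_carlo",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Likert-ratings summary: per-system means and pairwise system tests.

    Raters are averaged within each (timeline, system, criterion) first; the
    per-system mean then averages those per-timeline means. For every system
    pair and criterion a paired permutation test on the per-timeline mean
    scores gives p, and Cohen d is computed on the same per-timeline values
    (a zero pooled variance is reported as d = 0 with ``degenerate_effect``
    set).

    Returns ``(means, comparisons)`` DataFrames.
    """
    per_tl = _per_timeline_means(ratings)
    means = (
        per_tl.groupby(["system_id", "criterion"], sort=True)["score"]
        .mean()
        .reset_index()
        .rename(columns={"score": "mean_score"})
    )
    systems = sorted(per_tl["system_id"].unique())
    rows = []
    for criterion in sorted(per_tl["criterion"].unique()):
        crit = per_tl[per_tl["criterion"] == criterion]
        by_system = {
            s: g.set_index("timeline_id")["score"]
            for s, g in crit.groupby("system_id")
        }
        for system_a, system_b in combinations(systems, 2):
            s_a = by_system.get(system_a)
            s_b = by_system.get(system_b)
            if s_a is None or s_b is None:
                missing = system_a if s_a is None else system_b
                raise PairingError(
                    f"criterion {criterion!r}: no ratings for system "
                    f"{missing!r}"
                )
            unpaired = sorted(set(s_a.index) ^ set(s_b.index))
            if unpaired:
                raise PairingError(
                    f"criterion {criterion!r}, pair ({system_a!r}, "
                    f"{system_b!r}): unpaired timelines: {', '.join(unpaired)}"
                )
            timelines = sorted(s_a.index)
            va = s_a.loc[timelines].to_numpy(dtype=float)
            vb = s_b.loc[timelines].to_numpy(dtype=float)

            def diff_fn(mask: np.ndarray, va=va, vb=vb) -> float:
                a = np.where(mask, vb, va)
                b = np.where(mask, va, vb)
                return float(a.mean() - b.mean())

            row_seed = derive_seed(seed, system_a, system_b, criterion)
            observed, p_value, n_perm = _permutation_pvalue(
                diff_fn, len(timelines), B, row_seed, mode
            )
            degenerate = False
            if len(timelines) >= 2:
                try:
                    d = cohen_d(va, vb)
                except UndefinedEffectError:
                    d, degenerate = 0.0, True
            else:
                d, degenerate = 0.0, True
            rows.append(
                {
                    "pair": f"{system_a} vs {system_b}",
                    "metric": f"rating:{criterion}",
                    "value_a": float(va.mean()),
                    "value_b": float(vb.mean()),
                    "diff": observed,
                    "p_value": p_value,
                    "cohen_d": d,
                    "B": n_perm,
                    "seed": row_seed,
                    "mode": mode,
                    "degenerate_effect": degenerate,
                }
            )
    comparisons = pd.DataFrame(rows, columns=REPORT_COLUMNS + ["degenerate_effect"])
    return means, comparisons
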