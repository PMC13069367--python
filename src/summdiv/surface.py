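"""Surface (lexical) diversity: six ROUGE variants and self-ROUGE.

Self-ROUGE is a reference-free use of ROUGE: instead of scoring a candidate
against a gold reference, it averages the pairwise ROUGE F-measure over all
C(m, 2) unordered pairs of summaries *within* one system. High within-system
overlap means the system repeats itself across timelines; a *lower* self-ROUGE
therefore indicates *higher* surface diversity.

Variants
--------
rouge1 / rouge2 / rouge3
    Clipped unigram / bigram / trigram multiset overlap.
rougeL
    Longest-common-subsequence overlap (denominators are the sequence
    lengths).
rougeS2
    Skip-bigrams: ordered token pairs with at most ``max_gap = 2`` intervening
    tokens.
rougeSU2
    Count-wise union of the unigram and gap-2 skip-bigram multisets.

All variants use clipped (multiset-min) overlap counting and F-measure with
beta = 1, which is symmetric in the two texts — the natural choice for
unordered within-system pairs. Precision and recall are retained on every
score for audit. Tokenization is deliberately minimal and documented:
lowercase, maximal alphanumeric runs with word-internal apostrophes kept, no
stemming, no stopword removal.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .corpus import SummaryCorpus
from .errors import ValidationError

__all__ = [
    "VARIANTS",
    "RougeScore",
    "SelfRougeResult",
    "tokenize",
    "extract_ngrams",
    "extract_skip_bigrams",
    "lcs_length",
    "rouge_pair",
    "self_rouge",
    "SKIP_BIGRAM_MAX_GAP",
]

#: Canonical variant identifiers (CLI spelling "rouge-1" etc. maps onto these).
VARIANTS = ("rouge1", "rouge2", "rouge3", "rougeL", "rougeS2", "rougeSU2")

#: Skip-bigram gap: at most this many intervening tokens (j - i - 1 <= gap).
SKIP_BIGRAM_MAX_GAP = 2

# Maximal runs of alphanumerics; apostrophes kept word-internal ("she's").
_TOKEN_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase word tokenization.

    Tokens are maximal runs of alphanumeric characters with apostrophes kept
    word-internal; everything else is a separator. No stemming or stopword
    removal. Deterministic; empty input yields an empty list.
    """
    return _TOKEN_RE.findall(text.lower())


def extract_ngrams(tokens: Sequence[str], n: int) -> Counter:
    """Multiset of all contiguous n-grams as a Counter of token tuples.

    Total count equals ``max(0, len(tokens) - n + 1)``.
    """
    if n < 1:
        raise ValueError(f"n-gram order must be >= 1, got {n}")
    return Counter(
        tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)
    )


def extract_skip_bigrams(tokens: Sequence[str], max_gap: int) -> Counter:
    """Multiset of ordered pairs (tokens[i], tokens[j]), i < j, with at most
    ``max_gap`` intervening tokens (j - i - 1 <= max_gap).

    ``max_gap = 0`` degenerates to contiguous bigrams.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    grams: Counter = Counter()
    for i in range(len(tokens)):
        for j in range(i + 1, min(len(tokens), i + max_gap + 2)):
            grams[(tokens[i], tokens[j])] += 1
    return grams


def lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    """Length of the longest common subsequence (dynamic programming).

    Symmetric in its arguments; O(len(a) * len(b)) time, O(min) space.
    """
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        curr = [0] * (len(b) + 1)
        for j, y in enumerate(b, start=1):
            if x == y:
                curr[j] = prev[j - 1] + 1
            else:
                curr[j] = max(prev[j], curr[j - 1])
        prev = curr
    return prev[-1]


@dataclass(frozen=True)
class RougeScore:
    """Precision / recall / F1 for one text pair under one variant."""

    variant: str
    precision: float
    recall: float
    fmeasure: float


def _clipped_overlap(c1: Counter, c2: Counter) -> int:
    if len(c2) < len(c1):
        c1, c2 = c2, c1
    return sum(min(count, c2[gram]) for gram, count in c1.items() if gram in c2)


def _gram_counts(tokens: Sequence[str], variant: str) -> Counter:
    """Gram multiset for the multiset-overlap variants (not rougeL)."""
    if variant == "rouge1":
        return extract_ngrams(tokens, 1)
    if variant == "rouge2":
        return extract_ngrams(tokens, 2)
    if variant == "rouge3":
        return extract_ngrams(tokens, 3)
    if variant == "rougeS2":
        return extract_skip_bigrams(tokens, SKIP_BIGRAM_MAX_GAP)
    if variant == "rougeSU2":
        # count-wise sum of unigrams and gap-2 skip-bigrams; unigrams are
        # 1-tuples and skip-bigrams 2-tuples, so the keys never collide
        return extract_ngrams(tokens, 1) + extract_skip_bigrams(
            tokens, SKIP_BIGRAM_MAX_GAP
        )
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def _prf(overlap: float, n_cand: float, n_ref: float, variant: str) -> RougeScore:
    precision = overlap / n_cand if n_cand > 0 else 0.0
    recall = overlap / n_ref if n_ref > 0 else 0.0
    if precision + recall == 0.0:
        fmeasure = 0.0
    else:
        fmeasure = 2.0 * precision * recall / (precision + recall)
    return RougeScore(variant, precision, recall, fmeasure)


def rouge_pair(
    cand: Sequence[str], ref: Sequence[str], variant: str
) -> RougeScore:
    """ROUGE score of a candidate token sequence against a reference.

    The F-measure is symmetric in (cand, ref) for every variant, so for
    unordered within-system pairs either order gives the same self-ROUGE
    contribution.
    """
    if variant == "rougeL":
        lcs = lcs_length(cand, ref)
        return _prf(float(lcs), len(cand), len(ref), variant)
    c_cand = _gram_counts(cand, variant)
    c_ref = _gram_counts(ref, variant)
    overlap = _clipped_overlap(c_cand, c_ref)
    return _prf(
        float(overlap), sum(c_cand.values()), sum(c_ref.values()), variant
    )


@dataclass(frozen=True)
class SelfRougeResult:
    """Within-system surface diversity for one system and one ROUGE variant.

    ``value`` is the mean F-measure over all unordered summary pairs; lower
    means more diverse. ``per_summary_link`` maps each timeline to the mean
    score of its summary against all others in the system (the per-summary
    unit used for effect sizes); its mean equals ``value``.
    """

    system_id: str
    variant: str
    value: float
    pair_scores: Mapping[tuple[str, str], float] = field(repr=False)
    per_summary_link: Mapping[str, float] = field(repr=False)
    score_component: str = "fmeasure"


def self_rouge(
    corpus: SummaryCorpus, system_id: str, variant: str
) -> SelfRougeResult:
    """Mean pairwise ROUGE over all summary pairs within one system.

    Requires at least two summaries. Pairs span different timelines within the
    same system; no cross-system pairs are formed. The result is invariant to
    summary ordering.
    """
    if variant not in VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {VARIANTS}"
        )
    docs = corpus.documents_for_system(system_id)
    if len(docs) < 2:
        raise ValidationError(
            f"self-ROUGE needs >= 2 summaries for system {system_id!r}, "
            f"got {len(docs)}"
        )
    tokens = {d.timeline_id: tokenize(d.text) for d in docs}
    # precompute gram multisets once per summary for the multiset variants
    grams = (
        {t: _gram_counts(toks, variant) for t, toks in tokens.items()}
        if variant != "rougeL"
        else None
    )
    pair_scores: dict[tuple[str, str], float] = {}
    link_sums: dict[str, float] = {d.timeline_id: 0.0 for d in docs}
    for t1, t2 in combinations(sorted(tokens), 2):
        if grams is not None:
            score = _prf(
                float(_clipped_overlap(grams[t1], grams[t2])),
                sum(grams[t1].values()),
                sum(grams[t2].values()),
                variant,
            ).fmeasure
        else:
            score = rouge_pair(tokens[t1], tokens[t2], variant).fmeasure
        pair_scores[(t1, t2)] = score
        link_sums[t1] += score
        link_sums[t2] += score
    m = len(docs)
    per_summary_link = {t: s / (m - 1) for t, s in link_sums.items()}
    value = sum(pair_scores.values()) / len(pair_scores)
    return SelfRougeResult(
        system_id=system_id,
        variant=variant,
        value=value,
        pair_scores=pair_scores,
        per_summary_link=per_summary_link,
    )
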