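"""Independent brute-force oracles for the ROUGE machinery.

Deliberately naive: grams are materialized as explicit lists and counted
with ``list.count``; the LCS is found by exhaustively enumerating every
subsequence of the shorter sequence (2^n subsets) and greedily checking
membership in the other. None of this shares code with the package's
dynamic-programming / Counter implementations.
"""

from __future__ import annotations

from itertools import combinations


def oracle_ngrams(tokens, n):
    return [tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


def oracle_skip_bigrams(tokens, max_gap):
    return [
        (tokens[i], tokens[j])
        for i in range(len(tokens))
        for j in range(i + 1, len(tokens))
        if j - i - 1 <= max_gap
    ]


def _clipped_count(grams_a, grams_b):
    return sum(
        min(grams_a.count(g), grams_b.count(g)) for g in set(grams_a)
    )


def _is_subsequence(sub, seq):
    it = iter(seq)
    return all(any(x == y for y in it) for x in sub)


def oracle_lcs(a, b):
    """Longest common subsequence by exhaustive subset enumeration."""
    if len(a) > len(b):
        a, b = b, a
    best = 0
    for k in range(len(a), 0, -1):
        for idx in combinations(range(len(a)), k):
            if _is_subsequence([a[i] for i in idx], b):
                best = k
                break
        if best:
            break
    return best


def _prf(overlap, n_cand, n_ref):
    p = overlap / n_cand if n_cand else 0.0
    r = overlap / n_ref if n_ref else 0.0
    f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f


def oracle_rouge(cand, ref, variant):
    """(precision, recall, fmeasure) for any of the six variants."""
    if variant == "rougeL":
        lcs = oracle_lcs(list(cand), list(ref))
        return _prf(lcs, len(cand), len(ref))
    if variant in ("rouge1", "rouge2", "rouge3"):
        n = int(variant[-1])
        g_c, g_r = oracle_ngrams(cand, n), oracle_ngrams(ref, n)
    elif variant == "rougeS2":
        g_c, g_r = oracle_skip_bigrams(cand, 2), oracle_skip_bigrams(ref, 2)
    elif variant == "rougeSU2":
        g_c = [(t,) for t in cand] + oracle_skip_bigrams(cand, 2)
        g_r = [(t,) for t in ref] + oracle_skip_bigrams(ref, 2)
    else:
        raise ValueError(variant)
    return _prf(_clipped_count(g_c, g_r), len(g_c), len(g_r))
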