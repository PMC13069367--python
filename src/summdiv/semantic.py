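"""Embedding-based semantic diversity.

The statistic: embed every summary of a system, take the centroid (the
componentwise arithmetic mean — the center of the embedding distribution) and
report the mean cosine similarity of the summaries to that centroid. Lower
mean similarity means the summaries scatter more widely in meaning space,
i.e. greater semantic diversity.

Embeddings are unit-normalized on ingestion, which makes the statistic
scale-free and the centroid a spherical mean direction; the centroid itself
is *not* re-normalized before the cosine is taken.

Embedders are pluggable through a small registry keyed by string id. The
always-available ``reference`` embedder is a deterministic hashed
bag-of-words encoder: each token is hashed (BLAKE2b, platform-independent)
into one of ``dim`` buckets, bucket counts are accumulated and the vector is
scaled to unit norm. It needs no model download and is reproducible across
runs and platforms. Sentence-transformer models can be registered as plugins
under their model names; nothing in the library requires them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus import SummaryCorpus
from .errors import DegenerateGeometryError, SummdivError, ValidationError
from .surface import tokenize

__all__ = [
    "Embedder",
    "ReferenceEmbedder",
    "SemanticDiversityResult",
    "reference_embedding",
    "embed_texts",
    "mean_centroid_similarity",
    "semantic_diversity",
    "get_embedder",
    "register_embedder",
    "available_embedders",
]


@runtime_checkable
class Embedder(Protocol):
    """Embedder contract: deterministic, fixed dimension, finite values."""

    id: str
    dim: int

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        """Return an array of shape (len(texts), dim), order-aligned."""
        ...


class ReferenceEmbedder:
    """Deterministic hashed bag-of-words embedder (the bundled reference).

    Permutation-invariant by construction: "a b" and "b a" embed identically.
    """

    def __init__(self, dim: int = 64):
        if dim < 8:
            raise ValueError(f"reference embedder needs dim >= 8, got {dim}")
        self.id = "reference"
        self.dim = dim

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        return np.stack(
            [reference_embedding(t, self.dim) for t in texts]
        ) if texts else np.zeros((0, self.dim))


def _token_bucket(token: str, dim: int) -> int:
    digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big") % dim


def reference_embedding(text: str, dim: int = 64) -> np.ndarray:
    """Hashed token-count vector scaled to unit Euclidean norm.

    An all-zero vector (no tokens) stays all-zero. Fully deterministic
    across runs and platforms (fixed BLAKE2b token hash).
    """
    if dim < 8:
        raise ValueError(f"dim must be >= 8, got {dim}")
    vec = np.zeros(dim)
    for token in tokenize(text):
        vec[_token_bucket(token, dim)] += 1.0
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


# registry -------------------------------------------------------------------

_EMBEDDERS: dict[str, Callable[[], Embedder]] = {
    "reference": ReferenceEmbedder,
}


def register_embedder(embedder_id: str, factory: Callable[[], Embedder]) -> None:
    """Register an embedder plugin (e.g. a sentence-transformer wrapper)."""
    _EMBEDDERS[embedder_id] = factory


def available_embedders() -> tuple[str, ...]:
    return tuple(sorted(_EMBEDDERS))


def get_embedder(embedder: str | Embedder) -> Embedder:
    if isinstance(embedder, str):
        try:
            return _EMBEDDERS[embedder]()
        except KeyError:
            raise SummdivError(
                f"unknown embedder {embedder!r}; "
                f"available: {', '.join(available_embedders())}"
            ) from None
    return embedder


def embed_texts(texts: Sequence[str], embedder: str | Embedder) -> np.ndarray:
    """Embed texts, enforcing the contract; failures name the text index."""
    emb = get_embedder(embedder)
    if not texts:
        return np.zeros((0, emb.dim))
    vectors = np.asarray(emb.embed(list(texts)), dtype=float)
    if vectors.shape != (len(texts), emb.dim):
        raise SummdivError(
            f"embedder {emb.id!r} returned shape {vectors.shape}, "
            f"expected {(len(texts), emb.dim)}"
        )
    bad = np.where(~np.isfinite(vectors).all(axis=1))[0]
    if bad.size:
        raise SummdivError(
            f"embedder {emb.id!r} produced non-finite values for text "
            f"index {int(bad[0])}"
        )
    return vectors


@dataclass(frozen=True)
class SemanticDiversityResult:
    """Mean cosine similarity of one system's summaries to their centroid.

    ``value`` in [-1, 1]; lower means more semantically diverse.
    ``per_summary_sims`` maps each timeline to its summary's cosine
    similarity with the centroid; its mean equals ``value``.
    """

    system_id: str
    embedder_id: str
    value: float
    per_summary_sims: Mapping[str, float] = field(repr=False)


def mean_centroid_similarity(
    vectors: np.ndarray, ids: Sequence[str] | None = None
) -> tuple[float, dict[str, float]]:
    """Mean cosine similarity of unit-normalized vectors to their centroid.

    Vectors are unit-normalized on ingestion; a zero-norm vector or an
    all-zero centroid (e.g. an antipodal pair) is a degenerate geometry
    error naming the offending id.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValidationError(
            f"need >= 2 embedding vectors, got shape {vectors.shape}"
        )
    if ids is None:
        ids = [str(i) for i in range(vectors.shape[0])]
    norms = np.linalg.norm(vectors, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise DegenerateGeometryError(
            f"zero-norm embedding for {ids[int(zero[0])]!r}"
        )
    unit = vectors / norms[:, None]
    centroid = unit.mean(axis=0)
    c_norm = np.linalg.norm(centroid)
    if c_norm == 0:
        raise DegenerateGeometryError(
            "centroid of the embeddings is the zero vector; cosine "
            "similarity to it is undefined"
        )
    sims = unit @ centroid / c_norm
    return float(sims.mean()), {i: float(s) for i, s in zip(ids, sims)}


def semantic_diversity(
    corpus: SummaryCorpus,
    system_id: str,
    embedder: str | Embedder = "reference",
) -> SemanticDiversityResult:
    """Semantic diversity of one system's summaries under one embedder."""
    emb = get_embedder(embedder)
    docs = corpus.documents_for_system(system_id)
    if len(docs) < 2:
        raise ValidationError(
            f"semantic diversity needs >= 2 summaries for system "
            f"{system_id!r}, got {len(docs)}"
        )
    vectors = embed_texts([d.text for d in docs], emb)
    value, sims = mean_centroid_similarity(
        vectors, [d.timeline_id for d in docs]
    )
    return SemanticDiversityResult(
        system_id=system_id,
        embedder_id=emb.id,
        value=value,
        per_summary_sims=sims,
    )
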