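"""User-level text representations and activity-based inclusion filters.

A post is represented by mean-pooling token vectors from a pluggable
embedder; a user is the unweighted mean of their post vectors (every post
counts once regardless of length).  The default embedder is a deterministic
hashing mock standing in for a large contextualized-embedding model: it
assigns every token — including non-words and emoji — a fixed pseudo-random
vector, which preserves the bag-of-tokens information the synthetic
generator encodes while keeping the package self-contained.  Adapters for
real pretrained embedders can implement the same two-method contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import re
from typing import Protocol

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "tokenize", "Embedder", "MockEmbedder", "mock_embedder", "embed_post",
    "embed_user", "UserEmbedding", "embed_users", "FilterReport",
    "apply_inclusion_filters",
]

_TOKEN_RE = re.compile(r"[\w']+|[^\w\s]", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercased whitespace/punctuation tokenization; punctuation marks and
    emoji survive as single-character tokens."""
    return _TOKEN_RE.findall(text.lower())


class Embedder(Protocol):
    name: str
    dimension: int

    def embed_tokens(self, tokens: list[str]) -> np.ndarray:
        """(len(tokens), dimension) array; deterministic per instance."""
        ...


class MockEmbedder:
    """Deterministic token-hashing embedder.

    Each token string is hashed (seeded BLAKE2) to seed a generator that
    draws its fixed vector, so the map is stable across processes and
    platforms and every conceivable token — "Lolll", emoji, punctuation —
    has a representation.  Distinct tokens get nearly orthogonal vectors at
    typical dimensions.
    """

    def __init__(self, dimension: int = 1024, seed: int = 0):
        if dimension < 1:
            raise ValueError("dimension must be positive")
        self.name = f"mock-d{dimension}-s{seed}"
        self.dimension = dimension
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def _vector(self, token: str) -> np.ndarray:
        v = self._cache.get(token)
        if v is None:
            digest = hashlib.blake2b(
                f"{self.seed}\x00{token}".encode(), digest_size=8).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            v = rng.standard_normal(self.dimension) / np.sqrt(self.dimension)
            self._cache[token] = v
        return v

    def embed_tokens(self, tokens: list[str]) -> np.ndarray:
        return np.array([self._vector(t) for t in tokens])


def mock_embedder(dimension: int = 1024, seed: int = 0) -> MockEmbedder:
    return MockEmbedder(dimension=dimension, seed=seed)


def embed_post(text: str, embedder: Embedder) -> np.ndarray:
    """Mean-pooled token vectors of one post."""
    tokens = tokenize(text)
    if not tokens:
        raise ValueError("post has no tokens")
    return embedder.embed_tokens(tokens).mean(axis=0)


@dataclasses.dataclass
class UserEmbedding:
    user_id: str
    vector: np.ndarray
    post_count: int


def embed_user(posts: list[str], embedder: Embedder,
               user_id: str = "") -> UserEmbedding:
    """Unweighted mean of post vectors.  Posts that tokenize to nothing are
    skipped with a warning; at least one usable post is required."""
    vectors = []
    for post in posts:
        if not tokenize(post):
            log.warning("skipping empty post for user %r", user_id)
            continue
        vectors.append(embed_post(post, embedder))
    if not vectors:
        raise ValueError(f"user {user_id!r} has no usable posts")
    return UserEmbedding(user_id=user_id,
                         vector=np.mean(vectors, axis=0),
                         post_count=len(vectors))


def embed_users(posts_by_user: dict[str, list[str]], embedder: Embedder
                ) -> tuple[list[str], np.ndarray]:
    """Embed every user; returns (user_ids, matrix) in input order."""
    ids, rows = [], []
    for uid, posts in posts_by_user.items():
        ue = embed_user(posts, embedder, user_id=uid)
        ids.append(uid)
        rows.append(ue.vector)
    return ids, np.array(rows)


# ---------------------------------------------------------------------------
# Inclusion filters
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FilterReport:
    n_initial: int
    n_zero_posts_removed: int
    median_posts: float            # median over users with >= 1 post
    median_posts_all_users: float  # candidate median over everyone
    n_below_median_removed: int
    n_retained: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def apply_inclusion_filters(cohort):
    """Activity filters: drop zero-post users, then keep users whose post
    count is at least the median count of the remaining (posting) users.
    Ties at the median are retained, which is the only rule consistent with
    a retention above one half.  Returns (filtered cohort, FilterReport)."""
    counts = np.array([u.post_count for u in cohort.users])
    nonzero = counts > 0
    if not nonzero.any():
        raise ValueError("no users with posts")
    median = float(np.median(counts[nonzero]))
    keep = nonzero & (counts >= median)
    if not keep.any():
        raise ValueError("empty cohort after filtering")
    report = FilterReport(
        n_initial=len(counts),
        n_zero_posts_removed=int((~nonzero).sum()),
        median_posts=median,
        median_posts_all_users=float(np.median(counts)),
        n_below_median_removed=int((nonzero & ~keep).sum()),
        n_retained=int(keep.sum()),
    )
    return cohort.subset(np.flatnonzero(keep)), report
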