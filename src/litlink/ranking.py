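"""Cosine-similarity candidate ranking over node embeddings.

For every starting entity the K most similar entities (default K=100,
restricted to gene-typed nodes) are extracted by cosine similarity and the
rank of a pathway partner within that list is the evaluation signal.  A
partner outside the list is NOT_CAPTURED.  Note the asymmetry: cosine is
symmetric, but the rank of (start, target) depends on the start's
competitor set, so reversing a pair can change its rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NOT_CAPTURED",
    "RankRecord",
    "SimilarityList",
    "cosine_similarity",
    "top_k_similar",
    "rank_of_target",
    "rank_table",
]

log = logging.getLogger(__name__)

#: sentinel rank for a target absent from the start's top-K list
NOT_CAPTURED = None

DEFAULT_K = 100
GENE_TYPE = "gene"


@dataclass(frozen=True)
class RankRecord:
    """Rank of one (start, target) link under one method."""

    start: str
    target: str
    rank: int | None  # 1-based, or NOT_CAPTURED
    k: int = DEFAULT_K
    method: str = "node2vec"

    def __post_init__(self):
        if self.rank is not NOT_CAPTURED and not 1 <= self.rank <= self.k:
            raise ValueError(f"rank {self.rank} outside [1, {self.k}]")

    @property
    def captured(self) -> bool:
        return self.rank is not NOT_CAPTURED


@dataclass(frozen=True)
class SimilarityList:
    """Top-K candidates for one starting entity, descending cosine."""

    start: str
    entries: tuple[tuple[str, float], ...]
    k: int = DEFAULT_K

    def __post_init__(self):
        if any(e == self.start for e, _ in self.entries):
            raise ValueError("start must not appear among its own candidates")
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("similarity scores must be non-increasing")
        if len(self.entries) > self.k:
            raise ValueError(f"{len(self.entries)} entries exceed K={self.k}")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u| |v|); both vectors must be nonzero and same length."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def top_k_similar(
    emb,
    start: str,
    k: int = DEFAULT_K,
    type_filter: str | None = GENE_TYPE,
    node_types: Mapping[str, str] | None = None,
) -> SimilarityList:
    """K nearest candidates of ``start`` by cosine similarity.

    Candidates are all embedded nodes except the start, optionally
    restricted to one semantic type (when ``node_types`` provides labels;
    unlabeled nodes are kept).  Ties are broken lexicographically.
    """
    if start not in emb:
        raise KeyError(f"entity {start!r} has no embedding vector")
    sv = np.asarray(emb[start], dtype=float)
    cands: list[tuple[str, float]] = []
    for node in emb:
        if node == start:
            continue
        if type_filter is not None and node_types is not None:
            if node_types.get(node, type_filter) != type_filter:
                continue
        cands.append((node, cosine_similarity(sv, np.asarray(emb[node], dtype=float))))
    cands.sort(key=lambda t: (-t[1], t[0]))
    return SimilarityList(start, tuple(cands[:k]), k)


def rank_of_target(sim: SimilarityList, target: str) -> RankRecord:
    """1-based position of ``target`` in the list, or NOT_CAPTURED."""
    for i, (node, _score) in enumerate(sim.entries, start=1):
        if node == target:
            return RankRecord(sim.start, target, i, sim.k)
    return RankRecord(sim.start, target, NOT_CAPTURED, sim.k)


def rank_table(
    emb,
    pairs: Iterable[tuple[str, str]],
    k: int = DEFAULT_K,
    type_filter: str | None = GENE_TYPE,
    node_types: Mapping[str, str] | None = None,
    method: str = "node2vec",
) -> list[RankRecord]:
    """Rank every (start, target) pair; unembedded starts or targets are
    NOT_CAPTURED (with a logged warning for missing starts)."""
    out: list[RankRecord] = []
    cache: dict[str, SimilarityList] = {}
    for start, target in pairs:
        if start not in emb:
            log.warning("start entity %r has no embedding; reporting NOT_CAPTURED", start)
            out.append(RankRecord(start, target, NOT_CAPTURED, k, method))
            continue
        if start not in cache:
            cache[start] = top_k_similar(emb, start, k, type_filter, node_types)
        rec = rank_of_target(cache[start], target)
        out.append(RankRecord(start, target, rec.rank, k, method))
    return out
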