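"""Node embeddings from second-order biased random walks (node2vec).

The walk phase samples r truncated walks of length l from every node.  The
next step from ``cur`` after ``prev`` is drawn with probability
proportional to ``alpha(prev, x) * w(cur, x)`` where the bias alpha is
1/p when x == prev (return), 1 when x is a neighbour of prev (stay close)
and 1/q otherwise (move outward); q < 1 therefore favours outward,
community-exploring walks (homophily).  DeepWalk is the p = q = 1 special
case, i.e. plain first-order walks.  Walks are fed to a skip-gram model
with negative sampling trained by plain SGD, exactly as in word2vec, with
nodes as words and walks as sentences.

Alias tables are precomputed per directed (prev, cur) pair so each step is
O(1); all randomness flows from the single seed in the configs, making
walks and training fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import networkx as nx

__all__ = [
    "WalkConfig",
    "TrainConfig",
    "WalkCorpus",
    "EmbeddingMatrix",
    "transition_bias",
    "simulate_walks",
    "train_skipgram",
    "node2vec_embed",
    "deepwalk_embed",
]


@dataclass(frozen=True)
class WalkConfig:
    """Random-walk parameters.

    p: return parameter (>0); large p avoids revisiting the previous node.
    q: in-out parameter (>0); q < 1 biases outward (community structure).
    r: walks per node; l: walk length counted in nodes (l nodes = l-1 steps).
    weighted: multiply biases by edge weights during transitions.
    """

    p: float = 1.0
    q: float = 0.5
    r: int = 10
    l: int = 10
    weighted: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.r < 1 or self.l < 2:
            raise ValueError("need r >= 1 and l >= 2")


@dataclass(frozen=True)
class TrainConfig:
    """Skip-gram-with-negative-sampling hyperparameters.

    d: embedding dimension; k: one-sided context window (in walk positions);
    negative: noise samples per positive pair, drawn from the unigram^0.75
    distribution; learning rate decays linearly over all updates.
    """

    d: int = 128
    k: int = 10
    negative: int = 5
    epochs: int = 5
    initial_learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.d < 1 or self.k < 1:
            raise ValueError("need d >= 1 and k >= 1")
        if self.negative < 1 or self.epochs < 1 or self.initial_learning_rate <= 0:
            raise ValueError("invalid training hyperparameters")


@dataclass(frozen=True)
class WalkCorpus:
    walks: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.walks)

    def __iter__(self):
        return iter(self.walks)

    def nodes(self) -> set[str]:
        return {n for w in self.walks for n in w}


class EmbeddingMatrix:
    """Per-node continuous vectors of a fixed dimension d.

    Mapping-like: ``emb[node]`` returns the vector, ``node in emb`` tests
    membership, iteration yields node identifiers in sorted order.  Nodes
    that occurred in no walk have no vector.
    """

    def __init__(self, nodes: Sequence[str], matrix: np.ndarray):
        if len(nodes) != matrix.shape[0]:
            raise ValueError("node list and matrix rows differ")
        order = np.argsort(np.asarray(nodes, dtype=object))
        self._nodes = [nodes[i] for i in order]
        self._matrix = np.asarray(matrix, dtype=np.float64)[order]
        self._index = {n: i for i, n in enumerate(self._nodes)}

    @property
    def dim(self) -> int:
        return self._matrix.shape[1]

    @property
    def nodes(self) -> list[str]:
        return list(self._nodes)

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    def __getitem__(self, node: str) -> np.ndarray:
        return self._matrix[self._index[node]]


# ---------------------------------------------------------------------------
# transition biases and alias sampling

def transition_bias(prev, candidate, graph_distance_prev_to_candidate: int,
                    p: float, q: float) -> float:
    """Search bias alpha for stepping to ``candidate`` after visiting
    ``prev``: 1/p at distance 0 (return), 1 at distance 1, 1/q at
    distance 2 (outward)."""
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    d = graph_distance_prev_to_candidate
    if d == 0:
        return 1.0 / p
    if d == 1:
        return 1.0
    if d == 2:
        return 1.0 / q
    raise ValueError(f"distance must be 0, 1 or 2, got {d}")


def _alias_setup(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Walker's alias method: O(n) setup, O(1) draws."""
    n = len(probs)
    q = probs * n
    alias = np.zeros(n, dtype=np.int64)
    small = [i for i in range(n) if q[i] < 1.0]
    large = [i for i in range(n) if q[i] >= 1.0]
    while small and large:
        s, g = small.pop(), large.pop()
        alias[s] = g
        q[g] = q[g] - (1.0 - q[s])
        (small if q[g] < 1.0 else large).append(g)
    return alias, q


def _alias_draw(alias: np.ndarray, q: np.ndarray, rng: np.random.Generator) -> int:
    i = int(rng.integers(len(q)))
    return i if rng.random() < q[i] else int(alias[i])


class _WalkSampler:
    """Precomputed alias tables for first- and second-order transitions."""

    def __init__(self, graph: nx.Graph, cfg: WalkConfig):
        self.nbrs = {n: sorted(graph.neighbors(n)) for n in graph.nodes}
        self.nbr_sets = {n: set(v) for n, v in self.nbrs.items()}

        def w(u, v):
            return float(graph[u][v].get("weight", 1.0)) if cfg.weighted else 1.0

        self.first: dict[str, tuple] = {}
        for n, nb in self.nbrs.items():
            if not nb:
                continue
            probs = np.array([w(n, x) for x in nb])
            self.first[n] = _alias_setup(probs / probs.sum())

        self.second: dict[tuple[str, str], tuple] = {}
        for prev in self.nbrs:
            for cur in self.nbrs[prev]:
                nb = self.nbrs[cur]
                probs = np.empty(len(nb))
                for i, x in enumerate(nb):
                    if x == prev:
                        alpha = 1.0 / cfg.p
                    elif x in self.nbr_sets[prev]:
                        alpha = 1.0
                    else:
                        alpha = 1.0 / cfg.q
                    probs[i] = alpha * w(cur, x)
                self.second[(prev, cur)] = _alias_setup(probs / probs.sum())

    def walk(self, start: str, l: int, rng: np.random.Generator) -> tuple[str, ...]:
        path = [start]
        if start not in self.first:  # isolated node
            return tuple(path)
        nb = self.nbrs[start]
        path.append(nb[_alias_draw(*self.first[start], rng)])
        while len(path) < l:
            prev, cur = path[-2], path[-1]
            nb = self.nbrs[cur]
            if not nb:
                break
            path.append(nb[_alias_draw(*self.second[(prev, cur)], rng)])
        return tuple(path)


def simulate_walks(graph: nx.Graph, cfg: WalkConfig) -> WalkCorpus:
    """r biased walks of up to l nodes from every node of the graph.

    Node start order is shuffled once per walk epoch; isolated nodes yield
    length-1 walks; identical seeds yield identical corpora.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot walk on an empty graph")
    sampler = _WalkSampler(graph, cfg)
    rng = np.random.default_rng(cfg.seed)
    nodes = sorted(graph.nodes)
    walks: list[tuple[str, ...]] = []
    for _ in range(cfg.r):
        for i in rng.permutation(len(nodes)):
            walks.append(sampler.walk(nodes[int(i)], cfg.l, rng))
    return WalkCorpus(tuple(walks))


# ---------------------------------------------------------------------------
# skip-gram with negative sampling

def train_skipgram(walks: WalkCorpus, cfg: TrainConfig) -> EmbeddingMatrix:
    """SGNS over walk windows, plain per-pair SGD, linear LR decay.

    Every node within k positions of a center node forms a positive
    (center, context) pair; each positive is contrasted against
    ``cfg.negative`` noise nodes from the unigram^0.75 distribution.
    Input vectors are returned as the embedding.
    """
    if len(walks) == 0 or all(len(w) == 0 for w in walks):
        raise ValueError("walk corpus is empty")
    vocab = sorted(walks.nodes())
    if not vocab:
        raise ValueError("walk corpus contains no nodes")
    index = {n: i for i, n in enumerate(vocab)}
    counts = np.zeros(len(vocab))
    for w in walks:
        for n in w:
            counts[index[n]] += 1

    noise = counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(cfg.seed)
    n, d = len(vocab), cfg.d
    W = (rng.random((n, d)) - 0.5) / d  # input (embedding) vectors
    C = np.zeros((n, d))                # output (context) vectors

    n_pairs = 0
    for w in walks:
        for i in range(len(w)):
            n_pairs += min(i, cfg.k) + min(len(w) - 1 - i, cfg.k)
    total = n_pairs * cfg.epochs
    if total == 0:
        raise ValueError("no (center, context) pairs under window k")

    lr0, lr_min = cfg.initial_learning_rate, cfg.initial_learning_rate * 1e-4
    done = 0
    for _ in range(cfg.epochs):
        for walk in walks:
            ids = [index[node] for node in walk]
            for i, center in enumerate(ids):
                lo, hi = max(0, i - cfg.k), min(len(ids), i + cfg.k + 1)
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ctx = ids[j]
                    lr = max(lr_min, lr0 * (1.0 - done / total))
                    done += 1
                    negs = np.searchsorted(noise_cdf, rng.random(cfg.negative))
                    targets = np.concatenate(([ctx], negs[negs != ctx]))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    wc = W[center]
                    ct = C[targets]
                    scores = np.clip(ct @ wc, -30.0, 30.0)
                    g = (labels - 1.0 / (1.0 + np.exp(-scores))) * lr
                    W[center] = wc + g @ ct
                    C[targets] += np.outer(g, wc)
    return EmbeddingMatrix(vocab, W)


# ---------------------------------------------------------------------------
# composed pipelines

def node2vec_embed(
    graph: nx.Graph,
    walk_cfg: WalkConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> EmbeddingMatrix:
    """Biased walks then SGNS; defaults p=1, q=0.5, d=128, r=l=10, k=10."""
    walk_cfg = walk_cfg or WalkConfig()
    train_cfg = train_cfg or TrainConfig(seed=walk_cfg.seed)
    return train_skipgram(simulate_walks(graph, walk_cfg), train_cfg)


def deepwalk_embed(
    graph: nx.Graph,
    walk_cfg: WalkConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> EmbeddingMatrix:
    """node2vec with p = q = 1 forced: uniform (first-order) truncated
    walks, identical code path so equal seeds give identical walks."""
    walk_cfg = walk_cfg or WalkConfig()
    walk_cfg = WalkConfig(
        p=1.0, q=1.0, r=walk_cfg.r, l=walk_cfg.l,
        weighted=walk_cfg.weighted, seed=walk_cfg.seed,
    )
    return node2vec_embed(graph, walk_cfg, train_cfg)
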