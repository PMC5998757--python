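"""KEGG-style pathway model, indirect-path expansion and evaluation.

A pathway is a typed entity/edge model: entities are genes, diseases or
molecular functions; edges are direct (solid line, physical interaction) or
indirect (dotted line, mediated through intermediates in an auxiliary
pathway).  Indirect edges are expanded through explicit chains of
intermediates into direct links, which form the evaluation set for link
prediction.  Evaluation compares per-method rank tables: capture counts at
K, within-threshold counts, head-to-head rank comparisons, direction
reversal and hub (degree-centrality) analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .ranking import NOT_CAPTURED, RankRecord, rank_of_target, top_k_similar

__all__ = [
    "PathwayEntity",
    "PathwayEdge",
    "ExpansionChain",
    "Pathway",
    "EvaluationReport",
    "expand_indirect_paths",
    "undirected_expansion_links",
    "capture_count",
    "within_rank_count",
    "head_to_head",
    "direction_reversal",
    "degree_centrality",
    "build_extended_network",
    "load_t2d_fixture",
]

GENE = "gene"
DISEASE = "disease"
MOLECULAR_FUNCTION = "molecular_function"

DIRECT = "direct"
INDIRECT = "indirect"


@dataclass(frozen=True)
class PathwayEntity:
    """Pathway node.  ``canonical`` is the merged label used on edges when
    several printed entity rows denote the same molecule (e.g. IRS1 and IRS
    are one node IRS1/IRS)."""

    id: str
    entity_type: str = GENE
    canonical: str | None = None

    @property
    def canonical_id(self) -> str:
        return self.canonical or self.id


@dataclass(frozen=True)
class PathwayEdge:
    source: str
    target: str
    interaction: str = DIRECT  # direct | indirect
    directed: bool = True
    participating_pathway: str | None = None

    def __post_init__(self):
        if self.source == self.target:
            raise ValueError(f"self-edge {self.source!r}")
        if self.interaction not in (DIRECT, INDIRECT):
            raise ValueError(f"unknown interaction type {self.interaction!r}")


@dataclass(frozen=True)
class ExpansionChain:
    """Chain of intermediates replacing one indirect edge.

    ``chain`` runs between the indirect edge's two endpoints (in either
    orientation, following the auxiliary pathway's flow); consecutive pairs
    become direct links.  Steps listed in ``undirected_steps`` (0-based) are
    links the auxiliary pathway leaves undirected: they belong to the
    extended network but not to the directed evaluation set.
    """

    edge_ref: int
    chain: tuple[str, ...]
    undirected_steps: frozenset[int] = frozenset()

    def __post_init__(self):
        if len(self.chain) < 3:
            raise ValueError("expansion chain needs at least one intermediate")
        bad = [i for i in self.undirected_steps if not 0 <= i < len(self.chain) - 1]
        if bad:
            raise ValueError(f"undirected step index out of range: {bad}")

    def pairs(self) -> list[tuple[str, str, bool]]:
        """(source, target, directed) for each consecutive chain pair."""
        return [
            (a, b, i not in self.undirected_steps)
            for i, (a, b) in enumerate(zip(self.chain, self.chain[1:]))
        ]


@dataclass
class Pathway:
    """Typed entity/edge pathway model."""

    entities: list[PathwayEntity] = field(default_factory=list)
    edges: list[PathwayEdge] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.id for e in self.entities]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate entity identifiers in pathway")

    @property
    def canonical_ids(self) -> set[str]:
        return {e.canonical_id for e in self.entities}

    def entity_type(self, canonical_id: str) -> str | None:
        for e in self.entities:
            if e.canonical_id == canonical_id:
                return e.entity_type
        return None

    def gene_gene_edges(self) -> list[PathwayEdge]:
        return [
            e
            for e in self.edges
            if self.entity_type(e.source) in (GENE, None)
            and self.entity_type(e.target) in (GENE, None)
        ]

    def direct_edges(self) -> list[PathwayEdge]:
        return [e for e in self.edges if e.interaction == DIRECT]

    def indirect_edges(self) -> list[PathwayEdge]:
        return [e for e in self.edges if e.interaction == INDIRECT]


# ---------------------------------------------------------------------------
# expansion

def _validate_chains(pathway: Pathway, chains: Sequence[ExpansionChain]) -> None:
    for ch in chains:
        if not 0 <= ch.edge_ref < len(pathway.edges):
            raise ValueError(f"chain references edge {ch.edge_ref}, pathway has {len(pathway.edges)}")
        edge = pathway.edges[ch.edge_ref]
        if edge.interaction != INDIRECT:
            raise ValueError(
                f"chain expands edge {edge.source}->{edge.target}, which is direct"
            )
        if {ch.chain[0], ch.chain[-1]} != {edge.source, edge.target}:
            raise ValueError(
                f"chain endpoints {ch.chain[0]}..{ch.chain[-1]} do not match "
                f"edge {edge.source}->{edge.target}"
            )


def expand_indirect_paths(
    pathway: Pathway, chains: Sequence[ExpansionChain]
) -> list[tuple[str, str]]:
    """Directed direct links after expanding indirect edges through chains.

    Returns the union of (a) the pathway's original direct gene-gene edges
    and (b) the directed consecutive pairs of every chain, deduplicated as
    ordered pairs in first-seen order.
    """
    _validate_chains(pathway, chains)
    out: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()

    def push(a: str, b: str) -> None:
        if (a, b) not in seen:
            seen.add((a, b))
            out.append((a, b))

    for e in pathway.direct_edges():
        if pathway.entity_type(e.source) in (GENE, None) and pathway.entity_type(e.target) in (GENE, None):
            push(e.source, e.target)
    for ch in chains:
        for a, b, directed in ch.pairs():
            if directed:
                push(a, b)
    return out


def undirected_expansion_links(chains: Sequence[ExpansionChain]) -> list[tuple[str, str]]:
    """Undirected links produced by chain steps marked undirected,
    deduplicated as unordered pairs in first-seen order."""
    out: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    for ch in chains:
        for a, b, directed in ch.pairs():
            if not directed and frozenset((a, b)) not in seen:
                seen.add(frozenset((a, b)))
                out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# evaluation metrics

def capture_count(records: Iterable[RankRecord], k: int | None = None) -> int:
    """Number of links whose target appeared in the start's top-K list."""
    records = list(records)
    if k is not None:
        ks = {r.k for r in records}
        if ks and ks != {k}:
            raise ValueError(f"records computed at K={sorted(ks)}, expected {k}")
    return sum(1 for r in records if r.rank is not NOT_CAPTURED)


def within_rank_count(records: Iterable[RankRecord], threshold: int) -> int:
    """Number of captured links with rank <= threshold."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return sum(1 for r in records if r.rank is not NOT_CAPTURED and r.rank <= threshold)


def head_to_head(
    a: Sequence[RankRecord], b: Sequence[RankRecord]
) -> tuple[int, int, int]:
    """Rank comparison of method a vs method b over shared pairs.

    Over pairs captured by BOTH methods: a win when a ranks strictly higher
    (smaller rank), a loss when strictly lower, a tie when equal.  Pairs
    missing from either method are excluded from the triple.
    """
    amap = {(r.start, r.target): r.rank for r in a}
    bmap = {(r.start, r.target): r.rank for r in b}
    if set(amap) != set(bmap):
        raise ValueError("rank tables cover different (start, target) pairs")
    wins = losses = ties = 0
    for pair, ra in amap.items():
        rb = bmap[pair]
        if ra is NOT_CAPTURED or rb is NOT_CAPTURED:
            continue
        if ra < rb:
            wins += 1
        elif ra > rb:
            losses += 1
        else:
            ties += 1
    return wins, losses, ties


def direction_reversal(emb, pairs, k: int = 100, node_types=None, type_filter=GENE):
    """Forward vs reversed rank for each (start, target) pair.

    Uses the same embedding both ways; because the competitor set changes
    with the starting node, reversing a pair can change (or lose) its rank
    even though cosine similarity itself is symmetric.
    """
    out = []
    for start, target in pairs:
        fwd = _rank_one(emb, start, target, k, node_types, type_filter, "forward")
        rev = _rank_one(emb, target, start, k, node_types, type_filter, "reversed")
        out.append(((start, target), fwd, rev))
    return out


def _rank_one(emb, start, target, k, node_types, type_filter, method):
    if start not in emb:
        return RankRecord(start, target, NOT_CAPTURED, k, method)
    lst = top_k_similar(emb, start, k, type_filter=type_filter, node_types=node_types)
    rec = rank_of_target(lst, target)
    return RankRecord(rec.start, rec.target, rec.rank, rec.k, method)


def degree_centrality(network: nx.Graph) -> dict[str, int]:
    """Raw degree per node (incident edge count, direction ignored)."""
    g = network.to_undirected() if network.is_directed() else network
    return {n: int(d) for n, d in g.degree()}


def build_extended_network(
    direct_links: Iterable[tuple[str, str]],
    extra_undirected: Iterable[tuple[str, str]] = (),
) -> nx.Graph:
    """Undirected network over the union of directed links and extra
    undirected links, deduplicated as unordered pairs."""
    g = nx.Graph()
    for a, b in list(direct_links) + list(extra_undirected):
        g.add_edge(a, b)
    return g


@dataclass
class EvaluationReport:
    """Summary of a multi-method pathway evaluation."""

    k: int
    rank_threshold: int
    n_links: int
    captured: dict[str, int]
    within_threshold: dict[str, int]
    missing: dict[str, int]
    head_to_head_results: dict[tuple[str, str], tuple[int, int, int]]
    hub_table: list[tuple[str, int]]

    def to_text(self) -> str:
        lines = [f"Evaluation over {self.n_links} direct links (K={self.k})"]
        for m in sorted(self.captured):
            lines.append(
                f"  {m}: captured {self.captured[m]}, "
                f"within rank {self.rank_threshold}: {self.within_threshold[m]}, "
                f"missing: {self.missing[m]}"
            )
        for (a, b), (w, l, t) in self.head_to_head_results.items():
            lines.append(f"  {a} vs {b}: wins {w}, losses {l}, ties {t}")
        if self.hub_table:
            hub, deg = self.hub_table[0]
            lines.append(f"  hub: {hub} (degree {deg})")
        return "\n".join(lines)


def evaluate_rank_tables(
    tables: Mapping[str, Sequence[RankRecord]],
    k: int = 100,
    rank_threshold: int = 10,
    extended_network: nx.Graph | None = None,
) -> EvaluationReport:
    """Build the full evaluation report from per-method rank tables."""
    methods = sorted(tables)
    n_links = len(next(iter(tables.values()))) if tables else 0
    captured = {m: capture_count(tables[m]) for m in methods}
    within = {m: within_rank_count(tables[m], rank_threshold) for m in methods}
    missing = {m: n_links - captured[m] for m in methods}
    h2h = {}
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            h2h[(a, b)] = head_to_head(tables[a], tables[b])
    hub_table: list[tuple[str, int]] = []
    if extended_network is not None:
        deg = degree_centrality(extended_network)
        hub_table = sorted(deg.items(), key=lambda t: (-t[1], t[0]))
    return EvaluationReport(k, rank_threshold, n_links, captured, within, missing, h2h, hub_table)


# ---------------------------------------------------------------------------
# shipped type 2 diabetes fixture

def load_t2d_fixture():
    """The shipped insulin-resistance subnetwork of the KEGG type 2
    diabetes pathway: (pathway, expansion chains, per-method rank table,
    extra undirected links).

    The pathway has the 19 printed entity rows (merged labels on edges),
    18 gene-gene edges of which 9 are indirect, expansion chains through
    the insulin-signaling and adipocytokine-signaling pathways, and the
    published top-100 ranks for node2vec, co-occurrence and DeepWalk over
    the 30 expanded direct links.
    """
    from . import io as _io

    pathway, chains = _io.read_pathway_json(_io.fixture_path("t2d_pathway.json"))
    tables = _io.read_rank_table_tsv(_io.fixture_path("t2d_ranks.tsv"))
    extra = undirected_expansion_links(chains)
    return pathway, chains, tables, extra
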