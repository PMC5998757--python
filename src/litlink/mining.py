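"""Sentence-level gene mention extraction and co-occurrence networks.

The pipeline links two biological entities whenever they are mentioned in
the same sentence; the edge weight of the resulting undirected network is
the number of co-mentioning sentences.  Entity recognition is dictionary
based: every canonical entity carries a synonym list and a semantic-type
label (mirroring UMLS Gene/Protein-like types), matches are case-insensitive
at token boundaries, and overlapping candidates are resolved longest-first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "GeneDictionary",
    "Mention",
    "AbstractRecord",
    "split_sentences",
    "extract_mentions",
    "build_cooccurrence_graph",
    "cooccurrence_topk",
]

#: semantic types accepted as gene/protein-like (UMLS-style labels)
GENE_LIKE_TYPES = frozenset(
    {
        "gene",
        "Gene or Genome",
        "Enzyme",
        "Receptor",
        "Amino Acid, Peptide, or Protein",
    }
)

DEFAULT_GENE_TYPE = "gene"


@dataclass(frozen=True)
class AbstractRecord:
    """One PubMed-style document: identifier, title and abstract text."""

    pmid: str
    title: str
    abstract: str

    def sentences(self, include_title: bool = True) -> list[str]:
        """Sentences of the record; the title counts as sentence 0."""
        out: list[str] = []
        if include_title and self.title.strip():
            out.append(self.title.strip())
        out.extend(split_sentences(self.abstract))
        return out


@dataclass(frozen=True)
class Mention:
    canonical_id: str
    surface_form: str
    sentence_index: int = 0
    record_id: str = ""
    start: int = 0


class GeneDictionary:
    """Canonical entity -> (synonyms, semantic type) lookup.

    The first synonym of each entry is treated as the primary surface form.
    The canonical identifier itself is always matchable.
    """

    def __init__(self, entries: dict[str, tuple[Sequence[str], str]] | None = None):
        self._entries: dict[str, tuple[tuple[str, ...], str]] = {}
        if entries:
            for cid, (syns, stype) in entries.items():
                self.add(cid, syns, stype)

    def add(self, canonical_id: str, synonyms: Iterable[str], semantic_type: str = DEFAULT_GENE_TYPE) -> None:
        if not canonical_id:
            raise ValueError("canonical identifier must be non-empty")
        syns = tuple(dict.fromkeys(s for s in synonyms))  # dedup, keep order
        if any(not s for s in syns):
            raise ValueError(f"empty synonym for {canonical_id!r}")
        if not syns:
            syns = (canonical_id,)
        self._entries[canonical_id] = (syns, semantic_type)
        self._invalidate()

    def _invalidate(self) -> None:
        self.__dict__.pop("_surface_index", None)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, canonical_id: str) -> bool:
        return canonical_id in self._entries

    def __iter__(self):
        return iter(self._entries)

    def synonyms(self, canonical_id: str) -> tuple[str, ...]:
        return self._entries[canonical_id][0]

    def semantic_type(self, canonical_id: str) -> str:
        return self._entries[canonical_id][1]

    def primary_name(self, canonical_id: str) -> str:
        return self._entries[canonical_id][0][0]

    @property
    def surface_index(self) -> list[tuple[str, str]]:
        """(surface_lower, canonical_id) pairs, longest surface first."""
        idx = self.__dict__.get("_surface_index")
        if idx is None:
            pairs: dict[str, str] = {}
            for cid, (syns, _stype) in self._entries.items():
                for s in (cid, *syns):
                    pairs.setdefault(s.lower(), cid)
            idx = sorted(pairs.items(), key=lambda kv: (-len(kv[0]), kv[0]))
            self.__dict__["_surface_index"] = idx
        return idx

    def items(self):
        return self._entries.items()


# ---------------------------------------------------------------------------
# sentence splitting

# tokens that end with a period but do not terminate a sentence
_ABBREVIATIONS = frozenset(
    {
        "i.e",
        "e.g",
        "etc",
        "vs",
        "cf",
        "ca",
        "al",
        "fig",
        "figs",
        "no",
        "dr",
        "st",
        "approx",
        "resp",
    }
)

_BOUNDARY = re.compile(r"([.!?]+)(\s+)")


def split_sentences(text: str) -> list[str]:
    """Split text into sentences at ``.!?`` followed by whitespace.

    Common abbreviations ("i.e.", "e.g.", "Fig.", single initials) and
    boundaries followed by a lowercase letter do not split.  Joining the
    returned sentences with single spaces recovers the input modulo
    boundary whitespace; empty input yields an empty list.
    """
    if not text or not text.strip():
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end(1)  # boundary candidate: keep terminator with sentence
        nxt = m.end(2)
        if nxt < len(text) and text[nxt].islower():
            continue
        # token preceding the terminator, without the terminator itself
        head = text[start : m.start(1)]
        raw_token = head.split()[-1] if head.split() else ""
        raw_token = raw_token.strip("()[]\"'")
        token = raw_token.lower()
        if token in _ABBREVIATIONS or token.rstrip(".") in _ABBREVIATIONS:
            continue
        # a single capital letter is a name initial only when followed by
        # another initial ("Smith J. A."); otherwise it may end a sentence
        after = text[nxt:].split(maxsplit=1)
        if re.fullmatch(r"[A-Z]", raw_token) and after and re.fullmatch(r"[A-Z]\.", after[0]):
            continue
        chunk = text[start:end].strip()
        if chunk:
            sentences.append(chunk)
        start = nxt
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# ---------------------------------------------------------------------------
# mention extraction

_token_boundary_cache: dict[str, re.Pattern] = {}


def _surface_pattern(surface_lower: str) -> re.Pattern:
    pat = _token_boundary_cache.get(surface_lower)
    if pat is None:
        # token boundary = non-alphanumeric delimiters; hyphens and slashes
        # inside a synonym are matched literally
        pat = re.compile(
            r"(?<![A-Za-z0-9])" + re.escape(surface_lower) + r"(?![A-Za-z0-9])",
            re.IGNORECASE,
        )
        _token_boundary_cache[surface_lower] = pat
    return pat


def extract_mentions(
    sentence: str,
    dictionary: GeneDictionary,
    sentence_index: int = 0,
    record_id: str = "",
) -> list[Mention]:
    """Dictionary matches in one sentence, longest-match-first.

    Matching is case-insensitive at token boundaries; once a span is claimed
    by a longer synonym, shorter overlapping synonyms are suppressed.  Each
    canonical entity is reported at most once per sentence, at its first
    occurrence, and mentions are returned in order of appearance.
    """
    if len(dictionary) == 0:
        raise ValueError("dictionary must be non-empty")
    claimed: list[tuple[int, int]] = []
    found: dict[str, tuple[int, str]] = {}
    for surface, cid in dictionary.surface_index:
        for m in _surface_pattern(surface).finditer(sentence):
            span = (m.start(), m.end())
            if any(s < span[1] and span[0] < e for s, e in claimed):
                continue
            claimed.append(span)
            prev = found.get(cid)
            if prev is None or span[0] < prev[0]:
                found[cid] = (span[0], m.group(0))
    return [
        Mention(cid, surf, sentence_index, record_id, start)
        for cid, (start, surf) in sorted(found.items(), key=lambda kv: (kv[1][0], kv[0]))
    ]


# ---------------------------------------------------------------------------
# co-occurrence network

def build_cooccurrence_graph(
    records: Iterable[AbstractRecord],
    dictionary: GeneDictionary,
    include_titles: bool = True,
) -> nx.Graph:
    """Sentence-level co-occurrence network over a corpus.

    Nodes are canonical entities (attribute ``semantic_type``); the weight
    of edge (u, v) is the number of sentences mentioning both u and v.
    Entities co-mentioned only across different sentences of one abstract
    share no edge.  An empty corpus yields an empty graph.
    """
    g = nx.Graph()
    for rec in records:
        for si, sent in enumerate(rec.sentences(include_title=include_titles)):
            ids = sorted({m.canonical_id for m in extract_mentions(sent, dictionary, si, rec.pmid)})
            for cid in ids:
                if cid not in g:
                    g.add_node(cid, semantic_type=dictionary.semantic_type(cid))
            for i, u in enumerate(ids):
                for v in ids[i + 1 :]:
                    if g.has_edge(u, v):
                        g[u][v]["weight"] += 1
                    else:
                        g.add_edge(u, v, weight=1)
    return g


def cooccurrence_topk(
    graph: nx.Graph,
    start: str,
    k: int = 100,
    type_filter: str | None = DEFAULT_GENE_TYPE,
) -> list[tuple[str, int]]:
    """Top-k co-occurring neighbours of ``start`` by descending count.

    Ranks only direct neighbours (entities never co-mentioned with the start
    have count 0 and are not ranked).  Ties are broken lexicographically by
    canonical identifier; ranks are 1-based by list position.
    """
    if start not in graph:
        raise KeyError(f"entity {start!r} not in co-occurrence graph")
    cands = []
    for nbr in graph.neighbors(start):
        if type_filter is not None and graph.nodes[nbr].get("semantic_type") != type_filter:
            continue
        cands.append((nbr, int(graph[start][nbr]["weight"])))
    cands.sort(key=lambda t: (-t[1], t[0]))
    return cands[:k]
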