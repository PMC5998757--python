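"""Readers and writers for the pipeline's file formats.

Formats: PubMed-style XML (read/write), plain TSV corpus, dictionary TSV
(canonical_id, semantic_type, pipe-separated synonyms), weighted edge-list
TSV and GraphML for graphs, word2vec text format for embeddings, a JSON
schema for pathways (entities / edges / expansions) and a long-format TSV
for rank tables (method, start, target, rank_or_dash, K).
"""

from __future__ import annotations

import csv
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from lxml import etree

from .embedding import EmbeddingMatrix
from .mining import AbstractRecord, GeneDictionary
from .pathway import ExpansionChain, Pathway, PathwayEdge, PathwayEntity
from .ranking import NOT_CAPTURED, RankRecord

log = logging.getLogger(__name__)

NOT_CAPTURED_MARK = "-"


class ParseError(ValueError):
    """Malformed input file."""


def fixture_path(name: str) -> Path:
    """Path of a data file shipped with the package."""
    return Path(str(resources.files("litlink") / "data" / name))


# ---------------------------------------------------------------------------
# PubMed XML

def read_pubmed_xml(path, query: str | None = None) -> list[AbstractRecord]:
    """Parse PubmedArticle records (PMID, ArticleTitle, AbstractText).

    Records without an abstract are skipped (count logged); multi-paragraph
    abstracts are concatenated with single spaces.  When ``query`` is
    given, only records containing the phrase (case-insensitive) in title
    or abstract are kept.  Malformed XML raises ParseError naming the byte
    offset of the fault.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        line, col = exc.position
        offset = 0
        with open(path, "rb") as fh:
            for _ in range(max(0, line - 1)):
                offset += len(fh.readline())
        offset += max(0, col - 1)
        raise ParseError(f"malformed XML in {path} at byte offset {offset}: {exc.msg}") from exc
    records: list[AbstractRecord] = []
    skipped = 0
    for art in tree.iter("PubmedArticle"):
        pmid_el = art.find(".//PMID")
        title_el = art.find(".//ArticleTitle")
        abstract_parts = ["".join(el.itertext()).strip() for el in art.findall(".//AbstractText")]
        abstract = " ".join(p for p in abstract_parts if p)
        if not abstract:
            skipped += 1
            continue
        pmid = (pmid_el.text or "").strip() if pmid_el is not None else ""
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        if query is not None:
            ql = query.lower()
            if ql not in title.lower() and ql not in abstract.lower():
                continue
        records.append(AbstractRecord(pmid=pmid, title=title, abstract=abstract))
    if skipped:
        log.info("skipped %d records lacking an abstract", skipped)
    read_pubmed_xml.last_skipped = skipped  # introspectable for callers/tests
    return records


read_pubmed_xml.last_skipped = 0


def write_pubmed_xml(records: Iterable[AbstractRecord], path) -> None:
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.pmid
        article = etree.SubElement(cit, "Article")
        etree.SubElement(article, "ArticleTitle").text = rec.title
        abstract = etree.SubElement(article, "Abstract")
        etree.SubElement(abstract, "AbstractText").text = rec.abstract
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# TSV corpus

def _clean(field: str) -> str:
    return " ".join(str(field).split())


def write_corpus_tsv(records: Iterable[AbstractRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["pmid", "title", "abstract"])
        for rec in records:
            w.writerow([rec.pmid, _clean(rec.title), _clean(rec.abstract)])


def read_corpus_tsv(path) -> list[AbstractRecord]:
    out: list[AbstractRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return out
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"{path}: row {i} has {len(row)} fields, expected 3")
            out.append(AbstractRecord(pmid=row[0], title=row[1], abstract=row[2]))
    return out


# ---------------------------------------------------------------------------
# dictionary TSV

def write_dictionary_tsv(dictionary: GeneDictionary, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for cid, (syns, stype) in sorted(dictionary.items()):
            w.writerow([cid, stype, "|".join(syns)])


def read_dictionary_tsv(path) -> GeneDictionary:
    d = GeneDictionary()
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise ParseError(f"{path}: row {i} has {len(row)} fields, expected 3")
            cid, stype, syns = row
            d.add(cid, [s for s in syns.split("|") if s], stype)
    return d


# ---------------------------------------------------------------------------
# graphs

def write_edgelist_tsv(graph: nx.Graph, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for u, v, data in sorted(graph.edges(data=True)):
            w.writerow([u, v, data.get("weight", 1)])


def read_edgelist_tsv(path) -> nx.Graph:
    g = nx.Graph()
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise ParseError(f"{path}: row {i} has {len(row)} fields, expected 3")
            u, v, w = row
            weight = float(w)
            g.add_edge(u, v, weight=int(weight) if weight.is_integer() else weight)
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(str(path))


# ---------------------------------------------------------------------------
# embeddings (word2vec text format)

def write_embeddings(emb: EmbeddingMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(emb)} {emb.dim}\n")
        for node in emb:
            vec = " ".join(repr(float(x)) for x in emb[node])
            fh.write(f"{node} {vec}\n")


def read_embeddings(path) -> EmbeddingMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}: expected 'n d' header line")
        n, d = int(header[0]), int(header[1])
        nodes: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            node, vals = parts[0], parts[1:]
            if len(vals) != d:
                raise ParseError(f"{path}: vector for {node!r} has {len(vals)} values, expected {d}")
            nodes.append(node)
            rows.append([float(x) for x in vals])
    if len(nodes) != n:
        raise ParseError(f"{path}: header declares {n} vectors, found {len(nodes)}")
    return EmbeddingMatrix(nodes, np.array(rows))


def write_walks(walks, path) -> None:
    with open(path, "w") as fh:
        for walk in walks:
            fh.write(" ".join(walk) + "\n")


# ---------------------------------------------------------------------------
# pathway JSON

def write_pathway_json(pathway: Pathway, chains: Sequence[ExpansionChain], path) -> None:
    doc = {
        "entities": [
            {"id": e.id, "type": e.entity_type,
             **({"canonical": e.canonical} if e.canonical else {})}
            for e in pathway.entities
        ],
        "edges": [
            {"source": e.source, "target": e.target, "interaction": e.interaction,
             "directed": e.directed, "participating_pathway": e.participating_pathway}
            for e in pathway.edges
        ],
        "expansions": [
            {"edge_ref": c.edge_ref, "chain": list(c.chain),
             **({"undirected_steps": sorted(c.undirected_steps)} if c.undirected_steps else {})}
            for c in chains
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_pathway_json(path) -> tuple[Pathway, list[ExpansionChain]]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    try:
        entities = [
            PathwayEntity(d["id"], d.get("type", "gene"), d.get("canonical"))
            for d in doc["entities"]
        ]
        edges = [
            PathwayEdge(d["source"], d["target"], d.get("interaction", "direct"),
                        bool(d.get("directed", True)), d.get("participating_pathway"))
            for d in doc["edges"]
        ]
        chains = [
            ExpansionChain(d["edge_ref"], tuple(d["chain"]),
                           frozenset(d.get("undirected_steps", ())))
            for d in doc.get("expansions", ())
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: invalid pathway document: {exc}") from exc
    return Pathway(entities, edges), chains


# ---------------------------------------------------------------------------
# rank tables (long format: method, start, target, rank_or_dash, K)

def write_rank_table_tsv(tables: Mapping[str, Sequence[RankRecord]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["method", "start", "target", "rank", "K"])
        for method in sorted(tables):
            for r in tables[method]:
                mark = NOT_CAPTURED_MARK if r.rank is NOT_CAPTURED else r.rank
                w.writerow([method, r.start, r.target, mark, r.k])


def read_rank_table_tsv(path) -> dict[str, list[RankRecord]]:
    tables: dict[str, list[RankRecord]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        for i, row in enumerate(reader, start=2):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 5:
                raise ParseError(f"{path}: row {i} has {len(row)} fields, expected 5")
            method, start, target, rank_s, k_s = row
            rank = NOT_CAPTURED if rank_s in (NOT_CAPTURED_MARK, "–", "") else int(rank_s)
            try:
                rec = RankRecord(start, target, rank, int(k_s), method)
            except ValueError as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from exc
            tables.setdefault(method, []).append(rec)
    return tables
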