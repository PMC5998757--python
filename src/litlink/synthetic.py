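"""Synthetic PubMed-style corpora driven by a planted gene network.

Every true edge of the planted network receives a Poisson(lambda_direct)
number of sentences co-mentioning its two genes; every non-edge gene pair
receives Poisson(lambda_noise) such sentences; edges flagged as
``absent_pairs`` receive exactly zero (emulating true interactions whose
evidence lives only in full text, not abstracts).  Co-mention events are
placed in uniformly chosen distinct (abstract, sentence) slots, so one
sentence carries at most one planted pair; remaining slots are filler
sentences that may carry a singleton gene mention.  Sentences come from a
small template set — downstream matching only needs sentence boundaries
and gene tokens, so no attempt is made at realistic prose.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .mining import AbstractRecord, GeneDictionary
from .pathway import DIRECT, GENE, Pathway, PathwayEdge, PathwayEntity

__all__ = [
    "PlantedNetwork",
    "CorpusConfig",
    "generate_corpus",
    "planted_truth_pathway",
    "synthetic_dictionary",
    "stochastic_block_network",
]


def _norm_pair(u: str, v: str) -> tuple[str, str]:
    if u == v:
        raise ValueError(f"self-edge {u!r}")
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class PlantedNetwork:
    """Ground-truth gene network: true edges drive co-mentions; the
    ``absent_pairs`` subset of edges is never co-mentioned in abstracts.

    ``absent_genes`` are genes whose interactions are reported only in
    full text: they never appear in abstracts at all (no co-mentions, no
    noise, no singletons), so every edge incident to them must be in
    ``absent_pairs``.
    """

    genes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    absent_pairs: frozenset[tuple[str, str]] = frozenset()
    absent_genes: frozenset[str] = frozenset()

    @classmethod
    def create(cls, genes, edges, absent_pairs=(), absent_genes=()):
        genes = tuple(genes)
        edges = frozenset(_norm_pair(*e) for e in edges)
        absent = frozenset(_norm_pair(*e) for e in absent_pairs)
        return cls(genes, edges, absent, frozenset(absent_genes))

    def __post_init__(self):
        gs = set(self.genes)
        if len(gs) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-edge {u!r}")
            if u not in gs or v not in gs:
                raise ValueError(f"edge endpoint not in gene list: ({u}, {v})")
        if not self.absent_pairs <= self.edges:
            raise ValueError("absent_pairs must be a subset of edges")
        if not self.absent_genes <= gs:
            raise ValueError("absent_genes must be listed genes")
        for u, v in self.edges - self.absent_pairs:
            if u in self.absent_genes or v in self.absent_genes:
                raise ValueError(
                    f"edge ({u}, {v}) touches an absent gene but is not in absent_pairs"
                )

    def present_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges - self.absent_pairs)

    def non_edges(self) -> list[tuple[str, str]]:
        """Non-edge pairs of corpus-present genes (noise candidates)."""
        present = sorted(set(self.genes) - self.absent_genes)
        return sorted(
            p for p in itertools.combinations(present, 2)
            if p not in self.edges
        )


@dataclass(frozen=True)
class CorpusConfig:
    """Corpus-level generation rates.

    lambda_direct / lambda_noise are expected co-mention sentence counts
    per true edge / per non-edge pair over the whole corpus.
    """

    n_abstracts: int = 2000
    sentences_per_abstract: tuple[int, int] = (4, 8)  # inclusive range
    lambda_direct: float = 50.0
    lambda_noise: float = 0.5
    synonym_usage_prob: float = 0.2
    singleton_prob: float = 0.1
    titles_with_genes: bool = False
    seed: int = 0

    def __post_init__(self):
        spa = self.sentences_per_abstract
        if isinstance(spa, int):
            object.__setattr__(self, "sentences_per_abstract", (spa, spa))
        lo, hi = self.sentences_per_abstract
        if self.n_abstracts < 1 or lo < 1 or hi < lo:
            raise ValueError("invalid corpus size parameters")
        if self.lambda_direct <= 0:
            raise ValueError("lambda_direct must be positive")
        if self.lambda_noise < 0:
            raise ValueError("lambda_noise must be non-negative")
        for prob in (self.synonym_usage_prob, self.singleton_prob):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


_PAIR_TEMPLATES = (
    "{a} interacts with {b} in pancreatic beta cells.",
    "Expression of {a} was correlated with {b} in patient cohorts.",
    "{a} signaling modulates {b} activity under hyperglycemic conditions.",
    "We observed that {a} binds {b} during insulin stimulation.",
    "Inhibition of {a} reduced {b} phosphorylation in vivo.",
)

_SINGLETON_TEMPLATES = (
    "Levels of {a} were elevated in the treatment group.",
    "The role of {a} in glucose homeostasis remains unclear.",
    "{a} expression was measured by quantitative PCR.",
)

_FILLER_SENTENCES = (
    "Patients were recruited from three clinical centers.",
    "Statistical analysis was performed with standard methods.",
    "Glucose tolerance tests were administered at baseline.",
    "The cohort was followed for five years.",
    "Dietary intake was assessed by questionnaire.",
)

_TITLE_TEMPLATES = (
    "A cohort study of metabolic regulation in type 2 diabetes",
    "Molecular mechanisms of insulin resistance revisited",
    "Signaling pathways in glucose homeostasis",
)


def synthetic_dictionary(genes, semantic_type: str = GENE) -> GeneDictionary:
    """Two-synonym dictionary for synthetic genes: the identifier itself
    and a lowercase '-syn' variant, to exercise canonicalization."""
    d = GeneDictionary()
    for g in genes:
        d.add(g, (g, f"{g.lower()}-syn"), semantic_type)
    return d


def _surface(gene: str, dictionary: GeneDictionary, cfg: CorpusConfig,
             rng: np.random.Generator) -> str:
    syns = dictionary.synonyms(gene)
    if len(syns) > 1 and rng.random() < cfg.synonym_usage_prob:
        return syns[1 + int(rng.integers(len(syns) - 1))]
    return syns[0]


def generate_corpus(
    network: PlantedNetwork,
    config: CorpusConfig,
    dictionary: GeneDictionary,
) -> list[AbstractRecord]:
    """Emit ``n_abstracts`` PubMed-style records realizing the planted
    co-mention rates.  Identical seeds give byte-identical corpora."""
    missing = [g for g in network.genes if g not in dictionary]
    if missing:
        raise ValueError(f"genes without dictionary entry: {missing}")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.sentences_per_abstract
    n_sent = rng.integers(lo, hi + 1, size=config.n_abstracts)
    slots = [(a, s) for a in range(config.n_abstracts) for s in range(int(n_sent[a]))]

    events: list[tuple[str, str]] = []
    for pair in network.present_edges():
        events.extend([pair] * int(rng.poisson(config.lambda_direct)))
    if config.lambda_noise > 0:
        for pair in network.non_edges():
            events.extend([pair] * int(rng.poisson(config.lambda_noise)))
    if len(events) > len(slots):
        raise ValueError(
            f"{len(events)} co-mention events exceed {len(slots)} sentence slots; "
            "increase n_abstracts or sentences_per_abstract"
        )
    chosen = rng.choice(len(slots), size=len(events), replace=False)

    assigned: dict[tuple[int, int], tuple[str, str]] = {
        slots[int(i)]: pair for i, pair in zip(chosen, events)
    }

    genes_sorted = sorted(set(network.genes) - network.absent_genes)
    records: list[AbstractRecord] = []
    for a in range(config.n_abstracts):
        sentences: list[str] = []
        for s in range(int(n_sent[a])):
            pair = assigned.get((a, s))
            if pair is not None:
                tpl = _PAIR_TEMPLATES[int(rng.integers(len(_PAIR_TEMPLATES)))]
                u, v = pair
                if rng.random() < 0.5:
                    u, v = v, u
                sentences.append(tpl.format(
                    a=_surface(u, dictionary, config, rng),
                    b=_surface(v, dictionary, config, rng),
                ))
            elif rng.random() < config.singleton_prob:
                tpl = _SINGLETON_TEMPLATES[int(rng.integers(len(_SINGLETON_TEMPLATES)))]
                g = genes_sorted[int(rng.integers(len(genes_sorted)))]
                sentences.append(tpl.format(a=_surface(g, dictionary, config, rng)))
            else:
                sentences.append(_FILLER_SENTENCES[int(rng.integers(len(_FILLER_SENTENCES)))])
        if config.titles_with_genes and rng.random() < 0.5:
            g = genes_sorted[int(rng.integers(len(genes_sorted)))]
            title = f"Role of {_surface(g, dictionary, config, rng)} in type 2 diabetes"
        else:
            title = _TITLE_TEMPLATES[int(rng.integers(len(_TITLE_TEMPLATES)))]
        records.append(AbstractRecord(
            pmid=f"SYN{a + 1:07d}",
            title=title,
            abstract=" ".join(sentences),
        ))
    return records


def planted_truth_pathway(network: PlantedNetwork) -> Pathway:
    """Ground-truth pathway matching the generator: every planted edge is a
    direct gene-gene interaction."""
    entities = [PathwayEntity(g, GENE) for g in sorted(network.genes)]
    edges = [
        PathwayEdge(u, v, interaction=DIRECT, directed=False)
        for u, v in sorted(network.edges)
    ]
    return Pathway(entities, edges)


def stochastic_block_network(
    n_genes: int = 30,
    n_blocks: int = 3,
    p_in: float = 0.5,
    p_out: float = 0.08,
    n_absent: int = 5,
    seed: int = 0,
) -> PlantedNetwork:
    """Assortative stochastic-block planted network with abstract-absent
    partner genes.

    The first ``n_genes - n_absent`` genes are split evenly into blocks;
    within-block pairs are edges with probability p_in, cross-block pairs
    with p_out.  Each of the last ``n_absent`` genes is an abstract-absent
    partner: it never appears in abstracts and carries exactly one true
    edge, flagged absent, to a distinct randomly chosen block gene.  This
    mirrors pathway chain links whose interacting partners are reported
    only in full text: the partner never enters the co-occurrence network,
    so no method working from abstracts can recover its link.
    """
    n_block_genes = n_genes - n_absent
    if n_block_genes < n_blocks:
        raise ValueError("need at least one block gene per block after absent partners")
    if n_absent > n_block_genes:
        raise ValueError("more absent partners than anchor genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    block_genes = genes[:n_block_genes]
    tail_genes = genes[n_block_genes:]
    block = {g: i * n_blocks // n_block_genes for i, g in enumerate(block_genes)}
    edges: list[tuple[str, str]] = []
    for u, v in itertools.combinations(block_genes, 2):
        prob = p_in if block[u] == block[v] else p_out
        if rng.random() < prob:
            edges.append((u, v))
    anchors = rng.choice(n_block_genes, size=n_absent, replace=False)
    absent = [(block_genes[int(a)], t) for a, t in zip(anchors, tail_genes)]
    return PlantedNetwork.create(genes, edges + absent, absent, tail_genes)
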