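# Methods

## Pipeline overview

`litlink` turns a corpus of abstracts into ranked gene–gene link
predictions in five stages: sentence segmentation → dictionary-based
mention extraction → sentence-level co-occurrence network → node
embedding (node2vec / DeepWalk) → cosine-similarity ranking.  Predictions
are scored against a typed pathway model whose indirect interactions have
been expanded into direct links.  This note records the modelling
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Text mining

**Sentence segmentation** is rule-based: a sentence ends at `.!?` followed
by whitespace, except after common abbreviations (i.e., e.g., Fig., no.,
etc.) and name initials (a single capital letter followed by another
initial), and never before a lowercase continuation.  Joining the output
recovers the input modulo boundary whitespace.  This is deliberately
simple; abbreviation lists are not exhaustive and biomedical prose with
unusual punctuation may over- or under-split.

**Mention extraction** is dictionary matching, not statistical NER.  Each
canonical entity carries a synonym list and a semantic-type label
(gene / disease / …), so type filtering of candidate pools stays
expressible.  Matching is case-insensitive at token boundaries (token
boundary = non-alphanumeric character; hyphens and slashes inside a
synonym such as `TNF-alpha` are literal), overlapping candidates are
resolved longest-match-first, and synonyms canonicalize to one node
(IRS1 and IRS are one entity `IRS1/IRS`).  A dictionary makes the whole
pipeline deterministic and testable against a brute-force all-substring
oracle; the price is no abbreviation disambiguation and no species
resolution.

**Co-occurrence network.** Two entities are linked when they are mentioned
in the same sentence; the edge weight is the number of such sentences.
The title counts as sentence 0, since corpora are typically filtered on
titles and abstracts.  No weight pruning is applied (weight ≥ 1 kept).
Co-mentions across different sentences of one abstract do *not* create
edges — the sentence-level rule is the core assumption, reflecting that
same-sentence co-mention is far better correlated with a real relationship
than same-abstract co-mention.

## Embedding

The second-order walk bias is `alpha = 1/p, 1, 1/q` for candidates at
graph distance 0, 1, 2 from the previous node, multiplied by the edge
weight (weighted transitions are the default because the input network is
weighted; a flag gives the binary alternative).  Alias tables are
precomputed per directed (prev, cur) pair, making each step O(1) — the
standard engineering for second-order walks.  Walk starts are shuffled
per epoch, and isolated nodes yield length-1 walks.

Defaults follow the study settings: p = 1, q = 0.5 (outward bias →
community structure), d = 128, r = l = 10, k = 10.  Walk length l counts
nodes (10 nodes = 9 steps).  DeepWalk is node2vec with p = q = 1 forced
through the same sampler, so equal seeds give byte-identical walks — the
comparison between methods then differs only in the walk distribution.

Skip-gram with negative sampling is trained by per-pair SGD: 5 negatives
per positive from the unigram^0.75 distribution, 5 epochs, initial
learning rate 0.025 decaying linearly to 1e-4 of its start value, logits
clipped at ±30 for numerical safety.  These hyperparameters are word2vec
conventions; they are recorded in `TrainConfig` for reproducibility.
Input vectors are the embedding; output (context) vectors are discarded.
Nodes appearing in no walk get **no** vector rather than a zero vector,
because cosine similarity is undefined at zero; callers must treat missing
vectors as "cannot be ranked".

All randomness — walk shuffling, alias draws, SGNS initialisation and
negative sampling — flows from the single seed in the configs, so runs are
fully deterministic.

## Ranking

For a starting entity, all embedded nodes of the requested semantic type
(default: genes) except the start are ranked by cosine similarity; ties
break lexicographically for reproducibility.  The top-K list (K = 100)
defines capture; known co-occurrence neighbours are *not* excluded from
the candidate pool, because the evaluation asks whether known pathway
partners are recovered.  Rank asymmetry is intrinsic: cosine is symmetric
but the competitor set changes with the start, so reversing (start,
target) can change or lose the rank — this is the mechanism that lets an
undirected embedding reflect reaction direction, and it is exercised by a
hand-constructed fixture in the tests.

## Pathway model and expansion

Pathways are typed entity/edge models; indirect edges carry the auxiliary
pathway that mediates them and are expanded through explicit chains of
intermediates.  Consecutive chain pairs become direct links, deduplicated
as ordered pairs in first-seen order.  Chain steps that the auxiliary
pathway leaves undirected are flagged (`undirected_steps`): they join the
extended network but not the directed evaluation set.  This distinction is
what makes the shipped fixture internally consistent — 30 directed
evaluation links and a 29-node / 35-edge extended network from the same
chains (the five undirected links are ADIPOR–AMPKK, AMPK–GLUT4,
TRAF2–IKK, TRAF2–JNK and TRAF2–mTOR).

Fixture encoding choices: entity rows are kept as printed (19 rows, with
IRS1 and IRS as separate rows merged onto one canonical node); the
PI3K→GLUT4 expansion keeps exactly the two biologically supported chains
through PDK1/2 (via AKT and via PKC); degree centrality is raw degree, not
normalised.  One chain (for the ERK→IRS1/IRS indirect edge) is recorded in
the orientation of its auxiliary pathway, opposite to the indirect edge's
direction; chain validation therefore matches endpoint *sets*, not ordered
endpoints.

Head-to-head comparison counts wins/losses/ties over pairs captured by
both methods; pairs missed by either method are excluded from the triple,
which keeps wins + losses + ties equal to the number of co-captured pairs.

## Synthetic corpus generator

The generator emulates an abstract corpus whose sentence-level co-mention
statistics follow a planted truth network:

- each true edge receives Poisson(λ_direct) co-mention sentences over the
  corpus; each non-edge pair of corpus-present genes receives
  Poisson(λ_noise); pairs flagged absent receive exactly zero;
- co-mention events are placed in uniformly chosen distinct
  (abstract, sentence) slots, so a sentence carries at most one planted
  pair and pair counts stay independent;
- surface forms are drawn per mention (synonym with probability
  `synonym_usage_prob`, default 0.2) to exercise canonicalization; filler
  sentences may carry singleton mentions;
- sentences come from a small template set — only sentence boundaries and
  gene tokens matter downstream, so no attempt is made at realistic
  biomedical prose, MeSH terms or publication dates.

The default conditions are 2000 abstracts of 4–8 sentences, λ_direct = 50,
λ_noise = 0.5.  λ_direct = 50 makes a true edge's weight ~100× a typical
noise weight, a separation consistent with the co-mention counts a strong
literature pair accumulates relative to chance pairs; 2000 abstracts keeps
an end-to-end run in seconds.

The planted truth is an assortative stochastic block model: 3 blocks over
the non-absent genes, within-block edge probability 0.5, cross-block 0.08.
Abstract-absent links are modelled after their real-world counterpart —
interactions reported only in full text: each attaches a dedicated partner
gene that *never appears in abstracts* (no co-mentions, no noise, no
singletons) to a randomly chosen block anchor.  Such partners never enter
the co-occurrence network, so they cannot be embedded or ranked — the
precise mechanism by which abstract-level mining misses full-text-only
links.  Consequently the λ_noise contract applies to pairs of
corpus-present genes; pairs involving an abstract-absent gene are zero by
construction.

What passing tests on this generator do **not** show: robustness to real
biomedical prose (ambiguous abbreviations, nested entity names), to
heavy-tailed mention frequencies, or to corpus-scale candidate pools
(thousands of genes rather than 30).  The generator validates the
pipeline's statistical machinery, not its linguistics.

## Numerical and procedural choices

- Alias sampling uses Walker's method; tie-breaking everywhere is
  lexicographic; node iteration orders are sorted before any stochastic
  use, so graphs built in different orders give identical results.
- The walk-distribution test compares empirical transition frequencies
  against exact enumeration.  Because hundreds of frequency cells are
  checked simultaneously, the test bounds each cell at 4 standard errors
  and the fraction of distributions with any cell beyond 3 SE at the
  multiple-comparison null rate; a genuinely biased sampler shifts many
  cells by tens of SE, so power is unaffected.
- Degenerate inputs: empty graph → error; empty corpus → empty graph;
  zero vectors → explicit cosine error; unembedded starting entities →
  NOT_CAPTURED with a logged warning.

## Known limitations

- Dictionary matching cannot resolve polysemous gene symbols or detect
  entities missing from the dictionary.
- Exact reproduction of published corpus-scale rank values would require
  the original ~100k-abstract corpus; the shipped fixture reproduces every
  count derivable from the encoded tables, and synthetic runs validate the
  pipeline end to end at desk scale (30 genes, 2000 abstracts).
- The SGNS implementation is single-threaded per-pair SGD, appropriate for
  networks up to a few thousand nodes, not for web-scale graphs.
- Co-occurrence evaluation ranks only direct neighbours; entities never
  co-mentioned with the start cannot be ranked by the baseline at all.
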