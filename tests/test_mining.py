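"""Sentence splitting, dictionary matching and co-occurrence counting."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from litlink import (
    AbstractRecord,
    GeneDictionary,
    build_cooccurrence_graph,
    cooccurrence_topk,
    extract_mentions,
    split_sentences,
)

# --------------------------------------------------------------------------
# sentence splitting


@pytest.mark.parametrize(
    "text,expected",
    [
        ("", []),
        ("   ", []),
        ("A binds B. C binds D.", ["A binds B.", "C binds D."]),
        ("Only one statement", ["Only one statement"]),
        ("What now? Then stop!", ["What now?", "Then stop!"]),
    ],
)
def test_split_sentences_basic(text, expected):
    assert split_sentences(text) == expected


# hand-segmented fixture: abbreviations and initials must not split
HAND_SEGMENTED = [
    (
        "The receptor, i.e. INSR, binds insulin. IRS1 is phosphorylated.",
        [
            "The receptor, i.e. INSR, binds insulin.",
            "IRS1 is phosphorylated.",
        ],
    ),
    (
        "Samples (e.g. plasma) were analyzed. Results follow.",
        ["Samples (e.g. plasma) were analyzed.", "Results follow."],
    ),
    (
        "As shown in Fig. 2, levels rose. See also ref. no. 3.",
        ["As shown in Fig. 2, levels rose.", "See also ref. no. 3."],
    ),
    (
        "Described by Smith J. A. in 1999. Confirmed later.",
        ["Described by Smith J. A. in 1999.", "Confirmed later."],
    ),
]


@pytest.mark.parametrize("text,expected", HAND_SEGMENTED)
def test_split_sentences_abbreviations(text, expected):
    assert split_sentences(text) == expected


@given(st.lists(st.sampled_from(
    ["INS binds INSR.", "Levels rose!", "Why?", "The i.e. case stays."]),
    min_size=1, max_size=6))
@settings(derandomize=True, deadline=None)
def test_split_concatenation_recovers_text(parts):
    text = " ".join(parts)
    joined = " ".join(split_sentences(text))
    assert re.sub(r"\s+", " ", joined) == re.sub(r"\s+", " ", text)
    assert all(s.strip() for s in split_sentences(text))


# --------------------------------------------------------------------------
# mention extraction


def brute_force_matches(sentence, dictionary):
    """All dictionary surface matches at token boundaries, resolved
    longest-first: the independent oracle for extract_mentions."""
    cands = []
    low = sentence.lower()
    for surface, cid in dictionary.surface_index:
        start = 0
        while True:
            i = low.find(surface, start)
            if i < 0:
                break
            j = i + len(surface)
            left_ok = i == 0 or not low[i - 1].isalnum()
            right_ok = j == len(low) or not low[j].isalnum()
            if left_ok and right_ok:
                cands.append((len(surface), i, cid))
            start = i + 1
    chosen, claimed = {}, []
    for ln, i, cid in sorted(cands, key=lambda t: (-t[0], t[1])):
        span = (i, i + ln)
        if any(s < span[1] and span[0] < e for s, e in claimed):
            continue
        claimed.append(span)
        if cid not in chosen or span[0] < chosen[cid]:
            chosen[cid] = span[0]
    return set(chosen)


def test_extract_direct_synonym_hits(t2d_dictionary):
    ms = extract_mentions("insulin receptor activates IRS1", t2d_dictionary)
    assert {m.canonical_id for m in ms} == {"INSR", "IRS1/IRS"}


def test_extract_no_dictionary_term(t2d_dictionary):
    assert extract_mentions("nothing relevant here", t2d_dictionary) == []


def test_extract_longest_match_wins(t2d_dictionary):
    # "IRS1" must be claimed as one mention, not the shorter synonym "IRS"
    ms = extract_mentions("IRS1 was phosphorylated", t2d_dictionary)
    assert [m.surface_form for m in ms] == ["IRS1"]
    assert brute_force_matches("IRS1 was phosphorylated", t2d_dictionary) == {"IRS1/IRS"}


def test_extract_requires_token_boundary(t2d_dictionary):
    assert extract_mentions("INSRX is unrelated", t2d_dictionary) == []
    # hyphen inside a synonym is literal; hyphen is a boundary otherwise
    ms = extract_mentions("TNF-alpha rose", t2d_dictionary)
    assert [m.canonical_id for m in ms] == ["TNFA"]


@pytest.mark.parametrize(
    "sentence",
    [
        "insulin receptor binds insulin and IRS near TNF-alpha",
        "Insulin Receptor AND irs1; GLP-1 in type 2 diabetes",
        "INS INS INS and INSR",
        "no entities at all",
    ],
)
def test_extract_agrees_with_bruteforce_oracle(sentence, t2d_dictionary):
    got = {m.canonical_id for m in extract_mentions(sentence, t2d_dictionary)}
    assert got == brute_force_matches(sentence, t2d_dictionary)


@given(st.lists(st.sampled_from(
    ["insulin receptor", "IRS", "IRS1", "TNF-alpha", "filler", "words"]),
    min_size=1, max_size=8))
@settings(derandomize=True, deadline=None)
def test_extract_idempotent_and_case_insensitive(tokens):
    d = GeneDictionary({
        "INSR": (["insulin receptor"], "gene"),
        "IRS1/IRS": (["IRS1", "IRS"], "gene"),
        "TNFA": (["TNF-alpha"], "gene"),
    })
    sentence = " ".join(tokens)
    first = extract_mentions(sentence, d)
    assert extract_mentions(sentence, d) == first
    swapped = {m.canonical_id for m in extract_mentions(sentence.swapcase(), d)}
    assert swapped == {m.canonical_id for m in first}
    assert len({m.canonical_id for m in first}) == len(first)  # one per entity


def test_extract_empty_dictionary_rejected():
    with pytest.raises(ValueError):
        extract_mentions("anything", GeneDictionary())


# --------------------------------------------------------------------------
# co-occurrence graph


def _rec(pmid, abstract, title=""):
    return AbstractRecord(pmid=pmid, title=title, abstract=abstract)


def test_single_sentence_pair_weight_one(t2d_dictionary):
    g = build_cooccurrence_graph([_rec("1", "INS binds INSR.")], t2d_dictionary)
    assert g["INS"]["INSR"]["weight"] == 1


def test_weight_adds_over_sentences(t2d_dictionary):
    text = "INS binds INSR. INS binds INSR. INS binds INSR."
    g = build_cooccurrence_graph([_rec("1", text)], t2d_dictionary)
    assert g["INS"]["INSR"]["weight"] == 3


def test_cross_sentence_mentions_share_no_edge(t2d_dictionary):
    g = build_cooccurrence_graph(
        [_rec("1", "INS levels rose sharply. INSR was unchanged.")], t2d_dictionary
    )
    assert g.has_node("INS") and g.has_node("INSR")
    assert not g.has_edge("INS", "INSR")


def test_title_counts_as_sentence_zero(t2d_dictionary):
    g = build_cooccurrence_graph(
        [_rec("1", "Nothing here.", title="INS and INSR in diabetes")], t2d_dictionary
    )
    assert g["INS"]["INSR"]["weight"] == 1


def test_empty_corpus_gives_empty_graph(t2d_dictionary):
    g = build_cooccurrence_graph([], t2d_dictionary)
    assert g.number_of_nodes() == 0


def test_graph_symmetry_and_total_weight(t2d_dictionary):
    recs = [
        _rec("1", "INS binds INSR. IRS and INSR interact."),
        _rec("2", "TNF-alpha, INS and INSR were measured."),
    ]
    g = build_cooccurrence_graph(recs, t2d_dictionary)
    for u, v, data in g.edges(data=True):
        assert g[v][u]["weight"] == data["weight"]
    # total edge weight = number of co-mentioning (sentence, pair) incidences
    # sentence 1: 1 pair, sentence 2: 1 pair, sentence 3: 3 pairs
    assert sum(d["weight"] for _, _, d in g.edges(data=True)) == 5


def test_semantic_type_attached(t2d_dictionary):
    g = build_cooccurrence_graph(
        [_rec("1", "insulin in type 2 diabetes")], t2d_dictionary
    )
    assert g.nodes["INS"]["semantic_type"] == "gene"
    assert g.nodes["T2DM"]["semantic_type"] == "disease"


# --------------------------------------------------------------------------
# co-occurrence ranking baseline


def _star(weights):
    import networkx as nx

    g = nx.Graph()
    for leaf, w in weights.items():
        g.add_edge("hub", leaf, weight=w)
    for n in g.nodes:
        g.nodes[n]["semantic_type"] = "gene"
    return g


def test_topk_orders_by_weight():
    g = _star({"X": 5, "Y": 3, "Z": 1})
    assert cooccurrence_topk(g, "hub", 100) == [("X", 5), ("Y", 3), ("Z", 1)]


def test_topk_no_neighbors():
    g = _star({"X": 1})
    assert cooccurrence_topk(g, "X", 100) == [("hub", 1)]
    g.add_node("lonely", semantic_type="gene")
    assert cooccurrence_topk(g, "lonely", 100) == []


def test_topk_tie_broken_lexicographically():
    g = _star({"B": 7, "C": 7, "A": 2})
    ranked = cooccurrence_topk(g, "hub", 100)
    assert ranked == [("B", 7), ("C", 7), ("A", 2)]
    # oracle: any valid ordering must sort by (-weight, name)
    assert ranked == sorted(ranked, key=lambda t: (-t[1], t[0]))


def test_topk_type_filter_and_missing_start(t2d_dictionary):
    g = build_cooccurrence_graph(
        [AbstractRecord("1", "", "insulin in type 2 diabetes")], t2d_dictionary
    )
    assert cooccurrence_topk(g, "INS", 10, type_filter="gene") == []
    assert cooccurrence_topk(g, "INS", 10, type_filter="disease") == [("T2DM", 1)]
    with pytest.raises(KeyError):
        cooccurrence_topk(g, "ABSENT", 10)
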