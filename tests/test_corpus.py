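"""Corpus model, XML/sidecar round trips, candidate generation, blinding."""

import itertools

import pytest
from hypothesis import given, strategies as st

from ppikex.corpus import (
    CorpusError,
    DependencyEdge,
    Mention,
    ParsedSentence,
    Token,
    blind_entities,
    generate_candidates,
    read_parses,
    read_ppi_xml,
    tokenize,
    write_parses,
    write_ppi_xml,
)
from ppikex.synthetic import SynthConfig, generate_corpus


def _sentence(words, mentions=(), edges=(), gold=None, sid="s", docid="d"):
    return ParsedSentence(
        sid, docid, [Token(i, w) for i, w in enumerate(words)], list(mentions), list(edges), gold
    )


# ---------------------------------------------------------------------------
# Tokenization


@pytest.mark.parametrize(
    "text, expected",
    [
        ("A binds B.", ["A", "binds", "B", "."]),
        ("through their receptors, CXCR1", ["through", "their", "receptors", ",", "CXCR1"]),
        ("Interleukin (IL)-8 has", ["Interleukin", "(IL)-8", "has"]),  # parens stay attached
        ("'quoted'", ["'", "quoted", "'"]),
        ("...", [".", ".", "."]),  # punctuation runs split; core stays non-empty
    ],
)
def test_tokenize_splits_edge_punctuation_but_keeps_entity_parens(text, expected):
    assert [s for s, _, _ in tokenize(text)] == expected


@given(st.lists(st.text(alphabet="abcXY(-)", min_size=1, max_size=6), min_size=1, max_size=8))
def test_tokenize_offsets_recover_surfaces(words):
    text = " ".join(words)
    for surface, a, b in tokenize(text):
        assert text[a:b] == surface


# ---------------------------------------------------------------------------
# XML round trip


def test_xml_round_trip_preserves_structure(tmp_path):
    sents = generate_corpus(SynthConfig(n_docs=3, sentences_per_doc=3, seed=11))
    path = tmp_path / "corpus.xml"
    write_ppi_xml(sents, path)
    back = read_ppi_xml(path)
    assert len(back) == len(sents)
    for a, b in zip(sents, back):
        assert a.sid == b.sid and a.docid == b.docid
        assert a.surfaces == b.surfaces
        assert [(m.id, m.start, m.end) for m in a.mentions] == [
            (m.id, m.start, m.end) for m in b.mentions
        ]
        assert [c.label for c in generate_candidates(a)] == [
            c.label for c in generate_candidates(b)
        ]


def test_single_sentence_corpus_counts(tmp_path):
    xml = """<?xml version="1.0"?>
<corpus source="t"><document id="d1">
<sentence id="d1.s0" text="A binds B and C .">
 <entity id="e0" charOffset="0-0" text="A" type="protein"/>
 <entity id="e1" charOffset="8-8" text="B" type="protein"/>
 <entity id="e2" charOffset="14-14" text="C" type="protein"/>
 <pair id="p0" e1="e0" e2="e1" interaction="True"/>
 <pair id="p1" e1="e0" e2="e2" interaction="True"/>
 <pair id="p2" e1="e1" e2="e2" interaction="False"/>
</sentence></document></corpus>"""
    path = tmp_path / "one.xml"
    path.write_text(xml)
    (s,) = read_ppi_xml(path)
    assert len(s.mentions) == 3
    assert len(s.gold_pairs) == 2


def test_empty_corpus(tmp_path):
    path = tmp_path / "empty.xml"
    path.write_text('<?xml version="1.0"?><corpus source="t"/>')
    assert read_ppi_xml(path) == []


def test_malformed_xml_raises(tmp_path):
    path = tmp_path / "bad.xml"
    path.write_text("<corpus><document></corpus>")
    with pytest.raises(CorpusError, match="malformed"):
        read_ppi_xml(path)


def test_unknown_pair_entity_raises(tmp_path):
    path = tmp_path / "bad_pair.xml"
    path.write_text(
        '<corpus source="t"><document id="d"><sentence id="s" text="A binds B">'
        '<entity id="e0" charOffset="0-0" text="A" type="protein"/>'
        '<pair id="p" e1="e0" e2="missing" interaction="True"/>'
        "</sentence></document></corpus>"
    )
    with pytest.raises(CorpusError, match="unknown entity"):
        read_ppi_xml(path)


def test_unresolvable_offset_names_sentence_and_offset(tmp_path):
    path = tmp_path / "bad_off.xml"
    path.write_text(
        '<corpus source="t"><document id="d"><sentence id="sX" text="short">'
        '<entity id="e0" charOffset="40-44" text="nope" type="protein"/>'
        "</sentence></document></corpus>"
    )
    with pytest.raises(CorpusError, match="sX.*40-44"):
        read_ppi_xml(path)


def test_mid_token_offsets_snap_outward_and_round_trip(tmp_path):
    xml = (
        '<corpus source="t"><document id="d"><sentence id="s" text="ABCD binds EFGH">'
        '<entity id="e0" charOffset="1-2" text="BC" type="protein"/>'
        '<entity id="e1" charOffset="11-12" text="EF" type="protein"/>'
        "</sentence></document></corpus>"
    )
    p1 = tmp_path / "a.xml"
    p1.write_text(xml)
    (s,) = read_ppi_xml(p1)
    assert (s.mentions[0].start, s.mentions[0].end) == (0, 1)  # snapped to ABCD
    assert (s.mentions[1].start, s.mentions[1].end) == (2, 3)
    p2 = tmp_path / "b.xml"
    write_ppi_xml([s], p2)
    (s2,) = read_ppi_xml(p2)
    assert [(m.start, m.end) for m in s2.mentions] == [(m.start, m.end) for m in s.mentions]


# ---------------------------------------------------------------------------
# Parse sidecar


def test_read_parses_attaches_edges(tmp_path):
    sents = [_sentence(["A", "binds", "B"])]
    sidecar = tmp_path / "p.conll"
    sidecar.write_text(
        "s\t1\tA\tNNP\t2\tNSUBJ\ns\t2\tbinds\tVBZ\t0\tROOT\ns\t3\tB\tNNP\t2\tDOBJ\n\n"
    )
    (s,) = read_parses(sidecar, sents)
    assert s.parsed
    assert {(e.head, e.dependent, e.relation) for e in s.edges} == {
        (1, 0, "NSUBJ"), (1, 2, "DOBJ")
    }
    assert [t.pos for t in s.tokens] == ["NNP", "VBZ", "NNP"]


def test_read_parses_deduplicates_edges(tmp_path):
    sents = [_sentence(["A", "B"])]
    sidecar = tmp_path / "p.conll"
    rows = "s\t1\tA\t_\t0\tROOT\ns\t2\tB\t_\t1\tDEP\n"
    sidecar.write_text(rows + rows)  # exact duplicate rows collapse to a set
    (s,) = read_parses(sidecar, sents)
    assert len(s.edges) == 1


def test_read_parses_token_count_mismatch_names_sentence(tmp_path):
    sents = [_sentence(["A", "B", "C"], sid="sZ")]
    sidecar = tmp_path / "p.conll"
    sidecar.write_text("sZ\t1\tA\t_\t0\tROOT\nsZ\t2\tB\t_\t1\tDEP\n")
    with pytest.raises(CorpusError, match="sZ"):
        read_parses(sidecar, sents)


def test_empty_sidecar_flags_all_unparsed(tmp_path):
    sents = [_sentence(["A", "B"], sid="x"), _sentence(["C"], sid="y")]
    sidecar = tmp_path / "p.conll"
    sidecar.write_text("\n")
    out = read_parses(sidecar, sents)
    assert all(not s.parsed for s in out)


def test_parse_sidecar_round_trip(tmp_path):
    sents = generate_corpus(SynthConfig(n_docs=2, sentences_per_doc=2, seed=5))
    path = tmp_path / "p.conll"
    write_parses(sents, path)
    stripped = [
        ParsedSentence(s.sid, s.docid, [Token(t.index, t.surface) for t in s.tokens],
                       s.mentions, [], s.gold_pairs)
        for s in sents
    ]
    back = read_parses(path, stripped)
    for a, b in zip(sents, back):
        assert set(a.edges) == set(b.edges)
        assert [t.pos for t in a.tokens] == [t.pos for t in b.tokens]


# ---------------------------------------------------------------------------
# Candidate generation


def test_three_mentions_give_three_pairs(il8_sentence):
    cands = generate_candidates(il8_sentence)
    assert len(cands) == 3
    assert sum(c.label == "positive" for c in cands) == 2


def test_single_mention_no_pairs():
    s = _sentence(["A", "alone"], [Mention("m0", 0, 1, "A")])
    assert generate_candidates(s) == []


@given(st.integers(min_value=0, max_value=6))
def test_candidate_count_is_n_choose_2(n):
    words = [f"P{i}" for i in range(max(n, 1))] + ["end"]
    mentions = [Mention(f"m{i}", i, i + 1, words[i]) for i in range(n)]
    s = _sentence(words, mentions)
    cands = generate_candidates(s)
    brute = {frozenset((a.id, b.id)) for a, b in itertools.combinations(mentions, 2)}
    assert len(cands) == n * (n - 1) // 2 == len(brute)
    assert {frozenset((c.m1, c.m2)) for c in cands} == brute


def test_positive_count_matches_gold_sum(small_corpus):
    total_gold = sum(len(s.gold_pairs or ()) for s in small_corpus)
    total_pos = sum(
        sum(c.label == "positive" for c in generate_candidates(s)) for s in small_corpus
    )
    assert total_pos == total_gold


# ---------------------------------------------------------------------------
# Entity blinding


def test_blinding_places_placeholders(il8_sentence):
    pair = generate_candidates(il8_sentence)[0]  # (IL)-8 ~ CXCR1
    b = blind_entities(il8_sentence, pair)
    assert b.surfaces[1] == "ENTITY1"
    assert b.surfaces[20] == "ENTITY2"
    assert b.surfaces[22] == "PROT0"
    assert il8_sentence.surfaces[1] == "(IL)-8"  # original untouched


def test_blinding_pair_covering_all_mentions_has_no_prot0():
    s = _sentence(
        ["A", "binds", "B"], [Mention("m0", 0, 1, "A"), Mention("m1", 2, 3, "B")]
    )
    b = blind_entities(s, generate_candidates(s)[0])
    assert "PROT0" not in b.surfaces


def test_blinding_middle_mention_yields_single_prot0_run():
    s = _sentence(
        ["A", "x", "B", "y", "C"],
        [Mention("m0", 0, 1, "A"), Mention("m1", 2, 3, "B"), Mention("m2", 4, 5, "C")],
    )
    pair = next(c for c in generate_candidates(s) if {c.m1, c.m2} == {"m0", "m2"})
    b = blind_entities(s, pair)
    runs = [k for k, g in itertools.groupby(b.surfaces, key=lambda w: w == "PROT0") if k]
    assert len(runs) == 1


def test_blinding_idempotent_and_length_preserving(small_corpus):
    for s in small_corpus[:5]:
        for p in generate_candidates(s):
            b1 = blind_entities(s, p)
            b2 = blind_entities(b1, p)
            assert len(b1.tokens) == len(s.tokens)
            assert b1.surfaces == b2.surfaces


def test_blinding_foreign_pair_raises(il8_sentence, rsfa_sentence):
    foreign = generate_candidates(rsfa_sentence)[0]
    with pytest.raises(CorpusError, match="does not belong"):
        blind_entities(il8_sentence, foreign)


def test_dependency_edge_rejects_self_loop():
    with pytest.raises(CorpusError):
        DependencyEdge(2, 2, "X")
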