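"""Corpus model and I/O for sentence-level protein interaction candidates.

The on-disk dialect is the unified PPI XML used by the public benchmark
releases (AIMed, BioInfer, IEPA, HPRD50, LLL): a ``corpus`` of ``document``
elements, each holding ``sentence`` elements with ``entity`` children located
by inclusive character offsets and ``pair`` children carrying gold interaction
labels.  Dependency parses travel in a CoNLL-style tab-separated sidecar
aligned to sentences by id.

Internally everything is 0-based with half-open token spans.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from lxml import etree

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"

#: Placeholders used when blinding a candidate pair.
ENTITY1 = "ENTITY1"
ENTITY2 = "ENTITY2"
PROT_OTHER = "PROT0"

# Characters peeled off token edges.  Parentheses and hyphens stay attached:
# they occur inside entity names such as "(IL)-8" and must not be separated.
_STRIP_CHARS = ".,;:!?\"'`"


class CorpusError(ValueError):
    """Raised for malformed corpora, parses, or candidate references."""


@dataclass(frozen=True)
class Token:
    index: int
    surface: str
    pos: str = ""

    def __post_init__(self) -> None:
        if not self.surface:
            raise CorpusError(f"empty token surface at index {self.index}")


@dataclass(frozen=True)
class Mention:
    """A tagged entity occupying the half-open token span [start, end)."""

    id: str
    start: int
    end: int
    text: str
    etype: str = "protein"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(f"mention {self.id}: bad span [{self.start}, {self.end})")


@dataclass(frozen=True)
class DependencyEdge:
    head: int
    dependent: int
    relation: str

    def __post_init__(self) -> None:
        if self.head == self.dependent:
            raise CorpusError(f"self-loop dependency at token {self.head}")


@dataclass
class ParsedSentence:
    sid: str
    docid: str
    tokens: list[Token]
    mentions: list[Mention] = field(default_factory=list)
    edges: list[DependencyEdge] = field(default_factory=list)
    gold_pairs: set[frozenset[str]] | None = None
    parsed: bool = False

    def __post_init__(self) -> None:
        n = len(self.tokens)
        for m in self.mentions:
            if m.end > n:
                raise CorpusError(f"{self.sid}: mention {m.id} exceeds sentence length")
        for e in self.edges:
            if not (0 <= e.head < n and 0 <= e.dependent < n):
                raise CorpusError(f"{self.sid}: dependency edge {e} out of range")
        ids = {m.id for m in self.mentions}
        for gp in self.gold_pairs or ():
            if len(gp) != 2 or not gp <= ids:
                raise CorpusError(f"{self.sid}: gold pair {set(gp)} references unknown mention")

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def mention_by_id(self, mid: str) -> Mention:
        for m in self.mentions:
            if m.id == mid:
                return m
        raise CorpusError(f"{self.sid}: unknown mention id {mid!r}")

    def mention_head(self, m: Mention) -> int:
        """Token index of the mention's syntactic head.

        The head is the span token whose governor lies outside the span (or
        which is the root); multi-headed or unparsed spans fall back to the
        last token, which is the head of most English noun phrases.
        """
        head_of = {e.dependent: e.head for e in self.edges}
        inside = range(m.start, m.end)
        heads = [i for i in inside if head_of.get(i, -1) not in inside]
        return heads[0] if len(heads) == 1 else m.end - 1


@dataclass(frozen=True)
class CandidatePair:
    """An unordered pair of distinct mentions in one sentence.

    ``m1 < m2`` lexicographically; the id is stable across runs.
    """

    sid: str
    m1: str
    m2: str
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.m1 == self.m2:
            raise CorpusError(f"{self.sid}: candidate pair of a mention with itself")
        if self.m1 > self.m2:
            raise CorpusError(f"{self.sid}: pair ids not in lexicographic order")

    @property
    def pid(self) -> str:
        return f"{self.m1}~{self.m2}"


# ---------------------------------------------------------------------------
# Tokenization


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Split ``text`` into (surface, char_start, char_end) triples.

    Whitespace-delimited chunks; leading/trailing punctuation in a fixed set
    is peeled into separate tokens.  ``char_end`` is exclusive.
    """
    out: list[tuple[str, int, int]] = []
    pos = 0
    for chunk in text.split():
        start = text.index(chunk, pos)
        pos = start + len(chunk)
        a, b = 0, len(chunk)
        lead = []
        while a < b - 1 and chunk[a] in _STRIP_CHARS:
            lead.append((chunk[a], start + a, start + a + 1))
            a += 1
        trail = []
        while b - 1 > a and chunk[b - 1] in _STRIP_CHARS:
            trail.append((chunk[b - 1], start + b - 1, start + b))
            b -= 1
        out.extend(lead)
        out.append((chunk[a:b], start + a, start + b))
        out.extend(reversed(trail))
    return out


def _span_from_charoffset(
    char_tokens: list[tuple[str, int, int]], a: int, b_incl: int, sid: str, eid: str
) -> tuple[int, int]:
    """Map an inclusive character interval to a half-open token span.

    Offsets that fall mid-token are snapped outward to token boundaries.
    """
    b = b_incl + 1
    covered = [i for i, (_, cs, ce) in enumerate(char_tokens) if cs < b and ce > a]
    if not covered:
        raise CorpusError(f"{sid}: entity {eid} charOffset {a}-{b_incl} resolves to no token")
    return covered[0], covered[-1] + 1


# ---------------------------------------------------------------------------
# Unified PPI XML


def read_ppi_xml(path) -> list[ParsedSentence]:
    """Read a unified-dialect PPI corpus file into ParsedSentence objects."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:  # lxml messages carry the line number
        raise CorpusError(f"malformed XML in {path}: {exc}") from exc
    sentences: list[ParsedSentence] = []
    for doc in tree.getroot().iter("document"):
        docid = doc.get("id", "")
        for sel in doc.iter("sentence"):
            sid = sel.get("id", "")
            text = sel.get("text", "")
            char_tokens = tokenize(text)
            tokens = [Token(i, s) for i, (s, _, _) in enumerate(char_tokens)]
            mentions = []
            for ent in sel.iter("entity"):
                eid = ent.get("id", "")
                off = ent.get("charOffset", "")
                try:
                    a_s, b_s = off.split("-")
                    a, b_incl = int(a_s), int(b_s)
                except ValueError as exc:
                    raise CorpusError(f"{sid}: entity {eid} bad charOffset {off!r}") from exc
                start, end = _span_from_charoffset(char_tokens, a, b_incl, sid, eid)
                mentions.append(
                    Mention(eid, start, end, ent.get("text", ""), ent.get("type", "protein"))
                )
            known = {m.id for m in mentions}
            gold: set[frozenset[str]] | None = None
            pair_elems = list(sel.iter("pair"))
            if pair_elems:
                gold = set()
                for pel in pair_elems:
                    e1, e2 = pel.get("e1", ""), pel.get("e2", "")
                    if e1 not in known or e2 not in known:
                        raise CorpusError(f"{sid}: pair references unknown entity {e1!r}/{e2!r}")
                    if pel.get("interaction", "False").lower() == "true":
                        gold.add(frozenset((e1, e2)))
            sentences.append(ParsedSentence(sid, docid, tokens, mentions, [], gold))
    return sentences


def write_ppi_xml(sentences: list[ParsedSentence], path, source: str = "ppikex") -> None:
    """Write sentences back to the unified dialect.

    Sentence text is the space-joined token sequence; entity offsets are
    recomputed against that text, so a read/write/read cycle is structurally
    stable.
    """
    root = etree.Element("corpus", source=source)
    docs: dict[str, etree._Element] = {}
    for s in sentences:
        del_ = docs.get(s.docid)
        if del_ is None:
            del_ = etree.SubElement(root, "document", id=s.docid)
            docs[s.docid] = del_
        text = " ".join(s.surfaces)
        sel = etree.SubElement(del_, "sentence", id=s.sid, text=text)
        starts = []
        pos = 0
        for t in s.tokens:
            starts.append(pos)
            pos += len(t.surface) + 1
        for m in s.mentions:
            a = starts[m.start]
            b_incl = starts[m.end - 1] + len(s.tokens[m.end - 1].surface) - 1
            etree.SubElement(
                sel, "entity", id=m.id, charOffset=f"{a}-{b_incl}", text=m.text, type=m.etype
            )
        if s.gold_pairs is not None:
            for k, pair in enumerate(
                sorted(generate_candidates(s), key=lambda p: p.pid)
            ):
                etree.SubElement(
                    sel,
                    "pair",
                    id=f"{s.sid}.p{k}",
                    e1=pair.m1,
                    e2=pair.m2,
                    interaction=str(pair.label == POSITIVE),
                )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# CoNLL-style parse sidecar


def read_parses(path, sentences: list[ParsedSentence]) -> list[ParsedSentence]:
    """Attach dependency edges and POS tags from a sidecar file.

    Rows are ``sid TAB index TAB surface TAB pos TAB head TAB relation`` with
    1-based token indices and head 0 marking the root; blank lines separate
    sentences.  Sentences without any sidecar rows keep ``parsed=False`` and
    are not dropped.  Duplicate edges are collapsed.
    """
    by_sid: dict[str, set[tuple[int, str, str, int, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            sid, idx, surface, pos, head, rel = line.split("\t")
            by_sid.setdefault(sid, set()).add((int(idx), surface, pos, int(head), rel))
    out = []
    for s in sentences:
        rows = by_sid.get(s.sid)
        if not rows:
            out.append(s)
            continue
        indices = {r[0] for r in rows}
        if indices != set(range(1, len(s.tokens) + 1)):
            raise CorpusError(
                f"{s.sid}: sidecar has {len(indices)} tokens, sentence has {len(s.tokens)}"
            )
        tokens = list(s.tokens)
        edge_set: set[DependencyEdge] = set()
        for idx, _surface, pos, head, rel in sorted(rows):
            i = idx - 1
            tokens[i] = Token(i, tokens[i].surface, pos)
            if head != 0:
                edge_set.add(DependencyEdge(head - 1, i, rel))
        out.append(
            replace(s, tokens=tokens, edges=sorted(edge_set, key=lambda e: (e.dependent, e.head)),
                    parsed=True)
        )
    return out


def write_parses(sentences: list[ParsedSentence], path) -> None:
    """Write the CoNLL-style sidecar consumed by :func:`read_parses`."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            if not s.parsed:
                continue
            head_of = {e.dependent: (e.head, e.relation) for e in s.edges}
            for t in s.tokens:
                head, rel = head_of.get(t.index, (-1, "ROOT"))
                fh.write(f"{s.sid}\t{t.index + 1}\t{t.surface}\t{t.pos}\t{head + 1}\t{rel}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Candidates and blinding


def generate_candidates(s: ParsedSentence) -> list[CandidatePair]:
    """All C(n, 2) unordered mention pairs of a sentence, in textual order.

    Labels come from ``gold_pairs`` when the sentence carries gold
    annotation, otherwise every candidate is ``unknown``.
    """
    ordered = sorted(s.mentions, key=lambda m: (m.start, m.end, m.id))
    pairs = []
    for a, b in itertools.combinations(ordered, 2):
        m1, m2 = sorted((a.id, b.id))
        if s.gold_pairs is None:
            label = UNKNOWN
        else:
            label = POSITIVE if frozenset((a.id, b.id)) in s.gold_pairs else NEGATIVE
        pairs.append(CandidatePair(s.sid, m1, m2, label))
    return pairs


def blind_entities(s: ParsedSentence, p: CandidatePair) -> ParsedSentence:
    """Return a copy of ``s`` with the pair's mentions replaced by placeholders.

    The textually earlier mention becomes ENTITY1, the later ENTITY2; every
    other mention's tokens become PROT0.  Token count and spans are unchanged,
    so the operation is idempotent per pair.
    """
    if p.sid != s.sid:
        raise CorpusError(f"pair {p.pid} does not belong to sentence {s.sid}")
    ma, mb = s.mention_by_id(p.m1), s.mention_by_id(p.m2)
    first, second = sorted((ma, mb), key=lambda m: (m.start, m.end))
    tokens = list(s.tokens)

    def stamp(m: Mention, placeholder: str) -> None:
        for i in range(m.start, m.end):
            tokens[i] = Token(i, placeholder, tokens[i].pos)

    for m in s.mentions:
        if m.id not in (p.m1, p.m2):
            stamp(m, PROT_OTHER)
    stamp(first, ENTITY1)
    stamp(second, ENTITY2)
    return replace(s, tokens=tokens)
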