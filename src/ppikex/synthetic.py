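"""Synthetic parsed corpora with a plantable interaction signal.

Every sentence receives two or three protein mentions and a projective
dependency tree.  Interacting (positive) adjacent mention pairs are marked
by a *lexical* cue — a trigger word from the keyword lexicon placed in the
short gap between them — and/or a *structural* cue — a dedicated dependency
relation (``INTERACT``) linking the two mention heads directly.  Negative
pairs get longer filler gaps and plain chain dependencies, so each kernel
family (lexical, path-tree, tag-graph) has something to detect.  Noise
parameters flip labels or sprinkle spurious triggers to make the task
arbitrarily hard.

The generator emulates the *shape* of the public interaction corpora
(sentence/mention/pair structure, class imbalance, parse sidecars), not
biomedical language: word order, vocabulary and syntax are schematic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import (
    DependencyEdge,
    Mention,
    ParsedSentence,
    Token,
    write_parses,
    write_ppi_xml,
)

SIGNAL_RELATION = "INTERACT"

_BASE_VOCAB = (
    "the a this report study cell cells tissue sample pathway process level "
    "expression sequence domain region analysis result effect response model "
    "assay gene factor signal growth stress membrane nucleus system type form"
).split()

_DEFAULT_TRIGGERS = ("binds", "activates", "inhibits", "phosphorylates", "interacts", "regulates")

_FILLER_POS = ("NN", "JJ", "DT", "RB", "IN")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic corpus.

    ``mention_rate`` in [2, 3] is the mean mentions per sentence (a sentence
    gets 3 mentions with probability ``mention_rate - 2``); ``pos_fraction``
    is the target share of positive candidate pairs; ``signal`` is one of
    ``lexical``, ``structural``, ``both``; ``noise_flip`` flips gold labels,
    ``noise_trigger`` plants spurious triggers next to negative pairs.
    """

    n_docs: int = 40
    sentences_per_doc: int = 5
    vocab_size: int = 120
    mention_rate: float = 2.5
    pos_fraction: float = 0.3
    signal: str = "both"
    trigger_words: tuple[str, ...] = _DEFAULT_TRIGGERS
    max_trigger_gap: int = 3
    noise_flip: float = 0.0
    noise_trigger: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pos_fraction", "noise_flip", "noise_trigger"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 2.0 <= self.mention_rate <= 3.0:
            raise ValueError("mention_rate must lie in [2, 3]")
        if self.signal not in ("lexical", "structural", "both"):
            raise ValueError(f"unknown signal kind {self.signal!r}")
        q = self.mention_rate - 2.0
        # positives only arise on adjacent mention pairs: 1 of 1 (2 mentions)
        # or 2 of 3 (3 mentions)
        self.p_adjacent = self.pos_fraction * (1.0 + 2.0 * q) / (1.0 + q)
        if self.p_adjacent > 1.0:
            raise ValueError(
                f"pos_fraction {self.pos_fraction} infeasible at mention_rate {self.mention_rate}"
            )


def _vocab(cfg: SynthConfig, rng: np.random.Generator) -> list[str]:
    """Base wordlist padded with seeded gibberish up to ``vocab_size``."""
    words = list(_BASE_VOCAB)
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    while len(words) < cfg.vocab_size:
        n = int(rng.integers(4, 9))
        words.append("".join(letters[rng.integers(0, 26, n)]))
    return words[: cfg.vocab_size]


def _filler(vocab, rng, n) -> list[str]:
    return [vocab[int(i)] for i in rng.integers(0, len(vocab), n)]


def _generate_sentence(
    sid: str, docid: str, cfg: SynthConfig, vocab: list[str], rng: np.random.Generator
) -> ParsedSentence:
    n_mentions = 2 + int(rng.random() < (cfg.mention_rate - 2.0))
    prot_ids = rng.choice(np.arange(1, 100), size=n_mentions, replace=False)
    names = [f"PROT{int(i)}" for i in prot_ids]

    surfaces: list[str] = []
    pos: list[str] = []
    override_head: dict[int, tuple[int, str]] = {}
    mention_at: list[int] = []

    def push(word: str, tag: str) -> int:
        surfaces.append(word)
        pos.append(tag)
        return len(surfaces) - 1

    for w in _filler(vocab, rng, int(rng.integers(1, 4))):
        push(w, _FILLER_POS[len(surfaces) % len(_FILLER_POS)])

    adjacent_positive: list[bool] = []
    for i, name in enumerate(names):
        idx = push(name, "NNP")
        mention_at.append(idx)
        if i == len(names) - 1:
            break
        positive = bool(rng.random() < cfg.p_adjacent)
        adjacent_positive.append(positive)
        if positive:
            gap = int(rng.integers(1, cfg.max_trigger_gap + 1))
            words = _filler(vocab, rng, gap)
            slot = int(rng.integers(0, gap))
            for j, w in enumerate(words):
                if j == slot and cfg.signal in ("lexical", "both"):
                    push(str(rng.choice(cfg.trigger_words)), "VBZ")
                else:
                    push(w, _FILLER_POS[len(surfaces) % len(_FILLER_POS)])
        else:
            # 4-8 filler words: negative pairs (and trigger-contaminated
            # cross pairs) always land in a farther distance bucket than the
            # planted positives, keeping the lexical signal separable
            gap = int(rng.integers(4, 9))
            words = _filler(vocab, rng, gap)
            spurious = rng.random() < cfg.noise_trigger
            slot = int(rng.integers(0, gap)) if spurious else -1
            for j, w in enumerate(words):
                if j == slot:
                    push(str(rng.choice(cfg.trigger_words)), "VBZ")
                else:
                    push(w, _FILLER_POS[len(surfaces) % len(_FILLER_POS)])
    for w in _filler(vocab, rng, int(rng.integers(1, 3))):
        push(w, _FILLER_POS[len(surfaces) % len(_FILLER_POS)])
    push(".", ".")

    if cfg.signal in ("structural", "both"):
        for i, positive in enumerate(adjacent_positive):
            if positive:
                override_head[mention_at[i + 1]] = (mention_at[i], SIGNAL_RELATION)

    tokens = [Token(i, w, t) for i, (w, t) in enumerate(zip(surfaces, pos))]
    edges = []
    for i in range(1, len(tokens)):
        head, rel = override_head.get(i, (i - 1, "FILL"))
        edges.append(DependencyEdge(head, i, rel))

    mentions = [
        Mention(f"{sid}.e{k}", idx, idx + 1, names[k]) for k, idx in enumerate(mention_at)
    ]
    gold: set[frozenset[str]] = set()
    for i, positive in enumerate(adjacent_positive):
        if positive:
            gold.add(frozenset((mentions[i].id, mentions[i + 1].id)))
    # label-flip noise applies to every candidate pair, positive or negative
    if cfg.noise_flip > 0.0:
        from itertools import combinations

        for a, b in combinations(mentions, 2):
            if rng.random() < cfg.noise_flip:
                key = frozenset((a.id, b.id))
                gold.symmetric_difference_update({key})
    return ParsedSentence(sid, docid, tokens, mentions, edges, gold, parsed=True)


def generate_corpus(
    cfg: SynthConfig, xml_path=None, parses_path=None
) -> list[ParsedSentence]:
    """Generate a corpus; optionally write the PPI XML and parse sidecar.

    Deterministic given ``cfg.seed``: identical configs produce byte-identical
    output files.
    """
    rng = np.random.default_rng(cfg.seed)
    vocab = _vocab(cfg, rng)
    sentences = []
    for d in range(cfg.n_docs):
        docid = f"d{d}"
        for s in range(cfg.sentences_per_doc):
            sid = f"{docid}.s{s}"
            sentences.append(_generate_sentence(sid, docid, cfg, vocab, rng))
    if xml_path is not None:
        write_ppi_xml(sentences, xml_path, source="ppikex-synthetic")
    if parses_path is not None:
        write_parses(sentences, parses_path)
    return sentences


def corpus_stats(sentences: list[ParsedSentence]) -> pd.DataFrame:
    """Corpus statistics table: texts, sentences, positives, negatives, total."""
    from .corpus import POSITIVE, generate_candidates

    docs = {s.docid for s in sentences}
    pos = neg = 0
    for s in sentences:
        for p in generate_candidates(s):
            if p.label == POSITIVE:
                pos += 1
            else:
                neg += 1
    return pd.DataFrame(
        [
            {
                "texts": len(docs),
                "sentences": len(sentences),
                "positive_pairs": pos,
                "negative_pairs": neg,
                "total_pairs": pos + neg,
            }
        ]
    )


# ---------------------------------------------------------------------------
# Hand-coded worked-example fixtures


def interleukin_example() -> ParsedSentence:
    """A three-mention sentence about IL-8 signaling through its receptors.

    Mentions (IL)-8, CXCR1 and CXCR2 give three candidate pairs of which the
    two receptor bindings are gold interactions; the (IL)-8/CXCR1 pair sits
    18 words apart with "their receptors" closing the gap.
    """
    words = (
        "Interleukin (IL)-8 has an important role in the pathogenesis of many "
        "inflammatory diseases by signaling mainly acting through their receptors "
        "CXCR1 and CXCR2 ."
    ).split()
    pos = {
        0: "NN", 1: "NNP", 2: "VBZ", 3: "DT", 4: "JJ", 5: "NN", 6: "IN", 7: "DT",
        8: "NN", 9: "IN", 10: "JJ", 11: "JJ", 12: "NNS", 13: "IN", 14: "VBG",
        15: "RB", 16: "VBG", 17: "IN", 18: "PRP$", 19: "NNS", 20: "NNP",
        21: "CC", 22: "NNP", 23: ".",
    }
    tokens = [Token(i, w, pos[i]) for i, w in enumerate(words)]
    edges = [
        DependencyEdge(2, 1, "NSUBJ"), DependencyEdge(1, 0, "NN"),
        DependencyEdge(2, 5, "DOBJ"), DependencyEdge(5, 3, "DET"),
        DependencyEdge(5, 4, "AMOD"), DependencyEdge(5, 6, "PREP"),
        DependencyEdge(6, 8, "POBJ"), DependencyEdge(8, 7, "DET"),
        DependencyEdge(8, 9, "PREP"), DependencyEdge(9, 12, "POBJ"),
        DependencyEdge(12, 10, "AMOD"), DependencyEdge(12, 11, "AMOD"),
        DependencyEdge(2, 13, "PREP"), DependencyEdge(13, 14, "POBJ"),
        DependencyEdge(14, 16, "PARTMOD"), DependencyEdge(16, 15, "ADVMOD"),
        DependencyEdge(16, 17, "PREP"), DependencyEdge(17, 19, "POBJ"),
        DependencyEdge(19, 18, "POSS"), DependencyEdge(19, 20, "APPOS"),
        DependencyEdge(20, 21, "CC"), DependencyEdge(20, 22, "CONJ"),
        DependencyEdge(2, 23, "PUNCT"),
    ]
    mentions = [
        Mention("s1.e0", 1, 2, "(IL)-8"),
        Mention("s1.e1", 20, 21, "CXCR1"),
        Mention("s1.e2", 22, 23, "CXCR2"),
    ]
    gold = {frozenset(("s1.e0", "s1.e1")), frozenset(("s1.e0", "s1.e2"))}
    return ParsedSentence("s1", "doc1", tokens, mentions, edges, gold, parsed=True)


def rsfa_example() -> ParsedSentence:
    """The sporulation-control sentence used to illustrate path extension.

    rsfA expression is under the control of both sigmaK and GerE; after
    blinding, the dependency path between the two entities is the single
    CONJ edge, which the extension rule grows through the POBJ and PREP
    governors ("of", "control").
    """
    words = "The expression of rsfA is under the control of both sigmaK and GerE .".split()
    pos = {
        0: "DT", 1: "NN", 2: "IN", 3: "NN", 4: "VBZ", 5: "IN", 6: "DT", 7: "NN",
        8: "IN", 9: "DT", 10: "NNP", 11: "CC", 12: "NNP", 13: ".",
    }
    tokens = [Token(i, w, pos[i]) for i, w in enumerate(words)]
    edges = [
        DependencyEdge(1, 0, "DET"), DependencyEdge(4, 1, "NSUBJ"),
        DependencyEdge(1, 2, "PREP"), DependencyEdge(2, 3, "POBJ"),
        DependencyEdge(4, 5, "PREP"), DependencyEdge(5, 7, "POBJ"),
        DependencyEdge(7, 6, "DET"), DependencyEdge(7, 8, "PREP"),
        DependencyEdge(8, 10, "POBJ"), DependencyEdge(10, 9, "PRECONJ"),
        DependencyEdge(10, 11, "CC"), DependencyEdge(10, 12, "CONJ"),
        DependencyEdge(4, 13, "PUNCT"),
    ]
    mentions = [Mention("s2.e0", 10, 11, "sigmaK"), Mention("s2.e1", 12, 13, "GerE")]
    return ParsedSentence("s2", "doc2", tokens, mentions, edges, set(), parsed=True)


def worked_example_sentences() -> tuple[ParsedSentence, ParsedSentence]:
    """Both hand-coded fixtures: the IL-8 receptor sentence and the rsfA one."""
    return interleukin_example(), rsfa_example()
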