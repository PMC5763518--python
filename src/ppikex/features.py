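"""Lexical feature extraction and the RBF feature kernel.

A candidate pair is described by sparse binary features of five kinds,
named by prefix:

``a_i__w``
    the i-th word inside either entity name, left to right;
``b_i__w``
    the i-th word strictly between the two entity names, or the null
    feature ``b_0__NULL`` when the gap is empty;
``l_i__w`` / ``r_i__w``
    up to ``window`` words immediately left of the earlier entity and
    right of the later one (i = 1 is adjacent);
``k_w``
    any between/around word found in the keyword lexicon (lowercased);
``d_3 | d_8 | d_15 | d_16``
    exactly one bucketed inter-entity distance feature.

Similarity between two feature vectors is the isotropic Gaussian
``K(x, y) = exp(-||x - y||^2 / (2 s^2))`` over the union of feature names.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf

from .corpus import CandidatePair, CorpusError, ParsedSentence

NULL_BETWEEN = "b_0__NULL"

FeatureVector = dict[str, int]


class KeywordLexicon:
    """A case-insensitive set of interaction-cue words."""

    def __init__(self, words) -> None:
        self.words = {w.lower() for w in words if w.strip()}

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.words

    def __len__(self) -> int:
        return len(self.words)

    @classmethod
    def from_file(cls, path) -> "KeywordLexicon":
        """Load a plain-text list, one word per line; ``#`` starts a comment."""
        words = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                words.append(line)
        return cls(words)

    @classmethod
    def default(cls) -> "KeywordLexicon":
        ref = resources.files("ppikex").joinpath("data/keywords.txt")
        with resources.as_file(ref) as path:
            return cls.from_file(path)


def distance_bucket(gap: int) -> str:
    """Bucket the count of words strictly between the two entities.

    <= 3 words -> ``d_3``; 4-8 -> ``d_8``; 9-15 -> ``d_15``; > 15 -> ``d_16``.
    """
    if gap < 0:
        raise ValueError(f"negative inter-entity gap {gap}")
    if gap <= 3:
        return "d_3"
    if gap <= 8:
        return "d_8"
    if gap <= 15:
        return "d_15"
    return "d_16"


def extract_features(
    s: ParsedSentence,
    p: CandidatePair,
    lex: KeywordLexicon | None = None,
    window: int = 3,
) -> FeatureVector:
    """Binary feature vector for candidate pair ``p`` in sentence ``s``.

    Context (``l_``/``r_``) is taken at the outer boundary of the pair: left
    of the earlier mention and right of the later one.  Keyword features fire
    for words between the mentions and inside the context windows.
    """
    if p.sid != s.sid:
        raise CorpusError(f"pair {p.pid} does not belong to sentence {s.sid}")
    if window < 1:
        raise ValueError("window must be >= 1")
    lex = lex if lex is not None else KeywordLexicon.default()
    first, second = sorted(
        (s.mention_by_id(p.m1), s.mention_by_id(p.m2)), key=lambda m: (m.start, m.end)
    )
    surfaces = s.surfaces
    feats: FeatureVector = {}

    i = 0
    for m in (first, second):
        for t in range(m.start, m.end):
            i += 1
            feats[f"a_{i}__{surfaces[t]}"] = 1

    between = surfaces[first.end : second.start]
    if between:
        for i, w in enumerate(between, start=1):
            feats[f"b_{i}__{w}"] = 1
    else:
        feats[NULL_BETWEEN] = 1

    left = surfaces[max(0, first.start - window) : first.start]
    for i, w in enumerate(reversed(left), start=1):
        feats[f"l_{i}__{w}"] = 1
    right = surfaces[second.end : second.end + window]
    for i, w in enumerate(right, start=1):
        feats[f"r_{i}__{w}"] = 1

    for w in between + left + right:
        if w in lex:
            feats[f"k_{w.lower()}"] = 1

    feats[distance_bucket(len(between))] = 1
    return feats


def rbf_kernel(x: FeatureVector, y: FeatureVector, s: float = 1.0) -> float:
    """Gaussian similarity of two sparse binary vectors; lies in (0, 1]."""
    if s <= 0:
        raise ValueError(f"bandwidth must be positive, got {s}")
    d2 = 0.0
    for name in x.keys() | y.keys():
        d2 += (x.get(name, 0) - y.get(name, 0)) ** 2
    return math.exp(-d2 / (2.0 * s * s))


def _gamma(X, s: float | str) -> float:
    """RBF exponent coefficient; supports the median-distance heuristic."""
    if isinstance(s, str):
        if s != "median":
            raise ValueError(f"unknown bandwidth rule {s!r}")
        sq = np.asarray(X.multiply(X).sum(axis=1)).ravel()
        d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T).toarray()
        off = d2[np.triu_indices_from(d2, k=1)]
        med = float(np.median(off[off > 0])) if np.any(off > 0) else 1.0
        return 1.0 / med
    if s <= 0:
        raise ValueError(f"bandwidth must be positive, got {s}")
    return 1.0 / (2.0 * s * s)


def feature_gram(vectors: list[FeatureVector], s: float | str = 1.0) -> np.ndarray:
    """Pairwise RBF Gram matrix over feature vectors (unit diagonal).

    ``s`` is the bandwidth scalar, or the string ``"median"`` to apply the
    median heuristic ``s^2 = median(||x - y||^2) / 2`` over distinct vector
    pairs — a scale-free choice when feature counts vary across corpora.
    """
    if not vectors:
        return np.zeros((0, 0))
    X = DictVectorizer(sparse=True).fit_transform(vectors)
    K = _sk_rbf(X, gamma=_gamma(X, s))
    np.fill_diagonal(K, 1.0)
    return (K + K.T) / 2.0


def feature_cross(
    test_vectors: list[FeatureVector], train_vectors: list[FeatureVector], s: float | str = 1.0
) -> np.ndarray:
    """Rectangular test-vs-train RBF block on a shared feature space.

    The median bandwidth, when requested, is estimated over the pooled
    vectors so train-side and cross blocks share one scale.
    """
    dv = DictVectorizer(sparse=True)
    X = dv.fit_transform(list(train_vectors) + list(test_vectors))
    gamma = _gamma(X, s)
    n_tr = len(train_vectors)
    return _sk_rbf(X[n_tr:], X[:n_tr], gamma=gamma)


def dump_features_tsv(
    pairs: list[CandidatePair], vectors: list[FeatureVector], path, header: str = ""
) -> None:
    """Debug dump: one row per pair with its sorted feature names."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for p, v in zip(pairs, vectors):
            fh.write("\t".join([p.pid] + sorted(v)) + "\n")
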