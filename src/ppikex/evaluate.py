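"""Precision/recall/F evaluation and document-grouped cross-validation.

Scores are percentages: P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R).
Cross-validation folds partition *documents*, never sentences, so two
candidate pairs from the same abstract can never land on both sides of a
train/test split — the standard protocol for the sentence-level interaction
corpora this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .corpus import (
    NEGATIVE,
    POSITIVE,
    CandidatePair,
    ParsedSentence,
    blind_entities,
    generate_candidates,
)
from .features import KeywordLexicon, extract_features, feature_cross, feature_gram
from .fusion import FusionWeights, predict, train, tune_weights
from .gram import GramSet
from .graphkernel import build_tag_graph, graph_cross, graph_gram
from .treekernel import pair_path_tree, tree_cross, tree_gram


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts with derived percentage scores.

    ``degenerate`` flags any 0/0 ratio that was defined as 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    p: float
    r: float
    f: float
    degenerate: bool = False

    def as_row(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
                "P": round(self.p, 2), "R": round(self.r, 2), "F": round(self.f, 2)}


def prf(tp: int, fp: int, fn: int, tn: int = 0) -> EvalResult:
    """P/R/F from confusion counts; degenerate 0/0 ratios become 0, flagged."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    degenerate = False
    if tp + fp == 0:
        p, degenerate = 0.0, True
    else:
        p = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        r, degenerate = 0.0, True
    else:
        r = 100.0 * tp / (tp + fn)
    if p + r == 0:
        f, degenerate = 0.0, True
    else:
        f = 2.0 * p * r / (p + r)
    return EvalResult(tp, fp, fn, tn, p, r, f, degenerate)


# ---------------------------------------------------------------------------
# Gram assembly


@dataclass
class PairIndex:
    """Candidate pairs of a corpus with their provenance, in corpus order."""

    pairs: list[CandidatePair]
    sentences: list[ParsedSentence]  # aligned with pairs
    docids: list[str]

    @property
    def pair_ids(self) -> list[str]:
        return [p.pid for p in self.pairs]


def index_candidates(sentences: list[ParsedSentence]) -> PairIndex:
    pairs, sents, docids = [], [], []
    for s in sentences:
        for p in generate_candidates(s):
            pairs.append(p)
            sents.append(s)
            docids.append(s.docid)
    return PairIndex(pairs, sents, docids)


def build_gram_set(sentences: list[ParsedSentence], cfg: RunConfig) -> tuple[GramSet, PairIndex]:
    """Compute one normalized Gram matrix per enabled kernel over a corpus."""
    idx = index_candidates(sentences)
    labels = np.array([1.0 if p.label == POSITIVE else -1.0 for p in idx.pairs])
    grams: dict[str, np.ndarray] = {}
    if "feature" in cfg.kernels:
        lex = KeywordLexicon.from_file(cfg.lexicon) if cfg.lexicon else KeywordLexicon.default()
        vecs = [extract_features(s, p, lex, cfg.window) for s, p in zip(idx.sentences, idx.pairs)]
        grams["feature"] = feature_gram(vecs, cfg.bandwidth)
    if "tree" in cfg.kernels:
        tcfg = cfg.tree_config()
        trees = [pair_path_tree(s, p, tcfg) for s, p in zip(idx.sentences, idx.pairs)]
        grams["tree"] = tree_gram(trees, tcfg)
    if "graph" in cfg.kernels:
        gcfg = cfg.graph_config()
        graphs = [
            build_tag_graph(blind_entities(s, p), p, gcfg)
            for s, p in zip(idx.sentences, idx.pairs)
        ]
        grams["graph"] = graph_gram(graphs, gcfg)
    return GramSet(idx.pair_ids, grams, labels), idx


def build_cross_grams(
    train_sentences: list[ParsedSentence],
    test_sentences: list[ParsedSentence],
    cfg: RunConfig,
) -> tuple[dict[str, np.ndarray], PairIndex, PairIndex]:
    """Rectangular test-vs-train kernel blocks for prediction.

    The two corpora may overlap (e.g. scoring the training corpus itself);
    kernel values are computed pair-against-pair, never by id.
    """
    tr, te = index_candidates(train_sentences), index_candidates(test_sentences)
    cross: dict[str, np.ndarray] = {}
    if "feature" in cfg.kernels:
        lex = KeywordLexicon.from_file(cfg.lexicon) if cfg.lexicon else KeywordLexicon.default()
        vtr = [extract_features(s, p, lex, cfg.window) for s, p in zip(tr.sentences, tr.pairs)]
        vte = [extract_features(s, p, lex, cfg.window) for s, p in zip(te.sentences, te.pairs)]
        cross["feature"] = feature_cross(vte, vtr, cfg.bandwidth)
    if "tree" in cfg.kernels:
        tcfg = cfg.tree_config()
        ttr = [pair_path_tree(s, p, tcfg) for s, p in zip(tr.sentences, tr.pairs)]
        tte = [pair_path_tree(s, p, tcfg) for s, p in zip(te.sentences, te.pairs)]
        cross["tree"] = tree_cross(tte, ttr, tcfg)
    if "graph" in cfg.kernels:
        gcfg = cfg.graph_config()
        gtr = [build_tag_graph(blind_entities(s, p), p, gcfg)
               for s, p in zip(tr.sentences, tr.pairs)]
        gte = [build_tag_graph(blind_entities(s, p), p, gcfg)
               for s, p in zip(te.sentences, te.pairs)]
        cross["graph"] = graph_cross(gte, gtr, gcfg)
    return cross, tr, te


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVReport:
    method: str
    folds: list[EvalResult]
    pooled: EvalResult
    fold_of_doc: dict[str, int]
    weights_per_fold: list[dict[str, float]]

    def macro_f(self) -> float:
        return float(np.mean([fr.f for fr in self.folds]))

    def to_jsonl(self) -> str:
        import json

        lines = [
            json.dumps({"method": self.method, "fold": i, **fr.as_row()})
            for i, fr in enumerate(self.folds)
        ]
        lines.append(json.dumps({"method": self.method, "fold": "pooled", **self.pooled.as_row()}))
        return "\n".join(lines) + "\n"


def assign_document_folds(docids: list[str], k: int, seed: int) -> dict[str, int]:
    """Shuffle documents with the seed and deal them round-robin into k folds."""
    docs = sorted(set(docids))
    if len(docs) < k:
        raise ValueError(f"cannot make {k} folds from {len(docs)} documents")
    rng = np.random.default_rng(seed)
    order = [docs[i] for i in rng.permutation(len(docs))]
    return {d: i % k for i, d in enumerate(order)}


def cross_validate_grams(
    gs: GramSet,
    docids: list[str],
    cfg: RunConfig,
    weights: FusionWeights | None = None,
    method: str = "",
) -> CVReport:
    """Document-grouped k-fold CV on precomputed Gram matrices.

    Per fold, training touches only train-slice rows/columns; fusion weights
    are tuned on the train slice when ``weights`` is None and the GramSet
    holds more than one kernel.
    """
    if gs.labels is None:
        raise ValueError("cross-validation requires labels")
    if len(set(gs.labels.tolist())) < 2:
        raise ValueError("cross-validation requires both classes")
    fold_of_doc = assign_document_folds(docids, cfg.folds, cfg.seed)
    fold = np.array([fold_of_doc[d] for d in docids])
    per_fold: list[EvalResult] = []
    weights_used: list[dict[str, float]] = []
    tp = fp = fn = tn = 0
    for f in range(cfg.folds):
        tr = np.flatnonzero(fold != f)
        te = np.flatnonzero(fold == f)
        if len(te) == 0:
            per_fold.append(prf(0, 0, 0, 0))
            weights_used.append({})
            continue
        gtrain = gs.subset(tr)
        if weights is not None:
            w = weights
        elif len(gs.grams) == 1:
            w = FusionWeights.single(next(iter(gs.grams)))
        else:
            w = tune_weights(
                gtrain, cfg.grid_step, cfg.inner_folds, cfg.seed, cfg.c, cfg.class_weight
            )
        model = train(gtrain, w, cfg.c, cfg.class_weight)
        pred, _ = predict(model, gs.cross(te, tr), gtrain.pair_ids)
        y = gs.labels[te]
        ftp = int(np.sum((pred == 1) & (y == 1)))
        ffp = int(np.sum((pred == 1) & (y == -1)))
        ffn = int(np.sum((pred == -1) & (y == 1)))
        ftn = int(np.sum((pred == -1) & (y == -1)))
        per_fold.append(prf(ftp, ffp, ffn, ftn))
        weights_used.append(dict(w.eta))
        tp, fp, fn, tn = tp + ftp, fp + ffp, fn + ffn, tn + ftn
    return CVReport(method, per_fold, prf(tp, fp, fn, tn), fold_of_doc, weights_used)


def cross_validate(
    sentences: list[ParsedSentence],
    cfg: RunConfig,
    weights: FusionWeights | None = None,
    method: str = "",
) -> CVReport:
    """End-to-end document-grouped CV: grams, per-fold training, pooled P/R/F."""
    gs, idx = build_gram_set(sentences, cfg)
    if weights is None and cfg.eta is not None:
        weights = FusionWeights(dict(cfg.eta))
    return cross_validate_grams(gs, idx.docids, cfg, weights, method or "+".join(cfg.kernels))


DEFAULT_METHODS = (
    ("feature", ("feature",)),
    ("tree", ("tree",)),
    ("graph", ("graph",)),
    ("feature+tree", ("feature", "tree")),
    ("feature+graph", ("feature", "graph")),
    ("tree+graph", ("tree", "graph")),
    ("feature+tree+graph", ("feature", "tree", "graph")),
)


def compare_methods(
    sentences: list[ParsedSentence],
    cfg: RunConfig,
    methods=DEFAULT_METHODS,
) -> tuple[pd.DataFrame, dict[str, CVReport]]:
    """CV every kernel combination on shared Grams; the comparison table.

    Returns a (method x P/R/F) DataFrame plus the full per-method reports.
    Gram matrices are computed once and sliced per method.
    """
    gs, idx = build_gram_set(sentences, cfg)
    reports: dict[str, CVReport] = {}
    rows = []
    for name, kernels in methods:
        sub = GramSet(gs.pair_ids, {k: gs.grams[k] for k in kernels}, gs.labels)
        fixed = None
        if cfg.eta is not None and set(cfg.eta) == set(kernels):
            fixed = FusionWeights(dict(cfg.eta))
        rep = cross_validate_grams(sub, idx.docids, cfg, fixed, name)
        reports[name] = rep
        rows.append({"method": name, **rep.pooled.as_row()})
    return pd.DataFrame(rows), reports
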