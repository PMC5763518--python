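"""Dependency-path trees and the convolution (subset-tree) kernel.

For a candidate pair the sentence is entity-blinded and the shortest
undirected path through the dependency graph is taken between the two entity
head tokens.  Each dependency edge on the path becomes a relation-labeled
node whose two leaf children are the governor and dependent word, and the
relation nodes hang in path order under a ``DEPENDENCY`` root, e.g.::

    (DEPENDENCY(CONJ(ENTITY1,ENTITY2)))

Paths shorter than ``min_path_len`` relation nodes carry too little context
to judge the relationship, so they are extended through the governor chain of
the path endpoints, which for the example above yields::

    (DEPENDENCY(PREP(control,of),POBJ(of,ENTITY1),CONJ(ENTITY1,ENTITY2)))

Two trees are compared with the subset-tree convolution kernel
``K_c(T1, T2) = sum_{n1 in N1} sum_{n2 in N2} Delta(n1, n2)`` where Delta
counts matching subtree fragments rooted at the node pair, attenuated by
``lam`` per production so large fragments do not dominate.  Values are
normalized to [0, 1] by ``K / sqrt(K11 * K22)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .corpus import CandidatePair, CorpusError, ParsedSentence, blind_entities

ROOT_LABEL = "DEPENDENCY"


@dataclass(frozen=True)
class DepPathTree:
    """A finite labeled ordered tree; leaves have no children."""

    label: str
    children: tuple["DepPathTree", ...] = ()

    def __iter__(self):
        yield self
        for c in self.children:
            yield from c

    @property
    def size(self) -> int:
        return sum(1 for _ in self)

    def production(self) -> tuple:
        return (self.label, tuple(c.label for c in self.children))


@dataclass(frozen=True)
class TreeKernelConfig:
    lam: float = 0.5
    min_path_len: int = 3
    max_extension_edges: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.lam < 1.0:
            raise ValueError(f"attenuation factor must lie in (0, 1), got {self.lam}")


# ---------------------------------------------------------------------------
# Bracketed serialization: label, parenthesized comma-separated children.
# The whole tree is wrapped in one outer pair of parentheses.

_SPECIAL = "(),\\"


def _escape(label: str) -> str:
    return "".join("\\" + ch if ch in _SPECIAL else ch for ch in label)


def _serialize(t: DepPathTree) -> str:
    if not t.children:
        return _escape(t.label)
    return _escape(t.label) + "(" + ",".join(_serialize(c) for c in t.children) + ")"


def to_bracketed(t: DepPathTree) -> str:
    """Serialize to the bracketed string form; inverse of :func:`from_bracketed`."""
    return "(" + _serialize(t) + ")"


def from_bracketed(text: str) -> DepPathTree:
    """Parse the bracketed form produced by :func:`to_bracketed`."""
    s = text.strip()
    if not (s.startswith("(") and s.endswith(")")):
        raise ValueError(f"not a bracketed tree: {text!r}")
    tree, pos = _parse_node(s, 1)
    if s[pos:] != ")":
        raise ValueError(f"trailing characters in bracketed tree: {s[pos:]!r}")
    return tree


def _parse_node(s: str, pos: int) -> tuple[DepPathTree, int]:
    label = []
    while pos < len(s):
        ch = s[pos]
        if ch == "\\" and pos + 1 < len(s):
            label.append(s[pos + 1])
            pos += 2
            continue
        if ch in "(),":
            break
        label.append(ch)
        pos += 1
    name = "".join(label)
    if pos < len(s) and s[pos] == "(":
        children = []
        pos += 1
        while True:
            child, pos = _parse_node(s, pos)
            children.append(child)
            if pos >= len(s):
                raise ValueError("unbalanced bracketed tree")
            if s[pos] == ",":
                pos += 1
                continue
            if s[pos] == ")":
                pos += 1
                break
        return DepPathTree(name, tuple(children)), pos
    return DepPathTree(name), pos


# ---------------------------------------------------------------------------
# Path-tree construction


@dataclass
class PathTree:
    """A dependency-path tree plus the bookkeeping needed for extension."""

    tree: DepPathTree
    path_tokens: tuple[int, ...] = ()
    endpoints: tuple[int, int] | None = None
    connected: bool = True


def _relation_node(s: ParsedSentence, head: int, dep: int, rel: str) -> DepPathTree:
    w = s.surfaces
    return DepPathTree(rel, (DepPathTree(w[head]), DepPathTree(w[dep])))


def build_path_tree(s: ParsedSentence, p: CandidatePair) -> PathTree:
    """Shortest-dependency-path tree between the pair's entity head tokens.

    ``s`` must already be blinded for ``p`` (see
    :func:`ppikex.corpus.blind_entities`); the word leaves then read ENTITY1 /
    ENTITY2 / PROT0.  Unparsed sentences and disconnected entity pairs yield
    a root-only tree flagged ``connected=False``.
    """
    ma, mb = s.mention_by_id(p.m1), s.mention_by_id(p.m2)
    first, second = sorted((ma, mb), key=lambda m: (m.start, m.end))
    if not s.edges:
        return PathTree(DepPathTree(ROOT_LABEL), (), None, connected=False)
    g = nx.Graph()
    g.add_nodes_from(range(len(s.tokens)))
    edge_info: dict[tuple[int, int], tuple[int, int, str]] = {}
    for e in sorted(s.edges, key=lambda e: (e.head, e.dependent, e.relation)):
        g.add_edge(e.head, e.dependent)
        edge_info.setdefault(tuple(sorted((e.head, e.dependent))), (e.head, e.dependent, e.relation))
    h1, h2 = s.mention_head(first), s.mention_head(second)
    try:
        path = nx.shortest_path(g, h1, h2)
    except nx.NetworkXNoPath:
        return PathTree(DepPathTree(ROOT_LABEL), (), (h1, h2), connected=False)
    children = []
    for u, v in zip(path, path[1:]):
        head, dep, rel = edge_info[tuple(sorted((u, v)))]
        children.append(_relation_node(s, head, dep, rel))
    return PathTree(DepPathTree(ROOT_LABEL, tuple(children)), tuple(path), (h1, h2))


def extend_short_path(
    pt: PathTree, s: ParsedSentence, cfg: TreeKernelConfig = TreeKernelConfig()
) -> PathTree:
    """Lengthen a too-short path by walking up the endpoints' governors.

    When the path carries fewer than ``cfg.min_path_len`` relation nodes, up
    to ``cfg.max_extension_edges`` extra dependency edges are attached: first
    the governor chain above the ENTITY1-side endpoint (prepended, outermost
    governor first), then — if that side is exhausted — the chain above the
    ENTITY2-side endpoint (appended).  Already-long or disconnected paths are
    returned unchanged.
    """
    if not pt.connected or pt.endpoints is None:
        return pt
    n_rel = len(pt.tree.children)
    if n_rel >= cfg.min_path_len:
        return pt
    head_of = {e.dependent: (e.head, e.relation) for e in s.edges}
    used = set(pt.path_tokens)
    prepend: list[DepPathTree] = []
    append: list[DepPathTree] = []
    added = 0
    for side, bucket in ((pt.endpoints[0], prepend), (pt.endpoints[1], append)):
        cur = side
        while n_rel + added < cfg.min_path_len and added < cfg.max_extension_edges:
            got = head_of.get(cur)
            if got is None or got[0] in used:
                break
            head, rel = got
            node = _relation_node(s, head, cur, rel)
            if bucket is prepend:
                bucket.insert(0, node)
            else:
                bucket.append(node)
            used.add(head)
            cur = head
            added += 1
    if not added:
        return pt
    tree = DepPathTree(ROOT_LABEL, tuple(prepend) + pt.tree.children + tuple(append))
    return PathTree(tree, pt.path_tokens, pt.endpoints, pt.connected)


def pair_path_tree(
    s: ParsedSentence, p: CandidatePair, cfg: TreeKernelConfig = TreeKernelConfig()
) -> DepPathTree:
    """Blind, build, and extend in one step; the usual entry point."""
    blinded = blind_entities(s, p)
    return extend_short_path(build_path_tree(blinded, p), blinded, cfg).tree


# ---------------------------------------------------------------------------
# Convolution kernel


def _internal(t: DepPathTree) -> list[DepPathTree]:
    return [n for n in t if n.children]


def tree_kernel(
    t1: DepPathTree, t2: DepPathTree, cfg: TreeKernelConfig = TreeKernelConfig()
) -> float:
    """Subset-tree convolution kernel between two labeled ordered trees.

    ``Delta(n1, n2)`` is 0 when the productions differ, ``lam`` when both
    nodes are pre-leaf (all children are leaves), and otherwise
    ``lam * prod_k (1 + Delta(child_k(n1), child_k(n2)))``.  Node pairs are
    grouped by production and Delta is memoized, so only potentially matching
    pairs are visited.
    """
    lam = cfg.lam
    n1, n2 = _internal(t1), _internal(t2)
    if not n1 or not n2:
        return 0.0
    by_prod: dict[tuple, list[DepPathTree]] = {}
    for n in n2:
        by_prod.setdefault(n.production(), []).append(n)
    memo: dict[tuple[int, int], float] = {}

    def delta(a: DepPathTree, b: DepPathTree) -> float:
        if not a.children or not b.children:
            return 0.0  # leaves carry no production
        if a.production() != b.production():
            return 0.0
        key = (id(a), id(b))
        if key in memo:
            return memo[key]
        if all(not c.children for c in a.children):
            val = lam
        else:
            val = lam
            for ca, cb in zip(a.children, b.children):
                val *= 1.0 + delta(ca, cb)
        memo[key] = val
        return val

    total = 0.0
    for a in n1:
        for b in by_prod.get(a.production(), ()):
            total += delta(a, b)
    return total


def normalize(kxy: float, kxx: float, kyy: float) -> float:
    """Cosine-style normalization ``kxy / sqrt(kxx * kyy)``; 0 on empty selves."""
    if kxx < 0 or kyy < 0:
        raise ValueError("self-kernel values must be non-negative")
    if kxx == 0.0 or kyy == 0.0:
        return 0.0
    return kxy / np.sqrt(kxx * kyy)


def tree_cross(
    test_trees: list[DepPathTree],
    train_trees: list[DepPathTree],
    cfg: TreeKernelConfig = TreeKernelConfig(),
) -> np.ndarray:
    """Rectangular normalized test-vs-train block of the convolution kernel."""
    self_te = [tree_kernel(t, t, cfg) for t in test_trees]
    self_tr = [tree_kernel(t, t, cfg) for t in train_trees]
    K = np.zeros((len(test_trees), len(train_trees)))
    for i, ti in enumerate(test_trees):
        for j, tj in enumerate(train_trees):
            K[i, j] = normalize(tree_kernel(ti, tj, cfg), self_te[i], self_tr[j])
    return K


def tree_gram(trees: list[DepPathTree], cfg: TreeKernelConfig = TreeKernelConfig()) -> np.ndarray:
    """Normalized Gram matrix of the convolution kernel over path trees.

    Rows for empty (root-only) trees are zero off-diagonal and zero on the
    diagonal: an unparsed sentence carries no structural evidence.
    """
    n = len(trees)
    self_k = np.array([tree_kernel(t, t, cfg) for t in trees])
    K = np.zeros((n, n))
    for i in range(n):
        K[i, i] = 1.0 if self_k[i] > 0 else 0.0
        for j in range(i + 1, n):
            K[i, j] = K[j, i] = normalize(tree_kernel(trees[i], trees[j], cfg),
                                          self_k[i], self_k[j])
    return K
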