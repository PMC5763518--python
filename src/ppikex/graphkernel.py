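"""Tiered tag graphs over sentence tokens and the all-paths tag-graph kernel.

Each (blinded) sentence becomes a directed graph: one node per token, one
edge per dependency arc (head -> dependent).  Every node carries one tag per
tier; the default tiers are

0. ``surface`` — the lowercased blinded word,
1. ``pos``     — the part-of-speech tag (``UNK`` when absent),
2. ``role``    — ENTITY1 / ENTITY2 / PROT0 / OTHER.

With adjacency matrix ``E`` and per-tier 0/1 label matrices ``L_r``
(|tags| x n, one 1 per column), the walk-weight matrix is the geometric
series ``M = sum_i xi^i E^i`` — entry ``[E^n]_ij`` counts directed walks of
length n from node i to node j, so ``M`` fuses paths of all lengths with
weight ``xi`` per edge.  Two graphs are compared tag-to-tag:

    K(G, H) = sum_r beta_r < L_r M L_r^T , L'_r M' L'_r^T >

where ``< , >`` is the elementwise (Frobenius) matrix inner product taken
over the union of the two graphs' tag vocabularies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .corpus import (
    CandidatePair,
    CorpusError,
    ENTITY1,
    ENTITY2,
    PROT_OTHER,
    ParsedSentence,
)
from .treekernel import normalize

CLOSED_FORM = "closed-form"
_ROLE_TAGS = (ENTITY1, ENTITY2, PROT_OTHER)


@dataclass(frozen=True)
class GraphKernelConfig:
    xi: float = 0.3
    betas: tuple[float, ...] = (1.0, 1.0, 1.0)
    max_path_len: int | str = 10
    tier_spec: tuple[str, ...] = ("surface", "pos", "role")

    def __post_init__(self) -> None:
        if not 0.0 < self.xi < 1.0:
            raise ValueError(f"path weight xi must lie in (0, 1), got {self.xi}")
        if len(self.betas) != len(self.tier_spec):
            raise ValueError("need one beta per tag tier")
        if any(b < 0 for b in self.betas) or not any(b > 0 for b in self.betas):
            raise ValueError("tier weights must be non-negative and not all zero")
        if isinstance(self.max_path_len, str) and self.max_path_len != CLOSED_FORM:
            raise ValueError(f"max_path_len must be an integer or {CLOSED_FORM!r}")


@dataclass
class TagGraph:
    """Directed tag graph: adjacency matrix plus one label matrix per tier."""

    n: int
    adjacency: np.ndarray
    tiers: list[tuple[list[str], np.ndarray]]  # (tag vocabulary, |tags| x n matrix)

    def __post_init__(self) -> None:
        if self.adjacency.shape != (self.n, self.n):
            raise ValueError("adjacency shape does not match node count")
        if self.n and np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        for tags, L in self.tiers:
            if L.shape != (len(tags), self.n):
                raise ValueError("label matrix shape does not match tag vocabulary")
            if self.n and not np.array_equal(L.sum(axis=0), np.ones(self.n)):
                raise ValueError("each node must carry exactly one tag per tier")


def _tier_tags(s: ParsedSentence, p: CandidatePair, tier: str) -> list[str]:
    if tier == "surface":
        return [w.lower() for w in s.surfaces]
    if tier == "pos":
        return [t.pos or "UNK" for t in s.tokens]
    if tier == "role":
        return [w if w in _ROLE_TAGS else "OTHER" for w in s.surfaces]
    raise ValueError(f"unknown tag tier {tier!r}")


def build_tag_graph(
    s: ParsedSentence, p: CandidatePair, cfg: GraphKernelConfig = GraphKernelConfig()
) -> TagGraph:
    """Tag graph of a sentence already blinded for candidate pair ``p``.

    Unparsed sentences produce an edgeless graph: nodes still carry tags, so
    the kernel degrades to tag-histogram overlap instead of failing.
    """
    if p.sid != s.sid:
        raise CorpusError(f"pair {p.pid} does not belong to sentence {s.sid}")
    n = len(s.tokens)
    E = np.zeros((n, n))
    for e in s.edges:
        E[e.head, e.dependent] = 1.0
    tiers = []
    for tier in cfg.tier_spec:
        tags = _tier_tags(s, p, tier)
        vocab = sorted(set(tags))
        row = {t: i for i, t in enumerate(vocab)}
        L = np.zeros((len(vocab), n))
        for j, t in enumerate(tags):
            L[row[t], j] = 1.0
        tiers.append((vocab, L))
    return TagGraph(n, E, tiers)


def path_series(E: np.ndarray, xi: float, max_path_len: int | str = 10) -> np.ndarray:
    """The walk-weight series ``sum_{i=0}^{m} xi^i E^i``.

    With ``max_path_len="closed-form"`` the infinite sum is returned exactly
    via the resolvent ``(I - xi E)^{-1}``, which requires the spectral radius
    of ``xi E`` to be strictly below 1; otherwise the series is truncated at
    ``max_path_len`` (always convergent).  Both modes agree on nilpotent
    adjacency matrices once the truncation covers the longest path.
    """
    if not 0.0 < xi < 1.0:
        raise ValueError(f"path weight xi must lie in (0, 1), got {xi}")
    n = E.shape[0]
    eye = np.eye(n)
    if isinstance(max_path_len, str):
        if max_path_len != CLOSED_FORM:
            raise ValueError(f"unknown series mode {max_path_len!r}")
        if n == 0:
            return E.copy()
        rho = max(abs(np.linalg.eigvals(xi * E)))
        if rho >= 1.0 - 1e-12:
            raise ValueError(
                f"spectral radius of xi*E is {rho:.3f} >= 1; the infinite series "
                "diverges — use an integer max_path_len to truncate"
            )
        return linalg.solve(eye - xi * E, eye)
    M = eye.copy()
    term = eye.copy()
    for _ in range(int(max_path_len)):
        term = xi * (term @ E)
        if not term.any():
            break
        M += term
    return M


def _tier_profiles(g: TagGraph, cfg: GraphKernelConfig) -> list[dict[tuple[str, str], float]]:
    """Per tier, the tag-to-tag walk-weight matrix as a sparse dict."""
    M = path_series(g.adjacency, cfg.xi, cfg.max_path_len)
    profiles = []
    for tags, L in g.tiers:
        phi = L @ M @ L.T
        prof = {
            (tags[i], tags[j]): phi[i, j]
            for i in range(len(tags))
            for j in range(len(tags))
            if phi[i, j] != 0.0
        }
        profiles.append(prof)
    return profiles


def tag_graph_kernel(
    g: TagGraph, h: TagGraph, cfg: GraphKernelConfig = GraphKernelConfig()
) -> float:
    """All-paths tag-graph kernel between two tag graphs.

    Tag vocabularies are implicitly unioned per tier; a tag absent from one
    graph contributes zero rows, so only shared tag pairs add to the sum.
    """
    if len(g.tiers) != len(h.tiers):
        raise ValueError("graphs have different tag tier counts")
    return _profile_kernel(_tier_profiles(g, cfg), _tier_profiles(h, cfg), cfg.betas)


def _profile_kernel(
    pg: list[dict], ph: list[dict], betas: tuple[float, ...]
) -> float:
    total = 0.0
    for beta, a, b in zip(betas, pg, ph):
        if beta == 0.0:
            continue
        if len(b) < len(a):
            a, b = b, a
        total += beta * sum(v * b.get(k, 0.0) for k, v in a.items())
    return total


def graph_cross(
    test_graphs: list[TagGraph],
    train_graphs: list[TagGraph],
    cfg: GraphKernelConfig = GraphKernelConfig(),
) -> np.ndarray:
    """Rectangular normalized test-vs-train block of the tag-graph kernel."""
    pte = [_tier_profiles(g, cfg) for g in test_graphs]
    ptr = [_tier_profiles(g, cfg) for g in train_graphs]
    self_te = [_profile_kernel(p, p, cfg.betas) for p in pte]
    self_tr = [_profile_kernel(p, p, cfg.betas) for p in ptr]
    K = np.zeros((len(pte), len(ptr)))
    for i, pi in enumerate(pte):
        for j, pj in enumerate(ptr):
            K[i, j] = normalize(_profile_kernel(pi, pj, cfg.betas), self_te[i], self_tr[j])
    return K


def graph_gram(
    graphs: list[TagGraph], cfg: GraphKernelConfig = GraphKernelConfig()
) -> np.ndarray:
    """Normalized Gram matrix of the tag-graph kernel (unit diagonal)."""
    profiles = [_tier_profiles(g, cfg) for g in graphs]
    n = len(graphs)
    self_k = np.array([_profile_kernel(p, p, cfg.betas) for p in profiles])
    K = np.zeros((n, n))
    for i in range(n):
        K[i, i] = 1.0 if self_k[i] > 0 else 0.0
        for j in range(i + 1, n):
            K[i, j] = K[j, i] = normalize(
                _profile_kernel(profiles[i], profiles[j], cfg.betas), self_k[i], self_k[j]
            )
    return K
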