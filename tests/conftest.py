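"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use brute force (explicit fragment
enumeration, recursive walk counting) so the kernel implementations are
checked against a second, structurally different computation.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppikex.config import RunConfig
from ppikex.evaluate import build_gram_set
from ppikex.synthetic import SynthConfig, generate_corpus, interleukin_example, rsfa_example
from ppikex.treekernel import DepPathTree

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture
def il8_sentence():
    return interleukin_example()


@pytest.fixture
def rsfa_sentence():
    return rsfa_example()


@pytest.fixture(scope="session")
def small_corpus():
    """~80 candidate pairs across 10 documents, clean mixed signal."""
    return generate_corpus(SynthConfig(n_docs=10, sentences_per_doc=4, seed=7))


@pytest.fixture(scope="session")
def small_gram_set(small_corpus):
    gs, idx = build_gram_set(small_corpus, RunConfig(bandwidth="median", folds=3, seed=7))
    return gs, idx


# ---------------------------------------------------------------------------
# Tree-kernel oracle: explicit subset-tree fragment enumeration


def enumerate_fragments(t: DepPathTree) -> Counter:
    """All subset-tree fragments of ``t``: Counter[(nested repr, n_productions)].

    A fragment is rooted at an internal node; at every internal node it
    either keeps the full ordered child list (recursing) or cuts the node to
    a leaf.  Leaves of the original tree are represented as (label, None).
    """
    out: Counter = Counter()

    def rooted(n: DepPathTree) -> list[tuple[tuple, int]]:
        options = []
        for ch in n.children:
            opts = [((ch.label, None), 0)]
            if ch.children:
                opts.extend(rooted(ch))
            options.append(opts)
        frags = []
        for combo in itertools.product(*options):
            rep = (n.label, tuple(r for r, _ in combo))
            frags.append((rep, 1 + sum(k for _, k in combo)))
        return frags

    for node in t:
        if node.children:
            for frag in rooted(node):
                out[frag] += 1
    return out


def tree_kernel_oracle(t1: DepPathTree, t2: DepPathTree, lam: float) -> float:
    """Sum over common fragments of count1 * count2 * lam^#productions."""
    c1, c2 = enumerate_fragments(t1), enumerate_fragments(t2)
    return sum(c1[f] * c2[f] * lam ** f[1] for f in c1.keys() & c2.keys())


def random_tree(rng: np.random.Generator, max_nodes: int = 8, labels: str = "ABCD") -> DepPathTree:
    """A random labeled ordered tree with at most ``max_nodes`` nodes."""
    budget = int(rng.integers(1, max_nodes + 1))

    def grow(budget: int) -> tuple[DepPathTree, int]:
        label = labels[int(rng.integers(0, len(labels)))]
        used = 1
        children = []
        while budget - used > 0 and rng.random() < 0.6:
            child, k = grow(budget - used)
            children.append(child)
            used += k
        return DepPathTree(label, tuple(children)), used

    tree, _ = grow(budget)
    return tree


# ---------------------------------------------------------------------------
# Graph-kernel oracle: recursive directed-walk enumeration


def count_walks(edges: set[tuple[int, int]], n: int, i: int, j: int, length: int) -> int:
    if length == 0:
        return int(i == j)
    return sum(
        count_walks(edges, n, k, j, length - 1) for k in range(n) if (i, k) in edges
    )


def walk_count_matrix(edges: set[tuple[int, int]], n: int, length: int) -> np.ndarray:
    return np.array(
        [[count_walks(edges, n, i, j, length) for j in range(n)] for i in range(n)]
    )


def random_digraph(rng: np.random.Generator, max_nodes: int = 6, p: float = 0.3):
    n = int(rng.integers(1, max_nodes + 1))
    E = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(E, 0.0)
    return n, E
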