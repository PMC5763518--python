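"""Named Gram matrices over a fixed candidate-pair order, with text I/O.

The text format is shared by all kernels: an optional ``#``-comment header
(carrying the kernel name and config hash), one line of tab-separated pair
ids, then one row of floats per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_SYM_TOL = 1e-9


@dataclass
class GramSet:
    """Square symmetric kernel matrices over one ordered candidate list."""

    pair_ids: list[str]
    grams: dict[str, np.ndarray]
    labels: np.ndarray | None = None  # +1 / -1 per pair, absent at predict time

    def __post_init__(self) -> None:
        n = len(self.pair_ids)
        if len(set(self.pair_ids)) != n:
            raise ValueError("pair ids must be unique")
        for name, K in self.grams.items():
            if K.shape != (n, n):
                raise ValueError(f"gram {name!r} has shape {K.shape}, expected {(n, n)}")
            if np.max(np.abs(K - K.T), initial=0.0) > _SYM_TOL:
                raise ValueError(f"gram {name!r} is not symmetric")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels length does not match pair ids")
            if not set(np.unique(self.labels)) <= {-1, 1}:
                raise ValueError("labels must be +1/-1")

    @property
    def n(self) -> int:
        return len(self.pair_ids)

    @property
    def kernel_names(self) -> list[str]:
        return sorted(self.grams)

    def subset(self, idx: np.ndarray) -> "GramSet":
        """Restrict rows and columns to the given index array (train slice)."""
        idx = np.asarray(idx)
        return GramSet(
            [self.pair_ids[i] for i in idx],
            {k: K[np.ix_(idx, idx)] for k, K in self.grams.items()},
            None if self.labels is None else self.labels[idx],
        )

    def cross(self, rows: np.ndarray, cols: np.ndarray) -> dict[str, np.ndarray]:
        """Rectangular test-vs-train kernel blocks (not a GramSet)."""
        rows, cols = np.asarray(rows), np.asarray(cols)
        return {k: K[np.ix_(rows, cols)] for k, K in self.grams.items()}


def write_gram(path, pair_ids: list[str], K: np.ndarray, header: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("\t".join(pair_ids) + "\n")
        for row in np.atleast_2d(K):
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")


def read_gram(path) -> tuple[list[str], np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    pair_ids = lines[0].split("\t")
    K = np.array([[float(v) for v in ln.split("\t")] for ln in lines[1:] if ln])
    if K.shape != (len(pair_ids), len(pair_ids)):
        raise ValueError(f"gram file {path}: matrix shape {K.shape} does not match header")
    return pair_ids, K
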