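"""Weighted kernel fusion, weight tuning, and max-margin training.

The fused kernel is the convex combination ``K = sum_i eta_i K_i`` with
``eta_i >= 0, sum eta_i = 1``.  Training solves the soft-margin SVM dual on
the fused precomputed Gram,

    L_d = sum_t alpha_t - 1/2 sum_t sum_s alpha_t alpha_s r_t r_s K(x_t, x_s),
    0 <= alpha_t <= C,   sum_t alpha_t r_t = 0,

and prediction evaluates the discriminant
``g(x) = sum_t alpha_t r_t sum_i eta_i K_i(x_t, x) + b`` over the support
pairs.  The quadratic program is delegated to scikit-learn's SMO solver on
the precomputed fused matrix; the contract is the optimality of the dual,
not the solver.

Fusion weights are tuned by exhaustive search over a simplex grid with inner
cross-validated F-score as the objective — deterministic and transparent,
unlike gradient-based multiple-kernel learning.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

PSD_TOL = 1e-8


@dataclass
class FusionWeights:
    """One non-negative weight per kernel name; weights sum to 1."""

    eta: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.eta.values()) or not any(v > 0 for v in self.eta.values()):
            raise ValueError("weights must be non-negative with at least one positive")
        total = sum(self.eta.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")

    @classmethod
    def uniform(cls, names) -> "FusionWeights":
        names = list(names)
        return cls({n: 1.0 / len(names) for n in names})

    @classmethod
    def single(cls, name: str) -> "FusionWeights":
        return cls({name: 1.0})


@dataclass
class TrainedModel:
    """Dual solution of the fused-kernel SVM, sufficient for prediction."""

    support_ids: list[str]
    alpha: np.ndarray  # alpha_t >= 0 per support pair
    support_labels: np.ndarray  # r_t in {-1, +1}
    bias: float
    weights: FusionWeights
    c: float
    psd_shift: float = 0.0  # diagonal added at train time for PSD repair

    @property
    def dual_coef(self) -> np.ndarray:
        return self.alpha * self.support_labels

    def to_json(self, path) -> None:
        payload = {
            "format": "ppikex-model-v1",
            "support_ids": self.support_ids,
            "alpha": self.alpha.tolist(),
            "support_labels": self.support_labels.astype(int).tolist(),
            "bias": self.bias,
            "eta": self.weights.eta,
            "c": self.c,
            "psd_shift": self.psd_shift,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TrainedModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            d["support_ids"],
            np.array(d["alpha"], dtype=float),
            np.array(d["support_labels"], dtype=float),
            float(d["bias"]),
            FusionWeights(d["eta"]),
            float(d["c"]),
            float(d.get("psd_shift", 0.0)),
        )


def fuse(grams: dict[str, np.ndarray], w: FusionWeights) -> np.ndarray:
    """Elementwise weighted sum of named kernel matrices."""
    missing = set(w.eta) - set(grams)
    if missing:
        raise ValueError(f"weights name unknown kernels: {sorted(missing)}")
    shapes = {grams[name].shape for name in w.eta}
    if len(shapes) > 1:
        raise ValueError(f"kernel matrices disagree in shape: {shapes}")
    out = None
    for name, eta in sorted(w.eta.items()):
        term = eta * grams[name]
        out = term if out is None else out + term
    return out


def simplex_grid(names: list[str], step: float) -> list[FusionWeights]:
    """All weightings on the simplex grid with the given step (e.g. 0.1)."""
    names = sorted(names)
    units = round(1.0 / step)
    if abs(units * step - 1.0) > 1e-9:
        raise ValueError("grid step must divide 1 exactly")
    out = []
    for combo in itertools.product(range(units + 1), repeat=len(names) - 1):
        if sum(combo) <= units:
            parts = list(combo) + [units - sum(combo)]
            out.append(FusionWeights({n: c / units for n, c in zip(names, parts)}))
    return out


def _repair_psd(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Floor-shift repair: add |most negative eigenvalue| to the diagonal."""
    w = np.linalg.eigvalsh((K + K.T) / 2.0)
    lo = float(w.min()) if len(w) else 0.0
    if lo < -PSD_TOL:
        shift = -lo
        return K + shift * np.eye(K.shape[0]), shift
    return K, 0.0


def _fit_svc(K: np.ndarray, y: np.ndarray, c: float, class_weight) -> SVC:
    svc = SVC(kernel="precomputed", C=c, class_weight=class_weight)
    svc.fit(K, y)
    return svc


def train(
    gs,
    w: FusionWeights,
    c: float = 1.0,
    class_weight: str | dict | None = "balanced",
) -> TrainedModel:
    """Fit the soft-margin dual on the fused precomputed kernel."""
    if gs.labels is None:
        raise ValueError("training requires labels")
    y = np.asarray(gs.labels, dtype=float)
    if len(set(y)) < 2:
        raise ValueError("training requires both classes")
    K, shift = _repair_psd(fuse(gs.grams, w))
    svc = _fit_svc(K, y, c, class_weight)
    sv = svc.support_
    dual = svc.dual_coef_[0]
    labels = y[sv]
    return TrainedModel(
        support_ids=[gs.pair_ids[i] for i in sv],
        alpha=np.abs(dual),
        support_labels=labels,
        bias=float(svc.intercept_[0]),
        weights=w,
        c=c,
        psd_shift=shift,
    )


def decision_values(
    model: TrainedModel, cross_grams: dict[str, np.ndarray], column_ids: list[str]
) -> np.ndarray:
    """Discriminant values g(x) for test rows given test-vs-train blocks.

    ``column_ids`` names the training pairs indexing the columns of every
    matrix in ``cross_grams``; all support pairs must be among them.
    """
    col_of = {pid: j for j, pid in enumerate(column_ids)}
    missing = [pid for pid in model.support_ids if pid not in col_of]
    if missing:
        raise ValueError(f"cross grams lack support columns: {missing[:5]}")
    X = fuse(cross_grams, model.weights)
    cols = [col_of[pid] for pid in model.support_ids]
    return X[:, cols] @ model.dual_coef + model.bias


def predict(
    model: TrainedModel, cross_grams: dict[str, np.ndarray], column_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Signed labels (+1/-1) and raw decision values for test pairs."""
    g = decision_values(model, cross_grams, column_ids)
    labels = np.where(g > 0, 1.0, -1.0)
    return labels, g


def tune_weights(
    gs,
    grid_step: float = 0.1,
    folds: int = 3,
    seed: int = 0,
    c: float = 1.0,
    class_weight: str | dict | None = "balanced",
    graph_kernel_name: str = "graph",
) -> FusionWeights:
    """Pick fusion weights by exhaustive simplex-grid search with inner CV.

    The objective is the pooled F-score over ``folds`` stratified inner
    folds.  Ties prefer a larger tag-graph weight, then the larger weight
    vector in lexicographic kernel-name order; the search is deterministic
    given the seed.
    """
    from .evaluate import prf  # local import to avoid a cycle

    if gs.labels is None or len(set(gs.labels.tolist())) < 2:
        raise ValueError("weight tuning requires labels from both classes")
    names = gs.kernel_names
    y = np.asarray(gs.labels, dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    best = None
    for w in simplex_grid(names, grid_step):
        K = fuse(gs.grams, w)
        tp = fp = fn = tn = 0
        for tr, te in splits:
            if len(set(y[tr])) < 2:
                continue
            Ktr, _ = _repair_psd(K[np.ix_(tr, tr)])
            svc = _fit_svc(Ktr, y[tr], c, class_weight)
            pred = svc.predict(K[np.ix_(te, tr)])
            tp += int(np.sum((pred == 1) & (y[te] == 1)))
            fp += int(np.sum((pred == 1) & (y[te] == -1)))
            fn += int(np.sum((pred == -1) & (y[te] == 1)))
            tn += int(np.sum((pred == -1) & (y[te] == -1)))
        score = prf(tp, fp, fn, tn).f
        key = (
            score,
            w.eta.get(graph_kernel_name, 0.0),
            tuple(w.eta.get(n, 0.0) for n in names),
        )
        if best is None or key > best[0]:
            best = (key, w)
    return best[1]
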