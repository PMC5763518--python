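"""One flat, serializable configuration object for the whole pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .graphkernel import GraphKernelConfig
from .treekernel import TreeKernelConfig


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with documented defaults.

    Kernel selection
        ``kernels``: any subset of ``feature``, ``tree``, ``graph``.
    Feature kernel
        ``bandwidth``: RBF scale s in exp(-||x-y||^2 / 2s^2), or "median"
        for the median-distance heuristic; ``window``:
        context tokens per side; ``lexicon``: keyword list path (packaged
        default when empty).
    Tree kernel
        ``lam``: attenuation in (0,1); ``min_path_len`` / ``max_extension_edges``:
        short-path extension rule.
    Graph kernel
        ``xi``: per-edge walk weight; ``betas``: tier weights; ``max_path_len``:
        series truncation order (or "closed-form"); ``tiers``: tag tiers.
    Training
        ``c``: soft-margin constant; ``class_weight``: "balanced" rescales C
        by inverse class frequency; ``eta``: fixed fusion weights, or null to
        tune by simplex grid (``grid_step``, ``inner_folds``).
    Evaluation
        ``folds``: document-grouped CV folds; ``seed``: master seed.
    """

    kernels: tuple[str, ...] = ("feature", "tree", "graph")
    bandwidth: float | str = 1.0
    window: int = 3
    lexicon: str = ""
    lam: float = 0.5
    min_path_len: int = 3
    max_extension_edges: int = 2
    xi: float = 0.3
    betas: tuple[float, ...] = (1.0, 1.0, 1.0)
    max_path_len: int | str = 10
    tiers: tuple[str, ...] = ("surface", "pos", "role")
    c: float = 1.0
    class_weight: str | None = "balanced"
    eta: dict[str, float] | None = None
    grid_step: float = 0.1
    inner_folds: int = 3
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.kernels) - {"feature", "tree", "graph"}
        if unknown:
            raise ValueError(f"unknown kernels: {sorted(unknown)}")
        # fail early on bad kernel parameters
        self.tree_config()
        self.graph_config()

    def tree_config(self) -> TreeKernelConfig:
        return TreeKernelConfig(self.lam, self.min_path_len, self.max_extension_edges)

    def graph_config(self) -> GraphKernelConfig:
        return GraphKernelConfig(self.xi, tuple(self.betas), self.max_path_len, tuple(self.tiers))

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kernels", "betas", "tiers"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        """Short digest embedded in every artifact this config produces."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
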