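"""Run configuration: every tunable of the pipeline with its default.

Guideline bands (warnings, not errors): ``min_mutual_overlap`` is best kept
between 0.80 and 0.99 — smaller values merge more sections into fewer
modules and lose information; t-SNE ``perplexity`` is usually adjusted
within 50-500 on large datasets (it is clamped below the point count
automatically for small sub-layers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace

from .io_formats import read_config_file, write_config_file

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # module identification / selection
    min_mutual_overlap: float = 0.8  # minOverlap: section-merge threshold
    top_mod_num: int = 30  # number of most widespread modules retained
    evalue_max: float = 1e-5
    min_section_len: int = 30  # nt
    min_members: int = 2
    max_hits_per_query: int = 10_000
    # dimensionality reduction
    perplexity: float = 50.0
    early_exaggeration: float = 12.0
    learning_rate: float = 200.0
    # layered clustering
    k_min: int = 2
    k_max: int = 8
    linkage: str = "average"
    split_jump: float = 1.5  # dendrogram merge-height jump ratio marking a real scale
    max_depth: int = 3
    assumption_min_corr: float = 0.1  # stop splitting when radial diagnostic drops below
    min_split_size: int = 50
    # validation
    n_sample: int = 20
    alpha: float = 0.05
    origin_quantile: float = 0.5  # fraction of origin-proximal points flagged low-confidence
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0.0 < self.min_mutual_overlap <= 1.0):
            raise ValueError(f"min_mutual_overlap {self.min_mutual_overlap} outside (0,1]")
        if not (0.80 <= self.min_mutual_overlap <= 0.99):
            warnings.warn(
                f"min_mutual_overlap={self.min_mutual_overlap}: recommended range "
                "is 0.80-0.99 (smaller values merge more modules and lose signal)",
                stacklevel=2,
            )
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if not (50 <= self.perplexity <= 500):
            warnings.warn(
                f"perplexity={self.perplexity}: the usual adjustment range is 50-500 "
                "(each adjustment should change it by at least 5%)",
                stacklevel=2,
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0,1)")
        if not (0.0 <= self.origin_quantile < 1.0):
            raise ValueError("origin_quantile must be in [0,1)")
        if self.max_depth < 0 or self.min_split_size < 1 or self.top_mod_num < 1:
            raise ValueError("invalid layering settings")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("invalid k range")

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path) -> None:
        write_config_file(self.to_dict(), path)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        raw = read_config_file(path)
        kwargs = {}
        defaults = cls()
        for key, val in raw.items():
            if not hasattr(defaults, key):
                raise ValueError(f"unknown config key: {key}")
            cur = getattr(defaults, key)
            if isinstance(cur, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(cur, int):
                kwargs[key] = int(val)
            elif isinstance(cur, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        kwargs.update(overrides)
        return cls(**kwargs)

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
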