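"""Analysis-wide configuration constants in one place."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


@dataclass
class AnalysisConfig:
    """Bundle of the pipeline's tunable constants with their defaults.

    Every stage accepts these values individually; the bundle exists so a
    whole analysis can be configured (and serialized) in one object.
    """

    prune_thresholds: Sequence[float] = (10.0, 25.0, 50.0)  # um, ascending
    score_cutoff: float = 0.3  # similarity pair selection
    secondary_cutoff: float = 0.2  # exploratory lower cutoff
    heatmap_cap: int = 10  # type-level heatmap display cap
    window_min_samples: int = 6  # detectable production window
    window_min_span: int = 2  # time points
    alpha_lineage: float = 0.01  # per-lineage length test
    alpha_paired: float = 0.05  # paired CV / class-count tests

    def __post_init__(self) -> None:
        th = list(self.prune_thresholds)
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("prune_thresholds must be strictly increasing")
        for name in ("score_cutoff", "secondary_cutoff"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.heatmap_cap < 1 or self.window_min_samples < 1 or self.window_min_span < 1:
            raise ValueError("counts must be positive")
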