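"""Run configuration: every tunable of the pipeline in one serializable object."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .evaluation import CVConfig
from .filters import FilterBudget
from .swarm import BeetleConfig


@dataclass
class WrapperConfig:
    """Population search budget and search-space bounds mode.

    Bounds are drawn per run: the lower bound uniformly from
    ``lower_range`` and the upper bound from ``upper_range``.
    """

    population: int = 30
    iterations: int = 100
    beetle: BeetleConfig = field(default_factory=BeetleConfig)
    lower_range: tuple[float, float] = (-1.0, -0.3)
    upper_range: tuple[float, float] = (0.3, 1.0)
    chaos_seed_param: float = 3.9


@dataclass
class POMConfig:
    """Restart-controller settings; ``thresholds`` overrides the RLIF-derived schedule."""

    i0: float = 1.0
    amplitudes: tuple[float, ...] = (2.743, 1.372, 0.914)
    frequencies: tuple[float, ...] = (0.1, 0.2, 0.4)
    phases: tuple[float, ...] = (0.0, 0.0, 0.0)
    patience_min: int = 3
    patience_max: int = 12
    ec_up: int = 3
    ec_down: int = 2
    thresholds: tuple[int, ...] | None = None


@dataclass
class RunConfig:
    """Everything a single HMF-W run needs besides the dataset itself."""

    budget: FilterBudget = field(default_factory=FilterBudget)
    mi_bins: int | None = 10  # equal-width bins for MI on continuous data
    wrapper: WrapperConfig = field(default_factory=WrapperConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    pom: POMConfig = field(default_factory=POMConfig)
    master_seed: int = 0
    runs: int = 10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Hash of the canonical serialization; detects silent default drift."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
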