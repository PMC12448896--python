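"""Pipeline constants and configuration.

All defaults mirror the analysis conventions used throughout the package:
times in seconds, positions in bregma-relative millimetres (ML positive
lateral, AP positive anterior), firing rates in spikes/s.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Peri-touch analysis epochs, seconds relative to food touch. Half-open
#: [start, end): a spike exactly at touch belongs to the post-touch epoch.
EPOCHS: dict[str, tuple[float, float]] = {
    "baseline": (-1.0, -0.7),
    "pre": (-0.3, 0.0),
    "post": (0.0, 0.3),
}

#: Full peri-touch analysis window (union of the defined epochs).
ANALYSIS_WINDOW: tuple[float, float] = (-1.0, 0.3)

PROXIMAL_CLASSES = ("Abd", "Add", "Ext", "Rtr", "Elv")
DISTAL_CLASSES = ("Opn", "Clo", "Ocs", "Sup")

#: Proximal movement classes that enter the cortical maps. Elevation is
#: classified but excluded from mapping (scattered, no coherent territory).
MAPPED_PROXIMAL_CLASSES = ("Abd", "Add", "Ext", "Rtr")


@dataclass
class PipelineConfig:
    """Tunable constants for the full analysis pipeline.

    The defaults are the values the analysis is defined with; changing them
    changes the analysis, not just its presentation.
    """

    bin_width_s: float = 0.020          # PSTH bin width
    kernel_width_bins: int = 15         # Gaussian SDF kernel support, in bins
    alpha: float = 0.05                 # significance level, all tests
    min_category: int = 4               # smallest analyzable subpopulation
    movement_cutoff_mm: float = 1.0     # minimal evoked marker displacement
    proximal_threshold_mm: float = 4.0  # dominant-axis displacement threshold
    proximal_ratio: float = 0.15        # cross-axis ratio for Abd/Add/Ext/Rtr
    representation_threshold: int = 2   # animals per gridpoint for a border
    strict_representation: bool = False  # use > instead of >= for the border
    n_sim: int = 10_000                 # Monte Carlo null sample size
    max_current_ua: float = 100.0       # ICMS current ceiling for responsiveness
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
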