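"""Tunable parameters of the WSS workflow.

All thresholds are exclusive: a sample or window is retained only when its
metric strictly exceeds (or, for low-depth fractions, does not strictly
exceed) the configured value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class WssConfig:
    """Parameters controlling window geometry, window usability and sample QC.

    Attributes
    ----------
    window_length : int
        Length in bases of the fixed, non-overlapping genomic windows the
        reference is tiled into (the final window may be shorter).
    depth_floor : int
        Per-base read depth below which a base counts as "low depth" for the
        window-usability rule.
    max_low_fraction : float
        A window is unusable for a sample pair when, in either sample, the
        fraction of its bases with depth below ``depth_floor`` strictly
        exceeds this value.
    min_breadth : float
        Minimum breadth of coverage (fraction of reference positions with
        depth >= 1) a sample must strictly exceed to enter pairwise
        comparisons.
    min_depth : float
        Minimum mean read depth (averaged over the full reference length,
        uncovered positions counting as zero) a sample must strictly exceed.
    """

    window_length: int = 1000
    depth_floor: int = 5
    max_low_fraction: float = 0.5
    min_breadth: float = 0.30
    min_depth: float = 3.5

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.depth_floor < 0:
            raise ValueError("depth_floor must be >= 0")
        if not 0.0 <= self.max_low_fraction <= 1.0:
            raise ValueError("max_low_fraction must be in [0, 1]")
        if not 0.0 <= self.min_breadth <= 1.0:
            raise ValueError("min_breadth must be in [0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WssConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


DEFAULT_CONFIG = WssConfig()
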