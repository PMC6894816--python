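"""Window-based SNV similarity (WSS) scoring.

The reference genome of each species is tiled into fixed, non-overlapping
windows. For a pair of samples, a window is "good/usable" unless, in either
sample, more than ``max_low_fraction`` of its bases have read depth below
``depth_floor``. A usable window is *identical* when no position called in
both samples carries differing allele strings. The WSS score is the
percentage of usable windows that are identical:

    WSS = 100 * n_identical / n_usable        (undefined when n_usable = 0)

Missing calls are non-informative: they neither match nor mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, WssConfig
from .variant_io import NO_CALL, SampleProfile

__all__ = [
    "WindowSpec",
    "PairComparison",
    "partition_windows",
    "window_usable",
    "window_identical",
    "wss_score",
    "pair_table",
    "write_pair_table",
]


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-window tiling of one reference genome.

    ``windows`` are 0-based half-open [start, end) intervals covering
    [0, reference_length) without gaps or overlap; the final window may be
    shorter than ``window_length``.
    """

    species_id: str
    window_length: int
    windows: tuple[tuple[int, int], ...]

    @property
    def reference_length(self) -> int:
        return self.windows[-1][1]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @cached_property
    def starts(self) -> np.ndarray:
        return np.asarray([w[0] for w in self.windows], dtype=np.intp)

    @cached_property
    def lengths(self) -> np.ndarray:
        return np.asarray([e - s for s, e in self.windows], dtype=np.int64)


@dataclass(frozen=True)
class PairComparison:
    """Window bookkeeping and WSS score for one sample pair on one species."""

    species_id: str
    sample_a: str
    sample_b: str
    n_windows_total: int
    n_windows_usable: int
    n_windows_identical: int

    def __post_init__(self) -> None:
        if not (
            0 <= self.n_windows_identical <= self.n_windows_usable <= self.n_windows_total
        ):
            raise ValueError(
                "window counts must satisfy identical <= usable <= total"
            )

    @property
    def wss_score(self) -> float | None:
        """WSS score in [0, 100], or None when no window is usable."""
        if self.n_windows_usable == 0:
            return None
        return 100.0 * self.n_windows_identical / self.n_windows_usable


def partition_windows(
    reference_length: int, window_length: int, species_id: str = ""
) -> WindowSpec:
    """Tile [0, reference_length) into consecutive windows of ``window_length``."""
    if reference_length < 1:
        raise ValueError("reference_length must be >= 1")
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    starts = range(0, reference_length, window_length)
    windows = tuple((s, min(s + window_length, reference_length)) for s in starts)
    return WindowSpec(species_id=species_id, window_length=window_length, windows=windows)


def window_usable(
    depths_a: Sequence[int],
    depths_b: Sequence[int],
    depth_floor: int = DEFAULT_CONFIG.depth_floor,
    max_low_fraction: float = DEFAULT_CONFIG.max_low_fraction,
) -> bool:
    """Low-coverage window rule for one window of one sample pair.

    The window is dropped iff in *either* sample strictly more than
    ``max_low_fraction`` of its bases have depth < ``depth_floor``; absent
    positions count as depth 0. Exactly the threshold fraction is usable.
    """
    da = np.asarray(depths_a)
    db = np.asarray(depths_b)
    if da.shape != db.shape:
        raise ValueError(f"depth vectors differ in length: {da.shape} vs {db.shape}")
    n = da.size
    if n == 0:
        raise ValueError("empty window")
    frac_a = (da < depth_floor).sum() / n
    frac_b = (db < depth_floor).sum() / n
    return not (frac_a > max_low_fraction or frac_b > max_low_fraction)


def window_identical(
    profile_a: SampleProfile, profile_b: SampleProfile, window: tuple[int, int]
) -> bool:
    """True iff no position in the window called in both samples differs.

    Positions missing in either sample are non-informative; a window with no
    both-called positions shows no observed difference and counts identical.
    """
    s, e = window
    a = profile_a.alleles[s:e]
    b = profile_b.alleles[s:e]
    both = (a != NO_CALL) & (b != NO_CALL)
    return not bool((both & (a != b)).any())


def wss_score(
    profile_a: SampleProfile,
    profile_b: SampleProfile,
    spec: WindowSpec,
    config: WssConfig = DEFAULT_CONFIG,
) -> PairComparison:
    """Compute the WSS comparison for one sample pair on one species.

    Usable windows are determined by the low-coverage rule applied to each
    sample separately; identity is assessed on usable windows only. The
    result is exactly symmetric in the two samples.
    """
    if profile_a.species_id != profile_b.species_id:
        raise ValueError(
            f"species mismatch: {profile_a.species_id} vs {profile_b.species_id}"
        )
    if profile_a.reference_length != profile_b.reference_length:
        raise ValueError("profiles disagree on reference length")
    if spec.reference_length != profile_a.reference_length:
        raise ValueError(
            f"window spec covers {spec.reference_length} bases, "
            f"profiles cover {profile_a.reference_length}"
        )
    starts = spec.starts
    lengths = spec.lengths

    low_a = np.add.reduceat((profile_a.depths < config.depth_floor).astype(np.int64), starts)
    low_b = np.add.reduceat((profile_b.depths < config.depth_floor).astype(np.int64), starts)
    unusable = (low_a / lengths > config.max_low_fraction) | (
        low_b / lengths > config.max_low_fraction
    )
    usable = ~unusable

    a = profile_a.alleles
    b = profile_b.alleles
    mismatch = (a != NO_CALL) & (b != NO_CALL) & (a != b)
    mm_counts = np.add.reduceat(mismatch.astype(np.int64), starts)
    identical = usable & (mm_counts == 0)

    return PairComparison(
        species_id=profile_a.species_id,
        sample_a=profile_a.sample_id,
        sample_b=profile_b.sample_id,
        n_windows_total=spec.n_windows,
        n_windows_usable=int(usable.sum()),
        n_windows_identical=int(identical.sum()),
    )


def pair_table(comparisons: Sequence[PairComparison]) -> pd.DataFrame:
    """Pair comparisons as a tidy table; undefined scores rendered as NA."""
    rows = [
        {
            "species_id": c.species_id,
            "sample_a": c.sample_a,
            "sample_b": c.sample_b,
            "n_total": c.n_windows_total,
            "n_usable": c.n_windows_usable,
            "n_identical": c.n_windows_identical,
            "wss_score": c.wss_score,
        }
        for c in comparisons
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "sample_a", "sample_b",
            "n_total", "n_usable", "n_identical", "wss_score",
        ],
    )


def write_pair_table(comparisons: Sequence[PairComparison], path: str | Path) -> Path:
    path = Path(path)
    pair_table(comparisons).to_csv(path, sep="\t", index=False, na_rep="NA")
    return path
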