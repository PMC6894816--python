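"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every quantity with plain Python loops,
independent of the vectorised implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from wsstrack import SampleProfile

BASES = ("A", "C", "G", "T")


def make_profile(
    sample_id: str,
    alleles: list[str],
    depths: list[int],
    species_id: str = "sp",
) -> SampleProfile:
    """Profile from explicit per-base allele ('' = no call) and depth lists."""
    return SampleProfile(
        sample_id,
        species_id,
        len(alleles),
        np.asarray(alleles, dtype=str),
        np.asarray(depths, dtype=np.int64),
    )


def random_profile(
    rng: np.random.Generator,
    length: int,
    sample_id: str = "s",
    species_id: str = "sp",
    max_depth: int = 12,
    missing_prob: float = 0.15,
) -> SampleProfile:
    depths = rng.integers(0, max_depth + 1, size=length)
    alleles = np.asarray([BASES[i] for i in rng.integers(0, 4, size=length)], dtype=str)
    missing = (depths == 0) | (rng.random(length) < missing_prob)
    alleles = alleles.copy()
    alleles[missing] = ""
    return SampleProfile(sample_id, species_id, length, alleles, np.asarray(depths))


def random_profile_pair(
    rng: np.random.Generator, length: int, shared_fraction: float = 0.7, **kw
):
    """Two profiles over the same reference, partially agreeing by design."""
    a = random_profile(rng, length, sample_id="a", **kw)
    b = random_profile(rng, length, sample_id="b", **kw)
    share = rng.random(length) < shared_fraction
    alleles_b = b.alleles.copy()
    alleles_b[share & (a.alleles != "") & (alleles_b != "")] = a.alleles[
        share & (a.alleles != "") & (alleles_b != "")
    ]
    b = SampleProfile("b", b.species_id, length, alleles_b, b.depths)
    return a, b


# ---------------------------------------------------------------- oracles


def brute_force_metrics(profile: SampleProfile) -> tuple[float, float]:
    covered = 0
    total_depth = 0
    for p in range(profile.reference_length):
        d = int(profile.depths[p])
        if d >= 1:
            covered += 1
        total_depth += d
    return covered / profile.reference_length, total_depth / profile.reference_length


def brute_force_window_usable(depths_a, depths_b, depth_floor=5, max_low_fraction=0.5):
    n = len(depths_a)
    for depths in (depths_a, depths_b):
        low = sum(1 for d in depths if d < depth_floor)
        if low / n > max_low_fraction:
            return False
    return True


def brute_force_comparison(
    a: SampleProfile,
    b: SampleProfile,
    windows,
    depth_floor: int = 5,
    max_low_fraction: float = 0.5,
) -> tuple[int, int, int]:
    """(n_total, n_usable, n_identical) by per-base loops."""
    n_usable = n_identical = 0
    for (s, e) in windows:
        if not brute_force_window_usable(
            a.depths[s:e], b.depths[s:e], depth_floor, max_low_fraction
        ):
            continue
        n_usable += 1
        identical = True
        for p in range(s, e):
            aa, bb = a.alleles[p], b.alleles[p]
            if aa != "" and bb != "" and aa != bb:
                identical = False
                break
        n_identical += int(identical)
    return len(windows), n_usable, n_identical


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
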