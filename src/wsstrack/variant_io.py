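"""Base-resolution variant-call I/O and sample-level QC metrics.

Reads multi-sample, base-resolution (gVCF-style) VCF files produced by a
haploid variant-calling workflow into per-sample :class:`SampleProfile`
objects, and computes the breadth-of-coverage / mean-depth metrics used to
decide whether a sample enters pairwise strain comparison at all.

Coordinate conventions: VCF positions are 1-based per the standard; profiles
store per-base arrays indexed 0-based, and all window arithmetic downstream
uses 0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .config import DEFAULT_CONFIG, WssConfig

__all__ = [
    "SampleProfile",
    "CohortManifest",
    "VcfParseError",
    "MissingDepthError",
    "PloidyError",
    "read_multisample_vcf",
    "write_multisample_vcf",
    "compute_sample_metrics",
    "passes_sample_filter",
    "sample_metrics_table",
    "write_sample_metrics",
]

NO_CALL = ""  # allele value marking a missing genotype


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed as a multi-sample haploid call set."""


class MissingDepthError(VcfParseError):
    """Raised when a sample genotype carries no per-sample depth (DP) annotation."""


class PloidyError(VcfParseError):
    """Raised on a genotype with ploidy > 1; the workflow is defined for haploid calls."""


class SampleProfile:
    """Per-species, per-base allele calls and read depths for one sample.

    Parameters
    ----------
    sample_id, species_id : str
        Identifiers of the sample and the reference species genome.
    reference_length : int
        Length of the reference sequence in bases; must be >= 1.
    alleles : ndarray of str, shape (reference_length,)
        Called allele string at each 0-based position; the empty string marks
        a missing call (no genotype).
    depths : ndarray of int, shape (reference_length,)
        Read depth at each position; positions never observed carry 0.
    """

    __slots__ = ("sample_id", "species_id", "reference_length", "alleles", "depths")

    def __init__(
        self,
        sample_id: str,
        species_id: str,
        reference_length: int,
        alleles: np.ndarray,
        depths: np.ndarray,
    ) -> None:
        if reference_length < 1:
            raise ValueError("reference_length must be >= 1")
        alleles = np.asarray(alleles)
        depths = np.asarray(depths, dtype=np.int64)
        if alleles.shape != (reference_length,) or depths.shape != (reference_length,):
            raise ValueError("alleles and depths must have shape (reference_length,)")
        if (depths < 0).any():
            raise ValueError("depths must be non-negative")
        self.sample_id = sample_id
        self.species_id = species_id
        self.reference_length = int(reference_length)
        self.alleles = alleles
        self.depths = depths

    @classmethod
    def from_calls(
        cls,
        sample_id: str,
        species_id: str,
        reference_length: int,
        calls: Mapping[int, tuple[str, int]],
    ) -> "SampleProfile":
        """Build a profile from a sparse {1-based position: (allele, depth)} map.

        Positions absent from ``calls`` are uncalled with depth 0.
        """
        alleles = np.full(reference_length, NO_CALL, dtype=object)
        depths = np.zeros(reference_length, dtype=np.int64)
        for pos, (allele, depth) in calls.items():
            if not 1 <= pos <= reference_length:
                raise ValueError(
                    f"position {pos} outside [1, {reference_length}] for sample {sample_id}"
                )
            alleles[pos - 1] = allele
            depths[pos - 1] = depth
        return cls(sample_id, species_id, reference_length, np.asarray(alleles, dtype=str), depths)

    @property
    def calls(self) -> dict[int, tuple[str, int]]:
        """Sparse view: {1-based position: (allele, depth)} over observed positions."""
        idx = np.flatnonzero((self.depths > 0) | (self.alleles != NO_CALL))
        return {int(i) + 1: (str(self.alleles[i]), int(self.depths[i])) for i in idx}

    @property
    def breadth(self) -> float:
        """Fraction of reference positions with read depth >= 1."""
        return float((self.depths >= 1).sum()) / self.reference_length

    @property
    def mean_depth(self) -> float:
        """Mean depth over the whole reference length; uncovered positions count 0."""
        return float(self.depths.sum()) / self.reference_length

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SampleProfile({self.sample_id!r}, {self.species_id!r}, "
            f"L={self.reference_length}, breadth={self.breadth:.3f}, "
            f"mean_depth={self.mean_depth:.2f})"
        )


@dataclass
class CohortManifest:
    """Read-count bookkeeping for one dataset of a cohort.

    Tracks raw and quality-filtered read counts per sample; filtered counts
    can never exceed raw counts, and dataset totals are sums over samples.
    """

    dataset_id: str
    read_counts_raw: dict[str, int] = field(default_factory=dict)
    read_counts_filtered: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, n_filt in self.read_counts_filtered.items():
            if s not in self.read_counts_raw:
                raise ValueError(f"sample {s} has filtered counts but no raw counts")
            if n_filt > self.read_counts_raw[s]:
                raise ValueError(
                    f"sample {s}: filtered reads ({n_filt}) exceed raw reads "
                    f"({self.read_counts_raw[s]})"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.read_counts_raw)

    @property
    def total_raw(self) -> int:
        return sum(self.read_counts_raw.values())

    @property
    def total_filtered(self) -> int:
        return sum(self.read_counts_filtered.values())


def combined_read_total(manifests: Iterable[CohortManifest], filtered: bool = False) -> int:
    """Total read count over several dataset manifests."""
    return sum(m.total_filtered if filtered else m.total_raw for m in manifests)


def _genotype_allele(rec, sample: str, record_index: int) -> str:
    data = rec.samples[sample]
    gt = data.get("GT")
    if gt is None:
        return NO_CALL
    if not isinstance(gt, tuple):
        gt = (gt,)
    called = [a for a in gt if a is not None]
    if len(gt) > 1:
        raise PloidyError(
            f"record {record_index} (pos {rec.pos}), sample {sample}: "
            f"genotype has ploidy {len(gt)}; haploid calls required"
        )
    if not called:
        return NO_CALL
    return rec.alleles[called[0]]


def read_multisample_vcf(
    path: str | Path, species_id: str, reference_length: int
) -> list[SampleProfile]:
    """Read a base-resolution multi-sample VCF into one profile per sample.

    Reference-called sites yield the reference allele; sites with a missing
    genotype are recorded with no allele but keep their reported depth.

    Raises
    ------
    VcfParseError
        On a malformed file (the message names the offending record), a
        sample genotype without a DP annotation, or a ploidy > 1 genotype.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: not a parseable VCF (header): {exc}") from exc

    samples = list(vcf.header.samples)
    alleles = {s: np.full(reference_length, NO_CALL, dtype=object) for s in samples}
    depths = {s: np.zeros(reference_length, dtype=np.int64) for s in samples}

    i = 0
    try:
        for i, rec in enumerate(vcf, start=1):
            pos0 = rec.pos - 1  # rec.pos is 1-based
            if not 0 <= pos0 < reference_length:
                raise VcfParseError(
                    f"{path}: record {i}: position {rec.pos} outside "
                    f"[1, {reference_length}]"
                )
            for s in samples:
                allele = _genotype_allele(rec, s, i)
                dp = rec.samples[s].get("DP")
                if dp is None:
                    raise MissingDepthError(
                        f"{path}: record {i} (pos {rec.pos}): sample {s} "
                        "has no DP (depth) annotation"
                    )
                alleles[s][pos0] = allele
                depths[s][pos0] = int(dp)
    except VcfParseError:
        raise
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: parse error at or after record {i}: {exc}") from exc
    finally:
        vcf.close()

    return [
        SampleProfile(s, species_id, reference_length,
                      np.asarray(alleles[s], dtype=str), depths[s])
        for s in samples
    ]


def write_multisample_vcf(
    profiles: Sequence[SampleProfile],
    reference: str | Sequence[str],
    path: str | Path,
) -> Path:
    """Write profiles of one species as a base-resolution multi-sample VCF.

    Every reference position is emitted (non-variant sites included), with
    haploid GT and per-sample DP, so the file round-trips bit-exactly through
    :func:`read_multisample_vcf` at all observed positions.

    Parameters
    ----------
    profiles : sequence of SampleProfile
        All for the same species and reference length.
    reference : str or sequence of single-base strings
        The reference sequence, used for the REF column.
    """
    if not profiles:
        raise ValueError("no profiles to write")
    species = {p.species_id for p in profiles}
    if len(species) > 1:
        raise ValueError(f"profiles span multiple species: {sorted(species)}")
    species_id = profiles[0].species_id
    length = profiles[0].reference_length
    if any(p.reference_length != length for p in profiles):
        raise ValueError("profiles disagree on reference length")
    ref = list(reference)
    if len(ref) != length:
        raise ValueError("reference length does not match profiles")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"conflicting (duplicate) sample ids: {ids}")

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={species_id},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for p in profiles:
        header.add_sample(p.sample_id)

    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for pos0 in range(length):
            ref_base = ref[pos0]
            site_alleles = [ref_base]
            for p in profiles:
                a = p.alleles[pos0]
                if a != NO_CALL and a != ref_base and a not in site_alleles:
                    site_alleles.append(str(a))
            # deterministic ALT ordering; monomorphic sites carry the
            # gVCF-style symbolic <NON_REF> alternate
            site_alleles = [ref_base] + sorted(site_alleles[1:])
            if len(site_alleles) == 1:
                site_alleles.append("<NON_REF>")
            rec = out.new_record(
                contig=species_id, start=pos0, stop=pos0 + 1,
                alleles=tuple(site_alleles),
            )
            for p in profiles:
                a = p.alleles[pos0]
                sdata = rec.samples[p.sample_id]
                if a == NO_CALL:
                    sdata["GT"] = (None,)
                else:
                    sdata["GT"] = (site_alleles.index(str(a)),)
                sdata["DP"] = int(p.depths[pos0])
            out.write(rec)
    return path


def compute_sample_metrics(profile: SampleProfile) -> tuple[float, float]:
    """Return (breadth, mean_depth) for one sample against its reference.

    Breadth is the fraction of reference positions with depth >= 1; mean
    depth averages over the whole reference length with uncovered positions
    contributing zero. The profile is not mutated.
    """
    return profile.breadth, profile.mean_depth


def passes_sample_filter(
    breadth: float,
    mean_depth: float,
    min_breadth: float = DEFAULT_CONFIG.min_breadth,
    min_depth: float = DEFAULT_CONFIG.min_depth,
) -> bool:
    """Sample QC: retained only when both metrics strictly exceed their thresholds."""
    return breadth > min_breadth and mean_depth > min_depth


def sample_metrics_table(
    profiles: Sequence[SampleProfile], config: WssConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-sample metrics and filter decision as a tidy table."""
    rows = []
    for p in profiles:
        breadth, mean_depth = compute_sample_metrics(p)
        rows.append(
            {
                "sample_id": p.sample_id,
                "species_id": p.species_id,
                "breadth": breadth,
                "mean_depth": mean_depth,
                "pass_filter": passes_sample_filter(
                    breadth, mean_depth, config.min_breadth, config.min_depth
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "species_id", "breadth", "mean_depth", "pass_filter"]
    )


def write_sample_metrics(
    profiles: Sequence[SampleProfile], path: str | Path, config: WssConfig = DEFAULT_CONFIG
) -> Path:
    path = Path(path)
    sample_metrics_table(profiles, config).to_csv(path, sep="\t", index=False)
    return path
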