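"""Synthetic twin cohorts with known strain-sharing truth.

The generator emulates the statistical structure the WSS workflow consumes,
without simulating reads: per species, a population pool of strain SNV
profiles with a fixed expected pairwise divergence; twin pairs seeded with a
shared pool strain whose two copies drift independently at a per-base
per-year substitution rate once the twins separate, and which may instead be
replaced wholesale by an independent pool strain; and a per-base Poisson
read-depth layer with dropout, so that breadth/mean-depth sample filters and
the low-coverage window rule are all exercised. Cohorts can be kept
in memory or emitted as multi-sample VCF + metadata + truth tables.

Default parameters describe the package's reference scenario: 100 kb
genomes tiled into 1 kb windows, mean depth 20x, within-lineage drift 1e-6
substitutions/base/year against an unrelated-strain divergence of 1e-3, and
one twin pair per separation interval from cohabiting to 55 years apart.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .variant_io import NO_CALL, SampleProfile, write_multisample_vcf

__all__ = [
    "SimulationParams",
    "SpeciesPool",
    "TruthRecord",
    "SimulatedCohort",
    "simulate_strain_pool",
    "simulate_cohort_profiles",
    "simulate_twin_cohort",
    "truth_confusion",
    "ConfusionResult",
]

BASES = np.array(["A", "C", "G", "T"])

TRUTH_SHARED = "shared-lineage"
TRUTH_REPLACED = "replaced"


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic twin-cohort generator.

    Attributes
    ----------
    n_species : int
        Number of reference species genomes simulated independently.
    reference_length : int
        Genome length in bases.
    population_size : int
        Number of distinct strains in each species' population pool.
    population_divergence : float
        Expected pairwise divergence (substitutions/base) between two
        unrelated pool strains.
    drift_rate : float
        Within-lineage substitution rate (substitutions/base/year) applied
        independently to each twin's copy after separation.
    replacement_prob_per_year : float
        Per-year probability that a twin's strain is replaced by an
        independent pool strain; over t years the replacement probability is
        1 - (1 - p)^t.
    n_pairs : int
        Number of twin pairs.
    separation_years : tuple of int
        Years each pair has lived apart (0 = cohabiting); length n_pairs.
    depth_mean : float
        Mean of the per-base Poisson read-depth model.
    dropout_prob : float
        Per-base probability that a position is unobserved (depth forced to
        0) regardless of the Poisson draw.
    seed : int
        Seed of the generator; identical params give identical cohorts.
    """

    n_species: int = 5
    reference_length: int = 100_000
    population_size: int = 25
    population_divergence: float = 1e-3
    drift_rate: float = 1e-6
    replacement_prob_per_year: float = 0.02
    n_pairs: int = 7
    separation_years: tuple[int, ...] = (0, 5, 15, 25, 35, 45, 55)
    depth_mean: float = 20.0
    dropout_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.reference_length < 1 or self.n_pairs < 1:
            raise ValueError("n_species, reference_length and n_pairs must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("population_divergence", "drift_rate",
                     "replacement_prob_per_year", "dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if len(self.separation_years) != self.n_pairs:
            raise ValueError("separation_years must have one entry per pair")
        if any(t < 0 for t in self.separation_years):
            raise ValueError("separation_years must be non-negative")
        if self.drift_rate >= self.population_divergence > 0:
            import warnings

            warnings.warn(
                "drift_rate is not well below population_divergence; "
                "related and unrelated pairs may not be identifiable"
            )

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["separation_years"] = list(d["separation_years"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        d = yaml.safe_load(Path(path).read_text())
        d["separation_years"] = tuple(d["separation_years"])
        return cls(**d)


@dataclass
class SpeciesPool:
    """Population pool of strain genomes for one species (base codes 0-3)."""

    species_id: str
    reference: np.ndarray  # int8 codes, shape (L,)
    strains: list[np.ndarray]  # each int8 codes, shape (L,)

    @property
    def reference_sequence(self) -> str:
        return "".join(BASES[self.reference])

    def pairwise_divergent_positions(self, i: int, j: int) -> int:
        return int((self.strains[i] != self.strains[j]).sum())


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one twin pair on one species."""

    pair_id: str
    species_id: str
    truth_label: str  # shared-lineage | replaced
    n_divergent_positions: int

    def __post_init__(self) -> None:
        if self.truth_label not in (TRUTH_SHARED, TRUTH_REPLACED):
            raise ValueError(f"unknown truth label {self.truth_label!r}")
        if self.n_divergent_positions < 0:
            raise ValueError("n_divergent_positions must be >= 0")


@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort: profiles, metadata, truth and pools."""

    params: SimulationParams
    profiles: dict[str, list[SampleProfile]]  # species_id -> profiles
    metadata: pd.DataFrame  # sample-level table
    truth: list[TruthRecord]
    pools: dict[str, SpeciesPool]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pair_id": t.pair_id,
                    "species_id": t.species_id,
                    "truth_label": t.truth_label,
                    "n_divergent_positions": t.n_divergent_positions,
                }
                for t in self.truth
            ]
        )


def _mutate(codes: np.ndarray, n_subs: int, rng: np.random.Generator) -> np.ndarray:
    """Apply n_subs substitutions at distinct uniform positions; each new
    base is uniform over the three non-current bases."""
    out = codes.copy()
    if n_subs == 0:
        return out
    n_subs = min(n_subs, out.size)
    pos = rng.choice(out.size, size=n_subs, replace=False)
    offsets = rng.integers(1, 4, size=n_subs)
    out[pos] = (out[pos] + offsets) % 4
    return out


def simulate_strain_pool(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> dict[str, SpeciesPool]:
    """Draw per-species population pools of strain genomes.

    Each strain mutates each reference base independently with probability
    ``population_divergence / 2``, so the expected pairwise divergence
    between two pool strains is approximately ``population_divergence``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    per_strain = params.population_divergence / 2.0
    pools: dict[str, SpeciesPool] = {}
    for s in range(params.n_species):
        species_id = f"species_{s + 1:02d}"
        reference = rng.integers(0, 4, size=params.reference_length, dtype=np.int8)
        strains = []
        for _ in range(params.population_size):
            n_subs = rng.binomial(params.reference_length, per_strain)
            strains.append(_mutate(reference, int(n_subs), rng))
        pools[species_id] = SpeciesPool(species_id, reference, strains)
    return pools


def _observe(
    sample_id: str,
    species_id: str,
    codes: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
) -> SampleProfile:
    """Depth layer: Poisson depth with dropout; uncovered positions uncalled."""
    length = codes.size
    depths = rng.poisson(params.depth_mean, size=length).astype(np.int64)
    if params.dropout_prob > 0:
        depths[rng.random(length) < params.dropout_prob] = 0
    alleles = BASES[codes].copy()
    alleles[depths == 0] = NO_CALL
    return SampleProfile(sample_id, species_id, length, alleles, depths)


def simulate_cohort_profiles(params: SimulationParams) -> SimulatedCohort:
    """Simulate a twin cohort in memory.

    Per species and pair: a seed strain is drawn from the pool; each twin
    keeps it (accumulating Poisson(drift_rate x L x years) substitutions
    after separation) or, with probability 1-(1-p)^years, has it replaced by
    a distinct pool strain. The observation layer then draws per-base
    depths. Deterministic given ``params`` (including the seed).
    """
    rng = np.random.default_rng(params.seed)
    pools = simulate_strain_pool(params, rng)

    pair_ids = [f"P{i + 1:02d}" for i in range(params.n_pairs)]
    metadata_rows = []
    for pid, years in zip(pair_ids, params.separation_years):
        for twin in (1, 2):
            metadata_rows.append(
                {
                    "sample_id": f"{pid}_T{twin}",
                    "pair_id": pid,
                    "family_id": f"F_{pid}",
                    "separation_years": int(years),
                    "age_years": 25 + int(years),
                }
            )
    metadata = pd.DataFrame(metadata_rows)

    profiles: dict[str, list[SampleProfile]] = {}
    truth: list[TruthRecord] = []
    length = params.reference_length
    for species_id, pool in pools.items():
        species_profiles: list[SampleProfile] = []
        # Distinct individuals carry distinct strains (the fingerprint
        # premise): allocate each pair a block of up to 3 distinct pool
        # strains (seed + one replacement per twin), without reuse across
        # pairs when the pool is large enough.
        if params.population_size >= 3 * params.n_pairs:
            order = rng.permutation(params.population_size)
            blocks = [order[3 * i: 3 * i + 3] for i in range(params.n_pairs)]
        else:
            blocks = [
                rng.choice(params.population_size,
                           size=min(3, params.population_size), replace=False)
                for _ in range(params.n_pairs)
            ]
        for pid, years, idx in zip(pair_ids, params.separation_years, blocks):
            seed_idx = int(idx[0])
            p_replace = 1.0 - (1.0 - params.replacement_prob_per_year) ** years
            twin_codes = []
            replaced = []
            for twin in (1, 2):
                if years > 0 and rng.random() < p_replace:
                    alt_idx = int(idx[twin]) if len(idx) > twin else seed_idx
                    twin_codes.append(pool.strains[alt_idx].copy())
                    replaced.append(True)
                else:
                    n_subs = rng.poisson(params.drift_rate * length * years)
                    twin_codes.append(_mutate(pool.strains[seed_idx], int(n_subs), rng))
                    replaced.append(False)
            label = TRUTH_REPLACED if any(replaced) else TRUTH_SHARED
            truth.append(
                TruthRecord(
                    pair_id=pid,
                    species_id=species_id,
                    truth_label=label,
                    n_divergent_positions=int((twin_codes[0] != twin_codes[1]).sum()),
                )
            )
            for twin, codes in zip((1, 2), twin_codes):
                species_profiles.append(
                    _observe(f"{pid}_T{twin}", species_id, codes, params, rng)
                )
        profiles[species_id] = species_profiles

    return SimulatedCohort(
        params=params, profiles=profiles, metadata=metadata, truth=truth, pools=pools
    )


def simulate_twin_cohort(
    params: SimulationParams, out_dir: str | Path
) -> SimulatedCohort:
    """Simulate a cohort and emit it as files under ``out_dir``.

    Writes one base-resolution multi-sample VCF per species
    (``<species_id>.vcf``), a sample metadata TSV, a truth TSV and the
    parameters as YAML. Output is byte-deterministic given ``params``.
    """
    cohort = simulate_cohort_profiles(params)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for species_id, species_profiles in cohort.profiles.items():
        ids = [p.sample_id for p in species_profiles]
        if len(set(ids)) != len(ids):
            raise ValueError(f"conflicting sample ids for {species_id}: {ids}")
        write_multisample_vcf(
            species_profiles,
            cohort.pools[species_id].reference_sequence,
            out_dir / f"{species_id}.vcf",
        )
    cohort.metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    cohort.truth_frame().to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    params.to_yaml(out_dir / "params.yaml")
    return cohort


@dataclass(frozen=True)
class ConfusionResult:
    """Classifier performance against simulator truth labels."""

    sensitivity: float
    specificity: float
    n_shared: int
    n_replaced: int
    n_indeterminate: int


def truth_confusion(classifications, truth: Sequence[TruthRecord]) -> ConfusionResult:
    """Sensitivity/specificity of relatedness calls against ground truth.

    Sensitivity: fraction of determinate truth shared-lineage pairs called
    related. Specificity: fraction of determinate truth replaced pairs
    called unrelated. Indeterminate calls are excluded from both and
    counted separately.
    """
    from .classification import CALL_INDETERMINATE, CALL_RELATED, CALL_UNRELATED

    truth_index = {(t.species_id, t.pair_id): t.truth_label for t in truth}
    calls = {(c.species_id, c.pair_id): c.call for c in classifications}
    shared_keys = set(truth_index) & set(calls)
    if not shared_keys:
        raise ValueError("no overlapping (species, pair) keys between calls and truth")
    tp = fn = tn = fp = indet = 0
    for key in shared_keys:
        call = calls[key]
        if call == CALL_INDETERMINATE:
            indet += 1
            continue
        if truth_index[key] == TRUTH_SHARED:
            if call == CALL_RELATED:
                tp += 1
            else:
                fn += 1
        else:
            if call == CALL_UNRELATED:
                tn += 1
            else:
                fp += 1
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return ConfusionResult(
        sensitivity=sens,
        specificity=spec,
        n_shared=tp + fn,
        n_replaced=tn + fp,
        n_indeterminate=indet,
    )
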