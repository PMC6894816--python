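"""Cohort-level aggregation: shared-strain fractions, separation-time groups,
one-way ANOVA with Tukey HSD, species-by-pair summary matrices, and
cross-method concordance.

Each twin pair contributes one observation per analysis: the fraction of the
configured strain universe called related for that pair. Fractions are
compared across separation-time groups (decade bins of years lived apart)
with a one-way ANOVA followed by Tukey's honestly-significant-difference
post hoc test (Tukey–Kramer form for unbalanced groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import (
    CALL_INDETERMINATE,
    CALL_RELATED,
    CALL_UNRELATED,
    PairClassification,
)

__all__ = [
    "SEPARATION_GROUPS",
    "TwinCohort",
    "CohortSummary",
    "RelatedFraction",
    "AnovaResult",
    "TukeyContrast",
    "ConcordanceTable",
    "related_fraction",
    "assign_separation_group",
    "one_way_anova",
    "tukey_hsd",
    "build_summary_matrix",
    "group_fractions",
    "concordance",
    "plot_group_fractions",
]

#: Ordered separation-interval labels: cohabiting pairs, then decade bins.
SEPARATION_GROUPS = (
    "no separation", "1-9", "10-19", "20-29", "30-39", "40-49", "50-59",
)


def assign_separation_group(separation_years: int) -> str:
    """Bin years lived apart into the ordered separation intervals.

    0 years means the pair never separated; 1–59 years fall into decade bins
    starting with 1–9.
    """
    years = int(separation_years)
    if years != separation_years:
        raise ValueError("separation_years must be an integer number of years")
    if years < 0 or years > 59:
        raise ValueError(f"separation_years {years} outside supported range [0, 59]")
    if years == 0:
        return SEPARATION_GROUPS[0]
    return SEPARATION_GROUPS[1 + years // 10]


@dataclass
class TwinCohort:
    """Sample metadata for a cohort of twin pairs.

    ``pairs`` has one row per twin pair with columns: pair_id, sample_a,
    sample_b, family_id, age_years, separation_years. Each pair belongs to
    exactly one separation group.
    """

    pairs: pd.DataFrame

    _REQUIRED = ("pair_id", "sample_a", "sample_b", "family_id",
                 "age_years", "separation_years")

    def __post_init__(self) -> None:
        missing = [c for c in self._REQUIRED if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if self.pairs["pair_id"].duplicated().any():
            dups = self.pairs.loc[self.pairs["pair_id"].duplicated(), "pair_id"]
            raise ValueError(f"duplicate pair ids: {sorted(set(dups))}")
        samples = pd.concat([self.pairs["sample_a"], self.pairs["sample_b"]])
        if samples.duplicated().any():
            raise ValueError("a sample id appears in more than one pair")
        self.pairs = self.pairs.reset_index(drop=True)

    @classmethod
    def from_sample_table(cls, samples: pd.DataFrame) -> "TwinCohort":
        """Build from a sample-level table (sample_id, pair_id, family_id,
        separation_years, age_years) with exactly two samples per pair."""
        rows = []
        for pair_id, grp in samples.groupby("pair_id", sort=True):
            if len(grp) != 2:
                raise ValueError(
                    f"pair {pair_id} has {len(grp)} samples; expected exactly 2"
                )
            grp = grp.sort_values("sample_id")
            rows.append(
                {
                    "pair_id": pair_id,
                    "sample_a": grp["sample_id"].iloc[0],
                    "sample_b": grp["sample_id"].iloc[1],
                    "family_id": grp["family_id"].iloc[0],
                    "age_years": grp["age_years"].iloc[0],
                    "separation_years": grp["separation_years"].iloc[0],
                }
            )
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TwinCohort":
        df = pd.read_csv(path, sep="\t")
        if "sample_id" in df.columns:
            return cls.from_sample_table(df)
        return cls(df)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.pairs["pair_id"])

    @property
    def groups(self) -> dict[str, str]:
        """pair_id → separation-interval label."""
        return {
            row.pair_id: assign_separation_group(row.separation_years)
            for row in self.pairs.itertuples()
        }

    def group_of(self, pair_id: str) -> str:
        return self.groups[pair_id]


@dataclass(frozen=True)
class RelatedFraction:
    """Shared-strain fraction for one twin pair.

    ``fraction`` is exact (n_related / n_total_strains); ``multiplier``
    is the per-strain reciprocal truncated to four decimals, matching how
    the multiplier is conventionally displayed (1/845 → 0.0011).
    """

    n_related: int
    n_total_strains: int
    fraction: float
    multiplier: float


def related_fraction(n_related: int, n_total_strains: int) -> RelatedFraction:
    """Fraction of the strain universe called related for one twin pair.

    The denominator is the configured total strain count of the analysis
    (not the per-pair number of determinate cells), so indeterminate calls
    do not inflate the fraction.
    """
    if n_total_strains < 1:
        raise ValueError("n_total_strains must be >= 1")
    if not 0 <= n_related <= n_total_strains:
        raise ValueError(
            f"n_related ({n_related}) must be in [0, n_total_strains ({n_total_strains})]"
        )
    # integer truncation to 4 decimals (exact; avoids float misrounding)
    multiplier = (10_000 // n_total_strains) / 10_000
    return RelatedFraction(
        n_related=n_related,
        n_total_strains=n_total_strains,
        fraction=n_related / n_total_strains,
        multiplier=multiplier,
    )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Fixed-effects one-way analysis of variance.

    F is the ratio of between-group to within-group mean squares; p is the
    upper tail of the F(k-1, N-k) distribution. When every value is
    identical (zero variance everywhere) F is undefined and reported as NaN.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group needs >= 1 value")
    n_total = sum(a.size for a in arrs)
    if n_total - k < 1:
        raise ValueError("need at least one group with >= 2 values")
    grand = sum(a.sum() for a in arrs) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(float("nan"), float("nan"), df_between, df_within)
        return AnovaResult(float("inf"), 0.0, df_between, df_within)
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(float(F), p, df_between, df_within)


@dataclass(frozen=True)
class TukeyContrast:
    contrast: str
    group_i: str
    group_j: str
    mean_diff: float
    adjusted_p: float


def tukey_hsd(
    groups: Sequence[Sequence[float]], names: Sequence[str] | None = None
) -> list[TukeyContrast]:
    """Tukey's HSD post hoc test over all unordered group pairs.

    Uses the studentized range distribution with the pooled within-group
    variance; unbalanced designs use the Tukey–Kramer standard error. With
    two groups the adjusted p collapses to the one-way ANOVA p.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group needs >= 1 value")
    if names is None:
        names = [f"g{i}" for i in range(k)]
    if len(names) != k:
        raise ValueError("names must match number of groups")
    n_total = sum(a.size for a in arrs)
    df_within = n_total - k
    if df_within < 1:
        raise ValueError("need at least one group with >= 2 values")
    ms_within = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_within
    out: list[TukeyContrast] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrs[j].mean() - arrs[i].mean())
            if ms_within == 0.0:
                adj_p = 1.0 if diff == 0.0 else 0.0
            else:
                se = np.sqrt(ms_within / 2.0 * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
                q = abs(diff) / se
                adj_p = float(stats.studentized_range.sf(q, k, df_within))
            out.append(
                TukeyContrast(
                    contrast=f"{names[j]}-{names[i]}",
                    group_i=str(names[i]),
                    group_j=str(names[j]),
                    mean_diff=diff,
                    adjusted_p=min(max(adj_p, 0.0), 1.0),
                )
            )
    return out


@dataclass
class CohortSummary:
    """Species × twin-pair classification matrix with per-pair fractions.

    Matrix cells are ``"R"`` (related), ``"U"`` (unrelated), ``"I"``
    (indeterminate, no score) or ``"I:<score>"`` (a score exists but the
    pair did not satisfy the comparison criteria).
    """

    matrix: pd.DataFrame
    n_related: pd.Series
    fractions: dict[str, RelatedFraction] = field(default_factory=dict)
    n_total_strains: int | None = None

    def fractions_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pair_id": pid,
                "n_related": rf.n_related,
                "n_total_strains": rf.n_total_strains,
                "fraction": rf.fraction,
                "multiplier": rf.multiplier,
            }
            for pid, rf in self.fractions.items()
        ]
        return pd.DataFrame(
            rows, columns=["pair_id", "n_related", "n_total_strains",
                           "fraction", "multiplier"]
        )


def _cell(c: PairClassification) -> str:
    if c.call == CALL_RELATED:
        return "R"
    if c.call == CALL_UNRELATED:
        return "U"
    if c.wss_score is not None:
        return f"I:{c.wss_score:.1f}"
    return "I"


def build_summary_matrix(
    classifications: Sequence[PairClassification],
    cohort: TwinCohort,
    n_total_strains: int | None = None,
) -> CohortSummary:
    """Assemble the species-by-pair summary matrix and per-pair fractions.

    ``n_total_strains`` is the fixed denominator of the shared-strain
    fraction (the total strain count of the analysis); when None it defaults
    to the number of species present in the classifications.
    """
    seen: set[tuple[str, str]] = set()
    for c in classifications:
        key = (c.species_id, c.pair_id)
        if key in seen:
            raise ValueError(f"duplicate classification for species/pair {key}")
        seen.add(key)

    species = sorted({c.species_id for c in classifications})
    pair_ids = [p for p in cohort.pair_ids
                if any(c.pair_id == p for c in classifications)]
    matrix = pd.DataFrame("I", index=species, columns=pair_ids, dtype=object)
    for c in classifications:
        if c.pair_id in matrix.columns:
            matrix.loc[c.species_id, c.pair_id] = _cell(c)

    n_related = (matrix == "R").sum(axis=0)
    n_related.name = "n_related"
    denom = n_total_strains if n_total_strains is not None else len(species)
    fractions = {
        pid: related_fraction(int(n_related[pid]), denom) for pid in pair_ids
    }
    return CohortSummary(
        matrix=matrix, n_related=n_related, fractions=fractions, n_total_strains=denom
    )


def group_fractions(
    summary: CohortSummary, cohort: TwinCohort
) -> dict[str, list[float]]:
    """Shared-strain fractions grouped by separation interval, in bin order."""
    groups = cohort.groups
    out: dict[str, list[float]] = {}
    for label in SEPARATION_GROUPS:
        vals = [
            summary.fractions[pid].fraction
            for pid in summary.fractions
            if groups.get(pid) == label
        ]
        if vals:
            out[label] = vals
    return out


@dataclass
class ConcordanceTable:
    """Agreement between two classification call sets on shared keys."""

    agree_related: int
    agree_unrelated: int
    disagree: int
    disagree_keys: list[tuple[str, str]]
    n_indeterminate: int

    @property
    def n_compared(self) -> int:
        return self.agree_related + self.agree_unrelated + self.disagree


def concordance(
    calls_a: Sequence[PairClassification], calls_b: Sequence[PairClassification]
) -> ConcordanceTable:
    """Tally agreement between two methods' calls, keyed by (species, pair).

    Keys where either method is indeterminate are counted separately; keys
    present in only one call set are ignored. A disjoint key set yields an
    empty table with a warning.
    """
    index_a = {(c.species_id, c.pair_id): c for c in calls_a}
    index_b = {(c.species_id, c.pair_id): c for c in calls_b}
    shared = sorted(set(index_a) & set(index_b))
    if not shared:
        warnings.warn("no overlapping (species, pair) keys between call sets")
        return ConcordanceTable(0, 0, 0, [], 0)
    agree_r = agree_u = disagree = indet = 0
    disagree_keys: list[tuple[str, str]] = []
    for key in shared:
        ca, cb = index_a[key].call, index_b[key].call
        if CALL_INDETERMINATE in (ca, cb):
            indet += 1
        elif ca == cb == CALL_RELATED:
            agree_r += 1
        elif ca == cb == CALL_UNRELATED:
            agree_u += 1
        else:
            disagree += 1
            disagree_keys.append(key)
    return ConcordanceTable(agree_r, agree_u, disagree, disagree_keys, indet)


def plot_group_fractions(
    fractions_by_group: Mapping[str, Sequence[float]], ax=None
):
    """Boxplot of shared-strain fractions per separation group (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    labels = [g for g in SEPARATION_GROUPS if g in fractions_by_group]
    data = [list(fractions_by_group[g]) for g in labels]
    ax.boxplot(data, tick_labels=labels, showmeans=True)
    ax.set_xlabel("separation interval (years)")
    ax.set_ylabel("fraction of related strains")
    ax.tick_params(axis="x", rotation=30)
    return ax
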