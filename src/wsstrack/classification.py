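"""Related / unrelated strain-pair calls against per-species WSS cut-offs.

A pair is *related* when its WSS score strictly exceeds the species cut-off,
*unrelated* when the score is defined but does not exceed it, and
*indeterminate* when the score is undefined (no usable window) or either
sample failed the sample-level QC filter. Cut-offs may be supplied
externally (e.g. values calibrated on an independent reference cohort) or
estimated empirically from the score distribution of truth-unrelated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .wss_core import PairComparison

__all__ = [
    "CutoffTable",
    "PairClassification",
    "MisclassificationRate",
    "classify_pair",
    "estimate_cutoffs",
    "misclassification_rate",
    "classification_table",
    "write_classification_table",
]

CALL_RELATED = "related"
CALL_UNRELATED = "unrelated"
CALL_INDETERMINATE = "indeterminate"


class CutoffTable:
    """Per-species WSS relatedness thresholds with explicit provenance.

    Provenance strings distinguish externally calibrated tables
    (``"external:..."``) from empirically estimated ones
    (``"empirical:<rule>"``).
    """

    def __init__(self, cutoffs: Mapping[str, float], provenance: str = "external") -> None:
        for sp, c in cutoffs.items():
            if not 0.0 <= c <= 100.0:
                raise ValueError(f"cutoff for {sp} must be in [0, 100], got {c}")
        self.cutoffs = dict(cutoffs)
        self.provenance = provenance

    def __getitem__(self, species_id: str) -> float:
        try:
            return self.cutoffs[species_id]
        except KeyError:
            raise KeyError(
                f"species {species_id!r} has no cut-off in this table "
                f"(provenance: {self.provenance})"
            ) from None

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.cutoffs

    def __iter__(self):
        return iter(self.cutoffs)

    def __len__(self) -> int:
        return len(self.cutoffs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": list(self.cutoffs),
                "cutoff": list(self.cutoffs.values()),
                "provenance": self.provenance,
            }
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CutoffTable":
        df = pd.read_csv(path, sep="\t")
        provenance = str(df["provenance"].iloc[0]) if "provenance" in df else "external"
        return cls(dict(zip(df["species_id"], df["cutoff"].astype(float))), provenance)


@dataclass(frozen=True)
class PairClassification:
    """Relatedness call for one twin (or sample) pair on one species."""

    species_id: str
    pair_id: str
    sample_a: str
    sample_b: str
    wss_score: float | None
    cutoff: float
    call: str

    def __post_init__(self) -> None:
        if self.call not in (CALL_RELATED, CALL_UNRELATED, CALL_INDETERMINATE):
            raise ValueError(f"unknown call {self.call!r}")


def classify_pair(
    comparison: PairComparison,
    cutoffs: CutoffTable,
    pair_id: str | None = None,
    sample_a_passes: bool = True,
    sample_b_passes: bool = True,
) -> PairClassification:
    """Call a pair related/unrelated/indeterminate against its species cut-off.

    Related requires score strictly above the cut-off; a score exactly at
    the cut-off is unrelated. Pairs with an undefined score, or where either
    sample failed the sample QC filter, are indeterminate.
    """
    cutoff = cutoffs[comparison.species_id]
    score = comparison.wss_score
    if score is None or not (sample_a_passes and sample_b_passes):
        call = CALL_INDETERMINATE
    elif score > cutoff:
        call = CALL_RELATED
    else:
        call = CALL_UNRELATED
    return PairClassification(
        species_id=comparison.species_id,
        pair_id=pair_id if pair_id is not None
        else f"{comparison.sample_a}|{comparison.sample_b}",
        sample_a=comparison.sample_a,
        sample_b=comparison.sample_b,
        wss_score=score,
        cutoff=cutoff,
        call=call,
    )


_RULES = ("max", "quantile", "mean_plus_k_sd")


def estimate_cutoffs(
    unrelated_scores: Mapping[str, Sequence[float]],
    rule: str = "max",
    q: float = 0.99,
    k: float = 3.0,
) -> CutoffTable:
    """Estimate per-species cut-offs from truth-unrelated pair scores.

    Rules
    -----
    ``max``
        The maximum unrelated score — the most conservative threshold
        against false relatedness calls (default).
    ``quantile``
        The ``q`` quantile of the unrelated scores.
    ``mean_plus_k_sd``
        Mean plus ``k`` sample standard deviations (``k=0`` is the mean).

    Cut-offs are clipped into [0, 100].
    """
    if rule not in _RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {_RULES}")
    cutoffs: dict[str, float] = {}
    for sp, scores in unrelated_scores.items():
        arr = np.asarray([s for s in scores if s is not None], dtype=float)
        if arr.size == 0:
            raise ValueError(f"no unrelated scores for species {sp}")
        if arr.size < 2:
            raise ValueError(
                f"species {sp}: need >= 2 unrelated scores to estimate a cut-off"
            )
        if rule == "max":
            c = float(arr.max())
        elif rule == "quantile":
            c = float(np.quantile(arr, q))
        else:
            sd = float(arr.std(ddof=1))
            c = float(arr.mean()) + k * sd
        cutoffs[sp] = float(np.clip(c, 0.0, 100.0))
    params = {"max": "max", "quantile": f"quantile(q={q})",
              "mean_plus_k_sd": f"mean_plus_k_sd(k={k})"}[rule]
    return CutoffTable(cutoffs, provenance=f"empirical:{params}")


@dataclass(frozen=True)
class MisclassificationRate:
    """Fraction of truth-unrelated pairs scoring above the cut-off.

    ``rate_percent`` is truncated (not rounded) to two decimal places, so
    2 of 1544 pairs reports as 0.12%.
    """

    n_exceed: int
    n_total: int
    rate_percent: float


def misclassification_rate(
    scores: Iterable[float], cutoff: float
) -> MisclassificationRate:
    """Rate at which truth-unrelated pairs would be called related.

    ``scores`` are WSS scores of pairs known to come from different
    individuals (the all-vs-all design); undefined scores must be excluded
    by the caller before counting.
    """
    vals = [float(s) for s in scores]
    n_total = len(vals)
    if n_total == 0:
        raise ValueError("no unrelated scores supplied")
    n_exceed = sum(1 for s in vals if s > cutoff)
    # integer truncation to 2 decimals: exact, no float misrounding
    rate = (10_000 * n_exceed // n_total) / 100.0
    return MisclassificationRate(n_exceed=n_exceed, n_total=n_total, rate_percent=rate)


def classification_table(classifications: Sequence[PairClassification]) -> pd.DataFrame:
    rows = [
        {
            "species_id": c.species_id,
            "pair_id": c.pair_id,
            "sample_a": c.sample_a,
            "sample_b": c.sample_b,
            "wss_score": c.wss_score,
            "cutoff": c.cutoff,
            "call": c.call,
        }
        for c in classifications
    ]
    return pd.DataFrame(
        rows,
        columns=["species_id", "pair_id", "sample_a", "sample_b",
                 "wss_score", "cutoff", "call"],
    )


def write_classification_table(
    classifications: Sequence[PairClassification], path: str | Path
) -> Path:
    path = Path(path)
    classification_table(classifications).to_csv(path, sep="\t", index=False, na_rep="NA")
    return path
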