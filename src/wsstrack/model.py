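"""Cohort-level strain-sharing analysis as a model / results pair.

:class:`StrainSharingModel` bundles the inputs of the analysis — per-species
sample profiles, the twin-pair metadata, the WSS configuration and
(optionally) an external cut-off table — and :meth:`StrainSharingModel.fit`
runs the whole pipeline: sample QC, pairwise WSS scoring, cut-off
estimation from cross-pair (truth-unrelated) comparisons when no table is
given, relatedness classification, the species-by-pair summary matrix with
shared-strain fractions, and the separation-group ANOVA + Tukey HSD. The
returned :class:`StrainSharingResults` carries every intermediate table and
prints a compact summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .classification import (
    CutoffTable,
    MisclassificationRate,
    PairClassification,
    classification_table,
    classify_pair,
    estimate_cutoffs,
    misclassification_rate,
)
from .cohort_stats import (
    AnovaResult,
    CohortSummary,
    TukeyContrast,
    TwinCohort,
    build_summary_matrix,
    group_fractions,
    one_way_anova,
    tukey_hsd,
)
from .config import DEFAULT_CONFIG, WssConfig
from .synthetic_cohort import (
    ConfusionResult,
    SimulatedCohort,
    SimulationParams,
    TruthRecord,
    simulate_cohort_profiles,
)
from .synthetic_cohort import truth_confusion as _truth_confusion
from .variant_io import (
    SampleProfile,
    read_multisample_vcf,
    sample_metrics_table,
)
from .wss_core import PairComparison, pair_table, partition_windows, wss_score

__all__ = ["StrainSharingModel", "StrainSharingResults"]


class StrainSharingModel:
    """Strain-sharing analysis of a twin cohort from base-resolution calls.

    Parameters
    ----------
    profiles : mapping species_id -> sequence of SampleProfile
        Per-species per-sample base-resolution call profiles.
    cohort : TwinCohort
        Twin-pair metadata (pair membership, separation years).
    cutoffs : CutoffTable, optional
        External per-species cut-offs. When omitted, cut-offs are estimated
        at fit time from all cross-pair (different-individual) comparisons.
    config : WssConfig
        Window geometry, window usability and sample QC thresholds.
    n_total_strains : int, optional
        Fixed denominator of the shared-strain fraction; defaults to the
        number of species supplied.
    """

    def __init__(
        self,
        profiles: Mapping[str, Sequence[SampleProfile]],
        cohort: TwinCohort,
        cutoffs: CutoffTable | None = None,
        config: WssConfig = DEFAULT_CONFIG,
        n_total_strains: int | None = None,
    ) -> None:
        if not profiles:
            raise ValueError("no species profiles supplied")
        self.profiles = {sp: list(ps) for sp, ps in profiles.items()}
        self.cohort = cohort
        self.cutoffs = cutoffs
        self.config = config
        self.n_total_strains = (
            n_total_strains if n_total_strains is not None else len(self.profiles)
        )

    @classmethod
    def from_vcf(
        cls,
        vcf_paths: Mapping[str, str | Path],
        reference_lengths: Mapping[str, int],
        cohort: TwinCohort,
        **kwargs,
    ) -> "StrainSharingModel":
        """Build from one multi-sample VCF per species."""
        profiles = {
            sp: read_multisample_vcf(path, sp, reference_lengths[sp])
            for sp, path in vcf_paths.items()
        }
        return cls(profiles, cohort, **kwargs)

    @classmethod
    def from_simulation(
        cls, params: SimulationParams, **kwargs
    ) -> tuple["StrainSharingModel", SimulatedCohort]:
        """Build from a synthetic cohort; returns (model, simulated cohort)."""
        sim = simulate_cohort_profiles(params)
        cohort = TwinCohort.from_sample_table(sim.metadata)
        model = cls(sim.profiles, cohort, **kwargs)
        return model, sim

    def fit(self, cutoff_rule: str = "max") -> "StrainSharingResults":
        """Run the full analysis and return a results object.

        When no external cut-off table was supplied, per-species cut-offs
        are estimated from the WSS scores of all cross-pair comparisons
        (samples from different twin pairs, i.e. truth-unrelated
        individuals) using ``cutoff_rule``.
        """
        cfg = self.config
        pair_of = {}
        for row in self.cohort.pairs.itertuples():
            pair_of[row.sample_a] = (row.pair_id, "a")
            pair_of[row.sample_b] = (row.pair_id, "b")

        metrics_frames = []
        within: list[tuple[PairComparison, str, bool, bool]] = []
        cross: dict[str, list[PairComparison]] = {}
        for sp, profs in self.profiles.items():
            metrics = sample_metrics_table(profs, cfg)
            metrics_frames.append(metrics)
            passes = dict(zip(metrics["sample_id"], metrics["pass_filter"]))
            spec = partition_windows(
                profs[0].reference_length, cfg.window_length, species_id=sp
            )
            by_id = {p.sample_id: p for p in profs}
            ids = sorted(by_id)
            cross[sp] = []
            for i, sa in enumerate(ids):
                for sb in ids[i + 1:]:
                    pa = pair_of.get(sa, (None, None))[0]
                    pb = pair_of.get(sb, (None, None))[0]
                    same_pair = pa is not None and pa == pb
                    comp = wss_score(by_id[sa], by_id[sb], spec, cfg)
                    if same_pair:
                        within.append((comp, pa, bool(passes[sa]), bool(passes[sb])))
                    else:
                        # different individuals: truth-unrelated comparison
                        if passes[sa] and passes[sb]:
                            cross[sp].append(comp)

        cutoffs = self.cutoffs
        if cutoffs is None:
            unrelated_scores = {
                sp: [c.wss_score for c in comps if c.wss_score is not None]
                for sp, comps in cross.items()
            }
            cutoffs = estimate_cutoffs(unrelated_scores, rule=cutoff_rule)

        classifications = [
            classify_pair(comp, cutoffs, pair_id=pid,
                          sample_a_passes=pa, sample_b_passes=pb)
            for comp, pid, pa, pb in within
        ]

        cohort_summary = build_summary_matrix(
            classifications, self.cohort, n_total_strains=self.n_total_strains
        )
        fractions_by_group = group_fractions(cohort_summary, self.cohort)

        anova: AnovaResult | None = None
        tukey: list[TukeyContrast] = []
        groups = [g for g in fractions_by_group.values()]
        names = list(fractions_by_group)
        n_values = sum(len(g) for g in groups)
        if len(groups) >= 2 and n_values - len(groups) >= 1:
            anova = one_way_anova(groups)
            tukey = tukey_hsd(groups, names=names)

        misclass = {
            sp: misclassification_rate(
                [c.wss_score for c in comps if c.wss_score is not None], cutoffs[sp]
            )
            for sp, comps in cross.items()
            if any(c.wss_score is not None for c in comps)
        }

        return StrainSharingResults(
            model=self,
            sample_metrics=pd.concat(metrics_frames, ignore_index=True),
            comparisons=[w[0] for w in within],
            unrelated_comparisons=cross,
            cutoffs=cutoffs,
            classifications=classifications,
            cohort_summary=cohort_summary,
            fractions_by_group=fractions_by_group,
            anova=anova,
            tukey=tukey,
            misclassification=misclass,
        )


@dataclass
class StrainSharingResults:
    """Fitted strain-sharing analysis: tables, calls and group statistics."""

    model: StrainSharingModel
    sample_metrics: pd.DataFrame
    comparisons: list[PairComparison]
    unrelated_comparisons: dict[str, list[PairComparison]]
    cutoffs: CutoffTable
    classifications: list[PairClassification]
    cohort_summary: CohortSummary
    fractions_by_group: dict[str, list[float]]
    anova: AnovaResult | None
    tukey: list[TukeyContrast] = field(default_factory=list)
    misclassification: dict[str, MisclassificationRate] = field(default_factory=dict)

    def classification_frame(self) -> pd.DataFrame:
        return classification_table(self.classifications)

    def comparison_frame(self) -> pd.DataFrame:
        return pair_table(self.comparisons)

    def truth_confusion(self, truth: Sequence[TruthRecord]) -> ConfusionResult:
        """Sensitivity/specificity of the fitted calls against simulator truth."""
        return _truth_confusion(self.classifications, truth)

    def plot_group_fractions(self, ax=None):
        from .cohort_stats import plot_group_fractions

        return plot_group_fractions(self.fractions_by_group, ax=ax)

    def to_tsvs(self, out_dir: str | Path) -> Path:
        """Write all result tables (metrics, comparisons, cut-offs,
        classifications, matrix, fractions, group stats) to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sample_metrics.to_csv(out / "sample_metrics.tsv", sep="\t", index=False)
        self.comparison_frame().to_csv(
            out / "pair_comparisons.tsv", sep="\t", index=False, na_rep="NA"
        )
        self.cutoffs.to_tsv(out / "cutoffs.tsv")
        self.classification_frame().to_csv(
            out / "classifications.tsv", sep="\t", index=False, na_rep="NA"
        )
        self.cohort_summary.matrix.to_csv(out / "summary_matrix.tsv", sep="\t")
        self.cohort_summary.fractions_frame().to_csv(
            out / "fractions.tsv", sep="\t", index=False
        )
        if self.tukey:
            pd.DataFrame(
                [
                    {
                        "contrast": t.contrast,
                        "mean_diff": t.mean_diff,
                        "adjusted_p": t.adjusted_p,
                    }
                    for t in self.tukey
                ]
            ).to_csv(out / "group_stats.tsv", sep="\t", index=False)
        return out

    def summary_text(self) -> str:
        return self.summary_str()

    def summary_str(self) -> str:
        lines: list[str] = []
        n_samples = self.sample_metrics["sample_id"].nunique()
        n_pass = int(self.sample_metrics["pass_filter"].sum())
        lines.append("Strain-sharing analysis (window-based SNV similarity)")
        lines.append("=" * 56)
        lines.append(
            f"species: {len(self.model.profiles)}   twin pairs: "
            f"{len(self.model.cohort.pairs)}   sample records: "
            f"{len(self.sample_metrics)} ({n_pass} pass QC; {n_samples} unique ids)"
        )
        lines.append(
            f"cut-offs: {self.cutoffs.provenance}   "
            f"fraction denominator: {self.cohort_summary.n_total_strains}"
        )
        calls = self.classification_frame()["call"].value_counts()
        lines.append(
            "calls: "
            + ", ".join(f"{k}={int(v)}" for k, v in calls.items())
        )
        lines.append("")
        lines.append("Shared-strain fraction by separation interval:")
        for label, vals in self.fractions_by_group.items():
            mean = sum(vals) / len(vals)
            lines.append(f"  {label:>13}: n={len(vals):2d}  mean fraction={mean:.4f}")
        if self.anova is not None:
            lines.append("")
            lines.append(
                f"one-way ANOVA: F({self.anova.df_between}, {self.anova.df_within}) "
                f"= {self.anova.F:.4g}, p = {self.anova.p:.4g}"
            )
            sig = [t for t in self.tukey if t.adjusted_p < 0.05]
            lines.append(
                f"Tukey HSD: {len(self.tukey)} contrasts, "
                f"{len(sig)} with adjusted p < 0.05"
            )
        return "\n".join(lines)

    # statsmodels-style alias
    def summary(self) -> str:
        """Human-readable summary of the fitted analysis."""
        return self.summary_str()
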