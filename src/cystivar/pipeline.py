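"""End-to-end analysis: variant table + patient table -> report directory.

Stages: per-mutation severity calls for the chosen predictor, per-patient
scores under the gene's inheritance model, severity-group phenotype
comparisons, and the disease-vs-population variant contrasts.  All table
outputs are deterministic given the inputs and configuration; rerunning
with identical inputs produces byte-identical TSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .cohort_analysis import (
    PHENOTYPE_COLUMNS,
    comparisons_to_frame,
    compare_groups,
    group_patients,
    summarize_groups,
)
from .patient_scoring import PatientGenotype, score_cohort
from .severity import (
    DEFAULT_METHOD_SPECS,
    Method,
    MethodSpec,
    SeverityCall,
    classify_mutation_severity,
    severity_for_consequence,
)
from .tables import (
    RunManifest,
    read_patient_table,
    read_variant_table,
    write_tsv,
)
from .variant_contrast import ContrastAttribute, contrast_all
from .variant_core import Consequence, Variant

__all__ = ["call_severities", "run_pipeline"]

logger = logging.getLogger(__name__)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: List[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(self.format(record))


def call_severities(
    variants: Sequence[Variant],
    method: Method,
    spec: Optional[MethodSpec] = None,
) -> Dict[str, SeverityCall]:
    """Severity call for every variant, keyed by HGVS p. string.

    Missense variants without a score for `method` are omitted from the
    result (downstream stages report them if the cohort needs them).
    """
    spec = spec or DEFAULT_METHOD_SPECS[method]
    calls: Dict[str, SeverityCall] = {}
    for v in variants:
        key = v.hgvs_p
        if v.mutation.consequence is not Consequence.MISSENSE:
            calls[key] = severity_for_consequence(v.mutation.consequence)
        elif method.value in v.predictor_scores:
            calls[key] = classify_mutation_severity(
                v.predictor_scores[method.value], spec, v.mutation
            )
    return calls


def _check_cohort_calls(
    cohort: Sequence[PatientGenotype], calls: Dict[str, SeverityCall], method: Method
) -> None:
    missing = sorted({
        str(m) for p in cohort for m in p.all_mutations() if str(m) not in calls
    })
    if missing:
        raise ValueError(
            f"severity stage: no {method.value} score for cohort mutation(s): "
            f"{', '.join(missing)}"
        )


def run_pipeline(
    variants_path,
    patients_path,
    method: Method,
    out_dir,
    spec: Optional[MethodSpec] = None,
    min_group_n: int = 2,
    family_size: Optional[int] = None,
    plots: bool = False,
    seed: Optional[int] = None,
) -> Path:
    """Run the full analysis and write the report directory.

    Outputs: severity_calls.tsv, patient_scores.tsv, group_summary.tsv,
    comparisons.tsv, contrast.tsv (+ contrast_histograms.tsv), optional
    figures, and a manifest.json recording inputs, configuration and any
    warnings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    method = Method(method)
    spec = spec or DEFAULT_METHOD_SPECS[method]

    collector = _WarningCollector()
    root = logging.getLogger("cystivar")
    root.addHandler(collector)
    try:
        manifest = RunManifest.start(
            version=__version__,
            input_paths=[variants_path, patients_path],
            config={
                "method": method.value,
                "severe_threshold": spec.severe_threshold,
                "boundary_rule": spec.boundary_rule.value,
                "min_group_n": min_group_n,
                "family_size": family_size,
                "dispersion": "sd",
            },
            seed=seed,
        )

        variants = read_variant_table(variants_path)
        cohort, phenotypes = read_patient_table(patients_path)

        calls = call_severities(variants, method, spec)
        _check_cohort_calls(cohort, calls, method)
        calls_df = pd.DataFrame(
            [
                {
                    "hgvs_p": key,
                    "method": method.value if call.method else "",
                    "score": call.score,
                    "severity": call.severity,
                    "reason": call.reason.value,
                }
                for key, call in sorted(calls.items())
            ]
        )
        write_tsv(calls_df, out / "severity_calls.tsv")

        scores = score_cohort(cohort, calls)
        scores_df = pd.DataFrame(
            [
                {"patient_id": s.patient_id, "gene": s.gene.value,
                 "score": s.score, "model": s.model.value}
                for s in scores
            ]
        ).sort_values("patient_id", ignore_index=True)
        write_tsv(scores_df, out / "patient_scores.tsv")

        # per-gene grouping and comparison (the two inheritance models have
        # incommensurate score ranges)
        summary_frames = []
        comparison_frames = []
        for gene in sorted({s.gene for s in scores}, key=lambda g: g.value):
            gene_scores = [s for s in scores if s.gene == gene]
            groups = group_patients(gene_scores, min_n=min_group_n)
            summary = summarize_groups(groups, phenotypes)
            summary.insert(0, "gene", gene.value)
            summary_frames.append(summary)
            comparisons = compare_groups(
                groups, phenotypes, min_n=min_group_n, family_size=family_size
            )
            frame = comparisons_to_frame(comparisons)
            frame.insert(0, "gene", gene.value)
            comparison_frames.append(frame)
        write_tsv(pd.concat(summary_frames, ignore_index=True),
                  out / "group_summary.tsv")
        write_tsv(pd.concat(comparison_frames, ignore_index=True),
                  out / "comparisons.tsv")

        disease = [v for v in variants if v.disease_associated]
        population = [v for v in variants if not v.disease_associated]
        if disease and population:
            reports = contrast_all(disease, population)
            contrast_df = pd.DataFrame([
                {
                    "attribute": r.attribute.value,
                    "n_disease": r.n_disease,
                    "n_population": r.n_population,
                    "median_disease": r.median_disease,
                    "median_population": r.median_population,
                    "rank_sum": r.test.statistic,
                    "p_raw": r.test.p_two_sided,
                    "p_adjusted": r.adjusted_p,
                }
                for r in reports
            ])
            write_tsv(contrast_df, out / "contrast.tsv")
            hist_rows = []
            for r in reports:
                for label, nd, np_ in zip(
                    r.bin_labels, r.hist_disease, r.hist_population
                ):
                    hist_rows.append({
                        "attribute": r.attribute.value, "bin": label,
                        "disease": nd, "population": np_,
                    })
            write_tsv(pd.DataFrame(hist_rows), out / "contrast_histograms.tsv")
        else:
            logger.warning(
                "variant table lacks a disease or population set; "
                "contrast stage skipped"
            )
            reports = []

        if plots:
            _write_plots(out, scores_df, phenotypes, reports)

        manifest.warnings = list(collector.messages)
        manifest.finish(out)
    finally:
        root.removeHandler(collector)
    return out


def _write_plots(out: Path, scores_df: pd.DataFrame,
                 phenotypes: pd.DataFrame, reports) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    merged = scores_df.merge(phenotypes, left_on="patient_id", right_index=True)
    for gene, sub in merged.groupby("gene"):
        fig, axes = plt.subplots(2, 4, figsize=(16, 7))
        for ax, col in zip(axes.ravel(), PHENOTYPE_COLUMNS):
            stats = sub.groupby("score")[col].agg(["mean", "std", "count"])
            ax.bar(stats.index.astype(str), stats["mean"], yerr=stats["std"],
                   capsize=3)
            ax.set_title(col, fontsize=9)
            ax.set_xlabel("severity group")
        axes.ravel()[-1].axis("off")
        fig.suptitle(f"{gene}: phenotype by severity group (mean ± SD)")
        fig.tight_layout()
        fig.savefig(fig_dir / f"phenotypes_{gene}.png", dpi=120)
        plt.close(fig)
    for r in reports:
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4), sharey=False)
        x = range(len(r.bin_labels))
        ax1.bar(x, r.hist_disease)
        ax1.set_title(f"disease (n={r.n_disease})", fontsize=9)
        ax2.bar(x, r.hist_population)
        ax2.set_title(f"population (n={r.n_population})", fontsize=9)
        for ax in (ax1, ax2):
            ax.set_xticks(list(x))
            ax.set_xticklabels(r.bin_labels, rotation=45, fontsize=7)
        fig.suptitle(r.attribute.value)
        fig.tight_layout()
        fig.savefig(fig_dir / f"contrast_{r.attribute.value}.png", dpi=120)
        plt.close(fig)
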