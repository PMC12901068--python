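"""End-to-end orchestration: nodal series -> RSS -> extrema -> group ANCOVA.

Per subject and per magnitude criterion, the pipeline z-scores the nodal
series, computes the RSS co-fluctuation trace (whole-brain or within a node
subset), extracts troughs/peaks and summarizes them; it then fits one ANCOVA
per outcome per criterion across the cohort. Subjects with too few troughs
under a strict criterion are excluded from that fit with a logged count, and
every run writes a manifest with analyzed + excluded = total.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .edges import compute_rss, zscore_nodes
from .extrema import TroughCriterion, summarize_subject
from .io import PipelineConfig, read_cohort_table, read_nodal_tsv, read_node_subset
from .stats import ancova_group_effect

__all__ = ["cohort_outcome_table", "summarize_subjects", "run_pipeline"]

logger = logging.getLogger("edgedyn")

OUTCOMES = ("mean_trough_duration_seconds", "mean_peak_height")


def summarize_subjects(
    subjects, criteria, node_subset=None, label: str | None = None
) -> pd.DataFrame:
    """Per-subject extrema summaries for every criterion.

    ``subjects`` is an iterable of objects with ``subject_id`` and ``series``
    (simulated subjects qualify directly).
    """
    rows = []
    for subj in subjects:
        z = zscore_nodes(subj.series)
        rss = compute_rss(z, node_subset=node_subset, label=label)
        for crit in criteria:
            s = summarize_subject(rss, crit, subj.subject_id, label=rss.label)
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "label": s.label,
                    "theta": crit.theta,
                    "mode": crit.mode,
                    "n_troughs": s.n_troughs,
                    "n_peaks": s.n_peaks,
                    "mean_trough_duration_seconds": s.mean_trough_duration_seconds,
                    "mean_peak_height": s.mean_peak_height,
                    "insufficient_troughs": s.insufficient_troughs,
                }
            )
    return pd.DataFrame(rows)


def cohort_outcome_table(
    subjects,
    covariates: pd.DataFrame,
    criterion: TroughCriterion,
    outcome: str = "mean_trough_duration_seconds",
    node_subset=None,
) -> pd.DataFrame:
    """Join per-subject summaries under one criterion with covariates, ready
    for ``ancova_group_effect`` (the chosen summary becomes ``outcome``)."""
    summaries = summarize_subjects(subjects, [criterion], node_subset=node_subset)
    merged = summaries.merge(covariates, on="subject_id", validate="one_to_one")
    merged = merged[~merged["insufficient_troughs"]]
    merged = merged.rename(columns={outcome: "outcome"})
    return merged[["subject_id", "group", "age_years", "brain_volume_ml", "outcome"]]


class _DiskSubject:
    """Lazy handle pairing a cohort-table row with its on-disk series."""

    def __init__(self, subject_id: str, series):
        self.subject_id = subject_id
        self.series = series


def run_pipeline(config: PipelineConfig, cohort_dir) -> pd.DataFrame:
    """Run the full analysis over an on-disk cohort directory.

    Expects ``cohort.csv`` (with series_path) inside ``cohort_dir``. Writes
    per-subject summaries, one ANCOVA row per (outcome x theta), and a
    manifest of subject counts and failures to ``config.output_dir``.
    Deterministic given identical inputs and configuration.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    cohort_dir = Path(cohort_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    covariates = read_cohort_table(cohort_dir / "cohort.csv")
    subset = read_node_subset(config.subset_path) if config.subset_path else None
    criteria = [TroughCriterion(theta, config.mode) for theta in config.theta_list]

    subjects = []
    failures = []
    for row in covariates.itertuples():
        try:
            series = read_nodal_tsv(cohort_dir / row.series_path, config.tr_seconds)
            subjects.append(_DiskSubject(row.subject_id, series))
        except Exception as exc:  # failed subjects are reported, not fatal
            logger.warning("subject %s failed to load: %s", row.subject_id, exc)
            failures.append({"subject_id": row.subject_id, "error": str(exc)})

    summaries = summarize_subjects(subjects, criteria, node_subset=subset)
    summaries.to_csv(out_dir / "subject_summaries.csv", index=False)

    results = []
    exclusions = {}
    for crit in criteria:
        mask = (summaries["theta"] == crit.theta) & (summaries["mode"] == crit.mode)
        block = summaries[mask].merge(covariates, on="subject_id", validate="one_to_one")
        usable = block[~block["insufficient_troughs"]]
        n_excluded = int(block["insufficient_troughs"].sum())
        exclusions[f"theta={crit.theta}"] = n_excluded
        if n_excluded:
            logger.warning(
                "theta=%g: excluded %d subject(s) with fewer than 2 troughs",
                crit.theta,
                n_excluded,
            )
        for outcome in OUTCOMES:
            table = usable.rename(columns={outcome: "outcome"})[
                ["subject_id", "group", "age_years", "brain_volume_ml", "outcome"]
            ].dropna(subset=["outcome"])
            try:
                fit = ancova_group_effect(table)
            except ValueError as exc:
                logger.warning("ANCOVA skipped for %s theta=%g: %s", outcome, crit.theta, exc)
                continue
            g0, g1 = fit.group_levels
            results.append(
                {
                    "outcome": outcome,
                    "theta": crit.theta,
                    "mode": crit.mode,
                    "n": fit.n,
                    "F": fit.f_statistic,
                    "df1": fit.df_numerator,
                    "df2": fit.df_denominator,
                    "p": fit.p_value,
                    f"adj_mean_{g0}": fit.adjusted_means[g0][0],
                    f"se_{g0}": fit.adjusted_means[g0][1],
                    f"adj_mean_{g1}": fit.adjusted_means[g1][0],
                    f"se_{g1}": fit.adjusted_means[g1][1],
                }
            )
    results_df = pd.DataFrame(results)
    results_df.to_csv(out_dir / "results.csv", index=False)

    manifest = {
        "total_subjects": int(len(covariates)),
        "loaded_subjects": len(subjects),
        "load_failures": failures,
        "excluded_by_criterion": exclusions,
        "thetas": list(config.theta_list),
        "mode": config.mode,
        "tr_seconds": config.tr_seconds,
        "node_subset_size": len(subset) if subset else None,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info(
        "pipeline complete: %d/%d subjects analyzed, results in %s",
        len(subjects),
        len(covariates),
        out_dir,
    )
    return results_df
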