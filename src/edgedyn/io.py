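"""File formats and configuration.

All tabular formats are plain text. Nodal series files are TSV/CSV with a
header row of node labels and one row per timepoint (delimiter auto-detected
between tab and comma). Node subsets are plain text, one label per line.
Cohort tables are CSV with subject_id, group, age_years, brain_volume_ml and,
when the series live on disk, a series_path column.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .edges import NodalTimeSeries, RssSeries

__all__ = [
    "PipelineConfig",
    "read_nodal_tsv",
    "write_nodal_tsv",
    "read_node_subset",
    "write_rss_tsv",
    "read_cohort_table",
    "write_cohort",
    "concatenate_runs",
    "load_config",
]

DEFAULT_TR_SECONDS = 0.72  # sub-second repetition time typical of multiband acquisitions


@dataclasses.dataclass
class PipelineConfig:
    tr_seconds: float = DEFAULT_TR_SECONDS
    theta_list: tuple = (0.0, 0.01, 0.02, 0.05)
    mode: str = "adjacent-sample"
    subset_path: str | None = None
    seed: int = 0
    output_dir: str = "edgedyn-out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.theta_list = tuple(float(t) for t in self.theta_list)
        for t in self.theta_list:
            if not 0 <= t < 0.5:
                raise ValueError(f"theta values must lie in [0, 0.5), got {t}")


def load_config(path) -> PipelineConfig:
    """Read a YAML or JSON pipeline configuration file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**data)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_nodal_tsv(path, tr_seconds: float = DEFAULT_TR_SECONDS) -> NodalTimeSeries:
    """Read a nodal time-series file (header = node labels, rows = timepoints).

    Errors on ragged rows, non-numeric cells and duplicate labels carry the
    offending line number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        labels = [c.strip() for c in first.rstrip("\n").split(delim)]
        if len(set(labels)) != len(labels):
            dup = next(l for l in labels if labels.count(l) > 1)
            raise ValueError(f"{path}:1: duplicate node label {dup!r}")
        rows = []
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not row:
                continue
            if len(row) != len(labels):
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(row)} cells, expected {len(labels)})"
                )
            rows.append(row)
    try:
        values = np.asarray(rows, dtype=float)
    except ValueError:
        for lineno, row in enumerate(rows, start=2):
            for cell in row:
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-numeric cell {cell!r}") from None
        raise
    return NodalTimeSeries(values, tr_seconds, tuple(labels))


def write_nodal_tsv(series: NodalTimeSeries, path) -> None:
    """Write a nodal series as TSV with full float precision (round-trip safe)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(series.node_labels) + "\n")
        for row in series.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_node_subset(path) -> list[str]:
    """Plain-text node subset: one label per line, blank lines ignored."""
    labels = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not labels:
        raise ValueError(f"{path}: empty node subset")
    return labels


def write_rss_tsv(rss: RssSeries, path) -> None:
    """Two-column TSV: time_seconds, rss."""
    with Path(path).open("w") as fh:
        fh.write("time_seconds\trss\n")
        for t, v in zip(rss.times_seconds, rss.values):
            fh.write(f"{float(t)!r}\t{float(v)!r}\n")


def read_rss_tsv(path, label: str = "whole-brain") -> RssSeries:
    df = pd.read_csv(path, sep="\t")
    times = df["time_seconds"].to_numpy(float)
    tr = float(times[1] - times[0]) if len(times) > 1 else DEFAULT_TR_SECONDS
    values = df["rss"].to_numpy(float)
    n_edges = 0  # unknown when loaded from disk
    return RssSeries(values=values, tr_seconds=tr, n_edges=n_edges, label=label)


def read_cohort_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"subject_id", "group", "age_years", "brain_volume_ml"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: cohort table missing column(s) {sorted(missing)}")
    return table


def write_cohort(subjects, table: pd.DataFrame, out_dir, spec=None) -> Path:
    """Write a simulated cohort: one series TSV per subject, cohort.csv with
    series paths, and the generating settings as spec.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_dir = out_dir / "series"
    series_dir.mkdir(exist_ok=True)
    paths = []
    for subj in subjects:
        p = series_dir / f"{subj.subject_id}.tsv"
        write_nodal_tsv(subj.series, p)
        paths.append(str(p.relative_to(out_dir)))
    table = table.copy()
    table["series_path"] = paths
    table.to_csv(out_dir / "cohort.csv", index=False)
    if spec is not None:
        payload = {
            f.name: getattr(spec, f.name)
            for f in dataclasses.fields(spec)
            if f.name != "state_covariances"
        }
        (out_dir / "spec.json").write_text(json.dumps(payload, indent=2, default=str))
    return out_dir / "cohort.csv"


def concatenate_runs(runs: list[NodalTimeSeries]) -> NodalTimeSeries:
    """Row-wise concatenation of scan runs, in order, before any z-scoring.

    All runs must share node labels and TR.
    """
    if not runs:
        raise ValueError("no runs to concatenate")
    first = runs[0]
    for k, run in enumerate(runs[1:], start=1):
        if run.node_labels != first.node_labels:
            raise ValueError(f"run {k} node labels differ from run 0")
        if run.tr_seconds != first.tr_seconds:
            raise ValueError(f"run {k} TR {run.tr_seconds} differs from run 0 {first.tr_seconds}")
    values = np.vstack([r.values for r in runs])
    return NodalTimeSeries(values, first.tr_seconds, first.node_labels)
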