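"""Trough/peak extraction from RSS co-fluctuation traces.

A trough is a strict local minimum of the RSS series; a peak is the highest
value between two consecutive troughs. Trough-to-trough duration (in seconds,
via the TR) measures the time between successive network reconfiguration
events; peak height is the absolute RSS value at the peak.

Shallow troughs can be pruned with a percent-magnitude criterion: a trough
must be at least a fraction ``theta`` lower than its reference values. Because
"reference" admits two readings, both are implemented as first-class modes:

* ``adjacent-sample`` — the immediately preceding and following samples;
* ``adjacent-peak``  — the flanking peaks in the alternating extrema
  sequence, with iterative removal of the shallowest violating trough.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edges import RssSeries

__all__ = [
    "TroughCriterion",
    "ExtremaResult",
    "SubjectSummary",
    "detect_base_extrema",
    "apply_magnitude_criterion",
    "detect_extrema",
    "trough_durations",
    "peak_heights",
    "summarize_subject",
]

MODES = ("adjacent-sample", "adjacent-peak")

# Relative tolerance for the boundary-inclusive percent test: a trough exactly
# theta lower than its reference counts as passing despite rounding in
# (1 - theta) * reference.
_BOUNDARY_RTOL = 1e-9


@dataclass(frozen=True)
class TroughCriterion:
    """Magnitude requirement for troughs: theta=0 is the base "any local
    minimum" rule; 0.01/0.02/0.05 demand a 1/2/5% drop below the reference."""

    theta: float = 0.0
    mode: str = "adjacent-sample"

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < 0.5:
            raise ValueError(f"theta must lie in [0, 0.5), got {self.theta}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class ExtremaResult:
    trough_indices: np.ndarray
    peak_indices: np.ndarray
    peak_heights: np.ndarray
    durations_seconds: np.ndarray
    criterion: TroughCriterion
    tr_seconds: float
    n_timepoints: int

    @property
    def n_troughs(self) -> int:
        return len(self.trough_indices)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_indices)


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject extrema statistics under one criterion."""

    subject_id: str
    label: str
    criterion: TroughCriterion
    mean_trough_duration_seconds: float
    mean_peak_height: float
    n_troughs: int
    n_peaks: int
    insufficient_troughs: bool


def _passes(value: float, reference: float, theta: float) -> bool:
    """Boundary-inclusive test: value <= (1 - theta) * reference."""
    bound = (1.0 - theta) * reference
    return value <= bound or np.isclose(value, bound, rtol=_BOUNDARY_RTOL, atol=0.0)


def _peaks_between(values: np.ndarray, troughs: np.ndarray):
    """Highest value strictly between consecutive troughs; earliest index on ties."""
    peak_idx = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        seg = values[a + 1 : b]
        peak_idx.append(a + 1 + int(np.argmax(seg)))
    peak_idx = np.asarray(peak_idx, dtype=np.intp)
    return peak_idx, values[peak_idx] if len(peak_idx) else np.empty(0)


def _assemble(values, troughs, criterion, tr_seconds) -> ExtremaResult:
    troughs = np.asarray(troughs, dtype=np.intp)
    peak_idx, peak_h = _peaks_between(values, troughs)
    durations = np.diff(troughs) * tr_seconds
    return ExtremaResult(
        trough_indices=troughs,
        peak_indices=peak_idx,
        peak_heights=np.asarray(peak_h, dtype=float),
        durations_seconds=np.asarray(durations, dtype=float),
        criterion=criterion,
        tr_seconds=tr_seconds,
        n_timepoints=len(values),
    )


def detect_base_extrema(rss: RssSeries) -> ExtremaResult:
    """Strict local minima (lower than both neighbours) and the peaks between.

    The first and last timepoints are never troughs or peaks; exact ties with
    a neighbour disqualify a trough.
    """
    v = rss.values
    if len(v) < 3:
        raise ValueError(f"need at least 3 timepoints to detect extrema, got {len(v)}")
    interior = np.arange(1, len(v) - 1)
    is_trough = (v[interior] < v[interior - 1]) & (v[interior] < v[interior + 1])
    troughs = interior[is_trough]
    return _assemble(v, troughs, TroughCriterion(0.0, "adjacent-sample"), rss.tr_seconds)


def _prune_adjacent_sample(v: np.ndarray, troughs: np.ndarray, theta: float) -> np.ndarray:
    keep = [
        t
        for t in troughs
        if _passes(v[t], v[t - 1], theta) and _passes(v[t], v[t + 1], theta)
    ]
    return np.asarray(keep, dtype=np.intp)


def _flank_references(v: np.ndarray, troughs: np.ndarray) -> np.ndarray:
    """min(left, right) flanking reference per trough.

    Flanks are the maxima of the open segments between neighbouring surviving
    troughs; boundary segments (before the first / after the last trough)
    supply the outer references, so endpoint samples can act as references
    even though they are never reported as peaks.
    """
    bounds = np.concatenate(([-1], troughs, [len(v)]))
    refs = np.empty(len(troughs))
    for k in range(len(troughs)):
        left_seg = v[bounds[k] + 1 : troughs[k]]
        right_seg = v[troughs[k] + 1 : bounds[k + 2]]
        left = left_seg.max() if left_seg.size else -np.inf
        right = right_seg.max() if right_seg.size else -np.inf
        refs[k] = min(left, right)
    return refs


def _prune_adjacent_peak(v: np.ndarray, troughs: np.ndarray, theta: float) -> np.ndarray:
    """Iteratively drop the shallowest trough violating the flanking-peak test.

    Removing a trough merges its two segments, so the surviving neighbours see
    the higher of the merged flanks; references are recomputed each round.
    """
    surviving = list(troughs)
    while surviving:
        arr = np.asarray(surviving, dtype=np.intp)
        refs = _flank_references(v, arr)
        depths = (refs - v[arr]) / refs
        violating = [
            k for k in range(len(arr)) if not _passes(v[arr[k]], refs[k], theta)
        ]
        if not violating:
            break
        worst = min(violating, key=lambda k: (depths[k], arr[k]))
        del surviving[worst]
    return np.asarray(surviving, dtype=np.intp)


def apply_magnitude_criterion(
    base: ExtremaResult, rss: RssSeries, criterion: TroughCriterion
) -> ExtremaResult:
    """Prune base troughs that are not at least ``theta`` lower than their
    references, then recompute peaks between the survivors.

    ``theta = 0`` returns the base result unchanged.
    """
    if base.n_timepoints != len(rss):
        raise ValueError(
            f"base extrema computed on {base.n_timepoints} timepoints, "
            f"RSS series has {len(rss)}"
        )
    if criterion.theta == 0.0:
        return ExtremaResult(
            trough_indices=base.trough_indices,
            peak_indices=base.peak_indices,
            peak_heights=base.peak_heights,
            durations_seconds=base.durations_seconds,
            criterion=criterion,
            tr_seconds=base.tr_seconds,
            n_timepoints=base.n_timepoints,
        )
    v = rss.values
    if criterion.mode == "adjacent-sample":
        troughs = _prune_adjacent_sample(v, base.trough_indices, criterion.theta)
    else:
        troughs = _prune_adjacent_peak(v, base.trough_indices, criterion.theta)
    return _assemble(v, troughs, criterion, base.tr_seconds)


def detect_extrema(rss: RssSeries, criterion: TroughCriterion | None = None) -> ExtremaResult:
    """Base detection followed by magnitude pruning in one call."""
    base = detect_base_extrema(rss)
    if criterion is None or criterion.theta == 0.0:
        crit = criterion or TroughCriterion()
        return apply_magnitude_criterion(base, rss, crit)
    return apply_magnitude_criterion(base, rss, criterion)


def trough_durations(result: ExtremaResult, tr_seconds: float | None = None) -> np.ndarray:
    """Trough-to-trough intervals in seconds; empty with fewer than 2 troughs."""
    tr = result.tr_seconds if tr_seconds is None else tr_seconds
    return np.diff(result.trough_indices) * tr


def peak_heights(result: ExtremaResult) -> np.ndarray:
    """Absolute RSS value at each peak (y-axis convention, not depth-relative)."""
    return result.peak_heights


def summarize_subject(
    rss: RssSeries,
    criterion: TroughCriterion,
    subject_id: str,
    label: str | None = None,
) -> SubjectSummary:
    """Mean trough duration and mean peak height for one subject.

    Subjects with fewer than 2 surviving troughs have no durations or peaks;
    they are flagged (``insufficient_troughs``) rather than silently dropped.
    """
    result = detect_extrema(rss, criterion)
    insufficient = result.n_troughs < 2
    return SubjectSummary(
        subject_id=subject_id,
        label=label if label is not None else rss.label,
        criterion=criterion,
        mean_trough_duration_seconds=(
            float(np.mean(result.durations_seconds)) if not insufficient else float("nan")
        ),
        mean_peak_height=(
            float(np.mean(result.peak_heights)) if result.n_peaks else float("nan")
        ),
        n_troughs=result.n_troughs,
        n_peaks=result.n_peaks,
        insufficient_troughs=insufficient,
    )
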