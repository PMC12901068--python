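"""Synthetic two-group resting-state cohorts with hidden covariance regimes.

Each subject's nodal series is drawn from a zero-mean multivariate normal
whose covariance follows a hidden Markov regime path: at every timepoint the
chain stays in its current regime with the group's stay probability, otherwise
jumps to a uniformly random different regime. Default regimes are
block-correlation states of graded amplitude — state k elevates the
within-block correlation of block k, and later states carry a larger overall
scale, emulating the punctuated high-amplitude co-fluctuation events seen in
empirical edge time series. Entering and leaving a high-amplitude state
produces the rises and deep troughs of the downstream RSS trace, so a group's
regime switching rate is identifiable from trough statistics: slower
switching means fewer events, hence fewer surviving troughs and longer
trough-to-trough durations.

Temporal smoothness comes from AR(1) node noise (bandpass-filtered resting
BOLD at sub-second TR is heavily oversampled, so consecutive samples are
strongly correlated); the regime's covariance factor is applied to the smooth
noise timepoint-wise, so each sample has exactly its regime's covariance and
regime changes take effect instantly. ``ar_phi=0`` gives temporally
independent draws.

Groups differ in their regime stay probability (the dynamics contrast of
interest) and in the means of two subject-level covariates, age and total
brain volume, which are independent of the series given group — so a
covariate-adjusted group comparison downstream has a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edges import NodalTimeSeries

__all__ = [
    "SyntheticSpec",
    "SyntheticSubject",
    "make_state_covariances",
    "simulate_subject",
    "simulate_cohort",
]

_PSD_TOL = 1e-8


def default_state_amplitudes(n_states: int, max_amplitude: float = 2.5) -> tuple[float, ...]:
    """Graded signal amplitudes from 1 up to ``max_amplitude`` across states."""
    if n_states == 1:
        return (1.0,)
    return tuple(1.0 + (max_amplitude - 1.0) * k / (n_states - 1) for k in range(n_states))


def make_state_covariances(
    n_nodes: int,
    n_states: int,
    within_block_r: float = 0.5,
    amplitudes=None,
) -> list[np.ndarray]:
    """Block-correlation states of graded amplitude.

    Nodes split into ``n_states`` nearly equal blocks; state k sets the
    correlation inside block k to ``r`` (off-block 0) and scales the whole
    matrix by ``amplitudes[k] ** 2``, so higher states are high-amplitude
    co-fluctuation events. ``amplitudes=None`` uses the graded default;
    pass all ones for pure correlation-rotation states.
    """
    if not 0 <= within_block_r < 1:
        raise ValueError(f"within-block correlation must be in [0, 1), got {within_block_r}")
    if amplitudes is None:
        amplitudes = default_state_amplitudes(n_states)
    if len(amplitudes) != n_states:
        raise ValueError(f"{len(amplitudes)} amplitudes for {n_states} states")
    bounds = np.linspace(0, n_nodes, n_states + 1).astype(int)
    covs = []
    for k in range(n_states):
        cov = np.eye(n_nodes)
        lo, hi = bounds[k], bounds[k + 1]
        block = np.full((hi - lo, hi - lo), within_block_r)
        np.fill_diagonal(block, 1.0)
        cov[lo:hi, lo:hi] = block
        covs.append(amplitudes[k] ** 2 * cov)
    return covs


@dataclass
class SyntheticSpec:
    """Generative settings for a two-group cohort.

    Defaults keep node count small for fast tests; covariate defaults follow
    the demographic profile of a large young-adult resting-state sample
    (group A male-like, group B female-like: ages ~27.9 vs ~29.5 years,
    total brain volumes ~1215 vs ~1064 ml).
    """

    n_nodes: int = 20
    n_timepoints: int = 600
    tr_seconds: float = 0.72
    n_states: int = 2
    stay_prob_per_group: dict = field(default_factory=lambda: {"A": 0.97, "B": 0.93})
    state_covariances: list | None = None
    within_block_r: float = 0.1
    state_amplitudes: tuple | None = None
    ar_phi: float = 0.97
    group_sizes: dict = field(default_factory=lambda: {"A": 30, "B": 30})
    age_mean_sd_per_group: dict = field(
        default_factory=lambda: {"A": (27.9, 2.4), "B": (29.5, 3.5)}
    )
    volume_mean_sd_per_group: dict = field(
        default_factory=lambda: {"A": (1215.13, 110.0), "B": (1063.80, 100.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be at least 3")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_states < 1:
            raise ValueError("n_states must be at least 1")
        if not -1 < self.ar_phi < 1:
            raise ValueError(f"ar_phi must lie in (-1, 1), got {self.ar_phi}")
        if not self.group_sizes:
            raise ValueError("at least one group is required")
        for g, size in self.group_sizes.items():
            if size < 1:
                raise ValueError(f"group {g!r} has size {size}; sizes must be >= 1")
        for g, p in self.stay_prob_per_group.items():
            if not 0 < p < 1:
                raise ValueError(f"stay probability for group {g!r} must be in (0, 1), got {p}")
        for g in self.group_sizes:
            for name, mapping in (
                ("stay_prob_per_group", self.stay_prob_per_group),
                ("age_mean_sd_per_group", self.age_mean_sd_per_group),
                ("volume_mean_sd_per_group", self.volume_mean_sd_per_group),
            ):
                if g not in mapping:
                    raise ValueError(f"group {g!r} missing from {name}")
        if self.state_covariances is None:
            self.state_covariances = make_state_covariances(
                self.n_nodes, self.n_states, self.within_block_r, self.state_amplitudes
            )
        if len(self.state_covariances) != self.n_states:
            raise ValueError(
                f"{len(self.state_covariances)} covariance matrices for {self.n_states} states"
            )
        self.state_covariances = [np.asarray(c, dtype=float) for c in self.state_covariances]
        for k, cov in enumerate(self.state_covariances):
            if cov.shape != (self.n_nodes, self.n_nodes):
                raise ValueError(f"state {k} covariance has shape {cov.shape}")
            if not np.allclose(cov, cov.T):
                raise ValueError(f"state {k} covariance is not symmetric")
            if np.linalg.eigvalsh(cov).min() < -_PSD_TOL:
                raise ValueError(f"state {k} covariance is not positive semi-definite")

    @property
    def groups(self) -> tuple:
        return tuple(self.group_sizes)

    @property
    def node_labels(self) -> tuple:
        return tuple(f"node{i:03d}" for i in range(self.n_nodes))


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    group: str
    age: float
    brain_volume: float
    series: NodalTimeSeries
    true_state_path: np.ndarray


def _simulate_state_path(n_timepoints, n_states, stay_prob, rng) -> np.ndarray:
    if n_states == 1:
        return np.zeros(n_timepoints, dtype=np.intp)
    path = np.empty(n_timepoints, dtype=np.intp)
    path[0] = rng.integers(n_states)
    stay = rng.random(n_timepoints - 1) < stay_prob
    jumps = rng.integers(1, n_states, size=n_timepoints - 1)  # offset to a different state
    for t in range(1, n_timepoints):
        path[t] = path[t - 1] if stay[t - 1] else (path[t - 1] + jumps[t - 1]) % n_states
    return path


def simulate_subject(
    spec: SyntheticSpec, group: str, rng: np.random.Generator | int
) -> SyntheticSubject:
    """Draw one subject of the given group: hidden regime path, AR(1)-smoothed
    regime-switching Gaussian series, and covariates."""
    if group not in spec.group_sizes:
        raise ValueError(f"unknown group {group!r}; expected one of {list(spec.group_sizes)}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    path = _simulate_state_path(
        spec.n_timepoints, spec.n_states, spec.stay_prob_per_group[group], rng
    )
    T, N = spec.n_timepoints, spec.n_nodes
    # Unit-variance AR(1) noise per node, then the regime's covariance factor
    # applied timepoint-wise: x_t = L_{s(t)} n_t is N(0, cov_{s(t)}) exactly,
    # temporally smooth within regimes, and adopts a new regime instantly.
    noise = rng.standard_normal((T, N))
    phi = spec.ar_phi
    if phi != 0.0:
        scale = np.sqrt(1.0 - phi**2)
        for t in range(1, T):
            noise[t] = phi * noise[t - 1] + scale * noise[t]
    x = np.empty_like(noise)
    for k, cov in enumerate(spec.state_covariances):
        rows = np.flatnonzero(path == k)
        if rows.size:
            # eigendecomposition factor handles PSD (possibly singular) states
            w, v = np.linalg.eigh(cov)
            factor = v * np.sqrt(np.clip(w, 0.0, None))
            x[rows] = noise[rows] @ factor.T

    age_mu, age_sd = spec.age_mean_sd_per_group[group]
    vol_mu, vol_sd = spec.volume_mean_sd_per_group[group]
    series = NodalTimeSeries(x, spec.tr_seconds, spec.node_labels)
    return SyntheticSubject(
        subject_id="",
        group=group,
        age=float(rng.normal(age_mu, age_sd)),
        brain_volume=float(rng.normal(vol_mu, vol_sd)),
        series=series,
        true_state_path=path,
    )


def simulate_cohort(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Simulate every subject of every group; returns the subject list and the
    cohort covariate table. Identical spec + seed give identical output."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    subjects: list[SyntheticSubject] = []
    rows = []
    counter = 0
    for group in spec.groups:
        for _ in range(spec.group_sizes[group]):
            counter += 1
            sid = f"sub-{counter:04d}"
            subj = simulate_subject(spec, group, rng)
            subj = SyntheticSubject(
                subject_id=sid,
                group=subj.group,
                age=subj.age,
                brain_volume=subj.brain_volume,
                series=subj.series,
                true_state_path=subj.true_state_path,
            )
            subjects.append(subj)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age_years": subj.age,
                    "brain_volume_ml": subj.brain_volume,
                }
            )
    return subjects, pd.DataFrame(rows)
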