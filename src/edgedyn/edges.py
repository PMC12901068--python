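"""Edge time series, co-fluctuation amplitude (RSS), and edge functional connectivity.

Edge time series (ETS) unfold a Pearson correlation into its per-timepoint
contributions: for z-scored nodal signals ``z_i``, ``z_j``, the edge series is
the element-wise product ``z_i(t) * z_j(t)``, whose time average equals the
correlation of nodes i and j. The root-sum-square (RSS) across all edges at
each timepoint gives a single whole-brain (or subnetwork) co-fluctuation
amplitude trace, and correlating edge series with each other gives the edge
functional connectivity (eFC) matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NodalTimeSeries",
    "EdgeIndex",
    "EdgeTimeSeries",
    "RssSeries",
    "EfcMatrix",
    "zscore_nodes",
    "build_edge_index",
    "compute_ets",
    "compute_rss",
    "compute_efc",
]

# z-scoring uses the sample (n-1) standard deviation throughout; the
# ETS-mean <-> Pearson identity in compute_ets relies on the same convention.
ZSCORE_DDOF = 1


@dataclass(frozen=True)
class NodalTimeSeries:
    """Parcellated BOLD signal: a timepoints x nodes matrix with TR and labels."""

    values: np.ndarray
    tr_seconds: float
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", tuple(str(l) for l in self.node_labels))
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D (timepoints x nodes), got ndim={values.ndim}")
        if values.shape[0] < 3:
            raise ValueError(f"need at least 3 timepoints, got {values.shape[0]}")
        if values.shape[1] < 2:
            raise ValueError(f"need at least 2 nodes, got {values.shape[1]}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain NaN or infinite entries")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if len(self.node_labels) != values.shape[1]:
            raise ValueError(
                f"{len(self.node_labels)} labels for {values.shape[1]} node columns"
            )
        if len(set(self.node_labels)) != len(self.node_labels):
            seen: set[str] = set()
            dup = next(l for l in self.node_labels if l in seen or seen.add(l))
            raise ValueError(f"duplicate node label: {dup!r}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EdgeIndex:
    """All unordered node pairs (i, j), i < j, in lexicographic order."""

    pairs: tuple[tuple[int, int], ...]
    n_nodes: int

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def rows(self) -> np.ndarray:
        return np.fromiter((p[0] for p in self.pairs), dtype=np.intp, count=len(self.pairs))

    @property
    def cols(self) -> np.ndarray:
        return np.fromiter((p[1] for p in self.pairs), dtype=np.intp, count=len(self.pairs))


@dataclass(frozen=True)
class EdgeTimeSeries:
    """Timepoints x edges matrix of per-pair co-fluctuation products."""

    values: np.ndarray
    edge_index: EdgeIndex
    tr_seconds: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape[1] != len(self.edge_index):
            raise ValueError(
                f"{values.shape[1]} edge columns but edge index has {len(self.edge_index)} pairs"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class RssSeries:
    """One co-fluctuation amplitude per timepoint (root-sum-square over edges)."""

    values: np.ndarray
    tr_seconds: float
    n_edges: int
    label: str = "whole-brain"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("RSS values must be a 1-D vector")
        if np.any(values < 0):
            raise ValueError("RSS values must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_seconds(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.tr_seconds


@dataclass(frozen=True)
class EfcMatrix:
    """Edge-by-edge Pearson correlation matrix (edge functional connectivity)."""

    values: np.ndarray
    edge_index: EdgeIndex
    excluded_edges: tuple[int, ...] = field(default=())


def zscore_nodes(series: NodalTimeSeries) -> NodalTimeSeries:
    """Z-transform each node column to mean 0, unit sample (ddof=1) SD.

    Raises ``ValueError`` naming the node if any column is constant.
    """
    x = series.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ZSCORE_DDOF)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"constant node column(s) cannot be z-scored: "
            f"{[series.node_labels[i] for i in bad]}"
        )
    return NodalTimeSeries((x - mean) / sd, series.tr_seconds, series.node_labels)


def build_edge_index(n_nodes: int) -> EdgeIndex:
    """All unordered node pairs i < j in lexicographic order; n*(n-1)/2 of them."""
    if n_nodes < 2:
        raise ValueError(f"need at least 2 nodes to form edges, got {n_nodes}")
    iu = np.triu_indices(n_nodes, k=1)
    pairs = tuple(zip(iu[0].tolist(), iu[1].tolist()))
    return EdgeIndex(pairs=pairs, n_nodes=n_nodes)


def compute_ets(zseries: NodalTimeSeries, edge_index: EdgeIndex) -> EdgeTimeSeries:
    """Element-wise products of z-scored node pairs: column (i,j) is z_i * z_j.

    The time mean of each edge column equals the Pearson correlation of its
    two nodes (up to the shared ddof convention).
    """
    if edge_index.n_nodes != zseries.n_nodes:
        raise ValueError(
            f"edge index built for {edge_index.n_nodes} nodes, series has {zseries.n_nodes}"
        )
    z = zseries.values
    ets = z[:, edge_index.rows] * z[:, edge_index.cols]
    return EdgeTimeSeries(values=ets, edge_index=edge_index, tr_seconds=zseries.tr_seconds)


def _resolve_subset(series: NodalTimeSeries, node_subset) -> np.ndarray:
    labels = list(series.node_labels)
    idx = []
    unknown = []
    for lab in node_subset:
        lab = str(lab)
        if lab in labels:
            idx.append(labels.index(lab))
        else:
            unknown.append(lab)
    if unknown:
        raise ValueError(f"unknown node label(s) in subset: {unknown}")
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate node labels in subset")
    return np.asarray(idx, dtype=np.intp)


def compute_rss(
    zseries: NodalTimeSeries,
    node_subset=None,
    *,
    explicit_edges: bool = False,
    label: str | None = None,
) -> RssSeries:
    """Root-sum-square co-fluctuation amplitude at each timepoint.

    ``RSS(t) = sqrt( sum_{i<j} (z_i(t) z_j(t))^2 )`` over all node pairs, or
    only within-subset pairs when ``node_subset`` (node labels) is given.

    By default uses the algebraic shortcut
    ``2 * RSS(t)^2 = (sum_i z_i^2)^2 - sum_i z_i^4``,
    avoiding materialising the full edge matrix; ``explicit_edges=True``
    forces the direct enumeration over edge columns instead.
    """
    if node_subset is not None:
        idx = _resolve_subset(zseries, node_subset)
        if idx.size < 2:
            raise ValueError(f"node subset must contain at least 2 nodes, got {idx.size}")
        z = zseries.values[:, idx]
        if label is None:
            label = "subnetwork"
    else:
        z = zseries.values
        if label is None:
            label = "whole-brain"
    n_nodes = z.shape[1]
    n_edges = n_nodes * (n_nodes - 1) // 2
    if explicit_edges:
        iu = np.triu_indices(n_nodes, k=1)
        prod = z[:, iu[0]] * z[:, iu[1]]
        rss = np.sqrt(np.sum(prod**2, axis=1))
    else:
        s2 = np.sum(z**2, axis=1)
        s4 = np.sum(z**4, axis=1)
        rss = np.sqrt(np.maximum(s2**2 - s4, 0.0) / 2.0)
    return RssSeries(values=rss, tr_seconds=zseries.tr_seconds, n_edges=n_edges, label=label)


def compute_efc(ets: EdgeTimeSeries) -> EfcMatrix:
    """Pearson correlation between every pair of edge time series.

    Constant edge columns cannot be correlated; they are excluded with a
    warning and recorded in ``excluded_edges`` (their rows/columns are NaN).
    """
    if ets.n_timepoints < 3:
        raise ValueError(f"need at least 3 timepoints for eFC, got {ets.n_timepoints}")
    x = ets.values
    sd = x.std(axis=0, ddof=ZSCORE_DDOF)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        warnings.warn(
            f"excluding {constant.size} constant edge column(s) from eFC: "
            f"{[ets.edge_index.pairs[i] for i in constant[:10]]}",
            stacklevel=2,
        )
    keep = np.flatnonzero(sd > 0)
    n = x.shape[1]
    efc = np.full((n, n), np.nan)
    if keep.size:
        sub = np.corrcoef(x[:, keep], rowvar=False)
        sub = np.atleast_2d(sub)
        np.clip(sub, -1.0, 1.0, out=sub)
        efc[np.ix_(keep, keep)] = sub
    return EfcMatrix(values=efc, edge_index=ets.edge_index, excluded_edges=tuple(constant.tolist()))
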