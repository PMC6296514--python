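"""Correlation-based network construction for node time series.

A run's functional connectivity is summarised by the matrix of zero-lag
Pearson correlations between every pair of node time series.  Because every
node pair is correlated to some degree, the continuous matrix is binarized
before graph metrics are computed.  Two thresholding schemes are supported:

``significance``
    Keep an edge wherever the correlation is significantly different from
    zero (two-sided exact t test on the Pearson r, uncorrected).
``mcc``
    The minimum connected component: insert edges in descending weight
    order and stop as soon as the graph becomes a single connected
    component spanning all nodes.  Ties with the stopping weight are all
    included, which makes the result independent of sort order.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

MODALITIES = ("VV", "AV", "AA")


@dataclass
class RunTimeSeries:
    """Node x time activity matrix for one run of one participant.

    ``data`` has one row per node and one column per time point.
    """

    subject_id: str
    modality: str
    run_index: int
    data: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-d node x time matrix")
        n_nodes, n_time = self.data.shape
        if n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if n_time < 4:
            raise ValueError("need at least 4 time points")
        if np.isnan(self.data).any():
            raise ValueError("time series contain missing values")
        if not self.node_labels:
            self.node_labels = tuple(f"n{i:03d}" for i in range(n_nodes))
        if len(self.node_labels) != n_nodes:
            raise ValueError("node_labels length does not match data")
        if len(set(self.node_labels)) != n_nodes:
            raise ValueError("node_labels must be unique")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations of one run, with sample size."""

    values: np.ndarray
    n_timepoints: int
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v
        if not self.node_labels:
            self.node_labels = tuple(f"n{i:03d}" for i in range(v.shape[0]))

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Symmetric 0/1 adjacency with zero diagonal.

    ``provenance`` records how the network was thresholded (alpha and the
    critical |r| for the significance scheme; the stopping weight and tie
    count for the MCC scheme).
    """

    adjacency: np.ndarray
    scheme: str
    provenance: dict = field(default_factory=dict)
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.int8)
        if not self.node_labels:
            self.node_labels = tuple(f"n{i:03d}" for i in range(a.shape[0]))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def is_connected(self) -> bool:
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(self.adjacency, directed=False)
        return n_comp == 1


def correlation_matrix(run: RunTimeSeries) -> CorrelationMatrix:
    """Zero-lag Pearson correlations between all pairs of node series."""
    sd = run.data.std(axis=1)
    scale = np.maximum(np.abs(run.data).max(axis=1), 1.0)
    zero_var = np.flatnonzero(sd < 1e-12 * scale)
    if zero_var.size:
        names = [run.node_labels[i] for i in zero_var]
        raise ValueError(f"zero-variance node(s): {names}")
    r = np.corrcoef(run.data)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, run.n_timepoints, run.node_labels)


def correlation_pvalues(corr: CorrelationMatrix) -> np.ndarray:
    """Two-sided p-values for each off-diagonal correlation.

    Uses the exact small-sample test t = r sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom.  |r| = 1 maps to p = 0.
    """
    n = corr.n_timepoints
    if n < 4:
        raise ValueError("need at least 4 time points for the t test")
    df = n - 2
    r = corr.values
    p = np.zeros_like(r)
    off = ~np.eye(r.shape[0], dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    perfect = np.abs(r) >= 1.0
    p[off] = 2.0 * stats.t.sf(np.abs(t[off]), df)
    p[perfect & off] = 0.0
    np.fill_diagonal(p, 0.0)
    return p


def critical_r(n_timepoints: int, alpha: float = 0.05) -> float:
    """|r| boundary above which the two-sided test rejects at ``alpha``."""
    df = n_timepoints - 2
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def significance_threshold(
    corr: CorrelationMatrix, alpha: float = 0.05, positive_only: bool = False
) -> BinaryNetwork:
    """Binarize by keeping correlations with two-sided p < alpha.

    Significant negative correlations produce edges by default (the test is
    two-sided); pass ``positive_only=True`` to restrict edges to positive r.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = correlation_pvalues(corr)
    adj = (p < alpha).astype(np.int8)
    if positive_only:
        adj &= (corr.values > 0).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(
        adj,
        scheme="significance",
        provenance={
            "alpha": alpha,
            "critical_r": critical_r(corr.n_timepoints, alpha),
            "positive_only": positive_only,
            "n_timepoints": corr.n_timepoints,
        },
        node_labels=corr.node_labels,
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.n_components = n

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        self.n_components -= 1
        return True


def mcc_threshold(corr: CorrelationMatrix, rank: str = "signed") -> BinaryNetwork:
    """Minimum connected component of a weighted adjacency matrix.

    Edges are inserted in descending order of weight until the graph first
    becomes one connected component spanning every node.  All edges whose
    weight is strictly greater than that stopping weight, plus all edges
    tied with it, form the result — so the output does not depend on how
    the sort broke ties.

    ``rank="signed"`` (default) treats the most positive correlation as the
    strongest weight; ``rank="abs"`` ranks by absolute value instead.
    """
    n = corr.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    iu, ju = np.triu_indices(n, k=1)
    w = corr.values[iu, ju]
    key = np.abs(w) if rank == "abs" else w
    if rank not in ("signed", "abs"):
        raise ValueError("rank must be 'signed' or 'abs'")
    order = np.argsort(-key, kind="stable")
    uf = _UnionFind(n)
    stop_key = None
    for e in order:
        uf.union(int(iu[e]), int(ju[e]))
        if uf.n_components == 1:
            stop_key = key[e]
            break
    if stop_key is None:  # unreachable: the complete graph is connected
        raise RuntimeError("failed to connect graph")
    keep = key >= stop_key
    n_ties = int(np.sum(key == stop_key))
    if n_ties > 1:
        logger.info("mcc_threshold: %d edges tied at stopping weight %.6g", n_ties, stop_key)
    if keep.all():
        logger.info("mcc_threshold: all weights tied; degenerating to the complete graph")
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    net = BinaryNetwork(
        adj,
        scheme="mcc",
        provenance={"stopping_weight": float(stop_key), "rank": rank, "n_ties": n_ties},
        node_labels=corr.node_labels,
    )
    assert net.is_connected()
    return net


def threshold(corr: CorrelationMatrix, scheme: str, **kwargs) -> BinaryNetwork:
    """Dispatch to the named thresholding scheme."""
    if scheme == "significance":
        return significance_threshold(corr, **kwargs)
    if scheme == "mcc":
        return mcc_threshold(corr, **kwargs)
    raise ValueError(f"unknown thresholding scheme: {scheme!r}")


# ---------------------------------------------------------------------------
# plain-text I/O


def read_timeseries_matrix(path: str | Path) -> np.ndarray:
    """Read a delimited node x time matrix (tab or comma, optional header).

    A header row is detected by attempting to parse the first line as
    numbers; if that fails the line is skipped.
    """
    path = Path(path)
    text = path.read_text()
    first = text.splitlines()[0] if text else ""
    delim = "\t" if "\t" in first else ("," if "," in first else None)
    tokens = first.replace(",", " ").replace("\t", " ").split()
    skip = 0
    try:
        [float(t) for t in tokens]
    except ValueError:
        skip = 1
    data = np.loadtxt(io.StringIO(text), delimiter=delim, skiprows=skip, ndmin=2)
    return data


def write_timeseries_matrix(path: str | Path, data: np.ndarray) -> None:
    np.savetxt(path, np.asarray(data, dtype=float), delimiter="\t", fmt="%.10g")


def write_adjacency(path: str | Path, net: BinaryNetwork) -> None:
    """Write a 0/1 adjacency as a delimited square matrix with node labels."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(net.node_labels) + "\n")
        for row in net.adjacency:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_adjacency(path: str | Path, scheme: str = "unknown") -> BinaryNetwork:
    path = Path(path)
    lines = path.read_text().splitlines()
    labels = tuple(lines[0].split("\t"))
    adj = np.array([[int(v) for v in ln.split("\t")] for ln in lines[1:]], dtype=np.int8)
    return BinaryNetwork(adj, scheme=scheme, node_labels=labels)


def run_file_name(subject_id: str, modality: str, run_index: int) -> str:
    return f"{subject_id}_{modality}_run{run_index}.tsv"


def parse_run_file_name(name: str) -> tuple[str, str, int]:
    stem = Path(name).stem
    subject_id, modality, run = stem.rsplit("_", 2)
    return subject_id, modality, int(run.removeprefix("run"))


def load_cohort_timeseries(directory: str | Path) -> list[RunTimeSeries]:
    """Load every ``<subject>_<modality>_run<k>.tsv`` file in a directory."""
    directory = Path(directory)
    runs = []
    for path in sorted(directory.glob("*.tsv")):
        subject_id, modality, run_index = parse_run_file_name(path.name)
        runs.append(
            RunTimeSeries(
                subject_id=subject_id,
                modality=modality,
                run_index=run_index,
                data=read_timeseries_matrix(path),
            )
        )
    if not runs:
        raise FileNotFoundError(f"no .tsv run files found in {directory}")
    return runs
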