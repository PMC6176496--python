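"""Density-thresholded networks and long/short-distance connection metrics.

The wPLI matrix over the 148 ROIs is pruned by keeping the strongest
connections up to a target edge density d (fraction of the N(N-1)/2 possible
edges). Edges whose endpoints lie in different coarse cortical areas are
long-distance, edges within one area short-distance. Per area k,

    L_k = sum of kept weights of edges with exactly one endpoint in area k,
    S_k = sum of kept weights of edges with both endpoints in area k,
    L_all = sum_k L_k,   S_all = sum_k S_k,   Ratio = L_all / S_all.

Each inter-area edge touches two areas and therefore appears in two L_k
terms, so L_all double-counts it; consequently the conserved quantity is
S_all + L_all / 2 = total kept weight. The density grid runs from the
integrity floor (average degree 2 ln N, about 6% for N = 148) up to 90%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .atlas import AreaPartition
from .config import ConfigError
from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)


def minimum_density(n_nodes: int) -> float:
    """Density at which the average degree equals 2 ln N: 2 ln(N)/(N-1)."""
    if n_nodes < 3:
        raise ConfigError("minimum density needs at least 3 nodes")
    return 2.0 * math.log(n_nodes) / (n_nodes - 1)


def minimum_density_percent(n_nodes: int) -> int:
    """The floor as a truncated integer percent (6 for N = 148)."""
    return int(minimum_density(n_nodes) * 100.0)


@dataclass
class ThresholdedGraph:
    """Kept edges of a density-thresholded connectivity matrix."""

    n_nodes: int
    density: float
    edge_i: np.ndarray  # 0-based, edge_i < edge_j
    edge_j: np.ndarray
    weights: np.ndarray  # sorted strongest-first

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        a[self.edge_i, self.edge_j] = self.weights
        a[self.edge_j, self.edge_i] = self.weights
        return a


@dataclass
class ConnectionMetrics:
    """Long/short-distance connection sums at one density."""

    density: float
    l_k: np.ndarray  # per-area long-distance weight, len 14
    s_k: np.ndarray  # per-area short-distance weight
    l_all: float
    s_all: float
    ratio: float  # NaN when S_all == 0
    labels: dict = field(default_factory=dict)


@dataclass
class DensitySweep:
    """Metrics at each grid density plus their arithmetic mean."""

    per_density: list[ConnectionMetrics]
    summary: ConnectionMetrics


def _sorted_edges(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges ordered by descending weight, ties by (i, j)."""
    n = w.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    vals = w[ii, jj]
    order = np.lexsort((jj, ii, -vals))
    return ii[order], jj[order], vals[order]


def n_kept_edges(n_nodes: int, density: float) -> int:
    total = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(density * total + 0.5))


def threshold_by_density(w: ConnectivityMatrix | np.ndarray,
                         density: float) -> ThresholdedGraph:
    """Keep the strongest floor(d * N(N-1)/2 + 0.5) edges.

    Densities below the 2 ln N integrity floor are allowed but logged as a
    warning. Ties in weight break deterministically by (i, j) index order.
    """
    mat = w.w if isinstance(w, ConnectivityMatrix) else np.asarray(w)
    n = mat.shape[0]
    if not 0 < density <= 1:
        raise ConfigError(f"density {density} outside (0, 1]")
    if n >= 3 and density < minimum_density(n):
        logger.warning("density %.3f below integrity floor %.3f (2 ln N)",
                       density, minimum_density(n))
    ii, jj, vals = _sorted_edges(mat)
    m = n_kept_edges(n, density)
    return ThresholdedGraph(n, density, ii[:m], jj[:m], vals[:m])


def area_metrics(graph: ThresholdedGraph,
                 partition: AreaPartition) -> ConnectionMetrics:
    """Classify every kept edge as long (inter-area) or short (intra-area)."""
    if partition.n_rois != graph.n_nodes:
        raise ConfigError("partition does not cover the graph's nodes")
    ai = partition.area_of[graph.edge_i]
    aj = partition.area_of[graph.edge_j]
    intra = ai == aj
    n_areas = partition.n_areas
    s_k = np.bincount(ai[intra], weights=graph.weights[intra],
                      minlength=n_areas)
    l_k = (np.bincount(ai[~intra], weights=graph.weights[~intra],
                       minlength=n_areas)
           + np.bincount(aj[~intra], weights=graph.weights[~intra],
                         minlength=n_areas))
    l_all = float(l_k.sum())
    s_all = float(s_k.sum())
    if s_all == 0.0:
        logger.warning("S_all = 0 at density %.3f: Ratio undefined",
                       graph.density)
        ratio = math.nan
    else:
        ratio = l_all / s_all
    return ConnectionMetrics(graph.density, l_k, s_k, l_all, s_all, ratio)


def density_sweep(w: ConnectivityMatrix | np.ndarray,
                  partition: AreaPartition,
                  grid: tuple[float, ...] | None = None) -> DensitySweep:
    """Metrics over a density grid (default 6%..90% in 1% steps).

    The edges are sorted once and per-density sums are prefix sums over the
    sorted classification, so the sweep costs O(E log E + areas * E). The
    summary is the arithmetic mean of each metric over the grid (NaN ratios
    propagate to the summary ratio).
    """
    mat = w.w if isinstance(w, ConnectivityMatrix) else np.asarray(w)
    n = mat.shape[0]
    if grid is None:
        grid = tuple(round(d / 100.0, 2) for d in range(6, 91))
    if len(grid) == 0:
        raise ConfigError("empty density grid")
    for d in grid:
        if not 0 < d <= 1:
            raise ConfigError(f"grid density {d} outside (0, 1]")

    ii, jj, vals = _sorted_edges(mat)
    ai, aj = partition.area_of[ii], partition.area_of[jj]
    intra = ai == aj
    n_areas = partition.n_areas
    e = len(vals)
    s_cum = np.zeros((e + 1, n_areas))
    l_cum = np.zeros((e + 1, n_areas))
    s_contrib = np.zeros((e, n_areas))
    l_contrib = np.zeros((e, n_areas))
    rows = np.arange(e)
    s_contrib[rows[intra], ai[intra]] = vals[intra]
    l_contrib[rows[~intra], ai[~intra]] = vals[~intra]
    l_contrib[rows[~intra], aj[~intra]] += vals[~intra]
    s_cum[1:] = np.cumsum(s_contrib, axis=0)
    l_cum[1:] = np.cumsum(l_contrib, axis=0)

    out = []
    n_undefined = 0
    for d in grid:
        m = n_kept_edges(n, d)
        l_k, s_k = l_cum[m], s_cum[m]
        l_all, s_all = float(l_k.sum()), float(s_k.sum())
        if s_all == 0.0:
            n_undefined += 1
            ratio = math.nan
        else:
            ratio = l_all / s_all
        out.append(ConnectionMetrics(d, l_k, s_k, l_all, s_all, ratio))
    if n_undefined:
        logger.warning("Ratio undefined (S_all = 0) at %d of %d grid "
                       "densities; grid-mean Ratio uses the defined ones",
                       n_undefined, len(grid))

    # the grid mean of Ratio skips densities where it is undefined; every
    # other metric is a plain mean over the full grid
    summary = ConnectionMetrics(
        density=math.nan,
        l_k=np.mean([m.l_k for m in out], axis=0),
        s_k=np.mean([m.s_k for m in out], axis=0),
        l_all=float(np.mean([m.l_all for m in out])),
        s_all=float(np.mean([m.s_all for m in out])),
        ratio=float(np.nanmean([m.ratio for m in out])),
        labels={"summary": "grid mean", "grid": grid,
                "n_ratio_undefined": n_undefined})
    return DensitySweep(out, summary)
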