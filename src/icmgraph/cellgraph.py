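"""The Delaunay Cell Graph (DCG).

Cell neighbourhood is approximated by the Delaunay tetrahedralization
of the nuclear centroids, with edges longer than a cutoff (30 um by
default) removed: cells in direct contact or at close distance are
neighbours.  Downstream statistics are computed on the analysis cell
set — all ICM cells plus those TE cells that neighbour at least one
ICM cell.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError, distance_matrix

from .core_io import Embryo, Lineage

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_UM = 30.0


@dataclass
class CellGraph:
    """Pruned Delaunay adjacency over nucleus centroids.

    ``node_ids`` are cell ids in the order of ``positions``; ``edges``
    is a set of unordered index pairs (i < j), every edge no longer
    than ``cutoff`` micrometres.
    """

    node_ids: list
    positions: np.ndarray
    edges: set[tuple[int, int]]
    cutoff: float
    _adj: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self._adj is None:
            adj: dict = {i: set() for i in range(len(self.node_ids))}
            for i, j in self.edges:
                adj[i].add(j)
                adj[j].add(i)
            self._adj = adj

    def neighbors(self, node_id) -> list:
        """Neighbouring cell ids of ``node_id``."""
        i = self.node_ids.index(node_id)
        return [self.node_ids[j] for j in sorted(self._adj[i])]

    def neighbor_indices(self, i: int) -> set[int]:
        return self._adj[i]

    def degree(self, node_id) -> int:
        return len(self._adj[self.node_ids.index(node_id)])

    def edge_length(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.positions[i] - self.positions[j]))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def _delaunay_edge_indices(positions: np.ndarray) -> set[tuple[int, int]]:
    tri = Delaunay(positions)
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(len(simplex)):
            for b in range(a + 1, len(simplex)):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((min(i, j), max(i, j)))
    return edges


def _complete_edge_indices(positions: np.ndarray) -> set[tuple[int, int]]:
    n = len(positions)
    return {(i, j) for i in range(n) for j in range(i + 1, n)}


def build_cell_graph(
    positions: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF_UM,
    node_ids: list | None = None,
) -> CellGraph:
    """Build the DCG over nucleus centroids.

    Edges are the Delaunay-tetrahedralization edges of the point set
    with Euclidean length <= ``cutoff`` (ties at the cutoff are kept).
    Point sets too small or too degenerate for a 3D triangulation
    (fewer than 5 points, or coplanar/collinear configurations) fall
    back to the complete distance graph thresholded at the cutoff.

    Raises on duplicate positions (within 1e-6 um).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must be an (n, 3) array")
    if len(positions) == 0:
        raise ValueError("need at least one position")
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions must be finite")
    if node_ids is None:
        node_ids = list(range(len(positions)))
    if len(node_ids) != len(positions):
        raise ValueError("node_ids and positions disagree in length")

    dist = distance_matrix(positions, positions)
    np.fill_diagonal(dist, np.inf)
    dup = np.argwhere(dist < 1e-6)
    if dup.size:
        i, j = dup[0]
        raise ValueError(
            f"duplicate positions for nodes {node_ids[i]!r} and {node_ids[j]!r}"
        )

    if len(positions) < 5:
        edges = _complete_edge_indices(positions)
        logger.debug("fewer than 5 points: complete thresholded graph used")
    else:
        try:
            edges = _delaunay_edge_indices(positions)
        except QhullError:
            logger.info(
                "degenerate point configuration: falling back to the "
                "complete thresholded graph"
            )
            edges = _complete_edge_indices(positions)

    pruned = {(i, j) for (i, j) in edges if dist[i, j] <= cutoff}
    return CellGraph(node_ids=list(node_ids), positions=positions, edges=pruned, cutoff=cutoff)


def build_embryo_graph(embryo: Embryo, cutoff: float = DEFAULT_CUTOFF_UM) -> CellGraph:
    """DCG over all nuclei of an embryo, keyed by cell id."""
    return build_cell_graph(
        embryo.positions(), cutoff=cutoff, node_ids=[n.cell_id for n in embryo.nuclei]
    )


def select_analysis_cells(embryo: Embryo, graph: CellGraph) -> set:
    """Cells entering the neighbourhood analyses.

    All ICM cells plus those TE cells with at least one ICM graph
    neighbour.  Downstream statistics restrict to the subgraph induced
    by this set.
    """
    lineage = {n.cell_id: n.lineage for n in embryo.nuclei}
    index = {cid: i for i, cid in enumerate(graph.node_ids)}
    selected = {cid for cid, lin in lineage.items() if lin is Lineage.ICM}
    for cid, lin in lineage.items():
        if lin is Lineage.TE:
            neigh = graph.neighbor_indices(index[cid])
            if any(lineage[graph.node_ids[j]] is Lineage.ICM for j in neigh):
                selected.add(cid)
    return selected


def subgraph_degrees(graph: CellGraph, subset: set) -> dict:
    """Degree of each cell in ``subset`` within the induced subgraph."""
    index = {cid: i for i, cid in enumerate(graph.node_ids)}
    sub_idx = {index[cid] for cid in subset}
    degrees = {}
    for cid in subset:
        i = index[cid]
        degrees[cid] = len(graph.neighbor_indices(i) & sub_idx)
    return degrees


def icm_analysis_degrees(embryo: Embryo, cutoff: float = DEFAULT_CUTOFF_UM) -> dict:
    """Neighbour count of each ICM cell within the analysis subgraph.

    Builds the DCG over all nuclei, restricts to the analysis set (ICM
    plus ICM-adjacent TE) and returns cell_id -> degree for the ICM
    cells only.
    """
    graph = build_embryo_graph(embryo, cutoff)
    analysis = select_analysis_cells(embryo, graph)
    degrees = subgraph_degrees(graph, analysis)
    icm_ids = {n.cell_id for n in embryo.icm_nuclei()}
    return {cid: d for cid, d in degrees.items() if cid in icm_ids}


def degree_distribution(graph: CellGraph, subset: set | None = None):
    """Histogram of neighbour counts within the induced subgraph.

    Returns ``(histogram, modal_degree)`` where ``histogram`` maps
    degree -> number of cells; the histogram sums to ``len(subset)``.
    The modal degree is the smallest degree of maximal count, or None
    for an empty subset.
    """
    if subset is None:
        subset = set(graph.node_ids)
    if not subset:
        return Counter(), None
    degrees = subgraph_degrees(graph, subset)
    hist = Counter(degrees.values())
    modal = min(d for d, c in hist.items() if c == max(hist.values()))
    return hist, modal
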