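"""Monmonier's maximum-difference boundary detection on a Delaunay network.

Populations are nodes of a Delaunay triangulation of their planar
coordinates; each Delaunay edge carries a genetic distance.  Distances
are Edwards' Euclidean distance

    D = sqrt(1 - (1/L) sum_loci sum_alleles sqrt(x_a * y_a))

optionally denoised by a principal-coordinate projection that keeps only
the first axis (distances among axis-1 scores), so that boundary
tracing follows the dominant gradient rather than locus noise.

A boundary is traced through the Voronoi dual: starting at the
not-yet-crossed edge of maximal distance, it extends in both directions,
at each step crossing the admissible neighbouring edge (sharing a
triangle) of maximal distance above the threshold, and stops at the
convex hull, at a previously crossed edge, or when no admissible edge
remains.  Ties break on the lowest edge index, so runs are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .datasets import GenotypeDataset, MicrohapDataset
from .structure import affinity_tensor


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def edwards_distance(freqs_a: list[np.ndarray], freqs_b: list[np.ndarray]) -> float:
    """Edwards' distance between two populations from per-locus allele
    frequency vectors."""
    if len(freqs_a) != len(freqs_b) or not freqs_a:
        raise ValueError("need matching, non-empty per-locus frequency lists")
    aff = [float(np.sqrt(np.asarray(x) * np.asarray(y)).sum())
           for x, y in zip(freqs_a, freqs_b)]
    mean_aff = float(np.mean(aff))
    return float(np.sqrt(max(1.0 - mean_aff, 0.0)))


def edwards_matrix(data: GenotypeDataset | MicrohapDataset,
                   pops: list[str] | None = None) -> pd.DataFrame:
    aff, pops = affinity_tensor(data, pops)
    D = np.sqrt(np.maximum(1.0 - aff.mean(axis=0), 0.0))
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=pops, columns=pops)


def pcoa_first_axis(D: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Scale a distance matrix onto the first principal coordinate.

    Classical PCoA: double-centre ``-D^2/2``, eigendecompose, keep the
    axis of the leading eigenvalue; the scaled distance between two
    populations is the absolute difference of their axis-1 scores.
    """
    if isinstance(D, pd.DataFrame):
        ids = list(D.index)
        M = D.to_numpy(dtype=float)
    else:
        M = np.asarray(D, dtype=float)
        ids = [str(i) for i in range(M.shape[0])]
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    lead = np.argmax(vals)
    if vals[lead] <= 1e-12:
        raise ValueError("first PCoA eigenvalue is not positive "
                         "(degenerate configuration)")
    scores = vecs[:, lead] * np.sqrt(vals[lead])
    scaled = np.abs(scores[:, None] - scores[None, :])
    return pd.DataFrame(scaled, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Delaunay network + Monmonier traversal
# ---------------------------------------------------------------------------

@dataclass
class Boundary:
    """One traced boundary: the ordered edges it crosses."""

    rank: int
    edges: list[tuple[int, int]]
    seed_edge: tuple[int, int]
    seed_distance: float


@dataclass
class PopulationNetwork:
    """Delaunay connectivity among populations with per-edge distances."""

    populations: list[str]
    coords: np.ndarray                       # (P, 2)
    edges: list[tuple[int, int]]             # index pairs, i < j
    edge_distance: np.ndarray
    triangles: list[tuple[int, int, int]]
    boundaries: list[Boundary] = field(default_factory=list)
    threshold: float | None = None
    converged_at_run: int | None = None

    def edge_labels(self) -> list[tuple[str, str]]:
        return [(self.populations[i], self.populations[j]) for i, j in self.edges]

    def boundary_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.boundaries:
            for order, (i, j) in enumerate(b.edges):
                rows.append({"rank": b.rank, "order": order,
                             "pop_a": self.populations[i],
                             "pop_b": self.populations[j],
                             "distance": self.edge_distance[self.edges.index((i, j))]})
        return pd.DataFrame(rows, columns=["rank", "order", "pop_a", "pop_b", "distance"])


def delaunay_network(coords: pd.DataFrame, distances: pd.DataFrame
                     ) -> PopulationNetwork:
    """Build the Delaunay network over population coordinates.

    ``coords`` has columns population/x/y; ``distances`` is a square
    matrix over the same populations (any scaled genetic distance).
    """
    pops = list(coords["population"])
    pts = coords[["x", "y"]].to_numpy(dtype=float)
    if len(pops) < 3:
        raise ValueError("Delaunay triangulation needs at least 3 populations")
    tri = Delaunay(pts)
    edges = set()
    triangles = []
    for simplex in tri.simplices:
        a, b, c = sorted(int(v) for v in simplex)
        triangles.append((a, b, c))
        edges.update([(a, b), (a, c), (b, c)])
    edges = sorted(edges)
    D = distances.loc[pops, pops].to_numpy(dtype=float)
    dist = np.array([D[i, j] for i, j in edges])
    return PopulationNetwork(populations=pops, coords=pts, edges=edges,
                             edge_distance=dist, triangles=triangles)


def _edge_triangles(net: PopulationNetwork) -> dict[tuple[int, int], list[int]]:
    adj: dict[tuple[int, int], list[int]] = {e: [] for e in net.edges}
    for t_idx, (a, b, c) in enumerate(net.triangles):
        for e in [(a, b), (a, c), (b, c)]:
            adj[e].append(t_idx)
    return adj


def monmonier(network: PopulationNetwork, n_runs: int = 3,
              threshold: float | None = None,
              threshold_relax: float = 0.05,
              relax: bool = False) -> PopulationNetwork:
    """Trace up to ``n_runs`` maximum-difference boundaries.

    ``threshold`` defaults to the third quartile of the network's edge
    distances.  A run whose best remaining edge falls at or below the
    threshold records convergence and stops.  With ``relax=True`` the
    whole procedure repeats once with the threshold lowered by
    ``threshold_relax`` (probing shallow structure), appending any new
    boundaries.
    """
    net = network
    if threshold is None:
        threshold = float(np.percentile(net.edge_distance, 75))
    net.threshold = threshold
    crossed: set[tuple[int, int]] = set()
    net.boundaries = []
    rank = 0
    rank = _trace_runs(net, n_runs, threshold, crossed, rank)
    if relax:
        _trace_runs(net, n_runs, threshold * (1.0 - threshold_relax), crossed, rank)
    return net


def _trace_runs(net: PopulationNetwork, n_runs: int, threshold: float,
                crossed: set[tuple[int, int]], rank_start: int) -> int:
    edge_tris = _edge_triangles(net)
    edge_index = {e: k for k, e in enumerate(net.edges)}
    rank = rank_start
    for run in range(n_runs):
        candidates = [(k, e) for k, e in enumerate(net.edges)
                      if e not in crossed and net.edge_distance[k] > threshold]
        if not candidates:
            net.converged_at_run = rank + 1
            break
        k_seed, seed = max(candidates, key=lambda ke: (net.edge_distance[ke[0]], -ke[0]))
        rank += 1
        crossed.add(seed)
        path = [seed]
        visited_tris: set[int] = set()
        # extend in each dual direction (one per adjacent triangle)
        for t0 in edge_tris[seed]:
            side = _extend(net, edge_tris, edge_index, seed, t0, threshold,
                           crossed, visited_tris)
            if side:
                path = side[::-1] + path if t0 == edge_tris[seed][0] else path + side
        net.boundaries.append(Boundary(rank=rank, edges=path, seed_edge=seed,
                                       seed_distance=float(net.edge_distance[k_seed])))
    return rank


def _extend(net: PopulationNetwork, edge_tris, edge_index, entry: tuple[int, int],
            tri: int, threshold: float, crossed: set, visited: set) -> list:
    """Walk the Voronoi dual from ``entry`` through triangle ``tri``."""
    out: list[tuple[int, int]] = []
    current_edge, current_tri = entry, tri
    while True:
        if current_tri in visited:
            break
        visited.add(current_tri)
        a, b, c = net.triangles[current_tri]
        others = [e for e in [(a, b), (a, c), (b, c)] if e != current_edge]
        admissible = [e for e in others
                      if e not in crossed and net.edge_distance[edge_index[e]] > threshold]
        if not admissible:
            break
        nxt = max(admissible, key=lambda e: (net.edge_distance[edge_index[e]],
                                             -edge_index[e]))
        crossed.add(nxt)
        out.append(nxt)
        neighbours = [t for t in edge_tris[nxt] if t != current_tri]
        if not neighbours:          # hull edge: this direction terminates
            break
        current_edge, current_tri = nxt, neighbours[0]
    return out
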