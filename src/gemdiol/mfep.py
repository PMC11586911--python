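"""Minimum free-energy paths and stationary states on gridded surfaces.

On a discrete free-energy surface the minimum free-energy path (MFEP)
between two basins is taken as the 8-connected path minimising the
*maximum* free energy encountered (the minimax / watershed criterion);
among minimax-equal paths the one with the smallest summed free energy
is preferred.  The transition state (TS) is the profile maximum along
the path, the barrier is G(TS) − G(start), and the reactant (RS) and
product (gem-diol, GD) states are the path endpoints' basin minima.
Unsampled cells are impassable.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass

import numpy as np

__all__ = ["SurfacePath", "find_minima", "mfep", "label_states", "write_path"]

_NEIGHBORS_8 = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]
_NEIGHBORS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


@dataclass
class SurfacePath:
    """An ordered grid-node path with its free-energy profile and labels."""

    nodes: list[tuple[int, int]]  # grid indices
    coords: list[tuple[float, float]]  # (cv1, cv2) of each node
    profile: np.ndarray  # kcal/mol along the path
    barrier: float  # max(profile) − profile[0]
    stationary: dict[str, int] = None  # label -> position along path
    concerted: bool | None = None

    @property
    def ts_index(self) -> int:
        return int(np.argmax(self.profile))


def _grid_arrays(grid):
    """Accept a PMFResult or a raw 2D array (+ optional axes)."""
    if hasattr(grid, "free_energy"):
        return grid.free_energy, grid.cv1_centers, grid.cv2_centers
    g = np.asarray(grid, dtype=float)
    return g, np.arange(g.shape[0], dtype=float), np.arange(g.shape[1], dtype=float)


def _neighbors(connectivity: int):
    if connectivity == 8:
        return _NEIGHBORS_8
    if connectivity == 4:
        return _NEIGHBORS_4
    raise ValueError("connectivity must be 4 or 8")


def find_minima(grid, connectivity: int = 8):
    """Local minima of an occupied grid: cells (or equal-value plateau
    basins) strictly below all occupied neighbours.

    Plateaus collapse to their lowest-row-major-index cell.  Returns a
    list of ``((i, j), value)`` sorted by value.
    """
    g, _, _ = _grid_arrays(grid)
    occ = np.isfinite(g)
    if not occ.any():
        raise ValueError("grid has no occupied cells")
    nbrs = _neighbors(connectivity)
    n1, n2 = g.shape
    visited = np.zeros_like(occ)
    minima = []
    for i in range(n1):
        for j in range(n2):
            if not occ[i, j] or visited[i, j]:
                continue
            # flood-fill the equal-value plateau containing (i, j)
            value = g[i, j]
            stack = [(i, j)]
            component = []
            visited[i, j] = True
            is_min = True
            while stack:
                a, b = stack.pop()
                component.append((a, b))
                for da, db in nbrs:
                    x, y = a + da, b + db
                    if not (0 <= x < n1 and 0 <= y < n2) or not occ[x, y]:
                        continue
                    if g[x, y] == value:
                        if not visited[x, y]:
                            visited[x, y] = True
                            stack.append((x, y))
                    elif g[x, y] < value:
                        is_min = False
            if is_min:
                rep = min(component)  # lowest row-major index
                minima.append((rep, float(value)))
    minima.sort(key=lambda t: (t[1], t[0]))
    return minima


def mfep(grid, start: tuple[int, int], end: tuple[int, int], connectivity: int = 8) -> SurfacePath:
    """Minimax (bottleneck) path from *start* to *end* grid nodes.

    Runs a Dijkstra-type search whose node cost is the lexicographic
    pair (maximum free energy so far, summed free energy so far), which
    yields the path minimising the highest point crossed and, among
    those, the lowest-lying one.  Raises ``ValueError`` when the
    endpoints are not connected through occupied cells.
    """
    g, c1, c2 = _grid_arrays(grid)
    occ = np.isfinite(g)
    for name, node in (("start", start), ("end", end)):
        if not occ[node]:
            raise ValueError(f"{name} node {node} is unsampled")
    nbrs = _neighbors(connectivity)
    n1, n2 = g.shape

    best: dict[tuple[int, int], tuple[float, float]] = {}
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    start_cost = (float(g[start]), float(g[start]))
    best[start] = start_cost
    heap = [(start_cost[0], start_cost[1], start)]
    while heap:
        cmax, csum, node = heapq.heappop(heap)
        if (cmax, csum) > best.get(node, (np.inf, np.inf)):
            continue
        if node == end:
            break
        for da, db in nbrs:
            x, y = node[0] + da, node[1] + db
            if not (0 <= x < n1 and 0 <= y < n2) or not occ[x, y]:
                continue
            cand = (max(cmax, float(g[x, y])), csum + float(g[x, y]))
            if cand < best.get((x, y), (np.inf, np.inf)):
                best[(x, y)] = cand
                parent[(x, y)] = node
                heapq.heappush(heap, (cand[0], cand[1], (x, y)))

    if end not in best:
        raise ValueError(f"no occupied corridor connects {start} and {end}")

    nodes = [end]
    while nodes[-1] != start:
        nodes.append(parent[nodes[-1]])
    nodes.reverse()
    profile = np.array([g[n] for n in nodes])
    coords = [(float(c1[i]), float(c2[j])) for i, j in nodes]
    return SurfacePath(
        nodes=nodes,
        coords=coords,
        profile=profile,
        barrier=float(profile.max() - profile[0]),
    )


def label_states(path: SurfacePath, grid=None) -> SurfacePath:
    """Label RS (start), GD (end) and TS (profile maximum between them).

    Also reports concertedness: the mechanism is concerted when no local
    minimum of the path profile lies strictly between RS and TS (no
    intermediate forms before the barrier is crossed).
    """
    if len(path.nodes) == 0:
        raise ValueError("empty path")
    p = path.profile
    ts = int(np.argmax(p))
    path.stationary = {"RS": 0, "TS": ts, "GD": len(p) - 1}
    concerted = True
    for k in range(1, ts):
        if p[k] < p[k - 1] and p[k] < p[k + 1]:
            concerted = False
            break
    path.concerted = concerted
    return path


def write_path(path: SurfacePath, tsv_path, json_path=None) -> None:
    """Path as `step cv1 cv2 free_energy label` TSV; summary as JSON."""
    labels = {}
    if path.stationary:
        labels = {v: k for k, v in path.stationary.items()}
    with open(tsv_path, "w") as fh:
        fh.write("step\tcv1\tcv2\tfree_energy\tlabel\n")
        for step, ((a, b), g) in enumerate(zip(path.coords, path.profile)):
            fh.write(f"{step}\t{a:.6f}\t{b:.6f}\t{g:.6f}\t{labels.get(step, '-')}\n")
    if json_path is not None:
        summary = {
            "barrier_kcal_mol": path.barrier,
            "concerted": path.concerted,
        }
        if path.stationary:
            for name, k in path.stationary.items():
                summary[name.lower()] = {
                    "cv1": path.coords[k][0],
                    "cv2": path.coords[k][1],
                    "free_energy": float(path.profile[k]),
                }
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")
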