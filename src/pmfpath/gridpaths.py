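"""Minimum-(free-)energy paths on gridded 2D surfaces.

The gridded surface is turned into a weighted graph: occupied bins are
nodes, each node has edges to its nearest neighbours (connectivity 4 by
default, 8 optional), and the edge weight is the *higher* of the two node
energies.  The minimum path between two states (by default the two lowest
distinct local minima of the grid) is found with Dijkstra's algorithm on
summed edge weights, with deterministic lexicographic tie-breaking.  The
profile along the path uses the accumulated Euclidean path length between
bin centers as the canonical reaction coordinate; stationary states along
it are labeled alternately (minima/maxima), the barrier being the energy
of the highest transition state relative to the chosen reference minimum.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .grids import EnergyGrid, PMFGrid, bin_centers

__all__ = [
    "WeightedGridGraph",
    "GridPath",
    "StationaryReport",
    "grid_to_graph",
    "shortest_path",
    "profile_along_path",
    "locate_states",
    "find_grid_minima",
]

_NEIGHBOURS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
_NEIGHBOURS_8 = _NEIGHBOURS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


@dataclass
class WeightedGridGraph:
    """Occupied grid bins as nodes; max-of-endpoints edge weights."""

    energies: dict            # (i, j) -> node energy
    adjacency: dict           # (i, j) -> list of ((i2, j2), weight)
    centers: tuple            # per-axis bin-center arrays
    connectivity: int = 4
    axis_names: tuple = ()

    @property
    def n_nodes(self) -> int:
        return len(self.energies)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.adjacency.values()) // 2


@dataclass
class GridPath:
    """An ordered bin sequence with its energy profile."""

    nodes: list               # [(i, j), ...]
    coordinates: np.ndarray   # (n, 2) rc values at bin centers, Å
    energies: np.ndarray      # per-node energies, kcal/mol
    lengths: np.ndarray       # accumulated Euclidean length, starts at 0
    total_weight: float       # summed edge weights (Dijkstra objective)
    axis_names: tuple = ()


@dataclass
class StationaryReport:
    """Labeled extrema along a profile plus barrier and reaction energy."""

    states: list = field(default_factory=list)  # dicts: label, position, index, energy, coordinates
    reference: str = ""
    barrier: float | None = None
    reaction_energy: float | None = None
    no_transition_state: bool = False


def _grid_arrays(grid):
    if isinstance(grid, (PMFGrid, EnergyGrid)):
        values = grid.values
        mask = grid.mask if isinstance(grid, PMFGrid) else np.isfinite(grid.values)
        centers = grid.centers
        names = grid.axis_names
    else:
        values = np.asarray(grid, dtype=float)
        mask = np.isfinite(values)
        centers = tuple(np.arange(n, dtype=float) for n in values.shape)
        names = ()
    return values, mask, centers, names


def grid_to_graph(grid, connectivity: int = 4) -> WeightedGridGraph:
    """Convert a 2D energy grid into the max-edge weighted graph.

    ``grid`` may be a :class:`PMFGrid`, an :class:`EnergyGrid`, or a bare
    2D array (NaN = masked).  Masked bins are excluded.
    """
    values, mask, centers, names = _grid_arrays(grid)
    if values.ndim != 2:
        raise ValueError("grid must be 2D")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    offs = _NEIGHBOURS_4 if connectivity == 4 else _NEIGHBOURS_8
    occupied = np.argwhere(mask)
    if len(occupied) < 2:
        raise ValueError("need at least 2 occupied bins")
    energies = {(int(ix[0]), int(ix[1])): float(values[tuple(ix)]) for ix in occupied}
    adjacency = {n: [] for n in energies}
    ni, nj = values.shape
    for (i, j), e in energies.items():
        for di, dj in offs:
            nb = (i + di, j + dj)
            if 0 <= nb[0] < ni and 0 <= nb[1] < nj and nb in energies:
                adjacency[(i, j)].append((nb, max(e, energies[nb])))
    return WeightedGridGraph(energies=energies, adjacency=adjacency,
                             centers=tuple(centers), connectivity=connectivity,
                             axis_names=tuple(names))


def shortest_path(graph: WeightedGridGraph, start, end,
                  objective: str = "sum") -> GridPath:
    """Dijkstra minimum path from ``start`` to ``end`` bins.

    ``objective="sum"`` minimizes the total of the max-of-endpoints edge
    weights (the default reading of a shortest path on the weighted graph;
    requires non-negative weights, i.e. a min-shifted energy grid).
    ``objective="minimax"`` minimizes the highest edge weight crossed — the
    bottleneck path, whose peak is guaranteed to sit at the lowest possible
    crossing (the connecting saddle on a gridded surface).

    Ties are broken deterministically: the priority queue orders by
    (distance, node) so equal-distance nodes pop in lexicographic order.
    Raises ``ValueError`` if either endpoint is unoccupied or no path
    exists.
    """
    start, end = tuple(start), tuple(end)
    if start == end:
        raise ValueError("start and end must differ")
    if objective not in ("sum", "minimax"):
        raise ValueError(f"unknown objective {objective!r}")
    for n in (start, end):
        if n not in graph.energies:
            raise ValueError(f"bin {n} is not an occupied node")
    if objective == "sum" and min(graph.energies.values()) < 0:
        raise ValueError(
            "summed-weight path requires non-negative energies; min-shift the grid")
    combine = (lambda d, w: d + w) if objective == "sum" else (lambda d, w: max(d, w))
    dist = {start: 0.0}
    pred: dict = {}
    done = set()
    heap = [(0.0, start)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == end:
            break
        for v, w in graph.adjacency[u]:
            nd = combine(d, w)
            if v not in dist or nd < dist[v] or (nd == dist[v] and u < pred.get(v, (np.inf,))):
                if v not in done:
                    dist[v] = nd
                    pred[v] = u
                    heapq.heappush(heap, (nd, v))
    if end not in done:
        raise ValueError(f"no path between {start} and {end}: grid is disconnected")
    nodes = [end]
    while nodes[-1] != start:
        nodes.append(pred[nodes[-1]])
    nodes.reverse()
    return _assemble_path(graph, nodes, dist[end])


def _assemble_path(graph: WeightedGridGraph, nodes, total_weight) -> GridPath:
    cx, cy = graph.centers
    coords = np.array([[cx[i], cy[j]] for i, j in nodes])
    energies = np.array([graph.energies[n] for n in nodes])
    seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    lengths = np.concatenate([[0.0], np.cumsum(seg)])
    return GridPath(nodes=list(nodes), coordinates=coords, energies=energies,
                    lengths=lengths, total_weight=float(total_weight),
                    axis_names=graph.axis_names)


def profile_along_path(path: GridPath) -> tuple[np.ndarray, np.ndarray]:
    """(accumulated length, energy) profile; length starts at 0."""
    if len(path.nodes) == 0:
        raise ValueError("empty path")
    return path.lengths.copy(), path.energies.copy()


def find_grid_minima(grid, connectivity: int = 4) -> list[tuple]:
    """Grid-local minima (strictly ≤ all occupied neighbours), sorted by energy."""
    values, mask, _, _ = _grid_arrays(grid)
    offs = _NEIGHBOURS_4 if connectivity == 4 else _NEIGHBOURS_8
    ni, nj = values.shape
    out = []
    for i, j in np.argwhere(mask):
        e = values[i, j]
        is_min = True
        for di, dj in offs:
            a, b = i + di, j + dj
            if 0 <= a < ni and 0 <= b < nj and mask[a, b] and values[a, b] < e:
                is_min = False
                break
        if is_min:
            out.append(((int(i), int(j)), float(e)))
    out.sort(key=lambda t: (t[1], t[0]))
    return [n for n, _ in out]


def minimum_energy_path(grid, connectivity: int = 4, start=None, end=None,
                        objective: str = "sum") -> GridPath:
    """Convenience wrapper: graph + Dijkstra between the two lowest distinct
    local minima of the grid (or explicit ``start``/``end`` bin indices)."""
    graph = grid_to_graph(grid, connectivity)
    if start is None or end is None:
        minima = find_grid_minima(grid, connectivity)
        if len(minima) < 2:
            raise ValueError("fewer than two local minima on the grid; "
                             "specify start and end explicitly")
        start = start if start is not None else minima[0]
        end = end if end is not None else minima[1]
    return shortest_path(graph, start, end, objective=objective)


def locate_states(
    profile,
    energies=None,
    smoothing_window: int = 0,
    reference: str | int = "first_minimum",
    plateau_tol: float = 0.0,
    coordinates=None,
) -> StationaryReport:
    """Label stationary states along an energy profile.

    ``profile`` may be a :class:`GridPath` or an array of path positions
    (then ``energies`` must be given).  Interior strict local extrema are
    labeled alternately; runs of equal values (within ``plateau_tol``) are
    collapsed to their midpoint.  Endpoints are labeled as minima of their
    side.  The barrier is E(highest TS) − E(reference); the reaction energy
    is E(last minimum) − E(reference).  ``reference`` is the first labeled
    minimum by default (the state the transfer starts from).  A profile
    with no interior maximum gets ``no_transition_state=True``.
    """
    if isinstance(profile, GridPath):
        pos, e = profile.lengths, profile.energies
        coordinates = profile.coordinates
    else:
        pos = np.asarray(profile, dtype=float)
        e = np.asarray(energies, dtype=float)
    if len(pos) < 3:
        raise ValueError("profile needs at least 3 points")
    if smoothing_window > 1:
        k = int(smoothing_window)
        pad = k // 2
        padded = np.concatenate([np.repeat(e[0], pad), e, np.repeat(e[-1], pad)])
        kernel = np.ones(k) / k
        e = np.convolve(padded, kernel, mode="valid")[: len(e)]

    # collapse plateau runs to their midpoint index
    keep = [0]
    run_start = 0
    for i in range(1, len(e)):
        if abs(e[i] - e[run_start]) > plateau_tol:
            if i - 1 > run_start:  # collapse the finished plateau run
                keep[-1] = (run_start + i - 1) // 2
            keep.append(i)
            run_start = i
    if len(e) - 1 > run_start:
        keep[-1] = (run_start + len(e) - 1) // 2
    idx = np.array(keep)
    ec = e[idx]

    extrema = []  # (index into idx, kind)
    for k in range(1, len(ec) - 1):
        if ec[k] > ec[k - 1] and ec[k] > ec[k + 1]:
            extrema.append((k, "max"))
        elif ec[k] < ec[k - 1] and ec[k] < ec[k + 1]:
            extrema.append((k, "min"))

    states = []

    def _state(label, k):
        i = int(idx[k])
        s = {"label": label, "index": i, "position": float(pos[i]), "energy": float(e[i])}
        if coordinates is not None:
            s["coordinates"] = tuple(float(c) for c in np.atleast_1d(coordinates[i]))
        return s

    n_min = 0
    n_ts = 0
    # endpoint start counts as the initial minimum unless profile descends into it
    if not extrema or extrema[0][1] == "max":
        states.append(_state("reactant", 0))
        n_min += 1
    for k, kind in extrema:
        if kind == "min":
            n_min += 1
            label = f"IM{n_min - 1}" if n_min > 1 else "reactant"
            states.append(_state(label, k))
        else:
            n_ts += 1
            states.append(_state(f"TS{n_ts}", k))
    # final endpoint: product
    states.append(_state("product", len(ec) - 1))

    report = StationaryReport(states=states)
    ts_states = [s for s in states if s["label"].startswith("TS")]
    min_states = [s for s in states if not s["label"].startswith("TS")]
    if not ts_states:
        report.no_transition_state = True
        report.reference = min_states[0]["label"]
        report.reaction_energy = min_states[-1]["energy"] - min_states[0]["energy"]
        return report
    if reference == "first_minimum":
        ref_state = min_states[0]
    elif isinstance(reference, int):
        ref_state = states[reference]
    else:
        ref_state = next(s for s in states if s["label"] == reference)
    report.reference = ref_state["label"]
    highest_ts = max(ts_states, key=lambda s: s["energy"])
    report.barrier = highest_ts["energy"] - ref_state["energy"]
    report.reaction_energy = min_states[-1]["energy"] - ref_state["energy"]
    return report
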