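"""Max-edge grid graphs, Dijkstra paths, profiles, stationary reports."""

import itertools

import numpy as np
import pytest

from pmfpath import (
    find_grid_minima,
    grid_to_graph,
    locate_states,
    minimum_energy_path,
    profile_along_path,
    shortest_path,
)
from pmfpath.grids import PMFGrid


def brute_force_optimum(grid, start, end):
    """Exhaustive minimum total max-edge weight over all simple paths
    (DFS with admissible pruning: weights are non-negative)."""
    graph = grid_to_graph(grid)
    best = [np.inf]

    def dfs(u, visited, w):
        if w >= best[0]:
            return
        if u == end:
            best[0] = w
            return
        for v, ew in graph.adjacency[u]:
            if v not in visited:
                visited.add(v)
                dfs(v, visited, w + ew)
                visited.remove(v)

    dfs(start, {start}, 0.0)
    return best[0]


class TestGraph:
    def test_two_bin_edge_takes_max(self):
        g = grid_to_graph(np.array([[1.0, 3.0]]))
        assert g.n_nodes == 2
        assert g.n_edges == 1
        assert g.adjacency[(0, 0)][0][1] == 3.0

    def test_2x2_uniform_four_edges(self):
        g = grid_to_graph(np.full((2, 2), 7.0))
        assert g.n_edges == 4
        assert all(w == 7.0 for nbrs in g.adjacency.values() for _, w in nbrs)

    def test_every_edge_weight_is_max_of_endpoints(self, rng):
        vals = rng.uniform(0, 10, (3, 3))
        g = grid_to_graph(vals, connectivity=8)
        for u, nbrs in g.adjacency.items():
            for v, w in nbrs:
                assert w == max(vals[u], vals[v])

    def test_masked_bins_excluded(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0]])
        g = grid_to_graph(vals)
        assert (0, 1) not in g.energies
        assert g.n_nodes == 3


class TestDijkstra:
    def test_forced_detour_through_low_node(self):
        grid = np.array([[0.0, 1.0], [10.0, 0.0]])
        p = shortest_path(grid_to_graph(grid), (0, 0), (1, 1))
        assert p.nodes == [(0, 0), (0, 1), (1, 1)]
        assert p.total_weight == pytest.approx(2.0)

    def test_flat_grid_weight_is_manhattan_distance(self):
        e = 2.5
        grid = np.full((4, 5), e)
        p = shortest_path(grid_to_graph(grid), (0, 0), (3, 4))
        assert p.total_weight == pytest.approx(e * 7)

    def test_disconnected_raises(self):
        vals = np.array([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="no path"):
            shortest_path(grid_to_graph(vals), (0, 0), (1, 1))

    def test_identical_inputs_give_identical_paths(self, rng):
        vals = rng.integers(0, 5, (6, 6)).astype(float)
        g = grid_to_graph(vals)
        p1 = shortest_path(g, (0, 0), (5, 5))
        p2 = shortest_path(g, (0, 0), (5, 5))
        assert p1.nodes == p2.nodes

    def test_matches_brute_force_on_small_grids(self):
        """Exhaustive-enumeration oracle across every grid shape up to 4x4,
        seeded integer energies 0-9."""
        rng = np.random.default_rng(42)
        for ni, nj in itertools.product(range(1, 5), range(1, 5)):
            if ni * nj < 2:
                continue
            for _ in range(10):
                vals = rng.integers(0, 10, (ni, nj)).astype(float)
                start, end = (0, 0), (ni - 1, nj - 1)
                p = shortest_path(grid_to_graph(vals), start, end)
                assert p.total_weight == pytest.approx(
                    brute_force_optimum(vals, start, end))

    def test_total_weight_matches_networkx_dijkstra(self, rng):
        """Independent library cross-check of the summed-weight optimum."""
        import networkx as nx

        for seed in range(10):
            vals = np.random.default_rng(seed).integers(0, 10, (6, 6)).astype(float)
            g = grid_to_graph(vals)
            G = nx.Graph()
            for u, nbrs in g.adjacency.items():
                for v, w in nbrs:
                    G.add_edge(u, v, weight=w)
            p = shortest_path(g, (0, 0), (5, 5))
            assert p.total_weight == pytest.approx(
                nx.dijkstra_path_length(G, (0, 0), (5, 5)))

    def test_constant_shift_preserves_path_and_shifts_weight(self, rng):
        vals = rng.uniform(0, 5, (5, 5))
        p1 = shortest_path(grid_to_graph(vals), (0, 0), (4, 4))
        p2 = shortest_path(grid_to_graph(vals + 11.0), (0, 0), (4, 4))
        assert p1.nodes == p2.nodes
        n_edges = len(p1.nodes) - 1
        assert p2.total_weight == pytest.approx(p1.total_weight + 11.0 * n_edges)

    def test_raising_one_node_never_lowers_optimum(self, rng):
        vals = rng.uniform(0, 5, (4, 4))
        base = shortest_path(grid_to_graph(vals), (0, 0), (3, 3)).total_weight
        for _ in range(5):
            i, j = rng.integers(0, 4, 2)
            bumped = vals.copy()
            bumped[i, j] += rng.uniform(0, 5)
            w = shortest_path(grid_to_graph(bumped), (0, 0), (3, 3)).total_weight
            assert w >= base - 1e-12


class TestProfile:
    def test_collinear_path_lengths(self):
        edges = (np.arange(0, 0.1001, 0.02), np.arange(0, 0.0401, 0.02))
        vals = np.zeros((5, 2))
        pmf = PMFGrid(edges, vals, np.ones_like(vals, bool), ("a", "b"), 300.0)
        p = shortest_path(grid_to_graph(pmf), (0, 0), (2, 0))
        lengths, energies = profile_along_path(p)
        assert np.allclose(lengths, [0.0, 0.02, 0.04])

    def test_diagonal_step_connectivity_8(self):
        edges = (np.arange(0, 0.0601, 0.02), np.arange(0, 0.0601, 0.02))
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 50.0  # force the diagonal
        pmf = PMFGrid(edges, vals, np.ones_like(vals, bool), ("a", "b"), 300.0)
        p = shortest_path(grid_to_graph(pmf, connectivity=8), (0, 0), (1, 1))
        lengths, _ = profile_along_path(p)
        assert lengths[1] - lengths[0] == pytest.approx(0.02 * np.sqrt(2))

    def test_lengths_strictly_increasing(self, rng):
        vals = rng.uniform(0, 3, (6, 6))
        p = shortest_path(grid_to_graph(vals), (0, 0), (5, 5))
        assert np.all(np.diff(p.lengths) > 0)


class TestLocateStates:
    def test_single_barrier_convention(self):
        """A (0, 5.4, -6.8) profile reads as barrier 5.4 and reaction energy
        -6.8 relative to the starting minimum."""
        rep = locate_states(np.array([0.0, 1.0, 2.0]), np.array([0.0, 5.4, -6.8]))
        assert rep.barrier == pytest.approx(5.4)
        assert rep.reaction_energy == pytest.approx(-6.8)
        assert [s["label"] for s in rep.states] == ["reactant", "TS1", "product"]

    def test_monotone_profile_flags_no_ts(self):
        rep = locate_states(np.arange(4.0), np.array([0.0, 1.0, 2.0, 3.0]))
        assert rep.no_transition_state
        assert [s["label"] for s in rep.states] == ["reactant", "product"]

    def test_barrier_uses_highest_transition_state(self):
        rep = locate_states(np.arange(5.0), np.array([0.0, 3.0, 1.0, 7.0, -2.0]))
        assert rep.barrier == pytest.approx(7.0)
        labels = [s["label"] for s in rep.states]
        assert labels == ["reactant", "TS1", "IM1", "TS2", "product"]

    def test_plateau_collapsed_to_midpoint(self):
        rep = locate_states(np.arange(5.0), np.array([0.0, 2.0, 2.0, 2.0, 0.0]))
        ts = [s for s in rep.states if s["label"] == "TS1"]
        assert len(ts) == 1
        assert ts[0]["index"] == 2

    def test_labels_alternate_min_max(self, rng):
        e = np.array([0.0, 4.0, 1.0, 5.0, 2.0, 6.0, -1.0])
        rep = locate_states(np.arange(float(len(e))), e)
        kinds = ["min" if not s["label"].startswith("TS") else "max"
                 for s in rep.states]
        for a, b in zip(kinds, kinds[1:]):
            assert a != b

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            locate_states(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


class TestOnSurfaces:
    @pytest.mark.parametrize("form", ["psp_step1_like", "psp_step2_like"])
    def test_mep_peak_near_true_saddle(self, form):
        """On the analytic surfaces gridded at 0.02 Å the bottleneck
        (minimax) path's highest point lies within one bin of the landscape
        report's connecting saddle; the summed-weight path must cross the
        ridge at or above that saddle energy."""
        from pmfpath import LandscapeSpec, stationary_points
        from pmfpath.landscapes import _potential_raw

        spec = LandscapeSpec(form)
        report = stationary_points(spec, resolution=0.05)
        saddles = [s for s in report if s.kind == "saddle"]
        axes = [np.arange(lo, hi + 1e-12, 0.02) for lo, hi in spec.domain]
        edges = [np.concatenate([a - 0.01, [a[-1] + 0.01]]) for a in axes]
        mesh = np.meshgrid(*axes, indexing="ij")
        vals = _potential_raw(spec, np.stack([m.ravel() for m in mesh], axis=-1))
        vals = vals.reshape(mesh[0].shape)
        shift = vals.min()
        vals = vals - shift
        pmf = PMFGrid(tuple(edges), vals, np.ones_like(vals, bool),
                      spec.axis_names, 300.0)
        path = minimum_energy_path(pmf, objective="minimax")
        peak = path.coordinates[np.argmax(path.energies)]
        dists = [np.linalg.norm(peak - np.array(s.position)) for s in saddles]
        assert min(dists) <= 0.02 * np.sqrt(2) + 1e-9
        lowest_saddle = min(s.energy for s in saddles) - shift
        summed = minimum_energy_path(pmf, objective="sum")
        assert summed.energies.max() >= lowest_saddle - 0.05

    def test_default_endpoints_are_two_lowest_minima(self, rng):
        vals = np.full((7, 7), 5.0)
        vals[1, 1] = 0.0
        vals[5, 5] = 0.5
        vals[3, 3] = 1.0  # shallow third minimum
        path = minimum_energy_path(vals)
        assert path.nodes[0] == (1, 1)
        assert path.nodes[-1] == (5, 5)
        assert find_grid_minima(vals)[:2] == [(1, 1), (5, 5)]
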