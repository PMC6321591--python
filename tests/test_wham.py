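"""WHAM: histogram conventions, fixed point, block errors, MBAR cross-check."""

import numpy as np
import pytest
from scipy.special import logsumexp

from pmfpath import (
    BiasWindow,
    LandscapeSpec,
    SampleSeries,
    analytic_pmf,
    block_error,
    build_histograms,
    build_window_grid,
    derive_window_seed,
    sample_windows,
    solve_wham,
)
from pmfpath.constants import KB_KCAL
from pmfpath.sampling import PRODUCTION, bias_energy


def _grid_windows(lo, hi, spacing, n_prod, seed_base, n_equil=1000):
    wins = build_window_grid([(lo, hi)], spacing, n_equil_steps=n_equil,
                             n_prod_steps=n_prod)
    return [BiasWindow(w.window_id, w.centers, w.force_constants,
                       w.n_equil_steps, w.n_prod_steps, w.temperature,
                       seed=derive_window_seed(seed_base, i))
            for i, w in enumerate(wins)]


@pytest.fixture(scope="module")
def harmonic_recovery():
    """Shared umbrella dataset on the stiffness-10 harmonic well."""
    spec = LandscapeSpec("harmonic", {"stiffness": 10.0},
                         domain=((-1.5, 1.5),), axis_names=("x",))
    windows = _grid_windows(-1.0, 1.0, 0.1, 51_000, seed_base=7)
    series = sample_windows(spec, windows)
    edges = np.arange(-1.0, 1.0 + 1e-12, 0.02)
    return spec, windows, series, edges


class TestHistograms:
    def test_single_series_single_bin(self):
        w = BiasWindow("w", (0.05,))
        s = SampleSeries("w", np.full((100, 1), 0.05))
        hist = build_histograms([s], [w], np.array([0.0, 0.1]))
        assert hist.counts.shape == (1, 1)
        assert hist.counts[0, 0] == 100

    def test_left_closed_edge_convention(self):
        """Bins are [a, b): a value just below an inner edge lands left of
        it, the edge value itself lands right."""
        w = BiasWindow("w", (0.1,))
        eps = 1e-9
        s = SampleSeries("w", np.array([[0.1 - eps], [0.1]]))
        hist = build_histograms([s], [w], np.array([0.0, 0.1, 0.2]))
        assert hist.counts[0, 0] == 1
        assert hist.counts[0, 1] == 1

    def test_out_of_range_dropped_and_counted(self):
        w = BiasWindow("w", (0.05,))
        s = SampleSeries("w", np.array([[0.05], [0.5]]))
        hist = build_histograms([s], [w], np.array([0.0, 0.1]))
        assert hist.counts.sum() == 1
        assert hist.n_dropped == 1

    def test_counts_conserved_total(self, rng):
        w = BiasWindow("w", (0.5,))
        vals = rng.uniform(0, 1, size=(500, 1))
        s = SampleSeries("w", vals)
        hist = build_histograms([s], [w], np.linspace(0, 1 + 1e-9, 21))
        assert hist.counts.sum() == 500

    def test_mismatched_window_id_rejected(self):
        s = SampleSeries("orphan", np.zeros((5, 1)) + 0.05)
        with pytest.raises(ValueError, match="orphan"):
            build_histograms([s], [BiasWindow("w", (0.05,))], np.array([0.0, 0.1]))


class TestSolveWham:
    def test_zero_bias_degenerates_to_histogram_estimator(self, rng):
        w = BiasWindow("w", (0.5,), force_constants={"equilibration": 1000.0,
                                                     "production": 1e-12})
        vals = rng.uniform(0, 1, size=(2000, 1))
        s = SampleSeries("w", vals)
        edges = np.linspace(0, 1 + 1e-9, 11)
        hist = build_histograms([s], [w], edges)
        pmf = solve_wham(hist)
        kT = KB_KCAL * 300.0
        counts = hist.counts[0]
        expect = -kT * np.log(counts)
        expect -= expect.min()
        assert np.allclose(pmf.values, expect, atol=1e-9)

    def test_invariant_under_dataset_duplication(self, harmonic_recovery):
        spec, windows, series, edges = harmonic_recovery
        sub_w, sub_s = windows[:6], series[:6]
        h1 = build_histograms(sub_s, sub_w, edges)
        pmf1 = solve_wham(h1)
        dup_w = sub_w + [BiasWindow(w.window_id + "_b", w.centers, w.force_constants,
                                    w.n_equil_steps, w.n_prod_steps, w.temperature,
                                    w.seed) for w in sub_w]
        dup_s = sub_s + [SampleSeries(s.window_id + "_b", s.values, s.stride)
                         for s in sub_s]
        pmf2 = solve_wham(build_histograms(dup_s, dup_w, edges))
        m = pmf1.mask & pmf2.mask
        assert np.allclose(pmf1.values[m], pmf2.values[m], atol=5e-5)

    def test_invariant_under_window_ordering(self, harmonic_recovery):
        spec, windows, series, edges = harmonic_recovery
        pmf1 = solve_wham(build_histograms(series, windows, edges))
        order = np.random.default_rng(0).permutation(len(windows))
        pmf2 = solve_wham(build_histograms([series[i] for i in order],
                                           [windows[i] for i in order], edges))
        m = pmf1.mask & pmf2.mask
        assert np.allclose(pmf1.values[m], pmf2.values[m], atol=1e-4)

    def test_invariant_under_constant_bias_offset(self, harmonic_recovery, monkeypatch):
        """Adding the same constant to every window's bias leaves F unchanged
        (the constant is absorbed into the shifts f_i)."""
        import pmfpath.wham as wham_mod

        spec, windows, series, edges = harmonic_recovery
        hist = build_histograms(series, windows, edges)
        pmf1 = solve_wham(hist)

        const = 3.7
        orig = wham_mod._bias_matrix
        monkeypatch.setattr(wham_mod, "_bias_matrix", lambda h: orig(h) + const)
        pmf2 = solve_wham(hist)
        m = pmf1.mask & pmf2.mask
        assert np.allclose(pmf1.values[m], pmf2.values[m], atol=1e-6)
        f1 = np.array(list(pmf1.window_shifts.values()))
        f2 = np.array(list(pmf2.window_shifts.values()))
        # shifts are gauge-fixed at f_1 = 0, so the constant cancels there too
        assert np.allclose(f1, f2, atol=1e-6)

    def test_recovers_analytic_pmf_on_harmonic_well(self, harmonic_recovery):
        spec, windows, series, edges = harmonic_recovery
        pmf = solve_wham(build_histograms(series, windows, edges))
        ref = analytic_pmf(spec, [0], edges, 300.0)
        sel = pmf.mask & (ref.values <= 4.0)
        rms = np.sqrt(np.mean((pmf.values[sel] - ref.values[sel]) ** 2))
        assert pmf.converged
        assert rms <= 0.15

    def test_basin_positions_recovered_on_step1_surface(self, step1_surface):
        """1D umbrella runs along the P-O coordinate of the 2D step-1-like
        surface's own 1D analogue: recovered minima match the landscape
        report within one bin width."""
        spec = LandscapeSpec("double_well_1d", {"h": 3.0, "a": 1.0})
        windows = _grid_windows(-1.4, 1.4, 0.1, 24_000, seed_base=21)
        series = sample_windows(spec, windows)
        # bin width chosen so the curvature signal over one bin exceeds the
        # statistical noise; otherwise one-bin localization is meaningless
        edges = np.arange(-1.4, 1.4 + 1e-12, 0.1)
        pmf = solve_wham(build_histograms(series, windows, edges))
        centers = 0.5 * (edges[:-1] + edges[1:])
        vals = np.where(pmf.mask, pmf.values, np.inf)
        left = np.argmin(np.where(centers < 0, vals, np.inf))
        right = np.argmin(np.where(centers > 0, vals, np.inf))
        found = sorted([centers[left], centers[right]])
        assert abs(found[0] - (-1.0)) <= 0.1 + 1e-9
        assert abs(found[1] - 1.0) <= 0.1 + 1e-9


class TestMBARCrossCheck:
    def test_wham_agrees_with_independent_mbar(self, harmonic_recovery):
        """Histogram WHAM vs a self-contained MBAR estimator (sample-weight
        self-consistency, no histogram in the solve): <= 0.05 kcal/mol RMS
        on the shared dataset after constant alignment."""
        spec, windows, series, edges = harmonic_recovery
        sub_w = windows
        # thin the records 4x (shared by both estimators) to keep the
        # sample-space MBAR matrix small
        sub_s = [SampleSeries(s.window_id, s.values[::4], s.stride * 4)
                 for s in series]
        pmf = solve_wham(build_histograms(sub_s, sub_w, edges))

        beta = 1.0 / (KB_KCAL * 300.0)
        x = np.concatenate([s.values[:, 0] for s in sub_s])
        N = np.array([s.n_records for s in sub_s], dtype=float)
        u = np.stack([beta * bias_energy(w, x[:, None], PRODUCTION)
                      for w in sub_w])  # (K, n)
        g = np.zeros(len(sub_w))
        for _ in range(2000):
            log_den = logsumexp(np.log(N)[:, None] + g[:, None] - u, axis=0)
            g_new = -logsumexp(-u - log_den[None, :], axis=1)
            g_new -= g_new[0]
            if np.max(np.abs(g_new - g)) < 1e-10:
                g = g_new
                break
            g = g_new
        log_w = -log_den  # sample weights up to a constant
        idx = np.digitize(x, edges) - 1
        ok = (idx >= 0) & (idx < len(edges) - 1)
        F_mbar = np.full(len(edges) - 1, np.nan)
        for b in range(len(edges) - 1):
            sel = ok & (idx == b)
            if sel.any():
                F_mbar[b] = -logsumexp(log_w[sel]) / beta
        m = pmf.mask & np.isfinite(F_mbar)
        diff = pmf.values[m] - F_mbar[m]
        diff -= diff.mean()
        rms = np.sqrt(np.mean(diff**2))
        assert rms <= 0.05


class TestBlockError:
    def test_duplicated_blocks_give_zero_error(self):
        spec = LandscapeSpec("harmonic", {"stiffness": 10.0},
                             domain=((-1.5, 1.5),), axis_names=("x",))
        windows = _grid_windows(-0.4, 0.4, 0.1, 6000, seed_base=3)
        series = sample_windows(spec, windows)
        tiled = [SampleSeries(s.window_id, np.tile(s.values[:s.n_records // 3], (3, 1)),
                              s.stride) for s in series]
        edges = np.arange(-0.5, 0.5 + 1e-12, 0.02)
        err, blocks = block_error(tiled, windows, edges)
        assert len(blocks) == 3
        finite = np.isfinite(err)
        assert finite.any()
        assert np.allclose(err[finite], 0.0, atol=1e-7)

    def test_indivisible_length_rejected(self):
        w = BiasWindow("w", (0.0,))
        s = SampleSeries("w", np.zeros((100, 1)))
        with pytest.raises(ValueError, match="divisible|blocks"):
            block_error([s], [w], np.array([-0.1, 0.0, 0.1]), n_blocks=3)

    def test_error_shrinks_with_longer_production(self):
        spec = LandscapeSpec("harmonic", {"stiffness": 10.0},
                             domain=((-1.5, 1.5),), axis_names=("x",))
        edges = np.arange(-0.6, 0.6 + 1e-12, 0.02)
        medians = []
        for n_prod in (12_000, 48_000):
            windows = _grid_windows(-0.5, 0.5, 0.1, n_prod, seed_base=13)
            series = sample_windows(spec, windows)
            err, _ = block_error(series, windows, edges)
            medians.append(np.nanmedian(err))
        assert medians[1] < medians[0]
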