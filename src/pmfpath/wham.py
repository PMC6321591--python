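"""Weighted Histogram Analysis Method for umbrella-sampling data.

Reconstructs the 1D/2D potential of mean force from per-window histograms
by the standard self-consistent WHAM fixed point

    p(b) ∝ sum_i n_i(b) / sum_i N_i exp[(f_i − U_i(b)) / kB T]
    f_i = −kB T ln sum_b p(b) exp(−U_i(b) / kB T)

with the bias U_i evaluated at bin centers using the same restraint
convention as the sampler (U = k (x−c)^2, production force constant).
F = −kB T ln p, shifted so the minimum over occupied bins is zero.

Errors are estimated the block way: the production series are cut into
``n_blocks`` contiguous equal time blocks, WHAM is solved per block, block
PMFs are aligned by a least-squares constant offset over the bins all
blocks occupy, and the per-bin standard deviation across blocks is the
error estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import KB_KCAL
from .grids import PMFGrid, bin_centers
from .sampling import PRODUCTION, BiasWindow, SampleSeries, bias_energy

__all__ = ["HistogramSet", "build_histograms", "solve_wham", "block_error"]

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100_000
DEFAULT_MIN_COUNT = 1
DEFAULT_BIN_WIDTH = 0.02


@dataclass
class HistogramSet:
    """Per-window histograms over a shared bin grid.

    ``counts`` has shape (n_windows, *n_bins); bins are left-closed
    half-open intervals [a, b); a value equal to the final edge falls
    outside and is dropped (with a logged count).
    """

    edges: tuple                 # per-axis bin edges
    counts: np.ndarray           # (n_windows, *bins)
    windows: list                # matching BiasWindow objects
    temperature: float
    n_dropped: int = 0

    @property
    def n_bins(self):
        return tuple(len(e) - 1 for e in self.edges)

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _digitize(values: np.ndarray, edges_list) -> tuple[np.ndarray, np.ndarray]:
    """Left-closed bin indices per axis; returns (indices, in_range mask)."""
    idx = np.empty(values.shape, dtype=np.intp)
    ok = np.ones(values.shape[0], dtype=bool)
    for ax, edges in enumerate(edges_list):
        j = np.searchsorted(edges, values[:, ax], side="right") - 1
        ok &= (j >= 0) & (j < len(edges) - 1)
        idx[:, ax] = np.clip(j, 0, len(edges) - 2)
    return idx, ok


def build_histograms(series, windows, bin_edges) -> HistogramSet:
    """Histogram each window's samples on a shared bin grid.

    ``series`` and ``windows`` are matched by ``window_id``; a series
    without a window (or vice versa) is an error.  Values outside the bin
    range are dropped and counted in ``n_dropped`` (logged).
    """
    windows = list(windows)
    by_id = {w.window_id: w for w in windows}
    if len(by_id) != len(windows):
        raise ValueError("duplicate window ids")
    series = list(series)
    edges_list = [np.asarray(e, dtype=float) for e in
                  (bin_edges if isinstance(bin_edges, (list, tuple)) and np.ndim(bin_edges[0]) == 1
                   else [np.asarray(bin_edges, float)])]
    temps = {w.temperature for w in windows}
    if len(temps) != 1:
        raise ValueError("all windows must share one temperature")
    matched_windows = []
    n_bins = tuple(len(e) - 1 for e in edges_list)
    counts = np.zeros((len(series),) + n_bins)
    dropped = 0
    for si, s in enumerate(series):
        if s.window_id not in by_id:
            raise ValueError(f"series {s.window_id!r} has no matching window")
        matched_windows.append(by_id[s.window_id])
        idx, ok = _digitize(s.values, edges_list)
        dropped += int((~ok).sum())
        np.add.at(counts[si], tuple(idx[ok].T), 1.0)
    if dropped:
        logger.warning("build_histograms: dropped %d out-of-range samples", dropped)
    return HistogramSet(edges=tuple(edges_list), counts=counts,
                        windows=matched_windows, temperature=temps.pop(),
                        n_dropped=dropped)


def _bias_matrix(hist: HistogramSet) -> np.ndarray:
    """U_i(bin center) for every window i and bin, production convention."""
    centers = [bin_centers(e) for e in hist.edges]
    mesh = np.meshgrid(*centers, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    U = np.stack([bias_energy(w, pts, PRODUCTION) for w in hist.windows])
    return U  # (n_windows, n_bins_flat)


def solve_wham(
    hist: HistogramSet,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    min_count: int = DEFAULT_MIN_COUNT,
    axis_names: tuple = (),
    accelerate: bool = True,
) -> PMFGrid:
    """Self-consistent WHAM solve to ``tol`` on max|Δf_i| (kcal/mol).

    Occupied bins are those with total counts ≥ ``min_count``; the PMF is
    min-shifted over those bins only.  Non-convergence within ``max_iter``
    returns the result flagged ``converged=False``.  Disconnected window
    coverage over bins is detected and logged (the per-component PMFs are
    still internally consistent but only defined up to per-component
    constants).

    With ``accelerate`` (default) the window shifts are first obtained by
    L-BFGS minimization of the convex WHAM log-likelihood in f — the same
    fixed point, reached in far fewer matrix passes — and the plain
    self-consistent iteration then runs from that start until the stated
    ``tol`` criterion is met, so the convergence contract is unchanged.
    """
    beta = 1.0 / (KB_KCAL * hist.temperature)
    n_windows = hist.counts.shape[0]
    if n_windows < 1:
        raise ValueError("need at least one window")
    shape = hist.n_bins
    counts = hist.counts.reshape(n_windows, -1)
    N = counts.sum(axis=1)
    total = counts.sum(axis=0)
    mask_flat = total >= min_count
    _warn_if_disconnected(counts, mask_flat)

    U = _bias_matrix(hist)  # (n_windows, n_bins_flat)
    bU = beta * U
    f = np.zeros(n_windows)  # in kcal/mol
    log_num = np.where(total > 0, np.log(np.maximum(total, 1e-300)), -np.inf)

    if accelerate and n_windows > 1 and np.all(N > 0):
        f = _lbfgs_shifts(counts, N, total, bU) / beta
        f = f - f[0]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # log denominator per bin: log sum_i N_i exp(beta f_i - beta U_i)
        a = beta * f[:, None] - bU + np.log(N)[:, None]
        amax = a.max(axis=0)
        log_den = amax + np.log(np.sum(np.exp(a - amax), axis=0))
        log_p = log_num - log_den  # unnormalized
        # new shifts: f_i = -kT ln sum_b p(b) exp(-beta U_i(b))
        b = log_p[None, :] - bU
        finite = np.isfinite(log_p)
        bmax = np.max(np.where(finite[None, :], b, -np.inf), axis=1)
        log_zi = bmax + np.log(np.sum(np.exp(b[:, finite] - bmax[:, None]), axis=1))
        f_new = -log_zi / beta
        f_new = f_new - f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("WHAM did not converge in %d iterations (Δf=%.3g)", max_iter, delta)

    a = beta * f[:, None] - bU + np.log(N)[:, None]
    amax = a.max(axis=0)
    log_den = amax + np.log(np.sum(np.exp(a - amax), axis=0))
    log_p = log_num - log_den
    F = np.full(counts.shape[1], np.nan)
    F[mask_flat] = -log_p[mask_flat] / beta
    F = F.reshape(shape)
    mask = mask_flat.reshape(shape)
    grid = PMFGrid(
        edges=hist.edges, values=F, mask=mask,
        axis_names=tuple(axis_names) or tuple(f"rc{i+1}" for i in range(len(shape))),
        temperature=hist.temperature,
        window_shifts={w.window_id: float(fi) for w, fi in zip(hist.windows, f)},
        converged=converged, iterations=it,
    )
    return grid.min_shift()


def _lbfgs_shifts(counts, N, total, bU) -> np.ndarray:
    """Dimensionless window shifts g = βf minimizing the WHAM likelihood.

    κ(g) = Σ_b M_b ln Σ_i N_i e^{g_i − βU_ib} − Σ_i N_i g_i over occupied
    bins; convex, gauge-invariant (κ(g + c) = κ(g) since ΣM = ΣN).
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp

    occ = total > 0
    M = total[occ]
    bU_occ = bU[:, occ]
    lnN = np.log(N)

    def fun(g):
        a = g[:, None] + lnN[:, None] - bU_occ
        ls = logsumexp(a, axis=0)
        kappa = float(np.dot(M, ls) - np.dot(N, g))
        w = np.exp(a - ls)          # (n_windows, n_occ)
        grad = w @ M - N
        return kappa, grad

    res = minimize(fun, np.zeros(len(N)), jac=True, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-9})
    return res.x


def _warn_if_disconnected(counts: np.ndarray, mask_flat: np.ndarray) -> None:
    """Warn when windows do not overlap into one connected component."""
    n = counts.shape[0]
    if n <= 1:
        return
    occupied = counts[:, mask_flat] > 0
    adj = occupied @ occupied.T > 0
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    while stack:
        i = stack.pop()
        if seen[i]:
            continue
        seen[i] = True
        stack.extend(np.flatnonzero(adj[i] & ~seen))
    if not seen.all():
        logger.warning("window coverage is disconnected (%d of %d windows reachable); "
                       "PMF components are only defined up to per-component constants",
                       int(seen.sum()), n)


def block_error(
    series,
    windows,
    bin_edges,
    n_blocks: int = 3,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    min_count: int = DEFAULT_MIN_COUNT,
    axis_names: tuple = (),
) -> tuple[np.ndarray, list[PMFGrid]]:
    """Block-averaged PMF error: (error grid, per-block PMFs).

    Each series is split into ``n_blocks`` contiguous equal-length time
    blocks (every series length must divide evenly); one WHAM solve per
    block; block PMFs are aligned by a least-squares constant offset over
    the bins occupied in *all* blocks; the error is the per-bin sample
    standard deviation (ddof=1) across the aligned blocks, NaN where any
    block is undefined.
    """
    series = list(series)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    for s in series:
        if s.n_records == 0 or s.n_records % n_blocks:
            raise ValueError(
                f"series {s.window_id!r} length {s.n_records} not divisible into "
                f"{n_blocks} equal blocks")
    block_pmfs = []
    for b in range(n_blocks):
        chunk = [SampleSeries(s.window_id,
                              s.values[b * (s.n_records // n_blocks):(b + 1) * (s.n_records // n_blocks)],
                              stride=s.stride)
                 for s in series]
        hist = build_histograms(chunk, windows, bin_edges)
        block_pmfs.append(solve_wham(hist, tol=tol, max_iter=max_iter,
                                     min_count=min_count, axis_names=axis_names))
    shared = np.logical_and.reduce([p.mask for p in block_pmfs])
    if not shared.any():
        raise ValueError("blocks share no occupied bins; cannot align")
    stack = np.stack([p.values for p in block_pmfs])
    # least-squares offsets: align each block to the cross-block mean on shared bins
    offsets = np.array([np.nanmean(stack[k][shared]) for k in range(n_blocks)])
    offsets = offsets - offsets.mean()
    aligned = stack - offsets[:, None, None] if stack.ndim == 3 else stack - offsets[:, None]
    err = np.std(aligned, axis=0, ddof=1)
    err = np.where(np.all(np.stack([p.mask for p in block_pmfs]), axis=0), err, np.nan)
    return err, block_pmfs
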