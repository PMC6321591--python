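"""Constrained potential-energy scans.

At each grid value of the scanned reaction coordinate(s) the scanned
coordinates are harmonically restrained (k = 1000 kcal mol^-1 Å^-2 by
default) and every other coordinate is relaxed to a gradient tolerance of
0.001 kcal mol^-1 Å^-1.  The reported energy is the *unbiased* potential at
the relaxed point — the restraint is scaffolding.  Points are warm-started
from the previous relaxed point, which is exactly what makes hysteresis
(sudden jumps in the relaxed orthogonal coordinate, visible as kinks in the
profile) reproducible; a bidirectional mode exposes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .landscapes import LandscapeSpec, _gradient_raw, _potential_raw

__all__ = ["ScanResult", "constrained_scan", "profile_kink_report"]

DEFAULT_RESTRAINT_K = 1000.0
DEFAULT_GRAD_TOL = 0.001


@dataclass
class ScanResult:
    """Scan grid, relaxed energies and coordinates, convergence flags."""

    scanned_axes: tuple          # axis indices into the landscape
    grid: tuple                  # per scanned axis: 1D array of scan values
    energies: np.ndarray         # unbiased V at relaxed points; NaN if not converged
    relaxed_points: np.ndarray   # (*grid_shape, ndim)
    converged: np.ndarray        # bool per grid point
    axis_names: tuple = ()

    @property
    def shape(self):
        return tuple(len(g) for g in self.grid)


def _relax(spec, scan_idx, free_idx, targets, x0, restraint_k, grad_tol):
    """Minimize V + k*sum((x_scan - target)^2) from x0; return (x, ok)."""
    lo = np.array([b[0] for b in spec.domain])
    hi = np.array([b[1] for b in spec.domain])

    def fun(x):
        v = _potential_raw(spec, x[None, :])[0]
        g = _gradient_raw(spec, x[None, :])[0]
        r = x[scan_idx] - targets
        v = v + restraint_k * np.dot(r, r)
        g = g.copy()
        g[scan_idx] += 2.0 * restraint_k * r
        return v, g

    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
        options={"gtol": grad_tol * 1e-3, "ftol": 1e-15, "maxiter": 500},
    )
    x = res.x
    g_unbiased = _gradient_raw(spec, x[None, :])[0]
    ok = bool(np.all(np.abs(g_unbiased[free_idx]) <= grad_tol)) if len(free_idx) else True
    return x, ok


def constrained_scan(
    spec: LandscapeSpec,
    scanned_axes,
    scan_values,
    restraint_k: float = DEFAULT_RESTRAINT_K,
    grad_tol: float = DEFAULT_GRAD_TOL,
    direction: str = "forward",
) -> ScanResult:
    """Run a 1D or 2D constrained scan.

    Parameters
    ----------
    scanned_axes : axis names or indices to scan.
    scan_values : one 1D array of grid values per scanned axis (uniform spacing).
    direction : "forward" (ascending warm-start order), "backward", or
        "both" — "both" returns the pointwise lower-energy envelope of the
        two passes (useful to expose hysteresis by comparison with a single
        pass).
    """
    scan_idx = np.array([spec.axis_names.index(a) if isinstance(a, str) else int(a)
                         for a in np.atleast_1d(scanned_axes)])
    vals = [np.asarray(v, dtype=float) for v in
            (scan_values if isinstance(scan_values, (list, tuple)) and np.ndim(scan_values[0]) == 1
             else [np.asarray(scan_values, float)])]
    if len(vals) != len(scan_idx):
        raise ValueError("one value grid per scanned axis required")
    for v in vals:
        if len(v) > 1:
            d = np.diff(v)
            if not np.allclose(d, d[0], rtol=0, atol=1e-9):
                raise ValueError("scan grid spacing must be uniform")
    free_idx = np.array([i for i in range(spec.ndim) if i not in scan_idx], dtype=int)

    if direction == "both":
        fwd = constrained_scan(spec, scan_idx, vals, restraint_k, grad_tol, "forward")
        bwd = constrained_scan(spec, scan_idx, vals, restraint_k, grad_tol, "backward")
        pick = np.where(np.nan_to_num(bwd.energies, nan=np.inf)
                        < np.nan_to_num(fwd.energies, nan=np.inf))
        energies = fwd.energies.copy()
        relaxed = fwd.relaxed_points.copy()
        conv = fwd.converged.copy()
        energies[pick] = bwd.energies[pick]
        relaxed[pick] = bwd.relaxed_points[pick]
        conv[pick] = bwd.converged[pick]
        return ScanResult(tuple(scan_idx), tuple(vals), energies, relaxed, conv,
                          tuple(spec.axis_names[i] for i in scan_idx))

    shape = tuple(len(v) for v in vals)
    energies = np.full(shape, np.nan)
    relaxed = np.zeros(shape + (spec.ndim,))
    conv = np.zeros(shape, dtype=bool)

    order = np.ndindex(shape)
    order = list(order)
    if direction == "backward":
        order = order[::-1]
    elif direction != "forward":
        raise ValueError(f"unknown direction {direction!r}")

    x_prev = None
    for ix in order:
        targets = np.array([vals[k][ix[k]] for k in range(len(scan_idx))])
        if len(free_idx) == 0:
            # fully scanned landscape: relaxation is a no-op evaluation
            x = np.zeros(spec.ndim)
            x[scan_idx] = targets
            x = np.clip(x, [b[0] for b in spec.domain], [b[1] for b in spec.domain])
            relaxed[ix] = x
            energies[ix] = _potential_raw(spec, x[None, :])[0]
            conv[ix] = True
            continue
        if x_prev is None:
            x0 = np.array([(b[0] + b[1]) / 2 for b in spec.domain])
        else:
            x0 = x_prev.copy()
        x0[scan_idx] = targets
        x, ok = _relax(spec, scan_idx, free_idx, targets, x0, restraint_k, grad_tol)
        relaxed[ix] = x
        conv[ix] = ok
        energies[ix] = _potential_raw(spec, x[None, :])[0] if ok else np.nan
        x_prev = x
    return ScanResult(tuple(scan_idx), tuple(vals), energies, relaxed, conv,
                      tuple(spec.axis_names[i] for i in scan_idx))


def profile_kink_report(result: ScanResult, threshold: float = 1.0) -> list[dict]:
    """Locations where |ΔE| between adjacent grid points exceeds ``threshold``.

    Works on 1D scans (the diagnostic for an insufficient one-dimensional
    reaction coordinate: a relaxed orthogonal degree of freedom jumping
    between basins shows up as a sudden energy change).  Returns ordered
    records with the grid index of the jump's right edge, its coordinate
    value, and the signed jump.
    """
    if len(result.shape) != 1:
        raise ValueError("kink report is defined for 1D scans")
    if result.shape[0] < 3:
        raise ValueError("need at least 3 grid points")
    e = result.energies
    g = result.grid[0]
    out = []
    for i in range(1, len(e)):
        if np.isnan(e[i - 1]) or np.isnan(e[i]):
            continue
        jump = e[i] - e[i - 1]
        if abs(jump) > threshold:
            out.append({"index": i, "grid_value": float(g[i]), "jump": float(jump)})
    return out
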