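"""Shared gridded-energy containers.

Both the analytic reference PMFs and the WHAM-reconstructed ones use
:class:`PMFGrid`; plain (potential) energy grids from scans use
:class:`EnergyGrid`.  Energies are in kcal/mol, coordinates in Å of
reaction-coordinate space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PMFGrid", "EnergyGrid", "bin_centers"]


def bin_centers(edges: np.ndarray) -> np.ndarray:
    """Midpoints of a 1D array of bin edges."""
    edges = np.asarray(edges, dtype=float)
    return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class PMFGrid:
    """Free energy on a 1D or 2D bin grid, shifted so the masked minimum is 0.

    Attributes
    ----------
    edges : tuple of arrays
        Bin edges per axis.
    values : ndarray
        Free energy F per bin, kcal/mol; ``np.nan`` outside the occupancy mask.
    mask : ndarray of bool
        True where F is defined (bins with enough samples / finite weight).
    axis_names : tuple of str
        Reaction-coordinate labels per axis.
    temperature : float
        Temperature the PMF refers to, K.
    window_shifts : dict
        Per-window free-energy shifts f_i (kcal/mol), empty for analytic PMFs.
    errors : ndarray or None
        Per-bin error estimate (kcal/mol), same shape as ``values``.
    converged : bool
        Whether the producing solver reached its tolerance.
    iterations : int
        Iteration count of the producing solver (0 for analytic PMFs).
    """

    edges: tuple
    values: np.ndarray
    mask: np.ndarray
    axis_names: tuple
    temperature: float
    window_shifts: dict = field(default_factory=dict)
    errors: np.ndarray | None = None
    converged: bool = True
    iterations: int = 0

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> tuple:
        return tuple(bin_centers(e) for e in self.edges)

    def min_shift(self) -> "PMFGrid":
        """Return self with values shifted so the masked minimum is exactly 0."""
        if self.mask.any():
            self.values = self.values - np.nanmin(self.values[self.mask])
        return self


@dataclass
class EnergyGrid:
    """Plain energy values on a rectangular grid (no statistical mask logic)."""

    edges: tuple
    values: np.ndarray
    axis_names: tuple

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> tuple:
        return tuple(bin_centers(e) for e in self.edges)
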