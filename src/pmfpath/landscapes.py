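"""Analytic model energy landscapes over 1–2 reaction coordinates.

These surfaces stand in for an expensive quantum-chemical energy function:
they are cheap, smooth, have analytic gradients, and their multi-basin
topology (intermediate basin, plateau-like dissociative transition region,
product basin) mimics the free-energy surfaces of the two phosphoryl-transfer
steps of phosphoserine phosphatase, with basins placed near the
reaction-coordinate values those steps exhibit (OPO ≈ −1.3 → +1.0 for the
serine-to-aspartate transfer, OPO ≈ −1.6 → +1.6 for the hydrolysis step).

Energies are kcal/mol, coordinates Å.  The exact Boltzmann-integrated PMF
(:func:`analytic_pmf`) serves as the reference oracle against which the
umbrella-sampling + WHAM reconstruction is validated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import optimize

from .constants import DEFAULT_TEMPERATURE, KB_KCAL
from .grids import PMFGrid

__all__ = [
    "LandscapeSpec",
    "DomainError",
    "evaluate_potential",
    "evaluate_gradient",
    "analytic_pmf",
    "stationary_points",
    "StationaryPoint",
]

FORMS = ("harmonic", "double_well_1d", "two_basin_2d", "psp_step1_like", "psp_step2_like")


class DomainError(ValueError):
    """A coordinate fell outside the landscape domain; names the axis."""


@dataclass(frozen=True)
class LandscapeSpec:
    """Declarative description of an analytic landscape.

    Parameters
    ----------
    form : str
        One of ``harmonic``, ``double_well_1d``, ``two_basin_2d``,
        ``psp_step1_like``, ``psp_step2_like``.
    params : dict
        Named real parameters; missing entries take the form's defaults.
    domain : tuple of (lo, hi)
        Closed per-axis bounds, Å.
    axis_names : tuple of str
        Reaction-coordinate labels, e.g. ``("OPO", "OHO")``.
    """

    form: str
    params: dict = field(default_factory=dict)
    domain: tuple = ()
    axis_names: tuple = ()

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown landscape form {self.form!r}; choose from {FORMS}")
        object.__setattr__(self, "params", dict(self.params))
        dom, names = _default_geometry(self.form, self.params)
        if not self.domain:
            object.__setattr__(self, "domain", dom)
        else:
            object.__setattr__(self, "domain", tuple((float(a), float(b)) for a, b in self.domain))
        if not self.axis_names:
            object.__setattr__(self, "axis_names", names[: self.ndim])
        if len(self.axis_names) != self.ndim:
            raise ValueError("axis_names length must match domain dimensionality")

    @property
    def ndim(self) -> int:
        return len(self.domain)

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "params": {k: float(v) if np.isscalar(v) else list(map(float, v)) for k, v in self.params.items()},
            "domain": [list(b) for b in self.domain],
            "axis_names": list(self.axis_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeSpec":
        return cls(
            form=d["form"],
            params=d.get("params", {}),
            domain=tuple(tuple(b) for b in d.get("domain", ())),
            axis_names=tuple(d.get("axis_names", ())),
        )


# --------------------------------------------------------------------------
# Functional forms.  Multi-basin surfaces are Gaussian mixtures plus a broad
# quadratic confinement: V(x) = sum_j A_j exp(-sum_i (x_i-mu_ji)^2 / 2 w_ji^2)
#                               + 1/2 c |x - x0|^2
# Negative amplitudes are basins; positive ones are barrier bumps, which may
# be anisotropic (ridges) to shape where the connecting saddle sits.

def _default_geometry(form: str, params: dict):
    if form == "harmonic":
        ndim = len(np.atleast_1d(params.get("center", 0.0)))
        return tuple((-3.0, 3.0) for _ in range(ndim)), ("x", "y")[:ndim] or ("x",)
    if form == "double_well_1d":
        ndim = 2 if "ortho_stiffness" in params else 1
        a = float(params.get("a", 1.0))
        dom = [(-2.5 * a, 2.5 * a)]
        if ndim == 2:
            dom.append((-2.0, 2.0))
        return tuple(dom), ("x", "y")
    if form == "two_basin_2d":
        return ((-2.2, 2.2), (-1.8, 1.8)), ("x", "y")
    if form == "psp_step1_like":
        return ((-2.2, 1.8), (-1.5, 1.5)), ("OPO", "OHO")
    if form == "psp_step2_like":
        return ((-2.5, 2.4), (-1.5, 1.5)), ("OPO", "OHO")
    raise ValueError(form)


def _gaussian_terms(spec: LandscapeSpec):
    """(amplitudes, centers, per-axis widths, confine, confine_center)."""
    p = spec.params

    def _w(value, ndim):
        w = np.atleast_1d(np.asarray(value, float))
        return np.full(ndim, w[0]) if w.size == 1 else w

    if spec.form == "two_basin_2d":
        amps = [-float(p.get("depth1", 8.0)), -float(p.get("depth2", 9.0))]
        cents = [np.asarray(p.get("min1", (-1.0, -0.5)), float),
                 np.asarray(p.get("min2", (1.0, 0.5)), float)]
        widths = [_w(p.get("width1", 0.55), 2), _w(p.get("width2", 0.55), 2)]
        conf = float(p.get("confine", 3.0))
        conf_c = np.asarray(p.get("confine_center", (0.0, 0.0)), float)
        return np.array(amps), np.array(cents), np.array(widths), conf, conf_c
    if spec.form == "psp_step1_like":
        # Basins at the intermediate (IM) and product (P) positions of the
        # serine→Asp11 transfer; a low ridge across the IM→P corridor shapes
        # the plateau-like dissociative transition region.
        amps = [-float(p.get("im_depth", 14.0)), -float(p.get("p_depth", 18.0)),
                float(p.get("barrier_height", 2.5))]
        cents = [np.asarray(p.get("im_pos", (-1.3, -0.8)), float),
                 np.asarray(p.get("p_pos", (1.0, 0.8)), float),
                 np.asarray(p.get("barrier_pos", (-0.45, 0.1)), float)]
        widths = [_w(p.get("im_width", 0.50), 2), _w(p.get("p_width", 0.55), 2),
                  _w(p.get("barrier_width", (0.35, 1.1)), 2)]
        conf = float(p.get("confine", 1.6))
        conf_c = np.asarray(p.get("confine_center", (-0.15, 0.0)), float)
        return np.array(amps), np.array(cents), np.array(widths), conf, conf_c
    if spec.form == "psp_step2_like":
        amps = [-float(p.get("im_depth", 14.0)), -float(p.get("p_depth", 14.0)),
                float(p.get("barrier_height", 3.0))]
        cents = [np.asarray(p.get("im_pos", (-1.6, -0.8)), float),
                 np.asarray(p.get("p_pos", (1.6, 0.8)), float),
                 np.asarray(p.get("barrier_pos", (0.5, 0.0)), float)]
        widths = [_w(p.get("im_width", 0.55), 2), _w(p.get("p_width", 0.55), 2),
                  _w(p.get("barrier_width", (0.35, 1.2)), 2)]
        conf = float(p.get("confine", 1.2))
        conf_c = np.asarray(p.get("confine_center", (0.0, 0.0)), float)
        return np.array(amps), np.array(cents), np.array(widths), conf, conf_c
    raise ValueError(spec.form)


def _check_domain(spec: LandscapeSpec, pts: np.ndarray) -> None:
    for i, (lo, hi) in enumerate(spec.domain):
        x = pts[..., i]
        if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
            raise DomainError(
                f"coordinate on axis {spec.axis_names[i]!r} outside domain [{lo}, {hi}]"
            )


def _as_points(spec: LandscapeSpec, point) -> tuple[np.ndarray, bool]:
    pts = np.asarray(point, dtype=float)
    scalar = pts.ndim <= 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != spec.ndim:
        raise ValueError(f"expected {spec.ndim} coordinates, got shape {pts.shape}")
    return pts, scalar


def _potential_raw(spec: LandscapeSpec, pts: np.ndarray) -> np.ndarray:
    p = spec.params
    offset = float(p.get("offset", 0.0))  # constant shift, all forms
    if offset:
        q = dict(p)
        q.pop("offset")
        base = LandscapeSpec(spec.form, q, spec.domain, spec.axis_names)
        return _potential_raw(base, pts) + offset
    if spec.form == "harmonic":
        s = np.atleast_1d(np.asarray(p.get("stiffness", 1.0), float))
        c = np.atleast_1d(np.asarray(p.get("center", 0.0), float))
        if s.size == 1:
            s = np.full(spec.ndim, s[0])
        if c.size == 1 and spec.ndim > 1:
            c = np.full(spec.ndim, c[0])
        return 0.5 * np.sum(s * (pts - c) ** 2, axis=-1)
    if spec.form == "double_well_1d":
        h = float(p.get("h", 5.0))
        a = float(p.get("a", 1.0))
        x = pts[..., 0]
        v = h * (x**2 - a**2) ** 2 / a**4
        if spec.ndim == 2:
            sy = float(p.get("ortho_stiffness", 0.0))
            v = v + 0.5 * sy * pts[..., 1] ** 2
        return v
    amps, cents, widths, conf, conf_c = _gaussian_terms(spec)
    diff = pts[..., None, :] - cents  # (..., n_terms, ndim)
    expo = np.sum(diff**2 / (2.0 * widths**2), axis=-1)
    v = np.sum(amps * np.exp(-expo), axis=-1)
    v = v + 0.5 * conf * np.sum((pts - conf_c) ** 2, axis=-1)
    return v


def _gradient_raw(spec: LandscapeSpec, pts: np.ndarray) -> np.ndarray:
    p = spec.params
    if p.get("offset"):
        q = dict(p)
        q.pop("offset")
        return _gradient_raw(LandscapeSpec(spec.form, q, spec.domain, spec.axis_names), pts)
    if spec.form == "harmonic":
        s = np.atleast_1d(np.asarray(p.get("stiffness", 1.0), float))
        c = np.atleast_1d(np.asarray(p.get("center", 0.0), float))
        if s.size == 1:
            s = np.full(spec.ndim, s[0])
        if c.size == 1 and spec.ndim > 1:
            c = np.full(spec.ndim, c[0])
        return s * (pts - c)
    if spec.form == "double_well_1d":
        h = float(p.get("h", 5.0))
        a = float(p.get("a", 1.0))
        g = np.zeros_like(pts)
        x = pts[..., 0]
        g[..., 0] = 4.0 * h * x * (x**2 - a**2) / a**4
        if spec.ndim == 2:
            g[..., 1] = float(p.get("ortho_stiffness", 0.0)) * pts[..., 1]
        return g
    amps, cents, widths, conf, conf_c = _gaussian_terms(spec)
    diff = pts[..., None, :] - cents  # (..., n_terms, ndim)
    expo = np.sum(diff**2 / (2.0 * widths**2), axis=-1)
    coef = (amps * np.exp(-expo))[..., None]  # (..., n_terms, 1)
    return -np.sum(coef * diff / widths**2, axis=-2) + conf * (pts - conf_c)


def evaluate_potential(spec: LandscapeSpec, point) -> float | np.ndarray:
    """Potential energy (kcal/mol) at one point or an array of points.

    Raises :class:`DomainError` (naming the offending axis) outside the
    stated domain.
    """
    pts, scalar = _as_points(spec, point)
    _check_domain(spec, pts)
    v = _potential_raw(spec, pts)
    return float(v[0]) if scalar else v


def evaluate_gradient(spec: LandscapeSpec, point) -> np.ndarray:
    """Analytic gradient (kcal mol^-1 Å^-1 per axis) at one or many points."""
    pts, scalar = _as_points(spec, point)
    _check_domain(spec, pts)
    g = _gradient_raw(spec, pts)
    return g[0] if scalar else g


# --------------------------------------------------------------------------
# Exact Boltzmann-integrated reference PMF.

def analytic_pmf(
    spec: LandscapeSpec,
    axes,
    bin_edges,
    temperature: float = DEFAULT_TEMPERATURE,
    tol: float = 1e-3,
) -> PMFGrid:
    """Exact PMF over bins: F(bin) = -kB T ln ∫ exp(-V/kB T).

    ``axes`` selects the kept axis/axes (names or indices); any remaining
    axis is integrated over its full domain (2D → 1D projection).  Gauss–
    Legendre quadrature is refined (node doubling) until the largest change
    in any F(bin) is below ``tol`` kcal/mol.  The result is shifted so the
    minimum over bins is exactly 0.

    Raises ``ValueError`` for empty or degenerate bins or non-positive
    temperature.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    axis_idx = [spec.axis_names.index(a) if isinstance(a, str) else int(a) for a in np.atleast_1d(axes)]
    if len(set(axis_idx)) != len(axis_idx):
        raise ValueError("duplicate axes")
    edges_list = [np.asarray(e, dtype=float) for e in
                  (bin_edges if isinstance(bin_edges, (list, tuple)) and
                   np.ndim(bin_edges[0]) == 1 else [np.asarray(bin_edges, float)])]
    if len(edges_list) != len(axis_idx):
        raise ValueError("one set of bin edges required per selected axis")
    for e in edges_list:
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing with >=1 bin")
    for ax, e in zip(axis_idx, edges_list):
        lo, hi = spec.domain[ax]
        if e[0] < lo - 1e-9 or e[-1] > hi + 1e-9:
            raise ValueError(f"bins on axis {spec.axis_names[ax]!r} exceed the domain")
    ortho_idx = [i for i in range(spec.ndim) if i not in axis_idx]
    beta = 1.0 / (KB_KCAL * temperature)

    def _compute(n_nodes: int) -> np.ndarray:
        gl_x, gl_w = leggauss(n_nodes)
        # per selected axis: nodes & weights per bin, flattened
        sel_nodes, sel_w = [], []
        for e in edges_list:
            a, b = e[:-1], e[1:]
            mid, half = 0.5 * (a + b), 0.5 * (b - a)
            sel_nodes.append(mid[:, None] + half[:, None] * gl_x)   # (nbin, n)
            sel_w.append(half[:, None] * gl_w)
        # orthogonal axes: panel-composite GL over the full domain
        ort_nodes, ort_w = [], []
        for ax in ortho_idx:
            lo, hi = spec.domain[ax]
            n_panel = max(8, n_nodes // 2)
            pe = np.linspace(lo, hi, n_panel + 1)
            mid, half = 0.5 * (pe[:-1] + pe[1:]), 0.5 * np.diff(pe)
            ort_nodes.append((mid[:, None] + half[:, None] * gl_x).ravel())
            ort_w.append((half[:, None] * gl_w).ravel())
        shape = tuple(len(e) - 1 for e in edges_list)
        F = np.empty(shape)
        for bins in itertools.product(*(range(s) for s in shape)):
            node_axes, w_axes = [], []
            full_nodes = [None] * spec.ndim
            for k, ax in enumerate(axis_idx):
                node_axes.append(sel_nodes[k][bins[k]])
                w_axes.append(sel_w[k][bins[k]])
            for k, ax in enumerate(ortho_idx):
                node_axes.append(ort_nodes[k])
                w_axes.append(ort_w[k])
            mesh = np.meshgrid(*node_axes, indexing="ij")
            order = axis_idx + ortho_idx
            for pos, ax in enumerate(order):
                full_nodes[ax] = mesh[pos]
            pts = np.stack(full_nodes, axis=-1).reshape(-1, spec.ndim)
            v = _potential_raw(spec, pts).reshape(mesh[0].shape)
            vmin = v.min()
            wmesh = np.meshgrid(*w_axes, indexing="ij")
            wtot = np.ones_like(mesh[0])
            for wm in wmesh:
                wtot = wtot * wm
            z = np.sum(wtot * np.exp(-beta * (v - vmin)))
            if z <= 0:
                raise ValueError("degenerate bin: zero Boltzmann weight")
            F[bins] = vmin - np.log(z) / beta
        return F

    n = 8
    F_prev = _compute(n)
    for _ in range(6):
        n *= 2
        F = _compute(n)
        if np.max(np.abs(F - F_prev)) < tol:
            F_prev = F
            break
        F_prev = F
    F = F_prev - F_prev.min()
    mask = np.ones_like(F, dtype=bool)
    return PMFGrid(
        edges=tuple(edges_list),
        values=F,
        mask=mask,
        axis_names=tuple(spec.axis_names[i] for i in axis_idx),
        temperature=temperature,
    )


# --------------------------------------------------------------------------
# Stationary-point report (basins and saddles), used by downstream tests and
# by path extraction to pick start/end states.

@dataclass(frozen=True)
class StationaryPoint:
    kind: str  # "minimum" | "saddle" | "maximum"
    position: tuple
    energy: float
    gradient_norm: float


def stationary_points(
    spec: LandscapeSpec,
    resolution: float = 0.02,
    grad_tol: float = 1e-8,
    dedupe_tol: float = 1e-3,
) -> list[StationaryPoint]:
    """Locate minima and saddles inside the domain.

    Candidates come from a dense grid scan (grid-local minima of V for
    basins, grid-local minima of |∇V|² for general stationary points); each
    is polished by Newton root-search on the analytic gradient and
    classified by the eigenvalues of a finite-difference Hessian.
    """
    axes = [np.arange(lo, hi + resolution / 2, resolution) for lo, hi in spec.domain]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack(mesh, axis=-1)
    flat = pts.reshape(-1, spec.ndim)
    V = _potential_raw(spec, flat).reshape(mesh[0].shape)
    G = _gradient_raw(spec, flat)
    g2 = np.sum(G**2, axis=-1).reshape(mesh[0].shape)

    def _local_minima(arr):
        m = np.ones_like(arr, dtype=bool)
        for ax in range(arr.ndim):
            lo = np.roll(arr, 1, axis=ax)
            hi = np.roll(arr, -1, axis=ax)
            sl_lo = [slice(None)] * arr.ndim
            sl_hi = [slice(None)] * arr.ndim
            sl_lo[ax], sl_hi[ax] = 0, -1
            lo[tuple(sl_lo)] = np.inf
            hi[tuple(sl_hi)] = np.inf
            m &= (arr <= lo) & (arr <= hi)
        return np.argwhere(m)

    candidates = [pts[tuple(ix)] for ix in _local_minima(V)]
    candidates += [pts[tuple(ix)] for ix in _local_minima(g2)]

    found: list[StationaryPoint] = []
    for x0 in candidates:
        try:
            sol = optimize.root(lambda x: _gradient_raw(spec, x[None, :])[0], x0, tol=1e-12)
        except Exception:
            continue
        if not sol.success:
            continue
        x = sol.x
        if any(x[i] < spec.domain[i][0] - 1e-9 or x[i] > spec.domain[i][1] + 1e-9
               for i in range(spec.ndim)):
            continue
        gnorm = float(np.linalg.norm(_gradient_raw(spec, x[None, :])[0]))
        if gnorm > max(grad_tol, 1e-6):
            continue
        if any(np.linalg.norm(x - np.asarray(s.position)) < dedupe_tol for s in found):
            continue
        H = _fd_hessian(spec, x)
        ev = np.linalg.eigvalsh(H)
        n_neg = int(np.sum(ev < -1e-6))
        kind = "minimum" if n_neg == 0 else ("saddle" if n_neg == 1 else "maximum")
        found.append(StationaryPoint(kind, tuple(float(c) for c in x),
                                     float(_potential_raw(spec, x[None, :])[0]), gnorm))
    found.sort(key=lambda s: s.energy)
    return found


def _fd_hessian(spec: LandscapeSpec, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian from the analytic gradient."""
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        gp = _gradient_raw(spec, (x + e)[None, :])[0]
        gm = _gradient_raw(spec, (x - e)[None, :])[0]
        H[i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)
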