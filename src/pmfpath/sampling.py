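"""Umbrella sampling of reaction-coordinate landscapes.

Each window restrains the system near a grid point of the reaction
coordinate(s) with a harmonic bias U = k (x - c)^2 (CHARMM restraint
convention, no 1/2 factor) and samples the biased Boltzmann distribution
exp(-(V + U)/kB T) by Metropolis random-walk Monte Carlo.  The protocol
mirrors the common umbrella workflow: a stiff equilibration phase
(k = 1000 kcal mol^-1 Å^-2 by default), a softer production phase
(k = 200), window centers on a 0.1 Å grid, 300 K, and production series
whose record count divides into three equal blocks for block-averaged
error estimation.

The Metropolis proposal width is auto-tuned toward ~40% acceptance during
equilibration.  Per-window random streams are derived from
``numpy.random.SeedSequence`` so a window's trajectory is identical whether
it is sampled alone or in a vectorized batch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB_KCAL
from .landscapes import LandscapeSpec, _potential_raw

__all__ = [
    "BiasWindow",
    "SampleSeries",
    "build_window_grid",
    "bias_energy",
    "sample_window",
    "sample_windows",
    "derive_window_seed",
]

logger = logging.getLogger(__name__)

EQUILIBRATION = "equilibration"
PRODUCTION = "production"

DEFAULT_K_EQUIL = 1000.0
DEFAULT_K_PROD = 200.0
DEFAULT_N_EQUIL = 10_000
DEFAULT_N_PROD = 60_000
DEFAULT_STRIDE = 10


@dataclass(frozen=True)
class BiasWindow:
    """One umbrella window: target center(s), phase force constants, seed."""

    window_id: str
    centers: tuple
    force_constants: dict = field(
        default_factory=lambda: {EQUILIBRATION: DEFAULT_K_EQUIL, PRODUCTION: DEFAULT_K_PROD}
    )
    n_equil_steps: int = DEFAULT_N_EQUIL
    n_prod_steps: int = DEFAULT_N_PROD
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "centers", tuple(float(c) for c in np.atleast_1d(self.centers)))
        for phase in (EQUILIBRATION, PRODUCTION):
            if self.force_constants.get(phase, 0.0) <= 0:
                raise ValueError(f"force constant for {phase} must be positive")
        if self.n_equil_steps < 0 or self.n_prod_steps <= 0:
            raise ValueError("step counts must be positive")

    @property
    def ndim(self) -> int:
        return len(self.centers)


@dataclass
class SampleSeries:
    """Recorded production-phase reaction-coordinate values for one window."""

    window_id: str
    values: np.ndarray  # (n_records, ndim)
    stride: int = DEFAULT_STRIDE

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def ndim(self) -> int:
        return self.values.shape[1]


def build_window_grid(
    ranges,
    spacing: float = 0.1,
    **window_kwargs,
) -> list[BiasWindow]:
    """Regular grid of umbrella windows, inclusive of both range ends.

    ``ranges`` is a sequence of (lo, hi) per axis; each width must be a
    positive multiple of ``spacing`` (within 1e-9), otherwise a ValueError
    suggests the nearest commensurate upper bound.
    """
    ranges = [tuple(map(float, r)) for r in (ranges if np.ndim(ranges[0]) else [ranges])]
    axes = []
    for i, (lo, hi) in enumerate(ranges):
        width = hi - lo
        if width <= 0:
            raise ValueError(f"range {i} has non-positive width")
        n = width / spacing
        if abs(n - round(n)) > 1e-9 * max(1.0, abs(n)):
            lo_hi = lo + math.floor(n) * spacing
            hi_hi = lo + math.ceil(n) * spacing
            raise ValueError(
                f"range [{lo}, {hi}] is not commensurate with spacing {spacing}; "
                f"nearest commensurate bounds are {lo_hi:.10g} or {hi_hi:.10g}"
            )
        axes.append(lo + spacing * np.arange(int(round(n)) + 1))
    mesh = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([m.ravel() for m in mesh], axis=-1)
    windows = []
    for idx, c in enumerate(centers):
        wid = "w" + "_".join(f"{v:+.4f}" for v in c)
        windows.append(BiasWindow(window_id=wid, centers=tuple(c), **window_kwargs))
    return windows


def bias_energy(window: BiasWindow, point, phase: str = PRODUCTION):
    """Harmonic restraint energy U = k_phase * sum_axes (x - c)^2, kcal/mol.

    The same function backs both the sampler and the WHAM unbiasing, so the
    restraint convention cannot drift between them.
    """
    if phase not in (EQUILIBRATION, PRODUCTION):
        raise ValueError(f"unknown phase {phase!r}")
    k = float(window.force_constants[phase])
    pts = np.asarray(point, dtype=float)
    c = np.asarray(window.centers)
    scalar = pts.ndim <= 1
    pts = np.atleast_2d(pts)
    u = k * np.sum((pts - c) ** 2, axis=-1)
    return float(u[0]) if scalar else u


def derive_window_seed(master_seed: int, window_index: int) -> int:
    """Splittable per-window seed: SeedSequence([master, index]) -> < 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(window_index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SamplerSettings:
    stride: int = DEFAULT_STRIDE
    target_acceptance: float = 0.40
    tune_interval: int = 200
    initial_width: float | None = None  # default: sqrt(kB T / 2 k_equil)
    chunk_steps: int = 4000


def sample_window(spec: LandscapeSpec, window: BiasWindow,
                  settings: SamplerSettings | None = None) -> SampleSeries:
    """Sample one umbrella window; see :func:`sample_windows`."""
    return sample_windows(spec, [window], settings)[0]


def sample_windows(spec: LandscapeSpec, windows, settings: SamplerSettings | None = None
                   ) -> list[SampleSeries]:
    """Metropolis-sample many umbrella windows, vectorized across windows.

    Every window advances one MC step per iteration using randoms drawn
    from its own seeded stream, so results are independent of how windows
    are batched.  Equilibration uses the equilibration force constant and
    is discarded; production values are recorded every ``stride`` steps.
    A window whose final acceptance rate leaves (0.05, 0.95) triggers a
    logged warning (not an error).
    """
    settings = settings or SamplerSettings()
    windows = list(windows)
    if not windows:
        return []
    ndim = spec.ndim
    lo = np.array([b[0] for b in spec.domain])
    hi = np.array([b[1] for b in spec.domain])
    for w in windows:
        if w.ndim != ndim:
            raise ValueError(f"window {w.window_id} dimensionality mismatch")
        if np.any(np.array(w.centers) < lo) or np.any(np.array(w.centers) > hi):
            raise ValueError(f"window {w.window_id} center outside landscape domain")
        if w.n_prod_steps % settings.stride:
            raise ValueError("production steps must be divisible by the stride")

    nw = len(windows)
    centers = np.array([w.centers for w in windows])
    temps = np.array([w.temperature for w in windows])
    beta = 1.0 / (KB_KCAL * temps)
    rngs = [np.random.default_rng(w.seed) for w in windows]

    x = centers.copy()
    v_land = _potential_raw(spec, x)

    k_eq = np.array([w.force_constants[EQUILIBRATION] for w in windows])
    k_pr = np.array([w.force_constants[PRODUCTION] for w in windows])
    if settings.initial_width is not None:
        width = np.full(nw, float(settings.initial_width))
    else:
        width = np.sqrt(KB_KCAL * temps / (2.0 * k_eq))

    n_equil = windows[0].n_equil_steps
    n_prod = windows[0].n_prod_steps
    if any(w.n_equil_steps != n_equil or w.n_prod_steps != n_prod for w in windows):
        raise ValueError("all windows in a batch must share step counts")

    records = np.empty((n_prod // settings.stride, nw, ndim))

    def _run_phase(n_steps, k_phase, record, tune):
        nonlocal x, v_land
        accepted = np.zeros(nw)
        since_tune = 0
        acc_since = np.zeros(nw)
        rec_i = 0
        step = 0
        while step < n_steps:
            chunk = min(settings.chunk_steps, n_steps - step)
            # per-window random streams, drawn chunk-wise
            normals = np.empty((chunk, nw, ndim))
            unifs = np.empty((chunk, nw))
            for j, rng in enumerate(rngs):
                normals[:, j, :] = rng.standard_normal((chunk, ndim))
                unifs[:, j] = rng.random(chunk)
            for t in range(chunk):
                prop = x + width[:, None] * normals[t]
                inside = np.all((prop >= lo) & (prop <= hi), axis=1)
                v_prop = np.where(inside, _potential_raw(spec, np.clip(prop, lo, hi)), np.inf)
                du = (v_prop + k_phase * np.sum((prop - centers) ** 2, axis=1)) - (
                    v_land + k_phase * np.sum((x - centers) ** 2, axis=1)
                )
                acc = inside & (unifs[t] < np.exp(np.minimum(0.0, -beta * du)))
                x[acc] = prop[acc]
                v_land[acc] = v_prop[acc]
                accepted += acc
                acc_since += acc
                since_tune += 1
                global_step = step + t + 1
                if tune and since_tune >= settings.tune_interval:
                    rate = acc_since / since_tune
                    factor = np.clip(rate / settings.target_acceptance, 0.5, 2.0)
                    width[:] = np.clip(width * factor, 1e-6, np.max(hi - lo))
                    acc_since[:] = 0.0
                    since_tune = 0
                if record and global_step % settings.stride == 0:
                    records[rec_i] = x
                    rec_i += 1
            step += chunk
        return accepted / max(n_steps, 1)

    if n_equil:
        _run_phase(n_equil, k_eq, record=False, tune=True)
    acc_rate = _run_phase(n_prod, k_pr, record=True, tune=False)

    out = []
    for j, w in enumerate(windows):
        if not (0.05 < acc_rate[j] < 0.95):
            logger.warning(
                "window %s: production acceptance rate %.3f outside (0.05, 0.95)",
                w.window_id, acc_rate[j],
            )
        out.append(SampleSeries(window_id=w.window_id, values=records[:, j, :].copy(),
                                stride=settings.stride))
    return out
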