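"""End-to-end orchestration: landscape → windows → sampling → WHAM (+ block
errors) → minimum-free-energy path → profile → stationary report.

A :class:`RunConfig` fully determines a run; its SHA-256 hash is written
into every output header, and reruns with the same config (hence the same
master seed and derived per-window seeds) are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .gridpaths import locate_states, minimum_energy_path
from .landscapes import LandscapeSpec, stationary_points
from .sampling import (
    DEFAULT_K_EQUIL,
    DEFAULT_K_PROD,
    BiasWindow,
    SamplerSettings,
    build_window_grid,
    derive_window_seed,
    sample_windows,
)
from .wham import block_error, build_histograms, solve_wham

__all__ = ["RunConfig", "run_pipeline", "step1_demo_config", "PipelineResult"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    landscape: dict                      # LandscapeSpec.to_dict() form
    window_ranges: list                  # [(lo, hi), ...] per axis
    window_spacing: float = 0.1
    k_equilibration: float = DEFAULT_K_EQUIL
    k_production: float = DEFAULT_K_PROD
    n_equil_steps: int = 2000
    n_prod_steps: int = 6000
    stride: int = 10
    temperature: float = 300.0
    master_seed: int = 1
    bin_width: float = 0.02
    wham_tol: float = 1e-6
    wham_max_iter: int = 100000
    min_count: int = 1
    n_blocks: int = 3
    compute_block_errors: bool = True
    connectivity: int = 4
    path_start: list | None = None       # bin indices, else auto minima
    path_end: list | None = None
    # profile smoothing for the stationary report; statistical PMFs carry
    # bin-scale noise below the block error that would otherwise register
    # as spurious intermediate states
    report_smoothing_window: int = 3
    output_dir: str = "pmfpath_run"
    log_level: str = "INFO"

    def validate(self) -> None:
        spec = self.landscape_spec()
        if not self.window_ranges:
            raise ValueError("config has no umbrella window ranges")
        if len(self.window_ranges) != spec.ndim:
            raise ValueError("window_ranges dimensionality does not match landscape")
        if self.n_prod_steps // self.stride % self.n_blocks:
            raise ValueError("recorded production length must divide into n_blocks")
        if self.window_spacing <= 0 or self.bin_width <= 0:
            raise ValueError("spacings must be positive")

    def landscape_spec(self) -> LandscapeSpec:
        return LandscapeSpec.from_dict(self.landscape)

    def config_hash(self) -> str:
        """Hash of the physics-determining fields (where the run is written
        and how verbosely it logs do not change its results)."""
        d = asdict(self)
        d.pop("output_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineResult:
    config: RunConfig
    windows: list
    series: list
    pmf: object
    error_grid: object
    path: object
    report: object
    artifacts: dict = field(default_factory=dict)


def _build_windows(config: RunConfig) -> list[BiasWindow]:
    windows = build_window_grid(
        config.window_ranges, config.window_spacing,
        force_constants={"equilibration": config.k_equilibration,
                         "production": config.k_production},
        n_equil_steps=config.n_equil_steps,
        n_prod_steps=config.n_prod_steps,
        temperature=config.temperature,
    )
    return [BiasWindow(w.window_id, w.centers, w.force_constants,
                       w.n_equil_steps, w.n_prod_steps, w.temperature,
                       seed=derive_window_seed(config.master_seed, i))
            for i, w in enumerate(windows)]


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Run every stage in order and (optionally) write all artifacts as TSV."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    spec = config.landscape_spec()
    chash = config.config_hash()
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("stage=windows hash=%s", chash)
    windows = _build_windows(config)
    logger.info("stage=sampling windows=%d steps=%d+%d", len(windows),
                config.n_equil_steps, config.n_prod_steps)
    try:
        series = sample_windows(spec, windows, SamplerSettings(stride=config.stride))
    except Exception as exc:
        raise RuntimeError(f"stage 'sampling' failed: {exc}") from exc

    edges = [np.arange(lo, hi + config.bin_width * 0.5 + 1e-12, config.bin_width)
             for lo, hi in config.window_ranges]
    try:
        hist = build_histograms(series, windows, edges)
        pmf = solve_wham(hist, tol=config.wham_tol, max_iter=config.wham_max_iter,
                         min_count=config.min_count, axis_names=spec.axis_names)
        logger.info("stage=wham iterations=%d converged=%s", pmf.iterations, pmf.converged)
    except Exception as exc:
        raise RuntimeError(f"stage 'wham' failed: {exc}") from exc

    error_grid = None
    if config.compute_block_errors:
        try:
            error_grid, _ = block_error(series, windows, edges, n_blocks=config.n_blocks,
                                        tol=config.wham_tol, max_iter=config.wham_max_iter,
                                        min_count=config.min_count,
                                        axis_names=spec.axis_names)
            pmf.errors = error_grid
        except Exception as exc:
            raise RuntimeError(f"stage 'block_error' failed: {exc}") from exc

    path = report = None
    if spec.ndim == 2:
        try:
            start = tuple(config.path_start) if config.path_start else None
            end = tuple(config.path_end) if config.path_end else None
            path = minimum_energy_path(pmf, connectivity=config.connectivity,
                                       start=start, end=end)
            report = locate_states(path, smoothing_window=config.report_smoothing_window)
            logger.info("stage=path nodes=%d barrier=%s", len(path.nodes), report.barrier)
        except Exception as exc:
            raise RuntimeError(f"stage 'path' failed: {exc}") from exc

    artifacts = {}
    if write:
        meta = {"config_hash": chash}
        for s, w in zip(series, windows):
            p = out / f"series_{w.window_id}.tsv"
            pio.write_series(p, s, w)
            artifacts[f"series:{w.window_id}"] = p
        p = out / "pmf.tsv"
        pio.write_pmf(pmf, p, extra_meta=meta)
        artifacts["pmf"] = p
        if path is not None:
            p = out / "mep.tsv"
            pio.write_grid_path(path, p)
            artifacts["mep"] = p
            p = out / "stationary_report.tsv"
            _write_report(report, p, chash)
            artifacts["report"] = p
        config.to_yaml(out / "config.yaml")
        artifacts["config"] = out / "config.yaml"
    return PipelineResult(config=config, windows=windows, series=series, pmf=pmf,
                          error_grid=error_grid, path=path, report=report,
                          artifacts=artifacts)


def _write_report(report, path, chash) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        fh.write(f"# reference={report.reference}\n")
        fh.write(f"# barrier={report.barrier}\n")
        fh.write(f"# reaction_energy={report.reaction_energy}\n")
        fh.write(f"# no_transition_state={int(report.no_transition_state)}\n")
        fh.write("label\tposition\tenergy\trelative_energy\tcoordinates\n")
        ref_e = next(s["energy"] for s in report.states if s["label"] == report.reference) \
            if report.reference else 0.0
        for s in report.states:
            coords = ",".join(f"{c:.17g}" for c in s.get("coordinates", ()))
            fh.write(f"{s['label']}\t{s['position']:.17g}\t{s['energy']:.17g}\t"
                     f"{s['energy'] - ref_e:.17g}\t{coords}\n")


def step1_demo_config(master_seed: int = 1, output_dir: str = "step1_demo_out") -> RunConfig:
    """Bundled demonstration: the serine→Asp11-like 2D landscape end to end.

    Window grid 0.1 Å over the basin-to-basin region, short (demo-scale)
    equilibration/production, 0.05 Å bins; produces a 2D PMF, a
    minimum-free-energy path and a stationary report whose labeled
    sequence runs reactant → TS → product.
    """
    spec = LandscapeSpec("psp_step1_like")
    return RunConfig(
        landscape=spec.to_dict(),
        window_ranges=[(-1.6, 1.2), (-1.1, 1.1)],
        window_spacing=0.1,
        n_equil_steps=2000,
        n_prod_steps=6000,
        stride=10,
        bin_width=0.05,
        master_seed=master_seed,
        output_dir=output_dir,
    )


def landscape_report(config: RunConfig) -> list:
    """Stationary points of the configured landscape (basins/saddles)."""
    return stationary_points(config.landscape_spec())
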