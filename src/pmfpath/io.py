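"""Plain-TSV readers and writers for every pipeline artifact.

All files share one shape: '#'-prefixed ``key=value`` metadata lines, one
tab-separated header row, then data rows.  Floats are written with 17
significant digits so write∘read is the identity on values; comment lines
anywhere are ignored; malformed rows raise with their line number.
"""

from __future__ import annotations

import io as _io
import os

import numpy as np

from .chains import ChainPath
from .gridpaths import GridPath
from .grids import PMFGrid, bin_centers
from .rcoords import DistanceFrame
from .sampling import BiasWindow, SampleSeries
from .scans import ScanResult

__all__ = [
    "write_series", "read_series",
    "write_pmf", "read_pmf",
    "write_scan", "read_scan",
    "write_grid_path", "read_grid_path",
    "write_chain", "read_chain",
    "write_frames", "read_frames",
]


def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return "1" if x else "0"
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return "nan"
        return f"{float(x):.17g}"
    return str(x)


def _write(path, meta: dict, header: list, rows) -> None:
    buf = _io.StringIO()
    for k, v in meta.items():
        if isinstance(v, (list, tuple, np.ndarray)):
            v = ",".join(_fmt(x) for x in v)
        buf.write(f"# {k}={v}\n")
    buf.write("\t".join(header) + "\n")
    for row in rows:
        buf.write("\t".join(_fmt(x) for x in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _read(path):
    """Return (meta, header, rows) where rows are (line_number, fields)."""
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip()[1:].strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{os.fspath(path)}: line {ln}: expected {len(header)} columns, "
                    f"got {len(fields)}")
            rows.append((ln, fields))
    if header is None:
        raise ValueError(f"{os.fspath(path)}: no header row found")
    return meta, header, rows


def _floats(fields, ln, path):
    try:
        return [float(x) for x in fields]
    except ValueError as exc:
        raise ValueError(f"{os.fspath(path)}: line {ln}: {exc}") from None


# -- SampleSeries ----------------------------------------------------------

def write_series(path, series: SampleSeries, window: BiasWindow) -> None:
    meta = {
        "window_id": series.window_id,
        "centers": window.centers,
        "k_equilibration": window.force_constants["equilibration"],
        "k_production": window.force_constants["production"],
        "n_equil_steps": window.n_equil_steps,
        "n_prod_steps": window.n_prod_steps,
        "temperature": window.temperature,
        "seed": window.seed,
        "stride": series.stride,
    }
    header = ["step"] + [f"rc{i+1}" for i in range(series.ndim)]
    rows = ((i * series.stride,) + tuple(v) for i, v in enumerate(series.values, start=1))
    _write(path, meta, header, rows)


def read_series(path) -> tuple[SampleSeries, BiasWindow]:
    meta, header, rows = _read(path)
    ndim = len(header) - 1
    values = np.array([_floats(f[1:], ln, path) for ln, f in rows]) if rows else \
        np.empty((0, ndim))
    window = BiasWindow(
        window_id=meta["window_id"],
        centers=tuple(float(x) for x in meta["centers"].split(",")),
        force_constants={"equilibration": float(meta["k_equilibration"]),
                         "production": float(meta["k_production"])},
        n_equil_steps=int(meta["n_equil_steps"]),
        n_prod_steps=int(meta["n_prod_steps"]),
        temperature=float(meta["temperature"]),
        seed=int(meta["seed"]),
    )
    series = SampleSeries(window_id=meta["window_id"], values=values,
                          stride=int(meta.get("stride", 1)))
    return series, window


# -- PMFGrid ---------------------------------------------------------------

def write_pmf(pmf: PMFGrid, path, extra_meta: dict | None = None) -> None:
    meta = dict(extra_meta or {})
    meta.update({
        "ndim": pmf.ndim,
        "temperature": pmf.temperature,
        "axis_names": ",".join(pmf.axis_names),
        "converged": int(pmf.converged),
        "iterations": pmf.iterations,
    })
    for i, e in enumerate(pmf.edges):
        meta[f"edges{i+1}"] = e
    for wid, f in pmf.window_shifts.items():
        meta[f"f[{wid}]"] = _fmt(f)
    centers = pmf.centers
    header = [f"center_{n}" for n in pmf.axis_names] + ["F", "error", "mask"]
    rows = []
    err = pmf.errors
    for ix in np.ndindex(pmf.values.shape):
        row = [centers[d][ix[d]] for d in range(pmf.ndim)]
        row += [pmf.values[ix], (err[ix] if err is not None else float("nan")),
                bool(pmf.mask[ix])]
        rows.append(row)
    _write(path, meta, header, rows)


def read_pmf(path) -> PMFGrid:
    meta, header, rows = _read(path)
    ndim = int(meta["ndim"])
    edges = tuple(np.array([float(x) for x in meta[f"edges{i+1}"].split(",")])
                  for i in range(ndim))
    shape = tuple(len(e) - 1 for e in edges)
    values = np.full(shape, np.nan)
    errors = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    for ln, f in rows:
        nums = _floats(f[:-1], ln, path)
        ctr = nums[:ndim]
        ix = tuple(int(np.argmin(np.abs(bin_centers(edges[d]) - ctr[d])))
                   for d in range(ndim))
        values[ix] = nums[ndim]
        errors[ix] = nums[ndim + 1]
        mask[ix] = f[-1] == "1"
    shifts = {k[2:-1]: float(v) for k, v in meta.items()
              if k.startswith("f[") and k.endswith("]")}
    has_err = np.isfinite(errors).any()
    return PMFGrid(edges=edges, values=values, mask=mask,
                   axis_names=tuple(meta["axis_names"].split(",")),
                   temperature=float(meta["temperature"]),
                   window_shifts=shifts,
                   errors=errors if has_err else None,
                   converged=bool(int(meta["converged"])),
                   iterations=int(meta["iterations"]))


# -- ScanResult ------------------------------------------------------------

def write_scan(result: ScanResult, path) -> None:
    names = result.axis_names or tuple(f"rc{i+1}" for i in range(len(result.grid)))
    meta = {"scanned_axes": ",".join(str(a) for a in result.scanned_axes),
            "axis_names": ",".join(names),
            "ndim_landscape": result.relaxed_points.shape[-1]}
    for i, g in enumerate(result.grid):
        meta[f"grid{i+1}"] = g
    nd = result.relaxed_points.shape[-1]
    header = list(names) + ["energy"] + [f"x{i+1}" for i in range(nd)] + ["converged"]
    rows = []
    for ix in np.ndindex(result.shape):
        row = [result.grid[d][ix[d]] for d in range(len(result.grid))]
        row += [result.energies[ix]]
        row += list(result.relaxed_points[ix])
        row += [bool(result.converged[ix])]
        rows.append(row)
    _write(path, meta, header, rows)


def read_scan(path) -> ScanResult:
    meta, header, rows = _read(path)
    scanned = tuple(int(a) for a in meta["scanned_axes"].split(","))
    grid = tuple(np.array([float(x) for x in meta[f"grid{i+1}"].split(",")])
                 for i in range(len(scanned)))
    nd = int(meta["ndim_landscape"])
    shape = tuple(len(g) for g in grid)
    energies = np.full(shape, np.nan)
    relaxed = np.zeros(shape + (nd,))
    conv = np.zeros(shape, dtype=bool)
    ng = len(grid)
    for ln, f in rows:
        nums = _floats(f[:ng + 1 + nd], ln, path)
        ix = tuple(int(np.argmin(np.abs(grid[d] - nums[d]))) for d in range(ng))
        energies[ix] = nums[ng]
        relaxed[ix] = nums[ng + 1:ng + 1 + nd]
        conv[ix] = f[ng + 1 + nd] == "1"
    return ScanResult(scanned, grid, energies, relaxed, conv,
                      tuple(meta["axis_names"].split(",")))


# -- GridPath --------------------------------------------------------------

def write_grid_path(path_obj: GridPath, path) -> None:
    names = path_obj.axis_names or ("rc1", "rc2")
    meta = {"total_weight": path_obj.total_weight, "axis_names": ",".join(names)}
    header = ["index", "bin_i", "bin_j", *names, "length", "energy"]
    rows = [(k, n[0], n[1], c[0], c[1], l, e)
            for k, (n, c, l, e) in enumerate(zip(path_obj.nodes, path_obj.coordinates,
                                                 path_obj.lengths, path_obj.energies))]
    _write(path, meta, header, rows)


def read_grid_path(path) -> GridPath:
    meta, header, rows = _read(path)
    nodes, coords, lengths, energies = [], [], [], []
    for ln, f in rows:
        nums = _floats(f, ln, path)
        nodes.append((int(nums[1]), int(nums[2])))
        coords.append(nums[3:5])
        lengths.append(nums[5])
        energies.append(nums[6])
    return GridPath(nodes=nodes, coordinates=np.array(coords),
                    energies=np.array(energies), lengths=np.array(lengths),
                    total_weight=float(meta["total_weight"]),
                    axis_names=tuple(meta["axis_names"].split(",")))


# -- ChainPath -------------------------------------------------------------

def write_chain(chain: ChainPath, path, saddle_comment: str | None = None) -> None:
    nd = chain.points.shape[1]
    meta = {"converged": int(chain.converged)}
    header = ["index"] + [f"x{i+1}" for i in range(nd)] + ["energy", "fixed"]
    e = chain.energies if chain.energies is not None else [float("nan")] * chain.n_points
    rows = [(i, *chain.points[i], e[i], bool(chain.fixed[i]))
            for i in range(chain.n_points)]
    _write(path, meta, header, rows)
    if saddle_comment:
        with open(path, "a") as fh:
            for line in saddle_comment.splitlines():
                fh.write(f"# {line}\n")


def read_chain(path) -> ChainPath:
    meta, header, rows = _read(path)
    nd = len(header) - 3
    pts, energies, fixed = [], [], []
    for ln, f in rows:
        nums = _floats(f[1:1 + nd + 1], ln, path)
        pts.append(nums[:nd])
        energies.append(nums[nd])
        fixed.append(f[-1] == "1")
    e = np.array(energies)
    return ChainPath(points=np.array(pts),
                     energies=None if np.isnan(e).all() else e,
                     fixed=np.array(fixed),
                     converged=bool(int(meta.get("converged", 1))))


# -- DistanceFrame tables --------------------------------------------------

def write_frames(frames, path) -> None:
    frames = list(frames)
    labels = sorted({lbl for f in frames for lbl in f.distances})
    header = ["frame"] + labels
    rows = [(f.frame, *(f.distances.get(l, float("nan")) for l in labels))
            for f in frames]
    _write(path, {}, header, rows)


def read_frames(path) -> list[DistanceFrame]:
    meta, header, rows = _read(path)
    labels = header[1:]
    out = []
    for ln, f in rows:
        nums = _floats(f, ln, path)
        d = {lbl: v for lbl, v in zip(labels, nums[1:]) if np.isfinite(v)}
        out.append(DistanceFrame(distances=d, frame=nums[0]))
    return out
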