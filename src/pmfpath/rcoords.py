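"""Reaction coordinates as signed linear combinations of interatomic distances.

The phosphoryl-transfer steps are described by one or two coordinates, each
a signed sum of named distances (Å):

* ``OPO_step1`` =  d(Ser-OG–P) − d(P–O-Asp11): breaking/forming P–O bonds of
  the serine→Asp11 transfer;
* ``OHO_step1`` = −d(Ser-OG–H) + d(H–OD-Asp13): the accompanying proton
  transfer;
* ``OPO_step2`` =  d(P–O-Asp11) − d(wat-O–P): phosphoaspartate hydrolysis;
* ``OHO_step2`` =  d(wat-O–H) − d(H–OT-Asp11): proton transfer variant with
  the phosphate's non-bridging oxygen as acceptor reference;
* ``OHO_step2_asp13`` = d(wat-O–H) − d(H–OD-Asp13): the variant used in the
  tabulated 2D analyses.  Both step-2 proton coordinates ship because the
  source analyses themselves use both; neither is privileged.

Distance labels vary across sources ("P–OD-Asp11" vs "P–O-Asp11", "watO"
vs "Wat-O"); a registry normalizes all known variants to canonical keys so
frames written with any of them evaluate identically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "RCDefinition",
    "DistanceFrame",
    "eval_rc",
    "canonical_rc",
    "project_profile",
    "canonical_label",
    "BUILTIN_RCS",
    "round_half_up",
    "load_scan_states",
]


def _normalize_token(label: str) -> str:
    s = label.strip().lower()
    s = s.replace("–", "-").replace("—", "-")  # en/em dashes
    s = re.sub(r"[\s_]+", "", s)
    s = s.replace("-", "")
    return s


#: variant spellings -> canonical distance key
_LABEL_REGISTRY: dict[str, str] = {}


def _register(canonical: str, *variants: str) -> None:
    for v in (canonical,) + variants:
        _LABEL_REGISTRY[_normalize_token(v)] = canonical


_register("Ser-OG-P", "SerOG–P", "Ser-OG–P")
_register("P-O-Asp11", "P–OD-Asp11", "P–O-Asp11", "P-OD-Asp11")
_register("H-OD-Asp13", "H–OD-Asp13")
_register("Ser-OG-H", "SerOG–H", "Ser-OG–H")
_register("Ser-OT-H", "Ser-OT–H")
_register("Wat-O-P", "watO–P", "Wat-O–P", "watO-P", "wat-O-P")
_register("Wat-O-H", "watO–H", "Wat-O–H", "watO-H", "wat-O-H")
_register("H-OT-Asp11", "H–OT-Asp11")


def canonical_label(label: str) -> str:
    """Map any registered spelling variant to its canonical distance key.

    Unregistered labels pass through unchanged (free-form labels are
    allowed; only exact-normalized matches are rewritten).
    """
    return _LABEL_REGISTRY.get(_normalize_token(label), label.strip())


@dataclass(frozen=True)
class RCDefinition:
    """A named signed linear combination of distances, units Å."""

    name: str
    terms: tuple  # ((sign, label), ...), sign in {+1, -1}

    def __post_init__(self):
        if not self.terms:
            raise ValueError("an RC definition needs at least one term")
        canon = tuple((int(s), canonical_label(lbl)) for s, lbl in self.terms)
        labels = [lbl for _, lbl in canon]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate distance labels in {self.name!r}")
        if any(s not in (1, -1) for s, _ in canon):
            raise ValueError("signs must be +1 or -1")
        object.__setattr__(self, "terms", canon)

    def negated(self) -> "RCDefinition":
        return RCDefinition(self.name + "_neg", tuple((-s, l) for s, l in self.terms))


@dataclass
class DistanceFrame:
    """Named interatomic distances (Å) for one frame or path point."""

    distances: dict
    frame: int | float = 0

    def __post_init__(self):
        d = {canonical_label(k): float(v) for k, v in self.distances.items()}
        if any(v <= 0 for v in d.values()):
            raise ValueError("all distances must be positive")
        self.distances = d


BUILTIN_RCS: dict[str, RCDefinition] = {
    "OPO_step1": RCDefinition("OPO_step1", ((+1, "Ser-OG-P"), (-1, "P-O-Asp11"))),
    "OHO_step1": RCDefinition("OHO_step1", ((-1, "Ser-OG-H"), (+1, "H-OD-Asp13"))),
    "OPO_step2": RCDefinition("OPO_step2", ((+1, "P-O-Asp11"), (-1, "Wat-O-P"))),
    "OHO_step2": RCDefinition("OHO_step2", ((+1, "Wat-O-H"), (-1, "H-OT-Asp11"))),
    "OHO_step2_asp13": RCDefinition("OHO_step2_asp13", ((+1, "Wat-O-H"), (-1, "H-OD-Asp13"))),
}


def eval_rc(defn: RCDefinition, frame: DistanceFrame) -> float:
    """Σ sign · distance over the definition's terms, Å."""
    total = 0.0
    for sign, label in defn.terms:
        if label not in frame.distances:
            raise KeyError(f"frame is missing distance {label!r} required by {defn.name!r}")
        total += sign * frame.distances[label]
    return total


def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero at the given decimal, as printed tables do."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def canonical_rc(path, normalize: bool = False) -> np.ndarray:
    """Accumulated arc length along a path — the canonical reaction coordinate.

    ``path`` may be a ChainPath/GridPath (anything with ``points`` or
    ``coordinates``) or a plain (n, d) array.  Starts at 0 and is strictly
    increasing; with ``normalize=True`` it is rescaled to [0, 1].
    """
    pts = getattr(path, "points", None)
    if pts is None:
        pts = getattr(path, "coordinates", None)
    if pts is None:
        pts = np.asarray(path, dtype=float)
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("empty path")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if normalize:
        if s[-1] == 0:
            raise ValueError("zero-length path cannot be normalized")
        s = s / s[-1]
    return s


def load_scan_states(step: int) -> list[dict]:
    """Bundled stationary-state distance rows for a transfer step (1 or 2).

    Each row dict has ``block``, ``state``, printed rc values ``rc1``/``rc2``
    (None where absent), per-component exactness flags, the OHO definition
    name applicable to ``rc2`` (step 2 only), and a :class:`DistanceFrame`
    holding the printed distances.
    """
    from importlib import resources

    if step not in (1, 2):
        raise ValueError("step must be 1 or 2")
    name = f"step{step}_scan_states.tsv"
    text = resources.files("pmfpath.data").joinpath(name).read_text()
    lines = [l for l in text.splitlines() if l.strip() and not l.lstrip().startswith("#")]
    header = lines[0].split("\t")
    out = []
    for i, line in enumerate(lines[1:]):
        f = dict(zip(header, line.split("\t")))
        meta_cols = {"block", "state", "rc1", "rc2", "oho_defn", "exact_rc1", "exact_rc2"}
        distances = {k: float(v) for k, v in f.items() if k not in meta_cols and v}
        out.append({
            "block": f["block"],
            "state": f["state"],
            "rc1": float(f["rc1"]) if f.get("rc1") else None,
            "rc2": float(f["rc2"]) if f.get("rc2") else None,
            "oho_defn": f.get("oho_defn") or None,
            "exact_rc1": f.get("exact_rc1") == "1",
            "exact_rc2": f.get("exact_rc2") == "1",
            "frame": DistanceFrame(distances=distances, frame=i),
        })
    return out


def project_profile(energies, frames, definitions):
    """Project a path energy profile onto 1–2 distance-based coordinates.

    Returns ``(rc_values, energies, report)`` where ``rc_values`` has one
    column per definition and rows follow *path order* — deliberately not
    re-sorted, so a projection that doubles back (corner cutting) stays
    visible.  The report states whether each projected coordinate is
    strictly monotone and whether the projection is injective.
    """
    defs = [definitions] if isinstance(definitions, RCDefinition) else list(definitions)
    if not 1 <= len(defs) <= 2:
        raise ValueError("1 or 2 RC definitions required")
    energies = np.asarray(energies, dtype=float)
    frames = list(frames)
    if len(frames) != len(energies):
        raise ValueError(
            f"length mismatch: {len(energies)} energies vs {len(frames)} frames")
    rc = np.array([[eval_rc(d, f) for d in defs] for f in frames])
    report = {}
    for j, d in enumerate(defs):
        diffs = np.diff(rc[:, j])
        report[d.name] = {
            "strictly_increasing": bool(np.all(diffs > 0)),
            "strictly_decreasing": bool(np.all(diffs < 0)),
        }
    seen = set()
    injective = True
    for row in np.round(rc, 12):
        key = tuple(row)
        if key in seen:
            injective = False
            break
        seen.add(key)
    report["injective"] = injective
    report["monotone"] = all(
        v["strictly_increasing"] or v["strictly_decreasing"]
        for k, v in report.items() if isinstance(v, dict)
    )
    return rc, energies.copy(), report
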