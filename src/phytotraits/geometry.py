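"""Geometric cell/individual forms and biovolume computation.

Fourteen simple solids cover the cell and individual shapes used for
phytoplankton biovolume estimation (EN 16695 / Hillebrand-style models):
sphere, cylinder, rotational ellipsoid, flattened ellipsoid, cymbelloid,
staurastrum and ceratium forms, oval cylinder, double cone, parallelepiped,
prisms on parallelogram and triangular bases, cone with half sphere, and
tetrahedron.  Every shape carries a closed-form volume in µm³ and a
membership predicate over an axis-aligned bounding box, so each formula is
verifiable against the hit-or-miss Monte-Carlo estimator in this module.

Composite forms are explicit decompositions:

* cymbelloid — half elliptic cylinder, V = (π/8)·l·w·h;
* ceratium form — flattened-ellipsoid body plus ``n_horns`` cones,
  V = (π/6)·l·w·t + n·(π/12)·horn_d²·horn_l (default 3 horns);
* staurastrum form — double-cone body plus ``n_arms`` conical arms,
  V = (π/12)·d²·h + n·(π/12)·arm_d²·arm_l (default 4 arms).

Horn/arm counts are integer parameters, not linear dimensions, so every
volume is homogeneous of degree 3 in its dimension set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ShapeSpec",
    "ShapeError",
    "MonteCarloEstimate",
    "SHAPES",
    "list_shapes",
    "get_shape",
    "cell_biovolume",
    "monte_carlo_volume",
    "individual_biovolume",
]


class ShapeError(ValueError):
    """Invalid shape name, dimension set, or dimension value."""


# A primitive solid for Monte-Carlo sampling: bounding-box edge lengths and
# a vectorised membership predicate over coordinates centred in that box.
@dataclass(frozen=True)
class _Solid:
    box: tuple[float, float, float]
    contains: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ShapeSpec:
    """One geometric form: required dimensions, volume, and MC solids."""

    name: str
    dims: tuple[str, ...]
    description: str
    volume_fn: Callable[[Mapping[str, float], Mapping[str, int]], float]
    solids_fn: Callable[[Mapping[str, float], Mapping[str, int]], list[_Solid]]
    counts: Mapping[str, int] = field(default_factory=dict)
    constraints: tuple[Callable[[Mapping[str, float]], str | None], ...] = ()

    def volume(self, dims: Mapping[str, float], counts: Mapping[str, int] | None = None) -> float:
        return self.volume_fn(dims, self._merge_counts(counts))

    def solids(self, dims: Mapping[str, float], counts: Mapping[str, int] | None = None):
        return self.solids_fn(dims, self._merge_counts(counts))

    def _merge_counts(self, counts: Mapping[str, int] | None) -> dict[str, int]:
        merged = dict(self.counts)
        for k, v in (counts or {}).items():
            if k not in merged:
                raise ShapeError(f"shape {self.name!r} has no count parameter {k!r}")
            if int(v) < 1:
                raise ShapeError(f"count parameter {k!r} must be >= 1, got {v}")
            merged[k] = int(v)
        return merged


def _validate_dims(spec: ShapeSpec, dims: Mapping[str, float]) -> dict[str, float]:
    got, want = set(dims), set(spec.dims)
    missing = want - got
    if missing:
        raise ShapeError(f"shape {spec.name!r}: missing dimension(s) {sorted(missing)}")
    extra = got - want
    if extra:
        raise ShapeError(f"shape {spec.name!r}: unknown dimension(s) {sorted(extra)}")
    clean = {}
    for k in spec.dims:
        v = float(dims[k])
        if not math.isfinite(v) or v <= 0:
            raise ShapeError(f"shape {spec.name!r}: dimension {k!r} must be > 0, got {dims[k]}")
        clean[k] = v
    for constraint in spec.constraints:
        msg = constraint(clean)
        if msg:
            raise ShapeError(f"shape {spec.name!r}: {msg}")
    return clean


# ---------------------------------------------------------------------------
# Primitive solids
# ---------------------------------------------------------------------------

def _ellipsoid(a: float, b: float, c: float) -> _Solid:
    # full axes a, b, c
    def contains(x, y, z):
        return (x / (a / 2)) ** 2 + (y / (b / 2)) ** 2 + (z / (c / 2)) ** 2 <= 1.0

    return _Solid((a, b, c), contains)


def _elliptic_cylinder(l: float, w: float, h: float, half: bool = False) -> _Solid:
    wy = w / 2 if half else w

    def contains(x, y, z):
        if half:
            # half-ellipse section: y in [-w/4, w/4] box, shift to [0, w/2]
            yy = y + w / 4
            ok = yy >= 0
            return ok & ((x / (l / 2)) ** 2 + (yy / (w / 2)) ** 2 <= 1.0)
        return (x / (l / 2)) ** 2 + (y / (w / 2)) ** 2 <= 1.0

    return _Solid((l, wy, h), contains)


def _box(l: float, w: float, h: float) -> _Solid:
    return _Solid((l, w, h), lambda x, y, z: np.ones_like(x, dtype=bool))


def _cone(d: float, h: float) -> _Solid:
    # apex at z = +h/2, base at z = -h/2
    def contains(x, y, z):
        frac = 0.5 - z / h  # 1 at base, 0 at apex
        return x * x + y * y <= (d / 2 * frac) ** 2

    return _Solid((d, d, h), contains)


def _double_cone(d: float, h: float) -> _Solid:
    def contains(x, y, z):
        frac = 1.0 - 2.0 * np.abs(z) / h
        return x * x + y * y <= (d / 2 * frac) ** 2

    return _Solid((d, d, h), contains)


def _rhombic_prism(l: float, w: float, h: float) -> _Solid:
    # prism of length l, rhombic section with diagonals w (y) and h (z)
    def contains(x, y, z):
        return np.abs(y) / (w / 2) + np.abs(z) / (h / 2) <= 1.0

    return _Solid((l, w, h), contains)


def _triangular_prism(l: float, w: float, h: float) -> _Solid:
    # prism of length l, isosceles triangular section (base w, height h)
    def contains(x, y, z):
        zz = z + h / 2  # 0 at base
        return np.abs(y) <= (w / 2) * (1.0 - zz / h)

    return _Solid((l, w, h), contains)


def _cone_half_sphere(d: float, h: float) -> _Solid:
    r = d / 2
    hc = h - r  # cone height above the hemisphere

    def contains(x, y, z):
        zz = z + h / 2 - r  # hemisphere centre at zz = 0, flat side up
        rho2 = x * x + y * y
        in_hemi = (zz <= 0) & (rho2 + zz * zz <= r * r)
        if hc > 0:
            frac = 1.0 - zz / hc
            in_cone = (zz > 0) & (zz <= hc) & (rho2 <= (r * np.maximum(frac, 0.0)) ** 2)
        else:
            in_cone = np.zeros_like(in_hemi)
        return in_hemi | in_cone

    return _Solid((d, d, h), contains)


def _tetrahedron(a: float, h: float) -> _Solid:
    # pyramid over an equilateral triangle (edge a), apex over the centroid
    R = a / math.sqrt(3.0)  # circumradius of the base
    verts = [
        (R * math.cos(t), R * math.sin(t))
        for t in (math.pi / 2, math.pi * 7 / 6, math.pi * 11 / 6)
    ]
    ymin, ymax = -R / 2, R

    def contains(x, y, z):
        zz = z + h / 2  # base at zz = 0
        yy = y + (ymin + ymax) / 2  # recentre base in its bounding box
        s = 1.0 - zz / h  # linear shrink factor toward the apex
        inside = s > 0
        for (x1, y1), (x2, y2) in zip(verts, verts[1:] + verts[:1]):
            # vertices are CCW: interior points lie left of every edge
            cross = (x2 - x1) * (yy - s * y1) - (y2 - y1) * (x - s * x1)
            inside &= cross >= 0
        return inside

    return _Solid((a, ymax - ymin, h), contains)


# ---------------------------------------------------------------------------
# The 14-form registry
# ---------------------------------------------------------------------------

def _simple(name, dims, desc, vol, solid, constraints=()):
    return ShapeSpec(
        name=name,
        dims=tuple(dims),
        description=desc,
        volume_fn=lambda d, c: vol(d),
        solids_fn=lambda d, c: [solid(d)],
        constraints=tuple(constraints),
    )


def _ceratium_volume(d, c):
    body = math.pi / 6 * d["l"] * d["w"] * d["t"]
    horns = c["n_horns"] * math.pi / 12 * d["horn_d"] ** 2 * d["horn_l"]
    return body + horns


def _ceratium_solids(d, c):
    solids = [_ellipsoid(d["l"], d["w"], d["t"])]
    solids += [_cone(d["horn_d"], d["horn_l"]) for _ in range(c["n_horns"])]
    return solids


def _staurastrum_volume(d, c):
    body = math.pi / 12 * d["d"] ** 2 * d["h"]
    arms = c["n_arms"] * math.pi / 12 * d["arm_d"] ** 2 * d["arm_l"]
    return body + arms


def _staurastrum_solids(d, c):
    solids = [_double_cone(d["d"], d["h"])]
    solids += [_cone(d["arm_d"], d["arm_l"]) for _ in range(c["n_arms"])]
    return solids


SHAPES: dict[str, ShapeSpec] = {
    s.name: s
    for s in [
        _simple(
            "sphere", ["d"], "sphere of diameter d",
            lambda d: math.pi / 6 * d["d"] ** 3,
            lambda d: _ellipsoid(d["d"], d["d"], d["d"]),
        ),
        _simple(
            "cylinder", ["d", "h"], "circular cylinder, diameter d, height h",
            lambda d: math.pi / 4 * d["d"] ** 2 * d["h"],
            lambda d: _elliptic_cylinder(d["d"], d["d"], d["h"]),
        ),
        _simple(
            "rotational_ellipsoid", ["d", "h"],
            "spheroid: equatorial diameter d, polar axis h",
            lambda d: math.pi / 6 * d["d"] ** 2 * d["h"],
            lambda d: _ellipsoid(d["d"], d["d"], d["h"]),
        ),
        _simple(
            "flattened_ellipsoid", ["l", "w", "t"],
            "triaxial ellipsoid: length l, width w, thickness t",
            lambda d: math.pi / 6 * d["l"] * d["w"] * d["t"],
            lambda d: _ellipsoid(d["l"], d["w"], d["t"]),
        ),
        _simple(
            "cymbelloid", ["l", "w", "h"],
            "half elliptic cylinder (cymbelloid section): length l, width w, height h",
            lambda d: math.pi / 8 * d["l"] * d["w"] * d["h"],
            lambda d: _elliptic_cylinder(d["l"], d["w"], d["h"], half=True),
        ),
        ShapeSpec(
            name="staurastrum",
            dims=("d", "h", "arm_d", "arm_l"),
            description="double-cone body (d, h) with n_arms conical arms (arm_d, arm_l)",
            volume_fn=_staurastrum_volume,
            solids_fn=_staurastrum_solids,
            counts={"n_arms": 4},
        ),
        ShapeSpec(
            name="ceratium",
            dims=("l", "w", "t", "horn_d", "horn_l"),
            description="flattened-ellipsoid body (l, w, t) with n_horns cones (horn_d, horn_l)",
            volume_fn=_ceratium_volume,
            solids_fn=_ceratium_solids,
            counts={"n_horns": 3},
        ),
        _simple(
            "oval_cylinder", ["l", "w", "h"],
            "elliptic cylinder: section axes l and w, height h",
            lambda d: math.pi / 4 * d["l"] * d["w"] * d["h"],
            lambda d: _elliptic_cylinder(d["l"], d["w"], d["h"]),
        ),
        _simple(
            "double_cone", ["d", "h"],
            "two cones joined base to base: diameter d, total height h",
            lambda d: math.pi / 12 * d["d"] ** 2 * d["h"],
            lambda d: _double_cone(d["d"], d["h"]),
        ),
        _simple(
            "parallelepiped", ["l", "w", "h"], "rectangular box l x w x h",
            lambda d: d["l"] * d["w"] * d["h"],
            lambda d: _box(d["l"], d["w"], d["h"]),
        ),
        _simple(
            "prism_on_parallelogram_base", ["l", "w", "h"],
            "prism of length l on a rhombic base with diagonals w and h",
            lambda d: 0.5 * d["l"] * d["w"] * d["h"],
            lambda d: _rhombic_prism(d["l"], d["w"], d["h"]),
        ),
        _simple(
            "prism_on_triangular_base", ["l", "w", "h"],
            "prism of length l on a triangular base (base w, height h)",
            lambda d: 0.5 * d["l"] * d["w"] * d["h"],
            lambda d: _triangular_prism(d["l"], d["w"], d["h"]),
        ),
        _simple(
            "cone_with_half_sphere", ["d", "h"],
            "cone capped by a hemisphere; d diameter, h total height (h >= d/2)",
            lambda d: math.pi / 12 * d["d"] ** 2 * (d["h"] + d["d"] / 2),
            lambda d: _cone_half_sphere(d["d"], d["h"]),
            constraints=[
                lambda d: (
                    f"total height h={d['h']} must be >= d/2={d['d'] / 2}"
                    if d["h"] < d["d"] / 2 else None
                )
            ],
        ),
        _simple(
            "tetrahedron", ["a", "h"],
            "pyramid over an equilateral triangle of edge a, height h",
            lambda d: math.sqrt(3.0) / 12 * d["a"] ** 2 * d["h"],
            lambda d: _tetrahedron(d["a"], d["h"]),
        ),
    ]
}


def list_shapes() -> list[ShapeSpec]:
    """All 14 registered cell/individual forms."""
    return list(SHAPES.values())


def get_shape(name: str) -> ShapeSpec:
    try:
        return SHAPES[name]
    except KeyError:
        raise ShapeError(
            f"unknown shape {name!r}; known shapes: {sorted(SHAPES)}"
        ) from None


def cell_biovolume(
    shape: str | ShapeSpec,
    dims: Mapping[str, float],
    counts: Mapping[str, int] | None = None,
) -> float:
    """Closed-form biovolume (µm³) of one cell of the given form."""
    spec = get_shape(shape) if isinstance(shape, str) else shape
    clean = _validate_dims(spec, dims)
    return spec.volume(clean, counts)


@dataclass(frozen=True)
class MonteCarloEstimate:
    """Hit-or-miss volume estimate with its standard error."""

    value: float
    stderr: float
    n: int
    n_hits: int


def monte_carlo_volume(
    shape: str | ShapeSpec,
    dims: Mapping[str, float],
    n: int = 1_000_000,
    seed: int = 0,
    counts: Mapping[str, int] | None = None,
) -> MonteCarloEstimate:
    """Hit-or-miss Monte-Carlo volume estimate in µm³.

    Component solids of composite forms are sampled in disjoint boxes
    stacked along x (their volumes are additive by construction), so the
    estimate is unbiased for the declared decomposition.  Reproducible for
    a fixed seed.
    """
    if n < 10_000:
        raise ShapeError("monte_carlo_volume requires n >= 10000")
    spec = get_shape(shape) if isinstance(shape, str) else shape
    clean = _validate_dims(spec, dims)
    solids = spec.solids(clean, counts)

    # stack component boxes along x
    lx = sum(s.box[0] for s in solids)
    ly = max(s.box[1] for s in solids)
    lz = max(s.box[2] for s in solids)
    box_volume = lx * ly * lz

    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, lx, n)
    y = rng.uniform(-ly / 2, ly / 2, n)
    z = rng.uniform(-lz / 2, lz / 2, n)

    hit = np.zeros(n, dtype=bool)
    offset = 0.0
    for s in solids:
        bx, by, bz = s.box
        sel = (x >= offset) & (x < offset + bx) & (np.abs(y) <= by / 2) & (np.abs(z) <= bz / 2)
        if sel.any():
            hit[sel] |= s.contains(x[sel] - offset - bx / 2, y[sel], z[sel])
        offset += bx
    k = int(hit.sum())
    p = k / n
    value = box_volume * p
    stderr = box_volume * math.sqrt(max(p * (1.0 - p), 0.0) / n)
    return MonteCarloEstimate(value=value, stderr=stderr, n=n, n_hits=k)


def individual_biovolume(
    cell_bv: float,
    life_form: str,
    cells_per_individual: float | None = None,
) -> float | None:
    """Biovolume of the natural unit (µm³).

    Unicellular taxa: the cell biovolume itself.  Colonies and filaments:
    cell biovolume times cells per individual; with the count missing the
    result is missing (None) and the caller records a flag.
    """
    if not (isinstance(cell_bv, (int, float)) and math.isfinite(cell_bv) and cell_bv > 0):
        raise ValueError(f"cell biovolume must be > 0, got {cell_bv!r}")
    if life_form not in ("cell", "colony", "filament"):
        raise ValueError(f"unknown life form {life_form!r}")
    if life_form == "cell":
        return float(cell_bv)
    if cells_per_individual is None or (
        isinstance(cells_per_individual, float) and math.isnan(cells_per_individual)
    ):
        return None
    if cells_per_individual <= 0:
        raise ValueError(
            f"cells per individual must be > 0, got {cells_per_individual!r}"
        )
    return float(cell_bv) * float(cells_per_individual)
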