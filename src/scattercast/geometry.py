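"""Scene description and exact ray-solid intersection kernels.

The world frame has the beam isocenter at the origin, +z up, +y along the
patient's longitudinal axis (head toward +y) and +x toward the patient's
left, which is where the x-ray tube sits at LAO 90 degrees.  All lengths
are centimetres.

Solids are elliptic cylinders and (possibly oriented) boxes, each carrying a
material; the scene resolves any point to exactly one material by solid
priority (list order: staff phantom > patient > table > floor/ceiling > air).
Phase-space surfaces are axis-aligned boxes tagged with the scatterer group
they enclose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .materials import Material

LATERAL_ONLY = "lateral_only"
WITH_CAPS = "with_caps"

SURFACE_ROLES = ("phase_space_patient_table", "phase_space_floor", "phase_space_ceiling",
                 "world_boundary")

# surface_tag codes used in phase-space records
TAG_PATIENT_TABLE = 0
TAG_FLOOR = 1
TAG_CEILING = 2
TAG_NAMES = {TAG_PATIENT_TABLE: "patient_table", TAG_FLOOR: "floor", TAG_CEILING: "ceiling"}
TAG_CODES = {v: k for k, v in TAG_NAMES.items()}

_EPS_SURFACE = 1e-9


class OutOfWorldError(ValueError):
    """Point lies outside the world bounding box."""


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def _frame_for_axis(axis, a_direction=None):
    """Orthonormal rows (a_dir, b_dir, axis) for a cylinder local frame."""
    axis = _unit(axis)
    if a_direction is None:
        trial = np.array([1.0, 0.0, 0.0])
        if abs(axis @ trial) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        a_dir = trial - (trial @ axis) * axis
    else:
        a_dir = np.asarray(a_direction, dtype=float)
        a_dir = a_dir - (a_dir @ axis) * axis
    a_dir = _unit(a_dir)
    b_dir = np.cross(axis, a_dir)
    return np.vstack([a_dir, b_dir, axis])


@dataclass(frozen=True)
class EllipticCylinder:
    """Elliptic cylinder solid: axis midpoint ``center``, unit ``axis``,
    lateral semi-axes ``semi_axis_a``/``semi_axis_b`` along the local frame,
    half-height along the axis."""

    center: np.ndarray
    axis: np.ndarray
    semi_axis_a: float
    semi_axis_b: float
    half_height: float
    material: Material
    name: str = "cylinder"
    a_direction: np.ndarray | None = None
    absorber: bool = False

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "axis", _unit(self.axis))
        if min(self.semi_axis_a, self.semi_axis_b, self.half_height) <= 0:
            raise ValueError("semi-axes and half_height must be positive")
        object.__setattr__(self, "_rot", _frame_for_axis(self.axis, self.a_direction))

    @property
    def rotation(self) -> np.ndarray:
        """World->local rotation; rows are the local frame axes."""
        return self._rot

    @property
    def volume_cm3(self) -> float:
        return float(np.pi * self.semi_axis_a * self.semi_axis_b * 2.0 * self.half_height)

    @property
    def mass_g(self) -> float:
        return self.volume_cm3 * self.material.density

    def translated(self, offset) -> "EllipticCylinder":
        return replace(self, center=self.center + np.asarray(offset, dtype=float))

    def contains(self, points) -> np.ndarray:
        p = (np.atleast_2d(points) - self.center) @ self._rot.T
        inside = ((p[:, 0] / self.semi_axis_a) ** 2 + (p[:, 1] / self.semi_axis_b) ** 2 <= 1.0)
        inside &= np.abs(p[:, 2]) <= self.half_height
        return inside if np.ndim(points) == 2 else bool(inside[0])


@dataclass(frozen=True)
class Box:
    """Box solid (axis-aligned unless a rotation is given)."""

    center: np.ndarray
    half_extents: np.ndarray
    material: Material
    name: str = "box"
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    absorber: bool = False

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "half_extents", np.asarray(self.half_extents, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        if np.any(self.half_extents <= 0):
            raise ValueError("half_extents must be positive")

    def corners(self) -> np.ndarray:
        signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
        return self.center + (signs * self.half_extents) @ self.rotation

    def contains(self, points) -> np.ndarray:
        p = (np.atleast_2d(points) - self.center) @ self.rotation.T
        inside = np.all(np.abs(p) <= self.half_extents, axis=1)
        return inside if np.ndim(points) == 2 else bool(inside[0])


@dataclass(frozen=True)
class BoxSurface:
    """Axis-aligned phase-space recording box."""

    center: np.ndarray
    half_extents: np.ndarray
    role: str

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "half_extents", np.asarray(self.half_extents, dtype=float))
        if self.role not in SURFACE_ROLES:
            raise ValueError(f"unknown surface role {self.role!r}")
        if np.any(self.half_extents <= 0):
            raise ValueError("half_extents must be positive")

    @property
    def lo(self):
        return self.center - self.half_extents

    @property
    def hi(self):
        return self.center + self.half_extents

    @property
    def tag(self) -> int:
        return {"phase_space_patient_table": TAG_PATIENT_TABLE,
                "phase_space_floor": TAG_FLOOR,
                "phase_space_ceiling": TAG_CEILING}[self.role]

    def strict_interior(self, points) -> np.ndarray:
        p = np.atleast_2d(points) - self.center
        inside = np.all(np.abs(p) < self.half_extents, axis=1)
        return inside if np.ndim(points) == 2 else bool(inside[0])


@dataclass
class Scene:
    """The room: prioritized solids, phase-space surfaces, ambient material,
    world bounding box (axis-aligned, centered at the origin)."""

    solids: list
    surfaces: list
    ambient: Material
    world_half_extents: np.ndarray

    def __post_init__(self):
        self.world_half_extents = np.asarray(self.world_half_extents, dtype=float)
        names = [s.name for s in self.solids]
        if len(set(names)) != len(names):
            raise ValueError(f"solid names must be unique, got {names}")

    def solid(self, name: str):
        for s in self.solids:
            if s.name == name:
                return s
        raise KeyError(name)

    def with_solids(self, extra_front=(), remove=()):
        solids = [s for s in extra_front] + [s for s in self.solids if s.name not in remove]
        return Scene(solids, list(self.surfaces), self.ambient, self.world_half_extents.copy())

    def surface_by_tag(self, tag: int) -> BoxSurface:
        for s in self.surfaces:
            if s.role != "world_boundary" and s.tag == tag:
                return s
        raise KeyError(tag)


# ---------------------------------------------------------------------------
# Intersection kernels (vectorized over rays; scalar wrappers below)
# ---------------------------------------------------------------------------

def ellcyl_hit_distances(origins, directions, cyl: EllipticCylinder,
                         caps_mode: str = WITH_CAPS) -> np.ndarray:
    """Nearest positive hit distance per ray against an elliptic cylinder.

    Exact quadratic solve for the lateral surface in the cylinder frame,
    clipped to |axial| <= half_height; end caps included only in
    ``with_caps`` mode.  Misses return +inf.  Hits closer than 1e-9 are
    rejected (ray starting on the surface).
    """
    if caps_mode not in (LATERAL_ONLY, WITH_CAPS):
        raise ValueError(f"caps_mode must be {LATERAL_ONLY!r} or {WITH_CAPS!r}")
    o = (np.atleast_2d(origins) - cyl.center) @ cyl.rotation.T
    d = np.atleast_2d(directions) @ cyl.rotation.T
    a_, b_, h = cyl.semi_axis_a, cyl.semi_axis_b, cyl.half_height

    qa = (d[:, 0] / a_) ** 2 + (d[:, 1] / b_) ** 2
    qb = o[:, 0] * d[:, 0] / a_**2 + o[:, 1] * d[:, 1] / b_**2
    qc = (o[:, 0] / a_) ** 2 + (o[:, 1] / b_) ** 2 - 1.0

    best = np.full(o.shape[0], np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = qb * qb - qa * qc
        sq = np.sqrt(np.maximum(disc, 0.0))
        for sign in (-1.0, 1.0):
            t = (-qb + sign * sq) / qa
            z = o[:, 2] + t * d[:, 2]
            ok = (disc > 0) & (qa > 0) & (t > _EPS_SURFACE) & (np.abs(z) <= h)
            best = np.where(ok & (t < best), t, best)
        if caps_mode == WITH_CAPS:
            for zc in (-h, h):
                t = (zc - o[:, 2]) / d[:, 2]
                x = o[:, 0] + t * d[:, 0]
                y = o[:, 1] + t * d[:, 1]
                ok = (np.abs(d[:, 2]) > 0) & (t > _EPS_SURFACE) \
                    & ((x / a_) ** 2 + (y / b_) ** 2 <= 1.0)
                best = np.where(ok & (t < best), t, best)
    return best


def intersect_ray_elliptic_cylinder(origin, direction, cyl: EllipticCylinder,
                                    caps_mode: str = WITH_CAPS):
    """Scalar ray-cylinder test.

    Returns ``None`` on a miss, else ``(distance, point, normal)`` with the
    outward surface normal at the hit point.
    """
    direction = np.asarray(direction, dtype=float)
    n = np.linalg.norm(direction)
    if not np.isclose(n, 1.0, atol=1e-9):
        raise ValueError("direction must be unit norm")
    t = ellcyl_hit_distances(np.atleast_2d(origin), direction[None, :], cyl, caps_mode)[0]
    if not np.isfinite(t):
        return None
    point = np.asarray(origin, dtype=float) + t * direction
    local = cyl.rotation @ (point - cyl.center)
    if abs(abs(local[2]) - cyl.half_height) < 1e-7 and caps_mode == WITH_CAPS \
            and (local[0] / cyl.semi_axis_a) ** 2 + (local[1] / cyl.semi_axis_b) ** 2 < 1.0 - 1e-12:
        normal_local = np.array([0.0, 0.0, np.sign(local[2])])
    else:
        normal_local = np.array([local[0] / cyl.semi_axis_a**2,
                                 local[1] / cyl.semi_axis_b**2, 0.0])
        normal_local /= np.linalg.norm(normal_local)
    normal = normal_local @ cyl.rotation
    return float(t), point, normal


def box_entry_exit(origins, directions, lo, hi):
    """Slab-method entry/exit distances per ray against an axis-aligned box.

    Returns ``(t_entry, t_exit)`` arrays; rays that miss have
    ``t_entry > t_exit``.  Rays originating inside yield a negative entry.
    """
    o = np.atleast_2d(origins)
    d = np.atleast_2d(directions)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / d
        t1 = (lo - o) * inv
        t2 = (hi - o) * inv
        tmin = np.minimum(t1, t2)
        tmax = np.maximum(t1, t2)
        # Axes with zero direction: strictly inside the slab -> (-inf, +inf);
        # on or outside the face -> miss (degenerate grazing rays are no-hits).
        zero = d == 0.0
        inside_slab = (o > lo) & (o < hi)
        tmin = np.where(zero, np.where(inside_slab, -np.inf, np.inf), tmin)
        tmax = np.where(zero, np.where(inside_slab, np.inf, -np.inf), tmax)
    return tmin.max(axis=1), tmax.min(axis=1)


def intersect_ray_box(origin, direction, box) -> tuple[float, float] | None:
    """Entry/exit distances of a ray against a box (solid or surface box).

    Interior origins return entry 0.  Degenerate grazing rays (entry equals
    exit) resolve to no-hit.  Returns ``None`` on a miss.
    """
    direction = np.asarray(direction, dtype=float)
    if not np.isclose(np.linalg.norm(direction), 1.0, atol=1e-9):
        raise ValueError("direction must be unit norm")
    if isinstance(box, Box) and not np.allclose(box.rotation, np.eye(3)):
        o = (np.asarray(origin, dtype=float) - box.center) @ box.rotation.T
        d = direction @ box.rotation.T
        lo, hi = -box.half_extents, box.half_extents
    else:
        o, d = np.asarray(origin, dtype=float), direction
        lo, hi = box.center - box.half_extents, box.center + box.half_extents
    t0, t1 = box_entry_exit(o[None, :], d[None, :], lo, hi)
    t0, t1 = float(t0[0]), float(t1[0])
    if t1 <= max(t0, 0.0) or t1 <= _EPS_SURFACE or t0 >= t1:
        return None
    return max(t0, 0.0), t1


def locate(scene: Scene, point):
    """Resolve a point to ``(material, region_tag)`` by solid priority."""
    p = np.asarray(point, dtype=float)
    if np.any(np.abs(p) > scene.world_half_extents):
        raise OutOfWorldError(f"point {p} outside world half-extents {scene.world_half_extents}")
    for s in scene.solids:
        if getattr(s, "absorber", False):
            continue
        if s.contains(p[None, :])[0]:
            return s.material, s.name
    return scene.ambient, "ambient"
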