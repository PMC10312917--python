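"""Beam incidence angle on the skull from a 3D skull map.

The sonicated patch of the outer (transducer-facing) skull surface is
collected by marching rays parallel to the beam axis inside the converging
beam's footprint, a total-least-squares plane is fitted to the patch, and
the incidence angle is reported as ``90 - alpha`` degrees, where ``alpha``
is the angle between the fitted plane's normal and the propagation
direction.  Under this convention 90 deg means perpendicular (normal)
incidence, the geometry that transmits best through bone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .transducer import TransducerGeometry
from .volume import SkullMask

__all__ = [
    "SurfacePatch",
    "PlaneFit",
    "IncidenceResult",
    "beam_footprint_radius",
    "extract_outer_surface",
    "fit_plane",
    "incidence_angle",
    "estimate_incidence",
]


@dataclass
class SurfacePatch:
    """Outer-surface voxel centers (mm) inside the beam footprint."""

    points: np.ndarray  # (N, 3) mm

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self):
        return len(self.points)


@dataclass(frozen=True)
class PlaneFit:
    centroid: tuple[float, float, float]  # mm
    normal: tuple[float, float, float]  # unit
    rms_residual: float  # mm

    def __post_init__(self):
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("plane normal must be a unit vector")
        if self.rms_residual < 0:
            raise ValueError("residual must be non-negative")


@dataclass(frozen=True)
class IncidenceResult:
    alpha_deg: float  # angle between plane normal and propagation
    incidence_deg: float  # 90 - alpha; 90 = perpendicular incidence
    n_points: int = 0
    rms_residual_mm: float = 0.0
    footprint_radius_mm: float = float("nan")

    def __post_init__(self):
        if not 0.0 <= self.alpha_deg <= 90.0:
            raise ValueError("alpha must lie in [0, 90] degrees")
        if abs((90.0 - self.alpha_deg) - self.incidence_deg) > 1e-12:
            raise ValueError("incidence must equal 90 - alpha exactly")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "alpha_deg": self.alpha_deg,
                    "incidence_deg": self.incidence_deg,
                    "n_points": self.n_points,
                    "rms_residual_mm": self.rms_residual_mm,
                    "footprint_radius_mm": self.footprint_radius_mm,
                },
                fh,
                indent=2,
            )


def beam_footprint_radius(geom: TransducerGeometry, depth_mm: float, multiplier: float = 1.0) -> float:
    """Radius (mm) of the converging beam's ray envelope at a given depth.

    Models the focused beam as the geometric cone from the outer aperture
    to the focus: ``r = (OD / 2) * (F - depth) / F``.  Undefined at or
    beyond the focus in this model.
    """
    if not 0 < depth_mm < geom.focal_distance:
        raise ValueError("depth must lie strictly between the aperture plane and the focus")
    return multiplier * (geom.outer_diameter / 2) * (geom.focal_distance - depth_mm) / geom.focal_distance


def extract_outer_surface(
    mask: SkullMask,
    geom: TransducerGeometry,
    footprint_multiplier: float = 1.0,
) -> tuple[SurfacePatch, float]:
    """Collect the sonicated outer-surface patch inside the beam footprint.

    The beam axis is marched from the transducer origin until it meets the
    skull; the footprint radius is evaluated at that depth.  For every
    lateral position inside the footprint disc, a ray parallel to the
    propagation direction is marched and the center of the first mask voxel
    hit is recorded.  Returns the patch and the footprint radius (mm).
    """
    if not mask.data.any():
        raise ValueError("empty skull mask")
    origin = np.asarray(geom.origin, dtype=float)
    d = np.asarray(geom.propagation, dtype=float)
    step = min(mask.spacing) / 2.0

    # depth of the first axial hit
    t_max = float(np.linalg.norm(mask.grid.extent)) + float(np.linalg.norm(origin - mask.grid.center))
    ts = np.arange(0.0, t_max, step)
    axis_pts = origin[None, :] + ts[:, None] * d[None, :]
    hit = _mask_lookup(mask, axis_pts)
    if not hit.any():
        raise ValueError("beam misses skull")
    depth = float(ts[np.argmax(hit)])

    radius = beam_footprint_radius(geom, depth, footprint_multiplier)

    # lateral sampling grid perpendicular to the beam
    e1 = _orthonormal(d)
    e2 = np.cross(d, e1)
    # offsets are integer multiples of the lateral step, so rays stay
    # aligned with voxel centers instead of straddling voxel boundaries
    lat = min(mask.spacing)
    n_off = int(np.floor(radius / lat))
    offs = lat * np.arange(-n_off, n_off + 1)
    uu, vv = np.meshgrid(offs, offs, indexing="ij")
    keep = uu**2 + vv**2 <= radius**2
    uu, vv = uu[keep], vv[keep]
    starts = origin[None, :] + uu[:, None] * e1[None, :] + vv[:, None] * e2[None, :]

    # march all rays over a window around the axial hit depth (chunked so
    # the (rays x samples x 3) buffer stays modest on fine grids)
    t0 = max(0.0, depth - 1.5 * radius - 5.0)
    t1 = depth + 3.0 * radius + 10.0
    ts = np.arange(t0, t1, step)
    hit_list = []
    for lo in range(0, len(starts), 2048):
        chunk = starts[lo : lo + 2048]
        pts = chunk[:, None, :] + ts[None, :, None] * d[None, None, :]  # (rays, t, 3)
        inside = _mask_lookup(mask, pts.reshape(-1, 3)).reshape(pts.shape[:2])
        any_hit = inside.any(axis=1)
        first = np.argmax(inside, axis=1)
        hit_list.append(pts[np.nonzero(any_hit)[0], first[any_hit], :])
    hits = np.concatenate(hit_list, axis=0)
    # snap to voxel centers, deduplicate
    idx = np.rint(
        (hits - np.asarray(mask.origin)) / np.asarray(mask.spacing)
    ).astype(int)
    idx = np.unique(idx, axis=0)
    centers = np.asarray(mask.origin) + idx * np.asarray(mask.spacing)
    return SurfacePatch(centers), radius


def _orthonormal(d: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to d."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e = np.cross(d, ref)
    return e / np.linalg.norm(e)


def _mask_lookup(mask: SkullMask, pts: np.ndarray) -> np.ndarray:
    idx = np.rint(mask.mm_to_index(pts)).astype(int)
    inb = np.all((idx >= 0) & (idx < np.asarray(mask.data.shape)), axis=-1)
    out = np.zeros(len(pts), dtype=bool)
    if inb.any():
        good = idx[inb]
        out[inb] = mask.data[good[:, 0], good[:, 1], good[:, 2]]
    return out


def fit_plane(patch: SurfacePatch, propagation=None) -> PlaneFit:
    """Total-least-squares plane through the patch.

    The normal is the singular vector of the centered point scatter with
    the smallest singular value; when a propagation direction is given the
    normal's sign is chosen so that ``normal . propagation >= 0``, making
    downstream angles independent of the arbitrary normal orientation.
    """
    pts = patch.points
    if len(pts) < 3:
        raise ValueError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear or duplicate-degenerate scatter: no unique plane
    scale = max(svals[0], 1e-12)
    if svals[1] / scale < 1e-9:
        raise ValueError("degenerate patch: points are collinear or coincident")
    normal = vt[2]
    if propagation is not None and float(normal @ np.asarray(propagation, dtype=float)) < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    normal = normal / np.linalg.norm(normal)
    return PlaneFit(tuple(centroid), tuple(normal), rms)


def incidence_angle(plane: PlaneFit, geom: TransducerGeometry, **extra) -> IncidenceResult:
    """Incidence angle from a fitted plane: ``90 - alpha`` degrees, where
    alpha is the (unsigned) angle between the plane normal and the beam."""
    n = np.asarray(plane.normal, dtype=float)
    d = np.asarray(geom.propagation, dtype=float)
    alpha = float(np.degrees(np.arccos(np.clip(abs(float(n @ d)), 0.0, 1.0))))
    return IncidenceResult(
        alpha_deg=alpha,
        incidence_deg=90.0 - alpha,
        rms_residual_mm=plane.rms_residual,
        **extra,
    )


def estimate_incidence(
    mask: SkullMask,
    geom: TransducerGeometry,
    footprint_multiplier: float = 1.0,
) -> IncidenceResult:
    """Full chain: surface patch -> plane fit -> incidence angle."""
    patch, radius = extract_outer_surface(mask, geom, footprint_multiplier)
    plane = fit_plane(patch, geom.propagation)
    return incidence_angle(
        plane, geom, n_points=len(patch), footprint_radius_mm=radius
    )
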