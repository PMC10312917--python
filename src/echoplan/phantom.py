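"""Synthetic skull phantoms with analytically known ground truth.

Real cranial data for this pipeline (primate skull CT, hydrophone scans,
harmonic B-mode stacks) are not publicly deposited, so validation runs on
procedurally generated phantoms: curved or flat bone shells voxelized on a
grid, Hounsfield-unit volumes around them, and speckle-bearing B-mode slice
stacks in which the shell is hyperechoic.  Every phantom carries its ground
truth (surface normal at the beam axis, shell thickness, landmark
distances) computed in closed form from the analytic geometry, never from
the voxelization, so downstream estimators can be scored against it.

Geometry conventions
--------------------
* The un-rotated shell is oriented with its outward normal (slab) or pole
  (spherical cap) along +z; the interrogating beam by default travels along
  -z, i.e. normal incidence on an un-rotated phantom.
* ``rotation_deg`` are intrinsic Euler angles applied about x, then y, then
  z, rotating the shell about ``center``.
* Suture gaps are planar slots perpendicular to the shell-local x axis;
  socket holes are cylindrical punch-outs along the shell-local z axis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .recon import BModeStack
from .volume import Grid, SkullMask, VoxelVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "ImagingParams",
    "make_shell_phantom",
    "make_hu_volume",
    "make_bmode_stack",
    "rotate_volume",
]

_SHAPES = ("flat_slab", "spherical_cap", "ellipsoidal_shell")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of an analytic bone-shell phantom.

    ``radius`` applies to ``spherical_cap``, ``semi_axes`` to
    ``ellipsoidal_shell``; ``flat_slab`` needs neither.  ``slab_extent`` is
    the lateral half-width of a slab (``None`` = unbounded, clipped by the
    grid).  HU defaults span the CT-conversion range: dense bone at 1000 HU
    over a water/soft-tissue background at 0 HU.
    """

    shape: str = "flat_slab"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    thickness: float = 5.0  # mm
    radius: float | None = None  # mm, spherical_cap
    semi_axes: tuple[float, float, float] | None = None  # mm, ellipsoidal_shell
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hu_bone: float = 1000.0
    hu_background: float = 0.0
    hu_noise_sd: float = 0.0
    slab_extent: float | None = None  # mm, lateral half-width of a slab
    cap_angle_deg: float = 60.0  # angular extent of a spherical cap from its pole
    suture_gaps: tuple[tuple[float, float], ...] = ()  # (local-x position mm, width mm)
    socket_holes: tuple[tuple[tuple[float, float], float], ...] = ()  # ((lx, ly) mm, radius mm)
    seed: int = 0

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown phantom shape {self.shape!r}; choose from {_SHAPES}")
        if not self.thickness > 0:
            raise ValueError("shell thickness must be positive")
        if self.shape == "spherical_cap":
            if self.radius is None:
                raise ValueError("spherical_cap requires a radius")
            if self.thickness >= self.radius:
                raise ValueError("shell thickness must be smaller than the radius")
        if self.shape == "ellipsoidal_shell":
            if self.semi_axes is None:
                raise ValueError("ellipsoidal_shell requires semi_axes")
            if self.thickness >= min(self.semi_axes):
                raise ValueError("shell thickness must be smaller than the smallest semi-axis")

    @property
    def rotation_matrix(self) -> np.ndarray:
        """Local-to-world rotation (intrinsic x -> y -> z)."""
        return Rotation.from_euler("XYZ", self.rotation_deg, degrees=True).as_matrix()

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("center", "rotation_deg", "semi_axes"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if "suture_gaps" in d:
            d["suture_gaps"] = tuple(tuple(g) for g in d["suture_gaps"] or ())
        if "socket_holes" in d:
            d["socket_holes"] = tuple((tuple(h[0]), h[1]) for h in d["socket_holes"] or ())
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form truth for a phantom, evaluated where the beam axis first
    meets the outer shell surface."""

    surface_normal_at_axis: tuple[float, float, float]
    incidence_angle_deg: float
    thickness_mm: float
    landmark_pairs: tuple = ()  # (pointA mm, pointB mm, distance mm)

    def __post_init__(self):
        n = np.asarray(self.surface_normal_at_axis, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("surface normal must be a unit vector")
        if not 0.0 < self.incidence_angle_deg <= 90.0:
            raise ValueError("incidence angle must lie in (0, 90] degrees")


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition parameters the B-mode emulator reproduces: 0.14 mm
    in-plane pixels with slices every 0.2 mm (full map) or 0.5 mm (partial
    map used for incidence estimation)."""

    in_plane_spacing: tuple[float, float] = (0.14, 0.14)  # mm
    slice_spacing: float = 0.2  # mm
    bone_level: float = 0.8  # mean echo intensity of bone (arbitrary units)
    background_level: float = 0.05
    speckle: bool = True


# ---------------------------------------------------------------------------
# analytic shell membership


def _local_coords(spec: PhantomSpec, xs, ys, zs):
    """Rotate world coordinates into the shell-local frame (broadcasting)."""
    R = spec.rotation_matrix
    cx, cy, cz = spec.center
    px, py, pz = xs - cx, ys - cy, zs - cz
    # q = R^T p
    qx = R[0, 0] * px + R[1, 0] * py + R[2, 0] * pz
    qy = R[0, 1] * px + R[1, 1] * py + R[2, 1] * pz
    qz = R[0, 2] * px + R[1, 2] * py + R[2, 2] * pz
    return qx, qy, qz


def _shell_membership_local(spec: PhantomSpec, qx, qy, qz):
    t = spec.thickness
    if spec.shape == "flat_slab":
        inside = np.abs(qz) <= t / 2
        if spec.slab_extent is not None:
            inside &= (np.abs(qx) <= spec.slab_extent) & (np.abs(qy) <= spec.slab_extent)
    elif spec.shape == "spherical_cap":
        r = np.sqrt(qx**2 + qy**2 + qz**2)
        inside = (r >= spec.radius - t) & (r <= spec.radius)
        with np.errstate(invalid="ignore", divide="ignore"):
            polar = np.where(r > 0, qz / np.maximum(r, 1e-300), 1.0)
        inside &= polar >= np.cos(np.deg2rad(spec.cap_angle_deg))
    else:  # ellipsoidal_shell
        a = np.asarray(spec.semi_axes, dtype=float)
        outer = (qx / a[0]) ** 2 + (qy / a[1]) ** 2 + (qz / a[2]) ** 2
        ai = a - t
        inner = (qx / ai[0]) ** 2 + (qy / ai[1]) ** 2 + (qz / ai[2]) ** 2
        inside = (outer <= 1.0) & (inner >= 1.0)
    # carve suture gaps (slots perpendicular to local x) and socket holes
    for pos, width in spec.suture_gaps:
        inside &= ~(np.abs(qx - pos) < width / 2)
    for (hx, hy), rad in spec.socket_holes:
        inside &= ~((qx - hx) ** 2 + (qy - hy) ** 2 < rad**2)
    return inside


def shell_membership(spec: PhantomSpec, points_mm: np.ndarray) -> np.ndarray:
    """Evaluate the analytic shell at arbitrary points (..., 3) in mm."""
    pts = np.asarray(points_mm, dtype=float)
    qx, qy, qz = _local_coords(spec, pts[..., 0], pts[..., 1], pts[..., 2])
    return _shell_membership_local(spec, qx, qy, qz)


# ---------------------------------------------------------------------------
# ground truth


def _first_outer_hit(spec: PhantomSpec, beam_point, beam_dir):
    """First intersection of the beam line with the *outer* shell surface
    and the outward unit normal there, both in local coordinates."""
    R = spec.rotation_matrix
    o = R.T @ (np.asarray(beam_point, dtype=float) - np.asarray(spec.center, dtype=float))
    d = R.T @ np.asarray(beam_dir, dtype=float)
    d = d / np.linalg.norm(d)

    if spec.shape == "flat_slab":
        if abs(d[2]) < 1e-12:
            raise ValueError("beam is parallel to the slab; no outer-surface hit")
        # proximal face is the one whose outward normal opposes the beam
        z_face = spec.thickness / 2 * (-np.sign(d[2]))
        t_hit = (z_face - o[2]) / d[2]
        q = o + t_hit * d
        if spec.slab_extent is not None and (
            abs(q[0]) > spec.slab_extent or abs(q[1]) > spec.slab_extent
        ):
            raise ValueError("beam misses the slab's lateral extent")
        n = np.array([0.0, 0.0, -np.sign(d[2])])
        return q, n

    if spec.shape == "spherical_cap":
        rad = spec.radius
        b = 2 * float(o @ d)
        c0 = float(o @ o) - rad**2
        disc = b * b - 4 * c0
        if disc < 0:
            raise ValueError("beam misses the spherical shell")
        cos_cap = np.cos(np.deg2rad(spec.cap_angle_deg))
        for t_hit in sorted(((-b - np.sqrt(disc)) / 2, (-b + np.sqrt(disc)) / 2)):
            q = o + t_hit * d
            if q[2] / rad >= cos_cap:
                n = q / rad
                if float(n @ d) > 0:
                    n = -n
                return q, n
        raise ValueError("beam misses the spherical cap")

    # ellipsoidal_shell
    a = np.asarray(spec.semi_axes, dtype=float)
    A = 1.0 / a**2
    aa = float(np.sum(A * d * d))
    bb = 2 * float(np.sum(A * o * d))
    cc = float(np.sum(A * o * o)) - 1.0
    disc = bb * bb - 4 * aa * cc
    if disc < 0:
        raise ValueError("beam misses the ellipsoidal shell")
    t_hit = (-bb - np.sqrt(disc)) / (2 * aa)
    q = o + t_hit * d
    n = A * q
    n = n / np.linalg.norm(n)
    if float(n @ d) > 0:
        n = -n
    return q, n


def _ground_truth(spec: PhantomSpec, beam_point, beam_dir) -> GroundTruth:
    R = spec.rotation_matrix
    d = np.asarray(beam_dir, dtype=float)
    d = d / np.linalg.norm(d)
    _, n_local = _first_outer_hit(spec, beam_point, beam_dir)
    n_world = R @ n_local
    alpha = np.degrees(np.arccos(np.clip(abs(float(n_world @ d)), 0.0, 1.0)))
    incidence = 90.0 - alpha

    landmarks = []
    for (hx, hy), rad in spec.socket_holes:
        # rim points of the punch-out at the mid-shell level: their
        # separation is the hole diameter by construction
        if spec.shape == "flat_slab":
            z_mid = 0.0
        elif spec.shape == "spherical_cap":
            z_mid = np.sqrt(max((spec.radius - spec.thickness / 2) ** 2 - hx**2 - hy**2, 0.0))
        else:
            a = np.asarray(spec.semi_axes, dtype=float) - spec.thickness / 2
            z_mid = a[2] * np.sqrt(max(1 - (hx / a[0]) ** 2 - (hy / a[1]) ** 2, 0.0))
        pa = np.asarray(spec.center) + R @ np.array([hx - rad, hy, z_mid])
        pb = np.asarray(spec.center) + R @ np.array([hx + rad, hy, z_mid])
        landmarks.append((tuple(pa), tuple(pb), 2.0 * rad))

    return GroundTruth(
        surface_normal_at_axis=tuple(n_world),
        incidence_angle_deg=float(incidence),
        thickness_mm=spec.thickness,
        landmark_pairs=tuple(landmarks),
    )


# ---------------------------------------------------------------------------
# generators


def make_shell_phantom(
    spec: PhantomSpec,
    grid: Grid,
    beam_point=None,
    beam_dir=(0.0, 0.0, -1.0),
) -> tuple[SkullMask, GroundTruth]:
    """Voxelize the analytic shell on ``grid`` and return it with its truth.

    A voxel belongs to the shell iff its *center* lies inside the analytic
    shell.  The ground-truth normal is evaluated where the beam line
    (through ``beam_point``, default the phantom center, along
    ``beam_dir``) first crosses the outer surface.
    """
    if beam_point is None:
        beam_point = spec.center
    xs, ys, zs = grid.meshgrid()
    qx, qy, qz = _local_coords(spec, xs, ys, zs)
    inside = _shell_membership_local(spec, qx, qy, qz)
    if not inside.any():
        raise ValueError("phantom outside field of view")
    mask = SkullMask(inside, grid.spacing, grid.origin)
    return mask, _ground_truth(spec, beam_point, beam_dir)


def make_hu_volume(mask: SkullMask, spec: PhantomSpec) -> VoxelVolume:
    """Paint the shell with bone HU over a uniform background, optionally
    adding seeded Gaussian noise inside the bone."""
    hu = np.full(mask.data.shape, spec.hu_background, dtype=np.float32)
    hu[mask.data] = spec.hu_bone
    if spec.hu_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu[mask.data] += rng.normal(0.0, spec.hu_noise_sd, int(mask.data.sum())).astype(np.float32)
    return VoxelVolume(hu, mask.spacing, mask.origin)


def make_bmode_stack(mask: SkullMask, imaging: ImagingParams = ImagingParams(), seed: int = 0) -> BModeStack:
    """Emulate the acquisition product of harmonic B-mode raster scanning.

    The segmented-bone geometry is resampled onto the imaging lattice, given
    a two-level echogenicity template (hyperechoic bone band over a dim
    background) and degraded with multiplicative Rayleigh speckle of unit
    mean -- the statistics a B-mode segmenter must tolerate.  Beamforming
    physics (diverging waves, pulse inversion) is out of scope; the emulator
    reproduces the image stack, not the acquisition chain.
    """
    sx, sy = imaging.in_plane_spacing
    sz = imaging.slice_spacing
    target = Grid(
        tuple(max(1, int(round(e / s))) for e, s in zip(mask.grid.extent, (sx, sy, sz))),
        (sx, sy, sz),
        mask.origin,
    )
    xs = [target.axis_coords(a) for a in range(3)]
    idx = [
        (x - mask.origin[a]) / mask.spacing[a]
        for a, x in enumerate(xs)
    ]
    coords = np.meshgrid(*idx, indexing="ij")
    resampled = ndimage.map_coordinates(
        mask.data.astype(np.uint8), np.stack(coords), order=0, mode="constant", cval=0
    ).astype(bool)

    template = np.where(resampled, imaging.bone_level, imaging.background_level).astype(np.float32)
    if imaging.speckle:
        rng = np.random.default_rng(seed)
        # Rayleigh with unit mean: scale = sqrt(2 / pi)
        template *= rng.rayleigh(scale=np.sqrt(2 / np.pi), size=template.shape).astype(np.float32)
    slices = [template[:, :, k] for k in range(template.shape[2])]
    return BModeStack(slices=slices, in_plane_spacing=(sx, sy), slice_spacing=sz, origin=mask.origin)


def rotate_volume(vol, euler_deg, interpolation: str = "trilinear"):
    """Resample a volume under an intrinsic x->y->z rotation about its
    physical center.  Masks are rotated with nearest-neighbour lookup and
    stay binary; scalar volumes default to trilinear interpolation with the
    minimum value as fill."""
    if interpolation not in ("nearest", "trilinear"):
        raise ValueError("interpolation must be 'nearest' or 'trilinear'")
    is_mask = isinstance(vol, SkullMask) or vol.data.dtype == bool
    order = 0 if (is_mask or interpolation == "nearest") else 1
    R = Rotation.from_euler("XYZ", euler_deg, degrees=True).as_matrix()
    s = np.asarray(vol.spacing)
    c_mm = s * (np.asarray(vol.data.shape) - 1) / 2.0  # center relative to origin
    # affine_transform maps output index -> input index: i_in = M i_out + b
    M = np.diag(1 / s) @ R.T @ np.diag(s)
    b = np.diag(1 / s) @ (c_mm - R.T @ c_mm)
    data = vol.data.astype(np.float32) if not is_mask else vol.data.astype(np.uint8)
    cval = float(data.min()) if not is_mask else 0
    out = ndimage.affine_transform(data, M, offset=b, order=order, mode="constant", cval=cval)
    if is_mask:
        return SkullMask(out.astype(bool), vol.spacing, vol.origin)
    return VoxelVolume(out, vol.spacing, vol.origin)
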