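"""Skull reconstruction from B-mode slice stacks, and morphometry.

A raster scan produces an ordered stack of 2D grayscale images.  Each slice
is segmented (automatically by thresholding + morphology, or by importing a
manually drawn polygon ROI), the per-slice masks are stacked into a 3D
binary skull map, and simple morphometric quantities -- bone thickness
along a probing line, caliper-style landmark distances -- are read off the
map in physical millimetres.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import tifffile
from shapely.geometry import Polygon
from skimage import filters, morphology

from .volume import SkullMask

__all__ = [
    "BModeStack",
    "segment_slice_auto",
    "segment_stack",
    "import_manual_roi",
    "stack_slices",
    "measure_thickness",
    "measure_distance",
]


@dataclass
class BModeStack:
    """An ordered stack of co-planar grayscale B-mode images.

    Slices are stacked along the third volume axis: a stack of N slices at
    ``slice_spacing`` millimetres spans ``N * slice_spacing`` mm.
    """

    slices: list
    in_plane_spacing: tuple[float, float]  # mm
    slice_spacing: float  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.slices) == 0:
            raise ValueError("stack must contain at least one slice")
        shapes = {np.asarray(s).shape for s in self.slices}
        if len(shapes) != 1:
            raise ValueError(f"all slices must share one shape, got {shapes}")
        if any(s <= 0 for s in self.in_plane_spacing) or self.slice_spacing <= 0:
            raise ValueError("spacings must be positive")
        self.slices = [np.asarray(s) for s in self.slices]

    def __len__(self):
        return len(self.slices)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (*self.in_plane_spacing, self.slice_spacing)

    @property
    def extent_mm(self) -> float:
        """Physical depth spanned along the stacking axis."""
        return len(self.slices) * self.slice_spacing

    def to_array(self) -> np.ndarray:
        return np.stack(self.slices, axis=2)

    def save(self, path, sidecar=None) -> None:
        """Write a multi-page TIFF plus a JSON sidecar carrying spacings."""
        arr = self.to_array()
        tifffile.imwrite(str(path), np.moveaxis(arr, 2, 0).astype(np.float32))
        sidecar = sidecar or str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "in_plane_spacing_mm": list(self.in_plane_spacing),
                    "slice_spacing_mm": self.slice_spacing,
                    "origin_mm": list(self.origin),
                    "n_slices": len(self.slices),
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path, sidecar=None) -> "BModeStack":
        arr = tifffile.imread(str(path))
        sidecar = sidecar or str(path) + ".json"
        with open(sidecar) as fh:
            meta = json.load(fh)
        slices = [arr[k] for k in range(arr.shape[0])]
        return cls(
            slices=slices,
            in_plane_spacing=tuple(meta["in_plane_spacing_mm"]),
            slice_spacing=meta["slice_spacing_mm"],
            origin=tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))),
        )


def segment_slice_auto(
    image: np.ndarray,
    threshold="otsu",
    min_component_px: int = 20,
    closing_radius: int = 1,
) -> np.ndarray:
    """Segment the hyperechoic bone band in one slice.

    Intensity thresholding (Otsu by default, or a fixed value), removal of
    components smaller than ``min_component_px``, then morphological
    closing with a disk of ``closing_radius`` pixels to fill speckle
    drop-outs inside the band.  An image with no super-threshold pixels
    yields an empty mask with a warning rather than an error, since slices
    beyond the skull legitimately contain no bone.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if threshold == "otsu":
        if np.ptp(image) == 0:
            warnings.warn("slice has uniform intensity; returning empty mask")
            return np.zeros(image.shape, dtype=bool)
        thr = filters.threshold_otsu(image)
    else:
        thr = float(threshold)
    mask = image > thr
    if not mask.any():
        warnings.warn("no super-threshold pixels; returning empty mask")
        return mask
    if min_component_px > 1:
        mask = morphology.remove_small_objects(mask, max_size=min_component_px - 1)
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    return mask


def segment_stack(
    stack: BModeStack,
    threshold="otsu",
    min_component_px: int = 20,
    closing_radius: int = 1,
) -> SkullMask:
    """Segment a whole B-mode stack into a 3D skull map.

    A single intensity threshold is derived from the pooled histogram of
    all slices (Otsu by default) and applied slice by slice with the usual
    morphology.  Pooling matters: a slice that contains no bone has a
    unimodal speckle histogram, and a per-slice threshold would bisect the
    background there; the pooled threshold separates bone from background
    consistently across the stack.
    """
    arr = stack.to_array()
    if threshold == "otsu":
        thr = float(filters.threshold_otsu(arr))
    else:
        thr = float(threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # bone-free slices legitimately come back empty
        masks = [
            segment_slice_auto(
                s, threshold=thr, min_component_px=min_component_px, closing_radius=closing_radius
            )
            for s in stack.slices
        ]
    return stack_slices(masks, stack.in_plane_spacing, stack.slice_spacing, origin=stack.origin)


def import_manual_roi(polygon_vertices, image_shape) -> np.ndarray:
    """Rasterize a manually drawn polygon ROI (pixel-center in/out rule).

    Vertices are (x, y) = (row, col) pixel coordinates.  Degenerate
    (zero-area) and self-intersecting polygons are rejected.
    """
    import shapely

    verts = np.asarray(polygon_vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    centered = verts - verts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("degenerate polygon with zero area (collinear vertices)")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise ValueError("self-intersecting polygon")
    if poly.area == 0:
        raise ValueError("degenerate polygon with zero area")
    shape = tuple(image_shape)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return shapely.contains_xy(poly, rr.ravel(), cc.ravel()).reshape(shape)


def stack_slices(masks, in_plane_spacing, slice_spacing, origin=(0.0, 0.0, 0.0)) -> SkullMask:
    """Assemble per-slice binary masks into a 3D skull map.

    The stacking axis is the third volume axis with voxel pitch
    ``slice_spacing`` (0.2 mm for a full map, 0.5 mm for a partial map).
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len(masks) == 0:
        raise ValueError("no slices to stack")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mixed slice shapes: {shapes}")
    vol = np.stack(masks, axis=2)
    return SkullMask(vol, (*in_plane_spacing, float(slice_spacing)), origin)


def measure_thickness(
    mask: SkullMask,
    line_start,
    line_direction,
    step_mm: float = 0.02,
    max_length_mm: float | None = None,
) -> float:
    """Bone thickness along a probing line, in mm.

    The line is sampled every ``step_mm`` with nearest-neighbour mask
    lookup; thickness is the distance between the first entry into and the
    last exit out of the mask (internal gaps such as diploe count as part
    of the bone band).  A line that never meets the mask raises.
    """
    p0 = np.asarray(line_start, dtype=float)
    d = np.asarray(line_direction, dtype=float)
    d = d / np.linalg.norm(d)
    if max_length_mm is None:
        max_length_mm = float(np.linalg.norm(np.asarray(mask.grid.extent))) * 2
    ts = np.arange(0.0, max_length_mm, step_mm)
    pts = p0[None, :] + ts[:, None] * d[None, :]
    idx = np.rint(mask.mm_to_index(pts)).astype(int)
    inb = np.all((idx >= 0) & (idx < np.asarray(mask.data.shape)), axis=1)
    inside = np.zeros(len(ts), dtype=bool)
    inside[inb] = mask.data[idx[inb, 0], idx[inb, 1], idx[inb, 2]]
    if not inside.any():
        raise ValueError("line misses skull")
    hit = np.nonzero(inside)[0]
    return float(ts[hit[-1]] - ts[hit[0]])


def measure_distance(point_a, point_b) -> float:
    """Euclidean caliper distance between two landmarks, in mm."""
    a = np.asarray(point_a, dtype=float)
    b = np.asarray(point_b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("landmark coordinates must be finite")
    return float(np.linalg.norm(a - b))
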