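"""Generate a synthetic skull phantom and its B-mode stack.

Builds a 5 mm bone slab tilted 20 degrees (a 70-degree beam incidence),
voxelizes it, paints a Hounsfield-unit volume around it, and emulates the
speckled harmonic B-mode raster scan a coaxial imaging probe would record.
"""

import numpy as np

from echoplan import Grid, PhantomSpec
from echoplan.phantom import ImagingParams, make_bmode_stack, make_hu_volume, make_shell_phantom

spec = PhantomSpec(
    shape="flat_slab",
    center=(0.0, 0.0, -82.5),  # slab surface 80 mm below the transducer
    thickness=5.0,
    rotation_deg=(0.0, 20.0, 0.0),  # tilt about y -> 70 deg incidence
    hu_bone=1000.0,
    seed=7,
)
grid = Grid(shape=(120, 120, 100), spacing=(0.5, 0.5, 0.5), origin=(-30.0, -30.0, -105.0))

mask, truth = make_shell_phantom(spec, grid)
hu = make_hu_volume(mask, spec)
stack = make_bmode_stack(mask, ImagingParams(in_plane_spacing=(0.25, 0.25), slice_spacing=0.5), seed=7)

print(f"mask voxels:            {mask.n_voxels}")
print(f"ground-truth incidence: {truth.incidence_angle_deg:.2f} deg (the known answer the")
print("                        estimation pipeline must recover)")
print(f"ground-truth thickness: {truth.thickness_mm:.1f} mm")
print(f"HU range:               {hu.data.min():.0f} .. {hu.data.max():.0f}")
print(f"B-mode stack:           {len(stack)} slices of {stack.slices[0].shape}, "
      f"{stack.slice_spacing} mm apart ({stack.extent_mm:.0f} mm of skull)")
print(f"mean image intensity:   {float(np.mean(stack.to_array())):.3f} "
      "(speckled; the bone band is hyperechoic)")
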