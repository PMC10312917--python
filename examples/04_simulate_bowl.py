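"""Free-field bowl simulation checked against the analytic field.

Runs the 2D k-space pseudospectral solver for the 250 kHz bowl in water
and compares the focal pressure with the Green's-function superposition
over the same source voxels (the discrete Rayleigh integral).
"""

import numpy as np

from echoplan import SimulationConfig, TransducerGeometry, make_bowl_source, simulate
from echoplan.ct_props import AcousticMediumMap
from echoplan.solver import point_source_field

dx = 0.4  # mm -> 15 points per wavelength in water at 250 kHz
shape = (320, 321)
geom = TransducerGeometry()
medium = AcousticMediumMap.homogeneous_water(shape, (dx, dx))
bowl = make_bowl_source(geom, shape, dx, apex_index=15)
print(f"arc source: {len(bowl)} voxels, all {geom.focal_distance} mm (+-dx) from the focus")

field = simulate(medium, bowl, SimulationConfig(f0=250e3))

peak = np.unravel_index(np.argmax(field.max_pressure), shape)
sim_peak = field.max_pressure[peak]
oracle = abs(
    point_source_field(bowl.indices * dx, (dx * 1e-3) ** 2, [bowl.focus_index * dx], 250e3, 1500.0, ndim=2)
)[0]
print(f"simulated focal max: {sim_peak:.4e} Pa per unit source strength")
print(f"analytic prediction: {oracle:.4e} Pa ({(sim_peak / oracle - 1) * 100:+.1f}%)")
print(f"peak voxel {tuple(int(i) for i in peak)} vs geometric focus "
      f"{tuple(float(i) for i in bowl.focus_index)}")
print("(the axial profile is flat to <1% over several mm, so the axial peak")
print(" position is only defined up to that plateau)")
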