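"""The attenuation-vs-incidence-angle experiment (reduced size).

Tilts a 5 mm bone slab through four incidence angles, re-estimates each
angle from the voxelized skull map with the imaging pipeline, simulates
the transcranial field per tilt against one free-field reference, and
fits the attenuation-vs-angle line.  The full experiment uses 8 angles;
four keep this example quick (a few minutes on one core).
"""

from echoplan import PhantomSpec
from echoplan.metrics import run_angle_sweep

spec = PhantomSpec(center=(0.0, 0.0, -82.5), thickness=5.0)
result = run_angle_sweep(spec, angles_deg=[50.0, 65.0, 78.0, 90.0], seed=1, verbose=True)

cols = ["angle_estimated_deg", "attenuation_pct", "axial_shift_mm", "lateral_shift_mm"]
print()
print(result.table[cols].round(2).to_string(index=False))
if result.regression is not None:
    r = result.regression
    print(
        f"\nOLS fit: attenuation = {r.slope:.2f} * angle + {r.intercept:.1f}  (R^2 = {r.r_squared:.2f})"
    )
print("Attenuation falls as the incidence angle approaches 90 deg (perpendicular),")
print("the relationship the planning pipeline exists to exploit.")
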