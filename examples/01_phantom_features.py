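"""Extract radiomics features from one phantom ROI with three software flavors.

Builds a small textured ADC-like phantom and runs the full feature
roster of each shipped flavor over it.  The per-flavor totals differ
because each flavor emulates one package's published feature list; the
same quantity can also differ in value across flavors when the
underlying algorithm diverges (symmetric vs asymmetric co-occurrence
matrices, mesh vs voxel volume, intensity binning policy).
"""

import numpy as np

import radstab as rs

rng = np.random.default_rng(0)
image, mask = rs.make_phantom_roi(
    "listed", values=rng.uniform(0, 4095, size=(3, 16, 16)),
    spacing=(4.0, 2.0, 2.0))

vectors = {}
for name in ("reference", "ibex-emulation", "mazda-emulation"):
    fv = rs.extract_features(image, mask, rs.get_flavor(name))
    vectors[name] = fv.values
    print(f"{name:16s} emits {len(fv.values):3d} features per map")

print("\nSame mask, two volume conventions:")
print(f"  reference mesh volume : {vectors['reference']['reference/SHAPE/Volume']:.1f} mm^3")
print(f"  ibex voxel 'Area'     : {vectors['ibex-emulation']['ibex-emulation/SHAPE/Area']:.1f} mm^3")

print("\nSame co-occurrence quantity, two discretizations:")
print(f"  reference GLCM Contrast d=1     : {vectors['reference']['reference/GLCM/Contrast/d=1']:.3f}")
print(f"  mazda-emulation GLCM Contrast d=1: {vectors['mazda-emulation']['mazda-emulation/GLCM/Contrast/d=1']:.3f}")
print("\nThe count triplet (125, 110, 79) matches the three packages'"
      "\nconfigured rosters; value differences reflect algorithmic variants.")
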