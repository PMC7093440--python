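"""Voxel-wise Patlak influx rate with an image-derived input function.

Extracts the whole-blood curve from the phantom's aorta VOI, corrects it
for blood-cell-bound activity to plasma, and fits the Patlak line
C_t/Cp vs (integral Cp)/Cp in every voxel.  Tissue medians are compared
with the generating Ki = K1*k3/(k2+k3).
"""

import numpy as np

from atlasquant import (
    correct_to_plasma,
    default_phantom_spec,
    extract_idif,
    make_reference,
    voxelwise_ki,
)

spec = default_phantom_spec(shape=(40, 32, 96), seed=0)
reference = make_reference(spec)

aorta = reference.true_labelmap.mask(spec.label_of("aorta"))
idif = extract_idif(reference.pet, aorta)
plasma = correct_to_plasma(idif, hematocrit=spec.hematocrit, rbc_partition=spec.rbc_partition)
t_star = spec.frames.t_star_default
ki, _ = voxelwise_ki(reference.pet, plasma, t_star=t_star)

print(f"Patlak window: frames with mid-time >= {t_star:.0f} min\n")
print(f"{'tissue':13s} {'Ki median':>10s} {'true Ki':>10s}   (x10^-2 /min)")
for name in ("brain", "heart", "liver", "muscle_right", "vat", "sat"):
    mask = reference.true_labelmap.mask(spec.label_of(name))
    med = float(np.median(ki.values[mask]))
    truth = reference.truth.loc[name, "ki_true"]
    print(f"{name:13s} {100*med:10.3f} {100*truth:10.3f}")

print("\nBrain and heart trap the most tracer, adipose depots the least —")
print("the ordering and magnitudes a clamped FDG study shows.")
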