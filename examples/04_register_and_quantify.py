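"""Register a deformed subject to the reference and quantify its tissues.

A subject is generated with a known smooth deformation; the hierarchical
demons registration (bone -> lean -> adipose, decreasing regularisation)
estimates the dense field back to the reference.  One reference-space VOI
set then yields every measurement: Jacobian-determinant volumes, filtered
FF readouts, warped-Ki readouts and the propagated-label Dice scores.
"""

import numpy as np

from atlasquant import (
    compute_fat_fraction,
    correct_to_plasma,
    default_phantom_spec,
    dice,
    extract_idif,
    jacobian_determinant,
    make_reference,
    make_subject,
    quantify_subject,
    random_deform_params,
    register,
    voxelwise_ki,
    warp_labels,
    warp_scalar,
)
from atlasquant.dixon import FatFractionImage

spec = default_phantom_spec(shape=(40, 32, 96), seed=0)
reference = make_reference(spec)
rng = np.random.default_rng(7)
subject = make_subject(reference, random_deform_params(rng), seed=42)

field = register(subject.water, subject.fat, reference.water, reference.fat)

# subject-space FF and Ki, warped into reference space with the same field
ff = compute_fat_fraction(subject.water, subject.fat)
idif = extract_idif(subject.pet, subject.true_labelmap.mask(spec.label_of("aorta")))
plasma = correct_to_plasma(idif, spec.hematocrit, spec.rbc_partition)
ki, _ = voxelwise_ki(subject.pet, plasma, spec.frames.t_star_default)
ff_warp, _ = warp_scalar(ff.as_scalar(), field)
ki_warp, _ = warp_scalar(ki, field)
ff_img = FatFractionImage(field.grid, np.clip(ff_warp.values, 0, 1),
                          np.ones(field.grid.shape, bool))

report = quantify_subject(field, reference.true_labelmap, spec.voi_table(), ff_img, ki_warp)
propagated = warp_labels(subject.true_labelmap, field)

print(f"{'tissue':13s} {'dice':>6s} {'vol auto':>9s} {'vol true':>9s} {'Ki med':>8s} {'Ki true':>8s}")
for name in ("brain", "liver", "sat", "muscle_right", "pancreas"):
    lid = spec.label_of(name)
    d = dice(propagated.mask(lid), reference.true_labelmap.mask(lid))
    print(
        f"{name:13s} {d:6.3f} {report.loc[name, 'volume_l']:9.4f} "
        f"{subject.truth.loc[name, 'volume_l']:9.4f} "
        f"{100*report.loc[name, 'ki_median']:8.3f} {100*subject.truth.loc[name, 'ki_true']:8.3f}"
    )
print("\nVolumes in L, Ki in x10^-2 /min. Large tissues recover well;")
print("the deliberately tiny pancreas analogue shows the single-atlas limits.")
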