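"""Fat-fraction maps from a 2-point-Dixon-style water/fat pair.

Computes FF = fat / (water + fat) per voxel and reads mean/median values
over two tissue masks: the subcutaneous fat ring (adipose, FF ~ 0.92) and
the thigh-muscle analogue (lean, FF ~ 0.08).  Background voxels with no
signal are flagged invalid rather than dividing 0/0.
"""

from atlasquant import compute_fat_fraction, default_phantom_spec, make_reference, voi_readout

spec = default_phantom_spec(shape=(40, 32, 96), seed=0)
reference = make_reference(spec)

ff = compute_fat_fraction(reference.water, reference.fat)
print(f"{(~ff.valid).sum()} voxels below the signal floor (air/lung) flagged invalid\n")

for name in ("sat", "muscle_right", "liver"):
    mask = reference.true_labelmap.mask(spec.label_of(name))
    mean = voi_readout(ff, mask, "mean")
    median = voi_readout(ff, mask, "median")
    truth = reference.truth.loc[name, "ff_true"]
    print(f"{name:13s} FF mean {mean:.3f}  median {median:.3f}  (generated with {truth:.2f})")

print("\nReadouts match the generating fractions up to MR noise;")
print("the 50% threshold on these values drives lean/adipose VOI filtering.")
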