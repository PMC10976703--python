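"""Render one converter phantom and recover its regional SUVr end to end.

Builds the nine-region block atlas, paints a PET volume whose regional means
invert the SUVr definition at the converter-group profile, adds 5% voxel
noise, then runs the pons-reference / SUVr / VOI-aggregation chain.
"""

import petvoi as pv
from petvoi.defaults import REGIONAL_SUVR, VOI_NAMES

atlas = pv.generate_atlas_phantom((48, 48, 48), (3.0, 3.0, 3.0))
targets = {v: REGIONAL_SUVR[("MCI_C", v)][0] for v in VOI_NAMES}

volume = pv.render_pet_volume(targets, atlas, pons_activity=1000.0,
                              noise_sd_fraction=0.05, seed=1)
reference = pv.extract_reference_mean(volume, atlas)  # whole-pons mean
suvr_volume = pv.compute_suvr_volume(volume, reference)
measured = pv.aggregate_vois(suvr_volume, atlas, subject_id="demo")

print(f"reference (pons) mean activity: {reference:.1f}")
print()
out = measured.set_index("voi")["mean_suvr"].round(3)
out = out.to_frame().assign(target=[round(targets[v], 3) for v in out.index])
print(out.to_string())
print()
print("Measured per-VOI SUVr matches the rendered targets to ~0.001-0.01;")
print("the residual is the 5% multiplicative voxel noise averaged over each region.")
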