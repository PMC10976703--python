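"""Run the complete pipeline and inspect the report bundle.

simulate -> render phantoms -> SUVr -> normative Z -> classify -> evaluate ->
trajectory model, with every table written to the output directory and
stamped with the seed and configuration hash.
"""

import logging
import sys

import petvoi as pv

logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")

config = pv.PipelineConfig(
    seed=0,
    group_sizes={"CN": 20, "MCI_NC": 15, "MCI_C": 18, "AD": 15},
    grid_shape=(32, 32, 32),
    voxel_size_mm=(3.0, 3.0, 3.0),
    output_dir="scratch/pipeline_demo",
)
bundle = pv.run_pipeline(config)

print(f"outputs in {bundle['output_dir']} (config {bundle['config_hash']})")
mtl = bundle["metrics"]["rules"]["MTL"]
print(f"MTL rule confusion: {mtl['confusion']}")
sens = mtl["metrics"]["sensitivity"]
print(f"MTL sensitivity {sens['value']:.3f} (95% CI {sens['ci95'][0]:.3f}-{sens['ci95'][1]:.3f})")
print()
print("The bundle holds every intermediate table (cohort, VOI SUVr, Z scores,")
print("calls, longitudinal scores, GEE fit); reruns with the same config and")
print("seed are byte-identical.")
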