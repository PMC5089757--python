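"""Run the full 4D MRA hemodynamic analysis on a synthetic tube phantom.

Builds a 32x32x32x12 inflow phantom with a known arrival-time gradient,
runs temporal MIP -> vessel segmentation -> curve sampling -> reference-curve
fit -> global and per-voxel TTP, and compares against the construction truth.
"""

import numpy as np

import cereflow as cf

phantom = cf.generate_phantom(cf.PhantomSpec(seed=7))
print(f"phantom: {phantom.vessel_mask.n_voxels} vessel voxels, "
      f"true global TTP {phantom.global_ttp_truth:.2f} frames")

result = cf.analyze_series(phantom.series, seed=7, n_curves=250)
rep = result.report
print(f"estimated global TTP: {rep['global_ttp_frames']:.2f} frames "
      f"({rep['global_ttp_frames'] * rep['frame_duration_ms']:.0f} ms)")

both = result.ttp_map.defined & phantom.vessel_mask.mask
err = result.ttp_map.values[both] - phantom.ttp_truth.values[both]
print(f"per-voxel TTP: {int(both.sum())} voxels mapped, "
      f"RMSE {np.sqrt(np.mean(err ** 2)):.2f} frames")

# The global TTP is the argmax of the smooth reference inflow curve; a
# longer TTP means slower inflow of labeled blood (lower cerebral blood
# flow). Artifacts can be written with result.save(report_path, ttp_path).
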