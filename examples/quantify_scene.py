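"""Quantify a synthetic en-face angiogram and compare against ground truth.

Generates a 3 x 3 mm-equivalent scene of branching vessels with known
centerline length and caliber, runs the three-way binarization and
skeletonization, and prints VAD / VSD / VDI next to their true values.
"""

import numpy as np

from octaquant import (
    SceneParams,
    binarize_enface,
    compute_vad,
    compute_vdi,
    compute_vsd,
    generate_scene,
    skeletonize,
)

params = SceneParams(shape=(256, 256), extent_mm=(1.313, 1.313),
                     faz_radius_mm=0.1208, target_vad=0.35)
image, truth = generate_scene(params, seed=7)

vessel_map = binarize_enface(image)
skeleton = skeletonize(vessel_map)
roi = np.ones(image.pixels.shape, bool)

vad = compute_vad(vessel_map, roi)
vsd = compute_vsd(skeleton, roi)
vdi_px, vdi_um = compute_vdi(vessel_map, skeleton, roi, image.pixel_pitch_um_mean)

print(f"VAD  measured {vad:.3f}   true {truth.truth_vad:.3f}   "
      "(fraction of the scan showing perfusion)")
print(f"VSD  measured {vsd:.3f}   true {truth.truth_vsd:.3f}   "
      "(skeleton-pixel fraction: vessel length, caliber-independent)")
print(f"VDI  measured {vdi_px:.2f} px = {vdi_um:.1f} um   "
      f"true mean caliber {truth.truth_mean_caliber_px:.2f} px")
print("A VAD near 0.35-0.43 and VDI near 19 um match healthy macular plexuses.")
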