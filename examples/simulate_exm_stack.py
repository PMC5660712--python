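"""Simulate a 20x expansion-microscopy confocal stack from synthetic neuropil.

Generates a dense ground-truth label volume, labels membranes/cytosol/
background with fluorophores, and renders the confocal stack with the
Debye-integral PSF plus Poisson and read noise.
"""

import numpy as np

from exmtool.pipeline import RunConfig, simulate_image, _make_psf
from exmtool.volume import generate_ground_truth, extract_membrane

cfg = RunConfig.mini(seed=0)
vol = generate_ground_truth(
    cfg.gt_shape, cfg.voxel_size,
    dict(count=cfg.neurite_count, radius_range=cfg.radius_range),
    seed=cfg.stage_seed("groundtruth"),
)
print(f"ground truth: {vol.shape} voxels at {vol.voxel_size} nm, "
      f"{vol.n_segments()} neurons, membrane fraction "
      f"{extract_membrane(vol).mask.mean():.3f}")

psf = _make_psf(cfg)
print(f"PSF kernel {psf.intensity.shape} at pitch {psf.voxel_pitch} nm "
      f"(pre-expansion, after the 20x scaling)")

stack = simulate_image(vol, psf, cfg, cfg.stage_rng("simulate"))
print(f"stack: {stack.shape} (z step {stack.z_step:.0f} nm, xy pitch "
      f"{stack.xy_pitch:.0f} nm), realized SNRs: Poisson {stack.snr_poisson:.1f}, "
      f"read {stack.snr_read:.1f}")
print("brightest pixel:", round(float(stack.data.max()), 1), "expected photons;")
print("the membrane channel shows bright punctate neurite outlines over a dim "
      "cytosolic/background haze, as in real 20x ExM data.")
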