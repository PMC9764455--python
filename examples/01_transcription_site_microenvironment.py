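"""Detect transcription sites in a 3D confocal phantom and profile the
chromatin-mark channel around them.

The phantom places 30 bright RNA-FISH-like puncta on a noisy nuclear
background and gives the second channel a 2-fold Gaussian enrichment
(decay length 0.5 µm) centered on each site. We detect the puncta, then
measure the average radial intensity of the mark as a function of
physical distance from the site.
"""

import numpy as np

from phenoquant import microenv, synthetic

cfg = synthetic.ConfocalPhantomConfig(
    shape_voxels=(40, 256, 256), n_sites=30, site_peak_snr=6,
    enrichment_amplitude=2.0, enrichment_sigma_um=0.5,
    min_separation_um=2.5, seed=42)
stack, truth = synthetic.gen_confocal_phantom(cfg)

sites = microenv.detect_sites(stack, "rna")
print(f"detected {len(sites)} sites (ground truth: {len(truth.sites)})")

profile = microenv.radial_profile(stack, "mark", sites)
for r, m in zip(profile.bin_centers_um[:8], profile.mean[:8]):
    print(f"  r = {r:4.2f} um   normalized mark intensity = {m:5.3f}")
print("-> the profile peaks in the innermost bin (the sites sit on a local")
print("   maximum of the mark) and decays to ~1, the far-field baseline.")

density = microenv.site_density(sites, np.ones(stack.shape[1:], dtype=bool),
                                pixel_size_um=cfg.voxel_size_um[1:])
print(f"site density: {density['density_per_px']:.5f} sites/pixel "
      f"({density['density_per_um2']:.4f} sites/um^2)")
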