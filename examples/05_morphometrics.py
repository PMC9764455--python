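"""Count trichomes in a cuticle phantom and measure a larval silhouette.

Trichomes are punctate maxima counted with a prominence-based detector
(robust to uneven illumination); body size comes from the thresholded
silhouette: area as pixel count x pixel area, length as the major axis of
the second-moment ellipse.
"""

import numpy as np
from skimage.draw import ellipse

from phenoquant import morpho, synthetic

img, truth = synthetic.gen_cuticle_phantom(n_trichomes=25, seed=3)
count, coords = morpho.count_trichomes(img, morpho.ROI.full(img.data.shape))
print(f"trichomes counted: {count} (ground truth {len(truth.coordinates)})")

px = 0.01  # mm per pixel
sil = np.zeros((400, 400))
rr, cc = ellipse(200, 200, 1.2 / px, 0.3 / px, shape=sil.shape)
sil[rr, cc] = 80.0
metrics = morpho.body_metrics(morpho.Image2D(sil, pixel_size_mm=px))
print(f"body area:   {metrics['area_mm2']:.3f} mm^2 "
      f"(analytic ellipse: {np.pi * 1.2 * 0.3:.3f})")
print(f"body length: {metrics['length_mm']:.3f} mm (analytic: 2.400)")
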