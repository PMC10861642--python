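"""GLCM statistics and LBP histograms on small analytic images.

Builds the bundled fixture images and prints the five orientation-pooled
GLCM statistics plus the dominant LBP histogram bins for each.  Contrast and
dissimilarity are 0 on a constant image and maximal on a 0/255 checkerboard;
a constant image maps every interior LBP code to 255 (all eight neighbors
tie the center).
"""

import numpy as np

from tumortex import glcm_feature_vector, lbp_code_image, lbp_histogram
from tumortex.synth import fixture_images

for name, image in fixture_images().items():
    if name == "tiny_glcm":
        continue  # 3 gray levels; shown separately below
    g = glcm_feature_vector(image)
    hist = lbp_histogram(lbp_code_image(image))
    top = np.argsort(hist)[::-1][:3]
    print(f"{name:>12}: contrast={g.contrast:10.2f} dissim={g.dissimilarity:8.3f} "
          f"homog={g.homogeneity:.3f} energy={g.energy:.3f} corr={g.correlation:+.3f}")
    print(f"{'':>12}  top LBP bins: " + ", ".join(f"{b}:{hist[b]:.3f}" for b in top))

from tumortex import GLCMConfig, compute_glcm

tiny = fixture_images()["tiny_glcm"]
P = compute_glcm(tiny, GLCMConfig(levels=3, symmetric=False, normalized=False), 0).P
print("\nhorizontal pair counts of [[0,0,1],[0,0,1],[0,2,2]]:")
print(P.astype(int))
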