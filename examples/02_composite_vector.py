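"""The 1547-dimensional composite feature vector of one image.

Generates one synthetic grating image and extracts the composite descriptor:
5 GLCM statistics, 256 LBP bins, their 1280 outer-product interaction
features, and 3 + 3 aggregated/statistical summaries.  The interaction block
sums to the sum of the GLCM vector because the LBP histogram is normalized.
"""

from tumortex import composite_vector
from tumortex.synth import default_class_specs, generate_texture_image

spec = default_class_specs()[2]  # the oriented grating class
image = generate_texture_image(spec, seed=0, index=0, size=(128, 128))
cv = composite_vector(image)

print(f"total features: {len(cv)}")
for name, sl in cv.blocks.items():
    block = cv.block(name)
    print(f"  {name:>12}: {sl.stop - sl.start:5d} values, sum = {block.sum():.6f}")
print(f"glcm block (C, D, H, E, Corr): {cv.block('glcm').round(4)}")
print(f"interaction sum == glcm sum: "
      f"{abs(cv.block('interaction').sum() - cv.block('glcm').sum()) < 1e-10}")
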