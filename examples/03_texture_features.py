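"""Compute the 47-dimensional conventional texture descriptor of a patch.

The descriptor stacks second- and third-order co-occurrence statistics,
an autocorrelation granularity index, the Hurst fractal roughness
exponent, Sobel edge statistics, Laws texture-energy responses and the
Shannon entropies of a two-level Haar decomposition. Patches from the
coarse lesion texture show lower co-occurrence contrast and a smoother
(higher) Hurst exponent than the fine background texture.
"""

from echotex.features import extract_feature_vector
from echotex.patches import generate_patches
from echotex.phantoms import PhantomSpec, generate_annotated_phantom

image = generate_annotated_phantom(PhantomSpec(seed=1))
patches = generate_patches(image)
hcc = next(p for p in patches if p.label == "HCC")
par = next(p for p in patches if p.label == "PAR")

for patch in (hcc, par):
    fv = extract_feature_vector(patch)
    print(f"\n{patch.label} patch at {patch.origin}: {len(fv.values)} features")
    for name in ("glcm2_contrast", "glcm2_homogeneity", "hurst", "edge_frequency"):
        print(f"  {name:18s} = {fv.values[name]:.4f}")

print(
    "\nThe coarse HCC texture has lower contrast, higher homogeneity and a "
    "higher Hurst exponent (smoother surface) than the fine PAR speckle."
)
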