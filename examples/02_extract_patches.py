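"""Cut HCC and PAR training patches out of an annotated phantom frame.

The sliding-window rules accept 56x56 windows fully inside the tumor
polygon (HCC) and windows just outside it with a corner on the boundary
(PAR), each essentially disjoint from all previously accepted windows.
The printout lists the per-class counts and shows the ten-fold seeded
augmentation used to enlarge a training set.
"""

from collections import Counter

from echotex.patches import augment, generate_patches
from echotex.phantoms import PhantomSpec, generate_annotated_phantom

image = generate_annotated_phantom(PhantomSpec(seed=3))
patches = generate_patches(image)

counts = Counter(p.label for p in patches)
print(f"frame {image.shape}: {counts['HCC']} HCC and {counts['PAR']} PAR patches")
print("first HCC window origins:", [p.origin for p in patches if p.label == "HCC"][:4])

augmented = augment(patches[0], seed=0)
print(
    f"augmentation: 1 patch -> {len(augmented)} patches "
    "(original + 9 seeded rotation/zoom/reflection draws)"
)
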