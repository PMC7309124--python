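"""Generate a small annotated speckle-phantom cohort and save it to disk.

Builds three synthetic "patients", each with two B-mode-like frames in
which a coarser speckle texture (the tumor stand-in) is composited inside
an elliptical polygon, then writes the images plus a VIA-style annotation
file. The printed statistics show the intended contrast: the lesion is
brighter and coarser than the background.
"""

from pathlib import Path

import numpy as np

from echotex.io_via import write_image, write_via_annotations
from echotex.phantoms import generate_cohort

out_dir = Path("scratch/phantom_cohort")
out_dir.mkdir(parents=True, exist_ok=True)

images = generate_cohort(n_patients=3, images_per_patient=2, seed=7)
for image in images:
    write_image(image, out_dir / image.source_path)
write_via_annotations(images, out_dir / "annotations.json")

print(f"wrote {len(images)} frames to {out_dir}")
for image in images[:3]:
    poly = image.annotations[0]
    xmin, ymin, xmax, ymax = poly.bounding_box()
    ys, xs = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    inside = (
        (xs > xmin) & (xs < xmax) & (ys > ymin) & (ys < ymax)
    )  # coarse box approximation for the printout
    print(
        f"{image.source_path}: lesion mean {image.pixels[inside].mean():5.1f}, "
        f"background mean {image.pixels[~inside].mean():5.1f} "
        f"(the lesion texture is brighter and coarser by construction)"
    )
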