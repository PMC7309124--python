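"""Sliding-window patch generation, augmentation and dataset splitting.

Tumor regions are annotated as polygons; training samples are 56x56
windows. A raster-order (row-major, stride-1) greedy scan accepts

* **HCC patches**: windows fully inside the polygon whose
  intersection-over-union with every previously accepted patch is below a
  small tolerance (0.1% by default), and
* **PAR patches**: windows fully outside the polygon with at least one
  corner on the (rasterized) polygon boundary and an intersection below the
  tolerance of their own area with every accepted patch.

The traversal order and greedy acceptance make the output deterministic;
the tolerance keeps the selected windows effectively disjoint, which gives
variety in the sampled tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.draw import polygon2mask
from skimage.transform import rescale, rotate

from .io_via import HCC, PAR, AnnotatedImage

__all__ = [
    "Patch",
    "SplitSpec",
    "generate_patches",
    "augment",
    "split_dataset",
    "AUGMENT_MULTIPLIER",
]

AUGMENT_MULTIPLIER = 10  # original + 9 sampled transforms


@dataclass
class Patch:
    """One labeled intensity window cut from an annotated frame."""

    pixels: np.ndarray
    label: str
    origin: tuple[int, int]  # (x, y) of the window's top-left pixel
    source: str = ""  # "patient_id/image" reference
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("patch pixels must be 2-D")
        if self.label not in (HCC, PAR):
            raise ValueError(f"label must be HCC or PAR, got {self.label!r}")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def _box_intersection(x: int, y: int, xs: np.ndarray, ys: np.ndarray, size: int) -> np.ndarray:
    """Vector of intersection areas between window (x, y) and accepted windows."""
    iw = np.minimum(x, xs) + size - np.maximum(x, xs)
    ih = np.minimum(y, ys) + size - np.maximum(y, ys)
    return np.clip(iw, 0, None) * np.clip(ih, 0, None)


def generate_patches(
    image: AnnotatedImage,
    patch_size: int = 56,
    overlap_tolerance: float = 0.001,
) -> list[Patch]:
    """Greedy raster-scan generation of HCC and PAR patches for one frame.

    Returns the accepted patches in scan order. If the polygon is too small
    to admit any interior window, the HCC list is empty and a warning is
    emitted (the PAR scan still runs).
    """
    if not image.annotations:
        raise ValueError("image has no polygon annotations")
    h, w = image.shape
    s = patch_size
    if s > h or s > w:
        raise ValueError("patch does not fit inside the image")

    # union of all annotated polygons (typically one)
    mask = np.zeros((h, w), dtype=bool)
    for poly in image.annotations:
        mask |= polygon2mask((h, w), np.column_stack([poly.ys, poly.xs]))

    # window-sum of the mask for every top-left position, via an integral image
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)
    ny, nx = h - s + 1, w - s + 1
    wsum = ii[s:, s:] - ii[:-s, s:] - ii[s:, :-s] + ii[:-s, :-s]
    wsum = wsum[:ny, :nx]

    inside_all = wsum == s * s
    outside_all = wsum == 0

    # rasterized polygon outline, thickened by 1 pixel for the corner test
    boundary = mask ^ binary_erosion(mask)
    near_boundary = binary_dilation(boundary, structure=np.ones((3, 3), dtype=bool))
    nb = np.zeros((h + 1, w + 1), dtype=bool)  # pad so x+s / y+s lookups stay in range
    nb[:h, :w] = near_boundary
    corner_on_boundary = (
        nb[:ny, :nx]
        | nb[:ny, s - 1 : s - 1 + nx]
        | nb[s - 1 : s - 1 + ny, :nx]
        | nb[s - 1 : s - 1 + ny, s - 1 : s - 1 + nx]
    )
    par_candidate = outside_all & corner_on_boundary
    candidate = inside_all | par_candidate

    out: list[Patch] = []
    area = float(s * s)
    src = image.source_path or image.patient_id

    # Greedy raster acceptance without visiting every candidate: a window
    # whose overlap with an already-accepted window violates its rule can
    # never be accepted later, so each acceptance marks the violating
    # neighborhood dead and the scan jumps straight to the next live
    # candidate. The comparisons are the literal rule ratios, so the result
    # is identical to checking every window in raster order.
    dxy = np.abs(np.arange(-(s - 1), s))  # |offset| for positions within reach
    inter_local = np.outer(s - dxy, s - dxy).astype(float)  # intersection areas
    kill_hcc = inter_local / (2.0 * area - inter_local) >= overlap_tolerance
    kill_par = inter_local / area >= overlap_tolerance

    alive = candidate.copy()
    flat = alive.ravel()
    total = flat.size
    pos = 0
    while True:
        nxt = int(np.argmax(flat[pos:]))
        if not flat[pos + nxt]:
            break
        pos += nxt
        y, x = divmod(pos, nx)
        label = HCC if inside_all[y, x] else PAR
        out.append(
            Patch(
                pixels=image.pixels[y : y + s, x : x + s].copy(),
                label=label,
                origin=(x, y),
                source=src,
                patient_id=image.patient_id,
            )
        )
        # mark windows whose future acceptance this one forbids
        y0, y1 = max(0, y - (s - 1)), min(ny, y + s)
        x0, x1 = max(0, x - (s - 1)), min(nx, x + s)
        ky0 = y0 - (y - (s - 1))
        kx0 = x0 - (x - (s - 1))
        kh = kill_hcc[ky0 : ky0 + (y1 - y0), kx0 : kx0 + (x1 - x0)]
        kp = kill_par[ky0 : ky0 + (y1 - y0), kx0 : kx0 + (x1 - x0)]
        region = alive[y0:y1, x0:x1]
        region[kh & inside_all[y0:y1, x0:x1]] = False
        region[kp & ~inside_all[y0:y1, x0:x1]] = False
        alive[y, x] = False
        pos += 1
        if pos >= total:
            break

    if not any(p.label == HCC for p in out):
        warnings.warn("polygon admits no interior window; no HCC patches generated")
    return out


# ---------------------------------------------------------------------------
# augmentation


def _transform_pool() -> list[tuple[float, float, bool]]:
    """All (angle, zoom, flip) combinations except the identity."""
    pool = [
        (float(angle), zoom, flip)
        for angle in range(-45, 50, 5)
        for zoom in (0.8, 1.0, 1.2)
        for flip in (False, True)
    ]
    pool.remove((0.0, 1.0, False))
    return pool


def apply_transform(pixels: np.ndarray, angle: float, zoom: float, flip: bool) -> np.ndarray:
    """Rotate/zoom/reflect a square patch back onto its own 56x56 support.

    Bilinear interpolation with reflect padding; zoom-out results are
    reflect-padded back to size, zoom-in results center-cropped.
    """
    s = pixels.shape[0]
    img = pixels.astype(float)
    if flip:
        img = img[:, ::-1]
    if angle != 0.0:
        img = rotate(img, angle, resize=False, order=1, mode="reflect", preserve_range=True)
    if zoom != 1.0:
        img = rescale(img, zoom, order=1, mode="reflect", preserve_range=True, anti_aliasing=False)
        t = img.shape[0]
        if t > s:  # center crop
            o = (t - s) // 2
            img = img[o : o + s, o : o + s]
        elif t < s:  # reflect-pad back
            before = (s - t) // 2
            after = s - t - before
            img = np.pad(img, ((before, after), (before, after)), mode="reflect")
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def augment(patch: Patch, seed: int | np.random.Generator = 0) -> list[Patch]:
    """Return the original patch plus 9 seeded distinct transformed copies.

    The transform pool is {rotations every 5 degrees in [-45, 45]} x
    {zoom 0.8, 1.0, 1.2} x {identity, horizontal reflection}; nine non-identity
    combinations are drawn without replacement, so the multiplier is exactly
    10 and labels are unchanged.
    """
    if patch.pixels.shape[0] != patch.pixels.shape[1]:
        raise ValueError("augment requires a square patch")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = _transform_pool()
    picks = rng.choice(len(pool), size=AUGMENT_MULTIPLIER - 1, replace=False)
    out = [patch]
    for idx in picks:
        angle, zoom, flip = pool[int(idx)]
        out.append(
            Patch(
                pixels=apply_transform(patch.pixels, angle, zoom, flip),
                label=patch.label,
                origin=patch.origin,
                source=patch.source,
                patient_id=patch.patient_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test proportions plus grouping and seeding."""

    train_fraction: float = 0.8
    validation_fraction: float = 0.0
    test_fraction: float = 0.2
    group_by_patient: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.validation_fraction, self.test_fraction)
        if any(f < 0 for f in fracs) or not np.isclose(sum(fracs), 1.0):
            raise ValueError("fractions must be non-negative and sum to 1")


def _proportional_counts(n: int, fracs: Sequence[float]) -> list[int]:
    raw = [f * n for f in fracs]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([-(r - c) for r, c in zip(raw, counts)], kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def split_dataset(
    patches: Sequence[Patch], spec: SplitSpec
) -> tuple[list[Patch], list[Patch], list[Patch]]:
    """Partition patches into (train, validation, test).

    Without grouping the split is stratified by class label; with
    ``group_by_patient`` all patches of a patient land in a single
    partition (preventing patient-level leakage) and the proportions are
    met as closely as whole patients allow. Deterministic given the seed.
    """
    patches = list(patches)
    if not patches:
        raise ValueError("no patches to split")
    rng = np.random.default_rng(spec.seed)
    fracs = (spec.train_fraction, spec.validation_fraction, spec.test_fraction)
    parts: tuple[list[Patch], list[Patch], list[Patch]] = ([], [], [])

    if spec.group_by_patient:
        ids = sorted({p.patient_id for p in patches})
        rng.shuffle(ids)
        by_id = {pid: [p for p in patches if p.patient_id == pid] for pid in ids}
        total = len(patches)
        targets = [f * total for f in fracs]
        filled = [0, 0, 0]
        for pid in ids:
            # place the patient where the relative deficit is largest
            deficits = [
                (targets[k] - filled[k]) / targets[k] if targets[k] > 0 else -np.inf
                for k in range(3)
            ]
            k = int(np.argmax(deficits))
            parts[k].extend(by_id[pid])
            filled[k] += len(by_id[pid])
    else:
        labels = sorted({p.label for p in patches})
        for lab in labels:
            idx = [i for i, p in enumerate(patches) if p.label == lab]
            rng.shuffle(idx)
            counts = _proportional_counts(len(idx), fracs)
            start = 0
            for k, c in enumerate(counts):
                parts[k].extend(patches[i] for i in idx[start : start + c])
                start += c
        for k, frac in enumerate(fracs):
            if frac > 0 and {p.label for p in parts[k]} != set(labels):
                raise ValueError(
                    "a class is absent from a requested partition; "
                    "not enough samples to stratify"
                )
    return parts
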