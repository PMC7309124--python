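"""Sliding-window patch generation, augmentation and splitting."""

import warnings

import numpy as np
import pytest
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.draw import polygon2mask

from echotex.io_via import AnnotatedImage, Polygon
from echotex.patches import (
    AUGMENT_MULTIPLIER,
    Patch,
    SplitSpec,
    apply_transform,
    augment,
    generate_patches,
    split_dataset,
)


def brute_force_patches(image, s=56, tol=0.001):
    """Literal raster-order application of the acceptance rules."""
    h, w = image.shape
    mask = np.zeros((h, w), bool)
    for poly in image.annotations:
        mask |= polygon2mask((h, w), np.column_stack([poly.ys, poly.xs]))
    boundary = mask ^ binary_erosion(mask)
    nearb = binary_dilation(boundary, structure=np.ones((3, 3), bool))
    nb = np.zeros((h + 1, w + 1), bool)
    nb[:h, :w] = nearb
    accepted = []
    area = s * s
    for y in range(h - s + 1):
        for x in range(w - s + 1):
            ssum = mask[y : y + s, x : x + s].sum()
            inter = [
                max(0, min(x, ax) + s - max(x, ax)) * max(0, min(y, ay) + s - max(y, ay))
                for ax, ay, _ in accepted
            ]
            if ssum == area:
                if any(i / (2.0 * area - i) >= tol for i in inter):
                    continue
                accepted.append((x, y, "HCC"))
            elif ssum == 0:
                corners = [(x, y), (x + s - 1, y), (x, y + s - 1), (x + s - 1, y + s - 1)]
                if not any(nb[cy, cx] for cx, cy in corners):
                    continue
                if any(i / area >= tol for i in inter):
                    continue
                accepted.append((x, y, "PAR"))
    return accepted


class TestGeneratePatches:
    def test_square_polygon_gives_nine_hcc_windows(self, square_annotated_image):
        """A 200x200 interior admits a 3x3 grid of effectively disjoint
        56-pixel windows under the 0.1% overlap rule."""
        patches = generate_patches(square_annotated_image)
        hcc = [p for p in patches if p.label == "HCC"]
        assert len(hcc) == 9
        xs = sorted({p.origin[0] for p in hcc})
        assert xs == [100, 156, 212]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cx, cy = rng.uniform(120, 180, 2)
        ang = np.sort(rng.uniform(0, 2 * np.pi, rng.integers(5, 9)))
        rad = rng.uniform(60, 110, len(ang))
        verts = [
            (min(max(cx + r * np.cos(a), 5), 294), min(max(cy + r * np.sin(a), 5), 294))
            for a, r in zip(ang, rad)
        ]
        image = AnnotatedImage(
            pixels=rng.integers(0, 256, (300, 300)).astype(np.uint8),
            annotations=[Polygon(verts)],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = [(p.origin[0], p.origin[1], p.label) for p in generate_patches(image)]
        assert got == brute_force_patches(image)

    def test_postconditions_hold(self, square_annotated_image):
        patches = generate_patches(square_annotated_image)
        mask = polygon2mask(
            (400, 400),
            np.column_stack(
                [
                    square_annotated_image.annotations[0].ys,
                    square_annotated_image.annotations[0].xs,
                ]
            ),
        )
        hcc_boxes = []
        for p in patches:
            x, y = p.origin
            sub = mask[y : y + 56, x : x + 56]
            if p.label == "HCC":
                assert sub.all()
                hcc_boxes.append((x, y))
            else:
                assert not sub.any()
            assert p.pixels.shape == (56, 56)
        for i, (x1, y1) in enumerate(hcc_boxes):
            for x2, y2 in hcc_boxes[i + 1 :]:
                inter = max(0, 56 - abs(x1 - x2)) * max(0, 56 - abs(y1 - y2))
                iou = inter / (2 * 56 * 56 - inter)
                assert iou < 0.001

    def test_small_polygon_yields_no_hcc(self):
        poly = Polygon([(100, 100), (140, 100), (140, 140), (100, 140)])
        image = AnnotatedImage(pixels=np.zeros((300, 300), np.uint8), annotations=[poly])
        with pytest.warns(UserWarning, match="no HCC"):
            patches = generate_patches(image)
        assert all(p.label == "PAR" for p in patches)

    def test_unannotated_image_raises(self):
        image = AnnotatedImage(pixels=np.zeros((100, 100), np.uint8))
        with pytest.raises(ValueError):
            generate_patches(image)


class TestAugment:
    def test_multiplier_and_original_first(self, labeled_patch):
        out = augment(labeled_patch, seed=0)
        assert len(out) == AUGMENT_MULTIPLIER == 10
        assert np.array_equal(out[0].pixels, labeled_patch.pixels)

    def test_labels_and_shapes_preserved(self, labeled_patch):
        for p in augment(labeled_patch, seed=1):
            assert p.label == labeled_patch.label
            assert p.pixels.shape == (56, 56)

    def test_deterministic(self, labeled_patch):
        a = augment(labeled_patch, seed=7)
        b = augment(labeled_patch, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.pixels, y.pixels)

    def test_transforms_are_distinct_from_original(self, labeled_patch):
        out = augment(labeled_patch, seed=3)
        assert sum(np.array_equal(p.pixels, labeled_patch.pixels) for p in out) == 1

    def test_identity_transform(self, random_patch):
        assert np.array_equal(apply_transform(random_patch, 0.0, 1.0, False), random_patch)

    def test_non_square_patch_rejected(self):
        p = Patch(pixels=np.zeros((56, 40), np.uint8), label="HCC", origin=(0, 0))
        with pytest.raises(ValueError):
            augment(p, seed=0)


def _make_patches(n, n_patients=5):
    rng = np.random.default_rng(0)
    out = []
    for i in range(n):
        out.append(
            Patch(
                pixels=rng.integers(0, 256, (56, 56)).astype(np.uint8),
                label="HCC" if i % 2 == 0 else "PAR",
                origin=(0, 0),
                patient_id=f"p{i % n_patients}",
            )
        )
    return out


class TestSplit:
    def test_eighty_twenty_counts(self):
        patches = _make_patches(100)
        spec = SplitSpec(0.8, 0.0, 0.2, group_by_patient=False, seed=0)
        train, val, test = split_dataset(patches, spec)
        assert (len(train), len(val), len(test)) == (80, 0, 20)

    def test_partitions_disjoint_and_exhaustive(self):
        patches = _make_patches(60)
        train, val, test = split_dataset(
            patches, SplitSpec(0.6, 0.2, 0.2, group_by_patient=False, seed=1)
        )
        ids = [id(p) for part in (train, val, test) for p in part]
        assert len(ids) == 60 and len(set(ids)) == 60

    def test_patient_grouping_prevents_leakage(self):
        patches = _make_patches(120, n_patients=10)
        train, _, test = split_dataset(patches, SplitSpec(0.8, 0.0, 0.2, seed=2))
        assert {p.patient_id for p in train}.isdisjoint({p.patient_id for p in test})

    def test_deterministic(self):
        patches = _make_patches(50)
        spec = SplitSpec(0.8, 0.0, 0.2, seed=3)
        a = split_dataset(patches, spec)
        b = split_dataset(patches, spec)
        for pa, pb in zip(a, b):
            assert [id(p) for p in pa] == [id(p) for p in pb]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(0.5, 0.2, 0.2)

    def test_stratification_failure_raises(self):
        patches = [
            Patch(np.zeros((56, 56), np.uint8), "HCC", (0, 0), patient_id="a"),
            Patch(np.zeros((56, 56), np.uint8), "PAR", (0, 0), patient_id="b"),
        ]
        with pytest.raises(ValueError):
            split_dataset(patches, SplitSpec(0.5, 0.0, 0.5, group_by_patient=False, seed=0))
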