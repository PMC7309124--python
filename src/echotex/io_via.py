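"""Image and annotation I/O.

B-mode ultrasound frames arrive as 8-bit raster images (BMP/PNG); tumor
outlines arrive as polygon regions in VGG Image Annotator (VIA) exports.
This module reads and writes both, plus the delimited feature tables
produced by :mod:`echotex.features`.

Coordinate convention: 0-based pixel indices, ``(x, y) = (column, row)``.
Polygon vertex order is preserved exactly as stored in the annotation file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "Polygon",
    "AnnotatedImage",
    "read_image",
    "write_image",
    "read_via_annotations",
    "write_via_annotations",
    "write_feature_table",
    "read_feature_table",
]

HCC = "HCC"
PAR = "PAR"


@dataclass
class Polygon:
    """Closed polygonal outline of an annotated region.

    Vertices are ``(x, y)`` pixel coordinates in image space; the ring is
    implicitly closed (last vertex connects back to the first).
    """

    vertices: list[tuple[float, float]]
    label: str = HCC

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]

    @property
    def xs(self) -> np.ndarray:
        return np.array([v[0] for v in self.vertices], dtype=float)

    @property
    def ys(self) -> np.ndarray:
        return np.array([v[1] for v in self.vertices], dtype=float)

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the vertex set."""
        return (
            float(self.xs.min()),
            float(self.ys.min()),
            float(self.xs.max()),
            float(self.ys.max()),
        )


@dataclass
class AnnotatedImage:
    """One grayscale frame plus its polygon annotations and provenance."""

    pixels: np.ndarray
    annotations: list[Polygon] = field(default_factory=list)
    patient_id: str = ""
    device_tag: str = ""
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        h, w = self.pixels.shape
        for poly in self.annotations:
            if (
                poly.xs.min() < 0
                or poly.ys.min() < 0
                or poly.xs.max() > w - 1
                or poly.ys.max() > h - 1
            ):
                raise ValueError("polygon vertex outside image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_image(path: str | Path, patient_id: str = "", device_tag: str = "") -> AnnotatedImage:
    """Read an 8-bit raster image (BMP/PNG) as an annotation-free frame.

    Color or paletted inputs are collapsed to luminance; output intensities
    are uint8 in [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with Image.open(path) as img:
        img.load()
        if img.mode != "L":
            img = img.convert("L")
        pixels = np.asarray(img, dtype=np.uint8)
    if pixels.size == 0:
        raise ValueError(f"zero-area image: {path}")
    return AnnotatedImage(
        pixels=pixels,
        patient_id=patient_id,
        device_tag=device_tag,
        source_path=str(path),
    )


def write_image(image: AnnotatedImage | np.ndarray, path: str | Path) -> None:
    """Write a grayscale frame as BMP or PNG (by file extension)."""
    pixels = image.pixels if isinstance(image, AnnotatedImage) else np.asarray(image)
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="L").save(str(path))


def _iter_via_entries(doc: dict) -> Iterable[dict]:
    # VIA 2.x project files nest the metadata; plain exports are flat
    # {"<filename><size>": {...}} dicts.
    if "_via_img_metadata" in doc:
        doc = doc["_via_img_metadata"]
    for entry in doc.values():
        if isinstance(entry, dict) and "filename" in entry:
            yield entry


def _regions_of(entry: dict) -> list[dict]:
    regions = entry.get("regions", [])
    if isinstance(regions, dict):  # VIA 1.x kept regions keyed by index
        regions = [regions[k] for k in sorted(regions)]
    return regions


def read_via_annotations(
    path: str | Path, image_store: str | Path, device_tag: str = ""
) -> list[AnnotatedImage]:
    """Read a VIA annotation export and the images it references.

    Each polygon region becomes a :class:`Polygon` whose label is taken from
    the region attributes (``label`` key, default ``"HCC"``). Only polygon
    regions are supported; any other shape type raises.
    """
    path = Path(path)
    image_store = Path(image_store)
    with open(path) as fh:
        doc = json.load(fh)

    out: list[AnnotatedImage] = []
    for entry in _iter_via_entries(doc):
        filename = entry["filename"]
        img_path = image_store / filename
        if not img_path.exists():
            raise FileNotFoundError(f"referenced image missing: {img_path}")
        attrs = entry.get("file_attributes", {})
        image = read_image(
            img_path,
            patient_id=str(attrs.get("patient_id", "")),
            device_tag=str(attrs.get("device_tag", device_tag)),
        )
        for region in _regions_of(entry):
            shape = region.get("shape_attributes", {})
            name = shape.get("name")
            if name != "polygon":
                raise ValueError(f"unsupported VIA region shape: {name!r}")
            xs = shape["all_points_x"]
            ys = shape["all_points_y"]
            label = region.get("region_attributes", {}).get("label", HCC)
            image.annotations.append(Polygon(list(zip(xs, ys)), label=label))
        # re-validate bounds now that annotations were attached
        image.__post_init__()
        out.append(image)
    return out


def write_via_annotations(images: Sequence[AnnotatedImage], path: str | Path) -> None:
    """Write VIA-style polygon annotations for a set of images.

    The produced JSON mirrors VIA's export structure (``regions`` with
    ``shape_attributes``/``all_points_x``/``all_points_y``) so the file can
    be opened in the annotator itself.
    """
    doc: dict[str, dict] = {}
    for image in images:
        filename = Path(image.source_path).name if image.source_path else f"{id(image)}.png"
        key = f"{filename}-1"
        doc[key] = {
            "filename": filename,
            "size": -1,
            "file_attributes": {
                "patient_id": image.patient_id,
                "device_tag": image.device_tag,
            },
            "regions": [
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [float(x) for x in poly.xs],
                        "all_points_y": [float(y) for y in poly.ys],
                    },
                    "region_attributes": {"label": poly.label},
                }
                for poly in image.annotations
            ],
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_feature_table(rows: Sequence["FeatureVectorLike"], path: str | Path) -> None:
    """Write feature vectors as a CSV table: one feature per column + label.

    All rows must share the same ordered feature-name header; values round
    trip at full printed precision.
    """
    rows = list(rows)
    if not rows:
        from .features import FEATURE_NAMES  # canonical header for empty tables

        pd.DataFrame(columns=[*FEATURE_NAMES, "label"]).to_csv(path, index=False)
        return
    header = list(rows[0].values.keys())
    for row in rows[1:]:
        if list(row.values.keys()) != header:
            raise ValueError("inconsistent feature headers across rows")
    df = pd.DataFrame([list(r.values.values()) for r in rows], columns=header)
    df["label"] = [r.label for r in rows]
    df.to_csv(path, index=False, float_format="%.17g")


def write_feature_frame(df: pd.DataFrame, path: str | Path) -> None:
    """Write an already-assembled feature table (features + ``label``)."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path, float_precision="round_trip")


class FeatureVectorLike:  # pragma: no cover - typing helper
    values: dict[str, float]
    label: str
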