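"""Synthetic two-class speckle phantoms.

Clinical B-mode liver acquisitions cannot be redistributed, so every
downstream stage of the package is exercised on synthetic phantoms that
emulate the *statistical* contrast between a tumor and the surrounding
cirrhotic parenchyma: two fully-developed-speckle textures with different
coarseness/heterogeneity, one composited inside a polygonal "lesion" and
annotated exactly like a clinical frame.

Speckle model
-------------
A complex circular-Gaussian scattering field is low-pass filtered at the
point-spread-function scale (``correlation_length``), its envelope magnitude
is taken (Rayleigh statistics), multiplied by a smooth multiplicative gain
field of relative amplitude ``heterogeneity``, log-compressed, standardized,
and mapped affinely to 8-bit intensities around ``mean_brightness`` with a
fluctuation amplitude proportional to ``contrast_scale``. This is the
standard fully-developed-speckle approximation; it reproduces granularity
and coarseness, not device-specific absolute intensity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon2mask

from .io_via import HCC, AnnotatedImage, Polygon

__all__ = [
    "TextureParams",
    "PhantomSpec",
    "generate_speckle_texture",
    "generate_annotated_phantom",
    "generate_cohort",
    "ellipse_polygon",
]

# std of the log-compressed envelope in gray levels at contrast_scale = 1
_CONTRAST_UNIT = 30.0


@dataclass(frozen=True)
class TextureParams:
    """Statistical knobs of one speckle texture.

    correlation_length
        Gaussian blur scale (pixels) of the scattering field; larger values
        give coarser speckle grains.
    mean_brightness
        Target mean 8-bit intensity of the texture.
    heterogeneity
        Relative amplitude of a smooth low-frequency gain field (0 = none),
        emulating large-scale echogenicity variation inside a tissue class.
    contrast_scale
        Multiplier on the speckle fluctuation amplitude; 1.0 corresponds to
        a gray-level standard deviation of about 30.
    """

    correlation_length: float = 1.5
    mean_brightness: float = 120.0
    heterogeneity: float = 0.2
    contrast_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.correlation_length < 0.5:
            raise ValueError("correlation_length must be >= 0.5")
        if self.mean_brightness <= 0 or self.contrast_scale < 0 or self.heterogeneity < 0:
            raise ValueError("texture parameters must be positive")


@dataclass
class PhantomSpec:
    """Full specification of one annotated phantom frame."""

    image_size: tuple[int, int] = (400, 400)  # (height, width)
    lesion_polygon: Polygon | str = "auto-ellipse"
    inside_texture: TextureParams = field(
        default_factory=lambda: TextureParams(correlation_length=4.0, mean_brightness=140.0)
    )
    outside_texture: TextureParams = field(
        default_factory=lambda: TextureParams(correlation_length=1.5, mean_brightness=110.0)
    )
    seed: int = 0
    margin: int = 56  # minimum clearance between lesion and image border

    def resolved_polygon(self) -> Polygon:
        if isinstance(self.lesion_polygon, Polygon):
            poly = self.lesion_polygon
        else:
            h, w = self.image_size
            poly = ellipse_polygon(
                center=(w / 2.0, h / 2.0),
                semi_axes=((w - 2 * self.margin) / 2.0 - 1, (h - 2 * self.margin) / 2.0 - 1),
            )
        self._check_margin(poly)
        return poly

    def _check_margin(self, poly: Polygon) -> None:
        h, w = self.image_size
        xmin, ymin, xmax, ymax = poly.bounding_box()
        if (
            xmin < self.margin
            or ymin < self.margin
            or xmax > w - 1 - self.margin
            or ymax > h - 1 - self.margin
        ):
            raise ValueError(
                f"lesion polygon must keep a {self.margin}-pixel margin to every border"
            )


def ellipse_polygon(
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    n_vertices: int = 24,
    label: str = HCC,
) -> Polygon:
    """Regular polygon approximating an axis-aligned ellipse."""
    cx, cy = center
    ax, ay = semi_axes
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return Polygon(
        [(cx + ax * np.cos(t), cy + ay * np.sin(t)) for t in theta], label=label
    )


def generate_speckle_texture(
    size: tuple[int, int],
    params: TextureParams,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate one fully-developed-speckle texture as a uint8 grid.

    Deterministic given the seed. In the degenerate limit
    ``heterogeneity = 0, contrast_scale -> 0`` the output approaches a
    constant plane at ``mean_brightness``.
    """
    h, w = int(size[0]), int(size[1])
    if h < 8 or w < 8:
        raise ValueError("texture size must be at least 8x8")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # complex circular-Gaussian scattering field, blurred at the PSF scale
    re = gaussian_filter(rng.standard_normal((h, w)), params.correlation_length, mode="wrap")
    im = gaussian_filter(rng.standard_normal((h, w)), params.correlation_length, mode="wrap")
    envelope = np.hypot(re, im)

    # smooth multiplicative gain field (large-scale echogenicity variation)
    gain_noise = gaussian_filter(rng.standard_normal((h, w)), max(h, w) / 8.0, mode="wrap")
    gstd = gain_noise.std()
    if gstd > 0:
        gain_noise = gain_noise / gstd
    gain = np.clip(1.0 + params.heterogeneity * gain_noise, 0.05, None)

    compressed = np.log(envelope * gain + 1e-6)
    cstd = compressed.std()
    z = (compressed - compressed.mean()) / cstd if cstd > 0 else np.zeros_like(compressed)
    out = params.mean_brightness + _CONTRAST_UNIT * params.contrast_scale * z
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def generate_annotated_phantom(spec: PhantomSpec) -> AnnotatedImage:
    """Composite the inside texture within the lesion polygon of a frame.

    The lesion border is blended over ~2 pixels to emulate the diffuse
    tumor/parenchyma transition seen clinically; the polygon is attached as
    an HCC annotation.
    """
    poly = spec.resolved_polygon()
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    outside = generate_speckle_texture((h, w), spec.outside_texture, rng).astype(float)
    if spec.inside_texture == spec.outside_texture:
        # identical parameters: a truly null phantom is one texture with an
        # arbitrary polygon on it -- blending two independent realizations
        # would leave a detectable seam and break the no-signal contract
        pixels = outside.astype(np.uint8)
    else:
        inside = generate_speckle_texture((h, w), spec.inside_texture, rng).astype(float)
        # polygon2mask takes (row, col) vertex order
        mask = polygon2mask((h, w), np.column_stack([poly.ys, poly.xs])).astype(float)
        blend = gaussian_filter(mask, 1.0)  # ~2-pixel soft transition band
        pixels = np.clip(np.rint(outside * (1.0 - blend) + inside * blend), 0, 255).astype(
            np.uint8
        )
    return AnnotatedImage(pixels=pixels, annotations=[poly])


def _jitter(params: TextureParams, rng: np.random.Generator) -> TextureParams:
    # small per-patient perturbation of the texture statistics
    return TextureParams(
        correlation_length=max(0.5, params.correlation_length * (1.0 + 0.08 * rng.standard_normal())),
        mean_brightness=float(np.clip(params.mean_brightness + 6.0 * rng.standard_normal(), 40, 220)),
        heterogeneity=max(0.0, params.heterogeneity * (1.0 + 0.15 * rng.standard_normal())),
        contrast_scale=max(0.05, params.contrast_scale * (1.0 + 0.08 * rng.standard_normal())),
    )


def generate_cohort(
    n_patients: int,
    images_per_patient: int,
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
    device_tag: str = "SYN",
) -> list[AnnotatedImage]:
    """Generate a reproducible multi-patient phantom cohort.

    Each patient gets jittered texture parameters (patients differ more than
    frames of the same patient, as in a clinical cohort) and a unique
    ``patient_id``; all randomness flows from ``seed`` through a splittable
    seed sequence so cohort members are independent but reproducible.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not (1 <= images_per_patient <= 1000):
        raise ValueError("images_per_patient must be within [1, 1000]")
    spec_template = spec_template or PhantomSpec()

    images: list[AnnotatedImage] = []
    patient_seqs = np.random.SeedSequence(seed).spawn(n_patients)
    for p, pseq in enumerate(patient_seqs):
        patient_id = f"{device_tag}-{p:04d}"
        prng = np.random.default_rng(pseq)
        inside = _jitter(spec_template.inside_texture, prng)
        if spec_template.inside_texture == spec_template.outside_texture:
            outside = inside  # keep null cohorts truly signal-free
        else:
            outside = _jitter(spec_template.outside_texture, prng)
        for k in range(images_per_patient):
            frame_seed = int(prng.integers(0, 2**31 - 1))
            spec = replace(
                spec_template,
                inside_texture=inside,
                outside_texture=outside,
                seed=frame_seed,
            )
            image = generate_annotated_phantom(spec)
            image.patient_id = patient_id
            image.device_tag = device_tag
            image.source_path = f"{patient_id}_{k:03d}.png"
            images.append(image)
    return images
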