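"""Conventional texture descriptors for 56x56 ultrasound patches.

The canonical per-patch descriptor has exactly 47 named features, computed
after a 3x3 median prefilter (speckle attenuation):

====================  ==  ========================================================
family                 n  features
====================  ==  ========================================================
order-2 GLCM           6  homogeneity, energy, entropy, correlation, contrast,
                          variance, each averaged over the 8 unit displacements
                          at multiples of 45 degrees
order-3 GLCM           6  the same statistics generalized to gray-level triples,
                          averaged over the 12 direction pairs (4 collinear +
                          8 right-angle) with offset magnitude 2
autocorrelation        1  normalized diagonal-lag spatial autocorrelation
Hurst index            1  fractal roughness exponent in [0, 1]
edge statistics        3  edge frequency, edge contrast, average edge orientation
Laws energy           10  density and frequency of the L5/E5/S5/W5/R5 maps
wavelet entropies     20  Shannon entropy of every first- and second-level Haar
                          component (4 + 16)
====================  ==  ========================================================

An optional local-binary-pattern (LBP) cell histogram extends the vector
for LBP+GLCM style comparisons.

All features are finite for every 8-bit input, including constant and
impulse patches; degenerate cases use documented conventions rather than
raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt
from scipy.ndimage import convolve as nd_convolve
from scipy.ndimage import median_filter, sobel
from skimage.filters import threshold_otsu

from .patches import Patch

__all__ = [
    "GLCMConfig",
    "GLCMTensor",
    "FeatureVector",
    "LBPConfig",
    "median_prefilter",
    "compute_glcm",
    "haralick_features",
    "autocorrelation_index",
    "hurst_index",
    "edge_statistics",
    "laws_features",
    "wavelet_entropies",
    "lbp_histogram",
    "extract_feature_vector",
    "FEATURE_NAMES",
    "order2_displacements",
    "order3_displacements",
]

HARALICK_NAMES = ("homogeneity", "energy", "entropy", "correlation", "contrast", "variance")
LAWS_VECTORS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}


def _unit_step(angle_deg: float, magnitude: int = 1) -> tuple[int, int]:
    """Displacement (dx, dy) for an angle in image coordinates (y down).

    Angles are multiples of 45 degrees, so the unit step lies on the
    8-neighborhood grid; each nonzero component then has magnitude
    ``magnitude`` (diagonal steps at magnitude 2 are (+/-2, +/-2)).
    """
    rad = math.radians(angle_deg)
    return (
        magnitude * int(round(math.cos(rad))),
        magnitude * int(round(-math.sin(rad))),
    )


def order2_displacements() -> list[tuple[tuple[int, int]]]:
    """The 8 unit displacement vectors at multiples of 45 degrees."""
    return [(_unit_step(a, 1),) for a in range(0, 360, 45)]


def order3_displacements(magnitude: int = 2) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """The 12 direction pairs of the third-order co-occurrence tensor.

    The current pixel sits centrally; the two companions lie at
    ``magnitude`` steps along a direction pair that is either collinear or
    forms a right angle at the center.
    """
    collinear = [(0, 180), (90, 270), (45, 225), (135, 315)]
    right_angle = [
        (0, 90), (90, 180), (180, 270), (0, 270),
        (45, 135), (135, 225), (225, 315), (45, 315),
    ]
    return [
        (_unit_step(a1, magnitude), _unit_step(a2, magnitude))
        for a1, a2 in collinear + right_angle
    ]


@dataclass(frozen=True)
class GLCMConfig:
    """Order, quantization depth and displacement set of a co-occurrence run."""

    order: int = 2
    gray_levels: int = 32
    displacements: tuple = ()

    def __post_init__(self) -> None:
        if self.order not in (2, 3):
            raise ValueError("order must be 2 or 3")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if not self.displacements:
            default = (
                order2_displacements() if self.order == 2 else order3_displacements()
            )
            object.__setattr__(self, "displacements", tuple(default))
        for disp in self.displacements:
            if len(disp) != self.order - 1:
                raise ValueError("each displacement config needs order-1 vectors")


@dataclass
class GLCMTensor:
    """Raw co-occurrence counts for one displacement configuration."""

    counts: np.ndarray
    config: GLCMConfig

    @property
    def order(self) -> int:
        return self.counts.ndim

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty co-occurrence tensor (no in-bounds tuples)")
        return self.counts / float(total)


def quantize(pixels: np.ndarray, gray_levels: int) -> np.ndarray:
    """Uniform binning of [0, 255] into ``gray_levels`` levels."""
    q = (pixels.astype(np.int64) * gray_levels) // 256
    return np.clip(q, 0, gray_levels - 1)


def median_prefilter(pixels: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter with reflect-padded borders (speckle attenuation)."""
    if kernel % 2 == 0:
        raise ValueError("median kernel must be odd")
    return median_filter(pixels, size=kernel, mode="reflect")


def compute_glcm(pixels: np.ndarray, config: GLCMConfig) -> list[GLCMTensor]:
    """Co-occurrence tensors of a patch, one per displacement configuration.

    The patch is quantized to ``config.gray_levels``; for every pixel the
    in-bounds tuple of quantized levels along the displacement vectors
    increments the corresponding count. One tensor per configuration is
    returned so feature averaging can happen downstream.
    """
    pixels = np.asarray(pixels)
    h, w = pixels.shape
    reach = max(
        max(abs(d[0]), abs(d[1])) for disp in config.displacements for d in disp
    )
    if h <= reach or w <= reach:
        raise ValueError("patch smaller than the largest displacement reach")
    q = quantize(pixels, config.gray_levels)
    g = config.gray_levels

    tensors = []
    for disp in config.displacements:
        # overlap region where the whole tuple stays in bounds
        dxs = [0] + [d[0] for d in disp]
        dys = [0] + [d[1] for d in disp]
        x0, x1 = -min(dxs), w - max(dxs)
        y0, y1 = -min(dys), h - max(dys)
        counts = np.zeros((g,) * config.order, dtype=np.int64)
        if x1 > x0 and y1 > y0:
            levels = [
                q[y0 + dy : y1 + dy, x0 + dx : x1 + dx].ravel()
                for dx, dy in zip(dxs, dys)
            ]
            flat = levels[0].astype(np.int64)
            for lv in levels[1:]:
                flat = flat * g + lv
            counts = np.bincount(flat, minlength=g**config.order).reshape(
                (g,) * config.order
            )
        tensors.append(GLCMTensor(counts=counts, config=config))
    return tensors


def _pairwise_sq_diff(order: int, g: int) -> np.ndarray:
    """Mean squared gray-level difference over tuple pairs, per tensor cell."""
    grids = np.meshgrid(*([np.arange(g)] * order), indexing="ij")
    pairs = [(i, j) for i in range(order) for j in range(i + 1, order)]
    acc = np.zeros_like(grids[0], dtype=float)
    for i, j in pairs:
        acc += (grids[i] - grids[j]) ** 2
    return acc / len(pairs)


def _haralick_one(p: np.ndarray) -> dict[str, float]:
    order = p.ndim
    g = p.shape[0]
    idx = np.arange(g, dtype=float)

    energy = float(np.sum(p * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    d2 = _pairwise_sq_diff(order, g)
    contrast = float(np.sum(p * d2))
    homogeneity = float(np.sum(p / (1.0 + d2)))

    # per-position marginals
    margins = []
    for axis in range(order):
        other = tuple(a for a in range(order) if a != axis)
        margins.append(p.sum(axis=other))
    mus = [float(np.dot(idx, m)) for m in margins]
    sigmas = [math.sqrt(max(float(np.dot((idx - mu) ** 2, m)), 0.0)) for mu, m in zip(mus, margins)]
    variance = float(np.mean([np.dot((idx - mu) ** 2, m) for mu, m in zip(mus, margins)]))

    grids = np.meshgrid(*([idx] * order), indexing="ij")
    corrs = []
    for i in range(order):
        for j in range(i + 1, order):
            if sigmas[i] == 0.0 or sigmas[j] == 0.0:
                corrs.append(0.0)  # zero-variance convention
            else:
                cov = float(np.sum(p * (grids[i] - mus[i]) * (grids[j] - mus[j])))
                corrs.append(cov / (sigmas[i] * sigmas[j]))
    correlation = float(np.mean(corrs))

    return {
        "homogeneity": homogeneity,
        "energy": energy,
        "entropy": entropy,
        "correlation": correlation,
        "contrast": contrast,
        "variance": variance,
    }


def haralick_features(tensors: Sequence[GLCMTensor]) -> dict[str, float]:
    """Haralick statistics averaged over a set of co-occurrence tensors.

    Each tensor is normalized to a distribution and the six statistics are
    computed on it; the returned value per statistic is the arithmetic mean
    over tensors (one per displacement configuration).
    """
    if not tensors:
        raise ValueError("need at least one tensor")
    orders = {t.order for t in tensors}
    if len(orders) != 1:
        raise ValueError("tensors must share the same order")
    per = [_haralick_one(t.normalized()) for t in tensors]
    return {name: float(np.mean([d[name] for d in per])) for name in HARALICK_NAMES}


def autocorrelation_index(pixels: np.ndarray) -> float:
    """Normalized spatial autocorrelation at diagonal unit lag.

    ``sum I(x, y) I(x+1, y+1) / sum I(x, y)^2`` with both sums over the
    (H-1) x (W-1) support; 0 for an all-zero patch.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape[0] < 2 or pixels.shape[1] < 2:
        raise ValueError("patch must be at least 2x2")
    a = pixels[:-1, :-1]
    b = pixels[1:, 1:]
    denom = float(np.sum(a * a))
    if denom == 0.0:
        return 0.0
    return float(np.sum(a * b) / denom)


def hurst_index(pixels: np.ndarray, max_lag: int = 8) -> float:
    """Fractal roughness exponent of the intensity surface, in [0, 1].

    Estimated as the slope of log mean absolute intensity increment against
    log lag over lags 1..``max_lag`` (horizontal and vertical increments
    pooled) -- the increment-scaling estimator for a fractional Brownian
    surface, where E|I(p+d) - I(p)| ~ d^H. A constant patch is defined as
    maximally smooth (H = 1).
    """
    pixels = np.asarray(pixels, dtype=float)
    if min(pixels.shape) < 2 * max_lag:
        raise ValueError("patch too small for the requested lag range")
    lags = np.arange(1, max_lag + 1)
    means = np.empty(len(lags))
    for i, d in enumerate(lags):
        horiz = np.abs(pixels[:, d:] - pixels[:, :-d])
        vert = np.abs(pixels[d:, :] - pixels[:-d, :])
        means[i] = (horiz.sum() + vert.sum()) / (horiz.size + vert.size)
    if np.any(means == 0.0):
        return 1.0  # constant (or lag-degenerate) surface: maximal smoothness
    slope = np.polyfit(np.log(lags), np.log(means), 1)[0]
    return float(np.clip(slope, 0.0, 1.0))


def edge_statistics(pixels: np.ndarray) -> dict[str, float]:
    """Sobel-based edge frequency, edge contrast and mean edge orientation.

    Edge pixels are those whose gradient magnitude exceeds the Otsu
    threshold of the magnitude map. Orientation is the circular mean of
    gradient angles folded to [0, pi); all three are 0 when no edge pixels
    exist (e.g. a constant patch).
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape[0] < 3 or pixels.shape[1] < 3:
        raise ValueError("patch must be at least 3x3")
    gx = sobel(pixels, axis=1, mode="reflect")
    gy = sobel(pixels, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    if mag.max() == 0.0:
        return {"edge_frequency": 0.0, "edge_contrast": 0.0, "edge_orientation": 0.0}
    try:
        thresh = threshold_otsu(mag)
    except ValueError:  # single-valued magnitude map
        thresh = mag.max()  # no pixel strictly above
    edges = mag > thresh
    if not edges.any():
        return {"edge_frequency": 0.0, "edge_contrast": 0.0, "edge_orientation": 0.0}
    freq = float(edges.mean())
    contrast = float(mag[edges].mean())
    theta = np.arctan2(gy[edges], gx[edges])
    # axial data: double the angles before averaging, then halve
    mean_angle = 0.5 * math.atan2(
        float(np.sin(2 * theta).sum()), float(np.cos(2 * theta).sum())
    )
    orientation = mean_angle % math.pi
    return {"edge_frequency": freq, "edge_contrast": contrast, "edge_orientation": orientation}


def laws_kernels() -> dict[str, np.ndarray]:
    """The five separable 5x5 Laws kernels used here.

    The level map uses L5'L5; each micro-structure vector (E5 edge, S5
    spot, W5 wave, R5 ripple) varies along rows and is paired with the
    smoothing vector L5 along columns.
    """
    L5 = LAWS_VECTORS["L5"]
    return {name: np.outer(vec, L5) for name, vec in LAWS_VECTORS.items()}


def laws_features(pixels: np.ndarray) -> dict[str, float]:
    """Density and frequency of the Laws texture-energy maps (10 features).

    Per map: density is the mean absolute filter response, frequency the
    fraction of pixels whose absolute response exceeds that mean. Zero-sum
    kernels annihilate constant patches, giving (0, 0) there.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape[0] < 5 or pixels.shape[1] < 5:
        raise ValueError("patch must be at least 5x5")
    out: dict[str, float] = {}
    for name, kernel in laws_kernels().items():
        resp = np.abs(nd_convolve(pixels, kernel, mode="reflect"))
        density = float(resp.mean())
        frequency = float((resp > density).mean()) if density > 0 else 0.0
        out[f"laws_{name}_density"] = density
        out[f"laws_{name}_frequency"] = frequency
    return out


def shannon_entropy(coefficients: np.ndarray, normalize: bool = True) -> float:
    """Shannon entropy of a coefficient array's magnitudes (bits).

    With ``normalize`` the magnitudes are L1-normalized first so the sum is
    a proper entropy and the value is scale invariant; the literal
    unnormalized reading ``-sum |c| log2 |c|`` is available with
    ``normalize=False``. An all-zero array has entropy 0.
    """
    mags = np.abs(np.asarray(coefficients, dtype=float)).ravel()
    total = mags.sum()
    if total == 0.0:
        return 0.0
    if normalize:
        mags = mags / total
    nz = mags[mags > 0]
    return float(-np.sum(nz * np.log2(nz)))


def wavelet_entropies(pixels: np.ndarray, normalize: bool = True) -> dict[str, float]:
    """Shannon entropies of the recursive Haar decomposition (20 features).

    One-level Haar gives components ll, lh, hl, hh; Haar is applied again
    to each, giving 16 second-level components. The entropy of every
    component's coefficient magnitudes is returned in fixed order
    (4 first-level + 16 second-level).
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape[0] % 4 or pixels.shape[1] % 4:
        raise ValueError("patch side must be divisible by 4")
    names = ("ll", "lh", "hl", "hh")

    def split(arr: np.ndarray) -> dict[str, np.ndarray]:
        ca, (ch, cv, cd) = pywt.dwt2(arr, "haar")
        return dict(zip(names, (ca, ch, cv, cd)))

    level1 = split(pixels)
    out: dict[str, float] = {
        f"wavelet_{k}": shannon_entropy(v, normalize) for k, v in level1.items()
    }
    for k1 in names:
        level2 = split(level1[k1])
        for k2 in names:
            out[f"wavelet_{k1}_{k2}"] = shannon_entropy(level2[k2], normalize)
    return out


@dataclass(frozen=True)
class LBPConfig:
    """Radius/neighbor-count/cell-size of the LBP histogram descriptor."""

    radius: float = 1.0
    neighbors: int = 8
    cell_size: int = 14

    def __post_init__(self) -> None:
        if self.neighbors < 4 or self.radius < 1:
            raise ValueError("need neighbors >= 4 and radius >= 1")


def lbp_codes(pixels: np.ndarray, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """Per-pixel LBP codes with strict sign comparison.

    Neighbor p sits at angle ``p * 2pi/N`` on a circle of radius R (bilinear
    interpolation); its bit is set iff the neighbor is strictly brighter
    than the center. Border pixels without a full neighborhood are skipped:
    the returned map covers the interior and is -1 elsewhere.
    """
    pixels = np.asarray(pixels, dtype=float)
    h, w = pixels.shape
    r = config.radius
    n = config.neighbors
    m = int(math.ceil(r))
    codes = np.full((h, w), -1, dtype=np.int64)
    ys, xs = np.mgrid[m : h - m, m : w - m]
    center = pixels[m : h - m, m : w - m]
    acc = np.zeros_like(center, dtype=np.int64)
    for p in range(n):
        angle = 2.0 * math.pi * p / n
        dx = r * math.cos(angle)
        dy = r * math.sin(angle)
        fx, fy = xs + dx, ys + dy
        x0, y0 = np.floor(fx).astype(int), np.floor(fy).astype(int)
        tx, ty = fx - x0, fy - y0
        # the +1 neighbors carry zero weight when the offset is integral,
        # so clamping them at the border is exact
        x1 = np.minimum(x0 + 1, w - 1)
        y1 = np.minimum(y0 + 1, h - 1)
        # interpolate the difference to the center so equal-valued
        # neighborhoods give an exact zero under the strict comparison
        diff = (
            (pixels[y0, x0] - center) * (1 - tx) * (1 - ty)
            + (pixels[y0, x1] - center) * tx * (1 - ty)
            + (pixels[y1, x0] - center) * (1 - tx) * ty
            + (pixels[y1, x1] - center) * tx * ty
        )
        acc += (diff > 0).astype(np.int64) << p
    codes[m : h - m, m : w - m] = acc
    return codes


def lbp_histogram(pixels: np.ndarray, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """Concatenated per-cell LBP code histograms (raster cell order).

    The patch is divided into non-overlapping ``cell_size`` cells; each
    contributes a 2^N-bin histogram of the codes of its pixels (border
    pixels without full neighborhoods are skipped).
    """
    pixels = np.asarray(pixels)
    h, w = pixels.shape
    if h % config.cell_size or w % config.cell_size:
        raise ValueError("cell_size must divide the patch side")
    codes = lbp_codes(pixels, config)
    bins = 2**config.neighbors
    cs = config.cell_size
    hists = []
    for cy in range(0, h, cs):
        for cx in range(0, w, cs):
            cell = codes[cy : cy + cs, cx : cx + cs]
            valid = cell[cell >= 0]
            hists.append(np.bincount(valid, minlength=bins)[:bins])
    return np.concatenate(hists).astype(np.int64)


@dataclass
class FeatureVector:
    """Ordered, named conventional texture descriptor of one patch."""

    values: dict[str, float]
    label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite features: {bad}")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def _canonical_names() -> list[str]:
    names = [f"glcm2_{n}" for n in HARALICK_NAMES]
    names += [f"glcm3_{n}" for n in HARALICK_NAMES]
    names += ["autocorrelation", "hurst"]
    names += ["edge_frequency", "edge_contrast", "edge_orientation"]
    for k in LAWS_VECTORS:
        names += [f"laws_{k}_density", f"laws_{k}_frequency"]
    names += [f"wavelet_{k}" for k in ("ll", "lh", "hl", "hh")]
    names += [
        f"wavelet_{k1}_{k2}"
        for k1 in ("ll", "lh", "hl", "hh")
        for k2 in ("ll", "lh", "hl", "hh")
    ]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(_canonical_names())
assert len(FEATURE_NAMES) == 47


def extract_feature_vector(
    patch: Patch | np.ndarray,
    order2_levels: int = 32,
    order3_levels: int = 16,
    include_lbp: bool = False,
    lbp_config: LBPConfig = LBPConfig(),
) -> FeatureVector:
    """The canonical 47-dimensional descriptor of one patch.

    Applies the median prefilter, then computes 6 order-2 + 6 order-3
    Haralick statistics, autocorrelation, Hurst index, 3 edge statistics,
    10 Laws features and 20 wavelet entropies, in the fixed order of
    ``FEATURE_NAMES``. Deterministic. With ``include_lbp`` the cell LBP
    histogram is appended (``lbp_000`` ...), as used in LBP+GLCM
    comparisons.
    """
    if isinstance(patch, Patch):
        pixels, label, source = patch.pixels, patch.label, patch.source
    else:
        pixels, label, source = np.asarray(patch), "", ""
    filtered = median_prefilter(pixels)

    values: dict[str, float] = {}
    h2 = haralick_features(compute_glcm(filtered, GLCMConfig(order=2, gray_levels=order2_levels)))
    values.update({f"glcm2_{k}": v for k, v in h2.items()})
    h3 = haralick_features(compute_glcm(filtered, GLCMConfig(order=3, gray_levels=order3_levels)))
    values.update({f"glcm3_{k}": v for k, v in h3.items()})
    values["autocorrelation"] = autocorrelation_index(filtered)
    values["hurst"] = hurst_index(filtered)
    values.update(edge_statistics(filtered))
    values.update(laws_features(filtered))
    values.update(wavelet_entropies(filtered))
    assert list(values.keys()) == list(FEATURE_NAMES)

    if include_lbp:
        hist = lbp_histogram(filtered, lbp_config)
        values.update({f"lbp_{i:04d}": float(c) for i, c in enumerate(hist)})
    return FeatureVector(values=values, label=label, source=source)


def extract_feature_table(patches: Sequence[Patch], **kwargs) -> "pd.DataFrame":
    """Feature table (one row per patch, plus label/patient columns)."""
    import pandas as pd

    rows = []
    for p in patches:
        fv = extract_feature_vector(p, **kwargs)
        row = dict(fv.values)
        row["label"] = p.label
        row["patient_id"] = p.patient_id
        rows.append(row)
    return pd.DataFrame(rows)
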