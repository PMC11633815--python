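"""Training-data preparation: resampling, cropping, HU normalization, augmentation.

Network inputs are Min-Max normalized from a fixed HU window to [-1, 1]:
the floor is -1000 HU (air) and the ceiling is 90% of the maximum HU
observed over the training set.  Values above the ceiling clip, which is
why very dense materials (bone-like inserts) cannot be recovered exactly
after a round trip — a deliberate property of the windowing, retained
here.  The normalizer is fitted once on the training corpus and frozen
into the model checkpoint so inference uses identical scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .phantom import CTImage, ParameterError


@dataclass(frozen=True)
class NormalizationSpec:
    """Affine HU window mapping [hu_floor, hu_ceiling] -> out_range, clipped."""

    hu_floor: float = -1000.0
    hu_ceiling: float = 1000.0
    out_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.hu_ceiling <= self.hu_floor:
            raise ParameterError(
                f"degenerate normalization window: ceiling {self.hu_ceiling} "
                f"<= floor {self.hu_floor}"
            )
        if self.out_range[1] <= self.out_range[0]:
            raise ParameterError("out_range must be increasing")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NormalizationSpec":
        d = json.loads(text)
        d["out_range"] = tuple(d["out_range"])
        return cls(**d)


def fit_normalizer(
    training_images: Iterable[CTImage],
    ceiling_fraction: float = 0.9,
    hu_floor: float = -1000.0,
    out_range: tuple[float, float] = (-1.0, 1.0),
    mode: str = "max",
) -> NormalizationSpec:
    """Fit the HU window from the training corpus.

    ``mode="max"`` sets the ceiling to ``ceiling_fraction`` times the global
    maximum HU (the literal reading of "90% of the maximum CT value");
    ``mode="percentile"`` uses the ``100 * ceiling_fraction`` percentile of
    all pixels instead.
    """
    if not (0.0 < ceiling_fraction <= 1.0):
        raise ParameterError("ceiling_fraction must be in (0, 1]")
    images = list(training_images)
    if not images:
        raise ParameterError("cannot fit a normalizer on an empty training set")
    global_max = max(float(img.pixels.max()) for img in images)
    if global_max <= hu_floor:
        raise ParameterError(
            f"training set maximum {global_max} HU does not exceed the "
            f"floor {hu_floor} HU; normalization window would be degenerate"
        )
    if mode == "max":
        ceiling = ceiling_fraction * global_max
    elif mode == "percentile":
        allpix = np.concatenate([img.pixels.ravel() for img in images])
        ceiling = float(np.percentile(allpix, 100.0 * ceiling_fraction))
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return NormalizationSpec(hu_floor=hu_floor, hu_ceiling=ceiling, out_range=out_range)


def normalize(img: CTImage, spec: NormalizationSpec) -> CTImage:
    """Map HU to ``spec.out_range`` affinely, clipping outside the window."""
    lo, hi = spec.out_range
    clipped = np.clip(img.pixels, spec.hu_floor, spec.hu_ceiling)
    scaled = (clipped - spec.hu_floor) / (spec.hu_ceiling - spec.hu_floor)
    out = img.copy()
    out.pixels = lo + scaled * (hi - lo)
    return out


def denormalize(norm_img: CTImage, spec: NormalizationSpec) -> CTImage:
    """Exact affine inverse of :func:`normalize` on in-range values."""
    lo, hi = spec.out_range
    scaled = (norm_img.pixels - lo) / (hi - lo)
    out = norm_img.copy()
    out.pixels = spec.hu_floor + scaled * (spec.hu_ceiling - spec.hu_floor)
    return out


def resample(img: CTImage, target_spacing_mm: float) -> CTImage:
    """Bilinear resample to isotropic ``target_spacing_mm``.

    Physical extent is preserved to within one pixel; metadata spacing is
    updated.  Identity spacing returns an unchanged copy.
    """
    if target_spacing_mm <= 0:
        raise ParameterError("target spacing must be > 0")
    sy, sx = img.spacing_mm
    if sy == target_spacing_mm and sx == target_spacing_mm:
        return img.copy()
    zoom = (sy / target_spacing_mm, sx / target_spacing_mm)
    pixels = ndimage.zoom(img.pixels, zoom, order=1, mode="nearest")
    out = CTImage(pixels, (target_spacing_mm, target_spacing_mm),
                  img.dose_mAs, img.seed)
    return out


def random_crop(
    img: CTImage,
    size: int,
    seed: int | np.random.Generator = 0,
    central_fraction: float = 0.5,
) -> CTImage:
    """Central random crop: a ``size`` square whose center is uniform
    within the central ``central_fraction`` window of the image.

    "Central" and "random" are combined literally: the patch center is
    jittered uniformly but confined near the image center, so patches
    always sample the phantom/patient rather than surrounding air.
    """
    rows, cols = img.shape
    if size > min(rows, cols):
        raise ParameterError(f"crop size {size} exceeds image {img.shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out_rc = []
    for dim in (rows, cols):
        half_window = central_fraction * dim / 2.0
        center = dim / 2.0 + rng.uniform(-half_window, half_window)
        top = int(round(center - size / 2.0))
        top = min(max(top, 0), dim - size)
        out_rc.append(top)
    r0, c0 = out_rc
    out = img.copy()
    out.pixels = img.pixels[r0 : r0 + size, c0 : c0 + size].copy()
    return out


@dataclass(frozen=True)
class AugmentationPolicy:
    """Geometric augmentation: flips, scale-and-clip, crop-resize, rotation.

    All transforms are pixel-rearranging or resampling operations; no
    intensity transform is ever applied, so the HU value distribution is
    preserved up to interpolation.
    """

    flip_vertical_prob: float = 0.5
    scale_prob: float = 0.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    crop_resize_prob: float = 0.0
    crop_resize_min_fraction: float = 0.8
    rotation_prob: float = 0.5
    rotation_degrees_range: tuple[float, float] = (0.0, 360.0)
    rotation_right_angles: bool = False
    fill_hu: float = -1000.0

    def __post_init__(self) -> None:
        for p in (self.flip_vertical_prob, self.scale_prob,
                  self.crop_resize_prob, self.rotation_prob):
            if not (0.0 <= p <= 1.0):
                raise ParameterError("probabilities must be in [0, 1]")
        lo, hi = self.rotation_degrees_range
        if not (0.0 <= lo <= hi <= 360.0):
            raise ParameterError("rotation range must lie within [0, 360]")


def _rotate(pixels: np.ndarray, angle_deg: float, fill: float) -> np.ndarray:
    # multiples of 90 degrees are exact pixel permutations
    if angle_deg % 90.0 == 0.0:
        return np.rot90(pixels, int(angle_deg // 90) % 4).copy()
    return ndimage.rotate(
        pixels, angle_deg, reshape=False, order=1, mode="constant", cval=fill
    )


def augment(
    patch: CTImage,
    policy: AugmentationPolicy,
    seed: int | np.random.Generator = 0,
) -> CTImage:
    """Apply the enabled geometric transforms, each with its probability.

    Deterministic per seed; with all probabilities zero the patch is
    returned bit-identically.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    px = patch.pixels
    size = px.shape[0]
    if policy.flip_vertical_prob and rng.random() < policy.flip_vertical_prob:
        px = px[::-1, :].copy()
    if policy.scale_prob and rng.random() < policy.scale_prob:
        factor = rng.uniform(*policy.scale_range)
        scaled = ndimage.zoom(px, factor, order=1, mode="nearest")
        px = _clip_to(scaled, size, policy.fill_hu)
    if policy.crop_resize_prob and rng.random() < policy.crop_resize_prob:
        frac = rng.uniform(policy.crop_resize_min_fraction, 1.0)
        sub = max(8, int(round(frac * px.shape[0])))
        r0 = rng.integers(0, px.shape[0] - sub + 1)
        c0 = rng.integers(0, px.shape[1] - sub + 1)
        cropped = px[r0 : r0 + sub, c0 : c0 + sub]
        px = ndimage.zoom(
            cropped, size / cropped.shape[0], order=1, mode="nearest"
        )
        px = _clip_to(px, size, policy.fill_hu)
    if policy.rotation_prob and rng.random() < policy.rotation_prob:
        if policy.rotation_right_angles:
            # exact pixel permutations: preserves noise statistics, which
            # interpolated rotation would smooth
            lo, hi = policy.rotation_degrees_range
            choices = [a for a in (0.0, 90.0, 180.0, 270.0) if lo <= a <= hi]
            angle = float(rng.choice(choices)) if choices else 0.0
        else:
            angle = rng.uniform(*policy.rotation_degrees_range)
        px = _rotate(px, angle, policy.fill_hu)
    out = patch.copy()
    out.pixels = np.ascontiguousarray(px, dtype=np.float64)
    return out


def _clip_to(pixels: np.ndarray, size: int, fill: float) -> np.ndarray:
    """Center-crop or center-pad to a ``size`` square."""
    out = np.full((size, size), fill, dtype=np.float64)
    r = min(size, pixels.shape[0])
    c = min(size, pixels.shape[1])
    sr = (pixels.shape[0] - r) // 2
    sc = (pixels.shape[1] - c) // 2
    dr = (size - r) // 2
    dc = (size - c) // 2
    out[dr : dr + r, dc : dc + c] = pixels[sr : sr + r, sc : sc + c]
    return out


def extract_patches(
    images: Sequence[CTImage],
    size: int,
    rng: np.random.Generator,
    policy: AugmentationPolicy | None = None,
    patches_per_image: int = 4,
    central_fraction: float = 0.5,
) -> list[CTImage]:
    """Sample augmented training patches from a corpus (one training epoch)."""
    patches = []
    for img in images:
        for _ in range(patches_per_image):
            p = random_crop(img, size, rng, central_fraction)
            if policy is not None:
                p = augment(p, policy, rng)
            patches.append(p)
    return patches
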