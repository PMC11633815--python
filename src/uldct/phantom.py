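"""Synthetic Catphan-style sensitometry phantom and dose-dependent CT noise.

This module renders a digital stand-in for the CTP404 module of a Catphan
quality-assurance phantom: a water-equivalent cylinder (default 20 cm
diameter) carrying small cylindrical inserts of known attenuation (air,
PMP, LDPE, polystyrene, acrylic, Delrin, Teflon).  Rendered images are
noise-free ground truth in Hounsfield units (HU); a separate dose
simulator degrades them with reconstruction-correlated noise whose
standard deviation scales as ``sqrt(reference_mAs / dose_mAs)``, the
photon-statistics relation between tube current-time product and image
noise in filtered back-projection CT.

The combination yields unpaired low-dose / normal-dose image corpora with
exact ground truth for every image-quality metric, so the enhancement
network can be trained and audited without patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import iradon, radon

AIR_HU = -1000.0

#: Nominal insert attenuations in HU.  These are editable defaults for the
#: simulated phantom, not measured claims about any physical phantom.
DEFAULT_INSERT_HU = {
    "air": -1000.0,
    "pmp": -200.0,
    "ldpe": -100.0,
    "polystyrene": -35.0,
    "acrylic": 120.0,
    "delrin": 340.0,
    "teflon": 990.0,
}

#: Radius of the ring on which sensitometry inserts sit, mm from center.
INSERT_RING_RADIUS_MM = 58.0


class GeometryError(ValueError):
    """An insert does not fit inside the phantom body."""


class ParameterError(ValueError):
    """A scan or simulation parameter is out of its physical domain."""


@dataclass(frozen=True)
class InsertSpec:
    """One cylindrical sensitometry insert.

    Parameters
    ----------
    name : str
        Material label, unique within a phantom.
    hu : float
        Nominal attenuation in HU.
    diameter_mm : float
        Insert diameter; 12.5 mm by default (1.25 cm rods).
    center_xy_mm : tuple of float
        Insert center relative to the phantom center, mm, (x, y) with +x
        to the right and +y downward (image row direction).
    """

    name: str
    hu: float
    diameter_mm: float = 12.5
    center_xy_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ParameterError(f"insert {self.name!r}: diameter must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of a sensitometry phantom section.

    ``uniform_module`` renders an insert-free uniformity section (used for
    noise-power-spectrum and uniformity measurements) regardless of the
    insert list.
    """

    body_diameter_mm: float = 200.0
    body_hu: float = 0.0
    inserts: tuple[InsertSpec, ...] = ()
    uniform_module: bool = False

    def __post_init__(self) -> None:
        if self.body_diameter_mm <= 0:
            raise ParameterError("body diameter must be > 0")
        names = [ins.name for ins in self.inserts]
        if len(names) != len(set(names)):
            raise GeometryError("insert names must be unique")
        for ins in self.inserts:
            cx, cy = ins.center_xy_mm
            reach = math.hypot(cx, cy) + ins.diameter_mm / 2.0
            if reach > self.body_diameter_mm / 2.0:
                raise GeometryError(
                    f"insert {ins.name!r} extends outside the phantom body "
                    f"(reach {reach:.1f} mm > body radius "
                    f"{self.body_diameter_mm / 2:.1f} mm)"
                )

    def insert(self, name: str) -> InsertSpec:
        for ins in self.inserts:
            if ins.name == name:
                return ins
        raise KeyError(f"no insert named {name!r}")


def default_phantom(
    body_hu: float = 0.0,
    insert_hu: dict[str, float] | None = None,
    ring_radius_mm: float = INSERT_RING_RADIUS_MM,
    diameter_mm: float = 12.5,
    uniform_module: bool = False,
) -> PhantomSpec:
    """CTP404-style phantom: seven inserts evenly spaced on a ring."""
    hus = dict(DEFAULT_INSERT_HU)
    if insert_hu:
        hus.update(insert_hu)
    inserts = []
    n = len(hus)
    for k, (name, hu) in enumerate(hus.items()):
        theta = 2.0 * math.pi * k / n
        cx = ring_radius_mm * math.cos(theta)
        cy = ring_radius_mm * math.sin(theta)
        inserts.append(
            InsertSpec(name=name, hu=hu, diameter_mm=diameter_mm, center_xy_mm=(cx, cy))
        )
    return PhantomSpec(
        body_hu=body_hu, inserts=tuple(inserts), uniform_module=uniform_module
    )


def small_phantom(
    body_hu: float = 0.0,
    insert_hu: dict[str, float] | None = None,
    uniform_module: bool = False,
) -> PhantomSpec:
    """Scaled-down sensitometry phantom for fast desk-scale experiments.

    Same seven materials as :func:`default_phantom` on a 56 mm body with
    8 mm inserts on a 20 mm ring, sized so a 64 x 64 image at 1 mm
    spacing holds the whole phantom.
    """
    spec = default_phantom(
        body_hu=body_hu,
        insert_hu=insert_hu,
        ring_radius_mm=20.0,
        diameter_mm=8.0,
        uniform_module=uniform_module,
    )
    return replace(spec, body_diameter_mm=56.0)


@dataclass
class CTImage:
    """A 2D HU-valued axial CT image with pixel-spacing metadata."""

    pixels: np.ndarray
    spacing_mm: tuple[float, float] = (0.9765, 0.9765)
    dose_mAs: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ParameterError("CTImage pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("CTImage pixels must be finite")
        if min(self.spacing_mm) <= 0:
            raise ParameterError("pixel spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "CTImage":
        return CTImage(
            self.pixels.copy(), tuple(self.spacing_mm), self.dose_mAs, self.seed
        )


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Scan protocol parameters for the normal-dose / low-dose pair.

    ``conversion_k`` is the adult abdominal/pelvic effective-dose
    conversion factor, 0.015 mSv/(mGy*cm).
    """

    kVp: float = 120.0
    tube_current_mAs: float = 200.0
    dlp_mGy_cm: float = 466.67
    conversion_k: float = 0.015

    def __post_init__(self) -> None:
        for name in ("kVp", "tube_current_mAs", "dlp_mGy_cm", "conversion_k"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


#: The paired protocols of the simulated study: 200 mAs normal dose and
#: 24 mAs ultra-low dose at 120 kVp.
NORMAL_DOSE_PROTOCOL = AcquisitionProtocol(
    kVp=120.0, tube_current_mAs=200.0, dlp_mGy_cm=466.67
)
LOW_DOSE_PROTOCOL = AcquisitionProtocol(
    kVp=120.0, tube_current_mAs=24.0, dlp_mGy_cm=44.67
)


def effective_dose(dlp_mGy_cm: float, k: float = 0.015) -> float:
    """Effective dose in mSv from dose-length product: ``DLP * k``.

    Use :func:`round_sig` for the 2-significant-figure display convention
    (466.67 mGy*cm at k=0.015 prints as 7.0 mSv; 44.67 prints as 0.67).
    """
    if dlp_mGy_cm < 0 or k < 0:
        raise ParameterError("DLP and k must be >= 0")
    return dlp_mGy_cm * k


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _disk_fraction(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    radius_px: float,
    supersample: int = 4,
) -> np.ndarray:
    """Area fraction of each pixel covered by a disk, by supersampling.

    Pixels whose centers are further than radius + 1 from the disk center
    are exactly 0; interior pixels are exactly 1; only the rim band is
    supersampled, which keeps rendering fast at 512 x 512.
    """
    rows, cols = shape
    cy, cx = center_px
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    dist = np.hypot(yy - cy, xx - cx)
    frac = np.zeros(shape, dtype=np.float64)
    frac[dist <= radius_px - 0.75] = 1.0
    rim = (dist > radius_px - 0.75) & (dist < radius_px + 0.75)
    if supersample <= 1:
        frac[rim] = (dist[rim] <= radius_px).astype(np.float64)
        return frac
    ry, rx = np.nonzero(rim)
    s = supersample
    # subpixel sample offsets at cell centers of an s x s grid
    off = (np.arange(s) + 0.5) / s - 0.5
    oy, ox = np.meshgrid(off, off, indexing="ij")
    sy = ry[:, None] + oy.ravel()[None, :]
    sx = rx[:, None] + ox.ravel()[None, :]
    inside = np.hypot(sy - cy, sx - cx) <= radius_px
    frac[ry, rx] = inside.mean(axis=1)
    return frac


def render_phantom(
    spec: PhantomSpec,
    matrix_size: int = 512,
    spacing_mm: float = 0.9765,
    supersample: int = 4,
) -> CTImage:
    """Render a noise-free HU image of the phantom.

    The image is ``matrix_size`` square with the phantom centered at the
    physical center ``matrix_size / 2 * spacing``.  Pixels outside the
    body are air (-1000 HU); insert disks take their nominal HU with
    area-weighted anti-aliasing at disk rims so ROI means are unbiased
    and edges are usable for MTF estimation.
    """
    if matrix_size < 32:
        raise ParameterError("matrix_size must be >= 32")
    if spacing_mm <= 0:
        raise ParameterError("spacing must be > 0")
    center = (matrix_size / 2.0, matrix_size / 2.0)
    body_r_px = spec.body_diameter_mm / 2.0 / spacing_mm
    body = _disk_fraction((matrix_size, matrix_size), center, body_r_px, supersample)
    img = AIR_HU + body * (spec.body_hu - AIR_HU)
    if not spec.uniform_module:
        for ins in spec.inserts:
            cx_mm, cy_mm = ins.center_xy_mm
            c = (center[0] + cy_mm / spacing_mm, center[1] + cx_mm / spacing_mm)
            r_px = ins.diameter_mm / 2.0 / spacing_mm
            frac = _disk_fraction((matrix_size, matrix_size), c, r_px, supersample)
            img = img + frac * (ins.hu - spec.body_hu)
    return CTImage(img, (spacing_mm, spacing_mm))


# ---------------------------------------------------------------------------
# Dose-dependent noise
# ---------------------------------------------------------------------------

#: Projection-noise standard deviation (line-integral units) injected at the
#: reference tube current.  Chosen so the 200 mAs scan shows ~12 HU of noise
#: in a uniform ROI and the 24 mAs scan ~35 HU — a realistic clinical pair
#: that puts the low-dose CNR of a 120 HU soft-tissue insert near 2.
DEFAULT_NOISE_AMPLITUDE = 7.0


def _fbp_noise_field(
    shape: tuple[int, int],
    sigma_proj: float,
    rng: np.random.Generator,
    n_views: int = 180,
    filter_name: str = "hann",
) -> np.ndarray:
    """Reconstruction-correlated noise: FBP of a pure-noise sinogram.

    White Gaussian noise is placed on parallel-beam projections and
    reconstructed by filtered back-projection; the backprojection sum over
    views correlates neighbouring pixels and the apodized ramp filter
    band-limits the texture, reproducing the low-frequency-weighted noise
    of smooth-kernel CT reconstructions.
    """
    n = shape[0]
    theta = np.linspace(0.0, 180.0, n_views, endpoint=False)
    det = int(np.ceil(np.hypot(*shape)))
    sino = rng.normal(0.0, sigma_proj, size=(det, n_views))
    noise = iradon(
        sino,
        theta=theta,
        output_size=n,
        filter_name=filter_name,
        circle=False,
    )
    return np.asarray(noise, dtype=np.float64)


def _fast_noise_field(
    shape: tuple[int, int],
    sigma_hu: float,
    rng: np.random.Generator,
    correlation_px: float = 1.2,
) -> np.ndarray:
    """Stationary correlated Gaussian noise (speed fallback).

    White noise low-pass filtered by a radially decaying Gaussian kernel in
    frequency space, renormalized to the requested spatial sigma.
    """
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f2 = fy**2 + fx**2
    kernel = np.exp(-2.0 * (np.pi * correlation_px) ** 2 * f2)
    field = np.fft.ifft2(np.fft.fft2(white) * kernel).real
    field *= sigma_hu / field.std()
    return field


def simulate_dose(
    clean: CTImage,
    dose_mAs: float,
    reference_mAs: float = 200.0,
    seed: int = 0,
    noise_amplitude: float = DEFAULT_NOISE_AMPLITUDE,
    method: str = "fbp",
    n_views: int = 180,
) -> CTImage:
    """Degrade a clean image to the noise level of ``dose_mAs``.

    The injected noise field is linear in its amplitude, so the uniform-ROI
    noise standard deviation scales exactly as
    ``sqrt(reference_mAs / dose_mAs)`` relative to the level injected at the
    reference current.  Deterministic per seed; amplitude 0 returns the
    input bit-identically (the clean image is never passed through the
    projector).

    Parameters
    ----------
    method : {"fbp", "fast"}
        "fbp" reconstructs a noisy sinogram by filtered back-projection
        (correlated, band-limited texture); "fast" uses stationary
        Gaussian-correlated noise for quick tests.
    """
    if dose_mAs <= 0 or reference_mAs <= 0:
        raise ParameterError("dose_mAs and reference_mAs must be > 0")
    scale = math.sqrt(reference_mAs / dose_mAs)
    out = clean.copy()
    out.dose_mAs = dose_mAs
    out.seed = seed
    if noise_amplitude == 0:
        return out
    rng = np.random.default_rng(seed)
    if method == "fbp":
        field = _fbp_noise_field(
            clean.shape, noise_amplitude * scale, rng, n_views=n_views
        )
        # iradon output is in line-integral units per pixel; express in HU
        # relative to the pixel size so noise level is resolution-stable.
        field = field * (1000.0 / clean.spacing_mm[0]) * 0.1
    elif method == "fast":
        # 1.7 HU per unit amplitude matches the FBP route's noise level
        field = _fast_noise_field(clean.shape, noise_amplitude * scale * 1.7, rng)
    else:
        raise ParameterError(f"unknown noise method {method!r}")
    out.pixels = clean.pixels + field
    return out


def _jittered(spec: PhantomSpec, rng: np.random.Generator,
              pos_jitter_mm: float, hu_jitter_frac: float) -> PhantomSpec:
    """Randomly perturb insert positions and HUs (unpaired-domain variation)."""
    inserts = []
    for ins in spec.inserts:
        dx, dy = rng.uniform(-pos_jitter_mm, pos_jitter_mm, size=2)
        hu = ins.hu * (1.0 + rng.uniform(-hu_jitter_frac, hu_jitter_frac))
        inserts.append(
            replace(ins, hu=hu, center_xy_mm=(ins.center_xy_mm[0] + dx,
                                              ins.center_xy_mm[1] + dy))
        )
    return replace(spec, inserts=tuple(inserts))


def make_unpaired_dataset(
    spec: PhantomSpec,
    n_per_domain: int,
    low_mAs: float = 24.0,
    high_mAs: float = 200.0,
    seed: int = 0,
    matrix_size: int = 512,
    spacing_mm: float = 0.9765,
    pos_jitter_mm: float = 2.0,
    hu_jitter_frac: float = 0.03,
    noise_amplitude: float = DEFAULT_NOISE_AMPLITUDE,
    method: str = "fbp",
) -> tuple[list[CTImage], list[CTImage]]:
    """Generate unpaired low-dose (domain A) and normal-dose (domain B) corpora.

    Each image comes from an independently jittered phantom variant with its
    own noise seed; A and B use non-overlapping seed streams so the domains
    share no pixel-aligned pairs.
    """
    if n_per_domain < 1:
        raise ParameterError("n_per_domain must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_a, child_b = ss.spawn(2)
    domains: list[list[CTImage]] = []
    for child, dose in ((child_a, low_mAs), (child_b, high_mAs)):
        images = []
        for img_ss in child.spawn(n_per_domain):
            rng = np.random.default_rng(img_ss)
            var = (
                spec
                if pos_jitter_mm == 0 and hu_jitter_frac == 0
                else _jittered(spec, rng, pos_jitter_mm, hu_jitter_frac)
            )
            clean = render_phantom(var, matrix_size, spacing_mm)
            noise_seed = int(rng.integers(0, 2**31 - 1))
            images.append(
                simulate_dose(
                    clean,
                    dose,
                    reference_mAs=high_mAs,
                    seed=noise_seed,
                    noise_amplitude=noise_amplitude,
                    method=method,
                )
            )
        domains.append(images)
    return domains[0], domains[1]
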