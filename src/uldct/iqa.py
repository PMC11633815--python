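"""Objective CT image-quality metrics on sensitometry phantom images.

Implements the standard phantom metrics used to compare low-dose,
enhanced, and normal-dose scans:

* CNR  — contrast-to-noise ratio of a material insert against background,
  ``|mean_m - mean_b| / sqrt(sigma_m^2 + sigma_b^2)``;
* LCV  — low-contrast visibility from the LDPE and polystyrene inserts,
  ``2 |mean_LDPE - mean_PS| / (sigma_LDPE + sigma_PS)``;
* UI   — CT-number uniformity, ``|mean_periphery - mean_center| /
  (mean_center + 1000)`` in percent;
* NPS  — noise power spectrum: detrended-ROI periodogram scaled by
  ``x0*y0 / (Nx*Ny)``, averaged over ROIs, with a radial profile;
* MTF  — modulation transfer function by the circular-edge method on a
  high-contrast insert, reported as MTF50 and MTF10 crossing
  frequencies in cycles/mm;
* MAE / MSE — pixelwise agreement against a reference image.

All standard deviations are population sigmas (divide by n), consistently
across every metric.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from scipy.signal.windows import tukey

from .phantom import CTImage, ParameterError, PhantomSpec

INF_CNR = float("inf")


class ROIError(ValueError):
    """An ROI is out of bounds or a required structure was not found."""


@dataclass(frozen=True)
class ROI:
    """A circular region of interest in mm relative to the phantom center."""

    center_xy_mm: tuple[float, float]
    radius_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ParameterError("ROI radius must be > 0")


@dataclass(frozen=True)
class ROIStats:
    mean_hu: float
    sigma_hu: float
    n_pixels: int


def _disk_pixels(img: CTImage, roi: ROI) -> np.ndarray:
    """Values of pixels whose centers fall inside the ROI disk."""
    rows, cols = img.shape
    sy, sx = img.spacing_mm
    cy = rows / 2.0 + roi.center_xy_mm[1] / sy
    cx = cols / 2.0 + roi.center_xy_mm[0] / sx
    r_px = roi.radius_mm / sy
    if cy - r_px < 0 or cx - r_px < 0 or cy + r_px > rows or cx + r_px > cols:
        raise ROIError(f"ROI {roi.label!r} extends outside the image")
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    vals = img.pixels[mask]
    if vals.size == 0:
        raise ROIError(f"ROI {roi.label!r} covers no pixel centers")
    return vals


def roi_stats(img: CTImage, roi: ROI) -> ROIStats:
    """Mean and population sigma over a circular ROI."""
    vals = _disk_pixels(img, roi)
    return ROIStats(float(vals.mean()), float(vals.std()), int(vals.size))


def cnr(img: CTImage, roi_material: ROI, roi_background: ROI) -> float:
    """Contrast-to-noise ratio between a material ROI and background."""
    m = roi_stats(img, roi_material)
    b = roi_stats(img, roi_background)
    denom = math.sqrt(m.sigma_hu**2 + b.sigma_hu**2)
    numer = abs(m.mean_hu - b.mean_hu)
    if denom == 0.0:
        return 0.0 if numer == 0.0 else INF_CNR
    return numer / denom


def lcv(img: CTImage, roi_ldpe: ROI, roi_ps: ROI) -> float:
    """Low-contrast visibility from the LDPE and polystyrene inserts."""
    a = roi_stats(img, roi_ldpe)
    b = roi_stats(img, roi_ps)
    denom = a.sigma_hu + b.sigma_hu
    numer = 2.0 * abs(a.mean_hu - b.mean_hu)
    if denom == 0.0:
        return INF_CNR if numer > 0 else 0.0
    return numer / denom


def ui(
    img: CTImage, roi_center: ROI, rois_periphery: list[ROI]
) -> dict[str, float]:
    """CT-number uniformity index in percent.

    Returns the mean-periphery variant (peripheral ROI means averaged
    before differencing) and, with multiple peripheral ROIs, the
    maximum-deviation variant as well.
    """
    if not rois_periphery:
        raise ParameterError("at least one peripheral ROI is required")
    c = roi_stats(img, roi_center)
    if c.mean_hu == -1000.0:
        raise ParameterError("uniformity undefined for a center ROI at -1000 HU")
    periph = [roi_stats(img, r).mean_hu for r in rois_periphery]
    denom = c.mean_hu + 1000.0
    mean_dev = abs(float(np.mean(periph)) - c.mean_hu) / denom * 100.0
    max_dev = max(abs(p - c.mean_hu) for p in periph) / denom * 100.0
    return {"ui_percent": mean_dev, "ui_percent_max": max_dev}


# ---------------------------------------------------------------------------
# Noise power spectrum
# ---------------------------------------------------------------------------

@dataclass
class NPSResult:
    """2D noise power spectrum in HU^2 mm^2 with a radially binned profile."""

    nps2d: np.ndarray
    freq_x: np.ndarray  # cycles/mm, fftshifted
    freq_y: np.ndarray
    radial_freq: np.ndarray
    radial_power: np.ndarray
    pixel_mm: tuple[float, float]
    roi_shape: tuple[int, int]
    n_rois: int
    mean_roi_variance: float

    def total_power(self) -> float:
        """Integral of the 2D NPS over frequency (equals noise variance)."""
        du = 1.0 / (self.roi_shape[1] * self.pixel_mm[1])
        dv = 1.0 / (self.roi_shape[0] * self.pixel_mm[0])
        return float(self.nps2d.sum() * du * dv)

    def band_power(self, f_lo: float, f_hi: float) -> float:
        """Integrated 2D power over radial frequencies in [f_lo, f_hi)."""
        fy = self.freq_y[:, None]
        fx = self.freq_x[None, :]
        fr = np.hypot(fy, fx)
        sel = (fr >= f_lo) & (fr < f_hi)
        du = 1.0 / (self.roi_shape[1] * self.pixel_mm[1])
        dv = 1.0 / (self.roi_shape[0] * self.pixel_mm[0])
        return float(self.nps2d[sel].sum() * du * dv)


def _detrend_first_order(roi: np.ndarray) -> np.ndarray:
    """Subtract a least-squares 2D first-order polynomial (a + bx + cy)."""
    ny, nx = roi.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    a = np.column_stack([np.ones(roi.size), xx.ravel(), yy.ravel()])
    coef, *_ = np.linalg.lstsq(a, roi.ravel(), rcond=None)
    return roi - (a @ coef).reshape(roi.shape)


def nps(
    rois: list[np.ndarray],
    pixel_spacing_mm: tuple[float, float],
    n_radial_bins: int | None = None,
    min_rois: int = 4,
) -> NPSResult:
    """Noise power spectrum from square uniform-region ROIs.

    Each ROI is detrended by subtracting a fitted first-order 2D
    polynomial (removing DC and low-frequency shading), its periodogram
    ``|DFT|^2 * x0*y0/(Nx*Ny)`` computed, and the periodograms averaged.
    The radial profile is obtained by annular binning of the fftshifted
    2D spectrum.
    """
    if len(rois) < min_rois:
        raise ParameterError(f"need at least {min_rois} ROIs, got {len(rois)}")
    shape = rois[0].shape
    if any(r.shape != shape for r in rois):
        raise ParameterError("all NPS ROIs must share one shape")
    if n_radial_bins is None:
        n_radial_bins = max(4, min(shape) // 2)
    ny, nx = shape
    sy, sx = pixel_spacing_mm
    acc = np.zeros(shape, dtype=np.float64)
    var_acc = 0.0
    for roi in rois:
        d = _detrend_first_order(np.asarray(roi, dtype=np.float64))
        var_acc += d.var()
        acc += np.abs(np.fft.fft2(d)) ** 2
    nps2d = np.fft.fftshift(acc / len(rois) * (sx * sy) / (nx * ny))
    freq_x = np.fft.fftshift(np.fft.fftfreq(nx, d=sx))
    freq_y = np.fft.fftshift(np.fft.fftfreq(ny, d=sy))
    fr = np.hypot(freq_y[:, None], freq_x[None, :])
    f_max = min(0.5 / sx, 0.5 / sy)
    edges = np.linspace(0.0, f_max, n_radial_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    power = np.zeros(n_radial_bins)
    for k in range(n_radial_bins):
        sel = (fr >= edges[k]) & (fr < edges[k + 1])
        power[k] = nps2d[sel].mean() if sel.any() else 0.0
    return NPSResult(
        nps2d=nps2d,
        freq_x=freq_x,
        freq_y=freq_y,
        radial_freq=centers,
        radial_power=power,
        pixel_mm=(sy, sx),
        roi_shape=shape,
        n_rois=len(rois),
        mean_roi_variance=var_acc / len(rois),
    )


def extract_nps_rois(
    img: CTImage,
    roi_size: int = 16,
    grid: int = 4,
    margin_fraction: float = 0.9,
) -> list[np.ndarray]:
    """Tile a ``grid x grid`` array of square ROIs over the uniform body.

    The body is segmented (pixels above -500 HU) and ROIs are laid out
    inside its largest inscribed central square, shrunk by
    ``margin_fraction`` to avoid rim partial volume.  ROIs may overlap
    when the body is small relative to ``grid * roi_size``.
    """
    body = img.pixels > -500.0
    if not body.any():
        raise ParameterError("no body found for NPS ROI extraction")
    rows, cols = img.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    cy = yy[body].mean()
    cx = xx[body].mean()
    r_body = math.sqrt(body.sum() / math.pi)
    half = int(r_body / math.sqrt(2.0) * margin_fraction)
    span = 2 * half
    if span < roi_size:
        raise ParameterError(
            f"uniform region {span} px too small for {roi_size} px ROIs"
        )
    r0 = int(round(cy)) - half
    c0 = int(round(cx)) - half
    step = (span - roi_size) / max(grid - 1, 1)
    out = []
    for i in range(grid):
        for j in range(grid):
            rr = r0 + int(round(i * step))
            cc = c0 + int(round(j * step))
            out.append(img.pixels[rr : rr + roi_size, cc : cc + roi_size].copy())
    return out


# ---------------------------------------------------------------------------
# Modulation transfer function (circular-edge method)
# ---------------------------------------------------------------------------

@dataclass
class MTFCurve:
    """MTF vs spatial frequency, with the 50% and 10% crossing frequencies."""

    frequencies: np.ndarray  # cycles/mm
    mtf: np.ndarray
    mtf50: float
    mtf10: float


def _first_crossing(freq: np.ndarray, curve: np.ndarray, level: float) -> float:
    below = np.nonzero(curve < level)[0]
    if below.size == 0 or below[0] == 0:
        raise ROIError(f"MTF never crosses {level}")
    i = below[0]
    f0, f1 = freq[i - 1], freq[i]
    m0, m1 = curve[i - 1], curve[i]
    return float(f0 + (m0 - level) / (m0 - m1) * (f1 - f0))


def mtf(
    img: CTImage,
    insert_center_mm: tuple[float, float],
    insert_radius_mm: float,
    pixel_spacing_mm: float | None = None,
    band_mm: float = 4.0,
    oversample: int = 4,
    smooth_window: int = 5,
    min_contrast_hu: float = 20.0,
) -> MTFCurve:
    """MTF by the circular-edge (radial ESF) method.

    Pixels around the rim of a high-contrast cylindrical insert are binned
    by their distance to the fitted disk center into an oversampled edge
    spread function (bin width = spacing / oversample); the ESF is lightly
    smoothed (Savitzky-Golay, quadratic-preserving), differentiated to the
    line spread function, Hann-windowed, and Fourier-transformed.  The
    magnitude is normalized to 1 at zero frequency; MTF50 and MTF10 are
    the first downward crossings, linearly interpolated, in cycles/mm.
    """
    sp = pixel_spacing_mm if pixel_spacing_mm is not None else img.spacing_mm[0]
    rows, cols = img.shape
    cy0 = rows / 2.0 + insert_center_mm[1] / sp
    cx0 = cols / 2.0 + insert_center_mm[0] / sp
    r_px = insert_radius_mm / sp
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)

    # refine the disk center by intensity-weighted centroid in a local window
    win = (np.hypot(yy - cy0, xx - cx0) <= r_px + band_mm / sp)
    local = img.pixels[win]
    lo, hi = float(local.min()), float(local.max())
    if hi - lo < min_contrast_hu:
        raise ROIError("no detectable high-contrast edge at the stated insert")
    weights = np.abs(img.pixels - np.median(local)) * win
    if weights.sum() > 0:
        cy = float((yy * weights).sum() / weights.sum())
        cx = float((xx * weights).sum() / weights.sum())
    else:  # pragma: no cover - degenerate fallback
        cy, cx = cy0, cx0

    dist = np.hypot(yy - cy, xx - cx) * sp
    band = np.abs(dist - insert_radius_mm) <= band_mm
    r = dist[band] - insert_radius_mm
    v = img.pixels[band]

    bin_w = sp / oversample
    edges = np.arange(-band_mm, band_mm + bin_w, bin_w)
    idx = np.digitize(r, edges) - 1
    nbin = len(edges) - 1
    esf = np.full(nbin, np.nan)
    for k in range(nbin):
        sel = idx == k
        if sel.any():
            esf[k] = v[sel].mean()
    good = ~np.isnan(esf)
    centers = 0.5 * (edges[:-1] + edges[1:])
    esf = np.interp(centers, centers[good], esf[good])

    if smooth_window and smooth_window >= 5:
        esf = savgol_filter(esf, smooth_window, polyorder=2)
    # adjacent-bin first difference: the half-bin shift is pure phase and
    # the aperture droop sinc(f * bin_w) is negligible at these widths
    lsf = np.diff(esf) / bin_w
    # flat-top taper: unity over the central half, cosine tapered tails
    lsf = lsf * tukey(lsf.size, alpha=0.5)
    spec = np.abs(np.fft.rfft(lsf))
    if spec[0] == 0:
        raise ROIError("degenerate LSF: zero area")
    curve = spec / spec[0]
    freqs = np.fft.rfftfreq(lsf.size, d=bin_w)
    mtf50 = _first_crossing(freqs, curve, 0.5)
    mtf10 = _first_crossing(freqs, curve, 0.1)
    return MTFCurve(frequencies=freqs, mtf=curve, mtf50=mtf50, mtf10=mtf10)


# ---------------------------------------------------------------------------
# Pixelwise agreement
# ---------------------------------------------------------------------------

def _paired(p: CTImage | np.ndarray, o: CTImage | np.ndarray):
    a = p.pixels if isinstance(p, CTImage) else np.asarray(p, dtype=np.float64)
    b = o.pixels if isinstance(o, CTImage) else np.asarray(o, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch {a.shape} vs {b.shape}")
    return a, b


def mae(img_p, img_o) -> float:
    """Mean absolute HU error over all pixels."""
    a, b = _paired(img_p, img_o)
    return float(np.abs(a - b).mean())


def mse(img_p, img_o) -> float:
    """Mean squared HU error over all pixels."""
    a, b = _paired(img_p, img_o)
    return float(((a - b) ** 2).mean())


# ---------------------------------------------------------------------------
# Automatic ROI placement and the full report
# ---------------------------------------------------------------------------

def locate_catphan_rois(
    img: CTImage,
    spec: PhantomSpec,
    roi_shrink: float = 0.6,
    periphery_radius_mm: float = 35.0,
) -> dict[str, ROI]:
    """Place metric ROIs on a roughly centered phantom image.

    The body center is found as the centroid of pixels above -500 HU;
    insert ROIs are placed at their spec-relative offsets from that
    center with radius ``roi_shrink`` times the insert radius (margin
    against rim partial volume), a background ROI sits at the body
    center, and four peripheral uniformity ROIs at 12/3/6/9 o'clock on a
    ring inside the insert circle.
    """
    body = img.pixels > -500.0
    if not body.any():
        raise ROIError("no phantom body found (no pixels above -500 HU)")
    rows, cols = img.shape
    sy, sx = img.spacing_mm
    yy, xx = np.mgrid[0:rows, 0:cols]
    cy = float(yy[body].mean())
    cx = float(xx[body].mean())
    # centroid offset from the geometric image center, in mm
    off_x = (cx - cols / 2.0) * sx
    off_y = (cy - rows / 2.0) * sy

    rois: dict[str, ROI] = {}
    bg_r = min(8.0, spec.body_diameter_mm / 8.0)
    rois["background"] = ROI((off_x, off_y), bg_r, "background")
    for ins in spec.inserts:
        rois[ins.name] = ROI(
            (ins.center_xy_mm[0] + off_x, ins.center_xy_mm[1] + off_y),
            roi_shrink * ins.diameter_mm / 2.0,
            ins.name,
        )
    # peripheral uniformity ROIs must clear both the body rim and the
    # insert ring (relevant for scaled-down phantoms)
    p_roi_r = bg_r * 0.75
    pr = min(periphery_radius_mm, spec.body_diameter_mm / 2.0 - p_roi_r - 1.0)
    if spec.inserts and not spec.uniform_module:
        inner = min(
            math.hypot(*i.center_xy_mm) - i.diameter_mm / 2.0 for i in spec.inserts
        )
        pr = min(pr, inner - p_roi_r - 0.5)
    if pr <= p_roi_r:
        p_roi_r = max(1.0, pr * 0.5)
    for label, (ux, uy) in {
        "periphery_12": (0.0, -1.0),
        "periphery_3": (1.0, 0.0),
        "periphery_6": (0.0, 1.0),
        "periphery_9": (-1.0, 0.0),
    }.items():
        rois[label] = ROI((off_x + ux * pr, off_y + uy * pr), p_roi_r, label)
    return rois


@dataclass
class IQAReport:
    """All objective metrics for one labeled image."""

    label: str
    cnr_per_insert: dict[str, float] = field(default_factory=dict)
    lcv: float | None = None
    ui_percent: float | None = None
    ui_percent_max: float | None = None
    mtf50: float | None = None
    mtf10: float | None = None
    nps_total_power: float | None = None
    mae: float | None = None
    mse: float | None = None
    rois: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "lcv": self.lcv,
            "ui_percent": self.ui_percent,
            "ui_percent_max": self.ui_percent_max,
            "mtf50": self.mtf50,
            "mtf10": self.mtf10,
            "nps_total_power": self.nps_total_power,
            "mae": self.mae,
            "mse": self.mse,
        }
        for name, value in self.cnr_per_insert.items():
            d[f"cnr_{name}"] = value
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def evaluate(
    images: dict[str, CTImage],
    reference: CTImage | None,
    spec: PhantomSpec,
    uniform_images: dict[str, CTImage] | None = None,
    mtf_insert: str = "teflon",
    nps_roi_size: int = 16,
    nps_grid: int = 4,
) -> dict[str, IQAReport]:
    """Full objective report for each labeled image (e.g. LDCT/DLR/NDCT).

    CNR is computed per insert against the central background ROI, LCV
    from the LDPE and polystyrene inserts, UI from center vs peripheral
    ROIs, MTF from the high-contrast insert edge, MAE/MSE against the
    reference, and the NPS from a matching uniformity image when one is
    supplied under the same label.
    """
    reports: dict[str, IQAReport] = {}
    for label, img in images.items():
        rois = locate_catphan_rois(img, spec)
        rep = IQAReport(label=label)
        for name, roi in rois.items():
            s = roi_stats(img, roi)
            rep.rois[name] = (s.mean_hu, s.sigma_hu, s.n_pixels)
        for ins in spec.inserts:
            rep.cnr_per_insert[ins.name] = cnr(img, rois[ins.name], rois["background"])
        has = {i.name for i in spec.inserts}
        if {"ldpe", "polystyrene"} <= has:
            rep.lcv = lcv(img, rois["ldpe"], rois["polystyrene"])
        periph = [rois[k] for k in rois if k.startswith("periphery_")]
        u = ui(img, rois["background"], periph)
        rep.ui_percent = u["ui_percent"]
        rep.ui_percent_max = u["ui_percent_max"]
        if mtf_insert in has:
            ins = spec.insert(mtf_insert)
            try:
                curve = mtf(img, ins.center_xy_mm, ins.diameter_mm / 2.0)
                rep.mtf50, rep.mtf10 = curve.mtf50, curve.mtf10
            except ROIError:
                pass
        if reference is not None:
            rep.mae = mae(img, reference)
            rep.mse = mse(img, reference)
        if uniform_images and label in uniform_images:
            try:
                rois_u = extract_nps_rois(
                    uniform_images[label], roi_size=nps_roi_size, grid=nps_grid
                )
                rep.nps_total_power = nps(
                    rois_u, uniform_images[label].spacing_mm
                ).total_power()
            except ParameterError:
                pass
        reports[label] = rep
    return reports


def plot_nps(results: dict[str, NPSResult], path) -> None:
    """Radial NPS profiles for labeled images, written as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, res in results.items():
        ax.plot(res.radial_freq, res.radial_power, label=label)
    ax.set_xlabel("spatial frequency (cycles/mm)")
    ax.set_ylabel("NPS (HU$^2$ mm$^2$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mtf(curves: dict[str, MTFCurve], path) -> None:
    """MTF curves for labeled images, written as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.plot(curve.frequencies, curve.mtf, label=label)
    ax.axhline(0.5, ls=":", c="gray")
    ax.axhline(0.1, ls=":", c="gray")
    ax.set_xlabel("spatial frequency (cycles/mm)")
    ax.set_ylabel("MTF")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def reports_to_frame(reports: dict[str, IQAReport]):
    """Tabulate reports as a pandas DataFrame (one row per image)."""
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in reports.values()]).set_index("label")
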