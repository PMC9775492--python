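"""Colorimetric assay quantification and the synthetic micrograph renderer.

The enzymatic glucose assay develops a magenta product whose intensity
grows with glucose concentration.  Quantification follows the published
image-analysis recipe: binarize the brightfield micrograph to locate the
two chambers of an analysis unit, discard the sample chamber (the rounded
microvalve edges above it interfere), take the geometric centroid of the
reagent chamber, extract a 100 x 300 px region of interest (ROI) centred
on it, average each RGB channel over the ROI, convert the mean triple to
CMYK and read off the magenta channel.  Concentration comes either from
an ordinary least-squares calibration line (with a 3.3 sigma_blank/slope
limit of detection, the ICH convention) or from two-point referencing
against 0 mM and 8 mM solutions measured on the same device.

The synthetic renderer draws the two stacked rectangular 50 nL chambers
over a dark background, with the reagent chamber's magenta rising
linearly with concentration up to a saturation ceiling, plus Gaussian
pixel noise and an optional illumination gradient.  It exists so the
whole pipeline can be exercised, and its parameter-recovery checked,
without a microscope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops


class ImagingError(ValueError):
    """Pipeline failure: nothing detectable, degenerate input, bad shape."""


# ---------------------------------------------------------------------------
# Color conversion
# ---------------------------------------------------------------------------

def rgb_to_cmyk(r: float, g: float, b: float) -> "CMYKValue":
    """Standard RGB (0-255) to CMYK (0-1) conversion.

    k = 1 - max(r', g', b'); for pure black (k = 1) the chromatic
    channels are zero by convention; otherwise
    m = (1 - g' - k) / (1 - k) and analogously for c and y.
    """
    for name, v in (("r", r), ("g", g), ("b", b)):
        if not 0 <= v <= 255:
            raise ImagingError(f"{name}={v} outside [0, 255]")
    rp, gp, bp = r / 255.0, g / 255.0, b / 255.0
    k = 1.0 - max(rp, gp, bp)
    if k >= 1.0:
        return CMYKValue(0.0, 0.0, 0.0, 1.0)
    c = (1.0 - rp - k) / (1.0 - k)
    m = (1.0 - gp - k) / (1.0 - k)
    y = (1.0 - bp - k) / (1.0 - k)
    return CMYKValue(c, m, y, k)


class CMYKValue(NamedTuple):
    """Subtractive color coordinates, each in [0, 1]."""

    c: float
    m: float
    y: float
    k: float


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Detection:
    """A located chamber: 0-based half-open box, fractional centroid."""

    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    centroid: tuple[float, float]    # (row, col)
    area: int

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bbox
        cr, cc = self.centroid
        if not (r0 <= cr < r1 and c0 <= cc < c1):
            raise ImagingError("centroid outside bounding box")
        if self.area > (r1 - r0) * (c1 - c0):
            raise ImagingError("area exceeds bounding box")


@dataclass(frozen=True)
class ROISpec:
    """ROI extent: 100 px across the chamber, 300 px along it."""

    height_px: int = 100
    width_px: int = 300

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ImagingError("ROI dimensions must be > 0")


def _as_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ImagingError(f"expected HxWx3 RGB image, got {img.shape}")
    return img


def binarize(img: np.ndarray) -> np.ndarray:
    """Foreground mask via Otsu's threshold on the grayscale mean.

    Chambers image brighter than the chip background in brightfield, so
    foreground is the above-threshold side.
    """
    img = _as_rgb(img)
    gray = img.astype(np.float64).mean(axis=2)
    if np.ptp(gray) == 0:
        raise ImagingError("no threshold: image is constant")
    return gray > threshold_otsu(gray)


def detect_chambers(mask: np.ndarray, min_area: int = 1000
                    ) -> list[Detection]:
    """Connected components of the mask, top-to-bottom by centroid row."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ImagingError("empty mask")
    detections = []
    for region in regionprops(cc_label(mask)):
        if region.area < min_area:
            continue
        detections.append(Detection(bbox=tuple(int(v) for v in region.bbox),
                                    centroid=tuple(region.centroid),
                                    area=int(region.area)))
    if len(detections) < 2:
        raise ImagingError(
            f"chambers not found: {len(detections)} component(s) with area "
            f">= {min_area}")
    return sorted(detections, key=lambda d: d.centroid[0])


def select_reagent_chamber(detections: Sequence[Detection]) -> Detection:
    """The bottom-most chamber: the sample chamber (top, under the rounded
    microvalves) is discarded."""
    if len(detections) < 2:
        raise ImagingError("need at least 2 detections")
    return max(detections, key=lambda d: d.centroid[0])


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def extract_roi(img: np.ndarray, d: Detection,
                spec: ROISpec = ROISpec()) -> np.ndarray:
    """Exact spec-sized window centred on the detection centroid.

    The centroid is rounded half-away-from-zero; the chamber box must be
    at least as large as the ROI (clipping is never performed).
    """
    img = _as_rgb(img)
    r0, c0, r1, c1 = d.bbox
    if (r1 - r0) < spec.height_px or (c1 - c0) < spec.width_px:
        raise ImagingError(
            f"chamber {r1 - r0}x{c1 - c0} smaller than ROI "
            f"{spec.height_px}x{spec.width_px}")
    cr = _round_half_away(d.centroid[0])
    cc = _round_half_away(d.centroid[1])
    top = cr - spec.height_px // 2
    left = cc - spec.width_px // 2
    if top < 0 or left < 0 or (top + spec.height_px) > img.shape[0] \
            or (left + spec.width_px) > img.shape[1]:
        raise ImagingError("ROI extends beyond the image")
    return img[top:top + spec.height_px, left:left + spec.width_px]


def align_to_reference(img: np.ndarray, ref: np.ndarray,
                       min_area: int = 1000) -> np.ndarray:
    """Integer-pixel translation matching the reagent-chamber centroids.

    Translation only (no rotation or scale), mirroring alignment on the
    bottom chambers; exposed pixels are filled with the image's median
    (background) value per channel.
    """
    img = _as_rgb(img)
    ref = _as_rgb(ref)
    d_img = select_reagent_chamber(detect_chambers(binarize(img), min_area))
    d_ref = select_reagent_chamber(detect_chambers(binarize(ref), min_area))
    dr = _round_half_away(d_ref.centroid[0] - d_img.centroid[0])
    dc = _round_half_away(d_ref.centroid[1] - d_img.centroid[1])
    out = np.empty_like(img)
    fill = np.median(img.reshape(-1, 3), axis=0).astype(img.dtype)
    out[:] = fill
    h, w = img.shape[:2]
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def magenta_of_roi(roi: np.ndarray, per_pixel: bool = False) -> float:
    """Magenta of the ROI.

    Canonical order: average each channel over the ROI first, then
    convert the mean RGB triple to CMYK (the channel means are the
    measured quantities; conversion is applied to them).  With
    ``per_pixel=True`` the alternative order - convert every pixel, then
    average magenta - is computed instead; the two differ whenever the
    dominant channel varies across pixels.
    """
    roi = _as_rgb(roi)
    if roi.size == 0:
        raise ImagingError("empty ROI")
    if per_pixel:
        flat = roi.reshape(-1, 3).astype(np.float64)
        return float(np.mean([rgb_to_cmyk(*px).m for px in flat]))
    r, g, b = roi.astype(np.float64).reshape(-1, 3).mean(axis=0)
    return rgb_to_cmyk(r, g, b).m


# ---------------------------------------------------------------------------
# Calibration and concentration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line of magenta vs concentration with blank-based LOD."""

    slope: float          # magenta per mM
    intercept: float      # magenta at 0 mM
    residual_sd: float
    blank_sd: float
    lod: float            # mM
    n_points: int

    def concentration(self, magenta: float) -> float:
        return (magenta - self.intercept) / self.slope

    def to_dict(self) -> dict:
        return {"slope_per_mM": self.slope, "intercept": self.intercept,
                "residual_sd": self.residual_sd, "blank_sd": self.blank_sd,
                "lod_mM": self.lod, "n_points": self.n_points}


def fit_calibration(points: Sequence[tuple[float, float]],
                    blank_replicates: Sequence[float] | None = None,
                    blank_sd: float | None = None) -> CalibrationCurve:
    """Ordinary least squares magenta-vs-concentration line.

    LOD = 3.3 * sd(blank) / slope (ICH Q2 convention).  The blank
    standard deviation comes from ``blank_replicates`` (sample sd,
    ddof=1) or may be supplied directly.
    """
    concs = np.array([p[0] for p in points], dtype=float)
    mags = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(concs)) < 3:
        raise ImagingError("need >= 3 distinct concentrations")
    if blank_sd is None:
        if blank_replicates is None or len(blank_replicates) < 2:
            raise ImagingError("need >= 2 blank replicates (or blank_sd) "
                               "for the LOD")
        blank_sd = float(np.std(blank_replicates, ddof=1))
    slope, intercept = np.polyfit(concs, mags, 1)
    if slope <= 0:
        raise ImagingError("non-responsive assay: calibration slope <= 0")
    resid = mags - (slope * concs + intercept)
    dof = max(1, len(points) - 2)
    residual_sd = float(np.sqrt(np.sum(resid ** 2) / dof))
    lod = 3.3 * blank_sd / slope
    return CalibrationCurve(slope=float(slope), intercept=float(intercept),
                            residual_sd=residual_sd, blank_sd=blank_sd,
                            lod=float(lod), n_points=len(points))


class TwoPointResult(NamedTuple):
    concentration_mM: float
    extrapolated: bool


def two_point_concentration(m0: float, m8: float, ms: float,
                            high_mM: float = 8.0) -> TwoPointResult:
    """Linear interpolation between same-device 0 mM and 8 mM references.

    Values outside [0, 8] mM are returned as-is with the extrapolation
    flag set.
    """
    if m8 == m0:
        raise ImagingError("reference magentas are equal; cannot interpolate")
    conc = high_mM * (ms - m0) / (m8 - m0)
    return TwoPointResult(conc, bool(conc < 0 or conc > high_mM))


# ---------------------------------------------------------------------------
# Synthetic renderer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderParams:
    """Geometry, photometry and noise of the synthetic micrograph.

    Two stacked rectangular chambers (sample above, reagent below) on a
    dark background.  The reagent chamber's magenta is
    ``base_magenta + magenta_gain_per_mM * conc`` capped at
    ``saturation_ceiling``; with ``chamber_level`` L the chamber renders
    as R = B = L, G = L * (1 - magenta), which converts back through CMYK
    to exactly the set magenta.  Intensities are 8-bit by default;
    ``dtype='float64'`` keeps continuous values for strict linearity
    checks.
    """

    image_shape: tuple[int, int] = (480, 640)
    chamber_shape: tuple[int, int] = (160, 400)
    chamber_gap: int = 40
    chamber_level: float = 250.0
    sample_rgb: tuple[float, float, float] = (240.0, 240.0, 228.0)
    background_gray: float = 60.0
    base_magenta: float = 0.0
    magenta_gain_per_mM: float = 0.08
    saturation_ceiling: float = 0.95
    noise_sd: float = 2.0
    illumination_amplitude: float = 0.0
    seed: int = 0
    dtype: str = "uint8"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ImagingError("noise_sd must be >= 0")
        if self.magenta_gain_per_mM <= 0:
            raise ImagingError("magenta gain must be > 0")
        if self.dtype not in ("uint8", "float64"):
            raise ImagingError("dtype must be uint8 or float64")

    def chamber_boxes(self) -> tuple[tuple[int, int, int, int],
                                     tuple[tuple[int, int, int, int]]]:
        """(sample_box, reagent_box) as (r0, c0, r1, c1), stacked and
        horizontally centred."""
        h, w = self.image_shape
        ch, cw = self.chamber_shape
        c0 = (w - cw) // 2
        total = 2 * ch + self.chamber_gap
        r0 = (h - total) // 2
        sample = (r0, c0, r0 + ch, c0 + cw)
        reagent = (r0 + ch + self.chamber_gap, c0,
                   r0 + 2 * ch + self.chamber_gap, c0 + cw)
        return sample, reagent


def render_assay_image(conc: float, params: RenderParams = RenderParams(),
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw one analysis-unit micrograph at the given concentration."""
    if conc < 0:
        raise ImagingError("concentration must be >= 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    img = np.full((h, w, 3), params.background_gray, dtype=np.float64)
    sbox, rbox = params.chamber_boxes()
    r0, c0, r1, c1 = sbox
    img[r0:r1, c0:c1] = params.sample_rgb
    m = min(params.saturation_ceiling,
            params.base_magenta + params.magenta_gain_per_mM * conc)
    level = params.chamber_level
    r0, c0, r1, c1 = rbox
    img[r0:r1, c0:c1] = (level, level * (1.0 - m), level)
    if params.illumination_amplitude:
        ramp = (np.linspace(-1.0, 1.0, w) * params.illumination_amplitude)
        img += ramp[None, :, None]
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    if params.dtype == "uint8":
        return np.round(img).astype(np.uint8)
    return img


# ---------------------------------------------------------------------------
# End-to-end analysis
# ---------------------------------------------------------------------------

def quantify_image(img: np.ndarray, roi_spec: ROISpec = ROISpec(),
                   min_area: int = 1000,
                   ref: np.ndarray | None = None) -> dict:
    """Full single-image pipeline: (align,) binarize, detect, select the
    reagent chamber, extract the ROI, average channels, convert.

    Returns the per-channel ROI means, the magenta value and the
    detection geometry.
    """
    if ref is not None:
        img = align_to_reference(img, ref, min_area)
    mask = binarize(img)
    detections = detect_chambers(mask, min_area)
    reagent = select_reagent_chamber(detections)
    roi = extract_roi(img, reagent, roi_spec)
    means = roi.astype(np.float64).reshape(-1, 3).mean(axis=0)
    return {
        "R_mean": float(means[0]),
        "G_mean": float(means[1]),
        "B_mean": float(means[2]),
        "magenta": magenta_of_roi(roi),
        "detection": reagent,
        "n_detections": len(detections),
    }


def analyze_run(sample_images: Sequence[np.ndarray],
                cal0_images: Sequence[np.ndarray],
                cal8_images: Sequence[np.ndarray],
                roi_spec: ROISpec = ROISpec(),
                min_area: int = 1000) -> tuple[pd.DataFrame, dict]:
    """Quantify a two-point-calibrated run.

    Each image is processed independently; per-image failures become
    error rows and the run only fails if an entire reference group fails.
    Returns the per-image table and a summary with group means +- sd and
    the pooled two-point concentration estimate.
    """
    if not (len(sample_images) and len(cal0_images) and len(cal8_images)):
        raise ImagingError("need at least one image per group")
    rows = []
    magentas: dict[str, list[float]] = {"cal0": [], "cal8": [], "sample": []}
    groups = [("cal0", cal0_images), ("cal8", cal8_images),
              ("sample", sample_images)]
    for group, images in groups:
        for i, img in enumerate(images):
            try:
                q = quantify_image(img, roi_spec, min_area)
                rows.append({"group": group, "index": i,
                             "R_mean": q["R_mean"], "G_mean": q["G_mean"],
                             "B_mean": q["B_mean"], "magenta": q["magenta"],
                             "error": ""})
                magentas[group].append(q["magenta"])
            except ImagingError as exc:
                rows.append({"group": group, "index": i,
                             "R_mean": np.nan, "G_mean": np.nan,
                             "B_mean": np.nan, "magenta": np.nan,
                             "error": str(exc)})
    for group in ("cal0", "cal8"):
        if not magentas[group]:
            raise ImagingError(f"all {group} reference images failed")
    m0 = float(np.mean(magentas["cal0"]))
    m8 = float(np.mean(magentas["cal8"]))
    concs = []
    for i, row in enumerate(rows):
        if row["group"] == "sample" and not row["error"]:
            res = two_point_concentration(m0, m8, row["magenta"])
            row["concentration_mM"] = res.concentration_mM
            row["extrapolated"] = res.extrapolated
            concs.append(res.concentration_mM)
        else:
            row["concentration_mM"] = np.nan
            row["extrapolated"] = False
    frame = pd.DataFrame(rows)
    summary = {
        "m0_mean": m0,
        "m0_sd": float(np.std(magentas["cal0"], ddof=1))
                 if len(magentas["cal0"]) > 1 else 0.0,
        "m8_mean": m8,
        "m8_sd": float(np.std(magentas["cal8"], ddof=1))
                 if len(magentas["cal8"]) > 1 else 0.0,
        "concentration_mM": float(np.mean(concs)) if concs else np.nan,
        "concentration_sd": float(np.std(concs, ddof=1))
                            if len(concs) > 1 else 0.0,
        "n_samples": len(concs),
    }
    return frame, summary


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF micrograph as 8-bit RGB.

    16-bit inputs are linearly rescaled to 8 bits (a warning is attached
    via the logging module); grayscale images are rejected.
    """
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise ImagingError(f"{path}: expected an RGB image, got {img.shape}")
    if img.dtype == np.uint16:
        import logging
        logging.getLogger(__name__).warning(
            "%s: 16-bit input rescaled to 8-bit", path)
        img = (img.astype(np.float64) / 257.0).round().astype(np.uint8)
    return np.asarray(img, dtype=np.uint8)


def write_image(path, img: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))
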