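"""Capillary quantification chain for disc-centered en face angiograms.

The chain mirrors the classical ImageJ-style workflow for peri-papillary
capillary measurement:

1. two-scale Hessian ridge filtering — sigma = 3 px highlights
   capillaries, sigma = 15 px highlights the wide radial vessels;
2. Otsu auto-thresholding of the 8-bit-rescaled filter response;
3. large-vessel mask cleanup by a median "remove outliers" step
   (radius 15 px) and subtraction of the large vessels from the initial
   binarized image, leaving the capillary mask;
4. topology-preserving skeletonization to one-pixel centerlines;
5. vessel length density (VLD, mm^-1) — skeleton centerline length per
   unit area — on the four quadrants (superior / nasal / inferior /
   temporal) of the annulus between the 1.5 and 2.25 mm circles centered
   on the disc, or on the whole ring between the 1 and 3 mm circles
   centered on the image in repeatability mode.

The vesselness functional is scale-normalized tubeness: with lambda_2 the
more-negative eigenvalue of the Gaussian-scale Hessian, the response is
sigma^2 * max(-lambda_2, 0), which is non-negative and large on bright
curvilinear structures of width ~2 sigma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import rank
from skimage.morphology import disk as disk_footprint
from skimage.morphology import skeletonize as _sk_skeletonize

from .image_io import CANONICAL_SCALE, AngiogramImage
from .reference import AL_GROUP_CUTOFF_MM

logger = logging.getLogger(__name__)

SQRT2 = float(np.sqrt(2.0))


# ---------------------------------------------------------------------------
# filtering and binarization


def hessian_vesselness(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalized bright-ridge strength at Gaussian scale ``sigma_px``.

    Returns sigma^2 * max(-lambda_2, 0) with lambda_2 the smaller Hessian
    eigenvalue; zero on constant images and on dark ridges.
    """
    if not sigma_px > 0:
        raise ValueError("sigma_px must be positive")
    img = np.asarray(image, dtype=float)
    H = hessian_matrix(
        img, sigma=sigma_px, order="rc", mode="reflect", use_gaussian_derivatives=True
    )
    eigs = hessian_matrix_eigvals(H)  # sorted descending along axis 0
    return sigma_px**2 * np.maximum(-eigs[-1], 0.0)


def rescale_to_uint8(image: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Min-max rescale over valid pixels to the 0-255 integer range."""
    img = np.asarray(image, dtype=float)
    sel = img if valid is None else img[valid]
    lo, hi = float(sel.min()), float(sel.max())
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    out = np.round((img - lo) / (hi - lo) * 255.0)
    return np.clip(out, 0, 255).astype(np.uint8)


def otsu_threshold(
    image: np.ndarray, valid: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Otsu threshold over the 256-bin histogram of an 8-bit image.

    Scans all 256 candidate thresholds t, maximizing the between-class
    variance of {values <= t} vs {values > t}; when the maximum is a
    plateau (e.g. a two-valued image) the threshold is the plateau
    midpoint.  Returns ``(threshold, mask)`` with mask = pixels strictly
    above the threshold, restricted to valid pixels.  A constant image
    yields an empty mask with a logged warning.
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("otsu_threshold expects a uint8 image (use rescale_to_uint8)")
    validm = np.ones(img.shape, dtype=bool) if valid is None else np.asarray(valid, bool)
    values = img[validm]
    if values.size == 0:
        raise ValueError("no valid pixels")
    counts = np.bincount(values, minlength=256).astype(float)
    total = counts.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(counts)
    sum0 = np.cumsum(counts * levels)
    mu_total = sum0[-1] / total
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = sum0 / w0
        mu1 = (sum0[-1] - sum0) / (total - w0)
        between = w0 * (total - w0) * (mu0 - mu1) ** 2
    between = np.nan_to_num(between[:-1], nan=-1.0)  # t = 255 puts all in one class
    best = between.max()
    if best <= 0:
        t = float(values.min())
        logger.warning("degenerate histogram (constant image): empty foreground at t=%g", t)
        return t, np.zeros(img.shape, dtype=bool)
    plateau = np.flatnonzero(np.isclose(between, best, rtol=1e-12, atol=0.0))
    t = float((plateau.min() + plateau.max()) / 2.0)
    mask = (img > t) & validm
    return t, mask


def remove_outliers(
    image: np.ndarray, radius_px: int = 15, deviation_threshold: float = 50.0
) -> np.ndarray:
    """Replace bright outliers by the local median (disc neighborhood).

    A pixel whose value exceeds the median of its disc-shaped
    ``radius_px`` neighborhood by more than ``deviation_threshold`` is
    replaced by that median; all other pixels are unchanged.  The default
    threshold of 50 applies to 0-255-scaled images.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    img = np.asarray(image)
    footprint = disk_footprint(radius_px)
    if img.dtype == np.uint8:
        med = rank.median(img, footprint=footprint)
    else:
        med = ndimage.median_filter(img, footprint=footprint)
    out = img.copy()
    bright = img.astype(float) - med.astype(float) > deviation_threshold
    out[bright] = med[bright]
    return out


# ---------------------------------------------------------------------------
# masks and skeleton


@dataclass
class PipelineParams:
    """Tunables of the quantification chain (pixel units on the 1024 frame)."""

    sigma_capillary_px: float = 3.0
    sigma_large_px: float = 15.0
    outlier_radius_px: int = 15
    outlier_threshold: float = 50.0


def extract_large_vessel_mask(
    image: np.ndarray,
    valid: np.ndarray | None = None,
    params: PipelineParams | None = None,
) -> np.ndarray:
    """Wide-vessel mask: sigma=15 tubeness -> Otsu -> remove outliers -> rebinarize."""
    p = params or PipelineParams()
    resp = hessian_vesselness(image, p.sigma_large_px)
    resp8 = rescale_to_uint8(resp, valid)
    t, mask = otsu_threshold(resp8, valid)
    cleaned = remove_outliers(
        (mask * np.uint8(255)), p.outlier_radius_px, p.outlier_threshold
    )
    out = cleaned > 0
    logger.debug("large-vessel mask: otsu=%g, %d px", t, int(out.sum()))
    return out


def extract_capillary_mask(
    image: np.ndarray,
    valid: np.ndarray | None = None,
    params: PipelineParams | None = None,
) -> np.ndarray:
    """Capillary mask: (sigma=3 tubeness -> Otsu) minus the large-vessel mask."""
    p = params or PipelineParams()
    resp = hessian_vesselness(image, p.sigma_capillary_px)
    resp8 = rescale_to_uint8(resp, valid)
    _, initial = otsu_threshold(resp8, valid)
    large = extract_large_vessel_mask(image, valid, p)
    return initial & ~large


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to one-pixel-wide centerlines."""
    return _sk_skeletonize(np.asarray(mask, dtype=bool))


# ---------------------------------------------------------------------------
# ROI geometry


@dataclass
class RingQuadrantROI:
    """Annulus ROI masks, either four quadrants or a single whole ring.

    Quadrants are split by the 45-degree diagonals through the center into
    half-open angular sectors, so they are pairwise disjoint and union to
    the annulus exactly.  For OD the image-right sector is nasal and
    image-left temporal (mirrored for OS).
    """

    center_px: tuple[float, float]
    inner_radius_px: float
    outer_radius_px: float
    masks: dict[str, np.ndarray]
    laterality: str | None
    coverage_fraction: float

    def annulus_mask(self) -> np.ndarray:
        out = np.zeros(next(iter(self.masks.values())).shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out


QUADRANT_MODE = "quadrant_1.5_2.25"
RING_MODE = "whole_1_3"


def build_ring_roi(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    scale: float = CANONICAL_SCALE,
    mode: str = QUADRANT_MODE,
    laterality: str | None = None,
) -> RingQuadrantROI:
    """Ring / ring-quadrant ROI masks at pixel resolution.

    ``mode='quadrant_1.5_2.25'``: annulus between the 1.5 and 2.25 mm
    diameter circles about ``center_px`` (the disc center), split into the
    four quadrant locations; requires ``laterality``.  ``mode='whole_1_3'``:
    single annulus between the 1 and 3 mm circles (repeatability ring).
    ``coverage_fraction`` reports the in-image fraction of the ideal
    annulus area.
    """
    if mode == QUADRANT_MODE:
        d_in, d_out = 1.5, 2.25
        if laterality not in ("OD", "OS"):
            raise ValueError("quadrant mode requires laterality 'OD' or 'OS'")
    elif mode == RING_MODE:
        d_in, d_out = 1.0, 3.0
    else:
        raise ValueError(f"unknown ROI mode {mode!r}")
    r_in = d_in / 2 / scale
    r_out = d_out / 2 / scale
    h, w = shape
    cx, cy = center_px
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    r = np.hypot(dx, dy)
    annulus = (r >= r_in) & (r < r_out)
    coverage = float(annulus.sum()) / (np.pi * (r_out**2 - r_in**2))
    if mode == RING_MODE:
        return RingQuadrantROI(
            center_px=center_px,
            inner_radius_px=r_in,
            outer_radius_px=r_out,
            masks={"whole_ring": annulus},
            laterality=laterality,
            coverage_fraction=coverage,
        )
    # clock angle from 'up', clockwise, in [0, 360); sectors half-open
    theta = np.degrees(np.arctan2(dx, -dy))
    phi = np.mod(theta + 45.0, 360.0)
    sectors = {
        "superior": annulus & (phi >= 0) & (phi < 90),
        "right": annulus & (phi >= 90) & (phi < 180),
        "inferior": annulus & (phi >= 180) & (phi < 270),
        "left": annulus & (phi >= 270),
    }
    nasal, temporal = ("right", "left") if laterality == "OD" else ("left", "right")
    masks = {
        "superior": sectors["superior"],
        "nasal": sectors[nasal],
        "inferior": sectors["inferior"],
        "temporal": sectors[temporal],
    }
    return RingQuadrantROI(
        center_px=center_px,
        inner_radius_px=r_in,
        outer_radius_px=r_out,
        masks=masks,
        laterality=laterality,
        coverage_fraction=coverage,
    )


# ---------------------------------------------------------------------------
# skeleton length and VLD


def skeleton_link_counts(
    skeleton: np.ndarray, region: np.ndarray | None = None
) -> tuple[int, int, int]:
    """Per-pixel link tallies of skeleton pixels inside ``region``.

    Returns (axial_links, diagonal_links, isolated_pixels), where each
    skeleton pixel contributes the number of its 8-neighbors that are also
    skeleton pixels (anywhere in the image, so tallies are exactly additive
    over a partition of the region).
    """
    sk = np.asarray(skeleton, dtype=bool)
    pad = np.pad(sk, 1)
    ax = (
        pad[:-2, 1:-1].astype(np.int32)
        + pad[2:, 1:-1]
        + pad[1:-1, :-2]
        + pad[1:-1, 2:]
    )
    di = (
        pad[:-2, :-2].astype(np.int32)
        + pad[:-2, 2:]
        + pad[2:, :-2]
        + pad[2:, 2:]
    )
    sel = sk if region is None else sk & np.asarray(region, dtype=bool)
    isolated = int((sel & (ax + di == 0)).sum())
    return int(ax[sel].sum()), int(di[sel].sum()), isolated


def skeleton_length_px(skeleton: np.ndarray, region: np.ndarray | None = None) -> float:
    """Centerline length in pixel units by half-link accounting.

    Each inter-pixel link (axial = 1 px, diagonal = sqrt(2) px) is shared
    half-and-half by its two endpoint pixels; an isolated skeleton pixel
    counts 1 px.  Summing the per-pixel contributions over disjoint regions
    reproduces the whole-skeleton length exactly.
    """
    a, d, iso = skeleton_link_counts(skeleton, region)
    return iso + 0.5 * (a + SQRT2 * d)


def compute_vld(
    skeleton: np.ndarray, roi: np.ndarray, scale: float = CANONICAL_SCALE
) -> float:
    """Vessel length density (mm^-1): skeleton length in ROI / ROI area."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != np.asarray(skeleton).shape:
        raise ValueError("skeleton and ROI shapes differ")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI has zero area")
    length_mm = skeleton_length_px(skeleton, roi) * scale
    area_mm2 = n_roi * scale**2
    return length_mm / area_mm2


# ---------------------------------------------------------------------------
# end-to-end quantification


@dataclass
class Measurement:
    """One VLD value keyed by eye, device, location and scan."""

    eye_id: str
    device: str
    location: str
    scan_index: int
    vld: float
    al_mm: float | None = None
    coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.vld < 0:
            raise ValueError("vld must be non-negative")

    @property
    def al_group(self) -> int | None:
        if self.al_mm is None:
            return None
        return 2 if self.al_mm >= AL_GROUP_CUTOFF_MM else 1


def quantify_eye(
    image: AngiogramImage,
    disc_center: tuple[float, float] | None = None,
    mode: str = QUADRANT_MODE,
    params: PipelineParams | None = None,
    eye_id: str = "eye",
    scan_index: int = 1,
    al_mm: float | None = None,
) -> list[Measurement]:
    """Run the full chain on one screened canonical image.

    Returns four quadrant measurements (quadrant mode, annulus centered on
    the disc) or one whole-ring measurement (repeatability mode, annulus
    centered on the image).  Deterministic; per-stage summaries are logged.
    """
    px = image.as_float()
    valid = image.valid_mask()
    cap = extract_capillary_mask(px, valid, params)
    skel = skeletonize(cap)
    logger.info(
        "quantify_eye[%s/%s]: capillary px=%d skeleton px=%d",
        eye_id,
        image.device,
        int(cap.sum()),
        int(skel.sum()),
    )
    if mode == QUADRANT_MODE:
        center = disc_center or image.disc_center
        if center is None:
            raise ValueError("quadrant mode needs a disc center")
        laterality = image.laterality
    else:
        h, w = px.shape
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
        laterality = image.laterality
    roi = build_ring_roi(px.shape, center, image.scale, mode, laterality)
    out = []
    for loc, mask in roi.masks.items():
        m = mask & valid
        vld = compute_vld(skel, m, image.scale)
        cov = roi.coverage_fraction * (m.sum() / max(int(mask.sum()), 1))
        out.append(
            Measurement(
                eye_id=eye_id,
                device=image.device or "unknown",
                location=loc,
                scan_index=scan_index,
                vld=vld,
                al_mm=al_mm,
                coverage_fraction=float(cov),
            )
        )
    return out


def measurements_to_frame(measurements: list[Measurement]) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for m in measurements:
        rows.append(
            {
                "eye_id": m.eye_id,
                "device": m.device,
                "location": m.location,
                "scan": m.scan_index,
                "vld": m.vld,
                "al_mm": m.al_mm,
                "al_group": m.al_group,
                "coverage_fraction": m.coverage_fraction,
            }
        )
    return pd.DataFrame(rows)
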