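"""Angiogram image containers, file IO, canonicalization and registration.

An en face angiogram is a square grayscale grid with isotropic physical
scale (mm per pixel) and acquisition metadata (device, laterality,
signal strength, disc center).  Images from different instruments are
brought to a canonical frame (1024 x 1024 pixels over 3 x 3 mm),
registered to one another from >= 4 manually matched landmark pairs
with a least-squares planar transform, and rescaled multiplicatively to
a common mean intensity before quantification.

Coordinate convention: pixel centers at integer coordinates, origin at
the top-left pixel center, x rightward (columns), y downward (rows),
0-based.  Landmarks and disc centers are (x, y) pixel pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage import transform as sktransform

CANONICAL_SIZE = 1024
CANONICAL_FIELD_MM = 3.0
CANONICAL_SCALE = CANONICAL_FIELD_MM / CANONICAL_SIZE  # mm per pixel

_SIDECAR_FIELDS = ("scale_mm_per_px", "laterality", "device", "signal_strength", "disc_center_px")


@dataclass
class AngiogramImage:
    """2-D grayscale angiogram with physical scale and acquisition metadata.

    ``pixels`` may be unsigned integer (as stored on disk) or float; use
    :meth:`as_float` for processing on a common [0, 1] scale.  ``valid``
    marks pixels that carry signal (False outside the warped field after
    registration); ROI statistics use valid pixels only.
    """

    pixels: np.ndarray
    scale: float
    laterality: str | None = None
    device: str | None = None
    signal_strength: float | None = None
    disc_center: tuple[float, float] | None = None  # (x, y) px
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("angiogram must be a single-channel 2-D grid")
        if not self.scale > 0:
            raise ValueError("scale (mm per pixel) must be positive")
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.all(
            np.isfinite(self.pixels)
        ):
            raise ValueError("pixel intensities must be finite")
        if self.laterality is not None and self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.pixels.shape:
                raise ValueError("validity mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def field_size_mm(self) -> tuple[float, float]:
        return (self.pixels.shape[0] * self.scale, self.pixels.shape[1] * self.scale)

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.valid

    def as_float(self) -> np.ndarray:
        """Intensities as float64 in [0, 1] (integer dtypes divided by their max)."""
        px = self.pixels
        if np.issubdtype(px.dtype, np.integer):
            return px.astype(np.float64) / np.iinfo(px.dtype).max
        return px.astype(np.float64)

    def is_canonical(self) -> bool:
        return self.pixels.shape == (CANONICAL_SIZE, CANONICAL_SIZE) and np.isclose(
            self.scale, CANONICAL_SCALE, rtol=1e-9
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_angiogram(image: AngiogramImage, path: str | Path) -> tuple[Path, Path]:
    """Write image pixels (TIFF or PNG by extension) plus a JSON metadata sidecar.

    Returns the (image, sidecar) paths.  Pixel values are written with
    their in-memory dtype; float images are stored as 16-bit by scaling
    [0, 1] to [0, 65535], so prefer integer grids for lossless round trips.
    """
    path = Path(path)
    px = image.pixels
    if np.issubdtype(px.dtype, np.floating):
        px = np.round(np.clip(px, 0.0, 1.0) * 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, px)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, px)
    else:
        raise ValueError(f"unsupported image format: {path.suffix!r} (use TIFF or PNG)")
    meta = {
        "scale_mm_per_px": image.scale,
        "laterality": image.laterality,
        "device": image.device,
        "signal_strength": image.signal_strength,
        "disc_center_px": list(image.disc_center) if image.disc_center else None,
    }
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=1))
    return path, sidecar


def read_angiogram(path: str | Path, sidecar: str | Path | None = None) -> AngiogramImage:
    """Read a TIFF/PNG angiogram and its JSON sidecar.

    The sidecar must supply ``scale_mm_per_px``; color input is rejected.
    """
    path = Path(path)
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"metadata sidecar not found for {path.name}: expected {sidecar.name} "
            "supplying 'scale_mm_per_px'"
        )
    meta = json.loads(sidecar.read_text())
    if meta.get("scale_mm_per_px") is None:
        raise ValueError(f"sidecar {sidecar.name} is missing required field 'scale_mm_per_px'")
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim != 2:
        raise ValueError(f"{path.name} is not single-channel grayscale (shape {px.shape})")
    dc = meta.get("disc_center_px")
    return AngiogramImage(
        pixels=px,
        scale=float(meta["scale_mm_per_px"]),
        laterality=meta.get("laterality"),
        device=meta.get("device"),
        signal_strength=meta.get("signal_strength"),
        disc_center=tuple(dc) if dc else None,
    )


def resample_to_canonical(
    image: AngiogramImage, allow_field_mismatch: bool = False
) -> AngiogramImage:
    """Resample to the canonical 1024 x 1024 frame over 3 x 3 mm.

    Bilinear interpolation (anti-aliased when downsampling); returns the
    input object unchanged if it is already canonical.  The physical field
    must be 3 x 3 mm (0.5% tolerance) unless ``allow_field_mismatch``.
    """
    if image.is_canonical():
        return image
    h_mm, w_mm = image.field_size_mm
    if not allow_field_mismatch:
        for dim in (h_mm, w_mm):
            if abs(dim - CANONICAL_FIELD_MM) > 0.005 * CANONICAL_FIELD_MM:
                raise ValueError(
                    f"field size {h_mm:.3f} x {w_mm:.3f} mm is not the canonical "
                    f"{CANONICAL_FIELD_MM} x {CANONICAL_FIELD_MM} mm field"
                )
    factor = CANONICAL_SIZE / image.pixels.shape[0]
    px = sktransform.resize(
        image.as_float(),
        (CANONICAL_SIZE, CANONICAL_SIZE),
        order=1,
        anti_aliasing=factor < 1,
        preserve_range=True,
    )
    valid = None
    if image.valid is not None:
        valid = (
            sktransform.resize(
                image.valid.astype(float), (CANONICAL_SIZE, CANONICAL_SIZE), order=0
            )
            > 0.5
        )
    dc = None
    if image.disc_center is not None:
        fx = CANONICAL_SIZE / image.pixels.shape[1]
        fy = CANONICAL_SIZE / image.pixels.shape[0]
        dc = (image.disc_center[0] * fx, image.disc_center[1] * fy)
    return replace(
        image, pixels=px, scale=CANONICAL_SCALE, disc_center=dc, valid=valid
    )


@dataclass
class PlanarTransform:
    """Invertible planar map (similarity or affine) acting on (x, y) pixel coords."""

    kind: str
    matrix: np.ndarray  # 3x3 homogeneous
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.kind not in ("similarity", "affine"):
            raise ValueError("kind must be 'similarity' or 'affine'")
        if self.matrix.shape != (3, 3) or abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix must be an invertible 3x3 matrix")

    def _sk(self) -> sktransform.ProjectiveTransform:
        if self.kind == "similarity":
            return sktransform.SimilarityTransform(matrix=self.matrix)
        return sktransform.AffineTransform(matrix=self.matrix)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) source (x, y) points to destination coordinates."""
        return self._sk()(np.atleast_2d(np.asarray(points, dtype=float)))

    def inverse(self) -> "PlanarTransform":
        return PlanarTransform(self.kind, np.linalg.inv(self.matrix))


def estimate_transform(
    src: Sequence[Sequence[float]],
    dst: Sequence[Sequence[float]],
    kind: str = "similarity",
) -> PlanarTransform:
    """Least-squares planar transform from >= 4 landmark correspondences.

    ``src``/``dst`` are matched (x, y) pixel pairs in corresponding order.
    Four pairs are required (mirroring manual four-feature matching) even
    though a similarity is determined by two; degenerate configurations
    (duplicate or, for affine, collinear points) are rejected.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matched (N, 2) landmark arrays")
    if src.shape[0] < 4:
        raise ValueError(f"at least 4 landmark pairs are required, got {src.shape[0]}")
    if len(np.unique(src, axis=0)) != len(src):
        raise ValueError("duplicate source landmarks")
    if kind == "affine":
        # collinear sources leave the affine fit underdetermined
        sv = np.linalg.svd(src - src.mean(axis=0), compute_uv=False)
        if sv[1] < 1e-9 * max(sv[0], 1.0):
            raise ValueError("degenerate landmark configuration (collinear source points)")
    tform = sktransform.estimate_transform(kind, src, dst)
    params = np.asarray(tform.params)
    if not np.all(np.isfinite(params)) or abs(np.linalg.det(params)) < 1e-12:
        raise ValueError("degenerate landmark configuration (collinear or coincident points)")
    residual = float(np.sqrt(np.mean(np.sum((tform(src) - dst) ** 2, axis=1))))
    return PlanarTransform(kind=kind, matrix=params, residual_rms=residual)


def apply_transform(image: AngiogramImage, t: PlanarTransform) -> AngiogramImage:
    """Warp an image forward through ``t`` (bilinear; masks nearest-neighbor).

    Output pixels that map outside the source field are marked invalid and
    excluded from downstream ROI statistics.
    """
    px = image.as_float()
    inv = t.inverse()._sk()
    warped = sktransform.warp(px, inverse_map=inv, order=1, cval=0.0, preserve_range=True)
    src_valid = image.valid_mask().astype(float)
    valid = sktransform.warp(src_valid, inverse_map=inv, order=0, cval=0.0) > 0.5
    dc = None
    if image.disc_center is not None:
        dc = tuple(t(np.asarray(image.disc_center))[0])
    return replace(image, pixels=warped, valid=valid, disc_center=dc)


def normalize_mean_intensity(
    images: Sequence[AngiogramImage], target: float | None = None
) -> list[AngiogramImage]:
    """Multiplicatively rescale each image so its valid-pixel mean equals ``target``.

    With ``target=None`` the common level is the average of the input means.
    Pure positive scaling: relative pixel ordering (hence any quantile- or
    histogram-shape-based threshold) is preserved.
    """
    means = []
    for im in images:
        m = float(im.as_float()[im.valid_mask()].mean())
        if m <= 0:
            raise ValueError("cannot normalize an image with non-positive mean intensity")
        means.append(m)
    if target is None:
        target = float(np.mean(means))
    if target <= 0:
        raise ValueError("target mean must be positive")
    out = []
    for im, m in zip(images, means):
        out.append(replace(im, pixels=im.as_float() * (target / m)))
    return out
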