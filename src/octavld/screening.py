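"""Image-eligibility rules, artifact detectors, tallies and scan selection.

An acquisition is excluded when any of three criteria fires, checked in
fixed order:

1. *artifact* — three or more saccades (horizontal misalignment bands)
   or at least one dark shadow patch obscuring vessels outside the disc;
2. *decentration* — the target annulus is not achievable after matching
   the images from the different instruments;
3. *low signal* — signal strength below the device's stated minimum
   (25 Spectralis, 50 Optovue/Angiovue, 50 Triton, 7 Cirrus/Zeiss).

The original grading was human; here the rules form a deterministic
engine over declared flags, with optional heuristic detectors that
populate the flags from pixels (validated only against synthetic
artifact injections).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, label

from .image_io import AngiogramImage
from .reference import MIN_SIGNAL

logger = logging.getLogger(__name__)

SACCADE_LIMIT = 3  # exclusion at >= 3 saccade events


@dataclass
class ScreeningRecord:
    """Flags and decision for one acquisition."""

    eye_id: str
    device: str
    scan_index: int
    saccade_count: int
    shadow_patch_present: bool
    decentered: bool
    signal_strength: float
    min_signal: float
    decision: str = ""  # eligible | excluded
    reason: str = ""  # none | artifact | decentration | low_signal


def screen_acquisition(
    eye_id: str,
    device: str,
    scan_index: int,
    saccade_count: int,
    shadow_patch_present: bool,
    decentered: bool,
    signal_strength: float,
    min_signal: float | None = None,
) -> ScreeningRecord:
    """Apply the exclusion rules; pure and deterministic.

    ``min_signal`` defaults to the device's published threshold when the
    device name is recognized, otherwise it must be supplied.
    """
    if min_signal is None:
        if device not in MIN_SIGNAL:
            raise ValueError(
                f"min_signal not supplied and no known threshold for device {device!r}"
            )
        min_signal = MIN_SIGNAL[device]
    if saccade_count >= SACCADE_LIMIT or shadow_patch_present:
        decision, reason = "excluded", "artifact"
    elif decentered:
        decision, reason = "excluded", "decentration"
    elif signal_strength < min_signal:
        decision, reason = "excluded", "low_signal"
    else:
        decision, reason = "eligible", "none"
    return ScreeningRecord(
        eye_id=eye_id,
        device=device,
        scan_index=scan_index,
        saccade_count=saccade_count,
        shadow_patch_present=shadow_patch_present,
        decentered=decentered,
        signal_strength=signal_strength,
        min_signal=min_signal,
        decision=decision,
        reason=reason,
    )


def detect_saccades(
    image: AngiogramImage,
    shift_threshold_px: float = 4.0,
    max_shift_px: int = 40,
) -> int:
    """Count horizontal misalignment events by row-to-row correlation.

    The optimal horizontal shift of each row against its predecessor is
    estimated by circular cross-correlation (restricted to +/-
    ``max_shift_px``); cumulative offsets flag misaligned bands, and each
    maximal run of rows offset by more than ``shift_threshold_px`` counts
    as one saccade event.
    """
    px = image.as_float()
    h, w = px.shape
    rows = px - px.mean(axis=1, keepdims=True)
    F = np.fft.rfft(rows, axis=1)
    xc = np.fft.irfft(F[1:] * np.conj(F[:-1]), n=w, axis=1)
    lags = np.fft.fftfreq(w, d=1.0 / w).astype(int)  # 0, 1, ..., -1
    window = np.abs(lags) <= max_shift_px
    xc_win = xc[:, window]
    lag_win = lags[window]
    step = lag_win[np.argmax(xc_win, axis=1)]
    offset = np.concatenate([[0], np.cumsum(step)])
    misaligned = np.abs(offset) > shift_threshold_px
    events = int(np.sum(misaligned[1:] & ~misaligned[:-1]) + (1 if misaligned[0] else 0))
    logger.debug("detect_saccades: %d events, max |offset| %d px", events, int(np.abs(offset).max()))
    return events


def detect_shadow(
    image: AngiogramImage,
    intensity_fraction: float = 0.5,
    min_area_mm2: float = 0.03,
    disc_radius_mm: float = 0.75,
    smooth_sigma_px: float = 5.0,
) -> bool:
    """Detect a dark patch obscuring vessels outside the disc.

    True when any valid connected region outside the disc, larger than
    ``min_area_mm2``, has smoothed intensity below ``intensity_fraction``
    times the mean intensity outside the disc.
    """
    px = image.as_float()
    valid = image.valid_mask()
    h, w = px.shape
    outside_disc = np.ones((h, w), dtype=bool)
    if image.disc_center is not None:
        cx, cy = image.disc_center
        yy, xx = np.mgrid[0:h, 0:w]
        outside_disc = np.hypot(xx - cx, yy - cy) > disc_radius_mm / image.scale
    sel = valid & outside_disc
    if not sel.any():
        return False
    smoothed = gaussian_filter(px, smooth_sigma_px)
    dark = sel & (smoothed < intensity_fraction * smoothed[sel].mean())
    labels, n = label(dark)
    if n == 0:
        return False
    areas = np.bincount(labels.ravel())[1:]
    min_area_px = min_area_mm2 / image.scale**2
    return bool((areas >= min_area_px).any())


def screen_image(
    image: AngiogramImage,
    eye_id: str,
    scan_index: int = 1,
    decentered: bool = False,
    min_signal: float | None = None,
) -> ScreeningRecord:
    """Screen an image using the heuristic detectors to populate the flags."""
    return screen_acquisition(
        eye_id=eye_id,
        device=image.device or "unknown",
        scan_index=scan_index,
        saccade_count=detect_saccades(image),
        shadow_patch_present=detect_shadow(image),
        decentered=decentered,
        signal_strength=image.signal_strength or 0.0,
        min_signal=min_signal,
    )


def records_to_frame(records: list[ScreeningRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def tally_eligibility(records: pd.DataFrame | list[ScreeningRecord]) -> pd.DataFrame:
    """Per-device eligibility tally with a reason breakdown.

    Returns a frame indexed by device with columns ``eligible``, ``total``,
    ``percent`` (integer-rounded 100 * eligible/total) and one count column
    per exclusion reason; reason counts sum to total - eligible.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no screening records")
    rows = {}
    for device, grp in df.groupby("device", sort=False):
        total = len(grp)
        if total == 0:
            warnings.warn(f"device {device} has no records; omitted")
            continue
        eligible = int((grp["decision"] == "eligible").sum())
        row = {
            "eligible": eligible,
            "total": total,
            "percent": int(np.rint(100.0 * eligible / total)),
        }
        for reason in ("artifact", "decentration", "low_signal"):
            row[f"excluded_{reason}"] = int((grp["reason"] == reason).sum())
        rows[device] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def tally_from_counts(counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Tally directly from (eligible, total) pairs per device."""
    rows = {}
    for device, (eligible, total) in counts.items():
        if total == 0:
            warnings.warn(f"device {device} has no records; omitted")
            continue
        rows[device] = {
            "eligible": eligible,
            "total": total,
            "percent": int(np.rint(100.0 * eligible / total)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def select_better_scan(
    record1: ScreeningRecord, record2: ScreeningRecord
) -> int | None:
    """Pick the better of two repeated acquisitions of the same eye/device.

    Eligible beats excluded; among eligible scans the higher signal
    strength wins, then fewer saccades, then the lower scan index.
    Returns the chosen scan index, or None when both are excluded.
    """
    if (record1.eye_id, record1.device) != (record2.eye_id, record2.device):
        raise ValueError("scan pair must belong to the same eye and device")
    ok1 = record1.decision == "eligible"
    ok2 = record2.decision == "eligible"
    if not ok1 and not ok2:
        return None
    if ok1 != ok2:
        return record1.scan_index if ok1 else record2.scan_index
    key = lambda r: (-r.signal_strength, r.saccade_count, r.scan_index)
    return min((record1, record2), key=key).scan_index


def plot_exclusion_reasons(tally: pd.DataFrame, path: str | None = None):
    """Stacked bar chart of exclusion reasons per device."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reasons = [c for c in tally.columns if c.startswith("excluded_")]
    fig, ax = plt.subplots(figsize=(6, 4))
    bottom = np.zeros(len(tally))
    for r in reasons:
        ax.bar(tally.index, tally[r], bottom=bottom, label=r.removeprefix("excluded_"))
        bottom += tally[r].to_numpy()
    ax.set_ylabel("excluded acquisitions")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
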