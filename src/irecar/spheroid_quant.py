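"""Longitudinal tumor-spheroid quantification from two-channel fluorescence.

Multicellular tumor spheroids (MCTSs) built from GFP-expressing tumor
cells are tracked after electroporation and/or CAR T-cell addition.  The
green channel reports tumor viability; a deep-red channel reports
CellTracker-stained CAR T cells.  For each frame the spheroid is
segmented on the green channel, and both channels are summarized as the
mean intensity inside the spheroid minus the mean background outside it
(background subtraction removes illumination offset).  Per-well series
are normalized to the pre-treatment baseline, matching how normalized
GFP-intensity and area curves are reported.

An XTT metabolic readout is normalized by subtracting the 660-nm
reference-wavelength absorbance from the 475-nm signal and expressed as
fold of the untreated-control mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "FluorFrame",
    "SpheroidFrameMetrics",
    "SpheroidTrack",
    "XttRecord",
    "segment_mcts",
    "frame_metrics",
    "normalize_track",
    "track_from_frames",
    "xtt_normalize",
    "save_frame_tiff",
    "load_frame_tiff",
]

#: background exclusion zone: pixels within this many px of the mask border
#: are counted neither as spheroid nor as background (halo guard)
BACKGROUND_DILATION_PX = 10


@dataclass(frozen=True)
class FluorFrame:
    """One imaging timepoint of one well: green + deep-red channels."""

    well_id: str
    timepoint_h: float
    green: np.ndarray
    deepred: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.green.shape != self.deepred.shape:
            raise ValueError("channel shapes differ")
        if self.timepoint_h < 0 or self.pixel_size_um <= 0:
            raise ValueError("invalid frame metadata")


@dataclass(frozen=True)
class SpheroidFrameMetrics:
    well_id: str
    timepoint_h: float
    area_mm2: float
    mean_green_inside: float
    mean_green_background: float
    net_green: float
    net_deepred: float
    empty: bool = False


@dataclass(frozen=True)
class SpheroidTrack:
    """Per-well longitudinal metrics with baseline-normalized green and area."""

    well_id: str
    frames: tuple[SpheroidFrameMetrics, ...]
    normalized_green: tuple[float, ...]
    normalized_area: tuple[float, ...]

    @property
    def timepoints_h(self) -> tuple[float, ...]:
        return tuple(f.timepoint_h for f in self.frames)


@dataclass(frozen=True)
class XttRecord:
    well_id: str
    a475: float
    a660: float
    normalized_absorbance: float
    fold_of_control: float


def segment_mcts(green: np.ndarray, sigma_px: float = 2.0) -> np.ndarray:
    """Segment the spheroid: Otsu on a Gaussian-smoothed green channel,
    keep the largest connected component, fill holes.

    Returns a boolean mask; an all-False mask (no spheroid) for constant
    or foreground-free images rather than raising.
    """
    img = np.asarray(green, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    smooth = gaussian(img, sigma=sigma_px, preserve_range=True)
    if np.ptp(smooth) == 0:
        return np.zeros(img.shape, dtype=bool)
    mask = smooth > threshold_otsu(smooth)
    if not mask.any():
        return mask
    labels = cc_label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(labels == largest)


def frame_metrics(frame: FluorFrame, mask: np.ndarray) -> SpheroidFrameMetrics:
    """Area and background-subtracted channel intensities for one frame.

    Background is the mean outside a 10-px dilation of the mask; the
    deep-red channel uses the same green-derived mask (infiltration
    measure).  An empty mask yields area 0 and NaN intensities, flagged.
    """
    if mask.shape != frame.green.shape:
        raise ValueError("mask shape does not match frame")
    area_mm2 = float(np.count_nonzero(mask)) * (frame.pixel_size_um / 1000.0) ** 2
    if not mask.any():
        return SpheroidFrameMetrics(
            frame.well_id, frame.timepoint_h, 0.0, np.nan, np.nan, np.nan, np.nan, empty=True
        )
    halo = ndimage.binary_dilation(mask, iterations=BACKGROUND_DILATION_PX)
    background = ~halo
    if not background.any():
        background = ~mask  # tiny images: fall back to strict complement
    g_in = float(frame.green[mask].mean())
    g_bg = float(frame.green[background].mean())
    r_in = float(frame.deepred[mask].mean())
    r_bg = float(frame.deepred[background].mean())
    return SpheroidFrameMetrics(
        well_id=frame.well_id,
        timepoint_h=frame.timepoint_h,
        area_mm2=area_mm2,
        mean_green_inside=g_in,
        mean_green_background=g_bg,
        net_green=g_in - g_bg,
        net_deepred=r_in - r_bg,
    )


def normalize_track(frames: list[SpheroidFrameMetrics]) -> SpheroidTrack:
    """Divide each frame's net green and area by the pre-treatment baseline.

    The baseline is the first (earliest) frame; timepoints must be strictly
    increasing and the baseline net green and area positive.
    """
    if len(frames) < 2:
        raise ValueError("need at least two timepoints to form a track")
    times = [f.timepoint_h for f in frames]
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError("timepoints must be strictly increasing")
    base = frames[0]
    if not np.isfinite(base.net_green) or base.net_green <= 0:
        raise ValueError("baseline net green must be positive")
    if base.area_mm2 <= 0:
        raise ValueError("baseline area must be positive")
    return SpheroidTrack(
        well_id=base.well_id,
        frames=tuple(frames),
        normalized_green=tuple(f.net_green / base.net_green for f in frames),
        normalized_area=tuple(f.area_mm2 / base.area_mm2 for f in frames),
    )


def track_from_frames(
    frames: list[FluorFrame], roi_masks: list[np.ndarray] | None = None
) -> SpheroidTrack:
    """Segment, measure, and baseline-normalize a full well series.

    ``roi_masks`` accepts externally drawn regions of interest (one per
    frame) in place of automatic segmentation.
    """
    if roi_masks is None:
        roi_masks = [segment_mcts(f.green) for f in frames]
    metrics = [frame_metrics(f, m) for f, m in zip(frames, roi_masks)]
    return normalize_track(metrics)


def save_frame_tiff(frame: FluorFrame, path) -> None:
    """Write a frame as a two-page (green, deep-red) float32 TIFF."""
    import tifffile

    stack = np.stack([frame.green, frame.deepred]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={
        "well_id": frame.well_id,
        "timepoint_h": frame.timepoint_h,
        "pixel_size_um": frame.pixel_size_um,
    })


def load_frame_tiff(path) -> FluorFrame:
    """Read a two-page TIFF written by :func:`save_frame_tiff`."""
    import json

    import tifffile

    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        if isinstance(meta, str):
            meta = json.loads(meta)
    return FluorFrame(
        well_id=str(meta.get("well_id", "unknown")),
        timepoint_h=float(meta.get("timepoint_h", 0.0)),
        green=stack[0].astype(float),
        deepred=stack[1].astype(float),
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
    )


def xtt_normalize(
    a475: float, a660: float, control_mean: float, well_id: str = "", mode: str = "subtract"
) -> XttRecord:
    """Reference-wavelength-corrected XTT absorbance and fold of control.

    Default is the conventional subtraction correction,
    normalized = A475 - A660; ``mode="ratio"`` uses A475 / A660 instead.
    fold = normalized / control_mean, where ``control_mean`` is the mean
    normalized absorbance of untreated wells.
    """
    if a475 < 0 or a660 < 0:
        raise ValueError("absorbances must be non-negative")
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    if mode == "subtract":
        norm = a475 - a660
    elif mode == "ratio":
        if a660 == 0:
            raise ValueError("ratio mode requires a positive 660-nm reading")
        norm = a475 / a660
    else:
        raise ValueError(f"unknown XTT normalization mode {mode!r}")
    return XttRecord(well_id, a475, a660, norm, norm / control_mean)
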