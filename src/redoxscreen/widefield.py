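"""Widefield optical-redox-imaging (ORI) workflow.

One field of view per gel: an NAD(P)H / FAD autofluorescence image pair is
turned into a background-normalized optical redox ratio.  The chain is

1. rolling-ball background subtraction on the NAD(P)H image (vignetting /
   smooth illumination removal),
2. threshold + small-object removal to build a binary cell mask,
3. mean *raw* intensity of masked cell pixels in both channels,
4. mean intensity of three automatically chosen cell-free ROIs per channel
   (gel autofluorescence / illumination reference),
5. normalization and the redox ratio:

       I_NAD(P)H = I_cell,NAD(P)H / I_bg,NAD(P)H
       I_FAD     = I_cell,FAD     / I_bg,FAD
       ORR       = I_NAD(P)H / (I_NAD(P)H + I_FAD)

Dividing each channel by its own gel background cancels per-channel gain:
exposure drift, lamp power and substrate autofluorescence scale cells and
background together, so the normalized ORR is invariant to them — that
invariance is what makes day-to-day longitudinal comparisons meaningful.
The mask is derived from the corrected NAD(P)H image but always applied to
the raw channels; the rolling-ball output is used for masking only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import filters, morphology

from .errors import (
    BackgroundError,
    MaskingError,
    MeasurementError,
    NormalizationError,
    ParameterError,
    StageError,
)

__all__ = [
    "WidefieldPair",
    "CellMask",
    "GelRecord",
    "WidefieldConfig",
    "BackgroundEstimate",
    "rolling_ball_subtract",
    "make_cell_mask",
    "measure_masked_mean",
    "measure_background",
    "background_roi_candidates",
    "normalized_orr",
    "process_fov",
]


@dataclass
class WidefieldPair:
    """Registered NAD(P)H / FAD intensity images (arbitrary units)."""

    nadh: np.ndarray
    fad: np.ndarray
    metadata: dict = field(default_factory=dict)
    truth: object | None = field(default=None, repr=False)

    def __post_init__(self):
        self.nadh = np.asarray(self.nadh, dtype=float)
        self.fad = np.asarray(self.fad, dtype=float)
        if self.nadh.shape != self.fad.shape:
            raise ParameterError("NAD(P)H and FAD images must share a shape")
        if self.nadh.ndim != 2:
            raise ParameterError("channel images must be 2-D")
        if np.any(self.nadh < 0) or np.any(self.fad < 0):
            raise ParameterError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nadh.shape


@dataclass
class CellMask:
    """Binary cell mask plus the thresholding provenance that produced it."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class BackgroundEstimate:
    """Mean cell-free intensity and the ROI boxes it came from."""

    value: float
    rois: list[tuple[int, int, int]]  # (row0, col0, size)

    def __float__(self) -> float:
        return self.value


@dataclass
class GelRecord:
    """Per-FOV quantification: raw means, normalized intensities, ORR, QC."""

    i_cell_nadh: float
    i_bg_nadh: float
    i_cell_fad: float
    i_bg_fad: float
    i_norm_nadh: float
    i_norm_fad: float
    orr: float
    mask_area_fraction: float
    n_background_rois: int
    saturated: bool
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "i_cell_nadh": self.i_cell_nadh, "i_bg_nadh": self.i_bg_nadh,
            "i_cell_fad": self.i_cell_fad, "i_bg_fad": self.i_bg_fad,
            "i_norm_nadh": self.i_norm_nadh, "i_norm_fad": self.i_norm_fad,
            "orr": self.orr, "mask_area_fraction": self.mask_area_fraction,
            "n_background_rois": self.n_background_rois,
            "saturated": self.saturated,
        }
        d.update(self.metadata)
        return d


@dataclass
class WidefieldConfig:
    """Tunable knobs of the FOV pipeline (pixel units)."""

    rolling_ball_radius: int = 50
    threshold_method: str = "otsu"  # "otsu" | "percentile" | "fixed"
    threshold_value: float | None = None  # percentile (0-100) or fixed level
    min_object_px: int = 64
    n_background_rois: int = 3
    roi_size: int = 32
    background_margin: int = 8
    saturation_value: float | None = None
    manual_rois: Sequence[tuple[int, int, int]] | None = None

    @classmethod
    def for_shape(cls, shape: tuple[int, int], **overrides) -> "WidefieldConfig":
        """Knobs scaled to a small synthetic FOV (ball/ROI ~ 1/8 of field)."""
        side = min(shape)
        defaults = dict(rolling_ball_radius=max(8, side // 8),
                        roi_size=max(16, side // 8),
                        background_margin=max(4, side // 32))
        defaults.update(overrides)
        return cls(**defaults)


def rolling_ball_subtract(image: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball background subtraction.

    The background is the grayscale opening of the image with a disk
    structuring element of the given radius (the classic rolling-ball
    construction): smooth variation wider than the element — vignetting,
    illumination gradients — is retained in the background and removed,
    while features smaller than the element survive.  Output is
    ``clip(image - background, 0)`` and is everywhere <= the input.
    """
    image = np.asarray(image, dtype=float)
    if radius < 1:
        raise ParameterError("rolling-ball radius must be >= 1")
    if 2 * radius + 1 > min(image.shape):
        raise ParameterError(
            f"rolling-ball radius {radius} too large for image {image.shape}"
        )
    footprint = morphology.disk(radius, decomposition="sequence")
    background = morphology.opening(image, footprint)
    return np.clip(image - background, 0.0, None)


def make_cell_mask(
    corrected_nadh: np.ndarray,
    method: str = "otsu",
    min_object_px: int = 64,
    threshold_value: float | None = None,
) -> CellMask:
    """Threshold a background-corrected NAD(P)H image into a cell mask.

    ``method`` is ``"otsu"`` (default), ``"percentile"`` (threshold at the
    given percentile of pixel values) or ``"fixed"`` (absolute level).
    Connected components smaller than ``min_object_px`` are removed.
    """
    img = np.asarray(corrected_nadh, dtype=float)
    if np.ptp(img) == 0:
        raise MaskingError("no foreground separable: image is constant")
    if method == "otsu":
        thr = filters.threshold_otsu(img)
    elif method == "percentile":
        if threshold_value is None:
            raise ParameterError("percentile method needs threshold_value")
        thr = float(np.percentile(img, threshold_value))
    elif method == "fixed":
        if threshold_value is None:
            raise ParameterError("fixed method needs threshold_value")
        thr = float(threshold_value)
    else:
        raise ParameterError(f"unknown threshold method {method!r}")
    raw = img > thr
    # drop components strictly smaller than min_object_px
    mask = morphology.remove_small_objects(raw, max_size=min_object_px - 1)
    if not mask.any():
        raise MaskingError(
            "no foreground separable: mask empty after small-object removal"
        )
    return CellMask(mask, provenance={
        "method": method, "threshold": float(thr),
        "min_object_px": int(min_object_px),
    })


def _usable(image: np.ndarray, saturation_value: float | None) -> np.ndarray:
    if saturation_value is None:
        return np.ones(image.shape, dtype=bool)
    return image < saturation_value


def measure_masked_mean(
    image: np.ndarray,
    mask: CellMask | np.ndarray,
    saturation_value: float | None = None,
) -> float:
    """Mean raw intensity over masked pixels (saturated pixels excluded)."""
    image = np.asarray(image, dtype=float)
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask).astype(bool)
    m = m & _usable(image, saturation_value)
    if not m.any():
        raise MeasurementError("empty mask: nothing to measure")
    return float(image[m].mean())


def background_roi_candidates(
    mask: np.ndarray, roi_size: int, margin: int
) -> list[tuple[int, int, float]]:
    """Disjoint square ROI candidates ordered by (mask overlap, row, col).

    The cell mask is dilated by ``margin`` pixels before overlap is counted,
    keeping ROIs clear of mask fringes.  Candidates tile the image on a
    ``roi_size`` grid, so selected ROIs are disjoint by construction.
    """
    mask = np.asarray(mask).astype(bool)
    if margin > 0:
        mask = morphology.dilation(mask, morphology.disk(margin))
    rows, cols = mask.shape
    cands = []
    for r0 in range(0, rows - roi_size + 1, roi_size):
        for c0 in range(0, cols - roi_size + 1, roi_size):
            overlap = float(mask[r0:r0 + roi_size, c0:c0 + roi_size].mean())
            cands.append((r0, c0, overlap))
    cands.sort(key=lambda t: (t[2], t[0], t[1]))
    return cands


def measure_background(
    image: np.ndarray,
    mask: CellMask | np.ndarray,
    n_rois: int = 3,
    roi_size: int = 32,
    margin: int = 8,
    manual_rois: Sequence[tuple[int, int, int]] | None = None,
    saturation_value: float | None = None,
) -> BackgroundEstimate:
    """Mean intensity over ``n_rois`` cell-free square ROIs.

    ROIs are selected deterministically: grid candidates fully outside the
    dilated cell mask, lowest overlap first, ties broken by lexicographic
    position.  ``manual_rois`` — a list of ``(row0, col0, size)`` boxes —
    overrides the automatic selection (the reproduction path for manually
    chosen gel background locations).
    """
    image = np.asarray(image, dtype=float)
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask).astype(bool)

    if manual_rois is not None:
        boxes = [tuple(int(v) for v in roi) for roi in manual_rois]
    else:
        cands = background_roi_candidates(m, roi_size, margin)
        clear = [(r, c) for r, c, ov in cands if ov == 0.0]
        if len(clear) < n_rois:
            raise BackgroundError(
                f"only {len(clear)} cell-free ROIs of size {roi_size} found, "
                f"need {n_rois}; supply manual_rois"
            )
        boxes = [(r, c, roi_size) for r, c in clear[:n_rois]]

    means = []
    for r0, c0, size in boxes:
        patch = image[r0:r0 + size, c0:c0 + size]
        usable = _usable(patch, saturation_value)
        if patch.size == 0 or not usable.any():
            raise BackgroundError(f"ROI {(r0, c0, size)} empty or saturated")
        means.append(float(patch[usable].mean()))
    return BackgroundEstimate(float(np.mean(means)), boxes)


def normalized_orr(
    i_cell_nadh: float,
    i_bg_nadh: float,
    i_cell_fad: float,
    i_bg_fad: float,
) -> tuple[float, float, float]:
    """Background-normalized channel intensities and the redox ratio.

    Returns ``(i_norm_nadh, i_norm_fad, orr)`` with
    ``orr = i_norm_nadh / (i_norm_nadh + i_norm_fad)``; always in (0, 1)
    for positive inputs.
    """
    vals = (i_cell_nadh, i_bg_nadh, i_cell_fad, i_bg_fad)
    if any(not v > 0 for v in vals):
        raise NormalizationError(
            f"all intensities must be positive, got {vals}"
        )
    i_norm_nadh = i_cell_nadh / i_bg_nadh
    i_norm_fad = i_cell_fad / i_bg_fad
    orr = i_norm_nadh / (i_norm_nadh + i_norm_fad)
    return i_norm_nadh, i_norm_fad, orr


def process_fov(pair: WidefieldPair, config: WidefieldConfig | None = None) -> GelRecord:
    """Run the full per-FOV workflow and return a populated :class:`GelRecord`.

    Stage failures are re-raised as :class:`StageError` naming the stage.
    """
    cfg = config or WidefieldConfig()

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage tag
            raise StageError(name, exc) from exc

    corrected = _stage("rolling_ball_subtract", rolling_ball_subtract,
                       pair.nadh, cfg.rolling_ball_radius)
    mask = _stage("make_cell_mask", make_cell_mask, corrected,
                  method=cfg.threshold_method,
                  min_object_px=cfg.min_object_px,
                  threshold_value=cfg.threshold_value)
    i_cell_nadh = _stage("measure_masked_mean", measure_masked_mean,
                         pair.nadh, mask, cfg.saturation_value)
    i_cell_fad = _stage("measure_masked_mean", measure_masked_mean,
                        pair.fad, mask, cfg.saturation_value)
    bg_kw = dict(n_rois=cfg.n_background_rois, roi_size=cfg.roi_size,
                 margin=cfg.background_margin, manual_rois=cfg.manual_rois,
                 saturation_value=cfg.saturation_value)
    bg_nadh = _stage("measure_background", measure_background,
                     pair.nadh, mask, **bg_kw)
    bg_fad = _stage("measure_background", measure_background,
                    pair.fad, mask, **bg_kw)
    i_norm_nadh, i_norm_fad, orr = _stage(
        "normalized_orr", normalized_orr,
        i_cell_nadh, bg_nadh.value, i_cell_fad, bg_fad.value)

    saturated = False
    if cfg.saturation_value is not None:
        saturated = bool((pair.nadh >= cfg.saturation_value).any()
                         or (pair.fad >= cfg.saturation_value).any())
    return GelRecord(
        i_cell_nadh=i_cell_nadh, i_bg_nadh=bg_nadh.value,
        i_cell_fad=i_cell_fad, i_bg_fad=bg_fad.value,
        i_norm_nadh=i_norm_nadh, i_norm_fad=i_norm_fad, orr=orr,
        mask_area_fraction=mask.area_fraction,
        n_background_rois=len(bg_nadh.rois),
        saturated=saturated,
        metadata=dict(pair.metadata),
    )
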