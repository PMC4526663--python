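"""Synaptophysin area-fraction densitometry on Map2-defined ROIs.

The measurement follows the slide-constancy protocol: intensity thresholds
for the Map2 (dendritic marker) and synaptophysin channels are calibrated
once on a control image and then held fixed for every image of the slide.
Within each hand-drawn polygon, the ROI is the above-threshold Map2 area
grown by ~10% (to cover the perinuclear band where synaptophysin boutons
sit just outside the dendritic stain), and the readout is

    fraction = 100 * synaptophysin-positive area / Map2-defined ROI area.

Map2 normalizes for histological shrinkage/flattening; a companion ANOVA
on the Map2 ROI areas themselves (:func:`map2_area_check`) verifies the
denominator does not differ between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.morphology import disk

__all__ = [
    "Mosaic",
    "ThresholdSet",
    "RoiMeasure",
    "CalibrationError",
    "EmptyRoiWarning",
    "calibrate_thresholds",
    "enlarge_mask",
    "map2_roi",
    "measure_area_fraction",
    "measure_mosaic",
    "map2_area_check",
]


class CalibrationError(ValueError):
    """Threshold calibration impossible (e.g. constant-intensity channel)."""


class EmptyRoiWarning(UserWarning):
    """No Map2 signal inside a polygon; the measure is skipped."""


@dataclass
class Mosaic:
    """2D multi-channel mosaic image (channels, height, width)."""

    channels: np.ndarray
    channel_names: tuple[str, ...] = ("nuclei", "map2", "synaptophysin")

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 3:
            raise ValueError("channels must have shape (c, h, w)")
        if len(self.channel_names) != self.channels.shape[0]:
            raise ValueError("channel_names length must match channel count")

    def channel(self, name: str) -> np.ndarray:
        return self.channels[self.channel_names.index(name)]

    @property
    def map2(self) -> np.ndarray:
        return self.channel("map2")

    @property
    def synaptophysin(self) -> np.ndarray:
        return self.channel("synaptophysin")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-channel intensity cutoffs, frozen for all images of one slide."""

    map2_threshold: float
    syn_threshold: float
    calibration_image_id: Optional[str] = None


@dataclass(frozen=True)
class RoiMeasure:
    """Area-fraction readout for one ROI."""

    roi_name: str
    map2_roi_area: int
    syn_area: int
    fraction: float  # percent, 100 * syn_area / map2_roi_area
    slide_id: Optional[str] = None
    animal_id: Optional[str] = None
    pretreatment: Optional[str] = None


def _roi_union_mask(shape: tuple[int, int],
                    roi_polygons: Sequence[Sequence[Sequence[float]]]) -> np.ndarray:
    union = np.zeros(shape, dtype=bool)
    for poly in roi_polygons:
        pts = np.asarray(poly, dtype=float)
        union |= polygon2mask(shape, pts[:, ::-1])  # (x,y) -> (row,col)
    return union


def calibrate_thresholds(control: Mosaic,
                         roi_polygons: Optional[Sequence] = None,
                         image_id: Optional[str] = None) -> ThresholdSet:
    """Otsu thresholds for both channels from a control image.

    When ROI polygons are given, only pixels inside their union enter the
    between-class-variance criterion (background outside the tissue would
    otherwise dominate).  Deterministic given the image; a channel with no
    intensity contrast raises :class:`CalibrationError`.
    """
    if roi_polygons is not None:
        polys = [p[1] if (isinstance(p, tuple) and len(p) == 2 and isinstance(p[0], str))
                 else p for p in roi_polygons]
        sel = _roi_union_mask(control.map2.shape, polys)
    else:
        sel = np.ones(control.map2.shape, dtype=bool)
    cuts = []
    for name in ("map2", "synaptophysin"):
        vals = control.channel(name)[sel]
        if np.ptp(vals) < 1e-6:
            raise CalibrationError(f"channel {name!r} has no intensity contrast; cannot calibrate")
        cuts.append(float(threshold_otsu(vals)))
    return ThresholdSet(map2_threshold=cuts[0], syn_threshold=cuts[1],
                        calibration_image_id=image_id)


def enlarge_mask(mask: np.ndarray, enlargement: float = 0.10,
                 max_radius: int = 50) -> np.ndarray:
    """Grow a mask by dilation until its area reaches (1+enlargement)x.

    The first integer dilation radius reaching the target is used;
    overshoot past the target is inherent to integer radii and logged by
    the caller when relevant.  ``enlargement=0`` returns the mask itself.
    """
    if enlargement < 0:
        raise ValueError("enlargement must be >= 0")
    area0 = int(mask.sum())
    if area0 == 0:
        return mask.copy()
    target = (1.0 + enlargement) * area0
    if area0 >= target:
        return mask.copy()
    for r in range(1, max_radius + 1):
        grown = ndimage.binary_dilation(mask, structure=disk(r))
        if grown.sum() >= target:
            return grown
    raise RuntimeError(f"dilation radius {max_radius} insufficient to reach {enlargement:+.0%} area")


def map2_roi(mosaic: Mosaic, polygon: Sequence[Sequence[float]],
             thresholds: ThresholdSet, enlargement: float = 0.10) -> Optional[np.ndarray]:
    """ROI mask: above-threshold Map2 within the polygon, grown ~10%.

    Returns None (with :class:`EmptyRoiWarning`) when the polygon holds no
    Map2 signal, so the caller can skip the measure.
    """
    pts = np.asarray(polygon, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("polygon must have at least 3 vertices")
    pmask = polygon2mask(mosaic.map2.shape, pts[:, ::-1])
    core = pmask & (mosaic.map2 >= thresholds.map2_threshold)
    if not core.any():
        warnings.warn("no Map2 signal inside polygon; ROI skipped", EmptyRoiWarning)
        return None
    return enlarge_mask(core, enlargement=enlargement)


def measure_area_fraction(mosaic: Mosaic, roi_mask: np.ndarray,
                          thresholds: ThresholdSet, roi_name: str = "",
                          **meta: Optional[str]) -> RoiMeasure:
    """Count synaptophysin-positive pixels inside the ROI mask.

    fraction = 100 * syn_area / ROI area, in percent.
    """
    area = int(roi_mask.sum())
    if area == 0:
        raise ValueError("empty ROI mask: area fraction undefined")
    syn_area = int(np.count_nonzero(mosaic.synaptophysin[roi_mask] >= thresholds.syn_threshold))
    return RoiMeasure(roi_name=roi_name, map2_roi_area=area, syn_area=syn_area,
                      fraction=100.0 * syn_area / area, **meta)


def measure_mosaic(mosaic: Mosaic, roi_spec: Sequence[tuple[str, Sequence]],
                   thresholds: ThresholdSet, enlargement: float = 0.10,
                   **meta: Optional[str]) -> pd.DataFrame:
    """Measure every named ROI of a mosaic; skipped ROIs are omitted."""
    rows = []
    for name, poly in roi_spec:
        mask = map2_roi(mosaic, poly, thresholds, enlargement=enlargement)
        if mask is None:
            continue
        m = measure_area_fraction(mosaic, mask, thresholds, roi_name=name, **meta)
        rows.append(m.__dict__)
    return pd.DataFrame(rows)


def map2_area_check(measures: pd.DataFrame, group_col: str = "pretreatment") -> pd.DataFrame:
    """Per-ROI one-way ANOVA of Map2 ROI areas across groups.

    A validity check on the denominator: group differences in dendritic
    area would confound the synaptophysin fraction.  ROIs with fewer than
    two groups are reported with a note and NaN statistics.
    """
    from .stats import one_way_anova

    rows = []
    for roi, sub in measures.groupby("roi_name"):
        groups = sub[group_col].nunique()
        if groups < 2:
            rows.append({"roi_name": roi, "F": np.nan, "p": np.nan,
                         "note": "single group; ANOVA skipped"})
            continue
        table = sub.rename(columns={"map2_roi_area": "value"})[["value", group_col]]
        res = one_way_anova(table, factor=group_col)
        rows.append({"roi_name": roi, "F": res.statistic, "p": res.p_value, "note": ""})
    return pd.DataFrame(rows, columns=["roi_name", "F", "p", "note"])
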