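"""Nucleus segmentation and per-cell Arc classification in 3D stacks.

The classification criteria mirror the manual catFISH reading protocol:

* nuclear Arc-positive -- two intense intranuclear Cy3 foci, each visible
  across >= 3 consecutive z-planes;
* cytoplasmic Arc-positive -- nucleus > 60% surrounded by Cy3 signal in
  >= 4 z-planes (not necessarily consecutive);
* double -- both criteria; negative -- neither.

Glial nuclei (solid, bright counterstain) are excluded before
classification, and an optical-dissector window keeps only cells whose
nucleus centroid lies in the middle fraction (default 30%) of the stack,
avoiding partial-cell sampling bias at the stack faces.

Segmentation itself is replaceable plumbing (the original analysis was
counted by eye): pre-tabulated per-cell evidence can bypass the imaging
path entirely via :func:`classify_cell` and :func:`tabulate`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed
from skimage.feature import peak_local_max

from .simulate import ImageStack
from .sisc import CellCounts

__all__ = [
    "ClassifyParams",
    "CellRecord",
    "preprocess",
    "segment_nuclei",
    "is_neuron",
    "optical_dissector",
    "detect_foci",
    "cyto_coverage",
    "classify_cell",
    "classify_stack",
    "tabulate",
    "pool_counts",
]

LABELS = ("negative", "nuclear", "cytoplasmic", "double")


@dataclass(frozen=True)
class ClassifyParams:
    """Tunable thresholds of the classification pipeline.

    Defaults are calibrated on the synthetic renderer's intensity model
    (neuron mean 100, glia 180, foci 200, ring 150).

    median_radius : per-plane median-filter radius (px); 0 disables.
    cv_min, brightness_max : neuron/glia rule -- a nucleus is neuronal iff
        its within-mask coefficient of variation >= cv_min AND its mean
        counterstain intensity <= brightness_max.
    focus_threshold : Cy3 cutoff for transcription-focus pixels.
    focus_min_area, focus_max_area : per-plane focus component area (px).
    focus_link_dist : max centroid shift (px) linking a focus across planes.
    focus_min_span : consecutive planes a focus track must persist.
    ring_threshold : Cy3 cutoff for perinuclear signal.
    coverage_threshold : strict lower bound on per-plane angular coverage.
    coverage_min_planes : planes that must individually exceed it.
    coverage_consecutive : if True, those planes must be consecutive
        (default False -- "in 4 or more planes", not "across").
    n_sectors : angular sectors for coverage estimation.
    annulus_inner : guard shells (px) skipped next to the mask boundary,
        absorbing segmentation raggedness under noise.
    annulus_width : radial width (px) of the perinuclear band beyond the
        guard.
    sector_min_px : number of a sector's band pixels that must be above
        threshold for the sector to count as covered (capped at the
        sector's band size).
    dissector_fraction : central z-fraction retained by the dissector.
    """

    median_radius: int = 1
    min_volume: int = 200
    cv_min: float = 0.12
    brightness_max: float = 140.0
    focus_threshold: float = 100.0
    focus_min_area: int = 2
    focus_max_area: int = 80
    focus_link_dist: float = 3.0
    focus_min_span: int = 3
    min_foci: int = 2
    ring_threshold: float = 75.0
    coverage_threshold: float = 0.60
    coverage_min_planes: int = 4
    coverage_consecutive: bool = False
    n_sectors: int = 72
    annulus_inner: int = 1
    annulus_width: int = 3
    sector_min_px: int = 1
    dissector_fraction: float = 0.30


@dataclass
class CellRecord:
    """One segmented nucleus with its per-plane Arc evidence.

    ``mask`` is boolean within ``bbox`` (tuple of slices into the stack);
    ``focus_counts``/``coverage`` are indexed by absolute plane, and
    ``focus_spans`` holds the plane-span of every linked focus track.
    """

    cell_id: int
    bbox: tuple[slice, slice, slice]
    mask: np.ndarray
    centroid: tuple[float, float, float]
    volume: int = 0
    is_neuron: Optional[bool] = None
    focus_counts: Optional[np.ndarray] = None
    focus_spans: list[int] = field(default_factory=list)
    coverage: Optional[np.ndarray] = None
    label: Optional[str] = None

    @property
    def z_planes(self) -> range:
        return range(self.bbox[0].start, self.bbox[0].stop)


def preprocess(stack: ImageStack, radius: int = 1) -> ImageStack:
    """Per-plane 2D median filter on both channels; radius 0 is identity."""
    if radius < 0:
        raise ValueError("median radius must be >= 0")
    if radius == 0:
        return ImageStack(stack.channels.copy(), z_step=stack.z_step,
                          channel_names=stack.channel_names)
    size = 2 * radius + 1
    out = np.empty_like(stack.channels)
    for c in range(stack.channels.shape[0]):
        out[c] = ndimage.median_filter(stack.channels[c], size=(1, size, size))
    return ImageStack(out, z_step=stack.z_step, channel_names=stack.channel_names)


def segment_nuclei(stack: ImageStack, params: ClassifyParams = ClassifyParams()) -> list[CellRecord]:
    """Threshold + 3D label + marker-based watershed split of the counterstain.

    Returns records with masks and centroids only (no classification).
    A blank image yields an empty list.
    """
    cs = stack.counterstain
    if cs.max() <= 0 or np.isclose(cs.max(), cs.min()):
        return []
    th = threshold_otsu(cs)
    binary = cs > th
    binary = ndimage.binary_opening(binary, structure=np.ones((1, 3, 3), bool))
    # nuclear texture can dip below threshold inside a nucleus; closing
    # repairs boundary bays and hole-filling makes cross-sections solid
    binary = ndimage.binary_closing(binary, structure=np.ones((1, 3, 3), bool))
    for z in range(binary.shape[0]):
        binary[z] = ndimage.binary_fill_holes(binary[z])
    if not binary.any():
        return []
    # distance transform in voxel units; smoothing suppresses plateau
    # artifacts so one convex nucleus seeds exactly one marker
    dist = ndimage.distance_transform_edt(binary)
    dist_s = ndimage.gaussian_filter(dist, sigma=1.5)
    peaks = peak_local_max(dist_s, min_distance=7, labels=ndimage.label(binary)[0],
                           exclude_border=False)
    markers = np.zeros(binary.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    if markers.max() == 0:
        labeled, _ = ndimage.label(binary)
    else:
        labeled = watershed(-dist, markers, mask=binary)
    records: list[CellRecord] = []
    objects = ndimage.find_objects(labeled)
    cid = 0
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        m = labeled[sl] == lab
        vol = int(m.sum())
        if vol < params.min_volume:
            continue
        zz, yy, xx = np.nonzero(m)
        centroid = (float(zz.mean() + sl[0].start),
                    float(yy.mean() + sl[1].start),
                    float(xx.mean() + sl[2].start))
        records.append(CellRecord(cell_id=cid, bbox=sl, mask=m, centroid=centroid, volume=vol))
        cid += 1
    return records


def is_neuron(record: CellRecord, stack: ImageStack,
              params: ClassifyParams = ClassifyParams()) -> bool:
    """Texture/brightness rule separating neuronal from glial nuclei.

    Neuronal nuclei are textured (high within-mask CV) and dim; glia are
    solid and bright.  A degenerate single-voxel mask is treated as glial
    (excluded) with a warning; zero-mean masks get CV 0 by convention.
    """
    if record.mask.sum() <= 1:
        warnings.warn(f"cell {record.cell_id}: degenerate 1-voxel mask, excluding as glial")
        return False
    vals = stack.counterstain[record.bbox][record.mask]
    mean = float(vals.mean())
    cv = float(vals.std() / mean) if mean > 0 else 0.0
    return cv >= params.cv_min and mean <= params.brightness_max


def optical_dissector(records: Sequence[CellRecord], n_planes: int,
                      fraction: float = 0.30) -> list[CellRecord]:
    """Keep cells whose nucleus centroid lies in the middle z-fraction.

    The window is the closed plane interval
    ``[ceil(n*(1-f)/2), floor(n*(1+f)/2)]`` (0-based); e.g. 40 planes at
    30% keep centroids in planes 14..26.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("dissector fraction must lie in (0, 1]")
    lo = math.ceil(n_planes * (1.0 - fraction) / 2.0)
    hi = math.floor(n_planes * (1.0 + fraction) / 2.0)
    return [r for r in records if lo <= r.centroid[0] <= hi]


def detect_foci(record: CellRecord, arc_channel: np.ndarray,
                params: ClassifyParams = ClassifyParams()) -> np.ndarray:
    """Per-plane intranuclear focus counts, with cross-plane track linking.

    A focus candidate is a connected above-threshold component inside the
    nucleus mask with area in [focus_min_area, focus_max_area].
    Candidates in consecutive planes within ``focus_link_dist`` px are the
    same focus; the resulting track spans are stored on the record.
    Returns the per-plane counts (absolute plane indexing).
    """
    n_planes = arc_channel.shape[0]
    counts = np.zeros(n_planes, dtype=int)
    zsl, ysl, xsl = record.bbox
    tracks: list[dict] = []  # {"last_plane": int, "centroid": (y,x), "span": int}
    spans: list[int] = []
    for zi, z in enumerate(range(zsl.start, zsl.stop)):
        m2 = record.mask[zi]
        if not m2.any():
            continue
        arc2 = arc_channel[z, ysl, xsl]
        cand = (arc2 >= params.focus_threshold) & m2
        lab, n = ndimage.label(cand)
        cents = []
        for i in range(1, n + 1):
            comp = lab == i
            area = int(comp.sum())
            if params.focus_min_area <= area <= params.focus_max_area:
                ys, xs = np.nonzero(comp)
                cents.append((float(ys.mean()), float(xs.mean())))
        counts[z] = len(cents)
        # link to open tracks from the previous plane, greedily by distance
        open_tracks = [t for t in tracks if t["last_plane"] == z - 1]
        used = set()
        for t in open_tracks:
            best, best_d = None, params.focus_link_dist
            for j, c in enumerate(cents):
                if j in used:
                    continue
                d = math.hypot(c[0] - t["centroid"][0], c[1] - t["centroid"][1])
                if d <= best_d:
                    best, best_d = j, d
            if best is not None:
                used.add(best)
                t["last_plane"] = z
                t["centroid"] = cents[best]
                t["span"] += 1
        for j, c in enumerate(cents):
            if j not in used:
                tracks.append({"last_plane": z, "centroid": c, "span": 1})
    spans = [t["span"] for t in tracks]
    record.focus_counts = counts
    record.focus_spans = spans
    return counts


def cyto_coverage(record: CellRecord, arc_channel: np.ndarray,
                  params: ClassifyParams = ClassifyParams(),
                  exclude: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-plane angular coverage of the perinuclear annulus by Arc signal.

    For each plane intersecting the nucleus, the annulus is the band
    between the mask dilated by ``annulus_inner`` px (a guard against
    ragged segmentation boundaries) and the mask dilated by
    ``annulus_inner + annulus_width`` px.
    The band is divided into ``n_sectors`` angular sectors around the
    nucleus centroid; a sector is covered when at least ``sector_min_px``
    of its band pixels are above ``ring_threshold``.  Coverage is the
    covered fraction of non-empty sectors, in [0, 1].

    ``exclude`` (a (z, y, x) boolean mask, typically the union of all
    segmented nuclei) removes pixels that are not cytoplasm -- a
    neighbouring nucleus intruding into the annulus would otherwise dilute
    its sectors.
    """
    n_planes = arc_channel.shape[0]
    cov = np.zeros(n_planes, dtype=float)
    zsl, ysl, xsl = record.bbox
    pad = params.annulus_inner + params.annulus_width + 1
    se_out = disk(params.annulus_inner + params.annulus_width)
    se_in = disk(params.annulus_inner) if params.annulus_inner > 0 else None
    _, cy, cx = record.centroid
    for zi, z in enumerate(range(zsl.start, zsl.stop)):
        m2 = record.mask[zi]
        if not m2.any():
            continue
        # widen the working window so the annulus fits
        y0 = max(0, ysl.start - pad); y1 = min(arc_channel.shape[1], ysl.stop + pad)
        x0 = max(0, xsl.start - pad); x1 = min(arc_channel.shape[2], xsl.stop + pad)
        big = np.zeros((y1 - y0, x1 - x0), dtype=bool)
        big[ysl.start - y0: ysl.stop - y0, xsl.start - x0: xsl.stop - x0] = m2
        inner = big if se_in is None else ndimage.binary_dilation(big, structure=se_in)
        band = ndimage.binary_dilation(big, structure=se_out) & ~inner
        if exclude is not None:
            band &= ~exclude[z, y0:y1, x0:x1]
        if not band.any():
            continue
        by, bx = np.nonzero(band)
        ang = np.arctan2(by + y0 - cy, bx + x0 - cx)
        sector = ((ang + math.pi) / (2 * math.pi) * params.n_sectors).astype(int)
        sector = np.clip(sector, 0, params.n_sectors - 1)
        hot = arc_channel[z, y0:y1, x0:x1][band] >= params.ring_threshold
        n_band = np.bincount(sector, minlength=params.n_sectors)
        n_hot = np.bincount(sector, weights=hot.astype(float), minlength=params.n_sectors)
        nonempty = n_band > 0
        need = np.minimum(params.sector_min_px, n_band[nonempty])
        covered = n_hot[nonempty] >= need
        cov[z] = covered.sum() / nonempty.sum()
    record.coverage = cov
    return cov


def _max_consecutive(flags: np.ndarray) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def classify_cell(record: CellRecord, params: ClassifyParams = ClassifyParams()) -> str:
    """Assign the catFISH label from the record's stored per-plane evidence.

    nuclear    <=> >= ``min_foci`` focus tracks each spanning
                   >= ``focus_min_span`` consecutive planes;
    cytoplasmic <=> coverage strictly > ``coverage_threshold`` in
                   >= ``coverage_min_planes`` planes (consecutiveness per
                   ``coverage_consecutive``);
    double     <=> both; negative otherwise.

    Deterministic given the evidence: re-running on stored evidence
    reproduces the label bit-exactly.
    """
    if record.focus_counts is None or record.coverage is None:
        raise ValueError("per-plane evidence missing; run detect_foci and cyto_coverage first")
    long_tracks = sum(1 for s in record.focus_spans if s >= params.focus_min_span)
    nuclear = long_tracks >= params.min_foci
    hot = np.asarray(record.coverage) > params.coverage_threshold
    if params.coverage_consecutive:
        cyto = _max_consecutive(hot) >= params.coverage_min_planes
    else:
        cyto = int(hot.sum()) >= params.coverage_min_planes
    if nuclear and cyto:
        label = "double"
    elif nuclear:
        label = "nuclear"
    elif cyto:
        label = "cytoplasmic"
    else:
        label = "negative"
    record.label = label
    return label


def classify_stack(stack: ImageStack, params: ClassifyParams = ClassifyParams(),
                   *, apply_dissector: bool = True) -> list[CellRecord]:
    """Full path: preprocess, segment, exclude glia, dissector, classify.

    Returns the classified neuronal records (glia and out-of-window cells
    dropped).
    """
    filtered = preprocess(stack, params.median_radius)
    records = segment_nuclei(filtered, params)
    foreground = np.zeros(filtered.counterstain.shape, dtype=bool)
    for r in records:
        foreground[r.bbox] |= r.mask
        r.is_neuron = is_neuron(r, filtered, params)
    neurons = [r for r in records if r.is_neuron]
    if apply_dissector:
        neurons = optical_dissector(neurons, filtered.n_planes, params.dissector_fraction)
    arc = filtered.arc
    for r in neurons:
        detect_foci(r, arc, params)
        cyto_coverage(r, arc, params, exclude=foreground)
        classify_cell(r, params)
    return neurons


def tabulate(records: Sequence[CellRecord], **meta: Optional[str]) -> CellCounts:
    """Tally labeled records into :class:`CellCounts`.

    Every record must be labeled; the four class counts sum to the total
    by construction.
    """
    tally = {k: 0 for k in LABELS}
    for r in records:
        if r.label not in tally:
            raise ValueError(f"cell {r.cell_id} is unlabeled or has invalid label {r.label!r}")
        tally[r.label] += 1
    return CellCounts(neg=tally["negative"], nuc=tally["nuclear"],
                      cyt=tally["cytoplasmic"], dob=tally["double"], **meta)


def pool_counts(counts: Sequence[CellCounts]) -> CellCounts:
    """Pool tallies across the stacks of one animal/region."""
    if not counts:
        return CellCounts(0, 0, 0, 0)
    out = counts[0]
    for c in counts[1:]:
        out = out + c
    return out
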