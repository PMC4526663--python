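"""Synthetic two-epoch catFISH data with known ground truth.

Generates (a) per-cell activation labels from a bivariate Bernoulli model
whose overlap parameter ``kappa`` equals the expected similarity score of
the population, (b) two-channel 3D image stacks that render those labels
the way Arc catFISH material looks under the confocal (textured dim
neuronal nuclei, solid bright glia, paired intranuclear transcription foci
spanning several z-planes, perinuclear cytoplasmic rings), and (c) 2D
synaptophysin/Map2-like mosaics with known per-ROI area fractions.

The activation model: a neuron is active in epoch 1 with probability
``p1``, in epoch 2 with probability ``p2``, and jointly with probability

    p11 = p1*p2 + kappa * (min(p1, p2) - p1*p2)

so kappa=0 gives independent ensembles (expected SiSc 0) and kappa=1
nests the smaller ensemble inside the larger (expected SiSc 1).  Glial
cells are never active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .sisc import CellCounts

__all__ = [
    "SimConfig",
    "ImageStack",
    "CapacityError",
    "kappa_bounds",
    "simulate_labels",
    "counts_from_truth",
    "truth_label",
    "render_stack",
    "render_mosaic",
    "default_roi_layout",
    "ROI_NAMES",
]

#: The 14 dendritic-lamina ROI names used for synaptophysin/Map2 mosaics
#: (CA3 stratum oriens / lucidum / radiatum subfields plus the two CA1 ROIs).
ROI_NAMES = (
    "SOd", "SOm", "SOp", "SLd", "SLm", "SLp",
    "SRdm", "SRmm", "SRpm", "SRdd", "SRmd", "SRpd",
    "CA1_SO", "CA1_SR",
)


class CapacityError(RuntimeError):
    """Stack too crowded: nucleus placement failed after bounded retries."""


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for two-epoch activation and stack rendering.

    Defaults emulate the acquisition geometry of the source material:
    ~40 optical sections of 0.3 um through CA1/CA3 pyramidal layers, with
    roughly a third of neurons active per 5-min exploration epoch.

    Parameters
    ----------
    n_cells : number of nuclei to place (neurons + glia).
    p1, p2 : marginal activation probabilities for epochs 1 and 2.
    kappa : ensemble-overlap parameter; the expected SiSc of the
        generated population.  Must lie in ``[kappa_min, 1]`` (see
        :func:`kappa_bounds`); 0 = independent ensembles.
    glia_fraction : proportion of nuclei that are glial (never active).
    stack_shape : (z, y, x) voxel counts of the rendered stack.
    noise_sd : additive Gaussian noise scale, intensity units.
    foci_planes : z-span (consecutive planes) of each transcription focus.
    ring_planes : z-span of the cytoplasmic perinuclear ring.
    ring_coverage : angular fraction of the nucleus perimeter the ring
        covers, in [0, 1].
    nucleus_radius / nucleus_z_radius : nuclear semi-axes, px in-plane and
        planes in z (anisotropic voxels).
    seed : RNG seed; same config => bit-identical output.
    """

    n_cells: int = 50
    p1: float = 0.33
    p2: float = 0.33
    kappa: float = 0.5
    glia_fraction: float = 0.2
    stack_shape: tuple[int, int, int] = (40, 256, 256)
    noise_sd: float = 10.0
    foci_planes: int = 4
    ring_planes: int = 5
    ring_coverage: float = 0.7
    nucleus_radius: float = 8.0
    nucleus_z_radius: float = 6.0
    placement_clearance: float = 6.0
    z_step: float = 0.3
    # rendering intensity model
    background: float = 10.0
    neuron_mean: float = 100.0
    glia_brightness: float = 1.8      # glia mean = glia_brightness * neuron_mean
    speckle_sd: float = 0.25          # multiplicative texture on neuronal nuclei
    foci_amplitude: float = 200.0
    foci_radius: float = 2.0
    ring_amplitude: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.glia_fraction < 1.0:
            raise ValueError("glia_fraction must lie in [0, 1)")
        if not 0.0 <= self.ring_coverage <= 1.0:
            raise ValueError("ring_coverage must lie in [0, 1]")
        lo, hi = kappa_bounds(self.p1, self.p2)
        if not lo - 1e-12 <= self.kappa <= hi + 1e-12:
            raise ValueError(
                f"kappa={self.kappa} infeasible for p1={self.p1}, p2={self.p2}; "
                f"feasible interval is [{lo:.6g}, {hi:.6g}]"
            )


def kappa_bounds(p1: float, p2: float) -> tuple[float, float]:
    """Feasible interval for the overlap parameter.

    The joint probability must respect the Frechet bounds
    ``max(0, p1+p2-1) <= p11 <= min(p1, p2)``; mapping through
    ``p11 = p1*p2 + kappa*(min(p1,p2) - p1*p2)`` gives
    ``kappa_min = (max(0, p1+p2-1) - p1*p2) / (min(p1,p2) - p1*p2)`` and
    ``kappa_max = 1``.  For degenerate marginals (0 or 1) every kappa is
    equivalent; [0, 1] is returned.
    """
    denom = min(p1, p2) - p1 * p2
    if denom <= 0.0:
        return 0.0, 1.0
    lo = (max(0.0, p1 + p2 - 1.0) - p1 * p2) / denom
    return lo, 1.0


def _joint_probabilities(cfg: SimConfig) -> tuple[float, float, float, float]:
    """(p00, p01, p10, p11) of the bivariate Bernoulli."""
    p1, p2 = cfg.p1, cfg.p2
    p11 = p1 * p2 + cfg.kappa * (min(p1, p2) - p1 * p2)
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1.0 - p1 - p2 + p11
    probs = (p00, p01, p10, p11)
    if min(probs) < -1e-12:
        raise ValueError(f"infeasible joint distribution {probs}")
    return tuple(max(0.0, p) for p in probs)  # type: ignore[return-value]


def _place_nuclei(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping (z, y, x) centers by rejection sampling.

    Overlap is tested in anisotropy-corrected space (z scaled by
    r_xy / r_z) with ``placement_clearance`` px of surface-to-surface
    separation so rendered nuclei never touch in any plane.
    """
    nz, ny, nx = cfg.stack_shape
    r, rz = cfg.nucleus_radius, cfg.nucleus_z_radius
    zscale = r / rz
    margin_xy = r + 2.0
    margin_z = rz + 1.0
    if 2 * margin_z >= nz or 2 * margin_xy >= min(ny, nx):
        raise CapacityError(f"stack shape {cfg.stack_shape} too small for nucleus radius {r}")
    centers: list[tuple[float, float, float]] = []
    max_attempts = 500 * cfg.n_cells
    attempts = 0
    while len(centers) < cfg.n_cells:
        if attempts >= max_attempts:
            raise CapacityError(
                f"placed only {len(centers)}/{cfg.n_cells} nuclei after {max_attempts} attempts; "
                "stack too crowded"
            )
        attempts += 1
        z = rng.uniform(margin_z, nz - 1 - margin_z)
        y = rng.uniform(margin_xy, ny - 1 - margin_xy)
        x = rng.uniform(margin_xy, nx - 1 - margin_xy)
        ok = True
        for zc, yc, xc in centers:
            d = math.hypot((z - zc) * zscale, math.hypot(y - yc, x - xc))
            if d < 2 * r + cfg.placement_clearance:
                ok = False
                break
        if ok:
            centers.append((z, y, x))
    return np.asarray(centers, dtype=float)


def simulate_labels(config: SimConfig, place: bool = True) -> pd.DataFrame:
    """Draw per-cell ground truth: identity, activation flags, placement.

    Returns a DataFrame with columns ``cell_id, is_neuron, e1, e2, z, y,
    x, r``.  Neuronal (e1, e2) flags follow the bivariate Bernoulli with
    marginals ``p1``/``p2`` and overlap ``kappa``; glia are never active.

    ``place=False`` skips nucleus placement (coordinates become NaN) for
    label-level studies whose populations are larger than one renderable
    stack; rendering requires placed truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    n = config.n_cells
    is_neuron = rng.random(n) >= config.glia_fraction
    p00, p01, p10, p11 = _joint_probabilities(config)
    u = rng.random(n)
    # categorical draw over (00, 01, 10, 11), in that cumulative order
    e1 = (u >= p00 + p01) & is_neuron
    e2 = (((u >= p00) & (u < p00 + p01)) | (u >= p00 + p01 + p10)) & is_neuron
    if place:
        centers = _place_nuclei(config, rng)
    else:
        centers = np.full((n, 3), np.nan)
    return pd.DataFrame({
        "cell_id": np.arange(n),
        "is_neuron": is_neuron,
        "e1": e1,
        "e2": e2,
        "z": centers[:, 0],
        "y": centers[:, 1],
        "x": centers[:, 2],
        "r": np.full(n, config.nucleus_radius),
    })


def truth_label(e1: bool, e2: bool) -> str:
    """Map activation flags to the catFISH class a perfect reader assigns."""
    if e1 and e2:
        return "double"
    if e1:
        return "cytoplasmic"
    if e2:
        return "nuclear"
    return "negative"


def counts_from_truth(truth: pd.DataFrame, **meta: Optional[str]) -> CellCounts:
    """Tally ground-truth neurons into :class:`CellCounts` (glia excluded)."""
    neurons = truth[truth["is_neuron"]]
    e1 = neurons["e1"].to_numpy(bool)
    e2 = neurons["e2"].to_numpy(bool)
    dob = int(np.sum(e1 & e2))
    cyt = int(np.sum(e1 & ~e2))
    nuc = int(np.sum(~e1 & e2))
    neg = int(np.sum(~e1 & ~e2))
    return CellCounts(neg=neg, nuc=nuc, cyt=cyt, dob=dob, **meta)


@dataclass
class ImageStack:
    """Two-channel 3D intensity grid with voxel spacing.

    ``channels`` has shape (2, z, y, x); channel 0 is the nuclear
    counterstain (Sytox-like), channel 1 the Arc/Cy3 signal.
    """

    channels: np.ndarray
    z_step: float = 0.3
    channel_names: tuple[str, str] = ("counterstain", "arc")

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4 or self.channels.shape[0] != 2:
            raise ValueError("channels must have shape (2, z, y, x)")
        if self.channels.shape[1] < 3:
            raise ValueError("a stack needs at least 3 z-planes")

    @property
    def counterstain(self) -> np.ndarray:
        return self.channels[0]

    @property
    def arc(self) -> np.ndarray:
        return self.channels[1]

    @property
    def n_planes(self) -> int:
        return self.channels.shape[1]


def _nucleus_mask(cfg: SimConfig, zc: float, yc: float, xc: float,
                  shape: tuple[int, int, int]) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Boolean ellipsoid mask in its bounding box, clipped to the stack."""
    r, rz = cfg.nucleus_radius, cfg.nucleus_z_radius
    z0, z1 = max(0, int(zc - rz) - 1), min(shape[0], int(zc + rz) + 2)
    y0, y1 = max(0, int(yc - r) - 1), min(shape[1], int(yc + r) + 2)
    x0, x1 = max(0, int(xc - r) - 1), min(shape[2], int(xc + r) + 2)
    zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
    m = (((zz - zc) / rz) ** 2 + ((yy - yc) / r) ** 2 + ((xx - xc) / r) ** 2) <= 1.0
    return (slice(z0, z1), slice(y0, y1), slice(x0, x1)), m


def _plane_radius(cfg: SimConfig, dz: float) -> float:
    """In-plane nucleus radius at signed z-offset dz from the center."""
    frac = 1.0 - (dz / cfg.nucleus_z_radius) ** 2
    return cfg.nucleus_radius * math.sqrt(frac) if frac > 0 else 0.0


def render_stack(truth: pd.DataFrame, config: SimConfig) -> ImageStack:
    """Render a two-channel stack realizing the ground-truth table.

    Channel 0 (counterstain): neuronal nuclei are dim with multiplicative
    speckle texture; glial nuclei are uniform at ``glia_brightness`` times
    the neuronal mean.  Channel 1 (Arc): epoch-2-active neurons carry two
    bright intranuclear foci spanning ``foci_planes`` consecutive planes;
    epoch-1-active neurons carry a perinuclear ring covering
    ``ring_coverage`` of the perimeter over ``ring_planes`` planes.
    Gaussian noise of scale ``noise_sd`` is added to both channels.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    shape = config.stack_shape
    cs = np.full(shape, config.background, dtype=np.float32)
    arc = np.zeros(shape, dtype=np.float32)

    for row in truth.itertuples(index=False):
        zc, yc, xc = float(row.z), float(row.y), float(row.x)
        box, mask = _nucleus_mask(config, zc, yc, xc, shape)
        if bool(row.is_neuron):
            speckle = rng.normal(0.0, config.speckle_sd, size=mask.shape)
            speckle = ndimage.gaussian_filter(speckle, sigma=1.2)
            # renormalize after smoothing so within-nucleus CV stays near speckle_sd
            s = speckle.std()
            if s > 0:
                speckle *= config.speckle_sd / s
            # floor at 0.6: chromatin texture stays well above background so
            # a nucleus thresholds as one solid component
            intensity = config.neuron_mean * np.clip(1.0 + speckle, 0.75, None)
            cs[box][mask] = intensity[mask]
        else:
            cs[box][mask] = config.glia_brightness * config.neuron_mean
            continue  # glia carry no Arc signal

        if bool(row.e2):
            _render_foci(arc, config, rng, zc, yc, xc)
        if bool(row.e1):
            _render_ring(arc, config, rng, zc, yc, xc)

    if config.noise_sd > 0:
        cs += rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)
        arc += rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)
    np.clip(cs, 0.0, None, out=cs)
    np.clip(arc, 0.0, None, out=arc)
    return ImageStack(np.stack([cs, arc]), z_step=config.z_step)


def _render_foci(arc: np.ndarray, cfg: SimConfig, rng: np.random.Generator,
                 zc: float, yc: float, xc: float) -> None:
    """Two bright discs inside the nucleus, each on foci_planes consecutive planes."""
    nz = arc.shape[0]
    span = max(1, cfg.foci_planes)
    z_lo = int(round(zc)) - span // 2
    z_lo = int(np.clip(z_lo, 0, nz - span))
    # two antipodal positions inside the nucleus, far enough apart that a
    # small median filter cannot merge them into one component
    inner = max(1.0, cfg.nucleus_radius - cfg.foci_radius - 2.0)
    sep = min(7.0, 2.0 * inner)
    ang = rng.uniform(0, 2 * math.pi)
    jy, jx = rng.uniform(-0.5, 0.5, 2)
    pts = [(yc + jy + 0.5 * sep * math.sin(ang), xc + jx + 0.5 * sep * math.cos(ang)),
           (yc + jy - 0.5 * sep * math.sin(ang), xc + jx - 0.5 * sep * math.cos(ang))]
    yy, xx = np.ogrid[0:arc.shape[1], 0:arc.shape[2]]
    for fy, fx in pts:
        disc = (yy - fy) ** 2 + (xx - fx) ** 2 <= cfg.foci_radius ** 2
        for z in range(z_lo, z_lo + span):
            plane = arc[z]
            plane[disc] = np.maximum(plane[disc], cfg.foci_amplitude)


def _render_ring(arc: np.ndarray, cfg: SimConfig, rng: np.random.Generator,
                 zc: float, yc: float, xc: float) -> None:
    """Perinuclear arc of angular fraction ring_coverage on ring_planes planes.

    The ring sits just outside the nucleus cross-section of each plane
    (radial band +0.5..+3.5 px), following the ellipsoid profile.
    """
    nz = arc.shape[0]
    span = max(1, cfg.ring_planes)
    z_lo = int(round(zc)) - span // 2
    z_lo = int(np.clip(z_lo, 0, nz - span))
    a0 = rng.uniform(0, 2 * math.pi)
    width = 2 * math.pi * cfg.ring_coverage
    yy, xx = np.mgrid[0:arc.shape[1], 0:arc.shape[2]]
    dy, dx = yy - yc, xx - xc
    rr = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx) - a0, 2 * math.pi)
    in_angle = theta <= width
    if cfg.ring_coverage >= 1.0:
        in_angle = np.ones_like(in_angle)
    for z in range(z_lo, z_lo + span):
        rp = _plane_radius(cfg, z - zc)
        if rp <= 0:
            rp = 1.0
        band = (rr >= rp + 0.5) & (rr <= rp + 3.5) & in_angle
        plane = arc[z]
        plane[band] = np.maximum(plane[band], cfg.ring_amplitude)


# ---------------------------------------------------------------------------
# Synaptophysin / Map2 mosaics
# ---------------------------------------------------------------------------

def default_roi_layout(roi_size: tuple[int, int] = (90, 120), gap: int = 24,
                       n_cols: int = 4) -> list[tuple[str, list[list[float]]]]:
    """Rectangular stand-in layout for the 14 dendritic-lamina ROIs.

    The real segmentation follows hippocampal anatomy and is hand-drawn;
    here the 14 named ROIs are laid out on a grid with clearance so that
    the ~10% mask enlargement of one ROI cannot reach its neighbours.
    Polygons are (x, y) vertex lists, 0-based, y-down.
    """
    h, w = roi_size
    rois = []
    for i, name in enumerate(ROI_NAMES):
        row, col = divmod(i, n_cols)
        y0 = gap + row * (h + gap)
        x0 = gap + col * (w + gap)
        poly = [[float(x0), float(y0)], [float(x0 + w), float(y0)],
                [float(x0 + w), float(y0 + h)], [float(x0), float(y0 + h)]]
        rois.append((name, poly))
    return rois


def render_mosaic(roi_spec: Sequence[tuple[str, Sequence[Sequence[float]]]],
                  true_fractions: dict[str, float],
                  seed: int = 0,
                  *,
                  shape: Optional[tuple[int, int]] = None,
                  enlargement: float = 0.10,
                  background: float = 20.0,
                  signal: float = 200.0,
                  noise_sd: float = 4.0,
                  map2_fill: float = 0.75):
    """Render a 3-channel 2D mosaic (nuclei, Map2, synaptophysin).

    Each ROI's Map2 channel is filled with a blobby dendritic texture
    covering ~``map2_fill`` of the polygon; the synaptophysin channel is
    painted so that exactly ``true_fractions[name]`` percent of the
    measurement-defined ROI (thresholded Map2 mask grown by
    ``enlargement``) is above threshold.  Returns ``(mosaic, truth)``
    where ``mosaic`` is a :class:`~arcfish.densitometry.Mosaic` and
    ``truth`` maps ROI name to the realized fraction after rasterization.
    """
    from .densitometry import Mosaic, enlarge_mask  # local import to avoid cycle
    from skimage.draw import polygon2mask

    for name, frac in true_fractions.items():
        if not 0.0 <= frac <= 100.0:
            raise ValueError(f"true fraction for ROI {name!r} must lie in [0, 100], got {frac}")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    if shape is None:
        xs = [p[0] for _, poly in roi_spec for p in poly]
        ys = [p[1] for _, poly in roi_spec for p in poly]
        shape = (int(max(ys)) + 25, int(max(xs)) + 25)

    map2 = np.full(shape, background, dtype=np.float32)
    syn = np.full(shape, background, dtype=np.float32)
    nuc = np.full(shape, background, dtype=np.float32)
    # cosmetic scattered nuclei in the counterstain channel
    n_dots = max(20, shape[0] * shape[1] // 4000)
    dz = rng.integers(0, shape[0], n_dots), rng.integers(0, shape[1], n_dots)
    nuc[dz] = signal

    realized: dict[str, float] = {}
    for name, poly in roi_spec:
        pts = np.asarray(poly, dtype=float)
        if pts.shape[0] < 3:
            raise ValueError(f"ROI {name!r} polygon is degenerate")
        # polygon2mask takes (row, col) = (y, x)
        pmask = polygon2mask(shape, pts[:, ::-1])
        if not pmask.any():
            raise ValueError(f"ROI {name!r} rasterizes to an empty mask")
        # blobby dendritic texture: smooth noise, top map2_fill quantile
        field_ = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.5)
        cut = np.quantile(field_[pmask], 1.0 - map2_fill)
        dmask = pmask & (field_ >= cut)
        map2[dmask] = signal

        roi_mask = enlarge_mask(dmask, enlargement=enlargement)
        area = int(roi_mask.sum())
        frac = float(true_fractions.get(name, 0.0))
        n_paint = int(round(frac / 100.0 * area))
        idx = np.flatnonzero(roi_mask.ravel())
        paint = rng.choice(idx, size=n_paint, replace=False)
        syn.ravel()[paint] = signal
        realized[name] = 100.0 * n_paint / area

    if noise_sd > 0:
        for ch in (nuc, map2, syn):
            ch += rng.normal(0.0, noise_sd, size=shape).astype(np.float32)
            np.clip(ch, 0.0, None, out=ch)
    mosaic = Mosaic(np.stack([nuc, map2, syn]),
                    channel_names=("nuclei", "map2", "synaptophysin"))
    return mosaic, realized
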