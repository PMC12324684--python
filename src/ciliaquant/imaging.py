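"""Quantitative immunofluorescence on fixed-cell images.

Mirrors a standard ImageJ-style workflow for ciliary markers: maximum
projection of z-stacks, threshold segmentation of the cilium-marker
channel, skeleton-based length measurement, ciliary and periciliary
intensity measurement with local background subtraction, ciliation
percentage, depletion gating, FDR-based (ROUT) outlier removal and
normalization to the per-replicate control mean.

Conventions: pixel coordinates are 0-based row-major; physical lengths in
µm via ``pixel_size_um``; the periciliary region is a disc of area 5 µm²
(radius sqrt(5/pi) ≈ 1.2616 µm) centred at the ciliary base; discs are
rasterized by pixel-centre inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

PERICILIARY_AREA_UM2 = 5.0
PERICILIARY_RADIUS_UM = float(np.sqrt(PERICILIARY_AREA_UM2 / np.pi))

#: connected-component pixel-size window retained by the segmenter
MIN_COMPONENT_PX = 5
MAX_COMPONENT_PX = 500


@dataclass
class ImageStack:
    """Named fluorescence channels sharing one shape.

    ``channels`` maps channel name -> array of shape (Y, X) or (Z, Y, X).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {name: a.shape for name, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels differ in shape: {shapes}")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"no channel {name!r}; have {sorted(self.channels)}")
        return self.channels[name]


@dataclass
class CiliaryRoi:
    """A segmented cilium: pixel mask, skeleton length and base/tip."""

    mask: np.ndarray                 # boolean, image-shaped
    pixel_size_um: float
    skeleton_length_um: float
    base_yx: tuple[int, int] | None  # skeleton endpoint nearest a nucleus
    tip_yx: tuple[int, int] | None
    base_defined: bool = True

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um ** 2

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class MeasurementRecord:
    """Per-cell intensity measurements with exclusion flags.

    ``concentration`` is the background-subtracted mean in-ROI intensity.
    ``integrated_density`` is the conventional mean x area;
    ``mean_over_area`` additionally records mean intensity / area, matching
    how some figure legends label "integrated density" — both are kept
    under unambiguous names.
    """

    cell_id: str
    condition: str = ""
    replicate: str = ""
    roi_mean: float = np.nan
    background: float = np.nan
    concentration: float = np.nan
    integrated_density: float = np.nan
    mean_over_area: float = np.nan
    area_um2: float = np.nan
    periciliary_mean: float = np.nan
    depletion_intensity: float = np.nan
    normalized: float = np.nan
    flags: list[str] = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        return any(f in ("outlier", "insufficient-depletion", "no-background", "disc-out-of-bounds")
                   for f in self.flags)


def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {k: v for k, v in vars(r).items() if k != "flags"}
        d["flags"] = ";".join(r.flags)
        d["excluded"] = r.excluded
        rows.append(d)
    return pd.DataFrame(rows)


def max_project(stack: ImageStack) -> ImageStack:
    """Per-pixel maximum over z for every channel; 2D channels pass through."""
    projected = {}
    for name, arr in stack.channels.items():
        projected[name] = arr if arr.ndim == 2 else arr.max(axis=0)
    return ImageStack(channels=projected, pixel_size_um=stack.pixel_size_um)


_SKEL_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                          (0, 1), (1, -1), (1, 0), (1, 1)]


def skeleton_path_length_um(skel: np.ndarray, pixel_size_um: float) -> float:
    """Total 8-connected skeleton path length, diagonal steps counting √2."""
    ys, xs = np.nonzero(skel)
    length_px = 0.0
    coords = set(zip(ys.tolist(), xs.tolist()))
    for y, x in coords:
        for dy, dx in _SKEL_NEIGHBOR_OFFSETS:
            if (y + dy, x + dx) in coords:
                length_px += 0.5 * float(np.hypot(dy, dx))  # each edge counted twice
    return length_px * pixel_size_um


def _skeleton_endpoints(skel: np.ndarray) -> list[tuple[int, int]]:
    coords = set(zip(*map(list, np.nonzero(skel))))
    endpoints = []
    for y, x in coords:
        n = sum((y + dy, x + dx) in coords for dy, dx in _SKEL_NEIGHBOR_OFFSETS)
        if n <= 1:
            endpoints.append((y, x))
    return endpoints


def segment_cilia(
    stack: ImageStack,
    cilium_channel: str = "cilium",
    nucleus_channel: str = "nucleus",
    threshold: float | None = None,
    min_px: int = MIN_COMPONENT_PX,
    max_px: int = MAX_COMPONENT_PX,
) -> list[CiliaryRoi]:
    """Threshold segmentation of cilia with skeleton length and base call.

    The cilium-marker channel is median-filtered, thresholded (Otsu unless
    an explicit threshold is given) and split into connected components;
    components within the [min_px, max_px] size window become ROIs. Length
    is the 8-connected skeleton path length (diagonals √2) x pixel size.
    The base is the skeleton endpoint nearer the nearest nucleus centroid;
    without a nucleus channel the base is flagged undefined.
    """
    img = stack.channel(cilium_channel)
    if img.ndim == 3:
        img = img.max(axis=0)
    smoothed = median_filter(img.astype(float), footprint=np.ones((3, 3)))
    if threshold is None:
        if smoothed.max() == smoothed.min():
            return []
        threshold = threshold_otsu(smoothed)
    binary = smoothed > threshold

    nucleus_centroids: list[tuple[float, float]] = []
    have_nuclei = nucleus_channel in stack.channels
    if have_nuclei:
        nuc = stack.channel(nucleus_channel)
        if nuc.ndim == 3:
            nuc = nuc.max(axis=0)
        if nuc.max() > nuc.min():
            nuc_bin = nuc > threshold_otsu(nuc)
            nuc_lab = cc_label(nuc_bin)
            nucleus_centroids = [
                tuple(c) for c in ndimage.center_of_mass(nuc_bin, nuc_lab,
                                                         range(1, nuc_lab.max() + 1))
            ]

    labels = cc_label(binary)
    raw_binary = img > threshold
    rois: list[CiliaryRoi] = []
    for lbl in range(1, labels.max() + 1):
        core = labels == lbl
        if not (min_px <= int(core.sum()) <= max_px):
            continue
        # the median filter erodes thin rod ends; recover them from the raw
        # threshold restricted to the component's neighbourhood
        neighbourhood = ndimage.binary_dilation(core, iterations=2)
        refined = raw_binary & neighbourhood
        refined_labels = cc_label(refined)
        touching = np.unique(refined_labels[core & refined])
        touching = touching[touching > 0]
        mask = np.isin(refined_labels, touching) if len(touching) else core
        n = int(mask.sum())
        if not (min_px <= n <= max_px):
            continue
        skel = skeletonize(mask)
        length = skeleton_path_length_um(skel, stack.pixel_size_um)
        endpoints = _skeleton_endpoints(skel)
        base = tip = None
        base_defined = False
        if len(endpoints) >= 2 and nucleus_centroids:
            def dist_to_nucleus(pt):
                return min(np.hypot(pt[0] - cy, pt[1] - cx) for cy, cx in nucleus_centroids)
            endpoints.sort(key=dist_to_nucleus)
            base, tip = endpoints[0], endpoints[-1]
            base_defined = True
        elif len(endpoints) >= 2:
            base, tip = endpoints[0], endpoints[-1]
        rois.append(CiliaryRoi(
            mask=mask, pixel_size_um=stack.pixel_size_um,
            skeleton_length_um=length, base_yx=base, tip_yx=tip,
            base_defined=base_defined,
        ))
    return rois


def _background_mask(roi: CiliaryRoi, shape: tuple[int, int],
                     occupied: np.ndarray | None = None) -> np.ndarray | None:
    """Equal-dimension region adjacent to the ROI.

    The ROI mask is translated perpendicular to the cilium's principal
    axis by twice its minor width; the first of 8 candidate directions that
    stays inside the image and clear of the ROI (and other occupied
    pixels) is used.
    """
    ys, xs = np.nonzero(roi.mask)
    if len(ys) == 0:
        return None
    coords = np.column_stack([ys, xs]).astype(float)
    centered = coords - coords.mean(axis=0)
    # principal axis from the 2x2 scatter matrix
    cov = centered.T @ centered / max(len(coords) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    minor = evecs[:, 0]  # eigenvector of the smaller eigenvalue
    minor_width_px = max(2.0 * np.sqrt(max(evals[0], 0.25)), 1.0)
    shift_px = int(np.ceil(2.0 * minor_width_px)) + 1

    directions = [minor, -minor]
    major = evecs[:, 1]
    for d in (major, -major, minor + major, minor - major, -minor + major, -minor - major):
        directions.append(d / np.linalg.norm(d))
    for d in directions:
        dy, dx = int(round(d[0] * shift_px)), int(round(d[1] * shift_px))
        ny, nx = ys + dy, xs + dx
        if ny.min() < 0 or nx.min() < 0 or ny.max() >= shape[0] or nx.max() >= shape[1]:
            continue
        candidate = np.zeros(shape, dtype=bool)
        candidate[ny, nx] = True
        forbidden = roi.mask if occupied is None else (roi.mask | occupied)
        if (candidate & forbidden).any():
            continue
        return candidate
    return None


def measure_ciliary(
    roi: CiliaryRoi,
    stack: ImageStack,
    channel: str,
    cell_id: str = "",
    occupied: np.ndarray | None = None,
) -> MeasurementRecord:
    """Background-subtracted ciliary intensity of one ROI.

    Background is the mean intensity of an equal-area region placed
    adjacent to the cilium; concentration = mean in-ROI intensity −
    background. When no adjacent region fits (edge crowding) the record is
    flagged ``no-background`` and the intensity fields stay NaN.
    """
    img = stack.channel(channel)
    if img.ndim == 3:
        img = img.max(axis=0)
    rec = MeasurementRecord(cell_id=cell_id, area_um2=roi.area_um2)
    bg_mask = _background_mask(roi, img.shape, occupied=occupied)
    if bg_mask is None:
        rec.flags.append("no-background")
        return rec
    background = float(img[bg_mask].mean())
    roi_mean = float(img[roi.mask].mean())
    rec.roi_mean = roi_mean
    rec.background = background
    rec.concentration = roi_mean - background
    rec.integrated_density = (roi_mean - background) * roi.area_um2
    rec.mean_over_area = (roi_mean - background) / roi.area_um2 if roi.area_um2 > 0 else np.nan
    return rec


def disc_mask(shape: tuple[int, int], center_yx: tuple[float, float],
              radius_um: float, pixel_size_um: float) -> np.ndarray:
    """Rasterize a disc by pixel-centre inclusion."""
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    r_px = radius_um / pixel_size_um
    return (yy - center_yx[0]) ** 2 + (xx - center_yx[1]) ** 2 <= r_px ** 2


def measure_periciliary(
    roi: CiliaryRoi,
    stack: ImageStack,
    channel: str,
    cell_id: str = "",
) -> MeasurementRecord:
    """Mean intensity in the 5 µm² periciliary disc at the ciliary base.

    Background-subtracted with an adjacent equal-area region, as for the
    ciliary measurement. Discs extending beyond the image are flagged.
    """
    if roi.base_yx is None:
        raise ValueError("ROI has no defined base")
    img = stack.channel(channel)
    if img.ndim == 3:
        img = img.max(axis=0)
    rec = MeasurementRecord(cell_id=cell_id)
    r_px = PERICILIARY_RADIUS_UM / stack.pixel_size_um
    by, bx = roi.base_yx
    if (by - r_px < -0.5 or bx - r_px < -0.5
            or by + r_px > img.shape[0] - 0.5 or bx + r_px > img.shape[1] - 0.5):
        rec.flags.append("disc-out-of-bounds")
        return rec
    disc = disc_mask(img.shape, (by, bx), PERICILIARY_RADIUS_UM, stack.pixel_size_um)
    disc_roi = CiliaryRoi(mask=disc, pixel_size_um=stack.pixel_size_um,
                          skeleton_length_um=0.0, base_yx=None, tip_yx=None,
                          base_defined=False)
    bg_mask = _background_mask(disc_roi, img.shape, occupied=roi.mask)
    if bg_mask is None:
        rec.flags.append("no-background")
        return rec
    rec.background = float(img[bg_mask].mean())
    rec.periciliary_mean = float(img[disc].mean()) - rec.background
    rec.area_um2 = float(disc.sum()) * stack.pixel_size_um ** 2
    return rec


def ciliation_percentage(n_cilia: int, n_nuclei: int) -> float:
    """Percentage of ciliated cells in a field: cilia / nuclei x 100.

    Each cilium is assigned to at most one cell, so the count is capped at
    the nucleus count.
    """
    if n_nuclei < 1:
        raise ValueError("nuclei count must be >= 1")
    return min(n_cilia, n_nuclei) / n_nuclei * 100.0


def deplete_gate(
    records: list[MeasurementRecord],
    knockdown_conditions: set[str] | list[str],
    quantile: float = 0.25,
) -> list[MeasurementRecord]:
    """Flag insufficiently depleted cells in knockdown conditions.

    Within each knockdown condition, the ``quantile`` (default lower
    quartile) of the depletion-marker intensities is the gate; cells whose
    depletion-marker intensity lies *above* it are flagged
    ``insufficient-depletion`` (they still express the target). Values
    equal to the threshold are kept. Control conditions are never flagged.
    """
    knockdown_conditions = set(knockdown_conditions)
    by_condition: dict[str, list[MeasurementRecord]] = {}
    for r in records:
        by_condition.setdefault(r.condition, []).append(r)
    for condition, group in by_condition.items():
        if condition not in knockdown_conditions:
            continue
        vals = np.array([r.depletion_intensity for r in group], dtype=float)
        if np.isnan(vals).all():
            continue
        gate = float(np.nanquantile(vals, quantile))
        for r in group:
            if not np.isnan(r.depletion_intensity) and r.depletion_intensity > gate:
                r.flags.append("insufficient-depletion")
    return records


def rout_outliers(values, q_pct: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """ROUT outlier identification for a constant-mean model.

    Robust outlier removal with a target false-discovery rate Q (percent):
    the location is fit robustly (median), the scale is the robust standard
    deviation of the residuals (RSDR, from the 68.27th percentile of the
    absolute residuals with a small-sample correction), and each point's
    two-tailed t probability of its studentized residual is screened from
    the most extreme inward against Benjamini–Hochberg-style thresholds at
    rate Q. Returns boolean masks ``(kept, removed)`` aligned to the input.

    Needs n >= 3; smaller samples (or Q = 0) keep everything.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    kept = np.ones(n, dtype=bool)
    if n < 3 or q_pct <= 0:
        return kept, ~kept
    center = float(np.median(values))
    residuals = values - center
    k_params = 1  # constant model
    rsdr = float(np.percentile(np.abs(residuals), 68.27)) * n / (n - k_params)
    if rsdr == 0:
        return kept, ~kept
    t_stats = np.abs(residuals) / rsdr
    df = n - k_params
    pvals = 2.0 * stats.t.sf(t_stats, df)
    order = np.argsort(pvals)  # most extreme (smallest p) first
    q = q_pct / 100.0
    removed = np.zeros(n, dtype=bool)
    # step-down from the most extreme point: point i (1-based rank) is an
    # outlier if its p-value clears the FDR threshold and so did all more
    # extreme points before it
    for rank, idx in enumerate(order, start=1):
        threshold = q * rank / n
        if pvals[idx] < threshold:
            removed[idx] = True
        else:
            break
    return ~removed, removed


def normalize_to_control(
    records: list[MeasurementRecord],
    control_condition: str,
    value_attr: str = "concentration",
) -> list[MeasurementRecord]:
    """Divide each value by its replicate's control-group mean.

    After normalization the control group's mean is exactly 1 within each
    replicate. Flagged (excluded) records do not contribute to the control
    mean but are still normalized so nothing is silently dropped. A zero
    control mean is rejected.
    """
    replicates = sorted({r.replicate for r in records})
    for rep in replicates:
        controls = [getattr(r, value_attr) for r in records
                    if r.replicate == rep and r.condition == control_condition
                    and not r.excluded and not np.isnan(getattr(r, value_attr))]
        if not controls:
            raise ValueError(f"no control measurements in replicate {rep!r}")
        mean = float(np.mean(controls))
        if mean == 0:
            raise ValueError(f"zero control mean in replicate {rep!r}")
        for r in records:
            if r.replicate == rep and not np.isnan(getattr(r, value_attr)):
                r.normalized = getattr(r, value_attr) / mean
    return records
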