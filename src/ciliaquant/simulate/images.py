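"""Synthetic multi-channel fluorescence fields with known ground truth.

Each simulated cell contributes a nucleus blob (filled disc in the
nucleus channel) and a rod-shaped cilium (a dilated line segment in the
cilium channel, with the same rod optionally re-deposited at a different
amplitude in a protein-of-interest channel, plus a basal blob in a
vesicle-marker channel). Signal is deposited at a constant per-pixel
amplitude, so the planted per-pixel intensity, the integrated intensity
(amplitude x rod pixel count) and the rod length are all known exactly.
Images are corrupted by an additive uniform background level and Gaussian
noise; both default to zero so exact-recovery checks are possible.

This is deliberately not a photorealistic microscope model (no PSF, no
photon statistics, 2D only); it exists to give the measurement code
objects with known answers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation as grey_dilation, disk as disk_footprint

from ciliaquant.imaging import (
    PERICILIARY_RADIUS_UM,
    CiliaryRoi,
    ImageStack,
    disc_mask,
    skeleton_path_length_um,
)
from ciliaquant.simulate.config import GroundTruth, SimConfig
from skimage.morphology import skeletonize

PLACEMENT_RETRIES = 500


def roi_from_mask(mask: np.ndarray, pixel_size_um: float,
                  base_yx: tuple[int, int] | None = None) -> CiliaryRoi:
    """Wrap a known pixel mask as a measurable ROI (ground-truth masks)."""
    skel = skeletonize(mask)
    return CiliaryRoi(
        mask=mask.astype(bool), pixel_size_um=pixel_size_um,
        skeleton_length_um=skeleton_path_length_um(skel, pixel_size_um),
        base_yx=base_yx, tip_yx=None, base_defined=base_yx is not None,
    )


def simulate_images(
    config: SimConfig,
    n_cells: int,
    cilium_length_um: float = 4.0,
    cilium_length_sd_um: float = 0.8,
    cilium_amplitude: float = 200.0,
    poi_amplitude: float = 120.0,
    basal_amplitude: float = 80.0,
    nucleus_radius_um: float = 2.5,
    nucleus_amplitude: float = 150.0,
    ciliated_fraction: float = 1.0,
    background_level: float = 0.0,
    noise_sd: float = 0.0,
    rod_halfwidth_px: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Place ``n_cells`` nucleus+cilium objects on one field.

    Channels produced: ``cilium`` (membrane/axoneme marker), ``nucleus``,
    ``poi`` (a protein of interest deposited on the same rod at
    ``poi_amplitude`` per pixel) and ``basal`` (a periciliary blob of
    known amplitude at the ciliary base). ``ciliated_fraction`` of the
    cells get a cilium. Raises ``RuntimeError`` when cells cannot be
    placed without overlap inside the retry budget.
    """
    if rng is None:
        rng = config.rng(salt=2)
    shape = tuple(config.image_shape)
    px = config.pixel_size_um
    channels = {name: np.zeros(shape, dtype=float)
                for name in ("cilium", "nucleus", "poi", "basal")}
    occupied = np.zeros(shape, dtype=bool)

    from scipy.ndimage import distance_transform_edt

    nucleus_r_px = nucleus_radius_um / px
    # clearance keeps each cell's periciliary disc and its adjacent
    # background region free of neighbouring structures
    clearance_px = 2.0 * PERICILIARY_RADIUS_UM / px + 10.0
    # distance from every pixel to the nearest already-placed structure
    free_dist = np.full(shape, np.inf)
    rows = []
    for i in range(n_cells):
        placed = False
        for _ in range(PLACEMENT_RETRIES):
            length_um = max(float(rng.normal(cilium_length_um, cilium_length_sd_um)), 1.0)
            length_px = length_um / px
            ciliated = bool(rng.uniform() < ciliated_fraction)
            margin = nucleus_r_px + length_px + 20
            if 2 * margin >= min(shape):
                raise ValueError("image_shape too small for the requested objects")
            cy = float(rng.uniform(margin, shape[0] - margin))
            cx = float(rng.uniform(margin, shape[1] - margin))
            angle = float(rng.uniform(0, 2 * np.pi))
            # base sits just outside the nucleus rim, rod extends outward
            gap_px = 6.0
            by = cy + (nucleus_r_px + gap_px) * np.sin(angle)
            bx = cx + (nucleus_r_px + gap_px) * np.cos(angle)
            ty = by + length_px * np.sin(angle)
            tx = bx + length_px * np.cos(angle)

            nuc_rr, nuc_cc = draw_disk((cy, cx), nucleus_r_px, shape=shape)
            nuc_mask = np.zeros(shape, dtype=bool)
            nuc_mask[nuc_rr, nuc_cc] = True
            rod_mask = np.zeros(shape, dtype=bool)
            if ciliated:
                rr, cc = draw_line(int(round(by)), int(round(bx)),
                                   int(round(ty)), int(round(tx)))
                rod_mask[rr, cc] = True
                rod_mask = grey_dilation(rod_mask, disk_footprint(rod_halfwidth_px))
            structure = nuc_mask | rod_mask
            if float(free_dist[structure].min()) < clearance_px:
                continue
            occupied |= structure
            free_dist = distance_transform_edt(~occupied)
            channels["nucleus"][nuc_mask] += nucleus_amplitude
            n_rod_px = int(rod_mask.sum())
            if ciliated:
                channels["cilium"][rod_mask] += cilium_amplitude
                channels["poi"][rod_mask] += poi_amplitude
                # basal blob fills the 5 µm² periciliary disc exactly,
                # rasterized the same way the measurement rasterizes it
                basal_mask = disc_mask(shape, (round(by), round(bx)),
                                       PERICILIARY_RADIUS_UM, px)
                channels["basal"][basal_mask] += basal_amplitude
            rows.append({
                "cell_id": f"cell_{i:03d}",
                "ciliated": ciliated,
                "nucleus_y": cy, "nucleus_x": cx,
                "base_y": int(round(by)), "base_x": int(round(bx)),
                "tip_y": int(round(ty)), "tip_x": int(round(tx)),
                "length_um": length_um if ciliated else 0.0,
                "rod_px": n_rod_px,
                "cilium_amplitude": cilium_amplitude if ciliated else 0.0,
                "poi_amplitude": poi_amplitude if ciliated else 0.0,
                "basal_amplitude": basal_amplitude if ciliated else 0.0,
                "cilium_integrated": cilium_amplitude * n_rod_px,
                "poi_integrated": poi_amplitude * n_rod_px,
            })
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i} after {PLACEMENT_RETRIES} retries; "
                f"reduce n_cells or enlarge image_shape")

    for name in channels:
        channels[name] += background_level
        if noise_sd > 0:
            channels[name] += rng.normal(0.0, noise_sd, size=shape)
        np.clip(channels[name], 0.0, None, out=channels[name])

    stack = ImageStack(channels=channels, pixel_size_um=px)
    truth = GroundTruth(image_objects=pd.DataFrame(
        rows, columns=["cell_id", "ciliated", "nucleus_y", "nucleus_x", "base_y",
                       "base_x", "tip_y", "tip_x", "length_um", "rod_px",
                       "cilium_amplitude", "poi_amplitude", "basal_amplitude",
                       "cilium_integrated", "poi_integrated"]))
    return stack, truth
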