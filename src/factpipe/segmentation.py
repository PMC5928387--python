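"""Cell and nucleus segmentation of two-channel assay images.

The chain mirrors a high-content screening pipeline: (1) image enhancement —
large-kernel morphological background estimation, subtraction and mild
denoising; (2) multispectral foreground detection — a Gaussian mixture model
fitted to per-pixel log-intensity vectors across channels, with the
dimmest component(s) taken as background and the brighter components as
putative cells; (3) cross-spectral seeded watershed — nuclei detected on the
nuclear-stain channel seed a watershed over a topography built jointly from
both channels, splitting touching cells; (4) rule-based refinement — objects
violating morphological bounds (area, eccentricity, solidity, nucleus/cell
area ratio) are dropped and labels compacted.

All stochastic steps (GMM initialisation) take an explicit seed, so the whole
chain is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.morphology import disk
from skimage.measure import regionprops
from skimage.segmentation import watershed
from sklearn.mixture import GaussianMixture

__all__ = [
    "LabelMaps",
    "MorphologyRules",
    "enhance",
    "detect_foreground_gmm",
    "segment_cells",
    "refine",
    "segment_well",
    "object_table",
]


@dataclass
class LabelMaps:
    """Matched cell and nucleus label images (0 = background).

    Nucleus pixels of label k are a subset of the cell pixels of label k.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray

    @property
    def n_objects(self) -> int:
        return int(self.cell_labels.max())

    def labels(self) -> np.ndarray:
        values = np.unique(self.cell_labels)
        return values[values > 0]


@dataclass
class MorphologyRules:
    """Bounds on per-object morphology; defaults suit the simulator geometry."""

    min_cell_area: float = 150.0
    max_cell_area: float = 2500.0
    min_nucleus_area: float = 30.0
    max_nucleus_area: float = 700.0
    max_eccentricity: float = 0.95
    min_solidity: float = 0.65
    min_nucleus_cell_ratio: float = 0.05
    max_nucleus_cell_ratio: float = 0.85

    def __post_init__(self) -> None:
        for lo, hi, name in [
            (self.min_cell_area, self.max_cell_area, "cell area"),
            (self.min_nucleus_area, self.max_nucleus_area, "nucleus area"),
            (self.min_nucleus_cell_ratio, self.max_nucleus_cell_ratio, "area ratio"),
        ]:
            if lo >= hi:
                raise ValueError(f"{name} bounds inverted: {lo} >= {hi}")


def enhance(
    image: np.ndarray, *, opening_size: int = 96, smooth_sigma: float = 0.5
) -> np.ndarray:
    """Background-subtract and denoise one channel.

    The background field is a grey opening with a large square kernel
    (min-filter then max-filter, cheap and separable) smoothed with a wide
    Gaussian; any residual flat offset is removed as the median of the
    subtracted image (valid while background pixels are the majority).
    Output is clamped at zero.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("enhance expects a 2-D image")
    background = ndimage.minimum_filter(img, size=opening_size)
    background = ndimage.maximum_filter(background, size=opening_size)
    background = ndimage.gaussian_filter(background, opening_size / 4)
    out = img - background
    out -= np.median(out)
    if smooth_sigma > 0:
        out = ndimage.gaussian_filter(out, smooth_sigma)
    return np.clip(out, 0.0, None)


def detect_foreground_gmm(
    channels: Sequence[np.ndarray],
    n_components: int = 3,
    *,
    background_components: int = 1,
    seed: int = 0,
    max_fit_pixels: int = 50_000,
) -> np.ndarray:
    """Foreground mask from a Gaussian mixture over per-pixel channel vectors.

    Components are ranked by total mean log-intensity; the dimmest
    ``background_components`` are background and all brighter components form
    the mask.  The EM fit runs on a random pixel subsample (k-means
    initialised, fixed seed) and classifies every pixel.  A degenerate
    (zero-variance) input yields an all-background mask with a warning.
    """
    if not channels:
        raise ValueError("need at least one channel")
    shape = channels[0].shape
    if any(c.shape != shape for c in channels):
        raise ValueError("channels must share one shape")
    if not 1 <= background_components < n_components:
        raise ValueError("need 1 <= background_components < n_components")
    x = np.stack([np.asarray(c, dtype=float).ravel() for c in channels], axis=1)
    x = np.log1p(np.clip(x, 0.0, None))
    if np.allclose(x.std(axis=0), 0.0):
        warnings.warn("degenerate (constant) input; returning empty foreground mask")
        return np.zeros(shape, dtype=bool)
    rng = np.random.default_rng(seed)
    if x.shape[0] > max_fit_pixels:
        fit_x = x[rng.choice(x.shape[0], max_fit_pixels, replace=False)]
    else:
        fit_x = x
    gmm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        random_state=int(seed) % (2**31),
        n_init=1,
        reg_covar=1e-4,
    )
    try:
        gmm.fit(fit_x)
    except ValueError:
        warnings.warn("mixture fit failed; returning empty foreground mask")
        return np.zeros(shape, dtype=bool)
    order = np.argsort(gmm.means_.sum(axis=1))
    foreground = set(order[background_components:])
    assignment = gmm.predict(x)
    return np.isin(assignment, list(foreground)).reshape(shape)


def _normalize(image: np.ndarray) -> np.ndarray:
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return np.zeros_like(image, dtype=float)
    return (image - lo) / (hi - lo)


def segment_cells(
    nuclear: np.ndarray,
    reporter: np.ndarray,
    mask: np.ndarray,
    *,
    seed_min_distance: int = 10,
    smooth_sigma: float = 2.0,
    nucleus_threshold: float = 0.5,
    min_seed_radius: int = 3,
    mask_opening_radius: int = 2,
    seed: int = 0,
) -> LabelMaps:
    """Cross-spectral seeded watershed.

    Nuclei are the nuclear-channel pixels above ``nucleus_threshold`` times
    the channel's bright level (99th percentile within the mask) — nuclei are
    by far the brightest nuclear-stain structure, so a relative threshold
    separates them from the faint cell body.  The nuclear region is opened
    with a disk of ``min_seed_radius`` so noise speckle and sub-nuclear
    debris cannot seed cells.  Local maxima of the smoothed nuclear channel
    within that region seed a watershed over the inverted sum of the
    min-max-normalised smoothed channels, restricted to the foreground mask.
    Nucleus labels are the nuclear-bright pixels of each cell, which makes
    nucleus-in-cell containment structural.
    """
    nuclear = np.asarray(nuclear, dtype=float)
    reporter = np.asarray(reporter, dtype=float)
    nuclear_sm = ndimage.gaussian_filter(nuclear, smooth_sigma)
    reporter_sm = ndimage.gaussian_filter(reporter, smooth_sigma)
    mask = mask.astype(bool)
    if mask_opening_radius > 0 and mask.any():
        # shave the blurred-edge halo and sever thin bridges to debris before
        # flooding, otherwise watershed annexes them into cell regions
        mask = ndimage.binary_opening(mask, structure=disk(mask_opening_radius))
        mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        empty = np.zeros(nuclear.shape, dtype=np.int32)
        return LabelMaps(empty, empty.copy())

    nuclear_fine = ndimage.gaussian_filter(nuclear, 1.0)
    bright = float(np.percentile(nuclear_fine[mask], 99))
    nuclear_fg = (nuclear_fine > nucleus_threshold * bright) & mask
    if min_seed_radius > 0:
        nuclear_fg = ndimage.binary_opening(nuclear_fg, structure=disk(min_seed_radius))
    if not nuclear_fg.any():
        empty = np.zeros(nuclear.shape, dtype=np.int32)
        return LabelMaps(empty, empty.copy())

    coords = peak_local_max(
        nuclear_sm,
        min_distance=seed_min_distance,
        labels=nuclear_fg.astype(np.int32),
        exclude_border=False,
    )
    if coords.size == 0:
        empty = np.zeros(nuclear.shape, dtype=np.int32)
        return LabelMaps(empty, empty.copy())
    markers = np.zeros(nuclear.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)

    topography = -(_normalize(nuclear_sm) + _normalize(reporter_sm))
    cell_labels = watershed(topography, markers, mask=mask.astype(bool))
    nucleus_labels = np.where(nuclear_fg, cell_labels, 0).astype(np.int32)
    return LabelMaps(cell_labels.astype(np.int32), nucleus_labels)


def _scan_order_relabel(maps: LabelMaps, keep: set[int]) -> LabelMaps:
    """Keep only ``keep`` labels, renumbering 1..k by first pixel in scan order."""
    flat = maps.cell_labels.ravel()
    kept_idx = np.flatnonzero(np.isin(flat, list(keep)))
    uniq, first = np.unique(flat[kept_idx], return_index=True)
    ordered = uniq[np.argsort(first)]
    mapping = np.zeros(int(maps.cell_labels.max()) + 1, dtype=np.int32)
    for new, old in enumerate(ordered, start=1):
        mapping[old] = new
    return LabelMaps(mapping[maps.cell_labels], mapping[maps.nucleus_labels])


def refine(maps: LabelMaps, rules: MorphologyRules | None = None) -> LabelMaps:
    """Drop objects violating any morphology rule; relabel consecutively.

    A cell and its nucleus are removed together; survivors are renumbered
    from 1 in raster-scan order of their first pixel.
    """
    rules = rules or MorphologyRules()
    if maps.n_objects == 0:
        return LabelMaps(maps.cell_labels.copy(), maps.nucleus_labels.copy())
    nucleus_area = np.bincount(
        maps.nucleus_labels.ravel(), minlength=maps.cell_labels.max() + 1
    )
    keep: set[int] = set()
    for prop in regionprops(maps.cell_labels):
        lab = prop.label
        n_area = float(nucleus_area[lab])
        ratio = n_area / prop.area
        if (
            rules.min_cell_area <= prop.area <= rules.max_cell_area
            and rules.min_nucleus_area <= n_area <= rules.max_nucleus_area
            and prop.eccentricity <= rules.max_eccentricity
            and prop.solidity >= rules.min_solidity
            and rules.min_nucleus_cell_ratio <= ratio <= rules.max_nucleus_cell_ratio
        ):
            keep.add(lab)
    if not keep:
        empty = np.zeros_like(maps.cell_labels)
        return LabelMaps(empty, empty.copy())
    return _scan_order_relabel(maps, keep)


def segment_well(
    nuclear_raw: np.ndarray,
    reporter_raw: np.ndarray,
    *,
    n_components: int = 3,
    rules: MorphologyRules | None = None,
    seed_min_distance: int = 10,
    opening_size: int = 96,
    seed: int = 0,
) -> tuple[LabelMaps, np.ndarray, np.ndarray]:
    """Full chain for one well: enhance both channels, detect, segment, refine.

    Returns the refined label maps plus the enhanced nuclear and reporter
    channels (quantification runs on the enhanced reporter).
    """
    nuclear = enhance(nuclear_raw, opening_size=opening_size)
    reporter = enhance(reporter_raw, opening_size=opening_size)
    mask = detect_foreground_gmm([nuclear, reporter], n_components, seed=seed)
    maps = segment_cells(
        nuclear, reporter, mask, seed_min_distance=seed_min_distance, seed=seed
    )
    return refine(maps, rules), nuclear, reporter


def object_table(maps: LabelMaps) -> pd.DataFrame:
    """Per-object morphology table (label, centroid, areas, shape stats)."""
    nucleus_area = np.bincount(
        maps.nucleus_labels.ravel(), minlength=int(maps.cell_labels.max()) + 1
    )
    rows = []
    for prop in regionprops(maps.cell_labels):
        rows.append(
            {
                "label": prop.label,
                "centroid_row": prop.centroid[0],
                "centroid_col": prop.centroid[1],
                "cell_area": int(prop.area),
                "nucleus_area": int(nucleus_area[prop.label]),
                "eccentricity": prop.eccentricity,
                "solidity": prop.solidity,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "centroid_row",
            "centroid_col",
            "cell_area",
            "nucleus_area",
            "eccentricity",
            "solidity",
        ],
    )
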