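"""Ground-truthed synthetic two-channel plate images.

Emulates a nuclear-translocation reporter assay well: adherent cells are
drawn as circular disks with concentric nuclei.  The nuclear-stain channel
carries a bright nuclear disk per cell plus a faint whole-cell body (out-of-
focus light / autofluorescence) so that untransfected cell bodies remain
detectable.  In the reporter channel, each transfected cell distributes
signal between nucleus and cytoplasm such that the nuclear-to-cytoplasmic
mean ratio (NCR) equals a per-cell value sampled from the condition's
log-normal distribution; untransfected cells contribute nothing.  Cells may
touch (the minimum centre separation is below one cell diameter) but nuclei
stay separated so seeded segmentation is well-posed.  Rendering is additive,
then both channels get a Gaussian blur, a flat background, Gaussian read
noise and 16-bit clipping.

Every image set comes with a ground-truth table (cell centres, radii, true
NCR, transfection flag) for benchmarking segmentation and quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "ConditionSpec",
    "SimulationConfig",
    "PlateImageSet",
    "GroundTruthCell",
    "ConfigError",
    "generate_plate",
    "render_cell",
    "well_names",
    "write_plate",
    "read_plate",
]

CHANNELS = ("nuclear_stain", "reporter")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class ConditionSpec:
    """Log-normal per-cell NCR distribution of one condition."""

    ncr_median: float
    ncr_sigma: float = 0.15  # dispersion of log(NCR)

    def __post_init__(self) -> None:
        if self.ncr_median <= 0:
            raise ConfigError("ncr_median must be > 0")
        if self.ncr_sigma < 0:
            raise ConfigError("ncr_sigma must be >= 0")


@dataclass
class SimulationConfig:
    """Assay-well simulation parameters.

    Defaults emulate a moderately confluent 96-well field: ~400 cells of
    radius 12 px with half-radius nuclei, half of them transfected, six
    replicate wells per condition, flat background 100 ADU with 6 ADU read
    noise and a 0.8 px optical blur.
    """

    conditions: dict[str, ConditionSpec] = field(
        default_factory=lambda: {"WT": ConditionSpec(1.0)}
    )
    image_size: tuple[int, int] = (768, 768)
    cells_per_well: int = 400
    cell_radius_mean: float = 12.0
    cell_radius_sd: float = 1.5
    nucleus_radius_fraction: float = 0.5
    transfection_fraction: float = 0.5
    wells_per_condition: int = 6
    background_level: float = 100.0
    noise_sd: float = 6.0
    blur_sigma: float = 0.8
    nuclear_amplitude: float = 600.0
    reporter_cytoplasm_level: float = 300.0
    nuclear_crosstalk: float = 0.08  # faint cell body on the nuclear channel
    min_separation_factor: float = 1.6  # x cell_radius_mean; < 2 so cells touch
    debris_per_well: int = 0
    debris_radius: float = 2.0
    debris_amplitude: float = 400.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.nucleus_radius_fraction < 1.0:
            raise ConfigError(
                f"nucleus_radius_fraction {self.nucleus_radius_fraction} not in (0, 1)"
            )
        if self.cells_per_well < 0:
            raise ConfigError("cells_per_well must be >= 0")
        if self.wells_per_condition < 1:
            raise ConfigError("wells_per_condition must be >= 1")
        if not 0.0 <= self.transfection_fraction <= 1.0:
            raise ConfigError("transfection_fraction must be in [0, 1]")
        if not self.conditions:
            raise ConfigError("at least one condition required")


@dataclass
class PlateImageSet:
    """Two aligned intensity channels of one well."""

    well_id: str
    condition_id: str
    channels: dict[str, np.ndarray]  # CHANNELS -> uint16 arrays, same shape

    def __post_init__(self) -> None:
        shapes = {self.channels[c].shape for c in CHANNELS}
        if len(shapes) != 1:
            raise ValueError("channels must share one shape")


@dataclass(frozen=True)
class GroundTruthCell:
    well_id: str
    center: tuple[float, float]  # (row, col), 0-based
    cell_radius: float
    nucleus_radius: float
    true_ncr: float
    transfected: bool


def well_names(n: int) -> list[str]:
    """First n wells of a 96-well plate in row-major order (A01..H12)."""
    if n > 96:
        raise ConfigError(f"{n} wells exceed a 96-well plate")
    names = [f"{chr(ord('A') + r)}{c + 1:02d}" for r in range(8) for c in range(12)]
    return names[:n]


def _disk_patch(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Boolean disk mask within its clipped bounding box."""
    r0 = max(int(math.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(math.ceil(center[0] + radius)) + 2, shape[0])
    c0 = max(int(math.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(math.ceil(center[1] + radius)) + 2, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return (slice(r0, r1), slice(c0, c1)), mask


def render_cell(
    canvases: Mapping[str, np.ndarray], cell: GroundTruthCell, config: SimulationConfig
) -> None:
    """Add one cell's noise-free signal to the float channel canvases in place.

    Nuclear channel: bright nuclear disk plus a faint whole-cell body.
    Reporter channel (transfected cells only): uniform cytoplasm level and a
    nuclear level of cytoplasm_level * true_ncr, so the nucleus/cytoplasm
    mean ratio equals true_ncr exactly before blur and noise.  Overlapping
    cells sum additively.
    """
    shape = canvases["nuclear_stain"].shape
    box_cell, cell_mask = _disk_patch(shape, cell.center, cell.cell_radius)
    box_nuc, nuc_mask = _disk_patch(shape, cell.center, cell.nucleus_radius)
    canvases["nuclear_stain"][box_cell][cell_mask] += (
        config.nuclear_crosstalk * config.nuclear_amplitude
    )
    canvases["nuclear_stain"][box_nuc][nuc_mask] += config.nuclear_amplitude
    if cell.transfected:
        level = config.reporter_cytoplasm_level
        canvases["reporter"][box_cell][cell_mask] += level
        # top up the nucleus from the cytoplasm level to level * NCR
        canvases["reporter"][box_nuc][nuc_mask] += level * (cell.true_ncr - 1.0)


def _sample_centers(
    rng: np.random.Generator, config: SimulationConfig
) -> np.ndarray:
    """Dart-throwing placement with a hard minimum centre separation."""
    h, w = config.image_size
    margin = config.cell_radius_mean + 3.0 * config.cell_radius_sd
    min_d = config.min_separation_factor * config.cell_radius_mean
    min_d2 = min_d**2
    # occupancy grid with bins of the separation distance: only the 3x3
    # neighbourhood of a candidate can contain a conflicting centre
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    centers: list[tuple[float, float]] = []
    tries = 0
    max_tries = 200 * max(config.cells_per_well, 1)
    while len(centers) < config.cells_per_well and tries < max_tries:
        tries += 1
        cand = (
            rng.uniform(margin, h - margin),
            rng.uniform(margin, w - margin),
        )
        key = (int(cand[0] // min_d), int(cand[1] // min_d))
        ok = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for r, c in grid.get((key[0] + dr, key[1] + dc), ()):
                    if (cand[0] - r) ** 2 + (cand[1] - c) ** 2 < min_d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            centers.append(cand)
            grid.setdefault(key, []).append(cand)
    if len(centers) < config.cells_per_well:
        raise ConfigError(
            f"could not place {config.cells_per_well} cells at separation "
            f"{config.min_separation_factor} x radius; lower the density"
        )
    return np.asarray(centers, dtype=float)


def _simulate_well(
    rng: np.random.Generator,
    config: SimulationConfig,
    well_id: str,
    condition_id: str,
    spec: ConditionSpec,
) -> tuple[PlateImageSet, list[GroundTruthCell]]:
    canvases = {c: np.zeros(config.image_size, dtype=float) for c in CHANNELS}
    cells: list[GroundTruthCell] = []
    if config.cells_per_well > 0:
        centers = _sample_centers(rng, config)
        radii = np.clip(
            rng.normal(config.cell_radius_mean, config.cell_radius_sd, len(centers)),
            3.0,
            None,
        )
        transfected = rng.random(len(centers)) < config.transfection_fraction
        ncrs = spec.ncr_median * np.exp(
            spec.ncr_sigma * rng.standard_normal(len(centers))
        )
        for i, center in enumerate(centers):
            cell = GroundTruthCell(
                well_id=well_id,
                center=(float(center[0]), float(center[1])),
                cell_radius=float(radii[i]),
                nucleus_radius=float(radii[i] * config.nucleus_radius_fraction),
                true_ncr=float(ncrs[i]),
                transfected=bool(transfected[i]),
            )
            render_cell(canvases, cell, config)
            cells.append(cell)
    for _ in range(config.debris_per_well):
        center = (
            rng.uniform(0, config.image_size[0]),
            rng.uniform(0, config.image_size[1]),
        )
        box, mask = _disk_patch(config.image_size, center, config.debris_radius)
        canvases["nuclear_stain"][box][mask] += config.debris_amplitude

    channels = {}
    for name, canvas in canvases.items():
        if config.blur_sigma > 0:
            canvas = ndimage.gaussian_filter(canvas, config.blur_sigma)
        canvas = canvas + config.background_level
        if config.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sd, canvas.shape)
        channels[name] = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)
    return PlateImageSet(well_id, condition_id, channels), cells


def generate_plate(
    config: SimulationConfig,
) -> tuple[list[PlateImageSet], list[GroundTruthCell]]:
    """Simulate ``wells_per_condition`` wells for every configured condition.

    Deterministic given ``config.seed``: the same configuration yields
    bit-identical images and ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_wells = len(config.conditions) * config.wells_per_condition
    names = well_names(n_wells)
    images: list[PlateImageSet] = []
    truth: list[GroundTruthCell] = []
    i = 0
    for condition_id, spec in config.conditions.items():
        for _ in range(config.wells_per_condition):
            image, cells = _simulate_well(rng, config, names[i], condition_id, spec)
            images.append(image)
            truth.extend(cells)
            i += 1
    return images, truth


def write_plate(
    images: Sequence[PlateImageSet],
    truth: Sequence[GroundTruthCell],
    outdir: str | Path,
    plate: str = "P1",
) -> None:
    """Write per-well per-channel TIFFs, the plate layout CSV and ground truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = []
    for image in images:
        for channel in CHANNELS:
            tifffile.imwrite(
                outdir / f"{plate}_{image.well_id}_{channel}.tif",
                image.channels[channel],
            )
        layout.append({"well_id": image.well_id, "condition_id": image.condition_id})
    pd.DataFrame(layout).to_csv(outdir / f"{plate}_layout.csv", index=False)
    pd.DataFrame(
        [
            {
                "well_id": c.well_id,
                "center_row": c.center[0],
                "center_col": c.center[1],
                "cell_radius": c.cell_radius,
                "nucleus_radius": c.nucleus_radius,
                "true_ncr": c.true_ncr,
                "transfected": c.transfected,
            }
            for c in truth
        ]
    ).to_csv(outdir / f"{plate}_ground_truth.csv", index=False)


def read_plate(outdir: str | Path, plate: str = "P1") -> list[PlateImageSet]:
    """Load a plate previously written with :func:`write_plate`."""
    outdir = Path(outdir)
    layout = pd.read_csv(outdir / f"{plate}_layout.csv", dtype=str)
    images = []
    for _, row in layout.iterrows():
        channels = {
            channel: tifffile.imread(outdir / f"{plate}_{row['well_id']}_{channel}.tif")
            for channel in CHANNELS
        }
        images.append(PlateImageSet(row["well_id"], row["condition_id"], channels))
    return images
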