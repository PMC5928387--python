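"""End-to-end pipeline: simulate -> segment -> quantify -> score -> dose-response
-> predict -> stats.

Each stage reads and writes files under the run directory, so a stage can be
re-run standalone (``run_stage``) with results identical to the same stage
inside ``run_full``.  A run manifest records the configuration hash, stage
timings, the file inventory and library versions; with a fixed global seed
every numeric output is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from . import clinical_stats, cohort, ncr_quant, prediction, scoring, segmentation
from .segmentation import MorphologyRules
from .synthetic_imaging import (
    ConditionSpec,
    SimulationConfig,
    generate_plate,
    read_plate,
    write_plate,
)

__all__ = [
    "RunConfig",
    "STAGES",
    "run_full",
    "run_stage",
    "load_config",
    "analyze_plate",
]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "quantify", "score", "dose_response", "predict", "stats")


@dataclass
class SegmentationBlock:
    n_components: int = 3
    seed_min_distance: int = 10
    opening_size: int = 96
    rules: MorphologyRules = field(default_factory=MorphologyRules)


@dataclass
class QuantificationBlock:
    eps: float = 1.0
    min_cells_per_well: int = 50
    gate_k: float = 5.0
    boundary_erosion: int = 2
    cell_boundary_erosion: int = 3


@dataclass
class ScoringBlock:
    wt_condition: str = "WT"
    mt_condition: str = "MT"
    inhibition_mode: str = "absolute"  # or "relative"
    equal_var_ttest: bool = False


@dataclass
class PredictionBlock:
    cohort_source: str = cohort.BUILTIN_COHORT
    literature_csv: str | None = None  # None -> packaged table
    drug_targets_csv: str | None = None
    response_csv: str | None = None


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            conditions={
                "WT": ConditionSpec(1.0),
                "MT": ConditionSpec(3.0),
                "VUS": ConditionSpec(2.0),
            }
        )
    )
    segmentation: SegmentationBlock = field(default_factory=SegmentationBlock)
    quantification: QuantificationBlock = field(default_factory=QuantificationBlock)
    scoring: ScoringBlock = field(default_factory=ScoringBlock)
    prediction: PredictionBlock = field(default_factory=PredictionBlock)
    outdir: str = "runs/default"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.simulation.validate()
        if self.scoring.inhibition_mode not in {"absolute", "relative"}:
            raise ValueError(f"inhibition_mode {self.scoring.inhibition_mode!r}")
        if self.scoring.wt_condition == self.scoring.mt_condition:
            raise ValueError("wt and mt anchor conditions must differ")


def _build(cls, data: dict[str, Any]):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        if key == "conditions":
            value = {k: ConditionSpec(**v) for k, v in value.items()}
        elif key == "rules":
            value = MorphologyRules(**value)
        elif key == "image_size":
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read and schema-validate a YAML run configuration."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    blocks = {
        "simulation": SimulationConfig,
        "segmentation": SegmentationBlock,
        "quantification": QuantificationBlock,
        "scoring": ScoringBlock,
        "prediction": PredictionBlock,
    }
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in blocks:
            kwargs[key] = _build(blocks[key], value or {})
        elif key in {"outdir", "seed", "log_level"}:
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    config = RunConfig(**kwargs)
    config.validate()
    return config


def _config_hash(config: RunConfig) -> str:
    def default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(type(obj))

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyze_plate(
    images,
    *,
    seg_block: SegmentationBlock | None = None,
    quant_block: QuantificationBlock | None = None,
    seed: int = 0,
) -> tuple[dict[str, ncr_quant.ConditionResult], list[ncr_quant.WellNCR], int]:
    """In-memory segment + quantify of simulated wells.

    Returns per-condition results, all well records and the total detected
    cell count.  Equivalent to the segment/quantify stages without file I/O.
    """
    seg = seg_block or SegmentationBlock()
    quant = quant_block or QuantificationBlock()
    wells: list[ncr_quant.WellNCR] = []
    n_detected = 0
    for i, image in enumerate(images):
        maps, _, reporter = segmentation.segment_well(
            image.channels["nuclear_stain"],
            image.channels["reporter"],
            n_components=seg.n_components,
            rules=seg.rules,
            seed_min_distance=seg.seed_min_distance,
            opening_size=seg.opening_size,
            seed=seed + i,
        )
        n_detected += maps.n_objects
        cells = ncr_quant.compute_all_cells(
            maps,
            reporter,
            well_id=image.well_id,
            boundary_erosion=quant.boundary_erosion,
            cell_boundary_erosion=quant.cell_boundary_erosion,
            eps=quant.eps,
        )
        bg_mean, bg_sd = ncr_quant.estimate_background(reporter, maps.cell_labels)
        ncr_quant.gate_transfected(
            cells, background_mean=bg_mean, background_sd=bg_sd, k=quant.gate_k
        )
        wells.append(
            ncr_quant.well_ncr(
                cells,
                well_id=image.well_id,
                condition_id=image.condition_id,
                min_cells=quant.min_cells_per_well,
            )
        )
    conditions: dict[str, ncr_quant.ConditionResult] = {}
    by_condition: dict[str, list[ncr_quant.WellNCR]] = {}
    for well in wells:
        by_condition.setdefault(well.condition_id, []).append(well)
    for condition_id, group in by_condition.items():
        conditions[condition_id] = ncr_quant.condition_ncr(
            group, expected_wells=len(group)
        )
    return conditions, wells, n_detected


def _stage_simulate(config: RunConfig, outdir: Path) -> None:
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    images, truth = generate_plate(sim)
    write_plate(images, truth, outdir)
    logger.info("simulate: %d wells, %d cells", len(images), len(truth))


def _stage_segment(config: RunConfig, outdir: Path) -> None:
    images = read_plate(outdir)
    seg = config.segmentation
    for i, image in enumerate(images):
        maps, _, _ = segmentation.segment_well(
            image.channels["nuclear_stain"],
            image.channels["reporter"],
            n_components=seg.n_components,
            rules=seg.rules,
            seed_min_distance=seg.seed_min_distance,
            opening_size=seg.opening_size,
            seed=config.seed + i,
        )
        tifffile.imwrite(
            outdir / f"P1_{image.well_id}_cell_labels.tif",
            maps.cell_labels.astype(np.uint16),
        )
        tifffile.imwrite(
            outdir / f"P1_{image.well_id}_nucleus_labels.tif",
            maps.nucleus_labels.astype(np.uint16),
        )
        segmentation.object_table(maps).to_csv(
            outdir / f"P1_{image.well_id}_objects.csv", index=False
        )
        logger.info("segment: well %s -> %d cells", image.well_id, maps.n_objects)


def _stage_quantify(config: RunConfig, outdir: Path) -> None:
    images = read_plate(outdir)
    quant = config.quantification
    all_cells: list[pd.DataFrame] = []
    wells: list[ncr_quant.WellNCR] = []
    for image in images:
        maps = segmentation.LabelMaps(
            tifffile.imread(outdir / f"P1_{image.well_id}_cell_labels.tif").astype(np.int32),
            tifffile.imread(outdir / f"P1_{image.well_id}_nucleus_labels.tif").astype(np.int32),
        )
        reporter = segmentation.enhance(
            image.channels["reporter"], opening_size=config.segmentation.opening_size
        )
        cells = ncr_quant.compute_all_cells(
            maps,
            reporter,
            well_id=image.well_id,
            boundary_erosion=quant.boundary_erosion,
            cell_boundary_erosion=quant.cell_boundary_erosion,
            eps=quant.eps,
        )
        bg_mean, bg_sd = ncr_quant.estimate_background(reporter, maps.cell_labels)
        ncr_quant.gate_transfected(
            cells, background_mean=bg_mean, background_sd=bg_sd, k=quant.gate_k
        )
        wells.append(
            ncr_quant.well_ncr(
                cells,
                well_id=image.well_id,
                condition_id=image.condition_id,
                min_cells=quant.min_cells_per_well,
            )
        )
        all_cells.append(ncr_quant.cells_table(cells))
    if not wells or all(not w.valid for w in wells):
        bad = [w.well_id for w in wells if not w.valid]
        raise RuntimeError(f"quantify: too few cells in every well ({bad})")
    pd.concat(all_cells, ignore_index=True).to_csv(outdir / "cells.csv", index=False)
    pd.DataFrame(
        [
            {
                "well_id": w.well_id,
                "condition_id": w.condition_id,
                "median_ncr": w.median_ncr,
                "n_cells": w.n_cells,
                "valid": w.valid,
            }
            for w in wells
        ]
    ).to_csv(outdir / "wells.csv", index=False)
    conditions = []
    frame = pd.DataFrame(
        [{"condition_id": w.condition_id, "well": w} for w in wells]
    )
    for condition_id, grp in frame.groupby("condition_id", sort=False):
        result = ncr_quant.condition_ncr(
            list(grp["well"]), expected_wells=config.simulation.wells_per_condition
        )
        conditions.append(
            {
                "condition_id": condition_id,
                "mean_ncr": result.mean_ncr,
                "sd_ncr": result.sd_ncr,
                "n_wells": result.n_wells,
                "well_medians": json.dumps(result.well_medians),
            }
        )
        logger.info(
            "quantify: condition %s NCR %.3f over %d wells",
            condition_id, result.mean_ncr, result.n_wells,
        )
    pd.DataFrame(conditions).to_csv(outdir / "conditions.csv", index=False)


def _stage_score(config: RunConfig, outdir: Path) -> None:
    frame = pd.read_csv(outdir / "conditions.csv").set_index("condition_id")
    sc = config.scoring
    for anchor in (sc.wt_condition, sc.mt_condition):
        if anchor not in frame.index:
            raise ValueError(f"anchor condition {anchor!r} missing from conditions.csv")
    wt = frame.loc[sc.wt_condition]
    mt = frame.loc[sc.mt_condition]
    rows = []
    for condition_id, row in frame.iterrows():
        if condition_id in (sc.wt_condition, sc.mt_condition):
            continue
        score = scoring.normalize_score(row["mean_ncr"], wt["mean_ncr"], mt["mean_ncr"])
        p = scoring.ttest_vs_wt(
            json.loads(row["well_medians"]),
            json.loads(wt["well_medians"]),
            equal_var=sc.equal_var_ttest,
        )
        rows.append(
            {
                "condition_id": condition_id,
                "score": score,
                "p_value": p,
                "active": scoring.call_activity(score, p),
                "ncr_vus": row["mean_ncr"],
                "ncr_wt": wt["mean_ncr"],
                "ncr_mt": mt["mean_ncr"],
            }
        )
        logger.info("score: %s -> %.1f%% (p=%.3g)", condition_id, score, p)
    pd.DataFrame(rows).to_csv(outdir / "activity.csv", index=False)


def _stage_dose_response(config: RunConfig, outdir: Path) -> None:
    responses = prediction.load_response_fixture(config.prediction.response_csv)
    mode = config.scoring.inhibition_mode
    rows = []
    for result in responses.values():
        inhibited = scoring.call_inhibition(
            result.activity_by_dose, result.untreated_activity, mode=mode
        )
        for dose, activity in zip(result.doses_nm, result.activity_by_dose):
            rows.append(
                {
                    "variant_id": result.variant_id,
                    "drug": result.drug,
                    "dose_nM": dose,
                    "activity": activity,
                    "untreated_activity": result.untreated_activity,
                    "inhibited": inhibited,
                }
            )
        logger.info("dose_response: %s + %s -> inhibited=%s",
                    result.variant_id, result.drug, inhibited)
    pd.DataFrame(rows).to_csv(outdir / "dose_response.csv", index=False)


def _stage_predict(config: RunConfig, outdir: Path) -> None:
    records = cohort.load_cohort(config.prediction.cohort_source)
    literature = prediction.load_literature_rules(config.prediction.literature_csv)
    targets = prediction.load_drug_targets(config.prediction.drug_targets_csv)
    responses = prediction.load_response_fixture(config.prediction.response_csv)
    predictions = prediction.predict_cohort(
        records, prediction.fixture_activities(records), responses, literature, targets
    )
    prediction.write_predictions(predictions, outdir / "predictions.csv")
    n_pos = sum(p.label == "positive" for p in predictions)
    logger.info("predict: %d positive / %d negative", n_pos, len(predictions) - n_pos)


def _stage_stats(config: RunConfig, outdir: Path) -> None:
    records = cohort.load_cohort(config.prediction.cohort_source)
    predictions = pd.read_csv(outdir / "predictions.csv").set_index("patient_id")
    pfs: dict[str, list[float]] = {"positive": [], "negative": []}
    events: dict[str, list[bool]] = {"positive": [], "negative": []}
    for rec in records:
        label = predictions.loc[rec.patient_id, "label"]
        pfs[label].append(rec.pfs_months)
        events[label].append(rec.event)
    summaries, test = clinical_stats.summarize_groups(pfs, events)
    clinical_stats.write_stats(summaries, test, outdir / "stats.json")
    clinical_stats.plot_km(summaries, outdir / "km_curves.png")
    logger.info(
        "stats: medians %s, H=%.3f p=%.4f",
        {s.group: s.median_pfs for s in summaries}, test.h_statistic, test.p_value,
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "quantify": _stage_quantify,
    "score": _stage_score,
    "dose_response": _stage_dose_response,
    "predict": _stage_predict,
    "stats": _stage_stats,
}


def run_stage(name: str, config: RunConfig) -> None:
    """Run one pipeline stage standalone (inputs must exist in the run dir)."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; stages: {list(STAGES)}")
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _STAGE_FUNCS[name](config, outdir)


def run_full(config: RunConfig) -> dict:
    """Run every stage in order; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    timings: dict[str, float] = {}
    for name in STAGES:
        start = time.perf_counter()
        try:
            _STAGE_FUNCS[name](config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - start, 3)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_timings_s": timings,
        "files": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        "versions": {
            "factpipe": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
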