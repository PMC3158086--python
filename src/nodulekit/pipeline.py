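"""End-to-end orchestration: simulate plates, score them, write outputs.

The in-memory helpers (``simulate_well``, ``dose_series_records``,
``irradiance_series_records``) run the generator -> analysis loop without
touching disk and are what the acceptance harness uses; ``run_pipeline``
wraps them with file I/O, logging, and provenance for the CLI.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometry
from .config import RunConfig
from .errors import MissingInputError
from .image import read_culture_image, write_culture_image, write_label_map
from .synthetic.geometry import CultureField, sample_nodule_field
from .synthetic.render import LiveDeadRender, render_livedead
from .viability import (
    WellRecord,
    normalize_viability,
    well_viability,
    wells_to_frame,
)

__all__ = [
    "SimulatedWell",
    "simulate_well",
    "score_well",
    "dose_series_records",
    "irradiance_series_records",
    "run_pipeline",
]

logger = logging.getLogger("nodulekit")


@dataclass
class SimulatedWell:
    well_id: str
    condition: str
    dose: float
    irradiance: float
    atmosphere: str
    render: LiveDeadRender


def simulate_well(
    config: RunConfig,
    *,
    well_id: str,
    condition: str = "treated",
    dose: float = 0.0,
    irradiance: float | None = None,
    atmosphere: str = "normoxic",
    agent: str = "EtNBS",
    seed: int = 0,
) -> SimulatedWell:
    """Render one well of the default nodule-field layout."""
    render_cfg = config.render
    if irradiance is None:
        irradiance = float(render_cfg["irradiance"])
    nodules = sample_nodule_field(
        int(render_cfg["nodule_count"]),
        tuple(render_cfg["diameter_range"]),
        tuple(render_cfg["field_size"]),
        seed,
        rim_depth=float(render_cfg["rim_depth"]),
    )
    fld = CultureField(
        nodules=nodules,
        condition=condition,
        dose=dose,
        irradiance=irradiance,
        atmosphere=atmosphere,
        agent=agent,
    )
    render = render_livedead(
        fld,
        config.dose_response,
        noise=config.noise,
        pixel_size=float(render_cfg["pixel_size"]),
        seed=seed,
        field_size=tuple(render_cfg["field_size"]),
        brightness=float(render_cfg["brightness"]),
    )
    return SimulatedWell(
        well_id=well_id,
        condition=condition,
        dose=dose,
        irradiance=irradiance,
        atmosphere=atmosphere,
        render=render,
    )


def score_well(well: SimulatedWell) -> WellRecord:
    """Apply the image-based viability assay to a simulated well."""
    live = well.render.image["live"]
    dead = well.render.image["dead"]
    live_total, dead_total, viability = well_viability(live, dead)
    return WellRecord(
        well_id=well.well_id,
        condition=well.condition,
        dose=well.dose,
        irradiance=well.irradiance,
        atmosphere=well.atmosphere,
        live_total=live_total,
        dead_total=dead_total,
        viability=viability,
    )


def dose_series_records(
    config: RunConfig,
    *,
    doses: list[float] | None = None,
    replicates: int | None = None,
    base_seed: int = 1,
    atmosphere: str = "normoxic",
    irradiance: float | None = None,
) -> list[WellRecord]:
    """Simulate and score a dose series; wells at dose 0 are NT controls.

    Seeds run consecutively from ``base_seed``, one per well.
    """
    pipeline_cfg = config.pipeline
    if doses is None:
        doses = [float(d) for d in pipeline_cfg["doses"]]
    if replicates is None:
        replicates = int(pipeline_cfg["replicates"])
    records = []
    seed = base_seed
    for dose in doses:
        for rep in range(replicates):
            condition = "NT" if dose == 0 else "treated"
            well = simulate_well(
                config,
                well_id=f"D{dose:g}_r{rep + 1}",
                condition=condition,
                dose=dose,
                irradiance=irradiance,
                atmosphere=atmosphere,
                seed=seed,
            )
            records.append(score_well(well))
            seed += 1
    return normalize_viability(records)


def irradiance_series_records(
    config: RunConfig,
    *,
    irradiances: list[float] | None = None,
    fluence: float | None = None,
    replicates: int | None = None,
    base_seed: int = 41,
    nt_wells: int | None = None,
) -> list[WellRecord]:
    """Simulate and score a fixed-fluence irradiance series plus NT controls."""
    pipeline_cfg = config.pipeline
    if irradiances is None:
        irradiances = [float(e) for e in pipeline_cfg["irradiances"]]
    if fluence is None:
        fluence = float(pipeline_cfg["series_fluence"])
    if replicates is None:
        replicates = int(pipeline_cfg["replicates"])
    if nt_wells is None:
        nt_wells = replicates
    records = []
    seed = base_seed
    for irr in irradiances:
        for rep in range(replicates):
            well = simulate_well(
                config,
                well_id=f"E{irr:g}_r{rep + 1}",
                condition="treated",
                dose=fluence,
                irradiance=irr,
                seed=seed,
            )
            records.append(score_well(well))
            seed += 1
    for rep in range(nt_wells):
        well = simulate_well(
            config, well_id=f"NT_r{rep + 1}", condition="NT", seed=seed
        )
        records.append(score_well(well))
        seed += 1
    return normalize_viability(records)


def _simulate_stage(config: RunConfig, out: Path, seed: int) -> Path:
    """Write the default dose-series plate as TIFFs plus a plate CSV."""
    plate_rows = []
    pipeline_cfg = config.pipeline
    seed_i = seed
    for dose in pipeline_cfg["doses"]:
        for rep in range(int(pipeline_cfg["replicates"])):
            condition = "NT" if dose == 0 else "treated"
            well = simulate_well(
                config,
                well_id=f"D{dose:g}_r{rep + 1}",
                condition=condition,
                dose=float(dose),
                seed=seed_i,
            )
            img_path = out / "images" / f"{well.well_id}.tif"
            write_culture_image(well.render.image, img_path)
            write_label_map(
                well.render.labels, out / "images" / f"{well.well_id}_labels.tif"
            )
            truth = pd.DataFrame(
                [
                    {
                        "id": t.id,
                        "center_x": t.center_xy[0],
                        "center_y": t.center_xy[1],
                        "diameter": t.diameter,
                        "core_fraction": t.core_fraction,
                        "core_viability": t.core_viability,
                        "periphery_viability": t.periphery_viability,
                        "true_viability": t.true_viability,
                    }
                    for t in well.render.truth
                ]
            )
            truth.to_csv(out / "images" / f"{well.well_id}_truth.csv", index=False)
            plate_rows.append(
                {
                    "well_id": well.well_id,
                    "condition": condition,
                    "dose": float(dose),
                    "irradiance": well.irradiance,
                    "atmosphere": well.atmosphere,
                    "image_path": str(img_path.relative_to(out)),
                }
            )
            seed_i += 1
    plate = pd.DataFrame(plate_rows)
    plate.to_csv(out / "plate.csv", index=False)
    logger.info("simulated %d wells into %s", len(plate_rows), out)
    return out / "plate.csv"


def _viability_stage(config: RunConfig, out: Path, plate_csv: Path) -> Path:
    if not plate_csv.exists():
        raise MissingInputError(f"plate table not found: {plate_csv}")
    plate = pd.read_csv(plate_csv)
    pixel_size = float(config.render["pixel_size"])
    records = []
    for row in plate.itertuples():
        image = read_culture_image(plate_csv.parent / row.image_path, pixel_size)
        live_total, dead_total, viability = well_viability(
            image["live"], image["dead"]
        )
        records.append(
            WellRecord(
                well_id=row.well_id,
                condition=row.condition,
                dose=row.dose,
                irradiance=row.irradiance,
                atmosphere=row.atmosphere,
                live_total=live_total,
                dead_total=dead_total,
                viability=viability,
            )
        )
    normalize_viability(records)
    path = out / "wells.csv"
    wells_to_frame(records).to_csv(path, index=False)
    logger.info("scored %d wells -> %s", len(records), path)
    return path


def _nodules_stage(config: RunConfig, out: Path, plate_csv: Path) -> Path:
    if not plate_csv.exists():
        raise MissingInputError(f"plate table not found: {plate_csv}")
    plate = pd.read_csv(plate_csv)
    pixel_size = float(config.render["pixel_size"])
    min_diameter = float(config.pipeline["min_diameter"])
    frames = []
    for row in plate.itertuples():
        image = read_culture_image(plate_csv.parent / row.image_path, pixel_size)
        labels = morphometry.segment_nodules(
            image["live"], image["dead"], pixel_size, min_diameter
        )
        records, _ = morphometry.nodule_metrics(
            labels, image["live"], image["dead"], pixel_size
        )
        frame = morphometry.records_to_frame(records)
        frame.insert(0, "well_id", row.well_id)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    path = out / "nodules.csv"
    table.to_csv(path, index=False)

    usable = table[(table["volume"] > 0) & (table["live_dead_ratio"] > 0)]
    if len(usable) >= 3:
        fit = morphometry.fit_powerlaw(
            usable["volume"].to_numpy(), usable["live_dead_ratio"].to_numpy()
        )
        with open(out / "powerlaw.json", "w") as fh:
            json.dump(
                {
                    "prefactor": fit.prefactor,
                    "exponent": fit.exponent,
                    "r_squared": fit.r_squared,
                    "n": fit.n,
                },
                fh,
                indent=2,
            )
    logger.info("measured %d nodules -> %s", len(table), path)
    return path


def run_pipeline(
    config: RunConfig,
    command: str,
    out_dir: str | Path,
    *,
    seed: int = 1,
) -> Path:
    """Execute a named pipeline stage (or ``all``) into ``out_dir``.

    Writes the resolved configuration and a log file alongside the stage
    outputs; identical config and seed produce identical CSV outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.dump(out / "resolved_config.yaml")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        if command in ("simulate", "all"):
            plate_csv = _simulate_stage(config, out, seed)
        else:
            plate_csv = out / "plate.csv"
        if command in ("viability", "all"):
            _viability_stage(config, out, plate_csv)
        if command in ("nodules", "all"):
            _nodules_stage(config, out, plate_csv)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
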