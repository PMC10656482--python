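"""End-to-end orchestration: scenes + land-use rasters → report bundle.

``run_full_analysis`` executes, for every configured epoch: the four
indicator rasters (greenness, wetness, dryness, heat), optional water
masking, min–max normalization, the PCA composite (RSEI) and the five-level
quality map; and for every consecutive epoch pair: the land-use transfer
matrix, the dynamics report (structure change, single and comprehensive
dynamic degrees) and per-indicator change maps. Everything is written as
TIFF/CSV/JSON under ``out_dir`` and also returned as one dict. Runs are
deterministic given the config.
"""
from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .errors import RseikitError
from .indices import compute_ibi, compute_ndbsi, compute_ndvi, compute_si, compute_wet
from .io import (
    read_landuse,
    read_scene,
    write_area_table,
    write_index,
    write_raster,
    write_transfer_matrix,
)
from .landuse import class_areas, dynamics_report, transfer_matrix, validate_transfer_matrix
from .rsei import (
    apply_water_mask,
    change_classes,
    classify_levels,
    level_area_stats,
    normalize_01,
    pca_composite,
)
from .thermal import AtmosphericParams, ThermalCalibration, emissivity_from_ndvi, lst_pipeline
from .types import WATER

log = logging.getLogger("rseikit")

__all__ = ["run_full_analysis", "epoch_rsei"]

#: change-map sign convention per indicator
_SIGNS = {"NDVI": "benefit", "WET": "benefit", "RSEI": "benefit", "NDBSI": "cost", "LST": "cost"}


def epoch_rsei(scene, landuse, cfg: RunConfig):
    """Indicator stack + RSEI for one epoch. Returns (indicators, result, levels)."""
    cal = ThermalCalibration(**cfg.thermal.model_dump())
    ndvi = compute_ndvi(scene)
    wet = compute_wet(scene)
    ndbsi = compute_ndbsi(compute_si(scene), compute_ibi(scene))

    if cfg.atmosphere.emissivity_mode == "ndvi_threshold":
        emissivity = emissivity_from_ndvi(ndvi)
    else:
        emissivity = cfg.atmosphere.emissivity
    atm = AtmosphericParams(
        l_up=cfg.atmosphere.l_up,
        l_down=cfg.atmosphere.l_down,
        tau=cfg.atmosphere.tau,
        emissivity=emissivity,
    )
    lst = lst_pipeline(scene, cal, atm, kelvin_offset=cfg.kelvin_offset)

    stack = [ndvi, wet, ndbsi, lst]
    if cfg.water_mask and landuse is not None:
        stack = apply_water_mask(stack, landuse.class_mask(WATER))
    normalized = [normalize_01(idx, cfg.clip_percentiles) for idx in stack]
    result = pca_composite(normalized, pc1_transform=cfg.pc1_transform)
    levels = classify_levels(result.rsei)
    indicators = {"NDVI": ndvi, "WET": wet, "NDBSI": ndbsi, "LST": lst}
    return indicators, result, levels


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the whole workflow described by a validated RunConfig.

    Any stage error aborts with a stage-tagged message and removes the
    partially written output directory.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = cfg.model_dump_json()
    log.info(
        "run start: version=%s seed=%d config_sha256=%s",
        __version__, cfg.seed, hashlib.sha256(cfg_json.encode()).hexdigest()[:12],
    )
    stage = "setup"
    try:
        bundle: dict = {
            "version": __version__,
            "seed": cfg.seed,
            "config": json.loads(cfg_json),
            "epochs": {},
            "pairs": {},
        }
        per_epoch: dict = {}
        for ep in cfg.epochs:
            stage = f"epoch {ep.year}"
            scene = read_scene(ep.scene, sensor=ep.sensor, epoch=ep.year)
            lu = read_landuse(ep.landuse, epoch=ep.year) if ep.landuse else None
            indicators, result, levels = epoch_rsei(scene, lu, cfg)
            per_epoch[str(ep.year)] = (lu, indicators, result)

            edir = out / f"epoch_{ep.year}"
            for name, idx in indicators.items():
                write_index(edir / f"{name.lower()}.tif", idx)
            write_index(edir / "rsei.tif", result.rsei)
            write_raster(edir / "rsei_levels.tif", levels, nodata=0)
            cell_area = lu.cell_area if lu is not None else 0.0009
            level_stats = level_area_stats(levels, cell_area)
            level_stats.to_csv(edir / "rsei_level_stats.csv", index=False)
            epoch_report = {
                "rsei": result.report(),
                "levels": level_stats.to_dict(orient="records"),
                "mean_indicators": {
                    n: round(float(np.nanmean(idx.values)), 4)
                    for n, idx in indicators.items()
                },
            }
            if lu is not None:
                areas = class_areas(lu)
                write_area_table(edir / "class_areas.csv", areas)
                epoch_report["class_areas_km2"] = {
                    k: round(v, 3) for k, v in areas.named().items()
                }
            (edir / "report.json").write_text(json.dumps(epoch_report, indent=1))
            bundle["epochs"][str(ep.year)] = epoch_report

        for ep_a, ep_b in zip(cfg.epochs, cfg.epochs[1:]):
            stage = f"pair {ep_a.year}-{ep_b.year}"
            key = f"{ep_a.year}_{ep_b.year}"
            pdir = out / f"pair_{key}"
            lu_a, ind_a, res_a = per_epoch[str(ep_a.year)]
            lu_b, ind_b, res_b = per_epoch[str(ep_b.year)]
            pair_report: dict = {}

            if lu_a is not None and lu_b is not None:
                tm = transfer_matrix(lu_a, lu_b)
                write_transfer_matrix(pdir / "transfer_matrix.csv", tm)
                areas_a, areas_b = class_areas(lu_a), class_areas(lu_b)
                validation = validate_transfer_matrix(tm, areas_a, areas_b)
                years = abs(float(int(ep_b.year) - int(ep_a.year))) or 1.0
                dyn = dynamics_report(areas_a, areas_b, years, cfg.grading_by_code())
                (pdir / "dynamics.json").write_text(json.dumps(dyn.to_dict(), indent=1))
                pair_report["dynamics"] = dyn.to_dict()
                pair_report["transfer_validation"] = {
                    c.name: {"passed": c.passed, "max_residual": c.max_residual}
                    for c in validation.checks
                }

            changes = {}
            for name in ("NDVI", "WET", "NDBSI", "LST"):
                cm = change_classes(
                    ind_a[name], ind_b[name], epsilon=cfg.epsilon, sign=_SIGNS[name]
                )
                changes[name] = cm.summary().to_dict(orient="records")
            cm = change_classes(res_a.rsei, res_b.rsei, epsilon=cfg.epsilon, sign="benefit")
            write_raster(pdir / "rsei_change_categories.tif", cm.categories, nodata=-128)
            changes["RSEI"] = cm.summary().to_dict(orient="records")
            pair_report["change_classes"] = changes
            (pdir / "report.json").write_text(json.dumps(pair_report, indent=1))
            bundle["pairs"][key] = pair_report

        stage = "bundle"
        (out / "report.json").write_text(json.dumps(bundle, indent=1))
        log.info("run complete: %s", out / "report.json")
        return bundle
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise RseikitError(f"[{stage}] {exc}") from exc


def run_synthetic_demo(
    out_dir, seed: int = 0, shape: tuple[int, int] = (120, 120)
) -> dict:
    """Generate a three-epoch synthetic series, write it to disk, and run
    the full analysis on it. Returns the report bundle."""
    from .config import EpochConfig
    from .io import write_landuse, write_scene
    from .synth import default_scene_spec, generate_epoch_series

    out = Path(out_dir)
    data_dir = out / "inputs"
    spec = default_scene_spec(shape)
    plans = [spec.transitions, spec.transitions]
    series = generate_epoch_series(
        spec, plans, seed=seed, epochs=[2000, 2010, 2020]
    )
    epochs = []
    for lu, scene, _g in series:
        lu_path = data_dir / f"landuse_{lu.epoch}.tif"
        scene_path = data_dir / f"scene_{lu.epoch}.tif"
        write_landuse(lu_path, lu)
        write_scene(scene_path, scene)
        epochs.append(
            EpochConfig(
                year=lu.epoch, scene=str(scene_path), landuse=str(lu_path), sensor="TM"
            )
        )
    cfg = RunConfig(epochs=epochs, out_dir=str(out / "results"), seed=seed)
    return run_full_analysis(cfg)
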