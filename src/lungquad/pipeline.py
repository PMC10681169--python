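"""End-to-end orchestration: image -> masks -> quadrats -> statistics -> proximity.

A run is driven by a :class:`RunConfig` that is fully serialisable; the
emitted ``run_config.yaml`` in the output directory re-executes to
bit-identical outputs (all stochastic steps are seeded). Specimens are
analysed independently and only then aggregated per group, matching
per-animal-then-per-cohort reporting.

Inputs are either synthetic scene configs (grouped cohorts with known
ground truth) or calibrated TIFF paths with optional airway-annotation
masks. Every threshold, grid and convention actually used is logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import yaml

from .color_masking import ColorModel, HsvRange, classify
from .dispersion_stats import (DispersionSummary, compare_groups, classify_pattern,
                               summarize)
from .grid_quadrat import GridSpec, quantify
from .image_io import CalibratedImage, read_image, read_mask, write_mask
from .periairway_proximity import (DEFAULT_MIN_LUMEN_AREA_UM2, DEFAULT_RADIUS_UM,
                                   AirwayGeometry, airways_from_annotation,
                                   compare_proximity, derive_airways,
                                   proximity_fraction)
from .synthetic_scene import SceneConfig, generate_scene

__all__ = ["SpecimenInput", "RunConfig", "SpecimenResult", "run", "analyze_image",
           "load_run_config"]

log = logging.getLogger("lungquad")


@dataclass(frozen=True)
class SpecimenInput:
    """One specimen: either a TIFF path (+ calibration) or a scene config."""

    name: str
    group: str
    image_path: str | None = None
    microns_per_pixel: float | None = None
    airway_annotation_path: str | None = None
    scene: SceneConfig | None = None

    def __post_init__(self) -> None:
        if (self.image_path is None) == (self.scene is None):
            raise ValueError(f"specimen {self.name!r}: exactly one of image_path or scene required")
        if self.image_path is not None and self.microns_per_pixel is None:
            raise ValueError(
                f"specimen {self.name!r}: microns_per_pixel is mandatory for image inputs"
            )


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs."""

    specimens: tuple[SpecimenInput, ...]
    grid: GridSpec = GridSpec()
    color_model: ColorModel = ColorModel()
    proximity_radius_um: float = DEFAULT_RADIUS_UM
    min_lumen_area_um2: float = DEFAULT_MIN_LUMEN_AREA_UM2
    variance_convention: Literal["sample", "population"] = "sample"
    test: Literal["welch_t", "permutation"] = "welch_t"
    rng_seed: int = 0
    out_dir: str = "lungquad_run"
    log_level: str = "INFO"
    save_masks: bool = False


@dataclass
class SpecimenResult:
    name: str
    group: str
    summary: DispersionSummary
    pattern: str
    proximity: "ProximityResultDict"
    quadrat_csv: str


ProximityResultDict = dict


def analyze_image(
    image: CalibratedImage,
    color_model: ColorModel,
    grid: GridSpec,
    proximity_radius_um: float = DEFAULT_RADIUS_UM,
    min_lumen_area_um2: float = DEFAULT_MIN_LUMEN_AREA_UM2,
    airways: AirwayGeometry | None = None,
    variance_convention: Literal["sample", "population"] = "sample",
    image_id: str = "",
):
    """Single-specimen analysis; returns (masks, table, summary, proximity).

    The library-level entry point the CLI subcommands and ``run`` share.
    When no airway annotation is given, lumens are derived as area-filtered
    holes in the tissue mask.
    """
    masks = classify(image, color_model)
    table = quantify(masks, image, grid, image_id=image_id)
    summary = summarize(table, variance_convention=variance_convention)
    if airways is None:
        airways = derive_airways(masks.tissue_mask, min_lumen_area_um2,
                                 image.microns_per_pixel)
    prox = proximity_fraction(masks.particle_mask, airways, proximity_radius_um,
                              image.microns_per_pixel)
    return masks, table, summary, prox


def _load_specimen(spec: SpecimenInput) -> tuple[CalibratedImage, AirwayGeometry | None]:
    if spec.scene is not None:
        scene = generate_scene(spec.scene)
        return scene.image, None
    image = read_image(spec.image_path, spec.microns_per_pixel)
    airways = None
    if spec.airway_annotation_path:
        airways = airways_from_annotation(read_mask(spec.airway_annotation_path))
    return image, airways


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Emits per-specimen quadrat CSVs, a per-specimen summary JSON, group
    comparisons of D and of the peri-airway fraction (when two groups are
    present), the echoed config, and a log file. Any stage failure raises
    with a stage-attributed message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        _write_run_config(config, out / "run_config.yaml")
        log.info("grid: %s um cells, coverage >= %s, signal_mode=%s",
                 config.grid.cell_size_um, config.grid.coverage_threshold,
                 config.grid.signal_mode)
        log.info("proximity radius: %s um; lumen area floor: %s um^2; "
                 "variance convention: %s; test: %s",
                 config.proximity_radius_um, config.min_lumen_area_um2,
                 config.variance_convention, config.test)

        results: list[SpecimenResult] = []
        for spec in config.specimens:
            try:
                image, airways = _load_specimen(spec)
                masks, table, summary, prox = analyze_image(
                    image, config.color_model, config.grid,
                    config.proximity_radius_um, config.min_lumen_area_um2,
                    airways, config.variance_convention, image_id=spec.name,
                )
            except Exception as exc:
                raise RuntimeError(f"stage failure for specimen {spec.name!r}: {exc}") from exc
            csv_path = out / f"quadrats_{spec.name}.csv"
            table.to_csv(csv_path)
            if config.save_masks:
                write_mask(out / f"particle_mask_{spec.name}.tiff", masks.particle_mask)
                write_mask(out / f"tissue_mask_{spec.name}.tiff", masks.tissue_mask)
            pattern = classify_pattern(summary)
            log.info("specimen %s (%s): n_cells=%d mean=%.4f var=%.4f D=%.4f cv=%.4f "
                     "pattern=%s periairway_fraction=%.4f",
                     spec.name, spec.group, summary.n_cells, summary.mean,
                     summary.variance, summary.index_of_dispersion,
                     summary.coefficient_of_variation, pattern, prox.fraction)
            results.append(SpecimenResult(
                name=spec.name, group=spec.group, summary=summary,
                pattern=pattern, proximity=prox.to_dict(), quadrat_csv=str(csv_path),
            ))

        payload = {
            "specimens": [
                {"name": r.name, "group": r.group, "pattern": r.pattern,
                 "dispersion": r.summary.to_dict(), "proximity": r.proximity,
                 "quadrat_csv": r.quadrat_csv}
                for r in results
            ]
        }
        groups = sorted({r.group for r in results})
        if len(groups) == 2:
            ga = [r for r in results if r.group == groups[0]]
            gb = [r for r in results if r.group == groups[1]]
            if len(ga) >= 2 and len(gb) >= 2:
                d_cmp = compare_groups(
                    [r.summary.index_of_dispersion for r in ga],
                    [r.summary.index_of_dispersion for r in gb],
                    test=config.test, statistic_name="index_of_dispersion",
                    rng_seed=config.rng_seed,
                )
                p_cmp = compare_proximity(
                    [r.proximity["fraction"] for r in ga],
                    [r.proximity["fraction"] for r in gb],
                    test=config.test, rng_seed=config.rng_seed,
                )
                payload["group_comparisons"] = {
                    "groups": groups,
                    "index_of_dispersion": d_cmp.to_dict(),
                    "periairway_fraction": p_cmp.to_dict(),
                }
                log.info("group comparison (%s vs %s): D p=%.6g, periairway p=%.6g",
                         groups[0], groups[1], d_cmp.p_value, p_cmp.p_value)
        (out / "report.json").write_text(json.dumps(payload, indent=2))
        log.info("run complete: %s", out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


# ---------------------------------------------------------------------------
# config (de)serialisation
# ---------------------------------------------------------------------------

def _write_run_config(config: RunConfig, path: Path) -> None:
    path.write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=False))


def _config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["specimens"] = [
        {k: v for k, v in dataclasses.asdict(s).items() if v is not None}
        for s in config.specimens
    ]
    return d


def load_run_config(path: str | Path) -> RunConfig:
    """Rebuild a RunConfig from an emitted (or hand-written) YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    specimens = []
    for s in raw.pop("specimens"):
        scene = s.pop("scene", None)
        if scene is not None:
            for key in ("airway_radius_range_um",):
                if key in scene and isinstance(scene[key], list):
                    scene[key] = tuple(scene[key])
            scene = SceneConfig(**scene)
        specimens.append(SpecimenInput(scene=scene, **s))
    grid = raw.pop("grid", None)
    if isinstance(grid, dict):
        if isinstance(grid.get("origin_px"), list):
            grid["origin_px"] = tuple(grid["origin_px"])
        grid = GridSpec(**grid)
    cm = raw.pop("color_model", None)
    if isinstance(cm, dict):
        for rule in ("particle_rule", "autofluor_rule"):
            if isinstance(cm.get(rule), dict):
                cm[rule] = HsvRange(**cm[rule])
        cm = ColorModel(**cm)
    kwargs = dict(raw)
    if grid is not None:
        kwargs["grid"] = grid
    if cm is not None:
        kwargs["color_model"] = cm
    return RunConfig(specimens=tuple(specimens), **kwargs)
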