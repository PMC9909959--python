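"""End-to-end orchestration: simulate -> ROI -> %BTV / maps -> tables.

A run is driven by a :class:`RunConfig` (YAML-loadable).  One master seed is
fanned out per (bone, side) stage through ``SeedSequence`` derivation, so a
rerun with the same config and seed reproduces every output byte-for-byte;
the manifest records a content hash per file.  Log output goes to stderr
and to ``run.log``; data files never contain timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import densitometry, pattern_classify, phantom, stats, subchondral_roi, surface_mapping
from ._utils import derive_seed, sha256_file
from .imageio import write_btv_profile, write_density_map, write_table

log = logging.getLogger("ctoam")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Materialized configuration of one pipeline run."""

    out_dir: str = "ctoam_run"
    seed: int = 0
    n_per_group: int = 15
    bones: tuple[str, ...] = ("distal_femur", "tibial_plateau")
    sides: tuple[str, ...] = ("right", "left")
    # phantom geometry/profile overrides
    grid_shape: tuple[int, int, int] = (48, 48, 40)
    spacing_mm: tuple[float, float, float] = (0.625, 0.625, 0.625)
    shell_thickness_mm: float = 10.0
    noise_sd_hu: float = 30.0
    # detection / classification knobs
    threshold_hu: int = surface_mapping.HIGH_DENSITY_THRESHOLD_HU
    min_area_mm2: float = surface_mapping.MIN_AREA_MM2
    big_area_mm2: float = pattern_classify.BIG_AREA_MM2
    # statistics options
    alpha: float = 0.05
    welch: bool = False
    paired: bool = False
    correction: str | None = None
    # output options
    write_volumes: bool = False
    write_maps: bool = False
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bones", "sides", "grid_shape", "spacing_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_manifest_dict(self) -> dict:
        return dataclasses.asdict(self)


def _setup_logging(out_dir: Path, verbosity: str) -> None:
    log.setLevel(verbosity.upper())
    log.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(stream)
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    log.addHandler(fh)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir, config.verbosity)
    outputs: list[Path] = []

    for bone in config.bones:
        profiles: dict[str, list[densitometry.BTVProfile]] = {"control": [], "judo": []}
        detections: dict[str, list[surface_mapping.HighDensityAreas]] = {"control": [], "judo": []}
        labels: dict[str, list[pattern_classify.PatternLabel]] = {"control": [], "judo": []}

        for side in config.sides:
            stage = f"simulate[{bone},{side}]"
            try:
                base = phantom.PhantomSpec(
                    grid_shape=config.grid_shape,
                    spacing_mm=config.spacing_mm,
                    bone=bone,
                    side=side,
                    shell_thickness_mm=config.shell_thickness_mm,
                    noise_sd_hu=config.noise_sd_hu,
                )
                stage_seed = derive_seed(
                    config.seed, config.bones.index(bone), config.sides.index(side)
                )
                controls, judos = phantom.make_cohort(config.n_per_group, base, seed=stage_seed)
            except Exception as exc:  # noqa: BLE001
                raise StageError(stage, exc) from exc
            log.info("%s: %d + %d phantoms", stage, len(controls), len(judos))

            for group, cohort in (("control", controls), ("judo", judos)):
                for i, (vol, truth) in enumerate(cohort):
                    stem = f"{group}_{bone}_{side}_{i:02d}"
                    try:
                        roi = subchondral_roi.extract_roi(
                            vol, bone, side, plane_z=truth.epiphyseal_plane_z
                        )
                        labels_grid = densitometry.bin_voxels(vol, roi)
                        profile = densitometry.btv_profile(
                            labels_grid, vol.spacing_mm, bone=bone, side=side
                        )
                        dmap = surface_mapping.project_density(vol, roi)
                        grid = surface_mapping.nine_regions(dmap)
                        areas = surface_mapping.detect_high_density(
                            dmap, config.threshold_hu, config.min_area_mm2, regions=grid
                        )
                        label = pattern_classify.classify(
                            areas, grid, bone, big_area_mm2=config.big_area_mm2
                        )
                    except Exception as exc:  # noqa: BLE001
                        raise StageError(f"analyse[{stem}]", exc) from exc
                    profiles[group].append(profile)
                    detections[group].append(areas)
                    labels[group].append(label)

                    outputs.append(
                        write_btv_profile(profile, out_dir / "profiles" / f"{stem}_btv.csv")
                    )
                    if config.write_volumes:
                        paths = phantom.save_phantom(vol, truth, out_dir / "phantoms", stem)
                        outputs.extend(Path(p) for p in paths.values())
                    if config.write_maps:
                        outputs.extend(
                            write_density_map(
                                dmap,
                                png_path=out_dir / "maps" / f"{stem}.png",
                                csv_path=out_dir / "maps" / f"{stem}.csv",
                            )
                        )

        n_knees = config.n_per_group * len(config.sides)
        try:
            freq = {
                group: surface_mapping.region_frequency(detections[group], n_knees)
                for group in ("judo", "control")
            }
            freq_table = pd.DataFrame(
                {
                    "region": freq["judo"]["region"],
                    "judo_count": freq["judo"]["count"],
                    "judo_percent": freq["judo"]["percent"],
                    "control_count": freq["control"]["count"],
                    "control_percent": freq["control"]["percent"],
                }
            )
            outputs.append(write_table(freq_table, out_dir / "tables" / f"frequency_{bone}.csv"))

            pat = {
                group: pattern_classify.pattern_table(labels[group], n_knees)
                for group in ("judo", "control")
            }
            pat_table = pd.DataFrame(
                {
                    "pattern": pat["judo"]["pattern"],
                    "judo_count": pat["judo"]["count"],
                    "judo_percent": pat["judo"]["percent"],
                    "control_count": pat["control"]["count"],
                    "control_percent": pat["control"]["percent"],
                }
            )
            outputs.append(write_table(pat_table, out_dir / "tables" / f"patterns_{bone}.csv"))

            report = stats.btv_report(
                profiles["judo"],
                profiles["control"],
                group_names=("judo", "control"),
                alpha=config.alpha,
                welch=config.welch,
                paired=config.paired,
                correction=config.correction,
            )
            for side, df in report.between.items():
                outputs.append(
                    write_table(df, out_dir / "tables" / f"btv_comparison_{bone}_{side}.csv")
                )
            for group, df in report.within.items():
                outputs.append(
                    write_table(df, out_dir / "tables" / f"btv_left_right_{bone}_{group}.csv")
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"tables[{bone}]", exc) from exc

    manifest = {
        "config": config.to_manifest_dict(),
        "files": {
            str(p.relative_to(out_dir)): sha256_file(p) for p in sorted(set(outputs))
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %d files", len(manifest["files"]))
    return manifest
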