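"""Configuration-driven orchestration: read -> segment -> quantify -> export.

A run is fully described by a YAML configuration (validated into
:class:`RunConfig`) plus the input files; given the same config, seed and
inputs the output CSVs are byte-identical.  Execution streams one imaging
position at a time — at most one position's stack is resident in memory —
and the run log records per-stage counts, package version and a hash of the
normalized configuration, which is also embedded in every output file
header.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import __version__
from . import imgio, quantify, segment_nuclei, segment_nucleoli
from .segment_nuclei import NucleiParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "config_hash"]


class NucleiConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    backend: Literal["global", "watershed", "external"] = "watershed"
    min_area_px: int = 200
    drop_border: bool = True
    min_seed_separation: int = 10
    smoothing_sigma: float = 2.0
    external_mask_dir: Path | None = None

    def params(self) -> NucleiParams:
        return NucleiParams(
            min_area_px=self.min_area_px,
            drop_border=self.drop_border,
            min_seed_separation=self.min_seed_separation,
            smoothing_sigma=self.smoothing_sigma,
        )


class NucleoliConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    backend: Literal["classifier", "threshold", "external"] = "classifier"
    model_path: Path | None = None
    median_radius: int = 1
    min_area_px: int = 5
    external_mask_dir: Path | None = None


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    input_folder: Path
    pattern: str = "*_w-*_s-*_p-*.*"
    channel_roles: dict[str, int]
    frame_interval_min: float = 5.0
    conditions: dict[str, str] = {}
    nuclei: NucleiConfig = NucleiConfig()
    nucleoli: NucleoliConfig = NucleoliConfig()
    output_dir: Path
    per_cell_table: bool = False
    seed: int = 0

    @field_validator("frame_interval_min")
    @classmethod
    def _positive_interval(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("frame_interval_min must be > 0")
        return v

    @field_validator("channel_roles")
    @classmethod
    def _exactly_three_roles(cls, v: dict[str, int]) -> dict[str, int]:
        missing = [r for r in imgio.REQUIRED_ROLES if r not in v]
        extra = [r for r in v if r not in imgio.REQUIRED_ROLES]
        if missing or extra:
            raise ValueError(
                f"channel_roles must define exactly {list(imgio.REQUIRED_ROLES)}; "
                f"missing={missing}, unknown={extra}"
            )
        return v

    @model_validator(mode="after")
    def _paths_resolvable(self) -> "RunConfig":
        if not self.input_folder.is_dir():
            raise ValueError(f"input_folder does not exist: {self.input_folder}")
        if self.nucleoli.backend == "classifier":
            if self.nucleoli.model_path is None:
                raise ValueError("nucleoli.backend=classifier requires nucleoli.model_path")
            if not self.nucleoli.model_path.is_file():
                raise ValueError(f"classifier model not found: {self.nucleoli.model_path}")
        if self.nuclei.backend == "external" and (
            self.nuclei.external_mask_dir is None
            or not self.nuclei.external_mask_dir.is_dir()
        ):
            raise ValueError("nuclei.backend=external requires an existing external_mask_dir")
        if self.nucleoli.backend == "external" and (
            self.nucleoli.external_mask_dir is None
            or not self.nucleoli.external_mask_dir.is_dir()
        ):
            raise ValueError("nucleoli.backend=external requires an existing external_mask_dir")
        return self

    def to_yaml(self) -> str:
        """Canonical normalized echo of this config."""
        def enc(obj):
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in sorted(obj.items())}
            return obj
        return yaml.safe_dump(enc(self.model_dump()), sort_keys=True)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:12]


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected (listed in the error); defaults are filled
    in, so the returned object is the fully normalized configuration.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return RunConfig(**raw)


def _segment_nucleoli_movie(cfg: RunConfig, classifier, stack: imgio.ImageStack, stem: str):
    nc = cfg.nucleoli
    if nc.backend == "external":
        paths = sorted(nc.external_mask_dir.glob(f"{stem}_nucleoli_f*.tif"))
        return segment_nuclei.load_external_masks(
            paths, stack.pixels.shape[2:], stack.n_frames,
            NucleiParams(min_area_px=nc.min_area_px, drop_border=False),
        )
    marker = stack.channel("nucleolar_marker")
    out = []
    for frame in marker:
        if nc.backend == "classifier":
            prob = segment_nucleoli.predict_probability(classifier, frame)
            out.append(
                segment_nucleoli.probability_to_instances(
                    prob, median_radius=nc.median_radius, min_area_px=nc.min_area_px
                )
            )
        else:
            out.append(
                segment_nucleoli.threshold_instances(frame, min_area_px=nc.min_area_px)
            )
    return out


def _segment_nuclei_movie(cfg: RunConfig, stack: imgio.ImageStack, stem: str):
    params = cfg.nuclei.params()
    if cfg.nuclei.backend == "external":
        paths = sorted(cfg.nuclei.external_mask_dir.glob(f"{stem}_nuclei_f*.tif"))
        return segment_nuclei.load_external_masks(
            paths, stack.pixels.shape[2:], stack.n_frames, params
        )
    fn = (
        segment_nuclei.segment_nuclei_global
        if cfg.nuclei.backend == "global"
        else segment_nuclei.segment_nuclei_watershed
    )
    return [fn(frame, params) for frame in stack.channel("nuclear_stain")]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis for every position file in the input folder.

    Returns a run-log dict (also written as JSON to the output directory)
    with per-stage counts and output paths.  Any stage failure aborts with
    the stage name and the offending file in the exception message.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    (out_dir / "config_normalized.yaml").write_text(config.to_yaml())

    files = imgio.list_position_files(config.input_folder, config.pattern)

    classifier = None
    if config.nucleoli.backend == "classifier":
        classifier = segment_nucleoli.PixelClassifier.load(config.nucleoli.model_path)

    all_features = []
    grouping: dict[str, str] = {}
    log: dict = {
        "version": __version__,
        "config_hash": chash,
        "n_files": len(files),
        "files": [],
    }
    for path in files:
        stem = path.name.split(".")[0]
        try:
            meta = imgio.parse_position_name(path, config.conditions)
        except imgio.NameParseError as e:
            raise RuntimeError(f"stage=parse file={path.name}: {e}") from e
        condition = meta.condition if meta.condition is not None else meta.well
        try:
            stack = imgio.read_stack(
                path, config.channel_roles, config.frame_interval_min, config.conditions
            )
        except (OSError, ValueError) as e:
            raise RuntimeError(f"stage=read file={path.name}: {e}") from e
        try:
            nuclei_maps = _segment_nuclei_movie(config, stack, stem)
        except Exception as e:
            raise RuntimeError(f"stage=segment_nuclei file={path.name}: {e}") from e
        try:
            nucleoli_maps = _segment_nucleoli_movie(config, classifier, stack, stem)
            regions = [
                quantify.derive_regions(nuclei_maps[f], nucleoli_maps[f])
                for f in range(stack.n_frames)
            ]
        except Exception as e:
            raise RuntimeError(f"stage=segment_nucleoli file={path.name}: {e}") from e
        features = quantify.extract_features(stack, regions, image_id=stem)
        all_features.append(features)
        grouping[stem] = condition
        log["files"].append(
            {
                "file": path.name,
                "condition": condition,
                "n_frames": stack.n_frames,
                "n_cells_frame0": int(len(regions[0].cell_labels)),
                "n_nucleoli_discarded": int(sum(r.n_discarded for r in regions)),
            }
        )
        logger.info("processed %s (%d frames)", path.name, stack.n_frames)

    features = pd.concat(all_features, ignore_index=True)
    series = quantify.ratio_series(features, grouping, config.frame_interval_min)
    nuc_series = quantify.nuclear_intensity_series(
        features, grouping, config.frame_interval_min
    )

    comment = f"config_hash={chash} nucleoshuttle={__version__}"
    ratios_path = imgio.write_results(series.table, out_dir / "ratios.csv", comment)
    nuclear_path = imgio.write_results(
        nuc_series.table, out_dir / "nuclear_intensity.csv", comment
    )
    outputs = {"ratios": str(ratios_path), "nuclear_intensity": str(nuclear_path)}
    if config.per_cell_table:
        per_cell = out_dir / "per_cell.csv"
        with open(per_cell, "w", newline="") as fh:
            fh.write(f"# {comment}\n")
            features.to_csv(fh, index=False)
        outputs["per_cell"] = str(per_cell)

    log["n_cells_total"] = int(features[["image", "cell"]].drop_duplicates().shape[0])
    log["n_excluded_cell_frames"] = series.n_excluded
    log["outputs"] = outputs
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return log
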