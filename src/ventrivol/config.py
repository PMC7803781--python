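"""Run configuration, seed fan-out, and pipeline orchestration.

A single YAML file (strictly validated: unknown keys are rejected) drives
the whole pipeline: simulate -> prelabel -> build-dataset -> train ->
segment -> agree.  One global seed is fanned out to per-stage sub-seeds
through ``numpy.random.SeedSequence(seed).generate_state(...)`` (each
reduced mod 2^31), so every stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .agreement import PairedSeries, agreement_report
from .dataset import SagittalROI, build_dataset
from .model import SliceSegmenter, TrainConfig, train
from .prelabel import BlobCriteria, prelabel_volume
from .volume_io import LabelVolume, USVolume, write_nrrd
from .volumetrics import dsc_3d, measure_volumes, segment_volume

log = logging.getLogger(__name__)

_STAGES = ("simulate", "prelabel", "dataset", "train", "segment", "agree")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def plane_count(rotation_step_deg: float, range_deg: float = 180.0) -> int:
    """Number of rotational contouring planes: range / step.

    Documents the arithmetic of the manual rotational protocol (e.g. a
    15-degree step over a 180-degree range gives 12 contouring planes);
    the step must divide the range exactly.
    """
    if rotation_step_deg <= 0 or range_deg <= 0:
        raise ValueError("angles must be positive")
    ratio = range_deg / rotation_step_deg
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"rotation step {rotation_step_deg} does not divide range {range_deg}"
        )
    return int(round(ratio))


@dataclass
class RunConfig:
    """Top-level pipeline configuration."""

    seed: int = 0
    out_dir: str = "run"
    n_days: int = 4
    growth_per_day: float = 1.15
    intervention_day: Optional[int] = None
    shrink_per_day: float = 0.8
    phantom: ph.PhantomSpec = field(default_factory=ph.PhantomSpec)
    criteria: BlobCriteria = field(default_factory=BlobCriteria)
    training: TrainConfig = field(default_factory=TrainConfig)
    roi_margin: int = 2
    train_on: str = "truth"  # "truth" | "prelabel"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.train_on not in ("truth", "prelabel"):
            raise ConfigError(f"train_on must be 'truth' or 'prelabel', got {self.train_on!r}")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the global seed."""
        idx = _STAGES.index(stage)
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGES))
        return int(state[idx] % (2**31))


def _from_dict(cls, data: dict, path: str = ""):
    """Strict dataclass construction: unknown keys raise ConfigError."""
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {path or cls.__name__}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        nested = {
            "phantom": ph.PhantomSpec,
            "criteria": BlobCriteria,
            "training": TrainConfig,
        }.get(name)
        if nested is not None and isinstance(value, dict):
            kwargs[name] = _from_dict(nested, value, path=f"{path}.{name}" if path else name)
        else:
            if name in ("ventricle_axes_mm",) and isinstance(value, list):
                value = tuple(tuple(v) for v in value)
            elif name in ("grid_dims",) and isinstance(value, list):
                value = tuple(value)
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(RunConfig, data)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> str:
    """Execute all stages in dependency order; returns the run directory.

    The manifest records the config, the seed, and a SHA-256 of every
    stage output, so re-running with the same config and seed can be
    checked for bit-exact reproduction.  A stage failure raises
    ``PipelineError`` naming the stage; earlier outputs are preserved.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config_hash":
                      hashlib.sha256(repr(config).encode()).hexdigest()}
    artifacts: dict = {}
    try:
        _stage_simulate(config, out, artifacts, manifest)
        _stage_prelabel(config, out, artifacts, manifest)
        _stage_train(config, out, artifacts, manifest)
        _stage_segment(config, out, artifacts, manifest)
        _stage_agree(config, out, artifacts, manifest)
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "stage", "unknown")
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _record(manifest, stage, paths):
    manifest["stages"][stage] = {os.path.basename(p): _sha256(p) for p in paths}


def _stage_simulate(config, out, art, manifest):
    try:
        spec = ph.TrajectorySpec(
            base=dataclasses.replace(config.phantom, seed=config.stage_seed("simulate")),
            n_days=config.n_days,
            growth_per_day=config.growth_per_day,
            intervention_day=config.intervention_day,
            shrink_per_day=config.shrink_per_day,
        )
        series = ph.generate_trajectory(spec)
        paths, rows = [], []
        for day, (vol, lab) in enumerate(series):
            vol.patient_id = lab.patient_id = "phantom"
            p1 = write_nrrd(vol, os.path.join(out, f"us{day:03d}.nrrd"))
            p2 = write_nrrd(lab, os.path.join(out, f"us{day:03d}_label.nrrd"))
            paths += [p1, p2]
            for side in ("left", "right", "total"):
                rows.append({"acquisition_index": day, "side": side,
                             "true_volume_cm3": lab.meta["true_volume_cm3"][side]})
        truth = os.path.join(out, "truth.csv")
        pd.DataFrame(rows).to_csv(truth, index=False)
        art["series"] = series
        _record(manifest, "simulate", paths + [truth])
    except Exception as exc:
        raise PipelineError("simulate", exc) from exc


def _stage_prelabel(config, out, art, manifest):
    try:
        paths = []
        art["prelabels"] = []
        for day, (vol, _) in enumerate(art["series"]):
            res = prelabel_volume(vol, config.criteria)
            art["prelabels"].append(res)
            paths.append(
                write_nrrd(res.label, os.path.join(out, f"us{day:03d}_prelabel.nrrd"))
            )
        _record(manifest, "prelabel", paths)
    except Exception as exc:
        raise PipelineError("prelabel", exc) from exc


def _stage_train(config, out, art, manifest):
    try:
        series = art["series"]
        labels = (
            [lab for _, lab in series]
            if config.train_on == "truth"
            else [r.label for r in art["prelabels"]]
        )
        rois = [ph.auto_roi(lab, margin=config.roi_margin) for _, lab in series]
        art["rois"] = rois
        ds = build_dataset(
            [v for v, _ in series], labels, rois, seed=config.stage_seed("dataset")
        )
        art["dataset"] = ds
        tc = dataclasses.replace(config.training, seed=config.stage_seed("train"))
        model, metrics = train(ds, tc)
        art["model"] = model
        mpath = os.path.join(out, "model.npz")
        model.save(mpath)
        lpath = os.path.join(out, "training_log.csv")
        pd.DataFrame([dataclasses.asdict(m) for m in metrics]).to_csv(lpath, index=False)
        _record(manifest, "train", [mpath, lpath])
    except Exception as exc:
        raise PipelineError("train", exc) from exc


def _stage_segment(config, out, art, manifest):
    try:
        rows, paths = [], []
        for day, ((vol, lab), roi) in enumerate(zip(art["series"], art["rois"])):
            seg, auto_meas, metrics = segment_volume(art["model"], vol, roi,
                                                     reference=lab)
            paths.append(write_nrrd(seg, os.path.join(out, f"us{day:03d}_seg.nrrd")))
            manual_meas = measure_volumes(lab, method="manual")
            for m in auto_meas + manual_meas:
                rows.append(dataclasses.asdict(m))
            rows[-1]["dsc_3d"] = metrics.dsc_3d if metrics else float("nan")
        vpath = os.path.join(out, "volumes.csv")
        pd.DataFrame(rows).to_csv(vpath, index=False)
        _record(manifest, "segment", paths + [vpath])
    except Exception as exc:
        raise PipelineError("segment", exc) from exc


def _stage_agree(config, out, art, manifest):
    try:
        df = pd.read_csv(os.path.join(config.out_dir, "volumes.csv"))
        from .volumetrics import VentricleMeasurement

        def to_meas(rows):
            return [
                VentricleMeasurement(str(r.patient_id), int(r.acquisition_index),
                                     r.side, r.method, float(r.volume_cm3))
                for r in rows.itertuples()
            ]

        sided = df[df.side != "total"]
        series = PairedSeries.from_measurements(
            to_meas(sided[sided.method == "manual"]),
            to_meas(sided[sided.method == "auto"]),
        )
        report = agreement_report(series)
        rpath = os.path.join(out, "report.json")
        with open(rpath, "w") as fh:
            fh.write(report.to_json())
        art["report"] = report
        _record(manifest, "agree", [rpath])
    except Exception as exc:
        raise PipelineError("agree", exc) from exc
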