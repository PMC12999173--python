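"""End-to-end orchestration: strict run configs, staged execution, manifests.

A run config (YAML) names the stages to execute and one parameter block per
stage; unknown keys anywhere are rejected before anything runs.  Each stage
writes its outputs under the run directory and the manifest records a
checksum per input and output, so re-running an identical config reproduces
identical checksums for the deterministic stages and completed stages are
skipped when their inputs and parameters are unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import io as azio
from .benchmark import DEFAULT_MATCH_TOLERANCE_UM, parameter_sweep
from .core import VolumetricImage
from .psf import DEFAULT_RL_ITERATIONS, extract_psf, richardson_lucy
from .segment import DetectionParams, segment_stack, tile_and_stitch, upsample_xy
from .spatial import SpatialParams, annotate_spatial, sample_report
from .synthetic import Layout, SyntheticSpec, simulate

log = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "extract_psf", "deconvolve", "segment", "stats",
                "benchmark")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    stages: list[str]
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    extract_psf: dict = field(default_factory=dict)
    deconvolve: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    benchmark: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        allowed = {"stages", "seed", "log_level", *KNOWN_STAGES}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        stages = raw.get("stages")
        if not stages or not isinstance(stages, list):
            raise ConfigError("config must list at least one stage under 'stages'")
        bad = [s for s in stages if s not in KNOWN_STAGES]
        if bad:
            raise ConfigError(f"unknown stage(s): {', '.join(bad)}")
        cfg = cls(stages=list(stages), seed=int(raw.get("seed", 0)),
                  log_level=str(raw.get("log_level", "INFO")))
        for stage in KNOWN_STAGES:
            setattr(cfg, stage, dict(raw.get(stage, {})))
        _validate_blocks(cfg)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(azio.read_yaml(path))


_BLOCK_KEYS = {
    "simulate": {"spec", "stack", "truth"},
    "extract_psf": {"beads", "psf", "crop_size", "isolation_radius_um", "min_peak"},
    "deconvolve": {"input", "psf", "output", "iterations"},
    "segment": {"detect", "measure", "params", "table", "tiled"},
    "stats": {"table", "params", "report", "annotated"},
    "benchmark": {"image", "truth", "thresholds", "tolerances",
                  "match_tolerance_um", "output"},
}


def _validate_blocks(cfg: RunConfig) -> None:
    for stage in KNOWN_STAGES:
        block = getattr(cfg, stage)
        unknown = set(block) - _BLOCK_KEYS[stage]
        if unknown:
            raise ConfigError(
                f"stage '{stage}': unknown key(s): {', '.join(sorted(unknown))}")
    if "segment" in cfg.stages:
        params = cfg.segment.get("params", {})
        if "threshold" not in params or "noise_tolerance" not in params:
            raise ConfigError(
                "stage 'segment': params must set threshold and noise_tolerance")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _spec_from_block(block: dict, seed: int) -> SyntheticSpec:
    spec = dict(block)
    if "layout" in spec and spec["layout"] is not None:
        lay = spec["layout"]
        spec["layout"] = Layout(names=tuple(lay["names"]),
                                kind=lay.get("kind", "slabs"),
                                axis=lay.get("axis", "x"),
                                radius_um=lay.get("radius_um"))
    if "shape" in spec:
        spec["shape"] = tuple(spec["shape"])
    if "spacing" in spec:
        spec["spacing"] = tuple(spec["spacing"])
    spec.setdefault("seed", seed)
    return SyntheticSpec(**spec)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


def run_pipeline(config: RunConfig, workdir) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    Stage outputs with a recorded, matching stage key (parameter hash +
    input checksums) are reused rather than recomputed.
    """
    os.makedirs(workdir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
        "version": _package_version(),
        "stages": {},
    }
    for stage in config.stages:
        t0 = time.time()
        try:
            inputs, outputs = _STAGE_FN[stage](config, str(workdir))
        except Exception as exc:
            raise StageFailure(stage, exc) from exc
        manifest["stages"][stage] = {
            "inputs": {p: _sha256(p) for p in inputs},
            "outputs": {p: _sha256(p) for p in outputs},
            "started": t0,
            "finished": time.time(),
        }
    with open(os.path.join(str(workdir), "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _package_version() -> str:
    from . import __version__
    return __version__


def _cache_key(stage: str, params: dict, input_paths: list[str]) -> str:
    payload = {"stage": stage, "params": params,
               "inputs": {p: _sha256(p) for p in input_paths}}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _cached(workdir: str, stage: str, key: str, outputs: list[str]) -> bool:
    marker = os.path.join(workdir, f".{stage}.key")
    if not os.path.exists(marker) or not all(os.path.exists(p) for p in outputs):
        return False
    try:
        recorded = json.load(open(marker))
    except (json.JSONDecodeError, OSError):
        os.unlink(marker)   # corrupt cache marker: invalidate
        return False
    return recorded.get("key") == key


def _mark(workdir: str, stage: str, key: str) -> None:
    with open(os.path.join(workdir, f".{stage}.key"), "w") as fh:
        json.dump({"key": key}, fh)


def _stage_simulate(cfg: RunConfig, wd: str):
    block = cfg.simulate
    stack_path = os.path.join(wd, block.get("stack", "stack.tif"))
    truth_path = os.path.join(wd, block.get("truth", "truth.csv"))
    labels_path = os.path.join(wd, "compartments.tif")
    outputs = [stack_path, truth_path, labels_path]
    key = _cache_key("simulate", block | {"seed": cfg.seed}, [])
    if _cached(wd, "simulate", key, outputs):
        return [], outputs
    spec = _spec_from_block(block.get("spec", {}), cfg.seed)
    stack, truth, domain = simulate(spec)
    azio.write_stack(stack_path, stack)
    azio.write_truth(truth_path, truth)
    azio.write_labels(labels_path, domain)
    _mark(wd, "simulate", key)
    return [], outputs


def _stage_extract_psf(cfg: RunConfig, wd: str):
    block = cfg.extract_psf
    beads = os.path.join(wd, block["beads"])
    out = os.path.join(wd, block.get("psf", "psf.tif"))
    key = _cache_key("extract_psf", block, [beads])
    if _cached(wd, "extract_psf", key, [out]):
        return [beads], [out]
    stack = azio.read_stack(beads)
    psf = extract_psf(stack,
                      crop_size=tuple(block.get("crop_size", (21, 32, 32))),
                      isolation_radius_um=float(block.get("isolation_radius_um", 2.0)),
                      min_peak=float(block.get("min_peak", 100.0)))
    azio.write_psf(out, psf)
    _mark(wd, "extract_psf", key)
    return [beads], [out]


def _stage_deconvolve(cfg: RunConfig, wd: str):
    block = cfg.deconvolve
    src = os.path.join(wd, block.get("input", "stack.tif"))
    psf_path = os.path.join(wd, block["psf"])
    out = os.path.join(wd, block.get("output", "deconvolved.tif"))
    key = _cache_key("deconvolve", block, [src, psf_path])
    if _cached(wd, "deconvolve", key, [out]):
        return [src, psf_path], [out]
    image = azio.read_stack(src)
    psf = azio.read_psf(psf_path)
    iterations = int(block.get("iterations", DEFAULT_RL_ITERATIONS))
    log.info("deconvolve: Richardson-Lucy, %d iterations", iterations)
    result = richardson_lucy(VolumetricImage(image.data.astype(float), image.spacing),
                             psf, iterations)
    azio.write_stack(out, result.copy_with(result.data.astype(np.float32)))
    _mark(wd, "deconvolve", key)
    return [src, psf_path], [out]


def _stage_segment(cfg: RunConfig, wd: str):
    block = cfg.segment
    detect_path = os.path.join(wd, block.get("detect", "deconvolved.tif"))
    measure_path = os.path.join(wd, block.get("measure", "stack.tif"))
    out = os.path.join(wd, block.get("table", "clusters.csv"))
    key = _cache_key("segment", block, [detect_path, measure_path])
    if _cached(wd, "segment", key, [out]):
        return [detect_path, measure_path], [out]
    params = DetectionParams(**{k: (tuple(v) if isinstance(v, list) else v)
                                for k, v in block.get("params", {}).items()})
    detect = azio.read_stack(detect_path)
    measure = azio.read_stack(measure_path)
    factor = int(params.upsample_xy)
    log.info("segment: threshold=%g noise_tolerance=%g sd_value=%g upsample=%d "
             "tiles=%dx%d", params.threshold, params.noise_tolerance,
             params.sd_value, factor, *params.tile_grid)
    detect_up = upsample_xy(VolumetricImage(detect.data.astype(float), detect.spacing),
                            factor)
    measure_up = upsample_xy(VolumetricImage(measure.data.astype(float), measure.spacing),
                             factor)
    if block.get("tiled", True):
        table = tile_and_stitch(detect_up, measure_up, params)
    else:
        table = segment_stack(detect_up, measure_up, params)
    azio.write_table(out, table)
    _mark(wd, "segment", key)
    return [detect_path, measure_path], [out]


def _stage_stats(cfg: RunConfig, wd: str):
    block = cfg.stats
    src = os.path.join(wd, block.get("table", "clusters.csv"))
    report_path = os.path.join(wd, block.get("report", "stats.json"))
    annotated_path = os.path.join(wd, block.get("annotated", "clusters_annotated.csv"))
    key = _cache_key("stats", block, [src])
    outputs = [report_path, annotated_path]
    if _cached(wd, "stats", key, outputs):
        return [src], outputs
    params = SpatialParams(**block.get("params", {}))
    log.info("stats: radius_multiplier=%g", params.radius_multiplier)
    table = azio.read_table(src)
    annotated = annotate_spatial(table, params)
    azio.write_table(annotated_path, annotated)
    with open(report_path, "w") as fh:
        json.dump(sample_report(table, params), fh, indent=2)
    _mark(wd, "stats", key)
    return [src], outputs


def _stage_benchmark(cfg: RunConfig, wd: str):
    block = cfg.benchmark
    image_path = os.path.join(wd, block.get("image", "deconvolved.tif"))
    truth_path = os.path.join(wd, block.get("truth", "truth.csv"))
    out = os.path.join(wd, block.get("output", "sweep.csv"))
    summary = out + ".json"
    key = _cache_key("benchmark", block, [image_path, truth_path])
    if _cached(wd, "benchmark", key, [out, summary]):
        return [image_path, truth_path], [out, summary]
    image = azio.read_stack(image_path)
    truth = azio.read_truth(truth_path)
    sweep = parameter_sweep(
        image, truth[["x_um", "y_um", "z_um"]].to_numpy(),
        block["thresholds"], block["tolerances"],
        match_tolerance=float(block.get("match_tolerance_um",
                                        DEFAULT_MATCH_TOLERANCE_UM)))
    sweep.to_frame().to_csv(out)
    with open(summary, "w") as fh:
        json.dump({"best_threshold": sweep.best_params[0],
                   "best_noise_tolerance": sweep.best_params[1],
                   "best_f": sweep.best_f}, fh, indent=2)
    _mark(wd, "benchmark", key)
    return [image_path, truth_path], [out, summary]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "extract_psf": _stage_extract_psf,
    "deconvolve": _stage_deconvolve,
    "segment": _stage_segment,
    "stats": _stage_stats,
    "benchmark": _stage_benchmark,
}
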