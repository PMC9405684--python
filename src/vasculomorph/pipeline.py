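"""End-to-end orchestration: prepare -> segment/trace -> skeleton -> metrics.

A single config (YAML file or dict) drives the full run. Every intermediate
is written to the output directory and a manifest records parameters, seeds,
package version and a checksum per output, so any result is regenerable and
auditable from the config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, fractal, imaging_io, network_metrics, skeleton, synthetic, tracing

logger = logging.getLogger("vasculomorph")

__all__ = ["RunConfig", "StageError", "run_pipeline", "load_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input checksum."""

    def __init__(self, stage: str, input_checksum: str | None, cause: Exception):
        super().__init__(f"stage {stage!r} failed (input checksum {input_checksum}): {cause}")
        self.stage = stage
        self.input_checksum = input_checksum


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    input_path: str | None = None
    pixel_size_um: float = 1.0
    simulate: dict | None = None  # e.g. {'kind': 'tree', 'depth': 2, ...}
    roi_path: str | None = None
    prepare: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    trace_seeds_path: str | None = None
    tracing: dict = field(default_factory=dict)
    fractal: dict = field(default_factory=dict)
    collateral_roi_path: str | None = None

    def validate(self) -> None:
        if self.input_path is None and self.simulate is None:
            raise ValueError("config needs either input_path or a simulate block")
        for p in (self.input_path, self.roi_path, self.trace_seeds_path, self.collateral_roi_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def load_config(path: str | Path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text())
    return RunConfig(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return the manifest (also written as JSON).

    Stage order: acquire/simulate -> prepare -> segment (or trace when a seed
    file is given) -> thin/graph/measure -> network metrics + fractal
    analysis. Each stage writes its outputs before the next starts; a failure
    aborts with the stage name and the checksum of the stage input.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    logger.addHandler(handler)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "prepare": config.prepare,
            "segment": config.segment,
            "tracing": config.tracing,
            "fractal": config.fractal,
            "simulate": config.simulate,
        },
        "stages": {},
        "outputs": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    last_checksum: str | None = None
    try:
        stage = "acquire"
        gt = None
        if config.simulate is not None:
            sim = dict(config.simulate)
            kind = sim.pop("kind", "tree")
            if kind != "tree":
                raise ValueError(f"unknown simulate kind {kind!r}")
            sim.setdefault("seed", config.seed)
            spec = synthetic.TreeSpec(pixel_size_um=config.pixel_size_um, **sim)
            img, gt = synthetic.generate_tree(spec)
            (out_dir / "ground_truth.json").write_text(json.dumps(gt.to_dict(), indent=1))
            record("ground_truth", out_dir / "ground_truth.json")
        else:
            img = imaging_io.read_image(config.input_path, config.pixel_size_um)
        imaging_io.write_image(out_dir / "input.tif", img)
        record("input", out_dir / "input.tif")
        last_checksum = manifest["outputs"]["input"]["sha256"]
        manifest["stages"]["acquire"] = "ok"

        stage = "prepare"
        roi = imaging_io.read_roi(config.roi_path) if config.roi_path else None
        prepared = imaging_io.prepare_image(img, roi=roi, **config.prepare)
        imaging_io.write_image(out_dir / "prepared.tif", prepared)
        record("prepared", out_dir / "prepared.tif")
        last_checksum = manifest["outputs"]["prepared"]["sha256"]
        manifest["stages"]["prepare"] = "ok"

        stage = "segment"
        if config.trace_seeds_path:
            seeds = json.loads(Path(config.trace_seeds_path).read_text())
            params = tracing.TracingParams(**config.tracing)
            tr = tracing.trace_branches(prepared, seeds, params, source=str(config.input_path))
            tr.to_json(out_dir / "tracing.json")
            record("tracing", out_dir / "tracing.json")
            mask = tracing.rasterize_tracing(tr, prepared.values.shape, prepared.pixel_size_um)
        else:
            seg_cfg = dict(config.segment)
            if seg_cfg.pop("use_ground_truth_mask", False) and gt is not None:
                mask = imaging_io.BinaryMask(gt.stroke_mask, config.pixel_size_um)
            else:
                mask = network_metrics.segment_vessels(prepared, **seg_cfg)
        imaging_io.write_image(out_dir / "mask.tif", mask)
        record("mask", out_dir / "mask.tif")
        last_checksum = manifest["outputs"]["mask"]["sha256"]
        manifest["stages"]["segment"] = "ok"

        stage = "skeleton"
        sk, graph, measures, summary = skeleton.analyze_mask(mask)
        imaging_io.write_image(out_dir / "skeleton.tif", imaging_io.BinaryMask(sk.data, sk.pixel_size_um))
        record("skeleton", out_dir / "skeleton.tif")
        rows = [
            {
                "skeleton_id": 0,
                "branch_id": m.branch_id,
                "length_um": m.length_um,
                "v1x": m.v1_xy[0],
                "v1y": m.v1_xy[1],
                "v2x": m.v2_xy[0],
                "v2y": m.v2_xy[1],
                "euclidean_um": m.euclidean_um,
                "tortuosity": m.tortuosity,
            }
            for m in measures
        ]
        pd.DataFrame(rows).to_csv(out_dir / "branches.csv", index=False)
        record("branches", out_dir / "branches.csv")
        pd.DataFrame([summary.to_dict()]).to_csv(out_dir / "skeleton_summary.csv", index=False)
        record("skeleton_summary", out_dir / "skeleton_summary.csv")
        manifest["stages"]["skeleton"] = {"branch_count": summary.branch_count, "junction_count": summary.junction_count}
        if config.collateral_roi_path:
            c_roi = imaging_io.read_roi(config.collateral_roi_path)
            report = skeleton.analyze_collaterals(graph, measures, c_roi)
            (out_dir / "collaterals.json").write_text(json.dumps(report.to_dict(), indent=1))
            record("collaterals", out_dir / "collaterals.json")

        stage = "metrics"
        metrics = network_metrics.compute_network_metrics(mask, roi=None)
        pd.DataFrame([{"sample_id": Path(config.input_path or "simulated").stem, **metrics.to_dict()}]).to_csv(
            out_dir / "network_metrics.csv", index=False
        )
        record("network_metrics", out_dir / "network_metrics.csv")
        manifest["stages"]["metrics"] = "ok"

        stage = "fractal"
        fr_cfg = dict(config.fractal)
        window = int(fr_cfg.pop("window", 128))
        stride = int(fr_cfg.pop("stride", 64))
        min_fg = int(fr_cfg.pop("min_foreground", 50))
        if window <= min(mask.data.shape):
            lfd = fractal.local_fractal_map(mask, window, stride, min_fg)
            pd.DataFrame(
                {"x": lfd.origins[:, 0] if len(lfd) else [], "y": lfd.origins[:, 1] if len(lfd) else [], "lfd": lfd.values}
            ).to_csv(out_dir / "lfd_map.csv", index=False)
            record("lfd_map", out_dir / "lfd_map.csv")
            if len(lfd):
                hist = fractal.build_lfd_histogram(lfd, **fr_cfg)
                pd.DataFrame(
                    {"bin_lo": hist.bin_edges[:-1], "bin_hi": hist.bin_edges[1:], "count": hist.counts}
                ).to_csv(out_dir / "lfd_histogram.csv", index=False)
                record("lfd_histogram", out_dir / "lfd_histogram.csv")
                feats = fractal.extract_features(hist)
                pd.DataFrame([feats.to_dict()]).to_csv(out_dir / "lfd_features.csv", index=False)
                record("lfd_features", out_dir / "lfd_features.csv")
        manifest["stages"]["fractal"] = "ok"
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        logger.removeHandler(handler)
        raise StageError(stage, last_checksum, exc) from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.removeHandler(handler)
    handler.close()
    return manifest
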