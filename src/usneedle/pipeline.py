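"""End-to-end pipeline: voxel detection → RANSAC axis → in-plane view.

A :class:`RunConfig` (YAML-serializable) selects the detection method (patch
CNN or FCN, interchangeable behind one detector interface), locates the model
checkpoint, and fixes a global seed from which every stage seed is derived
deterministically.  Every artifact is stamped with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .axis import RansacConfig, designate_tip, ransac_fit, render_inplane_view, save_view_png
from .patchnet import PatchCNN, classify_volume_patchwise
from .phantom import load_manifest
from .segmenter import ShareFCN, binarize, segment_volume
from .volume import read_volume, write_volume

log = logging.getLogger("usneedle")


@dataclass
class RunConfig:
    """Configuration of a full detection run over a dataset manifest."""

    manifest: str = ""
    method: str = "fcn"  # "patch" or "fcn"
    model_path: str = ""
    out_dir: str = "runs/out"
    seed: int = 0
    threshold: float = 0.5
    gap_d_mm: float = 2.0  # fcn only
    stride: int = 1  # patch only
    ransac: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.method not in ("patch", "fcn"):
            raise ValueError("method must be 'patch' or 'fcn'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canonical = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _load_model(cfg: RunConfig):
    path = Path(cfg.model_path)
    if not path.with_suffix(".json").exists():
        raise FileNotFoundError(f"model checkpoint not found: {path.with_suffix('.json')}")
    with open(path.with_suffix(".json")) as fh:
        kind = json.load(fh)["type"]
    if kind == "PatchCNN":
        return PatchCNN.load(path)
    if kind == "ShareFCN":
        return ShareFCN.load(path)
    raise ValueError(f"unknown checkpoint type {kind!r}")


def _stage_seed(global_seed: int, stage: str, item: int) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}:{item}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % 2**31


def run_pipeline(cfg: RunConfig) -> dict:
    """Run detect → fit → render for every manifest volume.

    Returns a run report; per-volume failures are recorded with diagnostics
    rather than aborting the whole run (partial-results behaviour).
    """
    logging.basicConfig(level=cfg.log_level)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    model = _load_model(cfg)
    manifest = load_manifest(cfg.manifest)
    base = Path(cfg.manifest)
    base = base if base.is_dir() else base.parent
    fmt = manifest.get("format", "nrrd")

    report = {"volumes": [], **stamp}
    for entry in manifest["volumes"]:
        vid = entry["id"]
        record = {"id": vid, "status": "ok"}
        try:
            vol = read_volume(base / entry["volume"], fmt)
            if cfg.method == "fcn":
                prob = segment_volume(model, vol, gap_d_mm=cfg.gap_d_mm)
                detected = binarize(prob, cfg.threshold)
            else:
                prob, detected = classify_volume_patchwise(
                    model, vol, stride=cfg.stride, threshold=cfg.threshold
                )
            write_volume(prob, out_dir / f"prob_{vid:03d}.nrrd")
            write_volume(detected, out_dir / f"label_{vid:03d}.nrrd")

            rcfg = RansacConfig(**{**cfg.ransac,
                                   "seed": _stage_seed(cfg.seed, "ransac", vid)})
            fit = ransac_fit(detected, rcfg)
            if fit is None:
                record["status"] = "no_needle_found"
            else:
                fit = designate_tip(fit)
                axis_payload = json.loads(fit.to_json())
                axis_payload.update(stamp)
                with open(out_dir / f"axis_{vid:03d}.json", "w") as fh:
                    json.dump(axis_payload, fh, indent=1, sort_keys=True)
                view = render_inplane_view(vol, fit)
                save_view_png(view, out_dir / f"view_{vid:03d}.png")
                record["n_inliers"] = int(len(fit.inlier_points_mm))
                record["length_mm"] = fit.length_mm
        except Exception as exc:  # partial-results contract
            log.exception("volume %s failed", vid)
            record["status"] = "failed"
            record["error"] = repr(exc)
            record["traceback"] = traceback.format_exc()
        report["volumes"].append(record)
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
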