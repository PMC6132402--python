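"""Synthetic 3D ultrasound needle phantoms.

Emulates the statistics of envelope-detected B-mode volumes containing a
metallic needle: multiplicative Rayleigh speckle over a smooth echogenicity
field, bright curvilinear/blob distractor structures with intensity gains
overlapping the needle's, a voxelized straight needle of clinical diameter
(17 G ≈ 1.47 mm to 22 G ≈ 0.72 mm), optional beam-angle-dependent shaft
dropout (contiguous invisible runs) and optional acoustic shadowing below the
shaft.  Ground truth records the full needle (including invisible parts), as
a human annotator would label it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .volume import LabelVolume, UltrasoundVolume, write_volume


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration cannot be realized."""


@dataclass
class PhantomConfig:
    """Configuration of one synthetic needle phantom.

    Defaults follow the higher-resolution linear-array acquisition setting:
    0.2 mm isotropic voxels, a 17 G (1.47 mm) needle of up to 30 mm inserted
    at a 10–30° steepness angle to the coronal (lateral–elevational) plane.
    """

    shape: tuple[int, int, int] = (174, 189, 188)
    voxel_size_mm: float = 0.2
    needle_diameter_mm: float = 1.47
    needle_length_mm: float = 30.0
    entry_face: str = "lateral"  # face the needle enters through
    steepness_angle_deg: float = 20.0  # angle to the coronal plane
    horizontal_angle_deg: float = 0.0  # in-coronal-plane angle
    needle_intensity_gain: float = 5.0
    dropout_fraction: float = 0.0
    shadow_enabled: bool = True
    shadow_attenuation: float = 0.6
    n_distractors: int = 8
    speckle_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise PhantomConfigError("shape must be three positive integers")
        self.shape = tuple(int(s) for s in self.shape)
        if self.voxel_size_mm <= 0:
            raise PhantomConfigError("voxel_size_mm must be > 0")
        if self.needle_diameter_mm <= 0 or self.needle_length_mm <= 0:
            raise PhantomConfigError("needle diameter and length must be > 0")
        if self.entry_face not in ("lateral", "elevational"):
            raise PhantomConfigError("entry_face must be 'lateral' or 'elevational'")
        if not 0 <= self.dropout_fraction < 1:
            raise PhantomConfigError("dropout_fraction must be in [0, 1)")
        if not 0 <= self.shadow_attenuation <= 1:
            raise PhantomConfigError("shadow_attenuation must be in [0, 1]")
        if self.n_distractors < 0:
            raise PhantomConfigError("n_distractors must be >= 0")
        if self.speckle_scale <= 0:
            raise PhantomConfigError("speckle_scale must be > 0")


@dataclass
class PhantomTruth:
    """Ground truth for a generated phantom."""

    mask: LabelVolume
    axis_entry_mm: np.ndarray
    axis_direction: np.ndarray
    tip_mm: np.ndarray
    length_mm: float
    dropped_mask: LabelVolume | None = None

    def __post_init__(self) -> None:
        self.axis_entry_mm = np.asarray(self.axis_entry_mm, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        self.tip_mm = np.asarray(self.tip_mm, dtype=float)
        expected_tip = self.axis_entry_mm + self.length_mm * self.axis_direction
        if not np.allclose(self.tip_mm, expected_tip, atol=1e-9):
            raise ValueError("tip_mm must equal entry + length * direction")


def rasterize_cylinder(
    entry_mm: np.ndarray,
    direction: np.ndarray,
    length_mm: float,
    diameter_mm: float,
    shape: tuple[int, int, int],
    voxel_size_mm: float,
    origin_mm: np.ndarray | None = None,
) -> LabelVolume:
    """Voxelize a finite cylinder: a voxel is in the mask iff its centre lies
    within ``diameter_mm / 2`` of the axis segment."""
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    if length_mm <= 0:
        raise ValueError("zero/negative-length segment")
    if diameter_mm <= 0:
        raise ValueError("diameter must be > 0")
    entry_mm = np.asarray(entry_mm, dtype=float)
    origin = np.zeros(3) if origin_mm is None else np.asarray(origin_mm, dtype=float)
    radius = diameter_mm / 2.0

    # Restrict the exhaustive distance test to the segment's bounding box.
    tip = entry_mm + length_mm * direction
    lo_mm = np.minimum(entry_mm, tip) - radius - voxel_size_mm
    hi_mm = np.maximum(entry_mm, tip) + radius + voxel_size_mm
    lo = np.maximum(np.floor((lo_mm - origin) / voxel_size_mm - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil((hi_mm - origin) / voxel_size_mm - 0.5).astype(int) + 1,
                    np.asarray(shape))

    labels = np.zeros(shape, dtype=np.uint8)
    if np.any(lo >= hi):
        return LabelVolume(labels, voxel_size_mm, origin)
    grids = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
    centers = origin + (np.stack(grids, axis=-1) + 0.5) * voxel_size_mm
    rel = centers - entry_mm
    t = np.clip(rel @ direction, 0.0, length_mm)
    nearest = entry_mm + t[..., None] * direction
    dist = np.linalg.norm(centers - nearest, axis=-1)
    labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = (dist <= radius + 1e-9).astype(np.uint8)
    return LabelVolume(labels, voxel_size_mm, origin)


def _needle_geometry(cfg: PhantomConfig, rng: np.random.Generator):
    """Choose a needle entry point and direction that fit inside the volume."""
    steep = np.deg2rad(cfg.steepness_angle_deg)
    horiz = np.deg2rad(cfg.horizontal_angle_deg)
    if cfg.entry_face == "lateral":
        direction = np.array(
            [np.cos(steep) * np.cos(horiz), np.sin(steep), np.cos(steep) * np.sin(horiz)]
        )
    else:
        direction = np.array(
            [np.cos(steep) * np.sin(horiz), np.sin(steep), np.cos(steep) * np.cos(horiz)]
        )
    direction /= np.linalg.norm(direction)

    extent = np.asarray(cfg.shape) * cfg.voxel_size_mm
    margin = cfg.needle_diameter_mm / 2.0 + cfg.voxel_size_mm
    disp = cfg.needle_length_mm * direction
    lo = np.full(3, margin)
    hi = extent - margin
    # entry must satisfy lo <= entry <= hi and lo <= entry + disp <= hi
    entry_lo = np.maximum(lo, lo - disp)
    entry_hi = np.minimum(hi, hi - disp)
    # pin the entry to just inside its entry face
    face_axis = 0 if cfg.entry_face == "lateral" else 2
    entry_lo[face_axis] = margin
    entry_hi[face_axis] = min(entry_hi[face_axis], 2.0 * margin)
    if np.any(entry_lo > entry_hi):
        raise PhantomConfigError(
            f"needle of length {cfg.needle_length_mm} mm at "
            f"{cfg.steepness_angle_deg}°/{cfg.horizontal_angle_deg}° does not fit "
            f"inside volume extent {tuple(np.round(extent, 2))} mm"
        )
    entry = rng.uniform(entry_lo, entry_hi)
    return entry, direction


def _dropout_mask_1d(t: np.ndarray, length_mm: float, fraction: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Mark shaft positions (by axial coordinate ``t``) falling in contiguous
    dropped runs totalling ``fraction`` of the shaft length."""
    if fraction <= 0:
        return np.zeros(t.shape, dtype=bool)
    n_runs = int(rng.integers(1, 4))
    weights = rng.dirichlet(np.ones(n_runs))
    run_lengths = weights * fraction * length_mm
    visible_total = (1.0 - fraction) * length_mm
    gap_weights = rng.dirichlet(np.ones(n_runs + 1))
    gaps = gap_weights * visible_total
    dropped = np.zeros(t.shape, dtype=bool)
    pos = 0.0
    for g, rl in zip(gaps[:-1], run_lengths):
        pos += g
        dropped |= (t >= pos) & (t < pos + rl)
        pos += rl
    return dropped


def _background(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth echogenicity field × Rayleigh speckle, lightly blurred."""
    coarse_shape = tuple(max(2, s // 12) for s in cfg.shape)
    coarse = rng.normal(0.0, 1.0, size=coarse_shape)
    factors = [s / c for s, c in zip(cfg.shape, coarse_shape)]
    echo = zoom(coarse, factors, order=3)
    echo = echo[: cfg.shape[0], : cfg.shape[1], : cfg.shape[2]]
    pad = [(0, cfg.shape[a] - echo.shape[a]) for a in range(3)]
    if any(p[1] for p in pad):
        echo = np.pad(echo, pad, mode="edge")
    echo = 1.0 + 0.35 * echo / max(echo.std(), 1e-6)
    echo = np.clip(echo, 0.25, None)
    speckle = rng.rayleigh(scale=cfg.speckle_scale * np.sqrt(2.0 / np.pi), size=cfg.shape)
    img = echo * speckle
    return gaussian_filter(img, sigma=0.7)


def _add_distractors(img: np.ndarray, cfg: PhantomConfig, rng: np.random.Generator) -> None:
    """Bright tubes and ellipsoids with gains overlapping the needle's, so the
    detection problem is not separable on intensity alone."""
    extent = np.asarray(cfg.shape) * cfg.voxel_size_mm
    for _ in range(cfg.n_distractors):
        gain = rng.uniform(0.5, 1.1) * cfg.needle_intensity_gain
        if rng.random() < 0.6:  # curvilinear tube
            a = rng.uniform(0.1 * extent, 0.9 * extent)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            length = rng.uniform(0.15, 0.5) * extent.min()
            diam = rng.uniform(0.5, 2.5) * cfg.needle_diameter_mm
            m = rasterize_cylinder(a, d, length, diam, cfg.shape, cfg.voxel_size_mm)
            sel = m.labels.astype(bool)
        else:  # blob / ellipsoid
            c = rng.uniform(0.15 * extent, 0.85 * extent)
            radii = rng.uniform(0.5, 3.0, size=3) * cfg.needle_diameter_mm
            lo = np.maximum(np.floor((c - radii) / cfg.voxel_size_mm - 1).astype(int), 0)
            hi = np.minimum(np.ceil((c + radii) / cfg.voxel_size_mm + 1).astype(int),
                            np.asarray(cfg.shape))
            if np.any(lo >= hi):
                continue
            grids = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
            centers = (np.stack(grids, axis=-1) + 0.5) * cfg.voxel_size_mm
            r = np.linalg.norm((centers - c) / radii, axis=-1)
            sel = np.zeros(cfg.shape, dtype=bool)
            sel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = r <= 1.0
        img[sel] *= gain


def generate_phantom(cfg: PhantomConfig) -> tuple[UltrasoundVolume, PhantomTruth]:
    """Generate one speckle phantom with a voxelized needle and ground truth.

    Deterministic given ``cfg.seed`` (numpy PCG64 generator seeded with it).
    The truth mask marks the whole needle cylinder, including voxels rendered
    invisible by dropout; the acoustic shadow only forms under visible shaft.
    """
    rng = np.random.default_rng(cfg.seed)
    entry, direction = _needle_geometry(cfg, rng)
    img = _background(cfg, rng)
    _add_distractors(img, cfg, rng)

    mask = rasterize_cylinder(
        entry, direction, cfg.needle_length_mm, cfg.needle_diameter_mm,
        cfg.shape, cfg.voxel_size_mm,
    )
    sel = mask.labels.astype(bool)
    idx = np.argwhere(sel)
    centers = (idx + 0.5) * cfg.voxel_size_mm
    t = (centers - entry) @ direction
    dropped_1d = _dropout_mask_1d(t, cfg.needle_length_mm, cfg.dropout_fraction, rng)
    dropped = np.zeros(cfg.shape, dtype=bool)
    dropped[tuple(idx[dropped_1d].T)] = True
    visible = sel & ~dropped
    img[visible] *= cfg.needle_intensity_gain

    if cfg.shadow_enabled and cfg.shadow_attenuation < 1.0:
        # attenuate everything deeper (larger axial index) than visible shaft
        below = np.cumsum(visible, axis=1) > 0
        below &= ~visible
        img[below] *= cfg.shadow_attenuation

    vol = UltrasoundVolume(img.astype(np.float32), cfg.voxel_size_mm)
    truth = PhantomTruth(
        mask=mask,
        axis_entry_mm=entry,
        axis_direction=direction,
        tip_mm=entry + cfg.needle_length_mm * direction,
        length_mm=cfg.needle_length_mm,
        dropped_mask=LabelVolume(dropped.astype(np.uint8), cfg.voxel_size_mm),
    )
    return vol, truth


# ---------------------------------------------------------------------------
# Dataset manifests
# ---------------------------------------------------------------------------


def make_dataset(
    cfgs: list[PhantomConfig],
    out_dir,
    n_folds: int = 5,
    file_format: str = "nrrd",
) -> dict:
    """Generate phantoms to disk with a JSON manifest assigning fold indices.

    Folds are volume-disjoint (round-robin by volume index).  Returns the
    manifest dict; it is also written to ``out_dir/manifest.json``.
    """
    if len(cfgs) < n_folds:
        raise ValueError(f"need >= {n_folds} volumes for {n_folds}-fold use")
    seeds = [c.seed for c in cfgs]
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds in phantom configs", stacklevel=2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"nrrd": ".nrrd", "nifti": ".nii", "metaimage": ".mha"}[file_format]
    entries = []
    for i, cfg in enumerate(cfgs):
        vol, truth = generate_phantom(cfg)
        vol_path = out_dir / f"vol_{i:03d}{ext}"
        mask_path = out_dir / f"mask_{i:03d}{ext}"
        write_volume(vol, vol_path, file_format)
        write_volume(truth.mask, mask_path, file_format)
        entries.append(
            {
                "id": i,
                "volume": vol_path.name,
                "mask": mask_path.name,
                "fold": i % n_folds,
                "seed": cfg.seed,
                "config": asdict(cfg),
                "truth": {
                    "axis_entry_mm": truth.axis_entry_mm.tolist(),
                    "axis_direction": truth.axis_direction.tolist(),
                    "tip_mm": truth.tip_mm.tolist(),
                    "length_mm": truth.length_mm,
                },
            }
        )
    manifest = {"n_folds": n_folds, "format": file_format, "volumes": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_manifest(path) -> dict:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    with open(path) as fh:
        return json.load(fh)
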