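"""Needle axis estimation from detected voxels and in-plane view extraction.

Detected needle voxels are fitted with a straight cylinder of fixed diameter
(default 2 mm, slightly above clinical needle diameters) using RANSAC: two
distinct voxel centres are sampled repeatedly, the candidate axis with the
largest consensus of voxel centres within one cylinder radius wins, and the
winner is optionally refined as the principal axis of its inliers.  The tip
is designated as the inlier projection farthest from the entry face.  The
needle plane — the cross-section containing the whole needle and
perpendicular to the coronal (lateral–elevational) planes — is spanned by the
needle direction and the axial unit vector; it is the "in-plane view" a
physician steers by.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import (
    AXIAL_UNIT,
    ELEVATIONAL_UNIT,
    LabelVolume,
    PlaneSpec,
    UltrasoundVolume,
    extract_plane,
)


@dataclass
class RansacConfig:
    cylinder_diameter_mm: float = 2.0
    n_iterations: int = 1000
    min_inliers: int = 5
    seed: int = 0
    refine: bool = True

    def __post_init__(self) -> None:
        if self.cylinder_diameter_mm <= 0:
            raise ValueError("cylinder diameter must be > 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class NeedleAxis:
    """A fitted 3D needle axis with consensus voxels and (optionally) a tip."""

    point_mm: np.ndarray
    direction: np.ndarray
    inlier_indices: np.ndarray  # (M, 3) voxel indices
    inlier_points_mm: np.ndarray  # (M, 3) their centres
    tip_mm: np.ndarray | None = None
    entry_mm: np.ndarray | None = None
    length_mm: float | None = None
    bounds_mm: tuple | None = None  # physical box of the source volume

    def __post_init__(self) -> None:
        self.point_mm = np.asarray(self.point_mm, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            self.direction = self.direction / n
        if self.tip_mm is not None:
            tip = np.asarray(self.tip_mm, dtype=float)
            off = tip - self.point_mm
            perp = off - (off @ self.direction) * self.direction
            if np.linalg.norm(perp) > 1e-6:
                raise ValueError("tip_mm must lie on the axis line")

    def to_json(self) -> str:
        payload = {
            "point_mm": self.point_mm.tolist(),
            "direction": self.direction.tolist(),
            "n_inliers": int(len(self.inlier_points_mm)),
            "tip_mm": None if self.tip_mm is None else np.asarray(self.tip_mm).tolist(),
            "entry_mm": None if self.entry_mm is None else np.asarray(self.entry_mm).tolist(),
            "length_mm": self.length_mm,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _line_distances(points: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    rel = points - origin
    proj = rel @ direction
    return np.linalg.norm(rel - proj[:, None] * direction, axis=1)


def _principal_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through a point cloud (centroid + PC1)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    return centroid, d / np.linalg.norm(d)


def ransac_fit(detected: LabelVolume, cfg: RansacConfig) -> NeedleAxis | None:
    """RANSAC fit of a fixed-diameter cylinder to the detected voxel centres.

    Returns ``None`` ("no needle found") when fewer than two voxels are
    detected or the best consensus stays below ``cfg.min_inliers``.
    Deterministic given ``cfg.seed``; consensus ties keep the first model.
    """
    idx = np.argwhere(detected.labels)
    if len(idx) < 2:
        return None
    points = detected.voxel_center_mm(idx)
    radius = cfg.cylinder_diameter_mm / 2.0
    rng = np.random.default_rng(cfg.seed)

    best_count = -1
    best = None
    for _ in range(cfg.n_iterations):
        a, b = rng.choice(len(points), size=2, replace=False)
        d = points[b] - points[a]
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        d = d / norm
        count = int(np.sum(_line_distances(points, points[a], d) <= radius + 1e-12))
        if count > best_count:
            best_count = count
            best = (points[a], d)
    if best is None or best_count < cfg.min_inliers:
        return None

    origin, d = best
    inliers = _line_distances(points, origin, d) <= radius + 1e-12
    if cfg.refine and inliers.sum() >= 2:
        origin, d = _principal_axis(points[inliers])
        inliers = _line_distances(points, origin, d) <= radius + 1e-12
        if inliers.sum() < cfg.min_inliers:
            return None
    return NeedleAxis(
        point_mm=origin,
        direction=d,
        inlier_indices=idx[inliers],
        inlier_points_mm=points[inliers],
        bounds_mm=tuple(np.asarray(b) for b in detected.bounds_mm()),
    )


_ENTRY_FACES = ("lateral_min", "lateral_max", "elevational_min", "elevational_max")


def designate_tip(axis: NeedleAxis, entry_hint: str = "auto") -> NeedleAxis:
    """Designate tip and entry endpoints of a fitted axis.

    Inlier centres are projected onto the axis; the endpoints are the extreme
    projections.  The tip is the endpoint farther from the entry face
    (``auto``: the lateral/elevational volume face closest to either
    endpoint).  The direction is re-oriented entry → tip.
    """
    if len(axis.inlier_points_mm) < 2:
        raise ValueError("tip designation needs >= 2 inliers")
    if entry_hint not in _ENTRY_FACES + ("auto",):
        raise ValueError(f"entry_hint must be one of {_ENTRY_FACES + ('auto',)}")
    t = (axis.inlier_points_mm - axis.point_mm) @ axis.direction
    lo = axis.point_mm + t.min() * axis.direction
    hi = axis.point_mm + t.max() * axis.direction

    if entry_hint == "auto":
        if axis.bounds_mm is None:
            raise ValueError("auto entry designation needs volume bounds")
        bmin, bmax = axis.bounds_mm
        faces = {
            "lateral_min": (0, bmin[0]),
            "lateral_max": (0, bmax[0]),
            "elevational_min": (2, bmin[2]),
            "elevational_max": (2, bmax[2]),
        }
        entry_hint = min(
            faces,
            key=lambda f: min(abs(lo[faces[f][0]] - faces[f][1]),
                              abs(hi[faces[f][0]] - faces[f][1])),
        )
    face_axis = 0 if entry_hint.startswith("lateral") else 2
    if axis.bounds_mm is not None:
        bmin, bmax = axis.bounds_mm
        face_coord = bmin[face_axis] if entry_hint.endswith("min") else bmax[face_axis]
    else:
        coords = (lo[face_axis], hi[face_axis])
        face_coord = min(coords) if entry_hint.endswith("min") else max(coords)
    d_lo = abs(lo[face_axis] - face_coord)
    d_hi = abs(hi[face_axis] - face_coord)
    entry, tip = (lo, hi) if d_lo <= d_hi else (hi, lo)
    direction = tip - entry
    length = float(np.linalg.norm(direction))
    direction = direction / length if length > 0 else axis.direction
    return NeedleAxis(
        point_mm=entry,
        direction=direction,
        inlier_indices=axis.inlier_indices,
        inlier_points_mm=axis.inlier_points_mm,
        tip_mm=tip,
        entry_mm=entry,
        length_mm=length,
        bounds_mm=axis.bounds_mm,
    )


def needle_plane(axis: NeedleAxis) -> PlaneSpec:
    """The plane containing the whole axis and perpendicular to every coronal
    plane: spanned by the axis direction and the axial unit vector.

    Degenerate when the axis is (numerically) parallel to the axial axis; the
    lateral–axial plane through the axis point is returned, flagged.
    """
    n = np.cross(AXIAL_UNIT, axis.direction)
    norm = np.linalg.norm(n)
    if norm < 1e-6:
        return PlaneSpec(
            point_mm=axis.point_mm,
            normal=ELEVATIONAL_UNIT.copy(),
            in_plane_axes=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
            degenerate=True,
        )
    n = n / norm
    e1 = np.cross(n, AXIAL_UNIT)
    e1 /= np.linalg.norm(e1)
    return PlaneSpec(point_mm=axis.point_mm, normal=n,
                     in_plane_axes=np.stack([e1, AXIAL_UNIT]))


@dataclass
class InplaneView:
    """Rendered in-plane needle view with a sidecar overlay (never burned in)."""

    image: np.ndarray
    plane: PlaneSpec
    sample_step_mm: float
    overlay: dict = field(default_factory=dict)
    degenerate: bool = False

    def pixel_to_world(self, px: np.ndarray) -> np.ndarray:
        """Map (row, col) pixel coordinates back to 3D mm positions."""
        px = np.asarray(px, dtype=float)
        n_u, n_w = self.image.shape
        u = (px[..., 0] - (n_u - 1) / 2.0) * self.sample_step_mm
        w = (px[..., 1] - (n_w - 1) / 2.0) * self.sample_step_mm
        return self.plane.to_world(u, w)


def render_inplane_view(v: UltrasoundVolume, axis: NeedleAxis,
                        sample_step_mm: float | None = None) -> InplaneView:
    """Extract the in-plane needle view over the full volume footprint.

    The overlay records the axis endpoints and tip in both mm and pixel
    coordinates as a sidecar structure.
    """
    plane = needle_plane(axis)
    step = sample_step_mm or v.voxel_size_mm

    # project volume corners into the plane frame to cover the footprint
    bmin, bmax = v.bounds_mm()
    corners = np.array([[bmin[i] if b & (1 << i) else bmax[i] for i in range(3)]
                        for b in range(8)])
    rel = corners - plane.point_mm
    u_rng = rel @ plane.in_plane_axes[0]
    w_rng = rel @ plane.in_plane_axes[1]
    extent = (2 * float(np.abs(u_rng).max()), 2 * float(np.abs(w_rng).max()))
    image = extract_plane(v, plane, extent, step)

    def to_pixel(pt):
        relp = np.asarray(pt, dtype=float) - plane.point_mm
        u = relp @ plane.in_plane_axes[0]
        w = relp @ plane.in_plane_axes[1]
        n_u, n_w = image.shape
        return [u / step + (n_u - 1) / 2.0, w / step + (n_w - 1) / 2.0]

    t = (axis.inlier_points_mm - axis.point_mm) @ axis.direction
    p0 = axis.point_mm + t.min() * axis.direction
    p1 = axis.point_mm + t.max() * axis.direction
    overlay = {
        "axis_endpoints_mm": [p0.tolist(), p1.tolist()],
        "axis_endpoints_px": [to_pixel(p0), to_pixel(p1)],
        "tip_mm": None if axis.tip_mm is None else np.asarray(axis.tip_mm).tolist(),
        "tip_px": None if axis.tip_mm is None else to_pixel(axis.tip_mm),
    }
    return InplaneView(image=image, plane=plane, sample_step_mm=step,
                       overlay=overlay, degenerate=plane.degenerate)


def save_view_png(view: InplaneView, path) -> None:
    """Write the rendered view as a PNG with the overlay drawn on top, plus a
    sidecar JSON with the overlay geometry."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(view.image, cmap="gray", interpolation="nearest")
    (a, b) = view.overlay["axis_endpoints_px"]
    ax.plot([a[1], b[1]], [a[0], b[0]], "r-", lw=1.5)
    if view.overlay.get("tip_px") is not None:
        tp = view.overlay["tip_px"]
        ax.plot(tp[1], tp[0], "yo", ms=6, mfc="none")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
    sidecar = Path(path).with_suffix(".overlay.json")
    with open(sidecar, "w") as fh:
        json.dump({"sample_step_mm": view.sample_step_mm,
                   "degenerate": view.degenerate, **view.overlay}, fh, indent=1)
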