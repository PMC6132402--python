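"""Voxel-level and geometric evaluation of needle detection.

Voxel metrics follow the usual confusion-matrix definitions (recall =
detected needle voxels / true needle voxels, precision = detected needle
voxels / all detections, F1 = harmonic mean).  Geometric accuracy uses two
measures: the tip error ``ε_t`` — the point-plane distance from the
ground-truth tip to the detected needle plane, which is what matters
clinically since the tip must appear in the displayed view — and the
orientation error ``ε_v`` — the angle between detected and true axes,
treated as undirected lines.  Length-stratified curves sweep the inserted
needle length and report mean ± standard error of both errors over phantom
replicates.  A k-fold cross-validation harness trains on k−1 volume-disjoint
folds and evaluates full-volume voxel metrics on the held-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .phantom import PhantomConfig, generate_phantom
from .axis import RansacConfig, designate_tip, needle_plane, ransac_fit
from .volume import LabelVolume, PlaneSpec


@dataclass
class VoxelMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    recall: float
    precision: float | None
    specificity: float
    f1: float | None


def voxel_metrics(pred: LabelVolume, truth: LabelVolume) -> VoxelMetrics:
    """Confusion-matrix voxel metrics of a detection against ground truth.

    Precision (and hence F1) is reported as ``None`` — missing, not zero —
    when no voxel is predicted positive.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.labels.astype(bool)
    t = truth.labels.astype(bool)
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    if tp + fp == 0:
        precision = None
        f1 = None
    else:
        precision = tp / (tp + fp)
        f1 = (2 * precision * recall / (precision + recall)
              if (precision + recall) > 0 else 0.0)
    return VoxelMetrics(tp, fp, tn, fn, recall, precision, specificity, f1)


def tip_error(truth_tip_mm: np.ndarray, plane: PlaneSpec) -> float:
    """ε_t: point-plane distance of the ground-truth tip to the needle plane."""
    return abs(plane.signed_distance(truth_tip_mm))


def orientation_error(dir_a: np.ndarray, dir_b: np.ndarray) -> float:
    """ε_v: angle in degrees between two axes, treated as undirected lines."""
    a = np.asarray(dir_a, dtype=float)
    b = np.asarray(dir_b, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    return float(np.degrees(np.arccos(np.clip(abs(a @ b), 0.0, 1.0))))


def geometric_errors(truth, axis) -> dict:
    """ε_t, ε_v and detected length for one fitted (tip-designated) axis."""
    plane = needle_plane(axis)
    return {
        "tip_error_mm": tip_error(truth.tip_mm, plane),
        "orientation_error_deg": orientation_error(truth.axis_direction, axis.direction),
        "needle_length_mm": axis.length_mm,
        "degenerate_plane": plane.degenerate,
    }


def length_stratified_errors(
    detector,
    base_cfg: PhantomConfig,
    lengths_mm,
    n_replicates: int = 5,
    seed: int = 0,
    ransac_cfg: RansacConfig | None = None,
) -> pd.DataFrame:
    """ε_t / ε_v versus inserted needle length on phantom replicates.

    ``detector`` maps an :class:`UltrasoundVolume` to a :class:`LabelVolume`
    of detected voxels.  For each length, phantoms are generated with fresh
    seeds (all other settings from ``base_cfg``), the detector plus RANSAC
    pipeline runs, and the mean and standard error of the mean of both errors
    are tabulated.  Detector or fit failures are recorded as missing rows,
    never dropped silently.
    """
    rcfg = ransac_cfg or RansacConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    for li, length in enumerate(lengths_mm):
        reps = []
        n_failed = 0
        for r in range(n_replicates):
            phantom_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            cfg = replace(base_cfg, needle_length_mm=float(length), seed=phantom_seed)
            vol, truth = generate_phantom(cfg)
            detected = detector(vol)
            fit = ransac_fit(detected, replace(rcfg, seed=rcfg.seed + 997 * li + r))
            if fit is None:
                n_failed += 1
                continue
            fit = designate_tip(fit)
            reps.append(geometric_errors(truth, fit))
        et = np.array([x["tip_error_mm"] for x in reps])
        ev = np.array([x["orientation_error_deg"] for x in reps])
        rows.append(
            {
                "length_mm": float(length),
                "n": len(reps),
                "n_failed": n_failed,
                "tip_error_mean_mm": et.mean() if len(et) else np.nan,
                "tip_error_sem_mm": et.std(ddof=1) / np.sqrt(len(et)) if len(et) > 1 else np.nan,
                "orientation_error_mean_deg": ev.mean() if len(ev) else np.nan,
                "orientation_error_sem_deg": (
                    ev.std(ddof=1) / np.sqrt(len(ev)) if len(ev) > 1 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


class FoldLeakageError(RuntimeError):
    """Raised when a volume appears in both a training and a test fold."""


def crossval(manifest_entries, train_fn, detect_fn, k: int = 5) -> dict:
    """k-fold cross-validation over a fold-assigned dataset.

    ``manifest_entries`` is a list of dicts with keys ``id``, ``fold``,
    ``volume`` (an :class:`UltrasoundVolume`) and ``mask``
    (:class:`LabelVolume`) — i.e. a loaded manifest.  ``train_fn(pairs)``
    returns a fitted detector state, ``detect_fn(state, volume)`` a
    :class:`LabelVolume`.  Reports per-fold and fold-averaged (mean ± std)
    voxel metrics; folds with undefined precision are excluded from precision
    and F1 averaging and counted.
    """
    folds = sorted({e["fold"] for e in manifest_entries})
    if len(folds) != k:
        raise ValueError(f"manifest defines {len(folds)} folds, expected {k}")
    per_fold = []
    for fold in folds:
        train = [e for e in manifest_entries if e["fold"] != fold]
        test = [e for e in manifest_entries if e["fold"] == fold]
        train_ids = {e["id"] for e in train}
        test_ids = {e["id"] for e in test}
        if train_ids & test_ids:
            raise FoldLeakageError(
                f"volumes {sorted(train_ids & test_ids)} appear in both "
                f"train and test of fold {fold}"
            )
        state = train_fn([(e["volume"], e["mask"]) for e in train])
        fold_metrics = []
        for e in test:
            pred = detect_fn(state, e["volume"])
            fold_metrics.append(voxel_metrics(pred, e["mask"]))
        per_fold.append(
            {
                "fold": fold,
                "n_test": len(test),
                "recall": float(np.mean([m.recall for m in fold_metrics])),
                "precision": _mean_or_none([m.precision for m in fold_metrics]),
                "specificity": float(np.mean([m.specificity for m in fold_metrics])),
                "f1": _mean_or_none([m.f1 for m in fold_metrics]),
            }
        )
    summary = {}
    for key in ("recall", "precision", "specificity", "f1"):
        vals = [f[key] for f in per_fold if f[key] is not None]
        summary[key] = {
            "mean": float(np.mean(vals)) if vals else None,
            "std": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n_missing_folds": sum(1 for f in per_fold if f[key] is None),
        }
    return {"per_fold": per_fold, "summary": summary}


def _mean_or_none(values):
    kept = [v for v in values if v is not None]
    return float(np.mean(kept)) if kept else None


def gap_sweep(
    train_dataset,
    test_dataset,
    gaps_mm,
    fcn_cfg,
    train_cfg,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Fig-7-style protocol: train one ShareFCN per slice gap ``d`` and report
    the fused voxel F1 on held-out phantoms.  ``d = 0`` is the single-slice
    condition (three identical channels)."""
    from dataclasses import replace as dc_replace

    from .segmenter import binarize, segment_volume, train_fcn

    rows = []
    for d in gaps_mm:
        tcfg = dc_replace(train_cfg, gap_d_mm=float(d))
        model, _ = train_fcn(train_dataset, fcn_cfg, tcfg)
        f1s = []
        for vol, mask in test_dataset:
            fused = segment_volume(model, vol, gap_d_mm=float(d))
            m = voxel_metrics(binarize(fused, threshold), mask)
            f1s.append(0.0 if m.f1 is None else m.f1)
        rows.append({"gap_d_mm": float(d), "f1": float(np.mean(f1s)), "n_test": len(f1s)})
    return pd.DataFrame(rows)
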