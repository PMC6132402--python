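"""Triplanar patch classification of needle voxels.

Every voxel is described by three orthogonal 21×21 intensity cross-sections
(lateral–axial, lateral–elevational, axial–elevational) centred on it.  Two
small CNNs classify such triplanar patches: **ShareCNN** convolves all three
planes with one shared filter bank, **IndepCNN** trains an independent bank
per plane; both concatenate the resulting feature maps before three fully
connected stages (128, 64, 2) and a softmax.  The convolutional stack is four
unpadded 3×3 layers of 32, 48, 64 and 96 filters (21→19→17→15→13 px, no
pooling, preserving spatial accuracy).

Because needle voxels are outnumbered roughly 1:3000 by background, training
first balances classes by downsampling negatives, then runs bootstrap
rounds of hard-negative resampling: the trained model re-classifies its own
training volumes, false positives ("most-aggressive" background voxels) are
harvested, and the network is updated on them at a reduced learning rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import Conv2d, Dropout, Linear, ReLU, RMSProp, softmax, softmax_cross_entropy
from .volume import LabelVolume, ProbabilityVolume, UltrasoundVolume, same_geometry


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------


@dataclass
class TriplanarPatch:
    """Three orthogonal intensity tiles centred on one voxel.

    ``planes`` is a (3, side, side) array ordered (lateral–axial,
    lateral–elevational, axial–elevational).
    """

    planes: np.ndarray
    center_index: tuple[int, int, int]
    label: int | None = None

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3 or self.planes.shape[0] != 3 or (
            self.planes.shape[1] != self.planes.shape[2]
        ):
            raise ValueError("planes must be (3, side, side)")


def _extract_batch(intens: np.ndarray, centers: np.ndarray, half_size: int) -> np.ndarray:
    """Zero-padded triplanar tiles for many centers at once → (B, 3, s, s)."""
    h = half_size
    padded = np.pad(np.asarray(intens, dtype=np.float32), h)
    o = np.arange(-h, h + 1)
    i = centers[:, 0] + h
    j = centers[:, 1] + h
    k = centers[:, 2] + h
    p0 = padded[i[:, None, None] + o[None, :, None],
                j[:, None, None] + o[None, None, :],
                k[:, None, None]]
    p1 = padded[i[:, None, None] + o[None, :, None],
                j[:, None, None],
                k[:, None, None] + o[None, None, :]]
    p2 = padded[i[:, None, None],
                j[:, None, None] + o[None, :, None],
                k[:, None, None] + o[None, None, :]]
    return np.stack([p0, p1, p2], axis=1)


def extract_triplanar(
    v: UltrasoundVolume,
    center: tuple[int, int, int],
    half_size: int = 10,
    mode: str = "pad",
) -> TriplanarPatch:
    """Extract the three orthogonal ``(2·half_size+1)``² tiles at a voxel.

    ``mode='pad'`` zero-pads samples outside the volume; ``mode='strict'``
    raises if any tile would leave the volume (skip-border behaviour for
    callers that iterate centers themselves).
    """
    center = tuple(int(c) for c in center)
    if mode == "strict":
        for c, s in zip(center, v.shape):
            if c - half_size < 0 or c + half_size >= s:
                raise ValueError(f"patch at {center} leaves the volume (shape {v.shape})")
    elif mode != "pad":
        raise ValueError("mode must be 'pad' or 'strict'")
    planes = _extract_batch(v.intensities, np.asarray([center]), half_size)[0]
    return TriplanarPatch(planes, center)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class PatchModelConfig:
    """Architecture of the triplanar patch CNN."""

    variant: str = "ShareCNN"  # or "IndepCNN"
    conv_filters: tuple[int, ...] = (32, 48, 64, 96)
    kernel: int = 3
    fc_sizes: tuple[int, ...] = (128, 64, 2)
    dropout_p: float = 0.5
    patch_half_size: int = 10

    def __post_init__(self) -> None:
        if self.variant not in ("ShareCNN", "IndepCNN"):
            raise ValueError("variant must be 'ShareCNN' or 'IndepCNN'")
        if self.fc_sizes[-1] != 2:
            raise ValueError("final fully connected stage must have 2 outputs")

    @property
    def n_banks(self) -> int:
        return 1 if self.variant == "ShareCNN" else 3

    @property
    def patch_side(self) -> int:
        return 2 * self.patch_half_size + 1


def count_conv_parameters(cfg: PatchModelConfig) -> int:
    """Convolutional-layer parameter count under the filters × kernel-area
    convention: bias terms and input-channel depth are excluded, independent
    filter banks multiply the count."""
    per_bank = sum(f * cfg.kernel * cfg.kernel for f in cfg.conv_filters)
    return per_bank * cfg.n_banks


def count_conv_weights(cfg: PatchModelConfig, include_bias: bool = False) -> int:
    """Conventional convolutional weight count (input depth included)."""
    total = 0
    c_in = 1  # each plane enters its bank as a single channel
    for f in cfg.conv_filters:
        total += f * c_in * cfg.kernel * cfg.kernel
        if include_bias:
            total += f
        c_in = f
    return total * cfg.n_banks


class PatchCNN:
    """Triplanar patch classifier (ShareCNN or IndepCNN)."""

    def __init__(self, cfg: PatchModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

        def make_stack():
            layers = []
            c_in = 1
            for f in cfg.conv_filters:
                layers.append(Conv2d(c_in, f, cfg.kernel, rng, padding="valid"))
                layers.append(ReLU())
                c_in = f
            return layers

        self.banks = [make_stack() for _ in range(cfg.n_banks)]
        side = cfg.patch_side - len(cfg.conv_filters) * (cfg.kernel - 1)
        if side < 1:
            raise ValueError("conv stack consumes the whole patch")
        self._feat_side = side
        flat = 3 * cfg.conv_filters[-1] * side * side
        self.fcs = []
        c_in = flat
        for i, f in enumerate(cfg.fc_sizes):
            self.fcs.append(Linear(c_in, f, rng))
            if i < len(cfg.fc_sizes) - 1:
                self.fcs.append(ReLU())
                if i < 2:
                    self.fcs.append(Dropout(cfg.dropout_p, self._dropout_rng))
            c_in = f

    def params(self):
        out = []
        for bank in self.banks:
            for layer in bank:
                out.extend(layer.params())
        for layer in self.fcs:
            out.extend(layer.params())
        return out

    # -- forward / backward -------------------------------------------------

    def plane_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pre-concatenation feature maps, shape (N, 3, F, s, s)."""
        n = x.shape[0]
        if self.cfg.n_banks == 1:
            h = np.ascontiguousarray(x.reshape(n * 3, 1, *x.shape[2:]))
            for layer in self.banks[0]:
                h = layer.forward(h, train)
            return h.reshape(n, 3, *h.shape[1:])
        feats = []
        for p, bank in enumerate(self.banks):
            h = np.ascontiguousarray(x[:, p:p + 1])
            for layer in bank:
                h = layer.forward(h, train)
            feats.append(h)
        return np.stack(feats, axis=1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of triplanar patches (N, 3, side, side)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        feats = self.plane_features(x, train)
        self._n = x.shape[0]
        self._feat_shape = feats.shape
        h = feats.reshape(x.shape[0], -1)
        for layer in self.fcs:
            h = layer.forward(h, train)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.fcs):
            g = layer.backward(g)
        g = g.reshape(self._feat_shape)
        if self.cfg.n_banks == 1:
            gh = np.ascontiguousarray(g.reshape(self._n * 3, *self._feat_shape[2:]))
            for layer in reversed(self.banks[0]):
                gh = layer.backward(gh)
        else:
            for p, bank in enumerate(self.banks):
                gh = np.ascontiguousarray(g[:, p])
                for layer in reversed(bank):
                    gh = layer.backward(gh)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Two-class softmax probabilities, rows summing to 1."""
        return softmax(self.forward(x, train=False), axis=1)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(path.with_suffix(".npz"), **arrays)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump({"type": "PatchCNN", "seed": self.seed, "cfg": asdict(self.cfg)},
                      fh, indent=1)

    @classmethod
    def load(cls, path) -> "PatchCNN":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        cfg = meta["cfg"]
        cfg["conv_filters"] = tuple(cfg["conv_filters"])
        cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
        model = cls(PatchModelConfig(**cfg), seed=meta["seed"])
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"p{i}"]
        return model


def build_patch_model(cfg: PatchModelConfig, seed: int = 0) -> PatchCNN:
    """Instantiate a trainable patch classifier with seeded init."""
    return PatchCNN(cfg, seed)


# ---------------------------------------------------------------------------
# Sampling, bootstrapping and training
# ---------------------------------------------------------------------------


@dataclass
class PatchTrainConfig:
    """Schedule for balanced + bootstrap patch training."""

    lr_train: float = 1e-4
    lr_update: float = 1e-5
    per_class_n: int = 1000
    bootstrap_rounds: int = 1
    batch_size: int = 128
    max_epochs: int = 100
    update_epochs: int = 20
    patience: int = 5
    augment: bool = True
    harvest_stride: int = 2
    harvest_limit: int | None = None
    eval_stride: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lr_update < self.lr_train:
            raise ValueError("lr_update must be < lr_train")
        if self.bootstrap_rounds < 0:
            raise ValueError("bootstrap_rounds must be >= 0")


@dataclass
class PatchSet:
    """A labelled, optionally augmented set of triplanar patches."""

    X: np.ndarray  # (B, 3, side, side), volume-standardized intensities
    y: np.ndarray  # (B,) int, 1 = needle
    centers: np.ndarray  # (B, 3) voxel indices in the (possibly rotated) frame
    vol_ids: np.ndarray  # (B,)
    aug_k: np.ndarray  # (B,) number of 90° axial rotations applied


class InsufficientPositivesError(ValueError):
    pass


def _vol_stats(v: UltrasoundVolume) -> tuple[float, float]:
    m = float(v.intensities.mean())
    s = float(v.intensities.std())
    return m, max(s, 1e-6)


def _rot_center(center, shape, k):
    """Index of a voxel after k 90° rotations about the axial axis
    (``np.rot90(vol, k, axes=(0, 2))``)."""
    x, j, z = center
    n0, n1, n2 = shape
    for _ in range(k % 4):
        x, j, z = n2 - 1 - z, j, x
        n0, n2 = n2, n0
    return (x, j, z)


def sample_balanced_training_set(
    dataset,
    per_class_n: int,
    seed: int = 0,
    half_size: int = 10,
    augment: bool = True,
) -> PatchSet:
    """Equal numbers of needle and background patches, negatives uniform.

    ``dataset`` is a sequence of ``(UltrasoundVolume, LabelVolume)`` pairs.
    Augmentation rotates each patch by a random multiple of 90° around the
    axial axis (applied by extracting from the rotated volume).  Intensities
    are standardized per source volume.
    """
    rng = np.random.default_rng(seed)
    pos: list[tuple[int, tuple]] = []
    for vid, (_, mask) in enumerate(dataset):
        for c in np.argwhere(mask.labels):
            pos.append((vid, tuple(int(x) for x in c)))
    if len(pos) < per_class_n:
        raise InsufficientPositivesError(
            f"need {per_class_n} positives, dataset has {len(pos)}"
        )
    pos_sel = [pos[i] for i in rng.choice(len(pos), size=per_class_n, replace=False)]

    neg_sel: list[tuple[int, tuple]] = []
    shapes = [d[0].shape for d in dataset]
    sizes = np.array([np.prod(s) for s in shapes], dtype=float)
    probs = sizes / sizes.sum()
    while len(neg_sel) < per_class_n:
        vid = int(rng.choice(len(dataset), p=probs))
        c = tuple(int(rng.integers(0, s)) for s in shapes[vid])
        if not dataset[vid][1].labels[c]:
            neg_sel.append((vid, c))

    records = [(vid, c, 1) for vid, c in pos_sel] + [(vid, c, 0) for vid, c in neg_sel]
    ks = rng.integers(0, 4, size=len(records)) if augment else np.zeros(len(records), int)

    X = np.empty((len(records), 3, 2 * half_size + 1, 2 * half_size + 1), dtype=np.float32)
    y = np.empty(len(records), dtype=np.int64)
    centers = np.empty((len(records), 3), dtype=np.int64)
    vol_ids = np.empty(len(records), dtype=np.int64)
    rotated = {}
    stats = [_vol_stats(d[0]) for d in dataset]
    for i, ((vid, c, lab), k) in enumerate(zip(records, ks)):
        key = (vid, int(k))
        if key not in rotated:
            rotated[key] = np.rot90(dataset[vid][0].intensities, int(k), axes=(0, 2))
        arr = rotated[key]
        rc = _rot_center(c, dataset[vid][0].shape, int(k))
        m, s = stats[vid]
        X[i] = (_extract_batch(arr, np.asarray([rc]), half_size)[0] - m) / s
        y[i] = lab
        centers[i] = rc
        vol_ids[i] = vid
    return PatchSet(X, y, centers, vol_ids, np.asarray(ks))


@dataclass
class HardNegatives:
    """False-positive background patches ranked by predicted needle probability."""

    X: np.ndarray
    centers: np.ndarray
    vol_ids: np.ndarray
    probs: np.ndarray


def harvest_hard_negatives(
    model: PatchCNN,
    dataset,
    limit: int | None = None,
    stride: int = 1,
    batch: int = 2048,
    threshold: float = 0.5,
) -> HardNegatives:
    """Background voxels the current model classifies as needle, ranked by
    predicted probability (descending, ties kept in scan order)."""
    h = model.cfg.patch_half_size
    found_X, found_c, found_v, found_p = [], [], [], []
    for vid, (vol, mask) in enumerate(dataset):
        m, s = _vol_stats(vol)
        grid = np.argwhere(mask.labels[::stride, ::stride, ::stride] == 0) * stride
        for start in range(0, len(grid), batch):
            chunk = grid[start:start + batch]
            Xb = (_extract_batch(vol.intensities, chunk, h) - m) / s
            p = model.predict_proba(Xb)[:, 1]
            hit = p > threshold
            if hit.any():
                found_X.append(Xb[hit])
                found_c.append(chunk[hit])
                found_v.append(np.full(int(hit.sum()), vid))
                found_p.append(p[hit])
    if not found_X:
        side = model.cfg.patch_side
        return HardNegatives(
            np.empty((0, 3, side, side), np.float32),
            np.empty((0, 3), int), np.empty(0, int), np.empty(0),
        )
    X = np.concatenate(found_X)
    c = np.concatenate(found_c)
    v = np.concatenate(found_v)
    p = np.concatenate(found_p)
    order = np.argsort(-p, kind="stable")
    if limit is not None:
        order = order[:limit]
    return HardNegatives(X[order], c[order], v[order], p[order])


def _run_epochs(model, X, y, lr, epochs, batch_size, patience, rng, log):
    """Minibatch RMSProp training with early stopping on a held-out split."""
    n = len(X)
    n_val = max(1, n // 10) if n >= 10 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    opt = RMSProp(model.params(), lr=lr)
    best_val, best_state, wait = np.inf, None, 0
    for epoch in range(epochs):
        order = rng.permutation(len(tr_idx))
        losses = []
        for start in range(0, len(order), batch_size):
            sel = tr_idx[order[start:start + batch_size]]
            logits = model.forward(X[sel], train=True)
            loss, grad = softmax_cross_entropy(logits, y[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss at epoch {epoch})"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        if n_val:
            vlogits = model.forward(X[val_idx], train=False)
            vloss, _ = softmax_cross_entropy(vlogits, y[val_idx])
        else:
            vloss = float(np.mean(losses))
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": vloss})
        if vloss < best_val - 1e-5:
            best_val, wait = vloss, 0
            best_state = [p.value.copy() for p in model.params()]
        else:
            wait += 1
            if wait >= patience:
                break
    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.value[...] = v


def classify_volume_patchwise(
    model: PatchCNN,
    v: UltrasoundVolume,
    stride: int = 1,
    threshold: float = 0.5,
    batch: int = 2048,
) -> tuple[ProbabilityVolume, LabelVolume]:
    """Per-voxel needle probability on a stride grid (unvisited voxels 0)."""
    h = model.cfg.patch_half_size
    m, s = _vol_stats(v)
    prob = np.zeros(v.shape, dtype=np.float32)
    grid = np.argwhere(np.ones([int(np.ceil(d / stride)) for d in v.shape], bool)) * stride
    for start in range(0, len(grid), batch):
        chunk = grid[start:start + batch]
        Xb = (_extract_batch(v.intensities, chunk, h) - m) / s
        p = model.predict_proba(Xb)[:, 1]
        prob[chunk[:, 0], chunk[:, 1], chunk[:, 2]] = p
    pvol = ProbabilityVolume(prob, v.voxel_size_mm, v.origin_mm)
    lvol = LabelVolume((prob > threshold).astype(np.uint8), v.voxel_size_mm, v.origin_mm)
    return pvol, lvol


def train_patch_classifier(
    dataset,
    model_cfg: PatchModelConfig,
    train_cfg: PatchTrainConfig,
    heldout=None,
):
    """Balanced training followed by bootstrap hard-negative update rounds.

    ``dataset`` is a sequence of ``(UltrasoundVolume, LabelVolume)`` pairs;
    ``heldout`` an optional pair used for the per-round precision/recall
    entries in the report.  Returns ``(model, report)`` where ``report`` is a
    dict with one ``rounds`` entry per training round (round 0 is the initial
    balanced training).
    """
    from .evaluation import voxel_metrics

    ss = np.random.SeedSequence(train_cfg.seed)
    s_model, s_sample, s_train = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    rng = np.random.default_rng(s_train)
    model = build_patch_model(model_cfg, seed=s_model)
    base = sample_balanced_training_set(
        dataset, train_cfg.per_class_n, seed=s_sample,
        half_size=model_cfg.patch_half_size, augment=train_cfg.augment,
    )

    def heldout_entry(round_idx):
        entry = {"round": round_idx}
        if heldout is not None:
            vol, mask = heldout
            _, pred = classify_volume_patchwise(model, vol, stride=train_cfg.eval_stride)
            sub = slice(None, None, train_cfg.eval_stride)
            mm = voxel_metrics(
                LabelVolume(pred.labels[sub, sub, sub], mask.voxel_size_mm),
                LabelVolume(mask.labels[sub, sub, sub], mask.voxel_size_mm),
            )
            entry.update(precision=mm.precision, recall=mm.recall, f1=mm.f1)
        return entry

    report = {"rounds": [], "epochs": []}
    _run_epochs(model, base.X, base.y, train_cfg.lr_train, train_cfg.max_epochs,
                train_cfg.batch_size, train_cfg.patience, rng, report["epochs"])
    report["rounds"].append(heldout_entry(0))

    pos_X = base.X[base.y == 1]
    pos_y = base.y[base.y == 1]
    for r in range(1, train_cfg.bootstrap_rounds + 1):
        hard = harvest_hard_negatives(
            model, dataset, limit=train_cfg.harvest_limit or len(pos_X),
            stride=train_cfg.harvest_stride,
        )
        n_hard = min(len(hard.X), len(pos_X))
        neg_X = hard.X[:n_hard]
        if n_hard < len(pos_X):  # top up with fresh random negatives
            top_up = sample_balanced_training_set(
                dataset, len(pos_X) - n_hard, seed=s_sample + r,
                half_size=model_cfg.patch_half_size, augment=train_cfg.augment,
            )
            neg_X = np.concatenate([neg_X, top_up.X[top_up.y == 0]]) if n_hard else \
                top_up.X[top_up.y == 0]
        X = np.concatenate([pos_X, neg_X])
        y = np.concatenate([pos_y, np.zeros(len(neg_X), dtype=np.int64)])
        _run_epochs(model, X, y, train_cfg.lr_update, train_cfg.update_epochs,
                    train_cfg.batch_size, train_cfg.patience, rng, report["epochs"])
        entry = heldout_entry(r)
        entry["n_hard_negatives"] = int(n_hard)
        report["rounds"].append(entry)
    return model, report
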