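"""2.5D thick-slice semantic segmentation of needle voxels.

The volume is decomposed into cross-sections perpendicular to the lateral and
elevational axes.  Each cross-section is presented to a fully convolutional
network as a 3-channel "thick slice": the processing section plus its two
parallel neighbours at a gap of ``d`` mm (default 2.0 mm), giving the network
out-of-plane context at the native in-plane resolution.  One network with
shared weights (ShareFCN) serves both directions; its per-slice probability
maps are stacked back into two probability volumes that are fused voxelwise
by multiplicative averaging (geometric mean).

The network is a VGG-19-style encoder (stacked same-padded 3×3 convolutions
in five blocks of 2, 2, 4, 4 and 4 layers, each followed by 2× max pooling
with recorded indices) and a decoder of unpooling stages with factors 2, 2
and 8 and convolution stages of 512, 256 and 2 filters.  Skip connections tap
the encoder before the 4th and 5th pools and are fused by addition after a
channel-matching 1×1 convolution.  A ``width_scale`` knob shrinks all channel
counts proportionally for CPU-scale training; defaults reproduce the full
architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import rotate as nd_rotate

from .nn import Adam, Conv2d, Dropout, MaxPool2d, ReLU, softmax, softmax_cross_entropy
from .nn.layers import (
    max_unpool2d,
    max_unpool2d_backward,
    nearest_upsample,
    nearest_upsample_backward,
)
from .volume import LabelVolume, ProbabilityVolume, UltrasoundVolume, same_geometry

_DIR_AXIS = {"lateral": 0, "elevational": 2}


# ---------------------------------------------------------------------------
# Thick-slice extraction
# ---------------------------------------------------------------------------


@dataclass
class ThickSlice:
    """3-channel stack (previous, processing, next) perpendicular to an axis."""

    channels: np.ndarray  # (3, H, W)
    gap_d_mm: float
    position_index: int
    direction: str

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError("channels must be (3, H, W)")


def _take_slice(arr: np.ndarray, axis: int, index: int) -> np.ndarray:
    return np.take(arr, index, axis=axis)


def extract_thick_slices(
    v: UltrasoundVolume, direction: str, gap_d_mm: float
) -> list[ThickSlice]:
    """One ThickSlice per index along the direction axis.

    Neighbour channels sit at ±``round(gap_d_mm / voxel_size_mm)`` voxels,
    clamped to the volume boundary (border slices replicate themselves).
    """
    if direction not in _DIR_AXIS:
        raise ValueError("direction must be 'lateral' or 'elevational'")
    axis = _DIR_AXIS[direction]
    n = v.shape[axis]
    gap = int(round(gap_d_mm / v.voxel_size_mm))
    if gap >= n:
        raise ValueError(
            f"gap of {gap_d_mm} mm ({gap} voxels) exceeds the volume's "
            f"{direction} extent of {n} voxels"
        )
    out = []
    for i in range(n):
        prev_i = max(i - gap, 0)
        next_i = min(i + gap, n - 1)
        ch = np.stack([
            _take_slice(v.intensities, axis, prev_i),
            _take_slice(v.intensities, axis, i),
            _take_slice(v.intensities, axis, next_i),
        ])
        out.append(ThickSlice(ch, gap_d_mm, i, direction))
    return out


# ---------------------------------------------------------------------------
# ShareFCN
# ---------------------------------------------------------------------------


@dataclass
class FCNConfig:
    """Encoder–decoder architecture settings."""

    width_scale: float = 1.0
    dropout_p: float = 0.85
    skip_connections: bool = True
    upsample_mode: str = "index"  # index unpooling, or "nearest"
    encoder_channels: tuple[int, ...] = (64, 128, 256, 512, 512)
    encoder_convs: tuple[int, ...] = (2, 2, 4, 4, 4)
    decoder_channels: tuple[int, ...] = (512, 256, 2)

    def __post_init__(self) -> None:
        if not 0 < self.width_scale <= 1:
            raise ValueError("width_scale must be in (0, 1]")
        if self.upsample_mode not in ("index", "nearest"):
            raise ValueError("upsample_mode must be 'index' or 'nearest'")
        if len(self.encoder_channels) != 5 or len(self.encoder_convs) != 5:
            raise ValueError("encoder must have five stages")
        if self.decoder_channels[-1] != 2:
            raise ValueError("decoder must end in 2 class channels")

    def scaled(self, c: int) -> int:
        return max(2, int(round(c * self.width_scale)))


class ShareFCN:
    """Fully convolutional 2-class segmenter for 3-channel thick slices.

    Total encoder downsampling is ×32 (five 2× pools), matched by decoder
    upsampling factors 2·2·8.  The final ×8 stage uses index unpooling for
    its first ×2 (the pool-3 indices, whose channel count matches) and
    nearest-neighbour upsampling for the remaining ×4.
    """

    def __init__(self, cfg: FCNConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(rng.integers(2**31))
        s = cfg.scaled

        self.enc_blocks: list[list] = []
        c_in = 3
        for b, (n_convs, ch) in enumerate(zip(cfg.encoder_convs, cfg.encoder_channels)):
            block: list = []
            for i in range(n_convs):
                block.append(Conv2d(c_in, s(ch), 3, rng, padding="same"))
                block.append(ReLU())
                # heavy regularization on the two deepest encoder conv stages
                if b == 4 and i >= n_convs - 2 and cfg.dropout_p > 0:
                    block.append(Dropout(cfg.dropout_p, drop_rng))
                c_in = s(ch)
            self.enc_blocks.append(block)
        self.pools = [MaxPool2d() for _ in range(5)]

        c5 = s(cfg.encoder_channels[4])
        c4 = s(cfg.encoder_channels[3])
        c3 = s(cfg.encoder_channels[2])
        d1 = s(cfg.decoder_channels[0])
        d2 = s(cfg.decoder_channels[1])
        if cfg.skip_connections:
            self.skip5_proj = Conv2d(c5, c5, 1, rng, padding="same")
            self.skip4_proj = Conv2d(c4, d1, 1, rng, padding="same")
        self.dec1_conv = Conv2d(c5, d1, 3, rng, padding="same")
        self.dec1_relu = ReLU()
        self.dec2_conv = Conv2d(d1, d2, 3, rng, padding="same")
        self.dec2_relu = ReLU()
        if d2 != c3:
            # channel-matching 1×1 so pool-3 index unpooling stays applicable
            self.dec2_match = Conv2d(d2, c3, 1, rng, padding="same")
        else:
            self.dec2_match = None
        self.dec3_conv = Conv2d(c3, cfg.decoder_channels[2], 3, rng, padding="same")

    # -- parameters ---------------------------------------------------------

    def params(self):
        out = []
        for block in self.enc_blocks:
            for layer in block:
                out.extend(layer.params())
        if self.cfg.skip_connections:
            out.extend(self.skip5_proj.params())
            out.extend(self.skip4_proj.params())
        for layer in (self.dec1_conv, self.dec2_conv, self.dec3_conv):
            out.extend(layer.params())
        if self.dec2_match is not None:
            out.extend(self.dec2_match.params())
        return out

    # -- forward ------------------------------------------------------------

    @staticmethod
    def _pad32(x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        h, w = x.shape[2], x.shape[3]
        ph = (-h) % 32
        pw = (-w) % 32
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return x, (h, w)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-pixel class logits, shape (N, 2, H, W) matching the input."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        xp, (h0, w0) = self._pad32(x)
        self._orig_hw = (h0, w0)
        self._pad_hw = xp.shape[2:]
        idx_mode = self.cfg.upsample_mode == "index"

        h = xp
        taps = {}
        shapes = []
        for b, block in enumerate(self.enc_blocks):
            for layer in block:
                h = layer.forward(h, train)
            if b == 3:
                taps[4] = h
            elif b == 4:
                taps[5] = h
            shapes.append(h.shape)
            h = self.pools[b].forward(h)
        self._enc_shapes = shapes

        # decoder stage 1: ×2
        if idx_mode:
            u = max_unpool2d(h, self.pools[4].indices, shapes[4])
        else:
            u = nearest_upsample(h, 2)
        if self.cfg.skip_connections:
            u = u + self.skip5_proj.forward(taps[5], train)
        d1 = self.dec1_relu.forward(self.dec1_conv.forward(u, train), train)

        # decoder stage 2: ×2
        if idx_mode:
            u2 = max_unpool2d(d1, self.pools[3].indices, shapes[3])
        else:
            u2 = nearest_upsample(d1, 2)
        if self.cfg.skip_connections:
            u2 = u2 + self.skip4_proj.forward(taps[4], train)
        d2 = self.dec2_relu.forward(self.dec2_conv.forward(u2, train), train)
        if self.dec2_match is not None:
            d2 = self.dec2_match.forward(d2, train)

        # decoder stage 3: ×8 (index ×2 through pool-3, then nearest ×4)
        if idx_mode:
            u3 = max_unpool2d(d2, self.pools[2].indices, shapes[2])
            u3 = nearest_upsample(u3, 4)
        else:
            u3 = nearest_upsample(d2, 8)
        logits = self.dec3_conv.forward(u3, train)
        return logits[:, :, :h0, :w0]

    def backward(self, dlogits: np.ndarray) -> None:
        idx_mode = self.cfg.upsample_mode == "index"
        ph, pw = self._pad_hw
        h0, w0 = self._orig_hw
        g = np.zeros((dlogits.shape[0], dlogits.shape[1], ph, pw), dtype=np.float32)
        g[:, :, :h0, :w0] = dlogits

        g = self.dec3_conv.backward(g)
        if idx_mode:
            g = nearest_upsample_backward(g, 4)
            g = max_unpool2d_backward(g, self.pools[2].indices)
        else:
            g = nearest_upsample_backward(g, 8)
        if self.dec2_match is not None:
            g = self.dec2_match.backward(g)
        g = self.dec2_relu.backward(g)
        g = self.dec2_conv.backward(g)
        g_tap4 = self.skip4_proj.backward(g) if self.cfg.skip_connections else None
        if idx_mode:
            g = max_unpool2d_backward(g, self.pools[3].indices)
        else:
            g = nearest_upsample_backward(g, 2)
        g = self.dec1_relu.backward(g)
        g = self.dec1_conv.backward(g)
        g_tap5 = self.skip5_proj.backward(g) if self.cfg.skip_connections else None
        if idx_mode:
            g = max_unpool2d_backward(g, self.pools[4].indices)
        else:
            g = nearest_upsample_backward(g, 2)

        for b in range(4, -1, -1):
            g = self.pools[b].backward(g) if b == 4 else g
            if b == 4 and g_tap5 is not None:
                g = g + g_tap5
            for layer in reversed(self.enc_blocks[b]):
                g = layer.backward(g)
            if b > 0:
                g = self.pools[b - 1].backward(g)
                if b - 1 == 3 and g_tap4 is not None:
                    g = g + g_tap4

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False), axis=1)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(path.with_suffix(".npz"), **arrays)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump({"type": "ShareFCN", "seed": self.seed, "cfg": asdict(self.cfg)},
                      fh, indent=1)

    @classmethod
    def load(cls, path) -> "ShareFCN":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        cfg = meta["cfg"]
        for key in ("encoder_channels", "encoder_convs", "decoder_channels"):
            cfg[key] = tuple(cfg[key])
        model = cls(FCNConfig(**cfg), seed=meta["seed"])
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"p{i}"]
        return model


def build_fcn(cfg: FCNConfig, seed: int = 0) -> ShareFCN:
    """Instantiate a trainable ShareFCN with seeded init."""
    return ShareFCN(cfg, seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class FCNTrainConfig:
    """Training schedule for the ShareFCN."""

    lr: float = 1e-4
    batch_size: int = 1
    epochs: int = 5
    n_rotations: int = 10  # arbitrary-angle axial rotations per volume
    gap_d_mm: float = 2.0
    val_fraction: float = 0.1
    restarts: int = 1  # independent initializations; best by validation F1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size != 1:
            raise ValueError("thick-slice training uses a batch size of one sample")
        if self.gap_d_mm < 0:
            raise ValueError("gap_d_mm must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


def _standardize(v: UltrasoundVolume) -> np.ndarray:
    arr = v.intensities.astype(np.float32)
    return (arr - arr.mean()) / max(float(arr.std()), 1e-6)


def _slice_pool(dataset, gap_d_mm: float, n_rotations: int, rng: np.random.Generator):
    """Balanced thick-slice training set from both directions.

    Volumes are augmented by ``n_rotations`` arbitrary-angle rotations around
    the axial axis before slice extraction; needle-free sections are
    downsampled to match needle-containing ones.
    """
    Xs, Ys, has_needle = [], [], []
    for vol, mask in dataset:
        variants = [(vol.intensities, mask.labels)]
        for _ in range(n_rotations):
            ang = float(rng.uniform(0.0, 360.0))
            ri = nd_rotate(vol.intensities, ang, axes=(0, 2), reshape=False, order=1)
            rm = nd_rotate(mask.labels, ang, axes=(0, 2), reshape=False, order=0)
            variants.append((ri, rm))
        for intens, labels in variants:
            v = UltrasoundVolume(np.ascontiguousarray(intens), vol.voxel_size_mm)
            norm = _standardize(v)
            nv = UltrasoundVolume(norm, vol.voxel_size_mm)
            for direction in ("lateral", "elevational"):
                axis = _DIR_AXIS[direction]
                for sl in extract_thick_slices(nv, direction, gap_d_mm):
                    lab = _take_slice(labels, axis, sl.position_index).astype(np.int64)
                    Xs.append(sl.channels.astype(np.float32))
                    Ys.append(lab)
                    has_needle.append(bool(lab.any()))
    has_needle = np.asarray(has_needle)
    pos_idx = np.flatnonzero(has_needle)
    neg_idx = np.flatnonzero(~has_needle)
    if len(pos_idx) == 0:
        raise ValueError("no needle-containing slices in the training set")
    if len(neg_idx) > len(pos_idx):
        neg_idx = rng.choice(neg_idx, size=len(pos_idx), replace=False)
    keep = np.concatenate([pos_idx, neg_idx])
    rng.shuffle(keep)
    return [Xs[i] for i in keep], [Ys[i] for i in keep]


def _slice_f1(model: ShareFCN, Xs, Ys) -> float:
    tp = fp = fn = 0
    for x, yt in zip(Xs, Ys):
        pred = model.predict_proba(x[None])[0, 1] > 0.5
        tp += int(np.sum(pred & (yt == 1)))
        fp += int(np.sum(pred & (yt == 0)))
        fn += int(np.sum(~pred & (yt == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def train_fcn(dataset, cfg: FCNConfig, tcfg: FCNTrainConfig):
    """Train one shared-weight FCN on balanced slices from both directions.

    ``dataset`` is a sequence of ``(UltrasoundVolume, LabelVolume)`` pairs
    with truth masks.  Returns ``(model, report)``; the report logs per-epoch
    mean loss and pixel-pooled F1 over held-out slices.  With
    ``tcfg.restarts > 1``, several independently initialized runs are trained
    and the one with the best final validation F1 is kept (model selection on
    held-out slices only).
    """
    ss = np.random.SeedSequence(tcfg.seed)
    s_data = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
    rng = np.random.default_rng(s_data)
    Xs, Ys = _slice_pool(dataset, tcfg.gap_d_mm, tcfg.n_rotations, rng)
    n_val = max(1, int(round(tcfg.val_fraction * len(Xs))))
    Xval, Yval = Xs[:n_val], Ys[:n_val]
    Xtr, Ytr = Xs[n_val:], Ys[n_val:]
    if not Xtr:
        Xtr, Ytr = Xs, Ys

    best = None
    for restart, child in enumerate(ss.spawn(tcfg.restarts)):
        s_model, s_order = (int(c.generate_state(1)[0] % 2**31)
                            for c in child.spawn(2))
        order_rng = np.random.default_rng(s_order)
        model = build_fcn(cfg, seed=s_model)
        opt = Adam(model.params(), lr=tcfg.lr)
        report = {"epochs": [], "restart": restart,
                  "n_train_slices": len(Xtr), "n_val_slices": n_val}
        for epoch in range(tcfg.epochs):
            order = order_rng.permutation(len(Xtr))
            losses = []
            for i in order:
                logits = model.forward(Xtr[i][None], train=True)
                loss, grad = softmax_cross_entropy(logits, Ytr[i][None], axis=1)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"training diverged at epoch {epoch}")
                opt.zero_grad()
                model.backward(grad)
                opt.step()
                losses.append(loss)
            report["epochs"].append(
                {"epoch": epoch, "loss": float(np.mean(losses)),
                 "val_f1": _slice_f1(model, Xval, Yval)}
            )
        score = report["epochs"][-1]["val_f1"]
        if best is None or score > best[0]:
            best = (score, model, report)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Inference, fusion, thresholding
# ---------------------------------------------------------------------------


def segment_direction(
    model: ShareFCN,
    v: UltrasoundVolume,
    direction: str,
    gap_d_mm: float = 2.0,
    batch: int = 8,
) -> ProbabilityVolume:
    """Dense per-slice segmentation mapped back into a probability volume."""
    axis = _DIR_AXIS[direction]
    norm = _standardize(v)
    nv = UltrasoundVolume(norm, v.voxel_size_mm, v.origin_mm)
    slices = extract_thick_slices(nv, direction, gap_d_mm)
    prob = np.zeros(v.shape, dtype=np.float32)
    for start in range(0, len(slices), batch):
        chunk = slices[start:start + batch]
        x = np.stack([s.channels for s in chunk]).astype(np.float32)
        p = model.predict_proba(x)[:, 1]
        for s, pm in zip(chunk, p):
            if axis == 0:
                prob[s.position_index] = pm
            else:
                prob[:, :, s.position_index] = pm
    return ProbabilityVolume(np.clip(prob, 0.0, 1.0), v.voxel_size_mm, v.origin_mm)


def fuse_multiplicative(
    p_lat: ProbabilityVolume,
    p_elev: ProbabilityVolume,
    mode: str = "geometric_mean",
) -> ProbabilityVolume:
    """Voxelwise multiplicative averaging of two probability volumes.

    The geometric mean ``sqrt(p_lat * p_elev)`` (default) is the
    multiplicative analogue of averaging and is threshold-equivalent to the
    raw product, which is available as ``mode='product'``.
    """
    if not same_geometry(p_lat, p_elev):
        raise ValueError("probability volumes must share geometry")
    prod = p_lat.probabilities.astype(np.float64) * p_elev.probabilities
    if mode == "geometric_mean":
        fused = np.sqrt(prod)
    elif mode == "product":
        fused = prod
    else:
        raise ValueError("mode must be 'geometric_mean' or 'product'")
    return ProbabilityVolume(fused.astype(np.float32), p_lat.voxel_size_mm, p_lat.origin_mm)


def binarize(p: ProbabilityVolume, threshold: float = 0.5) -> LabelVolume:
    """Threshold a probability volume into a label volume."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return LabelVolume((p.probabilities > threshold).astype(np.uint8),
                       p.voxel_size_mm, p.origin_mm)


def segment_volume(model: ShareFCN, v: UltrasoundVolume, gap_d_mm: float = 2.0,
                   fusion: str = "geometric_mean") -> ProbabilityVolume:
    """Convenience: segment both directions and fuse."""
    p_lat = segment_direction(model, v, "lateral", gap_d_mm)
    p_elev = segment_direction(model, v, "elevational", gap_d_mm)
    return fuse_multiplicative(p_lat, p_elev, fusion)
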