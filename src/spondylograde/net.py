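"""Edge-attention U-Net with PointRend refinement for vertebra segmentation.

The model is a 4-stage encoder/decoder U-Net over 2-D grayscale radiographs.
Each encoder block applies two 3x3 convolutions (each followed by batch
normalisation and ReLU) and a 2x2 max-pool that quarters the feature-map
area, so the bottleneck is 1/16 of the input on each side. Decoder blocks
mirror the encoder, upsampling with 2x2/stride-2 transpose convolutions.

Skip connections pass through an edge-attention fusion: a Canny edge map is
extracted from the channel-mean of the encoder features, concatenated to
them, projected back to the decoder width by a learnable 1x1 convolution and
added to the decoder features at the same stage — sharpening vertebral
margins, which is where the downstream corner landmarks live.

A PointRend head re-predicts the most uncertain pixels (smallest top-2 logit
margin) from full-resolution encoder features, refining boundaries without
recomputing the whole map. Training uses Adam on a focal loss to counter the
heavy background/vertebra class imbalance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage import feature as skfeature

from . import autodiff as ad
from .autodiff import Tensor

log = logging.getLogger(__name__)

N_STAGES = 4


class NetConfigError(ValueError):
    pass


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    `encoder_channels` must have length 4 (one entry per encoder block).
    Canny thresholds act on the channel-mean feature map rescaled to 0..255.
    """

    n_classes: int = 7
    encoder_channels: tuple = (32, 64, 128, 256)
    pointrend_n_points: int = 1024
    pointrend_subdivisions: int = 2
    point_head_hidden: int = 64
    canny_low: float = 50.0
    canny_high: float = 150.0
    canny_sigma: float = 1.0

    def __post_init__(self):
        self.encoder_channels = tuple(int(c) for c in self.encoder_channels)
        if self.n_classes < 2:
            raise NetConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        if len(self.encoder_channels) != N_STAGES:
            raise NetConfigError(
                f"encoder_channels must have length {N_STAGES}, got {len(self.encoder_channels)}")
        if any(c <= 0 for c in self.encoder_channels):
            raise NetConfigError("encoder_channels must be positive")
        if self.pointrend_n_points < 0 or self.pointrend_subdivisions < 0:
            raise NetConfigError("PointRend point/subdivision counts must be >= 0")


@dataclass
class TrainConfig:
    """Optimisation hyperparameters.

    Training stops early when the loss changes by less than
    `early_stop_rel_change` (relative) across the trailing
    `early_stop_window` iterations; set `early_stop_window=0` to disable.
    """

    learning_rate: float = 1e-4
    batch_size: int = 16
    max_iterations: int = 500
    l2_weight: float = 1e-5
    focal_gamma: float = 2.0
    focal_alpha: np.ndarray | None = None  # None -> inverse class frequency
    early_stop_window: int = 50
    early_stop_rel_change: float = 0.10
    seed: int = 0
    train_point_head: bool = True
    point_loss_points: int = 128
    augment_flip: bool = False
    lr_schedule: str = "constant"  # "constant" or "cosine" (decay to 0)
    grad_clip_norm: float | None = None  # global-norm gradient clipping

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_iterations <= 0:
            raise NetConfigError("learning_rate, batch_size, max_iterations must be positive")
        if self.early_stop_window and not (0.0 < self.early_stop_rel_change < 1.0):
            raise NetConfigError("early_stop_rel_change must be in (0, 1)")
        if self.lr_schedule not in ("constant", "cosine"):
            raise NetConfigError(f"unknown lr_schedule {self.lr_schedule!r}")


# ---------------------------------------------------------------------------
# Edge attention
# ---------------------------------------------------------------------------

def compute_edge_map(features: np.ndarray, low: float = 50.0, high: float = 150.0,
                     sigma: float = 1.0) -> np.ndarray:
    """Canny edge map of a feature stack's channel mean.

    `features` is (C, H, W); the channel mean is min-max rescaled to 0..255
    before edge detection. Returns a float {0, 1} map of shape (H, W).
    """
    mean = np.asarray(features, dtype=float).mean(axis=0)
    lo, hi = mean.min(), mean.max()
    if hi > lo:
        mean = (mean - lo) / (hi - lo) * 255.0
    else:
        mean = np.zeros_like(mean)
    edges = skfeature.canny(mean, sigma=sigma, low_threshold=low, high_threshold=high,
                            use_quantiles=False)
    return edges.astype(features.dtype if hasattr(features, "dtype") else np.float32)


def edge_attention_fuse(encoder_features: Tensor, decoder_features: Tensor,
                        proj_weight: Tensor, proj_bias: Tensor,
                        canny_low: float = 50.0, canny_high: float = 150.0,
                        canny_sigma: float = 1.0) -> Tensor:
    """Fuse a skip connection with its Canny edge map into the decoder path.

    The edge map (one channel per sample, non-differentiable) is concatenated
    to the encoder features, projected to the decoder channel count by the
    1x1 convolution (`proj_weight`, `proj_bias`) and added element-wise to
    the decoder features.
    """
    if encoder_features.shape[2:] != decoder_features.shape[2:]:
        raise ValueError(
            f"spatial mismatch: encoder {encoder_features.shape[2:]} "
            f"vs decoder {decoder_features.shape[2:]}")
    edges = np.stack([
        compute_edge_map(encoder_features.data[b], canny_low, canny_high, canny_sigma)
        for b in range(encoder_features.shape[0])
    ])[:, None].astype(encoder_features.data.dtype)
    stacked = ad.concat([encoder_features, Tensor(edges)], axis=1)
    projected = ad.conv2d(stacked, proj_weight, proj_bias)
    return projected + decoder_features


# ---------------------------------------------------------------------------
# PointRend
# ---------------------------------------------------------------------------

def uncertain_points(logits: np.ndarray, n_points: int) -> np.ndarray:
    """Flat indices of the `n_points` pixels with smallest top-2 logit margin.

    `logits` is (K, H, W). Ties and ordering are resolved by a stable sort on
    the margin, so the selection is reproducible and matches an exhaustive
    sort. If `n_points` exceeds the pixel count it is clipped (with a logged
    warning).
    """
    k, h, w = logits.shape
    flat = logits.reshape(k, -1)
    part = np.partition(flat, -2, axis=0)
    margin = part[-1] - part[-2]
    if n_points > margin.size:
        log.warning("pointrend: n_points %d exceeds pixel count %d; clipping",
                    n_points, margin.size)
        n_points = margin.size
    order = np.argsort(margin, kind="stable")
    return order[:n_points]


def _point_head_forward(feats: Tensor, params: dict, prefix: str = "point_head") -> Tensor:
    """3-layer point-wise MLP: (N, P, F) -> (N, P, K)."""
    n, p, f = feats.shape
    x = feats.reshape(n * p, f)
    x = (x @ params[f"{prefix}.w1"] + params[f"{prefix}.b1"]).relu()
    x = (x @ params[f"{prefix}.w2"] + params[f"{prefix}.b2"]).relu()
    x = x @ params[f"{prefix}.w3"] + params[f"{prefix}.b3"]
    return x.reshape(n, p, -1)


def pointrend_refine(coarse_logits: np.ndarray, fine_features: np.ndarray,
                     n_points: int, params: dict, subdivisions: int = 1) -> np.ndarray:
    """Re-predict the most uncertain pixels from fine features.

    `coarse_logits` is (K, H, W), `fine_features` (C, H, W). Each round
    selects the `n_points` smallest-margin pixels of the current logits and
    replaces only those pixels with the point head's output; all other pixels
    are left bit-identical.
    """
    logits = np.array(coarse_logits, copy=True)
    k, h, w = logits.shape
    if n_points == 0 or subdivisions == 0:
        return logits
    for _ in range(subdivisions):
        idx = uncertain_points(logits, n_points)
        rows, cols = np.unravel_index(idx, (h, w))
        feats = np.concatenate([fine_features[:, rows, cols], logits[:, rows, cols]], axis=0).T
        out = _point_head_forward(Tensor(feats[None]), params).data[0]
        logits[:, rows, cols] = out.T
    return logits


# ---------------------------------------------------------------------------
# Focal loss
# ---------------------------------------------------------------------------

def focal_loss(prob_map: np.ndarray, target: np.ndarray, gamma: float = 2.0,
               alpha=1.0, eps: float = 1e-12) -> float:
    """Mean focal loss from per-pixel class probabilities.

    `prob_map` is (K, H, W) (or (N, K, H, W)) of probabilities, `target` the
    matching integer label mask. `alpha` is a scalar or per-class weight
    vector. Probabilities are clamped at `eps` before the log.
    """
    p = np.asarray(prob_map, dtype=float)
    t = np.asarray(target)
    if p.ndim == 3:
        p, t = p[None], t[None]
    if p.shape[0] != t.shape[0] or p.shape[2:] != t.shape[1:]:
        raise ValueError(f"shape mismatch: probs {p.shape} vs target {t.shape}")
    p_c = np.take_along_axis(p, t[:, None], axis=1)[:, 0]
    if (p_c < eps).any():
        log.warning("focal_loss: %d pixel(s) with true-class probability < eps clamped",
                    int((p_c < eps).sum()))
    p_c = np.maximum(p_c, eps)
    alpha = np.asarray(alpha, dtype=float)
    a_c = alpha[t] if alpha.ndim == 1 else alpha
    return float(np.mean(-a_c * (1.0 - p_c) ** gamma * np.log(p_c)))


def _focal_loss_from_logits(logits: Tensor, target: np.ndarray, gamma: float,
                            alpha: np.ndarray | float) -> Tensor:
    """Differentiable focal loss on raw logits (numerically stable path)."""
    logp = logits.log_softmax(axis=1)
    logp_c = logp.gather_class(target, axis=1)
    p_c = logp_c.exp()
    alpha_arr = np.asarray(alpha, dtype=logits.data.dtype)
    a_c = alpha_arr[target] if alpha_arr.ndim == 1 else float(alpha_arr)
    modulator = ((1.0 - p_c).clamp_min(1e-12)) ** gamma
    return (modulator * (-logp_c) * a_c).mean()


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class EdgeAttentionUNet:
    """The network: parameters, forward pass, and shape bookkeeping."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}
        self.bn_state: dict[str, dict] = {}
        self._init_params(np.random.default_rng(seed))

    # -- initialisation -------------------------------------------------------
    def _conv_param(self, rng, name, c_out, c_in, k):
        std = np.sqrt(2.0 / (c_in * k * k))
        self.params[f"{name}.w"] = Tensor(
            rng.normal(0, std, (c_out, c_in, k, k)).astype(np.float32), requires_grad=True)
        self.params[f"{name}.b"] = Tensor(np.zeros(c_out, np.float32), requires_grad=True)

    def _bn_param(self, name, c):
        self.params[f"{name}.gamma"] = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.params[f"{name}.beta"] = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.bn_state[name] = {"mean": np.zeros(c, np.float32), "var": np.ones(c, np.float32)}

    def _init_params(self, rng):
        ch = self.cfg.encoder_channels
        k_cls = self.cfg.n_classes
        c_in = 1
        for i, c in enumerate(ch):
            self._conv_param(rng, f"enc{i}.conv1", c, c_in, 3)
            self._bn_param(f"enc{i}.bn1", c)
            self._conv_param(rng, f"enc{i}.conv2", c, c, 3)
            self._bn_param(f"enc{i}.bn2", c)
            c_in = c
        # decoder stage i consumes the skip from encoder stage i
        for i in reversed(range(N_STAGES)):
            c_skip = ch[i]
            up_in = self._up_in(i)
            self.params[f"dec{i}.up.w"] = Tensor(
                rng.normal(0, np.sqrt(2.0 / (up_in * 4)),
                           (up_in, c_skip, 2, 2)).astype(np.float32), requires_grad=True)
            self.params[f"dec{i}.up.b"] = Tensor(np.zeros(c_skip, np.float32), requires_grad=True)
            self._conv_param(rng, f"dec{i}.edge_proj", c_skip, c_skip + 1, 1)
            c_out = ch[i - 1] if i > 0 else ch[0]
            self._conv_param(rng, f"dec{i}.conv1", c_out, c_skip, 3)
            self._bn_param(f"dec{i}.bn1", c_out)
            self._conv_param(rng, f"dec{i}.conv2", c_out, c_out, 3)
            self._bn_param(f"dec{i}.bn2", c_out)
        self._conv_param(rng, "head", k_cls, ch[0], 1)
        # PointRend head: fine features (ch[0]) + coarse logits (K) -> K
        f_in = ch[0] + k_cls
        hid = self.cfg.point_head_hidden
        for j, (fi, fo) in enumerate([(f_in, hid), (hid, hid), (hid, k_cls)], start=1):
            std = np.sqrt(2.0 / fi)
            self.params[f"point_head.w{j}"] = Tensor(
                rng.normal(0, std, (fi, fo)).astype(np.float32), requires_grad=True)
            self.params[f"point_head.b{j}"] = Tensor(np.zeros(fo, np.float32), requires_grad=True)

    def _up_in(self, stage: int) -> int:
        """Channel count entering decoder stage `stage`'s transpose conv."""
        ch = self.cfg.encoder_channels
        if stage == N_STAGES - 1:
            return ch[-1]          # straight from the bottleneck
        return ch[stage]           # output width of the stage above

    # -- forward --------------------------------------------------------------
    def _enc_block(self, x: Tensor, i: int, training: bool) -> Tensor:
        p, bn = self.params, self.bn_state
        x = ad.conv2d(x, p[f"enc{i}.conv1.w"], p[f"enc{i}.conv1.b"])
        x = ad.batchnorm2d(x, p[f"enc{i}.bn1.gamma"], p[f"enc{i}.bn1.beta"],
                           bn[f"enc{i}.bn1"], training).relu()
        x = ad.conv2d(x, p[f"enc{i}.conv2.w"], p[f"enc{i}.conv2.b"])
        x = ad.batchnorm2d(x, p[f"enc{i}.bn2.gamma"], p[f"enc{i}.bn2.beta"],
                           bn[f"enc{i}.bn2"], training).relu()
        return x

    def _dec_block(self, x: Tensor, skip: Tensor, i: int, training: bool) -> Tensor:
        p, bn = self.params, self.bn_state
        x = ad.conv_transpose2d(x, p[f"dec{i}.up.w"], p[f"dec{i}.up.b"])
        x = edge_attention_fuse(skip, x, p[f"dec{i}.edge_proj.w"], p[f"dec{i}.edge_proj.b"],
                                self.cfg.canny_low, self.cfg.canny_high, self.cfg.canny_sigma)
        x = ad.conv2d(x, p[f"dec{i}.conv1.w"], p[f"dec{i}.conv1.b"])
        x = ad.batchnorm2d(x, p[f"dec{i}.bn1.gamma"], p[f"dec{i}.bn1.beta"],
                           bn[f"dec{i}.bn1"], training).relu()
        x = ad.conv2d(x, p[f"dec{i}.conv2.w"], p[f"dec{i}.conv2.b"])
        x = ad.batchnorm2d(x, p[f"dec{i}.bn2.gamma"], p[f"dec{i}.bn2.beta"],
                           bn[f"dec{i}.bn2"], training).relu()
        return x

    def forward(self, images: np.ndarray, training: bool = False):
        """Full-resolution logits and stage-1 (fine) encoder features.

        `images` is (N, 1, H, W) float in [0, 1]; H and W must be divisible
        by 16 (callers pad otherwise). Returns (logits, fine_features).
        """
        n, _, h, w = images.shape
        if h % 16 or w % 16:
            raise ValueError(f"spatial dims must be divisible by 16, got {(h, w)}")
        x = Tensor(images.astype(np.float32))
        skips = []
        for i in range(N_STAGES):
            x = self._enc_block(x, i, training)
            skips.append(x)
            x = ad.maxpool2x2(x)
        for i in reversed(range(N_STAGES)):
            x = self._dec_block(x, skips[i], i, training)
        logits = ad.conv2d(x, self.params["head.w"], self.params["head.b"])
        return logits, skips[0]

    def probability_map(self, images: np.ndarray, training: bool = False) -> np.ndarray:
        """Per-pixel class probabilities (softmax over refined logits)."""
        logits, fine = self.forward(images, training=training)
        out = []
        for b in range(images.shape[0]):
            refined = pointrend_refine(logits.data[b], fine.data[b],
                                       self._n_points(images.shape[2:]), self.params,
                                       self.cfg.pointrend_subdivisions)
            z = refined - refined.max(axis=0, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=0, keepdims=True))
        return np.stack(out)

    def _n_points(self, hw) -> int:
        """PointRend budget scaled with image area (reference: 256x256)."""
        scale = (hw[0] * hw[1]) / (256.0 * 256.0)
        return max(1, int(round(self.cfg.pointrend_n_points * min(1.0, scale))))

    def trainable(self) -> list[Tensor]:
        return list(self.params.values())

    def stage_shapes(self, h: int, w: int) -> list[tuple]:
        """Spatial size after each encoder block's pooling (bottleneck last)."""
        shapes = []
        for _ in range(N_STAGES):
            h, w = h // 2, w // 2
            shapes.append((h, w))
        return shapes

    # -- serialization --------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param::{k}": v.data for k, v in self.params.items()}
        for name, st in self.bn_state.items():
            arrays[f"bnmean::{name}"] = st["mean"]
            arrays[f"bnvar::{name}"] = st["var"]
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "EdgeAttentionUNet":
        data = np.load(path)
        cfg = NetConfig(**json.loads(bytes(data["__config__"]).decode()))
        net = cls(cfg, seed=0)
        for key in data.files:
            if key.startswith("param::"):
                net.params[key[7:]] = Tensor(data[key], requires_grad=True)
            elif key.startswith("bnmean::"):
                net.bn_state[key[8:]]["mean"] = data[key]
            elif key.startswith("bnvar::"):
                net.bn_state[key[7:]]["var"] = data[key]
        return net


def build_network(cfg: NetConfig, seed: int = 0) -> EdgeAttentionUNet:
    """Construct the network with seeded parameter initialisation."""
    return EdgeAttentionUNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Training (Model / Results)
# ---------------------------------------------------------------------------

def should_stop(trace: list, window: int, rel_change: float) -> bool:
    """Early-stopping rule: relative loss change across the trailing window.

    True once the loss `window` iterations ago differs from the current loss
    by less than `rel_change` (relative). With a constant trace this fires
    exactly when the trace length reaches the window.
    """
    if not window or len(trace) < window:
        return False
    ref, cur = trace[-window], trace[-1]
    return abs(cur - ref) / max(abs(ref), 1e-12) < rel_change


def inverse_frequency_alpha(masks: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class focal weights proportional to inverse pixel frequency."""
    counts = np.bincount(np.asarray(masks).ravel(), minlength=n_classes).astype(float)
    counts = np.maximum(counts, 1.0)
    alpha = 1.0 / counts
    return (alpha / alpha.sum() * n_classes).astype(np.float32)


class SegmentationModel:
    """Vertebra segmentation model bound to a training set.

    Parameters
    ----------
    images, masks
        Arrays of shape (N, H, W): grayscale images (uint8 or float) and
        integer label masks (0 background, 1..5 lumbar, 6 sacrum).
    net_config
        Architecture settings; defaults follow :class:`NetConfig`.
    """

    def __init__(self, images: np.ndarray, masks: np.ndarray,
                 net_config: NetConfig | None = None):
        images = np.asarray(images)
        masks = np.asarray(masks)
        if images.ndim != 3 or masks.shape != images.shape:
            raise ValueError("images and masks must both be (N, H, W)")
        if images.shape[0] == 0:
            raise ValueError("training set is empty")
        self.images = images
        self.masks = masks.astype(np.int64)
        self.net_config = net_config or NetConfig()

    @classmethod
    def from_manifest(cls, manifest, data_dir, net_config: NetConfig | None = None):
        """Build from a phantom dataset manifest (paths relative to data_dir)."""
        from .phantom import load_pair

        if not manifest.entries:
            raise ValueError("manifest is empty")
        pairs = [load_pair(data_dir, e) for e in manifest.entries]
        images = np.stack([p[0] for p in pairs])
        masks = np.stack([p[1] for p in pairs])
        return cls(images, masks, net_config)

    def fit(self, train_config: TrainConfig | None = None) -> "SegmentationResults":
        """Train with Adam on the focal loss; returns fitted results."""
        cfg = train_config or TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        net = build_network(self.net_config, seed=cfg.seed)
        alpha = (np.asarray(cfg.focal_alpha, dtype=np.float32)
                 if cfg.focal_alpha is not None
                 else inverse_frequency_alpha(self.masks, self.net_config.n_classes))
        opt = ad.Adam(net.trainable(), lr=cfg.learning_rate, l2_weight=cfg.l2_weight)

        x_all = (self.images.astype(np.float32) / 255.0)[:, None]
        n = x_all.shape[0]
        order = rng.permutation(n)
        cursor = 0
        trace: list[float] = []
        stop_reason = "max_iterations"
        for it in range(cfg.max_iterations):
            if cursor + cfg.batch_size > n:
                order = rng.permutation(n)
                cursor = 0
            idx = order[cursor:cursor + cfg.batch_size]
            cursor += cfg.batch_size
            xb, yb = x_all[idx], self.masks[idx]
            if cfg.augment_flip and rng.random() < 0.5:
                xb, yb = xb[..., ::-1].copy(), yb[..., ::-1].copy()

            if cfg.lr_schedule == "cosine":
                opt.lr = cfg.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * it / cfg.max_iterations))
            logits, fine = net.forward(xb, training=True)
            loss = _focal_loss_from_logits(logits, yb, cfg.focal_gamma, alpha)
            if cfg.train_point_head and cfg.point_loss_points > 0:
                loss = loss + _point_loss(net, logits, fine, yb, cfg, alpha)
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite training loss at iteration {it}: {loss_val}")
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip_norm:
                _clip_grad_norm(net.trainable(), cfg.grad_clip_norm)
            opt.step()
            trace.append(loss_val)
            if should_stop(trace, cfg.early_stop_window, cfg.early_stop_rel_change):
                stop_reason = "early_stop"
                break
        return SegmentationResults(model=self, network=net, train_config=cfg,
                                   loss_trace=trace, stop_reason=stop_reason,
                                   focal_alpha=alpha)


def _clip_grad_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _point_loss(net: EdgeAttentionUNet, logits: Tensor, fine: Tensor,
                target: np.ndarray, cfg: TrainConfig, alpha) -> Tensor:
    """Auxiliary focal loss on the point head at the most uncertain pixels."""
    n, k, h, w = logits.shape
    # a single point set shared across the batch keeps the graph small:
    # the batch-mean uncertainty is a cheap deterministic proxy
    idx = uncertain_points(logits.data.mean(axis=0), cfg.point_loss_points)
    rows, cols = np.unravel_index(idx, (h, w))
    feats = ad.concat([fine.take_points(rows, cols), logits.take_points(rows, cols)], axis=2)
    point_logits = _point_head_forward(feats, net.params)  # (N, P, K)
    labels = target[:, rows, cols]  # (N, P)
    return _focal_loss_from_logits(
        point_logits.reshape(n * len(rows), k, 1, 1),
        labels.reshape(-1, 1, 1), cfg.focal_gamma, alpha)


class SegmentationResults:
    """Fitted segmentation model: parameters, loss trace and prediction."""

    def __init__(self, model, network: EdgeAttentionUNet, train_config: TrainConfig,
                 loss_trace: list, stop_reason: str, focal_alpha: np.ndarray):
        self.model = model
        self.network = network
        self.train_config = train_config
        self.loss_trace = list(loss_trace)
        self.stop_reason = stop_reason
        self.focal_alpha = focal_alpha

    @property
    def n_iterations(self) -> int:
        return len(self.loss_trace)

    def predict(self, image: np.ndarray, clean: bool = True) -> np.ndarray:
        """Predicted label mask for a single 2-D grayscale image.

        `clean` applies a light per-label morphological opening, which
        stabilises the convex-hull corners extracted downstream.
        """
        return predict(image, self.network, clean=clean)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (n_classes, H, W) for one image."""
        x, crop = _pad_to_16(np.asarray(image))
        probs = self.network.probability_map(x[None, None].astype(np.float32) / 255.0)[0]
        return probs[:, crop[0]:crop[1], crop[2]:crop[3]]

    def loss_frame(self):
        import pandas as pd

        return pd.DataFrame({"iteration": np.arange(1, self.n_iterations + 1),
                             "loss": self.loss_trace})

    def save_loss_trace(self, path) -> None:
        self.loss_frame().to_csv(path, index=False)

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, self.n_iterations + 1), self.loss_trace)
        ax.set_xlabel("iteration")
        ax.set_ylabel("focal loss")
        ax.set_title("training loss")
        return ax

    def summary(self) -> str:
        n_params = sum(p.data.size for p in self.network.params.values())
        lines = [
            "Edge-attention PointRend U-Net — training summary",
            "=" * 50,
            f"classes:            {self.network.cfg.n_classes}",
            f"encoder channels:   {self.network.cfg.encoder_channels}",
            f"parameters:         {n_params}",
            f"training images:    {self.model.images.shape[0]}",
            f"iterations run:     {self.n_iterations} ({self.stop_reason})",
            f"first-iter loss:    {self.loss_trace[0]:.6f}",
            f"final loss:         {self.loss_trace[-1]:.6f}",
            f"focal gamma:        {self.train_config.focal_gamma}",
            f"focal alpha:        {np.array2string(np.asarray(self.focal_alpha), precision=3)}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.network.save(path)

    @classmethod
    def load(cls, path) -> "SegmentationResults":
        net = EdgeAttentionUNet.load(path)
        return cls(model=None, network=net, train_config=TrainConfig(),
                   loss_trace=[], stop_reason="loaded", focal_alpha=np.ones(net.cfg.n_classes))


def _pad_to_16(image: np.ndarray):
    h, w = image.shape
    ph = (-h) % 16
    pw = (-w) % 16
    padded = np.pad(image, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else image
    return padded, (0, h, 0, w)


def train(manifest, data_dir, net_config: NetConfig | None = None,
          train_config: TrainConfig | None = None) -> SegmentationResults:
    """Convenience wrapper: fit a SegmentationModel from a dataset manifest."""
    return SegmentationModel.from_manifest(manifest, data_dir, net_config).fit(train_config)


def predict(image: np.ndarray, network: EdgeAttentionUNet, clean: bool = True) -> np.ndarray:
    """Segment one grayscale image into labels 0..n_classes-1.

    Images whose sides are not divisible by 16 are reflect-padded and the
    output cropped back. A light per-label morphological opening (`clean`)
    removes single-pixel boundary protrusions that would otherwise corrupt
    the convex-hull landmarks. Inference is deterministic for fixed
    parameters.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    padded, crop = _pad_to_16(image)
    probs = network.probability_map(padded[None, None].astype(np.float32) / 255.0)[0]
    mask = probs.argmax(axis=0).astype(np.uint8)
    mask = mask[crop[0]:crop[1], crop[2]:crop[3]]
    if clean:
        from .geometry import clean_mask

        mask = clean_mask(mask)
    return mask
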