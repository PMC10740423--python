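"""Edge-aware dual-decoder segmentation network and baseline UNet.

The edge-aware network (CEL-UNet) shares one encoder and splits the
decoding path into two parallel branches: one for semantic segmentation
(tibia / femur / background) and one for bone-boundary identification. At
every decoder level the edge branch's feature maps are concatenated into
the segmentation branch (edge -> segmentation only, never the reverse) and
fused by the level's convolution block, sharpening narrow-border detection.

Three training objectives are provided:

* combined edge loss (CEL): region term (soft-Dice + cross-entropy,
  averaged) on the segmentation head plus ``lambda_edge`` times a soft-Dice
  term on the edge head;
* distance cross-entropy (DCE): cross-entropy weighted by
  ``1 + beta * exp(-D/tau)`` with ``D`` the Euclidean distance (in voxels)
  to the nearest inter-class boundary of the target;
* focal loss (FOC): ``-(1 - p_t)^gamma * log p_t``.

Training is plain Adam on seeded mini-batches of patches; whole-volume
inference tiles the CT with the planned overlapping patches, softmax-
normalizes per-patch scores, mean-blends them back and takes the argmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from ._autodiff import (
    Adam,
    Parameter,
    Tensor,
    as_tensor,
    channel_standardize,
    concat,
    conv3d,
    log,
    maxpool2,
    no_grad,
    pow_const,
    relu,
    sigmoid,
    softmax_lastdim,
    tmean,
    tsum,
    upsample2,
)
from .core import CTVolume, ConfigurationError, DataQualityError, LabelVolume, logger
from .preprocessing import pad_to_patch, plan_patches, stitch_patches, strip_padding

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    ``input_patch`` is the cubic patch edge (160 at full scale; 32-64 for
    desk-scale experiments). ``depth`` counts resolution levels including
    the bottleneck; the patch edge must be divisible by ``2**(depth-1)``.
    """

    input_patch: int = 160
    depth: int = 4
    base_channels: int = 32
    classes: int = 3
    edge_branch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.input_patch % 2 ** (self.depth - 1) != 0:
            raise ConfigurationError(
                f"input_patch {self.input_patch} not divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}"
            )


@dataclass
class LossConfig:
    """Objective selection and coefficients."""

    kind: str = "CEL"           # CEL | DCE | FOC
    lambda_edge: float = 1.0
    gamma: float = 2.0
    dce_beta: float = 5.0
    dce_tau: float = 3.0        # voxels

    def __post_init__(self) -> None:
        if self.kind not in ("CEL", "DCE", "FOC"):
            raise ConfigurationError(f"unknown loss kind {self.kind!r}")
        if self.lambda_edge < 0 or self.gamma < 0 or self.dce_tau <= 0:
            raise ConfigurationError("invalid loss coefficients")


@dataclass
class TrainState:
    """Append-only training record: one entry per optimizer step / epoch."""

    steps: int = 0
    loss_history: List[Dict[str, float]] = field(default_factory=list)
    dice_history: List[float] = field(default_factory=list)
    seed: int = 0


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

class _ConvBlock:
    """conv3x3 -> per-channel standardize -> affine -> relu, twice."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, name: str):
        self.name = name
        self.params: Dict[str, Parameter] = {}
        self._w1 = self._conv_init(rng, 3, cin, cout, "c1")
        self._w2 = self._conv_init(rng, 3, cout, cout, "c2")

    def _conv_init(self, rng, k, cin, cout, tag):
        std = np.sqrt(2.0 / (k**3 * cin))
        w = Parameter(rng.normal(0.0, std, size=(k, k, k, cin, cout)).astype(np.float32))
        b = Parameter(np.zeros(cout, dtype=np.float32))
        gain = Parameter(np.ones(cout, dtype=np.float32))
        bias = Parameter(np.zeros(cout, dtype=np.float32))
        self.params.update({f"{self.name}.{tag}.w": w, f"{self.name}.{tag}.b": b,
                            f"{self.name}.{tag}.gain": gain, f"{self.name}.{tag}.bias": bias})
        return (w, b, gain, bias)

    def __call__(self, x: Tensor) -> Tensor:
        for w, b, gain, bias in (self._w1, self._w2):
            x = conv3d(x, w, b)
            x = channel_standardize(x)
            x = relu(x * gain + bias)
        return x


class _Head:
    """1x1x1 linear projection to class channels."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, name: str):
        std = np.sqrt(1.0 / cin)
        self.w = Parameter(rng.normal(0.0, std, size=(1, 1, 1, cin, cout)).astype(np.float32))
        self.b = Parameter(np.zeros(cout, dtype=np.float32))
        self.params = {f"{name}.w": self.w, f"{name}.b": self.b}

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b)


class SegmentationModel:
    """Shared-encoder UNet with an optional parallel edge decoder."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        ss = np.random.SeedSequence(cfg.seed)
        # independent init streams so the encoder is identical with and
        # without the edge branch at equal seed
        rng_enc, rng_edge, rng_seg, rng_hs, rng_he = (
            np.random.default_rng(c) for c in ss.spawn(5)
        )
        ch = [cfg.base_channels * 2**i for i in range(cfg.depth)]
        self.enc: List[_ConvBlock] = []
        cin = 1
        for i in range(cfg.depth):
            self.enc.append(_ConvBlock(rng_enc, cin, ch[i], f"enc{i}"))
            cin = ch[i]
        self.edge_dec: List[Optional[_ConvBlock]] = []
        self.seg_dec: List[_ConvBlock] = []
        for i in range(cfg.depth - 2, -1, -1):
            if cfg.edge_branch:
                self.edge_dec.append(_ConvBlock(rng_edge, ch[i + 1] + ch[i], ch[i], f"edge{i}"))
            seg_in = ch[i + 1] + ch[i] + (ch[i] if cfg.edge_branch else 0)
            self.seg_dec.append(_ConvBlock(rng_seg, seg_in, ch[i], f"seg{i}"))
        self.seg_head = _Head(rng_hs, ch[0], cfg.classes, "seg_head")
        self.edge_head = _Head(rng_he, ch[0], cfg.classes, "edge_head") if cfg.edge_branch else None

    def parameters(self) -> Dict[str, Parameter]:
        out: Dict[str, Parameter] = {}
        for blk in self.enc + [b for b in self.edge_dec if b] + self.seg_dec:
            out.update(blk.params)
        out.update(self.seg_head.params)
        if self.edge_head is not None:
            out.update(self.edge_head.params)
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def forward(self, x: Tensor) -> Tuple[Tensor, Optional[Tensor]]:
        """x: (N, D, H, W, 1) in [0, 1] -> (seg logits, edge logits or None)."""
        feats: List[Tensor] = []
        cur = x
        for i, blk in enumerate(self.enc):
            if i > 0:
                cur = maxpool2(cur)
            cur = blk(cur)
            feats.append(cur)
        e = feats[-1]
        s = feats[-1]
        for j, i in enumerate(range(self.cfg.depth - 2, -1, -1)):
            if self.cfg.edge_branch:
                e = self.edge_dec[j](concat([upsample2(e), feats[i]]))
                s = self.seg_dec[j](concat([upsample2(s), feats[i], e]))
            else:
                s = self.seg_dec[j](concat([upsample2(s), feats[i]]))
        seg_logits = self.seg_head(s)
        edge_logits = self.edge_head(e) if self.cfg.edge_branch else None
        return seg_logits, edge_logits


def build_cel_unet(cfg: NetworkConfig) -> SegmentationModel:
    """Dual-decoder edge-aware network (edge branch on unless disabled in cfg)."""
    return SegmentationModel(cfg)


def build_unet(cfg: NetworkConfig) -> SegmentationModel:
    """Baseline single-decoder UNet (identical encoder layout at equal seed)."""
    from dataclasses import replace

    return SegmentationModel(replace(cfg, edge_branch=False))


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

_EPS_LOG = 1e-12
_EPS_DICE = 1e-6


def _check_probs(p: np.ndarray) -> None:
    s = p.sum(axis=-1)
    if not np.allclose(s, 1.0, atol=1e-3):
        raise DataQualityError(
            "predictions are not normalized over classes (apply softmax first)"
        )


def _p_true(pred: Tensor, target_onehot: np.ndarray) -> Tensor:
    return tsum(pred * as_tensor(target_onehot), axis=-1)


def focal_loss(pred_probs, target_onehot: np.ndarray, gamma: float = 2.0) -> Tensor:
    """Mean over voxels of ``-(1-p_t)^gamma * log(p_t)``; gamma=0 is plain
    cross-entropy. Channel axis is last."""
    pred = as_tensor(pred_probs)
    _check_probs(pred.data)
    p_t = _p_true(pred, np.asarray(target_onehot))
    logp = log(p_t + _EPS_LOG)
    if gamma == 0.0:
        return tmean(-logp)
    return tmean(-(pow_const(as_tensor(1.0) - p_t, gamma) * logp))


def boundary_distance_map(labels: np.ndarray, spacing_voxels: float = 1.0) -> np.ndarray:
    """Euclidean distance (voxels) to the nearest inter-class boundary.

    A boundary voxel is one with a 6-neighbour of a different class; such
    voxels get distance 0. A uniform map has no boundary: all-infinite.
    """
    lab = np.asarray(labels)
    boundary = np.zeros(lab.shape, dtype=bool)
    for ax in range(lab.ndim):
        sl_a = [slice(None)] * lab.ndim
        sl_b = [slice(None)] * lab.ndim
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        diff = lab[tuple(sl_a)] != lab[tuple(sl_b)]
        boundary[tuple(sl_a)] |= diff
        boundary[tuple(sl_b)] |= diff
    if not boundary.any():
        return np.full(lab.shape, np.inf)
    return ndimage.distance_transform_edt(~boundary, sampling=spacing_voxels)


def distance_cross_entropy_loss(
    pred_probs, target_onehot: np.ndarray, target_labels: np.ndarray,
    dce_beta: float = 5.0, dce_tau: float = 3.0,
) -> Tensor:
    """Cross-entropy with boundary-emphasised weights
    ``w = 1 + beta * exp(-D / tau)``; beta=0 is plain cross-entropy."""
    pred = as_tensor(pred_probs)
    _check_probs(pred.data)
    lab = np.asarray(target_labels)
    if lab.ndim == pred.data.ndim - 1 and lab.shape[0] == pred.data.shape[0]:
        dmaps = np.stack([boundary_distance_map(lab[i]) for i in range(lab.shape[0])])
    else:
        dmaps = boundary_distance_map(lab)
    with np.errstate(over="ignore"):
        w = 1.0 + dce_beta * np.exp(-dmaps / dce_tau)
    p_t = _p_true(pred, np.asarray(target_onehot))
    return tmean(as_tensor(w) * (-log(p_t + _EPS_LOG)))


def soft_dice_loss(pred_probs, target_onehot: np.ndarray) -> Tensor:
    """1 - mean over classes of (2*sum(p*g)+eps)/(sum(p)+sum(g)+eps)."""
    pred = as_tensor(pred_probs)
    tgt = as_tensor(np.asarray(target_onehot, dtype=pred.data.dtype))
    axes = tuple(range(pred.data.ndim - 1))
    inter = tsum(pred * tgt, axis=axes)
    denom = tsum(pred, axis=axes) + tsum(tgt, axis=axes)
    dice = (as_tensor(2.0) * inter + _EPS_DICE) / (denom + _EPS_DICE)
    return as_tensor(1.0) - tmean(dice)


def combined_edge_loss(
    pred_seg_probs, pred_edge_probs, gt_seg_onehot: np.ndarray,
    gt_edge: Optional[np.ndarray], cfg: LossConfig,
) -> Tuple[Tensor, Dict[str, float]]:
    """Region term + lambda_edge * edge term.

    Region = (soft-Dice loss + cross-entropy) / 2 on the segmentation head;
    edge = soft-Dice loss on the per-class edge maps (sigmoid activations).
    Returns the total plus the individual terms for logging.
    """
    pred_seg = as_tensor(pred_seg_probs)
    _check_probs(pred_seg.data)
    ce = tmean(-log(_p_true(pred_seg, np.asarray(gt_seg_onehot)) + _EPS_LOG))
    dice = soft_dice_loss(pred_seg, gt_seg_onehot)
    region = as_tensor(0.5) * (dice + ce)
    if cfg.lambda_edge == 0.0:
        total = region
        terms = {"region": region.item(), "edge": 0.0, "total": total.item()}
        return total, terms
    if pred_edge_probs is None or gt_edge is None:
        raise DataQualityError(
            "edge branch is enabled but edge predictions or edge ground truth are missing"
        )
    edge = soft_dice_loss(as_tensor(pred_edge_probs), np.asarray(gt_edge))
    total = region + as_tensor(cfg.lambda_edge) * edge
    return total, {"region": region.item(), "edge": edge.item(), "total": total.item()}


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _onehot(labels: np.ndarray, classes: int) -> np.ndarray:
    return np.eye(classes, dtype=np.float32)[np.asarray(labels, dtype=np.int64)]


def compute_loss(
    model_out: Tuple[Tensor, Optional[Tensor]],
    labels: np.ndarray,
    edges: Optional[np.ndarray],
    cfg: LossConfig,
    classes: int,
) -> Tuple[Tensor, Dict[str, float]]:
    """Dispatch on the configured objective; labels (N,D,H,W), edges (N,D,H,W,C)."""
    seg_logits, edge_logits = model_out
    probs = softmax_lastdim(seg_logits)
    onehot = _onehot(labels, classes)
    if cfg.kind == "CEL":
        edge_probs = sigmoid(edge_logits) if edge_logits is not None else None
        return combined_edge_loss(probs, edge_probs, onehot, edges, cfg)
    if cfg.kind == "DCE":
        loss = distance_cross_entropy_loss(probs, onehot, labels, cfg.dce_beta, cfg.dce_tau)
    else:
        loss = focal_loss(probs, onehot, cfg.gamma)
    return loss, {"total": loss.item()}


def patch_dataset_from_volume(
    ct_norm: CTVolume,
    labels: LabelVolume,
    patch_size: int,
    edge_thickness: int = 1,
    bone_weight_floor: float = 0.05,
) -> Tuple[list, np.ndarray]:
    """Tile a normalized volume into training triples with sampling weights.

    Patches come from the planned overlapping tiling of the *whole* volume
    (background-only patches included, so inference sees no unfamiliar
    inputs); sampling weights are proportional to bone content plus a floor
    so background patches are still visited.
    """
    from .label_generation import edge_ground_truth
    from .preprocessing import extract_patches, pad_to_patch, plan_patches

    p = patch_size
    vox, _ = pad_to_patch(ct_norm.voxels, p)
    labv, _ = pad_to_patch(labels.voxels, p)
    grid = plan_patches(vox.shape, p)
    edges = edge_ground_truth(LabelVolume(labv, spacing=labels.spacing),
                              thickness=edge_thickness)
    xs = extract_patches(vox, grid)
    ys = extract_patches(labv, grid)
    es = [np.stack([e[i:i + p, j:j + p, k:k + p] for e in edges.voxels])
          for (i, j, k) in grid.placements()]
    bone_frac = np.array([float((y != 0).mean()) for y in ys])
    w = bone_weight_floor + bone_frac
    return list(zip(xs, ys, es)), w / w.sum()


def train(
    model: SegmentationModel,
    dataset: Sequence[Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]],
    loss_cfg: Optional[LossConfig] = None,
    steps: int = 200,
    batch_size: int = 2,
    lr: float = 1e-3,
    lr_min: Optional[float] = None,
    sample_weights: Optional[np.ndarray] = None,
    seed: int = 0,
    checkpoint_path: Optional[Union[str, Path]] = None,
    log_every: int = 25,
) -> TrainState:
    """Seeded mini-batch Adam training on (patch, label, edge) triples.

    ``dataset`` items: patch (D,H,W) float in [0,1]; labels (D,H,W) int;
    edges (classes, D, H, W) bool or None when the edge branch is off.
    ``lr_min`` enables a cosine decay from ``lr`` to ``lr_min``;
    ``sample_weights`` biases patch selection (e.g. toward bone content).
    Deterministic for fixed seed (data order, init, no augmentation).
    """
    if len(dataset) == 0:
        raise DataQualityError("training dataset is empty")
    loss_cfg = loss_cfg or LossConfig()
    p = model.cfg.input_patch
    for patch, _, _ in dataset:
        if patch.shape != (p, p, p):
            raise DataQualityError(f"patch shape {patch.shape} != model input {p}^3")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters().values(), lr=lr)
    state = TrainState(seed=seed)
    for step in range(steps):
        if lr_min is not None and steps > 1:
            opt.lr = lr_min + 0.5 * (lr - lr_min) * (1 + np.cos(np.pi * step / (steps - 1)))
        idx = rng.choice(len(dataset), size=batch_size, p=sample_weights)
        x = np.stack([dataset[i][0] for i in idx]).astype(np.float32)[..., None]
        y = np.stack([dataset[i][1] for i in idx])
        if model.cfg.edge_branch:
            e = np.stack([dataset[i][2] for i in idx])  # (N, C, D, H, W)
            e = np.moveaxis(e, 1, -1).astype(np.float32)
        else:
            e = None
        out = model.forward(Tensor(x))
        loss, terms = compute_loss(out, y, e, loss_cfg, model.cfg.classes)
        if not np.isfinite(loss.item()):
            raise RuntimeError(
                f"NaN/inf loss at step {step}: {terms}; aborting (check lr and inputs)"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        state.loss_history.append(terms)
        state.steps = step + 1
        if log_every and (step % log_every == 0 or step == steps - 1):
            logger.info("train step %d/%d loss=%.4f", step + 1, steps, terms["total"])
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, loss_cfg=loss_cfg, train_state=state)
    return state


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict_patch(model: SegmentationModel, patch: np.ndarray) -> np.ndarray:
    """Softmax class probabilities (C, D, H, W) for one patch."""
    with no_grad():
        seg_logits, _ = model.forward(Tensor(patch.astype(np.float32)[None, ..., None]))
        probs = softmax_lastdim(seg_logits).data[0]
    return np.moveaxis(probs, -1, 0)


def predict_volume(
    model: SegmentationModel, ct: CTVolume, patch_size: Optional[int] = None
) -> Tuple[LabelVolume, np.ndarray]:
    """Whole-volume inference: plan patches -> forward -> mean-stitch -> argmax.

    Returns the labelmap (grid metadata copied from the CT) and the stitched
    per-class score volume (C, Z, Y, X). Ties in the argmax go to the lowest
    class index.
    """
    p = patch_size or model.cfg.input_patch
    if p % 2 ** (model.cfg.depth - 1) != 0:
        raise ConfigurationError(
            f"patch size {p} incompatible with model depth {model.cfg.depth}"
        )
    v = ct.voxels
    if v.min() < -0.01 or v.max() > 1.01:
        raise DataQualityError("predict_volume expects a [0,1]-normalized volume")
    padded, pads = pad_to_patch(v, p)
    grid = plan_patches(padded.shape, p)
    blocks = []
    for (i, j, k) in grid.placements():
        patch = padded[i:i + p, j:j + p, k:k + p]
        blocks.append(predict_patch(model, patch))
    scores = stitch_patches(blocks, grid)
    scores = np.stack([strip_padding(scores[c], pads) for c in range(scores.shape[0])])
    labels = np.argmax(scores, axis=0).astype(np.int16)
    return LabelVolume(labels, spacing=ct.spacing, origin=ct.origin), scores


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    model: SegmentationModel,
    path: Union[str, Path],
    loss_cfg: Optional[LossConfig] = None,
    train_state: Optional[TrainState] = None,
) -> None:
    """Single-file weights (.npz) + JSON sidecar with configs and history."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **{name: p.data for name, p in model.parameters().items()})
    sidecar = {
        "network": asdict(model.cfg),
        "loss": asdict(loss_cfg) if loss_cfg else None,
        "n_parameters": model.n_parameters(),
        "train": {
            "steps": train_state.steps,
            "seed": train_state.seed,
            "final_loss": train_state.loss_history[-1] if train_state.loss_history else None,
        } if train_state else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: Union[str, Path]) -> SegmentationModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = SegmentationModel(NetworkConfig(**sidecar["network"]))
    weights = np.load(path if path.suffix else path.with_suffix(".npz"))
    params = model.parameters()
    for name, p in params.items():
        p.data = weights[name].astype(np.float32)
    return model
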