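"""End-to-end training of the cascade with Adam.

Defaults follow the segmentation protocol the package implements: Adam,
learning rate 1e-4, 300 epochs, batch size 1 (3D volumes), no
augmentation and no learning-rate schedule.  Both stages are optimized
jointly with an equal-weight sum of their cross-entropy terms; the
stage-1 term uses the target nearest-neighbour-downsampled to the coarse
grid.  Every stochastic source — weight initialization and data order —
derives from a single integer seed.

Checkpoints are ``.npz`` archives holding every parameter plus both
configs as JSON, and round-trip bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .backbone import BackboneConfig
from .cascade import CascadeConfig, CascadeModel
from .ct_io import BinaryMask3D, CTVolume
from .losses import class_weight_map, cross_entropy_loss, dice_coefficient
from .nn.optim import Adam
from .resample import resize_nearest


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults are the package's standard protocol."""

    learning_rate: float = 1e-4
    epochs: int = 300
    optimizer: str = "adam"
    batch_size: int = 1
    seed: int = 0
    checkpoint_dir: str | None = None
    class_weights: tuple[float, ...] = (1.0, 1.0)
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainResult:
    model: CascadeModel
    log: list[dict] = field(default_factory=list)
    best_checkpoint: Path | None = None
    final_checkpoint: Path | None = None


def _pair(case) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a dataset entry to (image (C,H,W,D) float32, target int)."""
    if hasattr(case, "image") and hasattr(case, "mask"):
        img, msk = case.image, case.mask
    else:
        img, msk = case
    if isinstance(img, CTVolume):
        img = img.voxels
    if isinstance(msk, BinaryMask3D):
        msk = msk.voxels
    img = np.asarray(img, dtype=np.float32)
    if img.ndim == 3:
        img = img[np.newaxis]
    return img, np.asarray(msk).astype(np.int64)


def save_checkpoint(model: CascadeModel, path: str | Path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    meta = json.dumps({
        "stage1": asdict(model.config.stage1),
        "stage2": asdict(model.config.stage2),
        "coarse_factor": model.config.coarse_factor,
        "bridge": model.config.bridge,
    })
    np.savez(p, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)
    return p


def load_checkpoint(path: str | Path) -> CascadeModel:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no checkpoint at {p}")
    with np.load(p) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    config = CascadeConfig(
        stage1=BackboneConfig(**meta["stage1"]),
        stage2=BackboneConfig(**meta["stage2"]),
        coarse_factor=meta["coarse_factor"],
        bridge=meta["bridge"],
    )
    model = CascadeModel(config, seed=0)
    model.load_state_dict(state)
    return model


def _step_case(model: CascadeModel, img: np.ndarray, target: np.ndarray,
               class_weights) -> float:
    """Forward + backward on one case; returns the summed loss."""
    p1c, p2 = model.forward_train(img)
    coarse_shape = p1c.shape[1:]
    t1 = resize_nearest(target, coarse_shape)
    w_full = class_weight_map(target, class_weights)
    w1 = class_weight_map(t1, class_weights)
    loss = (cross_entropy_loss(p1c, t1, w1)
            + cross_entropy_loss(p2, target, w_full))

    k2 = p2.shape[0]
    onehot2 = np.eye(k2)[target].transpose(3, 0, 1, 2)
    dlogits2 = (p2 - onehot2) * w_full[np.newaxis]
    k1 = p1c.shape[0]
    onehot1 = np.eye(k1)[t1].transpose(3, 0, 1, 2)
    dlogits1 = (p1c - onehot1) * w1[np.newaxis]
    model.backward(dlogits1, dlogits2)
    return float(loss)


def train(dataset, cascade_config: CascadeConfig, train_config: TrainConfig) -> TrainResult:
    """Jointly train both cascade stages on preprocessed image/mask pairs.

    ``dataset`` is a sequence of (image, mask) pairs or objects with
    ``image``/``mask`` attributes (e.g. PreprocessedCase).  All cases must
    share one spatial shape.  Returns the trained model, a per-epoch log
    of training loss and validation Dice, and checkpoint paths when
    ``checkpoint_dir`` is set (best-by-validation-Dice and final).
    """
    cases = [_pair(c) for c in dataset]
    if not cases:
        raise ValueError("empty dataset")
    shape0 = cases[0][0].shape
    for i, (img, msk) in enumerate(cases):
        if img.shape != shape0 or msk.shape != shape0[1:]:
            raise ValueError(
                f"case {i} has shape {img.shape}/{msk.shape}, expected {shape0} "
                f"images with {shape0[1:]} masks"
            )
    cascade_config.validate_shape(shape0[1:])

    ss = np.random.SeedSequence(train_config.seed)
    init_seed, shuffle_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    model = CascadeModel(cascade_config, seed=init_seed)
    opt = Adam(model, lr=train_config.learning_rate)
    rng = np.random.default_rng(shuffle_seed)

    # seeded 80/20 split; tiny sets validate on the training cases
    n = len(cases)
    n_val = int(round(train_config.val_fraction * n))
    perm = rng.permutation(n)
    if n_val >= 1 and n - n_val >= 1:
        val_idx, train_idx = perm[:n_val], perm[n_val:]
    else:
        val_idx, train_idx = perm, perm

    result = TrainResult(model=model)
    ckpt_dir = Path(train_config.checkpoint_dir) if train_config.checkpoint_dir else None
    best_dice = -1.0
    cw = train_config.class_weights

    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(train_idx)
        total = 0.0
        since_step = 0
        model.zero_grad()
        for j in order:
            img, target = cases[j]
            total += _step_case(model, img, target, cw)
            since_step += 1
            if since_step == train_config.batch_size:
                opt.step()
                model.zero_grad()
                since_step = 0
        if since_step:
            opt.step()
            model.zero_grad()

        val_dice = float(np.mean([
            dice_coefficient(np.argmax(model.cascade_forward(cases[j][0]), axis=0),
                             cases[j][1])
            for j in val_idx
        ]))
        entry = {"epoch": epoch, "loss": total / max(len(order), 1), "val_dice": val_dice}
        result.log.append(entry)

        if ckpt_dir is not None:
            if val_dice > best_dice:
                best_dice = val_dice
                result.best_checkpoint = save_checkpoint(model, ckpt_dir / "best.npz")
            result.final_checkpoint = save_checkpoint(model, ckpt_dir / "final.npz")
            (ckpt_dir / "log.jsonl").open("a").write(json.dumps(entry) + "\n")
    return result


def evaluate_split(model: CascadeModel, cases, lungseg_params=None,
                   preprocess_params=None) -> dict:
    """Per-case Dice of end-to-end predictions against ground truth.

    ``cases`` is a sequence of (CTVolume, BinaryMask3D truth) pairs in
    *original* space; each goes through the full predict pipeline.
    Returns ``{"per_case": [...], "mean_dice": float}``.
    """
    from .cascade import predict_case

    rows = []
    for i, (vol, truth) in enumerate(cases):
        if truth is None:
            raise ValueError(f"case {i}: missing ground truth")
        pred = predict_case(vol, model, lungseg_params=lungseg_params,
                            preprocess_params=preprocess_params)
        rows.append({"case": i, "dice": dice_coefficient(pred, truth)})
    mean = float(np.mean([r["dice"] for r in rows])) if rows else float("nan")
    return {"per_case": rows, "mean_dice": mean}
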