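"""Training, cross-validation and inference orchestration.

The optimiser is AdamW (weight decay 1e-4) with cosine-annealed learning
rate (initial 1e-4, minimum 1e-6, period 1000 epochs, warm restarts
beyond one period).  Early stopping monitors the validation Dice
coefficient (foreground class for the binary task, class mean for the
multiclass task) and halts after `early_stop_patience_epochs` epochs
without improvement; the best-scoring parameters are restored.

The training loss is the hybrid Dice+Focal objective on the logits plus
deeply supervised auxiliary Dice terms on the per-stage saliency maps,
weighted 0.4 / 0.3 / 0.2 / 0.1 from deep to shallow.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import losses, metrics, nn
from . import tensor as T
from .augment import AugmentConfig, augment
from .losses import LossConfig, class_weights_from_frequencies, hybrid_loss
from .network import (
    NetworkConfig,
    SegmentationNetwork,
    build_network,
    save_checkpoint,
)
from .phantom import ImageSample
from .tensor import Tensor

AUX_WEIGHTS = (0.4, 0.3, 0.2, 0.1)  # deep -> shallow


@dataclass
class TrainConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    lr_initial: float = 1e-4
    lr_min: float = 1e-6
    cosine_period_epochs: int = 1000
    weight_decay: float = 1e-4
    early_stop_patience_epochs: int = 20
    batch_size: int = 8
    max_epochs: int = 100
    seed: int = 0
    auto_class_weights: bool = True
    target_val_dsc: float | None = None  # stop once validation DSC reaches it

    def __post_init__(self):
        if self.lr_min >= self.lr_initial:
            raise ValueError("lr_min must be below lr_initial")
        if self.early_stop_patience_epochs < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")


@dataclass
class RunRecord:
    """Per-epoch log plus the best validation score and epoch."""

    epochs: pd.DataFrame
    best_val_dsc: float
    best_epoch: int
    stopped_early: bool

    def to_csv(self, path):
        self.epochs.to_csv(path, index=False)


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Cosine annealing with warm restart every `cosine_period_epochs`."""
    p = cfg.cosine_period_epochs
    phase = (epoch % p) / p
    return cfg.lr_min + 0.5 * (cfg.lr_initial - cfg.lr_min) * (
        1.0 + np.cos(np.pi * phase)
    )


def _as_arrays(samples):
    X = np.stack([np.asarray(s.image, dtype=np.float64) for s in samples])
    y = np.stack([np.asarray(s.mask, dtype=np.int64) for s in samples])
    return X, y


def _pool_target_fg(y: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean of the foreground indicator, for deep supervision."""
    fg = (y > 0).astype(np.float64)
    N, H, W = fg.shape
    return fg.reshape(N, H // factor, factor, W // factor, factor).mean((2, 4))


def training_loss(net: SegmentationNetwork, X: np.ndarray, y: np.ndarray,
                  cfg: TrainConfig):
    """Hybrid loss + deep-supervision terms on one batch; returns the
    scalar Tensor and a dict of float components."""
    out = net(Tensor(X[:, None]))
    total, comps = hybrid_loss(out.logits, y, cfg.loss)
    comps = {k: float(v.data) for k, v in comps.items()}
    for w, sal in zip(AUX_WEIGHTS, out.aux_saliency):
        factor = y.shape[-1] // sal.shape[-1]
        target = _pool_target_fg(y, factor)
        aux = losses.dice_loss(sal[:, 0], Tensor(target))
        total = total + w * aux
    comps["total"] = float(total.data)
    return total, comps


def _val_dsc(net: SegmentationNetwork, X: np.ndarray, y: np.ndarray) -> float:
    pred = net.predict_mask(X)
    n_cls = net.cfg.n_classes
    scores = []
    for p, t in zip(pred, y):
        if n_cls == 2:
            scores.append(metrics.dsc(metrics.confusion_counts(p, t, 1)))
        else:
            rep = metrics.evaluate_multiclass(p, t, 1.0, n_cls)
            scores.append(rep.dsc)
    return float(np.mean(scores))


def train(cfg: TrainConfig, train_samples, val_samples,
          out_dir=None, verbose: bool = False):
    """Optimise the network on `train_samples`, monitor `val_samples`.

    Returns (network, RunRecord); when `out_dir` is given, writes the
    best checkpoint, the per-epoch log CSV and the resolved config YAML.
    """
    if len(train_samples) < 1 or len(val_samples) < 1:
        raise ValueError("need at least one training and one validation sample")
    rng = np.random.default_rng(cfg.seed)
    net = build_network(cfg.network, seed=int(rng.integers(2**31 - 1)))
    Xtr, ytr = _as_arrays(train_samples)
    Xva, yva = _as_arrays(val_samples)

    if cfg.auto_class_weights and cfg.loss.class_weights is None:
        w = class_weights_from_frequencies(ytr, cfg.network.n_classes)
        cfg = dataclasses.replace(
            cfg, loss=dataclasses.replace(cfg.loss, class_weights=list(w))
        )

    opt = nn.AdamW(net.parameters(), lr=cfg.lr_initial,
                   weight_decay=cfg.weight_decay)
    rows = []
    best = (-np.inf, -1, None)  # dsc, epoch, state
    since_best = 0
    stopped = False
    for epoch in range(cfg.max_epochs):
        opt.lr = lr_at(epoch, cfg)
        net.train()
        order = rng.permutation(len(Xtr))
        ep_comps = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if cfg.augmentation.enabled:
                batch = [
                    augment(train_samples[i], cfg.augmentation, rng)
                    for i in idx
                ]
                Xb, yb = _as_arrays(batch)
            else:
                Xb, yb = Xtr[idx], ytr[idx]
            loss, comps = training_loss(net, Xb, yb, cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_comps.append(comps)
        mean_comps = {
            k: float(np.mean([c[k] for c in ep_comps])) for k in ep_comps[0]
        }
        val_dsc = _val_dsc(net, Xva, yva)
        rows.append(
            dict(epoch=epoch, lr=opt.lr, val_dsc=val_dsc, **mean_comps)
        )
        if verbose:
            print(
                f"epoch {epoch:4d} lr {opt.lr:.2e} "
                f"loss {mean_comps['total']:.4f} val DSC {val_dsc:.4f}"
            )
        if val_dsc > best[0]:
            best = (val_dsc, epoch, net.state_dict())
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience_epochs:
                stopped = True
                break
        if cfg.target_val_dsc is not None and val_dsc >= cfg.target_val_dsc:
            break
    if best[2] is not None:
        net.load_state_dict(best[2])
    net.eval()
    record = RunRecord(
        epochs=pd.DataFrame(rows),
        best_val_dsc=float(best[0]),
        best_epoch=int(best[1]),
        stopped_early=stopped,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(net, out_dir / "best_checkpoint.npz")
        record.to_csv(out_dir / "epochs.csv")
        write_resolved_config(cfg, out_dir / "resolved_config.yaml")
    return net, record


def crossval(cfg: TrainConfig, samples, k: int = 5, out_dir=None):
    """Seeded k-fold cross-validation; returns (per-fold reports DataFrame,
    mean/std summary dict)."""
    from sklearn.model_selection import KFold

    n = len(samples)
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    fold_rows = []
    for fold, (tr_idx, va_idx) in enumerate(kf.split(np.arange(n))):
        tr = [samples[i] for i in tr_idx]
        va = [samples[i] for i in va_idx]
        fold_dir = None if out_dir is None else Path(out_dir) / f"fold{fold}"
        net, rec = train(cfg, tr, va, out_dir=fold_dir)
        Xva, yva = _as_arrays(va)
        pred = net.predict_mask(Xva)
        reps = [
            metrics.evaluate_pair(p, t, va[0].pixel_spacing_mm)
            if cfg.network.n_classes == 2
            else metrics.evaluate_multiclass(
                p, t, va[0].pixel_spacing_mm, cfg.network.n_classes
            )
            for p, t in zip(pred, yva)
        ]
        fold_rows.append(
            dict(
                fold=fold,
                val_indices=list(map(int, va_idx)),
                dsc=float(np.mean([r.dsc for r in reps])),
                iou=float(np.mean([r.iou for r in reps])),
                hd95_mm=_nanmean([r.hd95_mm for r in reps]),
                assd_mm=_nanmean([r.assd_mm for r in reps]),
            )
        )
    df = pd.DataFrame(fold_rows)
    summary = {
        m: {"mean": float(df[m].mean()), "sd": float(df[m].std(ddof=0))}
        for m in ("dsc", "iou", "hd95_mm", "assd_mm")
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.drop(columns=["val_indices"]).to_csv(
            out_dir / "folds.csv", index=False
        )
    return df, summary


def _nanmean(vals):
    vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else float("nan")


def predict(net: SegmentationNetwork, images: np.ndarray) -> np.ndarray:
    """Eval-mode argmax masks; inputs whose size is not divisible by 16
    are reflect-padded, predicted, and cropped back."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    H, W = images.shape[-2:]
    ph = (-H) % 16
    pw = (-W) % 16
    if ph or pw:
        images = np.pad(images, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    masks = net.predict_mask(images)
    return masks[:, :H, :W]


def write_resolved_config(cfg: TrainConfig, path):
    import yaml

    d = dataclasses.asdict(cfg)
    d["network"] = cfg.network.to_dict()

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(clean(d), fh, sort_keys=False)


def load_train_config(path) -> TrainConfig:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if "network" in d:
        d["network"] = NetworkConfig.from_dict(d["network"])
    if "loss" in d:
        d["loss"] = LossConfig(**d["loss"])
    if "augmentation" in d:
        d["augmentation"] = AugmentConfig(**d["augmentation"])
    return TrainConfig(**d)
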