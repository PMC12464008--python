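"""Model/Results interface around the segmentation network.

``StemLeafSegmenter`` is built from labeled clouds; ``fit()`` trains the
network with class-weighted cross-entropy under Adam (step learning-rate
decay, weight decay) and returns a ``SegmentationResult`` carrying the loss
history, per-epoch training accuracy, prediction and evaluation methods, and
a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autograd import Tensor
from .cloud import LabeledCloud, denormalize, normalize, resample_to_count
from .metrics import confusion, iou_per_class, mean_iou, overall_accuracy
from .network import NetConfig, SegmentationNetwork


class TrainingError(ValueError):
    pass


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults: 50 epochs, batch 4, 8192 points,
    K=16, Adam at 1e-3 with 1e-4 weight decay, x0.7 lr step every 10 epochs)."""

    max_epoch: int = 50
    batch_size: int = 4
    num_points: int = 8192
    k: int = 16
    learning_rate: float = 0.001
    decay_rate: float = 1e-4
    lr_decay: float = 0.7
    lr_step: int = 10
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_epoch", "batch_size", "num_points", "k", "lr_step"):
            if getattr(self, name) < 1:
                raise TrainingError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise TrainingError("learning_rate must be positive")
        if not (0 < self.lr_decay <= 1):
            raise TrainingError("lr_decay must lie in (0, 1]")
        if self.decay_rate < 0:
            raise TrainingError("decay_rate must be >= 0")


class Adam:
    """Adam with decoupled-from-schedule weight decay added to the gradient."""

    def __init__(self, params: Sequence[Tensor], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  class_weights: Optional[np.ndarray] = None) -> Tensor:
    """Weighted mean per-point cross-entropy from raw logits."""
    labels = np.asarray(labels, dtype=np.int64)
    n, c = logits.shape
    if labels.shape != (n,):
        raise TrainingError(f"labels must have shape ({n},)")
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    shifted = logits - shift
    logsumexp = shifted.exp().sum(axis=1, keepdims=True).log()
    log_probs = shifted - logsumexp
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    picked = (log_probs * Tensor(onehot)).sum(axis=1)
    if class_weights is None:
        return -picked.mean()
    w = np.asarray(class_weights, dtype=np.float64)[labels]
    return -(picked * Tensor(w)).sum() / float(w.sum())


def inverse_frequency_weights(label_arrays: Sequence[np.ndarray],
                              n_classes: int = 2) -> np.ndarray:
    """Class weights proportional to inverse class frequency, mean-normalized."""
    counts = np.zeros(n_classes)
    for arr in label_arrays:
        counts += np.bincount(np.asarray(arr, dtype=np.int64), minlength=n_classes)
    counts = np.maximum(counts, 1.0)
    w = counts.sum() / counts
    return w / w.mean()


@dataclass
class _Sample:
    coords_norm: np.ndarray
    labels: np.ndarray


class StemLeafSegmenter:
    """Stem/leaf point-cloud segmentation model.

    Built from labeled training clouds; each cloud is resampled to the fixed
    network input size and min-max normalized to the unit cube before it
    reaches the network. ``fit`` returns a :class:`SegmentationResult`.
    """

    def __init__(
        self,
        clouds: Sequence[LabeledCloud],
        train_config: Optional[TrainConfig] = None,
        net_config: Optional[NetConfig] = None,
    ):
        if not clouds:
            raise TrainingError("training set must be non-empty")
        for c in clouds:
            if c.semantic_labels is None:
                raise TrainingError("every training cloud needs semantic labels")
        self.train_config = train_config or TrainConfig()
        if net_config is None:
            net_config = NetConfig(
                num_points=self.train_config.num_points,
                k=self.train_config.k,
                seed=self.train_config.seed,
            )
        if net_config.num_points != self.train_config.num_points:
            raise TrainingError("net and train num_points disagree")
        self.net_config = net_config
        self.network = SegmentationNetwork(net_config)
        self._samples = [
            self._prepare(c, self.train_config.seed + i) for i, c in enumerate(clouds)
        ]
        self.class_weights = inverse_frequency_weights(
            [s.labels for s in self._samples], net_config.n_classes
        )

    @classmethod
    def from_clouds(cls, clouds, **kwargs) -> "StemLeafSegmenter":
        return cls(clouds, **kwargs)

    def _prepare(self, cloud: LabeledCloud, seed: int) -> _Sample:
        res = resample_to_count(cloud, self.train_config.num_points, seed=seed)
        normed, _ = normalize(res)
        return _Sample(coords_norm=normed.coords, labels=normed.semantic_labels)

    def fit(self, verbose: bool = False) -> "SegmentationResult":
        cfg = self.train_config
        rng = np.random.default_rng(cfg.seed)
        opt = Adam(self.network.parameters(), cfg.learning_rate, cfg.decay_rate)
        history: list[dict] = []
        n = len(self._samples)
        for epoch in range(cfg.max_epoch):
            opt.lr = cfg.learning_rate * cfg.lr_decay ** (epoch // cfg.lr_step)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                self.network.zero_grad()
                losses = []
                for j in batch:
                    s = self._samples[j]
                    # FPS seed pinned per sample: the centre hierarchy of a
                    # cloud is fixed across epochs (and matches evaluation),
                    # only dropout varies between passes
                    logits = self.network.forward(
                        s.coords_norm, seed=cfg.seed + j, training=True,
                        dropout_seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    losses.append(cross_entropy(logits, s.labels, self.class_weights))
                loss = losses[0]
                for l in losses[1:]:
                    loss = loss + l
                loss = loss * (1.0 / len(losses))
                loss.backward()
                if cfg.grad_clip > 0:
                    params = opt.params
                    gn = np.sqrt(
                        sum(
                            float((p.grad**2).sum())
                            for p in params
                            if p.grad is not None
                        )
                    )
                    if gn > cfg.grad_clip:
                        scale = cfg.grad_clip / gn
                        for p in params:
                            if p.grad is not None:
                                p.grad *= scale
                opt.step()
                epoch_loss += float(loss.data) * len(batch)
            # epoch-end training accuracy in eval mode (no dropout)
            correct = 0
            total = 0
            for j, s in enumerate(self._samples):
                logits = self.network.forward(s.coords_norm, seed=cfg.seed + j,
                                              training=False)
                correct += int((np.argmax(logits.data, axis=1) == s.labels).sum())
                total += len(s.labels)
            rec = {
                "epoch": epoch + 1,
                "loss": epoch_loss / n,
                "train_oa": 100.0 * correct / total,
                "lr": opt.lr,
            }
            history.append(rec)
            if verbose:
                print(
                    f"epoch {rec['epoch']:3d}  loss {rec['loss']:.4f}  "
                    f"train OA {rec['train_oa']:.2f}%  lr {rec['lr']:.2e}"
                )
        return SegmentationResult(self, history)


class SegmentationResult:
    """Fitted segmentation model: history, prediction, evaluation, summary."""

    def __init__(self, model: StemLeafSegmenter, history: list[dict]):
        self.model = model
        self.history = history

    @property
    def final_loss(self) -> float:
        return self.history[-1]["loss"] if self.history else float("nan")

    @property
    def final_train_oa(self) -> float:
        return self.history[-1]["train_oa"] if self.history else float("nan")

    def predict(self, cloud: LabeledCloud, seed: int = 0) -> LabeledCloud:
        """Segment a metric cloud: resample to the network size, normalize,
        run the network, return the resampled cloud in metric coordinates with
        predicted semantic labels (true labels, if any, kept in features)."""
        res = resample_to_count(cloud, self.model.train_config.num_points, seed=seed)
        normed, state = normalize(res)
        logits = self.model.network.forward(normed.coords, seed=seed, training=False)
        pred = np.argmax(logits.data, axis=1)
        out = denormalize(normed, state)
        return LabeledCloud(
            coords=out.coords,
            semantic_labels=pred,
            instance_ids=res.instance_ids,
            features=None
            if res.semantic_labels is None
            else res.semantic_labels[:, None].astype(np.float64),
        )

    def evaluate(self, clouds: Sequence[LabeledCloud], seed: int = 0) -> dict:
        """OA / per-class IoU / mIoU of the model on labeled clouds."""
        cms = []
        for i, cloud in enumerate(clouds):
            if cloud.semantic_labels is None:
                raise TrainingError("evaluation clouds need semantic labels")
            res = resample_to_count(
                cloud, self.model.train_config.num_points, seed=seed + i
            )
            normed, _ = normalize(res)
            logits = self.model.network.forward(normed.coords, seed=seed + i,
                                                training=False)
            pred = np.argmax(logits.data, axis=1)
            cms.append(confusion(pred, normed.semantic_labels,
                                 self.model.net_config.n_classes))
        cm = np.sum(cms, axis=0)
        return {
            "oa": overall_accuracy(cm),
            "iou_per_class": iou_per_class(cm),
            "miou": mean_iou(cm),
            "confusion": cm,
        }

    def summary(self) -> str:
        cfg = self.model.train_config
        net = self.model.net_config
        lines = [
            "Stem-Leaf Segmentation Results",
            "=" * 46,
            f"{'SA layers':<28}{len(net.sa_channels)}",
            f"{'num_points':<28}{cfg.num_points}",
            f"{'K (neighbourhood)':<28}{cfg.k}",
            f"{'LSE / DAP':<28}{net.uses_lse} / {net.uses_dap}",
            f"{'epochs':<28}{cfg.max_epoch}",
            f"{'batch size':<28}{cfg.batch_size}",
            f"{'learning rate':<28}{cfg.learning_rate}",
            f"{'weight decay':<28}{cfg.decay_rate}",
            f"{'lr decay (step {0})'.format(cfg.lr_step):<28}{cfg.lr_decay}",
            "-" * 46,
            f"{'final loss':<28}{self.final_loss:.4f}",
            f"{'final training OA (%)':<28}{self.final_train_oa:.2f}",
        ]
        return "\n".join(lines)
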