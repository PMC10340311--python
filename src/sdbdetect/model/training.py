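"""Training loop: weighted BCE, Adam with decoupled weight decay, early
stopping on validation loss with best-weight restoration."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from ..dataset import Segment
from .config import TrainConfig
from .layers import sigmoid
from .network import SDBNet

log = logging.getLogger(__name__)


def weighted_bce_from_logits(
    logits: np.ndarray, target: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-timestep weighted binary cross-entropy, normalized by the weight
    sum.  Returns (loss, gradient w.r.t. logits); numerically stable."""
    l = np.asarray(logits, dtype=np.float64)
    # log(1 + exp(l)) - y*l, computed stably
    per = np.maximum(l, 0) - l * target + np.log1p(np.exp(-np.abs(l)))
    wsum = weights.sum()
    loss = float((weights * per).sum() / wsum)
    dlogits = (weights * (sigmoid(l) - target) / wsum).astype(logits.dtype)
    return loss, dlogits


def _stack(segments: Sequence[Segment]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.stack([s.inputs for s in segments])
    y = np.stack([s.target for s in segments])[..., None]
    w = np.stack([s.weights for s in segments])[..., None]
    return x, y, w


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, named_grads: list[tuple[str, np.ndarray, np.ndarray]]) -> None:
        """``named_grads``: (name, param array (updated in place), grad)."""
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for name, p, g in named_grads:
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _model_loss_and_step(
    model: SDBNet,
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    opt: Adam,
    tcfg: TrainConfig,
    rng: np.random.Generator,
) -> float:
    logits = model.forward_logits(x, train=True, rng=rng)
    loss, dlogits = weighted_bce_from_logits(logits, y, w)
    l2 = model.config.l2
    if l2 > 0:
        loss += 0.5 * l2 * sum(float(np.sum(layer.params[k] ** 2)) for _, layer, k in model.kernel_params())
    if not np.isfinite(loss):
        raise RuntimeError(f"training diverged: non-finite loss {loss}")
    model.backward(dlogits)
    kernels = {pname for pname, _, _ in model.kernel_params()}
    named = []
    for pname, layer, key in model.named_params():
        g = layer.grads[key]
        if l2 > 0 and pname in kernels:
            g = g + l2 * layer.params[key]
        # decoupled weight decay on kernels only
        if tcfg.weight_decay > 0 and pname in kernels:
            layer.params[key] *= 1.0 - tcfg.learning_rate * tcfg.weight_decay
        named.append((pname, layer.params[key], g))
    opt.step(named)
    for _, layer in model.layers:
        if hasattr(layer, "_sync"):
            layer._sync()
    return loss


def evaluate_loss(model: SDBNet, segments: Sequence[Segment], batch_size: int = 128) -> float:
    """Weighted BCE in inference mode (dropout off, BN running stats)."""
    total = 0.0
    wtot = 0.0
    for i in range(0, len(segments), batch_size):
        x, y, w = _stack(segments[i : i + batch_size])
        logits = model.forward_logits(x, train=False).astype(np.float64)
        per = np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
        total += float((w * per).sum())
        wtot += float(w.sum())
    return total / wtot


def train_model(
    model: SDBNet,
    train_segments: Sequence[Segment],
    val_segments: Sequence[Segment],
    tcfg: TrainConfig,
) -> tuple[SDBNet, dict[str, object]]:
    """Fit with Adam + decoupled weight decay; stop when validation loss has
    not improved for ``patience`` consecutive epochs; restore best weights."""
    if not train_segments or not val_segments:
        raise ValueError("train and validation segment sets must be non-empty")
    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(tcfg.learning_rate)
    history: dict[str, object] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.get_state()
    best_epoch = 0
    bad = 0
    n = len(train_segments)
    for epoch in range(1, tcfg.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, tcfg.batch_size):
            batch = [train_segments[j] for j in order[i : i + tcfg.batch_size]]
            x, y, w = _stack(batch)
            losses.append(_model_loss_and_step(model, x, y, w, opt, tcfg, rng))
        val = evaluate_loss(model, val_segments, tcfg.batch_size)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val))
        log.info("epoch %d: train %.4f val %.4f", epoch, np.mean(losses), val)
        if val < best_val - 1e-9:
            best_val = val
            best_state = model.get_state()
            best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if bad >= tcfg.patience:
                break
    model.set_state(best_state)
    history["best_epoch"] = best_epoch
    history["stopped_epoch"] = epoch
    return model, history


def predict_segments(
    model: SDBNet, segments: Sequence[Segment], batch_size: int = 128
) -> list[np.ndarray]:
    """Deterministic inference; one length-300 probability vector per segment."""
    out: list[np.ndarray] = []
    for i in range(0, len(segments), batch_size):
        x = np.stack([s.inputs for s in segments[i : i + batch_size]])
        p = model.forward(x, train=False)
        out.extend(p[j, :, 0].copy() for j in range(p.shape[0]))
    return out
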