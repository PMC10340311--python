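"""The bidirectional-GRU sequence labeler.

Layer stack (time length in brackets, default input 1200):

    [1200] BiGRU -> BiGRU -> BatchNorm -> MaxPool(2) -> ReLU -> Dropout
    [600]  BiGRU -> BiGRU -> BatchNorm -> MaxPool(2) -> ReLU -> Dropout
    [300]  Dense -> ReLU -> Dense(1) (+ sigmoid applied at the output)

Output: per-second event probability in (0, 1), one value per 1 Hz step.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np

from .config import ModelConfig
from .layers import BatchNorm, BiGRU, Dense, Dropout, Layer, MaxPool, ReLU, sigmoid


class SDBNet:
    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        H, D = config.gru_units, config.n_channels
        k = config.pool_stride
        dt = self.dtype = np.dtype(config.dtype).type
        self.layers: list[tuple[str, Layer]] = []

        def add(name: str, layer: Layer) -> None:
            self.layers.append((name, layer))

        add("b1_gru1", BiGRU(D, H, rng, dtype=dt))
        add("b1_gru2", BiGRU(2 * H, H, rng, dtype=dt))
        add("b1_bn", BatchNorm(2 * H, dtype=dt))
        add("b1_pool", MaxPool(k))
        add("b1_relu", ReLU())
        add("b1_drop", Dropout(config.dropout))
        add("b2_gru1", BiGRU(2 * H, H, rng, dtype=dt))
        add("b2_gru2", BiGRU(2 * H, H, rng, dtype=dt))
        add("b2_bn", BatchNorm(2 * H, dtype=dt))
        add("b2_pool", MaxPool(k))
        add("b2_relu", ReLU())
        add("b2_drop", Dropout(config.dropout))
        add("head_dense", Dense(2 * H, config.dense_units, rng, dtype=dt))
        add("head_relu", ReLU())
        add("head_out", Dense(config.dense_units, 1, rng, dtype=dt))

        # time-length ledger: input_len -> pool -> pool -> output_len
        ledger = config.input_len
        for _ in range(2):
            if ledger % k:
                raise ValueError("pooling strides cannot produce the output grid")
            ledger //= k
        assert ledger == config.output_len

    # -- passes ------------------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.config.input_len or x.shape[2] != self.config.n_channels:
            raise ValueError(
                f"expected input (B, {self.config.input_len}, {self.config.n_channels}), got {x.shape}"
            )
        h = np.asarray(x, dtype=self.dtype)
        for _, layer in self.layers:
            h = layer.forward(h, train=train, rng=rng)
        return h  # (B, output_len, 1)

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """Event probabilities in (0, 1), shape (B, output_len, 1)."""
        return sigmoid(self.forward_logits(x, train=train, rng=rng))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for _, layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    # -- parameter access --------------------------------------------------

    def named_params(self):
        for name, layer in self.layers:
            for key in layer.params:
                yield f"{name}.{key}", layer, key

    def kernel_params(self):
        for name, layer in self.layers:
            for key in layer.kernel_names:
                yield f"{name}.{key}", layer, key

    def get_state(self) -> dict[str, np.ndarray]:
        state = {pname: layer.params[key].copy() for pname, layer, key in self.named_params()}
        for name, layer in self.layers:
            if isinstance(layer, BatchNorm):
                state[f"{name}.running_mean"] = layer.running_mean.copy()
                state[f"{name}.running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for pname, layer, key in self.named_params():
            layer.params[key] = state[pname].copy()
        for name, layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{name}.running_mean"].copy()
                layer.running_var = state[f"{name}.running_var"].copy()
            if isinstance(layer, BiGRU):
                layer._sync()

    # -- checkpointing -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = json.dumps(copy.copy(self.config.__dict__))
        np.savez(path, __config__=meta, **self.get_state())

    @classmethod
    def load(cls, path: str | Path) -> "SDBNet":
        with np.load(path, allow_pickle=False) as z:
            cfg = ModelConfig(**json.loads(str(z["__config__"])))
            model = cls(cfg)
            model.set_state({k: z[k] for k in z.files if k != "__config__"})
        return model


def build_model(config: ModelConfig, seed: int = 0) -> SDBNet:
    return SDBNet(config, seed=seed)
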