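"""Model and training hyperparameter containers."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ModelConfig:
    """Architecture knobs.

    Two feature blocks (2x bidirectional GRU -> batch norm -> max-pool(2) ->
    ReLU -> dropout) followed by a dense-ReLU and a dense-sigmoid head; the
    two stride-2 pools map ``input_len`` to ``input_len / 4`` output steps
    (1200 -> 300 at the default settings).
    """

    gru_units: int = 128
    dense_units: int = 512
    dropout: float = 0.5
    pool_stride: int = 2
    l2: float = 1e-5
    input_len: int = 1200
    n_channels: int = 2
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.pool_stride < 1:
            raise ValueError("pool stride must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        total = self.pool_stride**2
        if self.input_len % total != 0:
            raise ValueError(
                f"input length {self.input_len} not divisible by the combined "
                f"pooling stride {total}; cannot build the output grid"
            )

    @property
    def output_len(self) -> int:
        return self.input_len // self.pool_stride**2

    @classmethod
    def reduced(cls, **kw) -> "ModelConfig":
        """Desk-scale preset for tests and smoke runs."""
        kw.setdefault("gru_units", 16)
        kw.setdefault("dense_units", 64)
        return cls(**kw)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 128
    patience: int = 20
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "patience", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be non-negative")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
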