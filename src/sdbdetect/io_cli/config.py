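"""Pipeline configuration with lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from ..model.config import ModelConfig, TrainConfig
from ..synthgen import SimConfig, StageParams


@dataclass
class EvalConfig:
    rule: str = "strict"
    auto_threshold: bool = True
    threshold: float = 0.5
    nbl_zones: dict[float, float] = field(default_factory=lambda: {5.0: 0.5, 15.0: 1.5, 30.0: 3.0})

    def __post_init__(self) -> None:
        if self.rule not in ("strict", "olsen"):
            raise ValueError("rule must be 'strict' or 'olsen'")


@dataclass
class PipelineConfig:
    out_dir: str = "runs/experiment"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: dict[str, Any] = field(default_factory=dict)
    model: ModelConfig = field(default_factory=ModelConfig.reduced)
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    split_fractions: tuple[float, float] = (0.25, 0.25)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        d["sim"]["event_mix"] = list(self.sim.event_mix)
        d["sim"]["ahi_bands"] = {k: list(v) for k, v in self.sim.ahi_bands.items()}
        for key in ("age_range", "bmi_range"):
            d["sim"][key] = list(getattr(self.sim, key))
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sim_d = dict(d.get("sim", {}))
        if "stage_params" in sim_d and isinstance(sim_d["stage_params"], dict):
            sim_d["stage_params"] = StageParams(**sim_d["stage_params"])
        for key in ("event_mix", "age_range", "bmi_range"):
            if key in sim_d:
                sim_d[key] = tuple(sim_d[key])
        if "ahi_bands" in sim_d:
            sim_d["ahi_bands"] = {k: tuple(v) for k, v in sim_d["ahi_bands"].items()}
        kw: dict[str, Any] = {
            "out_dir": d.get("out_dir", "runs/experiment"),
            "seed": d.get("seed", 0),
            "sim": SimConfig(**sim_d),
            "preprocess": dict(d.get("preprocess", {})),
            "model": ModelConfig(**d.get("model", {})),
            "train": TrainConfig(**d.get("train", {})),
            "evaluation": EvalConfig(**{
                **d.get("evaluation", {}),
                "nbl_zones": {float(k): float(v) for k, v in d.get("evaluation", {}).get(
                    "nbl_zones", {5.0: 0.5, 15.0: 1.5, 30.0: 3.0}).items()},
            }),
            "split_fractions": tuple(d.get("split_fractions", (0.25, 0.25))),
        }
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**kw)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


def smoke_config(out_dir: str = "runs/smoke", seed: int = 0) -> PipelineConfig:
    """Tiny configuration exercising the full pipeline in well under a minute
    per stage: 4 subjects, short nights, reduced model, 3 epochs."""
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        sim=SimConfig(n_subjects=4, duration_s=2700.0, ectopic_per_hour=0.0),
        model=ModelConfig.reduced(),
        train=TrainConfig(batch_size=32, max_epochs=3, patience=2, seed=seed),
    )
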