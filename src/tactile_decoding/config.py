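"""Run configuration: every analysis constant under a named key.

The defaults are the study conditions the pipeline models: 8 patterns,
up to 100 presentations 1.8 s apart, exponential kernel tau = 5 ms,
bootstrap group size 10 (3 in the state-conditioned mode), 200 combinations
per set, kNN with k = 9, 50 iterations, 2.5% AUC floor, 600 ms analysis
span.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .decoder import DecoderParams

__all__ = ["GeneratorConfig", "LfpConfig", "EcogConfig", "RunConfig"]


@dataclass
class GeneratorConfig:
    n_neurons: int = 20
    n_patterns: int = 8
    n_channels: int = 4
    pattern_duration_ms: float = 340.0
    repetitions_per_pattern: int = 100
    inter_trial_interval_ms: float = 1800.0
    baseline_rate_hz: float = 5.0
    n_bumps: int = 3
    reliability: float = 0.85
    pretrigger_ms: float = 500.0
    posttrigger_ms: float = 1000.0


@dataclass
class LfpConfig:
    sampling_rate_hz: float = 10_000.0
    pretrigger_ms: float = 400.0
    posttrigger_ms: float = 400.0
    se_pretrigger_ms: float = 100.0
    response_amplitude: float = 6.0
    noise_sd: float = 1.0
    boxcar_ms: float = 10.0
    resample_to_hz: float = 1000.0
    band_hz: tuple = (50.0, 499.0)


@dataclass
class EcogConfig:
    sampling_rate_hz: float = 1000.0
    segment_ms: float = 1000.0
    overlap_ms: float = 125.0
    band_hz: tuple = (0.0, 12.0)
    state_epoch_ms: float = 20_000.0
    state_group_size: int = 3


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "results/run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    decoder: DecoderParams = field(default_factory=DecoderParams)
    lfp: LfpConfig = field(default_factory=LfpConfig)
    ecog: EcogConfig = field(default_factory=EcogConfig)
    run_shuffled_control: bool = True
    run_cooperative: bool = True
    cooperative_n_neurons: int = 4
    cooperative_durations: tuple = (200.0, 400.0, 600.0)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = GeneratorConfig(**d.pop("generator", {}))
        dec = DecoderParams(**d.pop("decoder", {}))
        lfp = LfpConfig(**{k: tuple(v) if k == "band_hz" else v
                           for k, v in d.pop("lfp", {}).items()})
        ecog = EcogConfig(**{k: tuple(v) if k == "band_hz" else v
                             for k, v in d.pop("ecog", {}).items()})
        for key in ("cooperative_durations",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(generator=gen, decoder=dec, lfp=lfp, ecog=ecog, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
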