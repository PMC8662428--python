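"""Run configuration: named profiles, YAML loading, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .data import T_MAX_DEFAULT, T_MIN_DEFAULT
from .evaluate import DATA_RATE_LABELS, DATA_RATE_SIZES, K_TEST_WINDOWS, WINDOW_SIZES
from .model import ModelConfig

PROFILES = ("desk", "full")


@dataclass(frozen=True)
class SynthConfig:
    n_users: int = 16
    n_trials: int = 10
    separation: str = "default"
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 0 or self.n_trials < 1:
            raise ValueError("n_users must be >= 0 and n_trials >= 1")
        if self.separation not in ("low", "default", "high"):
            raise ValueError("separation must be low, default, or high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class DataConfig:
    t_min: int = T_MIN_DEFAULT
    t_max: int = T_MAX_DEFAULT
    k_test_windows: int = K_TEST_WINDOWS
    per_recording_normalization: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.t_min <= self.t_max):
            raise ValueError("need 1 <= t_min <= t_max")
        if self.k_test_windows < 1:
            raise ValueError("k_test_windows must be >= 1")


@dataclass(frozen=True)
class EvalConfig:
    sizes: tuple[int, ...] = WINDOW_SIZES
    rate_sizes: tuple[int, ...] = DATA_RATE_SIZES
    rate_labels: tuple[int, ...] = DATA_RATE_LABELS
    n_repeats: int = 5
    n_folds: int = 5

    def __post_init__(self) -> None:
        if len(self.rate_sizes) != len(self.rate_labels):
            raise ValueError("rate_sizes and rate_labels must pair up")
        if self.n_repeats < 1 or self.n_folds < 2:
            raise ValueError("need n_repeats >= 1 and n_folds >= 2")


@dataclass(frozen=True)
class RunConfig:
    profile: str = "desk"
    synth: SynthConfig = field(default_factory=SynthConfig)
    data: DataConfig = field(default_factory=DataConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {PROFILES}")


def default_config(profile: str = "desk") -> RunConfig:
    """The two named profiles: desk (scaled-down) and full (full-scale).

    ``full`` keeps the full-scale training schedule (1000 epochs); ``desk``
    is sized to run on one CPU in minutes while preserving every protocol
    choice (window ranges, fold structure, test sizes).
    """
    if profile == "full":
        return RunConfig(
            profile="full",
            model=ModelConfig(epochs=1000, windows_per_epoch=36828, batch_size=32),
        )
    return RunConfig(profile="desk", model=ModelConfig(epochs=40))


def _merge(dc, overrides: dict):
    if not overrides:
        return dc
    valid = set(dc.__dataclass_fields__)
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    coerced = {}
    for key, val in overrides.items():
        if isinstance(val, list):
            val = tuple(val)
        coerced[key] = val
    return replace(dc, **coerced)


def load_config(path: str | Path | None = None, profile: str | None = None) -> RunConfig:
    """Build a RunConfig from a profile plus an optional YAML override file.

    The YAML file mirrors the config structure: top-level keys ``profile``,
    ``synth``, ``data``, ``model``, ``eval``, each a mapping of field
    overrides.  Unknown keys raise.
    """
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    prof = profile or doc.get("profile", "desk")
    cfg = default_config(prof)
    unknown = set(doc) - {"profile", "synth", "data", "model", "eval"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return RunConfig(
        profile=prof,
        synth=_merge(cfg.synth, doc.get("synth", {})),
        data=_merge(cfg.data, doc.get("data", {})),
        model=_merge(cfg.model, doc.get("model", {})),
        eval=_merge(cfg.eval, doc.get("eval", {})),
    )


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
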