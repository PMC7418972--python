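"""Run configuration: defaults, YAML loading, provenance hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .betadiv import BetaShape
from .exceptions import InvalidInputError

__all__ = ["RunConfig", "load_config", "config_hash", "DEFAULT_BM1_LIST"]

# Benchmark-prior-1 ladder used throughout: symmetric betas of increasing
# concentration; benchmark prior 2 stays the flat Beta(1, 1) worst case.
DEFAULT_BM1_LIST: list[tuple[float, float]] = [
    (25.0, 25.0),
    (50.0, 50.0),
    (100.0, 100.0),
    (200.0, 200.0),
    (300.0, 300.0),
    (400.0, 400.0),
]


@dataclass
class RunConfig:
    """Structured configuration for the CLI experiments."""

    out_dir: str = "datarep-out"
    seed: int = 0
    patch_size: int = 15
    patch_counts: list[int] = field(default_factory=lambda: [100, 500])
    reps: int = 5
    bm1_list: list[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_BM1_LIST)
    )
    bm2: tuple[float, float] = (1.0, 1.0)
    band: float = 0.05
    n_build_scans: int = 15
    n_test_scans: int = 5
    n_subjects: int = 20
    image_size: int = 256
    scanners: list[str] = field(default_factory=lambda: ["scanner1", "scanner2"])
    image_format: str = "png"
    # tissue experiment
    unseen_budgets: list[int] = field(default_factory=lambda: [50, 200, 1000])
    tissue_reps: int = 3
    n_build_unseen: int = 5
    n_test_unseen: int = 3
    train_patches_per_scan: int = 500

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0 or self.patch_size < 1:
            raise InvalidInputError(
                f"patch_size must be odd and positive, got {self.patch_size}"
            )
        self.bm1_list = [tuple(BetaShape.coerce(b).as_tuple()) for b in self.bm1_list]
        self.bm2 = tuple(BetaShape.coerce(self.bm2).as_tuple())

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise InvalidInputError(f"config file {path} must hold a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the canonical JSON form, for provenance blocks.

    The output directory is excluded: two runs differing only in where
    their results land are the same experiment.
    """
    payload = {k: v for k, v in cfg.to_dict().items() if k != "out_dir"}
    canon = json.dumps(payload, sort_keys=True, default=list)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
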