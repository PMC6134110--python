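"""Analysis configuration: YAML key-value files with strict validation.

Unknown keys are rejected by name, every numeric parameter is range-checked,
and defaults (contact cutoff 0.6 nm, trailing window 0.5, histogram bin width
1 degree) are filled in before any computation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """Invalid analysis configuration (names the offending key)."""


@dataclass
class AnalysisConfig:
    """Parameters for a full pipeline run.

    ``structure``/``trajectory`` plus the selection expressions drive analysis
    of external data; when they are omitted the run uses the built-in
    synthetic scenario presets (``presets``).
    """

    outdir: str = "memtilt_out"
    seed: int = 0
    cutoff: float = 0.6            # contact cutoff, nm
    window: float = 0.5            # trailing fraction for summaries
    bin_width: float = 1.0         # angle histogram bin, degrees
    n_bins: int = 100              # charge-density bins
    n_frames: int = 200            # synthetic preset length
    noise_deg: float = 2.0         # synthetic preset angular noise
    presets: list[str] = field(default_factory=lambda: [
        "lps_glucer", "nolps_glucer", "lps_noglucer", "nolps_noglucer"])
    structure: str | None = None
    trajectory: str | None = None
    selections: dict[str, str] = field(default_factory=dict)
    block_sizes: list[int] | None = None
    absolute_angles: bool = False  # report |lateral|, |forward|


_REQUIRED_SELECTION_ROLES = ("proximal", "distal", "monomer_a", "monomer_b")


def _check_ranges(cfg: AnalysisConfig) -> None:
    if cfg.cutoff <= 0:
        raise ConfigError(f"cutoff must be positive, got {cfg.cutoff}")
    if not 0.0 < cfg.window <= 1.0:
        raise ConfigError(f"window must be in (0, 1], got {cfg.window}")
    if cfg.bin_width <= 0:
        raise ConfigError(f"bin_width must be positive, got {cfg.bin_width}")
    if cfg.n_bins < 10:
        raise ConfigError(f"n_bins must be >= 10, got {cfg.n_bins}")
    if cfg.n_frames < 2:
        raise ConfigError(f"n_frames must be >= 2, got {cfg.n_frames}")
    if cfg.noise_deg < 0:
        raise ConfigError(f"noise_deg must be >= 0, got {cfg.noise_deg}")
    if cfg.block_sizes is not None and any(b < 1 for b in cfg.block_sizes):
        raise ConfigError("block_sizes must all be >= 1")
    from .synthetic import PRESETS
    for p in cfg.presets:
        if p not in PRESETS:
            raise ConfigError(
                f"unknown preset {p!r}; choose from {sorted(PRESETS)}")
    if cfg.trajectory is not None:
        if cfg.structure is None:
            raise ConfigError("trajectory given without a structure file")
        missing = [r for r in _REQUIRED_SELECTION_ROLES
                   if r not in cfg.selections]
        if missing:
            raise ConfigError(
                f"selections missing required roles: {', '.join(missing)}")


def validate_config(path: str | Path | dict) -> AnalysisConfig:
    """Load, default-fill and range-check a config file (or pre-parsed dict)."""
    if isinstance(path, dict):
        raw = dict(path)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a key-value mapping")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    cfg = AnalysisConfig(**raw)
    _check_ranges(cfg)
    return cfg
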