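"""Declarative run configuration: a single YAML key-value file, fail-closed.

Defaults mirror the production sampling used for the published small-molecule
recoveries (n_q = 300, n_η = 5760, n_θ = 500, l_cut = 45, support width 5,
β = 0.9, 120 HIO iterations).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "validate_config"]


class ConfigError(ValueError):
    """Raised with the list of violated invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass
class RunConfig:
    n_q: int = 300
    n_eta: int = 5760
    n_theta: int = 500
    n_phi: int = 1000
    q_max: float = 9.0
    l_cut: int = 45
    support_width: int = 5
    beta: float = 0.9
    recipe: str = "120HIO"
    seed: int = 0


def validate_config(cfg: RunConfig) -> list[str]:
    """Return the list of broken invariants (empty when valid)."""
    v: list[str] = []
    if cfg.n_phi != 2 * cfg.n_theta:
        v.append(f"grid convention violated: n_phi ({cfg.n_phi}) != 2*n_theta ({cfg.n_theta})")
    if cfg.l_cut > cfg.n_theta // 2:
        v.append(f"l_cut ({cfg.l_cut}) exceeds the harmonic limit n_theta/2 ({cfg.n_theta // 2})")
    if cfg.support_width < 1 or cfg.support_width % 2 == 0:
        v.append(f"support_width ({cfg.support_width}) must be odd and positive")
    if not 0 < cfg.beta < 2:
        v.append(f"beta ({cfg.beta}) outside (0, 2)")
    if cfg.n_q < 2 or cfg.n_eta < 2:
        v.append("n_q and n_eta must be at least 2")
    if cfg.q_max <= 0:
        v.append("q_max must be positive")
    return v


def load_config(path: str | Path) -> RunConfig:
    """Load and validate; unknown keys are errors (fail closed)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError([f"unknown config key {k!r}" for k in unknown])
    cfg = RunConfig(**raw)
    violations = validate_config(cfg)
    if violations:
        raise ConfigError(violations)
    return cfg


def save_config(path: str | Path, cfg: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
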