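"""Run configuration: built-in defaults, config-file loading, overrides.

Defaults are the workflow's standard conditions: 298.15 K, a 1.20x charge
magnification with the (5/12)-percent sigma rule, the 17-point nonpolar
and 6-point polar lambda schedules, and 10 000 bootstrap resamples.
Values from a YAML or TOML config file override the defaults, and
command-line flags override both.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .dbalance import DEFAULT_CHARGE_SCALE, DEFAULT_SIGMA_COEFF
from .ti import NONPOLAR_LAMBDAS, POLAR_LAMBDAS

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    temperature: float = 298.15          # K
    charge_scale: float = DEFAULT_CHARGE_SCALE
    sigma_coeff: float = DEFAULT_SIGMA_COEFF
    sigma_mode: str = "per_atom_dq"
    lambda_nonpolar: tuple[float, ...] = NONPOLAR_LAMBDAS
    lambda_polar: tuple[float, ...] = POLAR_LAMBDAS
    n_boot: int = 10_000
    seed: int = 0
    units: str = "kJ/mol"

    def with_overrides(self, **kwargs) -> "RunConfig":
        """A copy with non-None keyword values replacing fields."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        unknown = set(updates) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return dataclasses.replace(self, **updates)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from defaults, an optional file, then overrides."""
    cfg = RunConfig()
    if path is not None:
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            import yaml

            data = yaml.safe_load(path.read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        for key in ("lambda_nonpolar", "lambda_polar"):
            if key in data:
                data[key] = tuple(float(x) for x in data[key])
        cfg = cfg.with_overrides(**data)
    return cfg.with_overrides(**overrides)
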