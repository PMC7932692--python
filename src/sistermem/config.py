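"""Simulation configuration and named presets.

A :class:`SimConfig` fully parameterises the synthetic sisters-machine
generator in :mod:`sistermem.growth_sim`.  Rates are per minute, times in
minutes, lengths in arbitrary length units and fluorescence in arbitrary
concentration units.  Presets are YAML files shipped with the package;
``"LB-default"`` encodes fast growth in rich medium (mean generation time
~34 min sampled every 3 min) with noise magnitudes set by the packaged
calibration utility.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["SimConfig", "load_config", "save_config", "get_preset", "PRESET_NAMES"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic sisters-machine experiment.

    Attributes
    ----------
    dt_min:
        Imaging frame interval (minutes).
    alpha_bar:
        Mean exponential elongation rate (1/min).
    delta_bar:
        Mean adder increment, i.e. length added per cycle (length units).
    sigma_delta_rel:
        Relative SD of the per-cycle adder increment.
    sigma_r:
        SD of the division fraction r around 0.5.
    phi_T, sigma_hT:
        Per-generation AR(1) retention and stationary SD of the heritable
        growth-rate factor (relative units).
    phi_L, sigma_hL:
        Same for the heritable adder-size factor.
    kappa, tau_c:
        Amplitude (1/min) and decay time (min) of the transient
        post-division growth-rate compensation; a daughter receiving the
        size fraction r starts with rate offset ``kappa * (1 - 2 r)`` so the
        smaller sister transiently grows faster.
    sigma_xi, tau_xi:
        Stationary SD (relative) and correlation time of the fast intrinsic
        Ornstein-Uhlenbeck growth-rate noise.
    sigma_env_static:
        SD of the static per-trap (micro-niche) growth-rate offset.
    sigma_env_dyn, tau_env:
        Stationary SD and correlation time of the dynamic trap-shared
        environment fluctuation.
    f_bar:
        Mean protein concentration (a.u.).
    sigma_f_intr, tau_f:
        Stationary SD and correlation time of the intrinsic fluorescence
        OU fluctuation.
    beta_f:
        Coupling of the cell's mean fluorescence to the static trap offset.
    sigma_meas_L, sigma_meas_f:
        Multiplicative (log-normal) measurement noise SDs on length and
        fluorescence.
    n_traps, n_generations:
        Number of v-traps and recorded generations per tip lineage.
    frac_unrelated:
        Fraction of traps whose two tips descend from two independent
        mothers (neighbour-cell traps); the rest start from the division of
        a single mother (sister traps).
    burn_in_generations:
        Generations simulated per mother before recording starts.
    seed:
        Base RNG seed; the whole output table is deterministic given it.
    """

    dt_min: float = 3.0
    alpha_bar: float = math.log(2.0) / 34.0
    delta_bar: float = 2.0
    sigma_delta_rel: float = 0.06
    sigma_r: float = 0.02
    phi_T: float = 2.0 ** (-1.0 / 9.0)
    sigma_hT: float = 0.13
    phi_L: float = 2.0 ** (-1.0 / 7.0)
    sigma_hL: float = 0.10
    kappa: float = 0.055
    tau_c: float = 10.0
    sigma_xi: float = 0.05
    tau_xi: float = 5.0
    sigma_env_static: float = 0.04
    sigma_env_dyn: float = 0.10
    tau_env: float = 34.0
    f_bar: float = 100.0
    sigma_f_intr: float = 10.0
    tau_f: float = 34.0
    beta_f: float = 3.0
    sigma_meas_L: float = 0.01
    sigma_meas_f: float = 0.02
    n_traps: int = 200
    n_generations: int = 24
    frac_unrelated: float = 0.5
    burn_in_generations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dt_min <= 0:
            raise ConfigError("dt_min must be positive")
        if self.alpha_bar <= 0:
            raise ConfigError("alpha_bar must be positive")
        if self.delta_bar <= 0:
            raise ConfigError("delta_bar must be positive")
        for name in (
            "sigma_delta_rel", "sigma_r", "sigma_hT", "sigma_hL", "sigma_xi",
            "sigma_env_static", "sigma_env_dyn", "sigma_f_intr",
            "sigma_meas_L", "sigma_meas_f",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("phi_T", "phi_L"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("tau_c", "tau_xi", "tau_env", "tau_f"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        # division fractions must stay well inside (0, 1) after truncation
        if self.sigma_r >= 0.15:
            raise ConfigError("sigma_r too large; division fractions would leave (0, 1)")
        if self.n_traps < 1:
            raise ConfigError("n_traps must be >= 1")
        if self.n_generations < 2:
            raise ConfigError("n_generations must be >= 2")
        if not 0.0 <= self.frac_unrelated <= 1.0:
            raise ConfigError("frac_unrelated must lie in [0, 1]")
        if self.burn_in_generations < 1:
            raise ConfigError("burn_in_generations must be >= 1")

    def replace(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)


PRESET_NAMES = ("LB-default",)
_PRESET_FILES = {"LB-default": "lb_default.yaml"}


def get_preset(name: str, **overrides) -> SimConfig:
    """Load a named preset, optionally overriding individual fields."""
    try:
        fname = _PRESET_FILES[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {PRESET_NAMES}") from None
    text = resources.files("sistermem.presets").joinpath(fname).read_text()
    cfg = SimConfig.from_dict(yaml.safe_load(text))
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg


def load_config(path: str | Path, **overrides) -> SimConfig:
    """Read a SimConfig from a flat-key YAML file (or a preset reference).

    A file containing ``preset: <name>`` loads that preset first and applies
    any remaining keys on top of it.
    """
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    preset = d.pop("preset", None)
    if preset is not None:
        return get_preset(preset, **{**d, **overrides})
    return SimConfig.from_dict({**d, **overrides})


def save_config(cfg: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
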