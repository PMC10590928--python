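"""Run configuration: model, solver and output blocks, from YAML/JSON."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .smoking_model import InitialState, ModelParams

__all__ = ["RunConfig", "ConfigError"]

_MODEL_PARAM_KEYS = {
    "theta", "chi1", "chi2", "gamma", "rho", "lambda", "lam", "beta", "mu", "sigma",
}
_INIT_KEYS = {"M0", "L0", "N0", "O0", "P0"}


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Everything a CLI run needs.

    Defaults: chi in {0.7, 0.8, 0.9, 1.0}, h = -1, n = 1, R = 6, K = 1,
    t in [0, 1] with 101 points.
    """

    params: ModelParams = field(default_factory=ModelParams)
    init: InitialState = field(default_factory=InitialState)
    chi_values: tuple[float, ...] = (0.7, 0.8, 0.9, 1.0)
    h: float = -1.0
    n: int = 1
    order: int = 6
    kcap: float = 1.0
    t_start: float = 0.0
    t_end: float = 1.0
    n_points: int = 101

    def __post_init__(self) -> None:
        if len(self.chi_values) == 0:
            raise ConfigError("chi list must be non-empty")
        for chi in self.chi_values:
            if not (0.0 < chi <= 1.0):
                raise ConfigError(f"chi={chi} outside (0, 1]")
        if not (self.t_end > self.t_start >= 0):
            raise ConfigError("need t_end > t_start >= 0")
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")
        if self.h == 0:
            raise ConfigError("h must be nonzero")
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if self.order < 1:
            raise ConfigError("order must be >= 1")
        if self.kcap <= 0:
            raise ConfigError("K must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        model_block = dict(raw.pop("model", {}) or {})
        solver_block = dict(raw.pop("solver", {}) or {})
        output_block = dict(raw.pop("output", {}) or {})
        if raw:
            raise ConfigError(f"unknown top-level config keys: {sorted(raw)}")

        param_kwargs = {k: v for k, v in model_block.items() if k in _MODEL_PARAM_KEYS}
        init_kwargs = {k: v for k, v in model_block.items() if k in _INIT_KEYS}
        unknown = set(model_block) - _MODEL_PARAM_KEYS - _INIT_KEYS
        if unknown:
            raise ConfigError(f"unknown model keys: {sorted(unknown)}")
        try:
            params = ModelParams.from_dict(param_kwargs)
            init = InitialState.from_dict(init_kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

        kwargs: dict = {"params": params, "init": init}
        chi = solver_block.pop("chi", None)
        if chi is not None:
            kwargs["chi_values"] = tuple(chi) if isinstance(chi, (list, tuple)) else (float(chi),)
        for src, dst in (("h", "h"), ("n", "n"), ("order", "order"), ("K", "kcap")):
            if src in solver_block:
                kwargs[dst] = solver_block.pop(src)
        if solver_block:
            raise ConfigError(f"unknown solver keys: {sorted(solver_block)}")
        for key in ("t_start", "t_end", "n_points"):
            if key in output_block:
                kwargs[key] = output_block.pop(key)
        output_block.pop("figure", None)
        if output_block:
            raise ConfigError(f"unknown output keys: {sorted(output_block)}")
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            try:
                raw = yaml.safe_load(fh)  # YAML is a superset of JSON
            except yaml.YAMLError as exc:
                raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls.from_dict(raw)
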