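"""Run configuration: strict YAML schema shared by the CLI subcommands.

Unknown keys are rejected with the schema path of the offending entry, and
a run is fully reproducible from ``(config, base_seed)`` alone.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .odes import (
    DEFAULT_INITIAL_STATES,
    DEFAULT_TRUE_PARAMS,
    ODEModel,
    SoftTissueConstants,
    get_model,
)
from .pipeline import FitConfig, WarpFitConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration (carries the offending schema path)."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    name: str
    theta: dict[str, float] | None = None
    x0: list[float] | None = None
    span: tuple[float, float] = (0.0, 10.0)
    constants: dict[str, float] | None = None  # soft-tissue physiological constants

    def build(self) -> ODEModel:
        kwargs = {}
        if self.name == "soft_tissue" and self.constants is not None:
            kwargs["consts"] = SoftTissueConstants(**self.constants)
        return get_model(self.name, **kwargs)

    def true_theta(self) -> dict[str, float]:
        if self.theta is not None:
            return self.theta
        if self.name in DEFAULT_TRUE_PARAMS:
            return DEFAULT_TRUE_PARAMS[self.name]
        raise ConfigError(f"model.theta required for model {self.name!r}")

    def initial_state(self) -> list[float]:
        if self.x0 is not None:
            return self.x0
        if self.name in DEFAULT_INITIAL_STATES:
            return DEFAULT_INITIAL_STATES[self.name]
        raise ConfigError(f"model.x0 required for model {self.name!r}")


class DataSection(_Strict):
    snr_db: list[float] = [40.0]
    n_reps: int = 3
    keep_every: int = 2
    n_solver_points: int | None = 56
    base_seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-8
    center: bool = True


class WarpSection(_Strict):
    lambda_t: float | None = None
    lambda_w_bounds: tuple[float, float] | None = None
    center_signal: bool = True
    n_restarts: int = 5
    maxiter: int = 200
    mlp_weight_variance: float = 1.0
    mlp_bias_variance: float = 1.0
    smooth_lam_grid: list[float] | None = None
    monotonicity_grid_points: int = 1000

    def build(self) -> WarpFitConfig:
        return WarpFitConfig(
            lambda_t=self.lambda_t,
            lambda_w_bounds=self.lambda_w_bounds,
            center_signal=self.center_signal,
            n_restarts=self.n_restarts,
            maxiter=self.maxiter,
            mlp_weight_variance=self.mlp_weight_variance,
            mlp_bias_variance=self.mlp_bias_variance,
            smooth_lam_grid=None
            if self.smooth_lam_grid is None
            else tuple(self.smooth_lam_grid),
            monotonicity_grid_points=self.monotonicity_grid_points,
        )


class MethodSection(_Strict):
    kernel_family: str = "rbf"
    lam_grid_low: float = 1e-6
    lam_grid_high: float = 1e2
    lam_grid_num: int = 12
    folds: int = 10
    cv_scheme: str = "random"
    hyper_starts: int = 5
    rounds: int = 2
    theta_starts: int = 5
    theta_bounds: dict[str, tuple[float, float]] | None = None
    warp: WarpSection = WarpSection()

    def build(self) -> FitConfig:
        grid = np.logspace(
            np.log10(self.lam_grid_low), np.log10(self.lam_grid_high), self.lam_grid_num
        )
        return FitConfig(
            kernel_family=self.kernel_family,
            lam_grid=tuple(grid),
            folds=self.folds,
            cv_scheme=self.cv_scheme,
            hyper_starts=self.hyper_starts,
            rounds=self.rounds,
            theta_bounds=self.theta_bounds,
            theta_starts=self.theta_starts,
            warp=self.warp.build(),
        )


class EvaluationSection(_Strict):
    ratio_pairs: list[tuple[str, str]] | None = None  # None -> model default
    fs_grid_points: int = 200
    alpha: float = 0.05

    def resolved_ratio_pairs(self, model_name: str) -> tuple[tuple[str, str], ...]:
        if self.ratio_pairs is not None:
            return tuple(tuple(p) for p in self.ratio_pairs)
        # k5/k6 are only weakly identifiable individually in the pathway model
        return (("k5", "k6"),) if model_name == "biopathway" else ()


class RunConfig(_Strict):
    model: ModelSection
    data: DataSection = DataSection()
    rkg: MethodSection = MethodSection()
    rkgw: MethodSection = MethodSection()
    evaluation: EvaluationSection = EvaluationSection()

    def method_config(self, method: str) -> FitConfig:
        if method == "rkg":
            return self.rkg.build()
        if method == "rkgw":
            return self.rkgw.build()
        raise ConfigError(f"unknown method {method!r}; expected 'rkg' or 'rkgw'")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"invalid config at {loc!r}: {first['msg']}") from exc
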