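"""Schema-validated run configuration (YAML) and packaged parameter sets."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .fm import DEFAULT_FM_EPOCHS, FMExperimentConfig
from .kinetics import RecruitmentRateFunction, ReleaseModelParams
from .protocols import StimulusProtocol, make_protocol

__all__ = ["ModelConfig", "ProtocolConfig", "EstimatorConfig", "FMSettings",
           "RunConfig", "load_config", "load_packaged_config", "packaged_config_names"]


class ModelConfig(BaseModel):
    """Generative model parameters (see ReleaseModelParams)."""

    n_high: int = 2880
    n_low: int = 320
    pv_high: float = 0.36
    pv_low: float = 0.12
    alpha_0: float = 5.4
    alpha_inf: float = 1.5
    tau_alpha: float = 2.0
    alpha_train: float = 5.0
    facilitation_increment: float = 0.0
    facilitation_tau: float = 0.1
    quantal_size: float = 0.1
    quantal_cv: float = 0.3
    mini_rate: float = 0.0
    rest_threshold: float = 0.1

    def to_params(self, seed: int = 0) -> ReleaseModelParams:
        rec = RecruitmentRateFunction(self.alpha_0, self.alpha_inf,
                                      self.tau_alpha, self.alpha_train)
        return ReleaseModelParams(
            n_high=self.n_high, n_low=self.n_low, pv_high=self.pv_high,
            pv_low=self.pv_low, recruitment=rec,
            facilitation_increment=self.facilitation_increment,
            facilitation_tau=self.facilitation_tau,
            quantal_size=self.quantal_size, quantal_cv=self.quantal_cv,
            mini_rate=self.mini_rate, rest_threshold=self.rest_threshold,
            seed=seed)


class ProtocolConfig(BaseModel):
    segments: list[tuple[float, int]]
    start_time: float = 0.0
    label: str = ""

    def to_protocol(self) -> StimulusProtocol:
        return make_protocol(self.segments, self.start_time, self.label)


class EstimatorConfig(BaseModel):
    preparation: Literal["calyx", "schaffer"] = "calyx"
    ss_window: Optional[tuple[float, float]] = None
    alpha: float | Literal["fit"] = "fit"
    tol: float = 0.1
    max_iter: int = 100


class FMSettings(BaseModel):
    reserve_size: Optional[float] = None
    stained_fraction_rrp: float = 0.5
    stained_fraction_reserve: float = 0.5
    rundown_slope: float = -0.02
    background_level: float = 100.0
    f_inf_level: float = 20.0
    noise_sd: float = 0.5
    frame_interval: float = 4.0
    gain: float = 1.0
    pv_scatter: float = 0.0
    n_rois: int = 1
    epochs: list[tuple[str, float, float]] = Field(
        default_factory=lambda: [list(e) for e in DEFAULT_FM_EPOCHS])

    def to_fm_config(self) -> FMExperimentConfig:
        return FMExperimentConfig(
            reserve_size=self.reserve_size,
            stained_fraction_rrp=self.stained_fraction_rrp,
            stained_fraction_reserve=self.stained_fraction_reserve,
            rundown_slope=self.rundown_slope,
            background_level=self.background_level,
            f_inf_level=self.f_inf_level, noise_sd=self.noise_sd,
            frame_interval=self.frame_interval, gain=self.gain,
            pv_scatter=self.pv_scatter, n_rois=self.n_rois)


class RunConfig(BaseModel):
    """Top-level configuration of a simulate/analyze run."""

    mode: Literal["simulate", "analyze", "both"] = "simulate"
    label: str = ""
    model: ModelConfig = Field(default_factory=ModelConfig)
    protocols: list[ProtocolConfig] = Field(default_factory=list)
    estimator: EstimatorConfig = Field(default_factory=EstimatorConfig)
    fm: Optional[FMSettings] = None
    n_sweeps: int = 20
    out_dir: str = "vesiclekit_out"
    seed: Optional[int] = None
    inputs: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_seed(self):
        if self.mode in ("simulate", "both") and self.seed is None:
            raise ValueError("seed is required in simulate mode")
        return self


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


def packaged_config_names() -> list[str]:
    root = resources.files("vesiclekit") / "configs"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_packaged_config(name: str) -> RunConfig:
    """Load a packaged parameter set, e.g. 'calyx_wt' or 'schaffer_qko'."""
    path = resources.files("vesiclekit") / "configs" / f"{name}.yaml"
    if not path.is_file():
        raise FileNotFoundError(
            f"no packaged config {name!r}; available: {packaged_config_names()}")
    return RunConfig.model_validate(yaml.safe_load(path.read_text()))
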