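"""Run configuration: schema-validated settings for every workbench command,
with YAML round-tripping and the four family presets."""

from __future__ import annotations

from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = ["RunConfig", "preset", "PRESET_NAMES", "load_config", "save_config"]

Number = Union[float, int]
NumberOrList = Union[float, int, list[float]]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelConfig(_Strict):
    """Which family member to run and how it is parameterized: either an
    explicit synthesis factor ``beta`` or (default) a target equilibrium
    ``x_target`` that beta is calibrated to."""

    synthesis_kind: Literal["monotonic", "non_monotonic"] = "monotonic"
    degradation_kind: Literal["saturable", "non_saturable"] = "non_saturable"
    gamma: float = 1.0
    x_target: Optional[float] = 1.0
    beta: Optional[float] = None
    n: NumberOrList = 10.0
    tau: NumberOrList = 5.0

    @field_validator("gamma")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise ValueError("gamma must be > 0")
        return v


class IntegratorConfig(_Strict):
    dt: float = 1e-3
    t_end: float = 500.0
    transient: Optional[float] = None  # default: max(50 tau, 200)
    method: Literal["euler", "rk4"] = "euler"


class HistoryConfig(_Strict):
    value: Optional[float] = None  # default: 1.1 x*
    jitter: float = 0.0
    seed: int = 0


class D2Config(_Strict):
    m_min: int = 1
    m_max: int = 10
    lag: Optional[int] = None
    theiler: Optional[int] = None
    points_per_period: int = 20
    max_points: int = 6000


class ReductionConfig(_Strict):
    orders: list[int] = [1, 2]
    switch_mode: Literal["auto", "extremes", "self_consistent"] = "auto"


class SweepConfig(_Strict):
    observable: Literal["period", "amplitude", "corrdim"] = "period"


class HopfConfig(_Strict):
    branches: int = 1


class RunConfig(_Strict):
    model: ModelConfig = ModelConfig()
    integrator: IntegratorConfig = IntegratorConfig()
    history: HistoryConfig = HistoryConfig()
    d2: D2Config = D2Config()
    reduction: ReductionConfig = ReductionConfig()
    sweep: SweepConfig = SweepConfig()
    hopf: HopfConfig = HopfConfig()

    def set_path(self, dotted: str, raw: str) -> None:
        """Apply an override like 'model.tau=5.5' (value parsed as YAML)."""
        parts = dotted.split(".")
        obj = self
        for p in parts[:-1]:
            if not hasattr(obj, p):
                raise KeyError(f"unknown config section {p!r}")
            obj = getattr(obj, p)
        if parts[-1] not in type(obj).model_fields:
            raise KeyError(f"unknown config key {dotted!r}")
        setattr(obj, parts[-1], yaml.safe_load(raw))
        # re-validate the whole tree
        RunConfig.model_validate(self.model_dump())


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)


PRESET_NAMES = ("mono_sat", "mono_nonsat", "nonmono_sat", "nonmono_nonsat")


def preset(name: str) -> RunConfig:
    """Ready-to-run calibrated configuration for one family member.

    All presets keep the equilibrium at x* = 1 with gamma = 1 and differ in
    the kind flags and in the (n, tau) grids: the robust (monotonic) members
    get the reduction-friendly large-n grid, the non-monotonic members the
    chaos scan used for the dimension analysis.
    """
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    syn = "monotonic" if name.startswith("mono_") else "non_monotonic"
    deg = "saturable" if name.endswith("_sat") else "non_saturable"
    cfg = RunConfig()
    cfg.model.synthesis_kind = syn
    cfg.model.degradation_kind = deg
    if syn == "monotonic":
        cfg.model.n = [4.0, 8.0, 12.0, 16.0, 20.0]
        cfg.model.tau = [2.0, 4.0, 6.0, 8.0, 10.0]
    else:
        cfg.model.n = [6.0, 8.0, 10.0]
        cfg.model.tau = [1.0, 1.6, 2.2, 2.8, 3.2]
        cfg.integrator.t_end = 2200.0
        cfg.integrator.transient = 200.0
        cfg.history.jitter = 0.05
        cfg.d2.m_max = 12
        cfg.d2.points_per_period = 24
        cfg.d2.max_points = 9000
    return cfg
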