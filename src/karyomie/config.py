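"""Run configuration: schema-validated YAML/JSON blocks wired to the model.

A run config declares the viable space, the three rate kernels, and the
analyses to execute. Unknown keys are rejected so a typo never silently
changes a run.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .karyospace import KaryotypeSpace, build_space
from .rates import (
    RateModel,
    constant_rates,
    linear_beta_kernel,
    sinusoidal_beta_kernel,
    tabulated_kernel,
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpaceConfig(_Strict):
    M: int = Field(ge=1)
    viable_lo: list[int]
    viable_hi: list[int]

    def build(self) -> KaryotypeSpace:
        return build_space(self.M, self.viable_lo, self.viable_hi)


class KernelConfig(_Strict):
    kind: Literal["constant", "linear", "sinusoidal", "tabulated"]
    value: Optional[float] = None  # constant kernels
    theta1: Optional[float] = None
    theta2: Optional[float] = None
    b0: Optional[float] = None
    c_ref: int = 2
    chromosome: int = 0
    p_peak: int = 66
    period: float = 44.0
    floor: float = 1e-4
    ceil: float = 1.0
    table: Optional[str] = None  # CSV path: state, rate

    @model_validator(mode="after")
    def _check(self):
        if self.kind == "constant" and self.value is None:
            raise ValueError("constant kernel requires 'value'")
        if self.kind == "linear" and (self.theta1 is None or self.b0 is None):
            raise ValueError("linear kernel requires 'theta1' and 'b0'")
        if self.kind == "sinusoidal" and (self.theta2 is None or self.b0 is None):
            raise ValueError("sinusoidal kernel requires 'theta2' and 'b0'")
        if self.kind == "tabulated" and self.table is None:
            raise ValueError("tabulated kernel requires 'table' (CSV path)")
        return self

    def build_fn(self, base_dir: Path | None = None):
        if self.kind == "constant":
            v = float(self.value)
            return (lambda k: v), "constant"
        if self.kind == "linear":
            return (
                linear_beta_kernel(
                    self.theta1, self.b0, self.c_ref, self.chromosome,
                    self.floor, self.ceil,
                ),
                "linear",
            )
        if self.kind == "sinusoidal":
            return (
                sinusoidal_beta_kernel(
                    self.theta2, self.b0, self.p_peak, self.period,
                    self.floor, self.ceil,
                ),
                "sinusoidal",
            )
        path = Path(self.table)
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        df = pd.read_csv(path)
        values = {
            tuple(int(float(c)) for c in str(state).split(";")): float(rate)
            for state, rate in zip(df.iloc[:, 0], df.iloc[:, 1])
        }
        return tabulated_kernel(values), "tabulated"


class RatesConfig(_Strict):
    birth: KernelConfig = KernelConfig(kind="constant", value=1.0)
    death: KernelConfig = KernelConfig(kind="constant", value=0.0)
    misseg: KernelConfig = KernelConfig(kind="constant", value=0.0)

    def build(self, base_dir: Path | None = None) -> RateModel:
        if (
            self.birth.kind == "constant"
            and self.death.kind == "constant"
            and self.misseg.kind == "constant"
        ):
            return constant_rates(self.birth.value, self.death.value, self.misseg.value)
        birth_fn, bk = self.birth.build_fn(base_dir)
        death_fn, dk = self.death.build_fn(base_dir)
        misseg_fn, mk = self.misseg.build_fn(base_dir)
        return RateModel(
            birth=birth_fn, death=death_fn, misseg=misseg_fn,
            birth_kind=bk, death_kind=dk, misseg_kind=mk,
        )


class SimulationConfig(_Strict):
    t_max: float = 1e4
    qss_tol: float = 0.001
    dt_check: float = 10.0
    initial: Literal["diploid"] = "diploid"


class CurveConfig(_Strict):
    parameter: Literal["beta", "theta1", "theta2"] = "beta"
    grid_start: float = 0.0
    grid_stop: float = 0.5
    grid_step: float = 0.02
    b0: float = 0.0  # baseline for kernel-parameter sweeps

    def grid(self) -> list[float]:
        import numpy as np

        return list(np.arange(self.grid_start, self.grid_stop + 1e-12, self.grid_step))


class AnalysisConfig(_Strict):
    curve: Optional[CurveConfig] = None
    gershgorin: bool = False


class RunConfig(_Strict):
    """Top-level run description; see the CLI subcommands for execution."""

    space: SpaceConfig
    rates: RatesConfig = RatesConfig()
    simulation: Optional[SimulationConfig] = None
    analysis: AnalysisConfig = AnalysisConfig()
    seed: int = 0
    out_dir: str = "results"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run config."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data)
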