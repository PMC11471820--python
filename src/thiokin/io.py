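"""Trace file I/O, run configuration and result reporting.

Traces travel as delimited text (CSV) with the fixed header columns
``delay_ps, dA, sigma`` — one file per probe energy, decimal points, no
locale handling — so runs diff cleanly under version control.  The run
configuration is a YAML document validated against a strict schema
(unknown keys rejected) before any computation starts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import kinetics
from .fitting import FitResult, FitSpec
from .kinetics import IRFModel, InvalidInputError, KineticParameters
from .observables import ChannelModel, TransientTrace
from .simulate import DEFAULT_NOISE_SIGMA, ExperimentDesign

logger = logging.getLogger("thiokin")

__all__ = [
    "TraceFormatError",
    "read_trace",
    "read_traces",
    "write_trace",
    "RunConfig",
    "load_config",
    "report",
]

TRACE_COLUMNS = ("delay_ps", "dA", "sigma")


class TraceFormatError(InvalidInputError):
    """Malformed trace file; message names the file and offending line."""


def read_trace(path: Union[str, Path], probe_energy: Optional[float] = None) -> TransientTrace:
    """Read one delay scan from a ``delay_ps,dA,sigma`` text table.

    The probe energy is taken from a ``# probe_energy_eV = ...`` comment
    line when present, else from the argument.  Validation failures name
    the file and the 1-based line number.
    """
    path = Path(path)
    header_energy = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "probe_energy_eV" in first:
        header_energy = float(first.split("=")[1])
    df = pd.read_csv(path, comment="#")
    if tuple(df.columns) != TRACE_COLUMNS:
        raise TraceFormatError(
            f"{path}: expected columns {TRACE_COLUMNS}, found {tuple(df.columns)}"
        )
    offset = 3 if header_energy is not None else 2  # data starts after header (+comment)
    for col in TRACE_COLUMNS:
        bad = np.where(~np.isfinite(df[col].to_numpy(dtype=float)))[0]
        if bad.size:
            raise TraceFormatError(f"{path}, line {bad[0] + offset}: non-numeric {col}")
    sigma = df["sigma"].to_numpy(dtype=float)
    bad = np.where(sigma <= 0)[0]
    if bad.size:
        raise TraceFormatError(
            f"{path}, line {bad[0] + offset}: sigma must be > 0, got {sigma[bad[0]]}"
        )
    delays = df["delay_ps"].to_numpy(dtype=float)
    nonmono = np.where(np.diff(delays) <= 0)[0]
    if nonmono.size:
        raise TraceFormatError(
            f"{path}, line {nonmono[0] + offset + 1}: delays not strictly increasing"
        )
    energy = header_energy if header_energy is not None else probe_energy
    if energy is None:
        raise TraceFormatError(f"{path}: probe energy neither in header nor given")
    trace = TransientTrace(energy, delays, df["dA"].to_numpy(dtype=float), sigma)
    logger.info("read %s: %d points at %.1f eV", path, len(trace), energy)
    return trace


def read_traces(paths: Sequence[Union[str, Path]]) -> List[TransientTrace]:
    return [read_trace(p) for p in paths]


def write_trace(trace: TransientTrace, path: Union[str, Path]) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# probe_energy_eV = {trace.probe_energy}\n")
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        for d, a, s in zip(trace.delays, trace.dA, trace.sigma):
            fh.write(f"{d:.6g},{a:.8g},{s:.8g}\n")
    logger.info("wrote %s: %d points", path, len(trace))


# ---------------------------------------------------------------------------
# Run configuration (strict schema)
# ---------------------------------------------------------------------------


class ChannelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    energy: float
    amplitude: float
    species: Dict[str, float]
    contamination_source: Optional[float] = None
    contamination_fraction: float = 0.08

    def to_model(self) -> ChannelModel:
        contamination = None
        if self.contamination_source is not None:
            contamination = (self.contamination_source, self.contamination_fraction)
        return ChannelModel(self.energy, dict(self.species), self.amplitude, contamination)


class IRFConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sigma: Optional[float] = None
    t0: float = 0.0
    components: Optional[List[float]] = None

    def to_model(self) -> IRFModel:
        if self.sigma is not None:
            return IRFModel(sigma=self.sigma, t0=self.t0)
        if self.components:
            return IRFModel(sigma=kinetics.quadrature_irf_width(self.components), t0=self.t0)
        raise InvalidInputError("irf config needs sigma or components")


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lin_start: float = -1.0
    lin_stop: float = 5.0
    lin_step: float = 0.05
    log_stop: float = 800.0
    log_points: int = 30
    noise_sigma: Union[float, Dict[float, float], None] = DEFAULT_NOISE_SIGMA
    shots: Optional[int] = None
    shot_sigma: Optional[float] = None
    drift_sigma: float = 0.0


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    vary: Dict[str, bool] = Field(default_factory=dict)
    bounds: Dict[str, Tuple[float, float]] = Field(default_factory=dict)
    initial: Dict[str, float] = Field(default_factory=dict)
    multistart: int = 0
    n_bootstrap: int = 0


class RunConfig(BaseModel):
    """Whole-pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: Optional[int] = None
    parameters: Dict[str, float] = Field(default_factory=dict)
    irf: IRFConfig = Field(default_factory=lambda: IRFConfig(sigma=0.087))
    channels: Optional[List[ChannelConfig]] = None
    design: DesignConfig = Field(default_factory=DesignConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    traces: List[str] = Field(default_factory=list)

    @field_validator("parameters")
    @classmethod
    def _check_parameters(cls, v: Dict[str, float]) -> Dict[str, float]:
        if v:
            KineticParameters.from_dict(
                {k: (math.inf if val in ("inf", None) else val) for k, val in v.items()}
            )
        return v

    # -- realized objects --------------------------------------------------
    def kinetic_parameters(self) -> KineticParameters:
        if not self.parameters:
            from .simulate import fixture_table1

            return fixture_table1()[0]
        return KineticParameters.from_dict(
            {k: float(v) for k, v in self.parameters.items()}
        )

    def channel_models(self) -> List[ChannelModel]:
        if self.channels is None:
            from .observables import default_channels

            return default_channels()
        return [c.to_model() for c in self.channels]

    def experiment_design(self, seed: Optional[int] = None) -> ExperimentDesign:
        d = self.design
        channels = self.channel_models()
        if isinstance(d.noise_sigma, dict):
            noise = dict(d.noise_sigma)
        elif d.noise_sigma is None:
            noise = None
        else:
            noise = {c.label: float(d.noise_sigma) for c in channels}
        return ExperimentDesign(
            channels=channels,
            lin_start=d.lin_start,
            lin_stop=d.lin_stop,
            lin_step=d.lin_step,
            log_stop=d.log_stop,
            log_points=d.log_points,
            noise_sigma=noise,
            shots=d.shots,
            shot_sigma=d.shot_sigma,
            drift_sigma=d.drift_sigma,
            seed=seed if seed is not None else self.seed,
        )

    def fit_spec(self) -> FitSpec:
        return FitSpec(
            channels=self.channel_models(),
            vary=dict(self.fit.vary),
            bounds={k: tuple(v) for k, v in self.fit.bounds.items()},
            initial=dict(self.fit.initial),
            multistart=self.fit.multistart,
            seed=self.seed,
            n_bootstrap=self.fit.n_bootstrap,
        )


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def report(
    fit: Optional[FitResult], out_path: Union[str, Path], text: bool = True
) -> Dict[str, object]:
    """Write a machine-readable fit report (JSON) plus a plain-text table.

    Derived quantities — the 20-ps thiyl recombined fraction, the
    asymptotic ground-state recovery and the recovery at 1 ns — are
    recomputed from the fitted parameters.  ``fit=None`` produces a stub
    report flagged as failed.
    """
    out_path = Path(out_path)
    if fit is None:
        doc: Dict[str, object] = {"success": False, "message": "no fit available"}
        out_path.write_text(json.dumps(doc, indent=2) + "\n")
        return doc

    p = fit.estimates
    traj = kinetics.solve_populations(p, np.array([1000.0]))
    derived = {
        "recombined_fraction_20ps": kinetics.recombined_fraction(p, 20.0),
        "asymptotic_recovery": kinetics.asymptotic_recovery(p),
        "recovery_1ns": float(traj.N0[0]),
        "q23": p.q23,
        "q32": p.q32,
        "q42": p.q42,
    }
    doc = {
        "success": fit.success,
        "message": fit.message,
        "parameters": fit.values(),
        "stderr": {k: v for k, v in fit.stderr.items()},
        "amplitudes": {str(k): v for k, v in fit.amplitudes.items()},
        "redchi": fit.redchi,
        "chisqr": fit.chisqr,
        "ndata": fit.ndata,
        "nvarys": fit.nvarys,
        "nfev": fit.nfev,
        "derived": derived,
    }
    out_path.write_text(json.dumps(doc, indent=2) + "\n")
    if text:
        lines = ["parameter      value      stderr", "-" * 34]
        for name, value in fit.values().items():
            err = fit.stderr.get(name)
            err_s = f"{err:.4g}" if err is not None else "--"
            lines.append(f"{name:10s} {value:10.4g}  {err_s}")
        lines.append("-" * 34)
        lines.append(f"reduced chi-square: {fit.redchi:.4f}")
        for name, value in derived.items():
            lines.append(f"{name}: {value:.4f}")
        out_path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    logger.info("wrote report %s (redchi=%.3f)", out_path, fit.redchi)
    return doc
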