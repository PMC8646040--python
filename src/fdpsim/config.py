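"""Run configuration: YAML schema, defaults, lossless round-trip.

A run is fully described by four sections plus a frequency grid::

    params:      {g_nmda: 0.002, tau_ca: 80.0, ...}   # ModelParams fields
    simulation:  {duration: 9.0e4, dt: 0.1, ...}      # SimulationConfig fields
    design:      {n_trains: 5, n_xi_seeds: 3,
                  cv_levels: [0, 1, 3, 5], base_seed: 0, ...}
    frequencies: {start: 1, stop: 20, step: 1}        # or an explicit list
    analysis:    {plateau_tol: 0.0, area_mode: literal,
                  test: welch, correction: holm, alpha: 0.05}
    output:      {save_traces: false, figures: true}

Every field is optional; unspecified fields take the model's published
defaults. Unknown keys are rejected by name so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .drive import ReplicateDesign
from .errors import ConfigurationError
from .params import ModelParams
from .simulator import SimulationConfig

__all__ = ["AnalysisOptions", "OutputOptions", "RunConfig",
           "load_config", "save_config"]

_TESTS = ("welch", "permutation")
_CORRECTIONS = ("holm", "none")
_AREA_MODES = ("literal", "deviation")


@dataclass(frozen=True)
class AnalysisOptions:
    """Options of the threshold/area/significance stage."""

    plateau_tol: float = 0.0
    area_mode: str = "deviation"
    test: str = "welch"
    correction: str = "holm"
    alpha: float = 0.05
    permutation_resamples: int = 10000

    def __post_init__(self):
        if self.area_mode not in _AREA_MODES:
            raise ConfigurationError(f"area_mode must be one of {_AREA_MODES}")
        if self.test not in _TESTS:
            raise ConfigurationError(f"test must be one of {_TESTS}")
        if self.correction not in _CORRECTIONS:
            raise ConfigurationError(f"correction must be one of {_CORRECTIONS}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class OutputOptions:
    """What the pipeline writes besides the canonical CSV/JSON."""

    save_traces: bool = False
    figures: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Complete, resolved description of one pipeline run."""

    params: ModelParams = field(default_factory=ModelParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    design: ReplicateDesign = field(default_factory=ReplicateDesign)
    frequencies: tuple = tuple(float(f) for f in range(1, 21))
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    output: OutputOptions = field(default_factory=OutputOptions)

    def __post_init__(self):
        freqs = tuple(float(f) for f in self.frequencies)
        if not freqs or any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ConfigurationError("frequencies must be non-empty and strictly increasing")
        object.__setattr__(self, "frequencies", freqs)

    def to_dict(self) -> dict:
        design = dataclasses.asdict(self.design)
        design["cv_levels"] = list(design["cv_levels"])
        return {
            "params": self.params.to_dict(),
            "simulation": self.simulation.to_dict(),
            "design": design,
            "frequencies": list(self.frequencies),
            "analysis": dataclasses.asdict(self.analysis),
            "output": dataclasses.asdict(self.output),
        }


def _section(d: dict, name: str) -> dict:
    sec = d.pop(name, None) or {}
    if not isinstance(sec, dict):
        raise ConfigurationError(f"section '{name}' must be a mapping")
    return _numeric_coerce(sec)


def _numeric_coerce(d: dict) -> dict:
    # YAML 1.1 reads "9.0e4" (no signed exponent) as a string; accept it
    out = {}
    for k, v in d.items():
        if isinstance(v, str):
            try:
                v = float(v)
            except ValueError:
                pass
        out[k] = v
    return out


def _from_fields(cls, d: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in '{section}': {', '.join(sorted(unknown))}"
        )
    return cls(**d)


def _parse_frequencies(spec) -> tuple:
    if spec is None:
        return tuple(float(f) for f in range(1, 21))
    if isinstance(spec, dict):
        unknown = set(spec) - {"start", "stop", "step"}
        if unknown:
            raise ConfigurationError(
                f"unknown key(s) in 'frequencies': {', '.join(sorted(unknown))}"
            )
        start = float(spec.get("start", 1.0))
        stop = float(spec.get("stop", 20.0))
        step = float(spec.get("step", 1.0))
        if step <= 0 or stop < start:
            raise ConfigurationError("frequencies need step > 0 and stop >= start")
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        return tuple(start + step * k for k in range(n))
    return tuple(float(f) for f in spec)


def config_from_dict(raw: dict) -> RunConfig:
    """Build a RunConfig from a (possibly partial) nested dict."""
    d = dict(raw or {})
    params = ModelParams.from_dict(_section(d, "params"))
    sim_d = _section(d, "simulation")
    if "trace_stride" in sim_d:
        sim_d["trace_stride"] = int(sim_d["trace_stride"])
    simulation = SimulationConfig.from_dict(sim_d)
    design_d = _section(d, "design")
    for int_key in ("n_trains", "n_xi_seeds", "base_seed"):
        if int_key in design_d:
            design_d[int_key] = int(design_d[int_key])
    if "cv_levels" in design_d:
        design_d["cv_levels"] = tuple(float(c) for c in design_d["cv_levels"])
    design = _from_fields(ReplicateDesign, design_d, "design")
    frequencies = _parse_frequencies(d.pop("frequencies", None))
    analysis = _from_fields(AnalysisOptions, _section(d, "analysis"), "analysis")
    output = _from_fields(OutputOptions, _section(d, "output"), "output")
    if d:
        raise ConfigurationError(
            f"unknown top-level key(s): {', '.join(sorted(d))}"
        )
    return RunConfig(params=params, simulation=simulation, design=design,
                     frequencies=frequencies, analysis=analysis, output=output)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; missing fields take the defaults.

    Raises
    ------
    ConfigurationError
        On parse failure or any unknown key (named in the message).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} must contain a YAML mapping")
    return config_from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    """Write the fully resolved configuration as YAML (round-trips)."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False, default_flow_style=False)
    )
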