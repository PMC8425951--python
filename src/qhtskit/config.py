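"""YAML run configuration for the command-line interface."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .plate import DilutionDesign, ScreenDesign
from .power import AssayControls
from .simulate import (
    LognormalParams,
    ProtectionParams,
    SimulationConfig,
    ToxicityParams,
    TruncNormalParams,
)

__all__ = ["AnalysisOptions", "PowerOptions", "RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """The configuration file is invalid."""


@dataclass(frozen=True)
class AnalysisOptions:
    estimator: str = "mm"
    reference: str = "vs_ablated"
    additivity_mode: str = "relative"
    alpha: float = 0.05
    family_size: int | None = None
    cutoff_k: float = 3.0

    def __post_init__(self):
        if self.estimator not in ("mm", "umvue"):
            raise ConfigError(f"unknown estimator {self.estimator!r}")
        if self.reference not in ("vs_ablated", "vs_nonablated"):
            raise ConfigError(f"unknown reference {self.reference!r}")
        if self.additivity_mode not in ("relative", "absolute_pp"):
            raise ConfigError(f"unknown additivity_mode {self.additivity_mode!r}")


@dataclass(frozen=True)
class PowerOptions:
    controls: AssayControls = field(
        default_factory=lambda: AssayControls(0.0, 42.3, 100.0, 42.3)
    )
    f_grid: tuple = (0.25, 0.5, 1.0)
    alpha_grid: tuple = (0.05,)
    beta_grid: tuple = (0.05,)
    sidedness: str = "one"
    method: str = "normal"


@dataclass(frozen=True)
class RunConfig:
    """Everything one CLI invocation needs; see docs for the YAML schema."""

    seed: int = 0
    output_dir: str = "out"
    design: ScreenDesign = field(default_factory=ScreenDesign.primary_default)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    power: PowerOptions = field(default_factory=PowerOptions)
    well_tables: tuple = ()
    exclusions_path: str | None = None
    pairs: tuple = ()
    lethal_pairs: tuple = ()


def _build_design(d: dict) -> ScreenDesign:
    dilution = DilutionDesign(
        top_concentration_uM=float(d.get("top_concentration_uM", 4.0)),
        fold=float(d.get("fold", 2.0)),
        n_levels=int(d.get("n_levels", 6)),
        replicates_per_level=int(d.get("replicates", 16)),
    )
    kwargs = {"stage": d.get("stage", "primary")}
    if "controls" in d:
        kwargs["controls"] = {k: int(v) for k, v in d["controls"].items()}
    return ScreenDesign(dilution, **kwargs)


def _build_simulation(d: dict, seed: int) -> SimulationConfig:
    kwargs: dict = {"seed": int(d.get("seed", seed))}
    for name in ("n_compounds",):
        if name in d:
            kwargs[name] = int(d[name])
    for name in ("frac_protective", "frac_toxic", "frac_autofluorescent",
                 "residual_fraction", "autofluor_gain", "dispensing_error_rate"):
        if name in d:
            kwargs[name] = float(d[name])
    if "baseline" in d:
        kwargs["baseline"] = LognormalParams(**d["baseline"])
    if "background" in d:
        kwargs["background"] = TruncNormalParams(**d["background"])
    if "protection" in d:
        kwargs["protection"] = ProtectionParams(**d["protection"])
    if "toxicity" in d:
        kwargs["toxicity"] = ToxicityParams(**d["toxicity"])
    return SimulationConfig(**kwargs)


def _build_power(d: dict) -> PowerOptions:
    kwargs: dict = {}
    if "controls" in d:
        kwargs["controls"] = AssayControls(**d["controls"])
    for name in ("f_grid", "alpha_grid", "beta_grid"):
        if name in d:
            kwargs[name] = tuple(float(v) for v in d[name])
    for name in ("sidedness", "method"):
        if name in d:
            kwargs[name] = d[name]
    return PowerOptions(**kwargs)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        seed = int(raw.get("seed", 0))
        return RunConfig(
            seed=seed,
            output_dir=str(raw.get("output_dir", "out")),
            design=_build_design(raw.get("design", {})),
            simulation=_build_simulation(raw.get("simulation", {}), seed),
            analysis=AnalysisOptions(**raw.get("analysis", {})),
            power=_build_power(raw.get("power", {})),
            well_tables=tuple(raw.get("inputs", {}).get("well_tables", [])),
            exclusions_path=raw.get("inputs", {}).get("exclusions"),
            pairs=tuple(tuple(p) for p in raw.get("pairs", [])),
            lethal_pairs=tuple(tuple(p) for p in raw.get("lethal_pairs", [])),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
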