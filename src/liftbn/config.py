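"""Scenario configuration: YAML schema, validation, and fixtures.

A scenario file is a small YAML document with degrees/kilograms/metres at
the boundary (SI internally).  Unknown keys are rejected so typos fail
loudly; every block except ``subject``, ``posture`` and ``hand_load`` has
defaults.  The packaged ``carbon-lifting`` fixture encodes the heavy-lifting
task used throughout the documentation: a 50th-percentile female
(161.8 cm / 65.6 kg) lifting 53.1 +/- 12.8 kg chunks of carbon, with
measured posture angles and measurement-error SDs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .anthropometry import SegmentParameterTable, Subject
from .exceptions import ConfigurationError
from .injury import InjuryEvidence, StrengthModel
from .statics import DEFAULT_DISC_REGRESSION, DEFAULT_MOMENT_ARM, DiscRegression, PostureSpec
from .stochastic import PostureStdDev, RandomScenario

__all__ = [
    "ScenarioConfig",
    "load_config",
    "save_config",
    "fixture_path",
    "list_fixtures",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SubjectConfig(_Strict):
    stature_m: float = Field(gt=0)
    body_mass_kg: float = Field(gt=0)


class AngleConfig(_Strict):
    mean_deg: float
    sd_deg: float = Field(default=0.0, ge=0)


class PostureConfig(_Strict):
    ankle: AngleConfig
    knee: AngleConfig
    torso: AngleConfig
    shoulder: AngleConfig
    elbow: AngleConfig


class HandLoadConfig(_Strict):
    mean_kg: float = Field(ge=0)
    sd_kg: float = Field(default=0.0, ge=0)


class DiscRegressionConfig(_Strict):
    intercept: float = DEFAULT_DISC_REGRESSION.intercept
    t_slope: float = DEFAULT_DISC_REGRESSION.t_slope
    k_slope: float = DEFAULT_DISC_REGRESSION.k_slope
    tk: float = 0.0
    t2: float = 0.0
    k2: float = 0.0


class StrengthConfig(_Strict):
    mean_n: float = 5448.0
    sd_n: float = Field(default=2366.0, gt=0)


class SimulationConfig(_Strict):
    n_iterations: int = Field(default=1_000_000, ge=1)
    seed: int = 0
    vary: Literal["posture", "hand_load", "hand", "both"] = "both"


class ScenarioConfig(_Strict):
    """Validated scenario description (see module docstring for units)."""

    subject: SubjectConfig
    posture: PostureConfig
    hand_load: HandLoadConfig
    erector_moment_arm_m: float = Field(default=DEFAULT_MOMENT_ARM, gt=0)
    disc_regression: DiscRegressionConfig = DiscRegressionConfig()
    strength: StrengthConfig = StrengthConfig()
    simulation: SimulationConfig = SimulationConfig()
    evidence: Literal["none", "true", "false"] = "none"
    mode: Literal["deterministic", "mc", "posterior"] = "deterministic"
    segments: Optional[Dict[str, Dict[str, float]]] = None

    # -- converters into domain objects -------------------------------------
    def to_subject(self) -> Subject:
        return Subject(self.subject.stature_m, self.subject.body_mass_kg)

    def to_posture_means(self) -> PostureSpec:
        p = self.posture
        return PostureSpec(
            ankle_deg=p.ankle.mean_deg,
            knee_deg=p.knee.mean_deg,
            torso_deg=p.torso.mean_deg,
            shoulder_deg=p.shoulder.mean_deg,
            elbow_deg=p.elbow.mean_deg,
        )

    def to_posture_sds(self) -> PostureStdDev:
        p = self.posture
        return PostureStdDev(
            ankle_deg=p.ankle.sd_deg,
            knee_deg=p.knee.sd_deg,
            torso_deg=p.torso.sd_deg,
            shoulder_deg=p.shoulder.sd_deg,
            elbow_deg=p.elbow.sd_deg,
        )

    def to_table(self) -> SegmentParameterTable:
        if self.segments:
            return SegmentParameterTable.with_overrides(self.segments)
        return SegmentParameterTable.default()

    def to_disc_regression(self) -> DiscRegression:
        d = self.disc_regression
        return DiscRegression(
            intercept=d.intercept, t_slope=d.t_slope, k_slope=d.k_slope,
            tk=d.tk, t2=d.t2, k2=d.k2,
        )

    def to_strength(self) -> StrengthModel:
        return StrengthModel(self.strength.mean_n, self.strength.sd_n)

    def to_evidence(self) -> InjuryEvidence:
        return InjuryEvidence(self.evidence)

    def to_random_scenario(
        self, n: Optional[int] = None, seed: Optional[int] = None
    ) -> RandomScenario:
        sim = self.simulation
        return RandomScenario(
            posture_means=self.to_posture_means(),
            posture_sds=self.to_posture_sds(),
            hand_mass_mean=self.hand_load.mean_kg,
            hand_mass_sd=self.hand_load.sd_kg,
            subject=self.to_subject(),
            n_iterations=n if n is not None else sim.n_iterations,
            seed=seed if seed is not None else sim.seed,
            table=self.to_table(),
            moment_arm=self.erector_moment_arm_m,
            coeffs=self.to_disc_regression(),
        )


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: str | Path) -> ScenarioConfig:
    """Read and validate a scenario YAML file.

    Raises :class:`ConfigurationError` naming the offending key for schema
    violations, including unknown keys.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a YAML mapping")
    try:
        return ScenarioConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(
            f"invalid scenario config {path}: {_format_validation_error(exc)}"
        ) from exc


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips to an equal config)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)


def list_fixtures() -> List[str]:
    """Names of packaged scenario fixtures."""
    root = resources.files("liftbn") / "fixtures"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (e.g. ``"carbon_lifting"``)."""
    path = resources.files("liftbn") / "fixtures" / f"{name}.yaml"
    if not path.is_file():
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}"
        )
    return Path(str(path))
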