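"""Monte Carlo propagation of posture and hand-load uncertainty.

Joint angles and the hand-load mass are modelled as independent,
untruncated normal random variables (the angle means and SDs come from
reported ergonomic measurement-error studies; the hand-load distribution
describes the task itself).  Draws are propagated through the vectorised
deterministic linkage model, and output distributions are summarised with
weight-aware statistics so the same machinery serves both plain forward
simulation (unit weights) and importance-weighted posterior inference.

Reproducibility: each varied input draws from its own child stream of a
``numpy.random.SeedSequence`` spawned from the scenario seed, so a given
(scenario, seed) pair yields a bit-identical sample set regardless of which
inputs are varied.

Negative hand-mass draws (probability about 2e-5 at the packaged scenario's
parameters) are clamped to zero and counted in ``SampleSet.n_clamped``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict

import numpy as np
import pandas as pd

from .anthropometry import SegmentParameterTable, Subject
from .exceptions import ConfigurationError
from .statics import (
    DEFAULT_DISC_REGRESSION,
    DEFAULT_MOMENT_ARM,
    DiscRegression,
    HandLoad,
    PostureSpec,
    evaluate,
)

__all__ = [
    "mad_to_sd",
    "PostureStdDev",
    "RandomScenario",
    "SampleSet",
    "WeightedSummary",
    "simulate",
    "summarize",
    "weighted_quantile",
]

_ANGLES = ("ankle", "knee", "torso", "shoulder", "elbow")

#: Accepted values for the ``vary`` argument of :func:`simulate`
#: ("hand" is accepted as a short alias of "hand_load").
VARY_CHOICES = ("posture", "hand_load", "both")


def mad_to_sd(mean_absolute_error: float) -> float:
    """Convert a mean absolute error to a normal standard deviation.

    For X ~ N(mu, sigma), E|X - mu| = sigma * sqrt(2/pi) (Geary's result),
    so sigma = MAD * sqrt(pi/2).
    """
    if mean_absolute_error < 0:
        raise ConfigurationError("mean absolute error must be >= 0")
    return mean_absolute_error * math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class PostureStdDev:
    """Per-angle standard deviations (degrees); all must be >= 0."""

    ankle_deg: float
    knee_deg: float
    torso_deg: float
    shoulder_deg: float
    elbow_deg: float

    def __post_init__(self) -> None:
        for name in ("ankle_deg", "knee_deg", "torso_deg", "shoulder_deg", "elbow_deg"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value >= 0):
                raise ConfigurationError(f"posture SD {name} must be >= 0, got {value}")


@dataclass(frozen=True)
class RandomScenario:
    """Full stochastic description of a lifting scenario."""

    posture_means: PostureSpec
    posture_sds: PostureStdDev
    hand_mass_mean: float
    hand_mass_sd: float
    subject: Subject
    n_iterations: int = 1_000_000
    seed: int = 0
    table: SegmentParameterTable | None = None
    moment_arm: float = DEFAULT_MOMENT_ARM
    coeffs: DiscRegression = DEFAULT_DISC_REGRESSION

    def __post_init__(self) -> None:
        if self.hand_mass_mean < 0:
            raise ConfigurationError("hand mass mean must be >= 0")
        if self.hand_mass_sd < 0:
            raise ConfigurationError("hand mass SD must be >= 0")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")


@dataclass(frozen=True)
class SampleSet:
    """Seeded Monte Carlo draws with their propagated linkage outputs.

    All arrays have equal length.  ``weights`` default to 1 for forward
    simulation and are replaced by likelihood weights under posterior
    inference; inputs and outputs are never altered by conditioning.
    """

    inputs: Dict[str, np.ndarray]
    outputs: Dict[str, np.ndarray]
    weights: np.ndarray
    seed: int
    n_clamped: int = 0

    def __post_init__(self) -> None:
        n = len(self.weights)
        for name, arr in {**self.inputs, **self.outputs}.items():
            if len(arr) != n:
                raise ConfigurationError(f"array {name!r} has length {len(arr)} != {n}")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ConfigurationError("weights must be >= 0 and not all zero")

    @property
    def n(self) -> int:
        return len(self.weights)

    def field(self, name: str) -> np.ndarray:
        if name in self.outputs:
            return self.outputs[name]
        if name in self.inputs:
            return self.inputs[name]
        raise ConfigurationError(f"unknown sample field {name!r}")

    def with_weights(self, weights: np.ndarray) -> "SampleSet":
        return replace(self, weights=np.asarray(weights, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({**self.inputs, **self.outputs, "weight": self.weights})


@dataclass(frozen=True)
class WeightedSummary:
    """Weighted moments, quartiles and effective sample size."""

    mean: float
    sd: float
    p25: float
    p50: float
    p75: float
    effective_sample_size: float

    def __post_init__(self) -> None:
        if not (self.p25 <= self.p50 <= self.p75):
            raise ConfigurationError("quartiles must be ordered p25 <= p50 <= p75")
        if self.sd < 0:
            raise ConfigurationError("sd must be >= 0")


def simulate(scenario: RandomScenario, vary: str = "both") -> SampleSet:
    """Draw input realisations and propagate them through the linkage model.

    ``vary`` selects which inputs are random: ``"posture"`` (five angles),
    ``"hand_load"`` (hand mass), or ``"both"``.  Non-varied inputs are held
    at their means.  All weights are 1.
    """
    if vary == "hand":
        vary = "hand_load"
    if vary not in VARY_CHOICES:
        raise ConfigurationError(f"vary must be one of {VARY_CHOICES}, got {vary!r}")

    n = scenario.n_iterations
    means = scenario.posture_means
    sds = scenario.posture_sds
    streams = np.random.SeedSequence(scenario.seed).spawn(len(_ANGLES) + 1)

    angles: Dict[str, np.ndarray] = {}
    for name, ss in zip(_ANGLES, streams[:-1]):
        mu = float(getattr(means, f"{name}_deg"))
        if vary in ("posture", "both"):
            sigma = float(getattr(sds, f"{name}_deg"))
            angles[name] = np.random.default_rng(ss).normal(mu, sigma, size=n)
        else:
            angles[name] = np.full(n, mu)

    if vary in ("hand_load", "both"):
        hand = np.random.default_rng(streams[-1]).normal(
            scenario.hand_mass_mean, scenario.hand_mass_sd, size=n
        )
    else:
        hand = np.full(n, scenario.hand_mass_mean)
    n_clamped = int(np.count_nonzero(hand < 0))
    if n_clamped:
        hand = np.where(hand < 0, 0.0, hand)

    posture = PostureSpec(
        ankle_deg=angles["ankle"],
        knee_deg=angles["knee"],
        torso_deg=angles["torso"],
        shoulder_deg=angles["shoulder"],
        elbow_deg=angles["elbow"],
    )
    result = evaluate(
        posture,
        HandLoad(hand),
        scenario.subject,
        scenario.table,
        scenario.moment_arm,
        scenario.coeffs,
    )
    outputs = {
        "elbow_moment": np.asarray(result.elbow.moment),
        "shoulder_moment": np.asarray(result.shoulder.moment),
        "l5s1_moment": np.asarray(result.l5s1.moment),
        "erector_force": np.asarray(result.erector_force),
        "disc_angle": np.asarray(result.disc.disc_angle),
        "compression": np.asarray(result.compression),
        "shear": np.asarray(result.shear),
    }
    inputs = {**{f"{k}_deg": v for k, v in angles.items()}, "hand_mass": hand}
    return SampleSet(
        inputs=inputs,
        outputs=outputs,
        weights=np.ones(n),
        seed=scenario.seed,
        n_clamped=n_clamped,
    )


def weighted_quantile(
    values: np.ndarray, weights: np.ndarray, q: np.ndarray | float
) -> np.ndarray | float:
    """Weighted empirical quantiles with Hazen plotting positions.

    Sorted values are placed at cumulative-probability positions
    ``(cumw - w/2) / sum(w)`` and linearly interpolated; with uniform
    weights this reduces to the classical Hazen sample quantile.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    positions = (cw - 0.5 * w) / cw[-1]
    return np.interp(q, positions, v)


def summarize(samples: SampleSet, field: str) -> WeightedSummary:
    """Weighted mean, SD, quartiles, and ESS of one sample field.

    The SD is the population-style weighted standard deviation
    ``sqrt(sum w (x - mean)^2 / sum w)``; with uniform weights all
    statistics coincide with their unweighted counterparts.  The effective
    sample size is ``(sum w)^2 / sum w^2``.
    """
    x = samples.field(field)
    w = samples.weights
    wsum = float(np.sum(w))
    mean = float(np.sum(w * x) / wsum)
    var = float(np.sum(w * (x - mean) ** 2) / wsum)
    p25, p50, p75 = (float(v) for v in weighted_quantile(x, w, [0.25, 0.50, 0.75]))
    ess = wsum**2 / float(np.sum(w * w))
    return WeightedSummary(
        mean=mean,
        sd=math.sqrt(max(var, 0.0)),
        p25=p25,
        p50=p50,
        p75=p75,
        effective_sample_size=ess,
    )
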