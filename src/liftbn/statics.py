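"""Deterministic 2D static top-down linkage model of sagittal lifting.

The chain starts at the hands and propagates intersegmental reaction forces
and moments proximally: elbow -> shoulder -> L5/S1.  At L5/S1 the net
extensor moment is balanced by a single equivalent erector spinae muscle
acting at a fixed moment arm, perpendicular to the disc; the reaction force
is resolved into compression (normal to the disc) and shear (tangential).

Geometry and sign conventions
-----------------------------
* Sagittal plane, x anterior (the direction the lifter faces), y up.
* Every posture angle is the orientation of its link measured
  counter-clockwise from the positive-x horizontal, proximal to distal
  (torso: L5/S1 -> shoulder; upper arm: shoulder -> elbow; forearm-hand:
  elbow -> grip centre).  Angles may be negative or exceed 180 degrees.
* Only gravity acts, so every reaction force is vertical.  ``JointLoad``
  stores the force the proximal structure exerts on the distal chain
  (upward positive); its vertical component equals the total supported
  weight distal of the joint.
* A joint's reaction moment is ``sum_i W_i * (x_i - x_joint)`` over all
  gravity loads distal of the joint: positive when the load lies anterior
  to the joint (an extensor demand), negative when posterior.  This is the
  convention under which the carbon-lifting scenario gives a positive elbow
  moment and a negative shoulder moment.
* The L5/S1 disc plane makes ``disc_angle`` degrees with the horizontal;
  the deviation of that angle from 40 degrees (``beta``) is predicted by a
  polynomial regression in the torso-from-vertical angle T and the included
  knee angle K.  Shear is reported positive when directed down the anterior
  slope of the disc.

All functions broadcast over NumPy arrays, so one code path serves both the
scalar deterministic model and vectorised Monte Carlo propagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from .anthropometry import SegmentParameterTable, Subject, segment_com, segment_lengths, segment_masses
from .exceptions import ConfigurationError

__all__ = [
    "GRAVITY",
    "DEFAULT_MOMENT_ARM",
    "DISC_BASE_ANGLE_DEG",
    "PostureSpec",
    "HandLoad",
    "DiscRegression",
    "DEFAULT_DISC_REGRESSION",
    "DiscGeometry",
    "JointLoad",
    "LinkageResult",
    "ResolvedBody",
    "elbow_load",
    "shoulder_load",
    "l5s1_load",
    "disc_angle",
    "erector_force",
    "compression_shear",
    "evaluate",
]

#: Gravitational acceleration (m/s^2).
GRAVITY = 9.81

#: Default erector spinae moment arm (m) for a model without intra-abdominal
#: pressure relief.
DEFAULT_MOMENT_ARM = 0.053

#: The disc-angle regression predicts the deviation from this base (degrees).
DISC_BASE_ANGLE_DEG = 40.0

ArrayLike = Union[float, np.ndarray]


def _check_finite(name: str, value: ArrayLike) -> None:
    if not np.all(np.isfinite(value)):
        raise ConfigurationError(f"{name} must be finite")


@dataclass(frozen=True)
class PostureSpec:
    """Five sagittal joint angles, degrees from the horizontal."""

    ankle_deg: ArrayLike
    knee_deg: ArrayLike
    torso_deg: ArrayLike
    shoulder_deg: ArrayLike
    elbow_deg: ArrayLike

    def __post_init__(self) -> None:
        for name in ("ankle_deg", "knee_deg", "torso_deg", "shoulder_deg", "elbow_deg"):
            _check_finite(name, getattr(self, name))


@dataclass(frozen=True)
class HandLoad:
    """Mass of the object held in the hands (kg, total over both hands)."""

    mass: ArrayLike

    def __post_init__(self) -> None:
        _check_finite("hand load mass", self.mass)
        if np.any(np.asarray(self.mass) < 0):
            raise ConfigurationError("hand load mass must be >= 0")


@dataclass(frozen=True)
class DiscRegression:
    """Polynomial regression for beta, the disc-angle deviation from 40 deg.

    ``beta = intercept + t_slope*T + k_slope*K + tk*T*K + t2*T^2 + k2*K^2``
    with T the torso angle from vertical and K the included knee angle, both
    in degrees.  The default coefficients are a reconstruction: the slopes
    are modest positive values of the order reported for lumbosacral posture
    regressions, and the intercept was calibrated once against the
    carbon-lifting verification shear force and then frozen.
    """

    intercept: float
    t_slope: float = 0.0
    k_slope: float = 0.0
    tk: float = 0.0
    t2: float = 0.0
    k2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("intercept", "t_slope", "k_slope", "tk", "t2", "k2"):
            value = getattr(self, name)
            if value is None or not np.isfinite(value):
                raise ConfigurationError(f"disc regression coefficient {name} missing or not finite")

    def beta(self, t_deg: ArrayLike, k_deg: ArrayLike) -> ArrayLike:
        t = np.asarray(t_deg, dtype=float)
        k = np.asarray(k_deg, dtype=float)
        out = (
            self.intercept
            + self.t_slope * t
            + self.k_slope * k
            + self.tk * t * k
            + self.t2 * t * t
            + self.k2 * k * k
        )
        return out if out.ndim else float(out)


#: Frozen default coefficients (see class docstring and docs/methods.md).
DEFAULT_DISC_REGRESSION = DiscRegression(
    intercept=-17.212463312002797, t_slope=0.30, k_slope=0.12
)


@dataclass(frozen=True)
class DiscGeometry:
    """L5/S1 disc orientation and the erector spinae geometry.

    T : torso angle from vertical (deg); K : included knee angle (deg);
    beta : disc-angle deviation from 40 deg; disc_angle = 40 + beta (deg
    from horizontal); erector_moment_arm in metres.
    """

    T: ArrayLike
    K: ArrayLike
    beta: ArrayLike
    disc_angle: ArrayLike
    erector_moment_arm: float = DEFAULT_MOMENT_ARM

    def __post_init__(self) -> None:
        if not self.erector_moment_arm > 0:
            raise ConfigurationError("erector moment arm must be > 0")


@dataclass(frozen=True)
class JointLoad:
    """Intersegmental reaction at a joint.

    ``fx``, ``fy``: force (N) the proximal structure exerts on the distal
    chain (y up, so ``fy`` equals the supported weight).  ``moment``: sagittal
    reaction moment (N.m), extensor-positive as defined in the module
    docstring.
    """

    fx: ArrayLike
    fy: ArrayLike
    moment: ArrayLike

    @property
    def reaction_force(self) -> np.ndarray:
        return np.stack([np.asarray(self.fx, dtype=float), np.asarray(self.fy, dtype=float)], axis=-1)


@dataclass(frozen=True)
class LinkageResult:
    """All outputs of one deterministic evaluation of the linkage model."""

    elbow: JointLoad
    shoulder: JointLoad
    l5s1: JointLoad
    erector_force: ArrayLike
    disc: DiscGeometry
    compression: ArrayLike
    shear: ArrayLike


@dataclass(frozen=True)
class ResolvedBody:
    """Per-side link geometry (m) and segment weights (N) for one subject.

    ``grip_from_elbow`` is the along-link distance from the elbow to the grip
    centre (forearm link plus the grip-centre offset within the hand), the
    point where both the hand weight and the external load act.
    """

    grip_from_elbow: float
    forearm_com_from_elbow: float
    upper_arm_length: float
    upper_arm_com: float
    torso_length: float
    torso_com: float
    hand_weight: float
    forearm_weight: float
    upper_arm_weight: float
    torso_weight: float

    @classmethod
    def resolve(
        cls, subject: Subject, table: SegmentParameterTable | None = None
    ) -> "ResolvedBody":
        table = table if table is not None else SegmentParameterTable.default()
        lengths = segment_lengths(subject, table)
        masses = segment_masses(subject, table)
        coms = segment_com(lengths, table)
        return cls(
            grip_from_elbow=lengths["forearm"] + coms["hand"],
            forearm_com_from_elbow=coms["forearm"],
            upper_arm_length=lengths["upper_arm"],
            upper_arm_com=coms["upper_arm"],
            torso_length=lengths["torso"],
            torso_com=coms["torso"],
            hand_weight=masses["hand"] * GRAVITY,
            forearm_weight=masses["forearm"] * GRAVITY,
            upper_arm_weight=masses["upper_arm"] * GRAVITY,
            torso_weight=masses["torso"] * GRAVITY,
        )


def _cos_deg(angle_deg: ArrayLike) -> ArrayLike:
    return np.cos(np.radians(np.asarray(angle_deg, dtype=float)))


def elbow_load(posture: PostureSpec, hand: HandLoad, body: ResolvedBody) -> JointLoad:
    """Reaction at one elbow: gravity of hand segment, half the hand load,
    and the forearm, balanced about the elbow."""
    grip_weight = np.asarray(hand.mass, dtype=float) / 2.0 * GRAVITY + body.hand_weight
    cos_e = _cos_deg(posture.elbow_deg)
    moment = (
        grip_weight * body.grip_from_elbow * cos_e
        + body.forearm_weight * body.forearm_com_from_elbow * cos_e
    )
    return JointLoad(fx=0.0 * cos_e, fy=grip_weight + body.forearm_weight, moment=moment)


def shoulder_load(
    elbow: JointLoad, posture: PostureSpec, body: ResolvedBody
) -> JointLoad:
    """Propagate the elbow reaction across the upper-arm link (one side)."""
    dx = body.upper_arm_length * _cos_deg(posture.shoulder_deg)
    com_dx = body.upper_arm_com * _cos_deg(posture.shoulder_deg)
    moment = elbow.moment + elbow.fy * dx + body.upper_arm_weight * com_dx
    return JointLoad(
        fx=elbow.fx, fy=elbow.fy + body.upper_arm_weight, moment=moment
    )


def l5s1_load(
    shoulder: JointLoad, posture: PostureSpec, body: ResolvedBody
) -> JointLoad:
    """Propagate both arms (doubled) plus the torso-link gravity load
    across the torso to L5/S1."""
    dx = body.torso_length * _cos_deg(posture.torso_deg)
    com_dx = body.torso_com * _cos_deg(posture.torso_deg)
    moment = 2.0 * shoulder.moment + 2.0 * shoulder.fy * dx + body.torso_weight * com_dx
    return JointLoad(
        fx=2.0 * shoulder.fx,
        fy=2.0 * shoulder.fy + body.torso_weight,
        moment=moment,
    )


def included_knee_angle(knee_deg: ArrayLike, ankle_deg: ArrayLike) -> ArrayLike:
    """Interior angle K (deg) between thigh and shank at the knee.

    The shank points ankle -> knee at ``ankle_deg`` and the thigh points
    knee -> hip at ``knee_deg``; the interior angle between the thigh and
    the reversed shank is ``180 - (knee_deg - ankle_deg)``.
    """
    return 180.0 - (np.asarray(knee_deg, dtype=float) - np.asarray(ankle_deg, dtype=float))


def disc_angle(
    posture: PostureSpec,
    coeffs: DiscRegression = DEFAULT_DISC_REGRESSION,
    moment_arm: float = DEFAULT_MOMENT_ARM,
) -> DiscGeometry:
    """Disc orientation from posture via the beta regression.

    T = 90 - torso_deg converts the torso angle to a from-vertical measure;
    K is the included knee angle.  ``disc_angle = 40 + beta(T, K)``.
    """
    t = 90.0 - np.asarray(posture.torso_deg, dtype=float)
    k = included_knee_angle(posture.knee_deg, posture.ankle_deg)
    beta = coeffs.beta(t, k)
    return DiscGeometry(
        T=t if np.ndim(t) else float(t),
        K=k if np.ndim(k) else float(k),
        beta=beta,
        disc_angle=DISC_BASE_ANGLE_DEG + np.asarray(beta, dtype=float)
        if np.ndim(beta)
        else DISC_BASE_ANGLE_DEG + beta,
        erector_moment_arm=moment_arm,
    )


def erector_force(l5s1: JointLoad, moment_arm: float = DEFAULT_MOMENT_ARM) -> ArrayLike:
    """Single-equivalent extensor force (N) balancing the net L5/S1 moment."""
    if not moment_arm > 0:
        raise ConfigurationError("erector moment arm must be > 0")
    return np.abs(l5s1.moment) / moment_arm


def compression_shear(
    l5s1: JointLoad, erector: ArrayLike, disc: DiscGeometry
) -> Tuple[ArrayLike, ArrayLike]:
    """Resolve the L5/S1 load into disc compression and shear (N).

    The force transmitted onto the disc is the negative of the stored
    reaction, ``(-fx, -fy)``.  Rotating it into the disc frame at
    ``disc_angle`` gives a normal (compressive) component ``fy*cos - fx*sin``
    and an anterior tangential component ``fy*sin + fx*cos``.  The erector
    spinae acts perpendicular to the disc, so it adds to compression only.
    """
    a = np.radians(np.asarray(disc.disc_angle, dtype=float))
    normal = np.asarray(l5s1.fy, dtype=float) * np.cos(a) - np.asarray(
        l5s1.fx, dtype=float
    ) * np.sin(a)
    shear = np.asarray(l5s1.fy, dtype=float) * np.sin(a) + np.asarray(
        l5s1.fx, dtype=float
    ) * np.cos(a)
    compression = np.asarray(erector, dtype=float) + normal
    if np.ndim(compression) == 0:
        return float(compression), float(shear)
    return compression, shear


def evaluate(
    posture: PostureSpec,
    hand: HandLoad,
    subject: Subject,
    table: SegmentParameterTable | None = None,
    moment_arm: float = DEFAULT_MOMENT_ARM,
    coeffs: DiscRegression = DEFAULT_DISC_REGRESSION,
) -> LinkageResult:
    """Run the full top-down chain for one posture/load (scalars or arrays)."""
    body = ResolvedBody.resolve(subject, table)
    elbow = elbow_load(posture, hand, body)
    shoulder = shoulder_load(elbow, posture, body)
    l5s1 = l5s1_load(shoulder, posture, body)
    disc = disc_angle(posture, coeffs, moment_arm)
    erector = erector_force(l5s1, moment_arm)
    compression, shear = compression_shear(l5s1, erector, disc)
    return LinkageResult(
        elbow=elbow,
        shoulder=shoulder,
        l5s1=l5s1,
        erector_force=erector,
        disc=disc,
        compression=compression,
        shear=shear,
    )
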