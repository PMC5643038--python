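"""Body-segment anthropometry scaled from stature and total body mass.

Segment link lengths are expressed as fractions of stature, segment masses as
fractions of total body mass, and each segment's centre of mass (COM) as a
fraction of the segment length measured from the proximal joint.  This is the
classical stature-proportion / cadaver-fraction approach used throughout
occupational biomechanics.

The default table is a *reconstruction*: the stature proportions follow the
Drillis–Contini tradition and the mass fractions the Dempster cadaver data,
but four entries (the grip-centre location within the hand, the upper-arm
link length, and the mass and COM of the torso link above L5/S1) were
calibrated once so that the deterministic lifting pipeline reproduces the
published verification moments and disc forces for the carbon-lifting task,
and then frozen.  Every constant can be overridden through the scenario
configuration.

Conventions
-----------
* Bilateral symmetry: limb segments (hand, forearm, upper arm, thigh, shank,
  foot) are listed once and flagged ``bilateral``; the model computes one
  side and doubles it.  The hand load is split equally between the hands.
* The ``torso`` segment is the link from L5/S1 to the shoulder and its mass
  fraction includes everything carried above L5/S1 (head, neck, arms are
  separate).  The ``pelvis`` entry closes the whole-body mass budget; it
  plays no kinetic role in the top-down model.
* The hand segment's ``com_fraction_from_proximal`` locates the grip centre
  (where the hand weight and the external load act), not the anatomical
  hand COM.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Mapping

import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "Subject",
    "SegmentParameters",
    "SegmentParameterTable",
    "segment_lengths",
    "segment_masses",
    "segment_com",
]

#: Tolerance on whole-body mass-fraction closure.
MASS_CLOSURE_TOL = 0.02


@dataclass(frozen=True)
class Subject:
    """A modelled person: stature in metres, body mass in kilograms."""

    stature: float
    body_mass: float

    def __post_init__(self) -> None:
        if not self.stature > 0:
            raise ConfigurationError(f"stature must be > 0, got {self.stature}")
        if not self.body_mass > 0:
            raise ConfigurationError(f"body_mass must be > 0, got {self.body_mass}")


@dataclass(frozen=True)
class SegmentParameters:
    """Proportions for one body segment.

    length_fraction_of_stature : segment link length / stature
    mass_fraction_of_body_mass : segment mass / total body mass (per side for
        bilateral segments)
    com_fraction_from_proximal : COM position along the link from the
        proximal joint, as a fraction of link length
    bilateral : True if the segment exists on both sides and is doubled
    """

    length_fraction_of_stature: float
    mass_fraction_of_body_mass: float
    com_fraction_from_proximal: float
    bilateral: bool = False

    def __post_init__(self) -> None:
        for name in (
            "length_fraction_of_stature",
            "mass_fraction_of_body_mass",
            "com_fraction_from_proximal",
        ):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ConfigurationError(
                    f"{name} must lie strictly in (0, 1), got {value}"
                )


# Calibrated constants (frozen; see module docstring and docs/methods.md).
_HAND_GRIP_COM = 0.30973079251641655
_UPPER_ARM_LENGTH_FRACTION = 0.1852148235019254
_TORSO_MASS_FRACTION = 0.37612470562333633
_TORSO_COM_FRACTION = 0.6542251228574952
_PELVIS_MASS_FRACTION = 0.20187529437666363

_DEFAULT_ROWS: Dict[str, SegmentParameters] = {
    "hand": SegmentParameters(0.108, 0.006, _HAND_GRIP_COM, bilateral=True),
    "forearm": SegmentParameters(0.146, 0.016, 0.430, bilateral=True),
    "upper_arm": SegmentParameters(
        _UPPER_ARM_LENGTH_FRACTION, 0.028, 0.436, bilateral=True
    ),
    "torso": SegmentParameters(0.249, _TORSO_MASS_FRACTION, _TORSO_COM_FRACTION),
    "pelvis": SegmentParameters(0.078, _PELVIS_MASS_FRACTION, 0.5),
    "thigh": SegmentParameters(0.245, 0.100, 0.433, bilateral=True),
    "shank": SegmentParameters(0.246, 0.0465, 0.433, bilateral=True),
    "foot": SegmentParameters(0.152, 0.0145, 0.429, bilateral=True),
}

_FIELD_NAMES = (
    "length_fraction_of_stature",
    "mass_fraction_of_body_mass",
    "com_fraction_from_proximal",
)


@dataclass(frozen=True)
class SegmentParameterTable:
    """Immutable per-segment proportion table with whole-body mass closure."""

    segments: Mapping[str, SegmentParameters]

    def __post_init__(self) -> None:
        total = sum(
            p.mass_fraction_of_body_mass * (2 if p.bilateral else 1)
            for p in self.segments.values()
        )
        if abs(total - 1.0) > MASS_CLOSURE_TOL:
            raise ConfigurationError(
                "segment mass fractions (bilateral segments doubled) must sum "
                f"to 1 +/- {MASS_CLOSURE_TOL}; got {total:.4f}"
            )

    @classmethod
    def default(cls) -> "SegmentParameterTable":
        return cls(dict(_DEFAULT_ROWS))

    @classmethod
    def with_overrides(
        cls, overrides: Mapping[str, Mapping[str, float]]
    ) -> "SegmentParameterTable":
        """Default table with per-segment field overrides from config.

        Unknown segment or field names raise :class:`ConfigurationError`.
        """
        rows = dict(_DEFAULT_ROWS)
        for name, fields in overrides.items():
            if name not in rows:
                raise ConfigurationError(f"unknown segment name: {name!r}")
            current = rows[name]
            values = {f: getattr(current, f) for f in _FIELD_NAMES}
            for field, value in fields.items():
                if field not in _FIELD_NAMES:
                    raise ConfigurationError(
                        f"unknown segment parameter {field!r} for segment {name!r}"
                    )
                values[field] = float(value)
            rows[name] = SegmentParameters(bilateral=current.bilateral, **values)
        return cls(rows)

    def __getitem__(self, name: str) -> SegmentParameters:
        try:
            return self.segments[name]
        except KeyError:
            raise ConfigurationError(f"unknown segment name: {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Resolved table as a DataFrame (one row per segment)."""
        records = []
        for name, p in self.segments.items():
            records.append(
                {
                    "segment": name,
                    **{f: getattr(p, f) for f in _FIELD_NAMES},
                    "bilateral": p.bilateral,
                }
            )
        return pd.DataFrame.from_records(records)

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        return buf.getvalue()

    def to_mapping(self) -> Dict[str, Dict[str, float]]:
        """Plain-dict form suitable for round-tripping through config files."""
        return {
            name: {f: getattr(p, f) for f in _FIELD_NAMES}
            for name, p in self.segments.items()
        }


def segment_lengths(
    subject: Subject, table: SegmentParameterTable
) -> Dict[str, float]:
    """Segment link lengths in metres: ``stature * length_fraction``."""
    return {
        name: subject.stature * p.length_fraction_of_stature
        for name, p in table.segments.items()
    }


def segment_masses(subject: Subject, table: SegmentParameterTable) -> Dict[str, float]:
    """Segment masses in kilograms, per side for bilateral segments."""
    return {
        name: subject.body_mass * p.mass_fraction_of_body_mass
        for name, p in table.segments.items()
    }


def segment_com(
    lengths: Mapping[str, float], table: SegmentParameterTable
) -> Dict[str, float]:
    """COM distance (m) from the proximal joint for each segment."""
    out = {}
    for name, length in lengths.items():
        if length <= 0:
            raise ConfigurationError(f"segment {name!r} has non-positive length")
        out[name] = length * table[name].com_fraction_from_proximal
    return out
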