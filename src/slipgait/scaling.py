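"""Dimensional analysis for the walking model.

All model quantities are dimensionless (Hof convention): lengths are
expressed in units of the model leg length ``l0``, masses in units of the
body mass ``m0`` and accelerations in units of gravity ``g``.  Derived
references follow: time ``sqrt(l0/g)``, speed ``sqrt(l0*g)``, force
``m0*g`` and stiffness ``m0*g/l0``.

The model leg length is obtained from body height through the
leg-to-body ratio ``Alh = h0/l0`` (1.78 for women, 1.70 for men), so a
subject is fully described by gait speed, body height, body mass and sex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

#: Leg-to-body ratio (body height / model leg length) by sex.
LEG_TO_BODY_RATIO = {"female": 1.78, "male": 1.70}

#: Standard gravity used for all dimensionalization, m/s^2.
STANDARD_GRAVITY = 9.81

#: Column names of the subject table dialect.
SUBJECT_COLUMNS = ["subject_id", "mass_kg", "height_m", "sex", "gait_speed_mps"]


class UnknownSexError(ValueError):
    """Raised for a sex label without a leg-to-body ratio (no silent default)."""


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometric descriptors of one walking subject.

    Parameters
    ----------
    body_mass : float
        Body mass ``m0`` in kg.
    body_height : float
        Body height ``h0`` in m.
    sex : str
        ``"female"`` or ``"male"``; selects the leg-to-body ratio.
    gait_speed : float
        Average gait speed ``vG`` in m/s.
    """

    body_mass: float
    body_height: float
    sex: str
    gait_speed: float

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError(f"body_mass must be positive, got {self.body_mass}")
        if self.body_height <= 0:
            raise ValueError(f"body_height must be positive, got {self.body_height}")
        if self.gait_speed <= 0:
            raise ValueError(f"gait_speed must be positive, got {self.gait_speed}")
        if self.sex not in LEG_TO_BODY_RATIO:
            raise UnknownSexError(
                f"unknown sex label {self.sex!r}; expected one of "
                f"{sorted(LEG_TO_BODY_RATIO)}"
            )

    @property
    def leg_length(self) -> float:
        """Model leg length ``l0 = h0 / Alh`` in m."""
        return leg_length_from_height(self.body_height, self.sex)


def leg_length_from_height(height: float, sex: str) -> float:
    """Model leg length from body height via the leg-to-body ratio.

    ``l0 = h0 / Alh`` with ``Alh`` 1.78 for women and 1.70 for men.
    """
    if height <= 0:
        raise ValueError(f"height must be positive, got {height}")
    try:
        ratio = LEG_TO_BODY_RATIO[sex]
    except KeyError:
        raise UnknownSexError(
            f"unknown sex label {sex!r}; expected one of {sorted(LEG_TO_BODY_RATIO)}"
        ) from None
    return height / ratio


@dataclass(frozen=True)
class ReferenceDimensions:
    """Reference values turning dimensionless model quantities physical.

    Each normalized quantity times its reference recovers the physical
    quantity exactly; :func:`normalize` and :func:`dimensionalize` are
    exact inverses.
    """

    leg_length: float
    body_mass: float
    gravity: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        for name in ("leg_length", "body_mass", "gravity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def for_subject(cls, subject: SubjectProfile,
                    gravity: float = STANDARD_GRAVITY) -> "ReferenceDimensions":
        return cls(leg_length=subject.leg_length, body_mass=subject.body_mass,
                   gravity=gravity)

    @property
    def time(self) -> float:
        """Time reference ``sqrt(l0/g)`` in s."""
        return math.sqrt(self.leg_length / self.gravity)

    @property
    def speed(self) -> float:
        """Speed reference ``sqrt(l0*g)`` in m/s."""
        return math.sqrt(self.leg_length * self.gravity)

    @property
    def force(self) -> float:
        """Force reference ``m0*g`` (body weight) in N."""
        return self.body_mass * self.gravity

    @property
    def stiffness(self) -> float:
        """Stiffness reference ``m0*g/l0`` in N/m."""
        return self.body_mass * self.gravity / self.leg_length

    def reference(self, kind: str) -> float:
        """Reference value for a quantity ``kind``.

        Supported kinds: length, mass, acceleration, time, speed, force,
        stiffness and frequency (the reciprocal of the time reference).
        """
        table = {
            "length": self.leg_length,
            "mass": self.body_mass,
            "acceleration": self.gravity,
            "time": self.time,
            "speed": self.speed,
            "velocity": self.speed,
            "force": self.force,
            "stiffness": self.stiffness,
            "frequency": 1.0 / self.time,
        }
        try:
            return table[kind]
        except KeyError:
            raise ValueError(
                f"unknown quantity kind {kind!r}; expected one of {sorted(table)}"
            ) from None


def normalize(value: float, kind: str, refs: ReferenceDimensions) -> float:
    """Convert a physical quantity to its dimensionless model value."""
    return value / refs.reference(kind)


def dimensionalize(value: float, kind: str, refs: ReferenceDimensions) -> float:
    """Convert a dimensionless model value to the physical quantity.

    Exact inverse of :func:`normalize` for every kind.
    """
    return value * refs.reference(kind)


def normalized_gait_speed(subject: SubjectProfile,
                          gravity: float = STANDARD_GRAVITY) -> float:
    """Dimensionless gait speed ``vG / sqrt(g*l0)`` of a subject."""
    refs = ReferenceDimensions.for_subject(subject, gravity=gravity)
    return normalize(subject.gait_speed, "speed", refs)


# ---------------------------------------------------------------------------
# Subject table I/O


def read_subjects(path) -> pd.DataFrame:
    """Read a subject table CSV (subject_id, mass_kg, height_m, sex, gait_speed_mps)."""
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table {path} is missing columns {missing}")
    return df[SUBJECT_COLUMNS + [c for c in df.columns if c not in SUBJECT_COLUMNS]]


def write_subjects(df: pd.DataFrame, path) -> None:
    """Write a subject table CSV in the standard column order."""
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table is missing columns {missing}")
    df.to_csv(path, index=False)


def subject_from_row(row) -> SubjectProfile:
    """Build a :class:`SubjectProfile` from one subject-table row."""
    return SubjectProfile(
        body_mass=float(row["mass_kg"]),
        body_height=float(row["height_m"]),
        sex=str(row["sex"]),
        gait_speed=float(row["gait_speed_mps"]),
    )
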