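"""Core record types shared across the gaitdf pipeline.

A recording session yields, per animal and hindlimb side, one landmark
trajectory per joint (metatarsus, ankle, knee) plus a set of step
annotations delimiting the strides of interest.  Every step is later
resampled onto a 100-bin percent-of-step-cycle axis; all downstream
statistics (bin-wise group comparison, dissimilarity factor) operate on
those :class:`NormalizedStepCurve` objects.

Conventions
-----------
* Coordinates are in arbitrary units (AU); x increases in the direction
  of travel, y increases upward (vertical displacement).
* Frame indices are 0-based; step annotations are half-open
  ``[start_frame, end_frame)``.
* Group membership is species x sex x condition, abbreviated with the
  standard one-letter codes, e.g. ``CMR`` = control male rat,
  ``LFM`` = lesioned female mouse.
* Condition is tied to recording session: control animals are recorded
  on day 0 (pre-injury), lesioned animals on day 7 post-injury.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_BINS = 100

JOINTS = ("metatarsus", "ankle", "knee")
SIDES = ("left", "right")
SPECIES = ("rat", "mouse")
SEXES = ("M", "F")
CONDITIONS = ("control", "lesioned")
SESSIONS = ("day0", "day7")

SESSION_FOR_CONDITION = {"control": "day0", "lesioned": "day7"}

#: Minimum number of frames in a step: a cubic interpolating spline
#: needs at least 4 support points.
MIN_STEP_FRAMES = 4


class FormatError(ValueError):
    """A trajectory/annotation file violates the tabular format."""


class DegenerateGeometryError(ValueError):
    """A calibration point configuration cannot determine a homography."""


def group_code(species: str, sex: str, condition: str) -> str:
    """Return the compact group label, e.g. ``("rat","M","control") -> "CMR"``."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    return condition[0].upper() + sex + species[0].upper()


def parse_group_code(code: str) -> tuple[str, str, str]:
    """Inverse of :func:`group_code`; returns (species, sex, condition)."""
    if len(code) != 3:
        raise ValueError(f"group code must have 3 characters, got {code!r}")
    cond = {"C": "control", "L": "lesioned"}.get(code[0])
    sex = code[1] if code[1] in SEXES else None
    spec = {"R": "rat", "M": "mouse"}.get(code[2])
    if cond is None or sex is None or spec is None:
        raise ValueError(f"unparseable group code {code!r}")
    return spec, sex, cond


@dataclass(frozen=True)
class StepAnnotation:
    """One step of one (animal, session, side), frames ``[start, end)``."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame < 0:
            raise ValueError(f"start_frame must be >= 0, got {self.start_frame}")
        if self.end_frame - self.start_frame < MIN_STEP_FRAMES:
            raise ValueError(
                f"step [{self.start_frame}, {self.end_frame}) has "
                f"{self.end_frame - self.start_frame} frames; at least "
                f"{MIN_STEP_FRAMES} are required for spline normalization"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class LandmarkTrajectory:
    """Per-frame (x, y) positions of one joint landmark.

    ``frame``, ``x`` and ``y`` are parallel arrays; ``frame`` must be
    strictly increasing (gaps are allowed, e.g. between annotated steps).
    """

    animal_id: str
    session: str
    species: str
    sex: str
    condition: str
    side: str
    joint: str
    fps: float
    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frame) == len(self.x) == len(self.y)):
            raise ValueError("frame, x, y must have equal length")
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if len(self.frame) > 1 and not np.all(np.diff(self.frame) > 0):
            raise ValueError(
                f"frame indices must be strictly increasing "
                f"(trajectory {self.animal_id}/{self.session}/{self.side}/{self.joint})"
            )
        for name, value, allowed in (
            ("session", self.session, SESSIONS),
            ("species", self.species, SPECIES),
            ("sex", self.sex, SEXES),
            ("condition", self.condition, CONDITIONS),
            ("side", self.side, SIDES),
            ("joint", self.joint, JOINTS),
        ):
            if value not in allowed:
                raise ValueError(f"unknown {name} {value!r}")
        if SESSION_FOR_CONDITION[self.condition] != self.session:
            raise ValueError(
                f"session/condition mismatch: {self.session} recorded for "
                f"{self.condition} animal {self.animal_id} (day0 <-> control, "
                f"day7 <-> lesioned)"
            )

    @property
    def group(self) -> str:
        return group_code(self.species, self.sex, self.condition)

    @property
    def n_frames(self) -> int:
        return len(self.frame)


@dataclass
class StepSegment:
    """Raw (t, x, y) samples of one annotated step, t in seconds."""

    animal_id: str
    species: str
    sex: str
    condition: str
    side: str
    joint: str
    step_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def group(self) -> str:
        return group_code(self.species, self.sex, self.condition)


@dataclass
class NormalizedStepCurve:
    """One step resampled to the 100-bin percent-of-step-cycle axis.

    Bin ``i`` (1..100) maps to normalized time ``u = (i - 1) / 99``, so
    bin 1 is the step start and bin 100 the step end.  Amplitudes stay
    in AU (time, not amplitude, is normalized).
    """

    curve_id: str
    animal_id: str
    species: str
    sex: str
    condition: str
    side: str
    joint: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != (N_BINS,) or self.y.shape != (N_BINS,):
            raise ValueError(
                f"curve {self.curve_id}: x and y must each have {N_BINS} bins"
            )
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError(f"curve {self.curve_id}: non-finite bin value")

    @property
    def group(self) -> str:
        return group_code(self.species, self.sex, self.condition)

    @property
    def bins(self) -> np.ndarray:
        return np.arange(1, N_BINS + 1)


@dataclass(frozen=True)
class DFRecord:
    """Dissimilarity factor of one cross-animal curve pair."""

    curve_id_a: str
    curve_id_b: str
    animal_id_a: str
    animal_id_b: str
    group_a: str
    group_b: str
    joint: str
    side: str
    df: float

    @property
    def group(self) -> str:
        """Pair label: the common group, or ``"A|B"`` for cross-group pairs."""
        if self.group_a == self.group_b:
            return self.group_a
        return f"{self.group_a}|{self.group_b}"
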