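"""Domain types, coordinate conventions and serialization for palpation trials.

Coordinate frame: right-handed, millimeters; x-y is the artificial-skin plane
with the origin at the workspace (octagon) center, z is height above the skin.
Timestamps are seconds from trial start; irregular sampling is accepted and
never resampled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTrialError,
    DomainError,
    FormatError,
    MalformedInputError,
)

WORKSPACE_RADIUS_MM = 100.0
TARGET_RING_RADIUS_MM = 50.0

FRAME_CSV_COLUMNS = ("t_s", "ix", "iy", "iz", "mx", "my", "mz")

SKIN_THICKNESSES_MM = (4, 6)
N_LOCATIONS = 8


class VibrationType(str, Enum):
    PULSE = "pulse"
    THRILL = "thrill"


class VibrationIntensity(str, Enum):
    STRONG = "strong"
    WEAK = "weak"


class Finger(str, Enum):
    INDEX = "index"
    MIDDLE = "middle"


@dataclass(frozen=True)
class HapticCondition:
    """One cell of the 2 (type) x 2 (intensity) x 2 (thickness) x 8 (location) factorial."""

    vibration_type: VibrationType
    vibration_intensity: VibrationIntensity
    skin_thickness_mm: int
    location_index: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "vibration_type", VibrationType(self.vibration_type)
        )
        object.__setattr__(
            self, "vibration_intensity", VibrationIntensity(self.vibration_intensity)
        )
        if self.skin_thickness_mm not in SKIN_THICKNESSES_MM:
            raise DomainError(
                f"skin_thickness_mm must be one of {SKIN_THICKNESSES_MM}, "
                f"got {self.skin_thickness_mm!r}"
            )
        if not (
            isinstance(self.location_index, (int, np.integer))
            and 1 <= self.location_index <= N_LOCATIONS
        ):
            raise DomainError(
                f"location_index must be an integer in 1..{N_LOCATIONS}, "
                f"got {self.location_index!r}"
            )
        object.__setattr__(self, "location_index", int(self.location_index))


@dataclass(frozen=True)
class TargetPoint:
    """Target location in the skin plane, mm, origin at the workspace center."""

    x_mm: float
    y_mm: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_mm) and math.isfinite(self.y_mm)):
            raise DomainError("target coordinates must be finite")
        if math.hypot(self.x_mm, self.y_mm) > WORKSPACE_RADIUS_MM + 1e-9:
            raise DomainError(
                f"target ({self.x_mm}, {self.y_mm}) lies outside the "
                f"{WORKSPACE_RADIUS_MM} mm workspace disc"
            )

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm], dtype=float)


@dataclass(frozen=True)
class Frame:
    """One motion-capture sample: time plus both fingertip positions (mm)."""

    t_s: float
    index_tip: tuple[float, float, float]
    middle_tip: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not math.isfinite(self.t_s) or self.t_s < 0:
            raise DomainError(f"t_s must be finite and >= 0, got {self.t_s!r}")
        for name, tip in (("index_tip", self.index_tip), ("middle_tip", self.middle_tip)):
            if len(tip) != 3 or not all(math.isfinite(c) for c in tip):
                raise DomainError(f"{name} must be 3 finite coordinates, got {tip!r}")


@dataclass(frozen=True)
class VelocitySeries:
    """Per-frame 3D fingertip velocities (mm/s), aligned 1:1 with a Trial's frames."""

    finger: Finger
    values: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise DomainError("velocity values must have shape (n, 3)")
        if not np.all(np.isfinite(v)):
            raise MalformedInputError("velocity values must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def speeds(self) -> np.ndarray:
        """3D speed per frame, mm/s."""
        return np.linalg.norm(self.values, axis=1)


@dataclass
class Trial:
    """A single palpation trial: two-fingertip trajectory plus its context.

    Positions are stored as arrays for efficiency; :attr:`frames` materializes
    `Frame` objects on demand.
    """

    trial_id: str
    participant_id: str
    condition: HapticCondition
    target: TargetPoint
    t_s: np.ndarray = field(repr=False)  # (n,)
    index_tip: np.ndarray = field(repr=False)  # (n, 3)
    middle_tip: np.ndarray = field(repr=False)  # (n, 3)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        idx = np.asarray(self.index_tip, dtype=float)
        mid = np.asarray(self.middle_tip, dtype=float)
        if t.ndim != 1:
            raise MalformedInputError("t_s must be one-dimensional")
        n = t.shape[0]
        if n < 2:
            raise DegenerateTrialError(
                f"trial {self.trial_id!r} has {n} frame(s); at least 2 required"
            )
        if idx.shape != (n, 3) or mid.shape != (n, 3):
            raise MalformedInputError("fingertip arrays must have shape (n, 3)")
        if not np.all(np.isfinite(t)) or t[0] < 0:
            raise MalformedInputError("timestamps must be finite and >= 0")
        if not (np.all(np.isfinite(idx)) and np.all(np.isfinite(mid))):
            raise MalformedInputError("fingertip coordinates must be finite")
        dt = np.diff(t)
        if np.any(dt <= 0):
            k = int(np.argmax(dt <= 0))
            raise MalformedInputError(
                f"timestamps must be strictly increasing; violation at row {k + 1} "
                f"(t={t[k]!r} -> t={t[k + 1]!r})"
            )
        self.t_s, self.index_tip, self.middle_tip = t, idx, mid

    @classmethod
    def from_frames(
        cls,
        trial_id: str,
        participant_id: str,
        condition: HapticCondition,
        target: TargetPoint,
        frames: Sequence[Frame],
    ) -> "Trial":
        if len(frames) < 2:
            raise DegenerateTrialError(
                f"trial {trial_id!r} has {len(frames)} frame(s); at least 2 required"
            )
        t = np.array([f.t_s for f in frames], dtype=float)
        idx = np.array([f.index_tip for f in frames], dtype=float)
        mid = np.array([f.middle_tip for f in frames], dtype=float)
        return cls(trial_id, participant_id, condition, target, t, idx, mid)

    @property
    def n_frames(self) -> int:
        return self.t_s.shape[0]

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    @property
    def frames(self) -> tuple[Frame, ...]:
        return tuple(
            Frame(float(t), tuple(i), tuple(m))
            for t, i, m in zip(self.t_s, self.index_tip, self.middle_tip)
        )

    def fingertip(self, finger: Finger | str) -> np.ndarray:
        """Position array (n, 3) for one fingertip."""
        finger = Finger(finger)
        return self.index_tip if finger is Finger.INDEX else self.middle_tip


def target_position(
    location_index: int, ring_radius_mm: float = TARGET_RING_RADIUS_MM
) -> TargetPoint:
    """Fixed target coordinates for a location slot.

    The 8 slots sit evenly spaced on a circle of radius ``ring_radius_mm``
    about the workspace origin; slot 1 is at angle 0 (positive x axis) and
    slots advance counterclockwise in 45-degree steps.  This layout is a
    package convention (the physical rig defines slots by box rotation only).
    """
    if not (
        isinstance(location_index, (int, np.integer))
        and 1 <= location_index <= N_LOCATIONS
    ):
        raise DomainError(
            f"location_index must be an integer in 1..{N_LOCATIONS}, got {location_index!r}"
        )
    theta = 2.0 * math.pi * (int(location_index) - 1) / N_LOCATIONS
    return TargetPoint(ring_radius_mm * math.cos(theta), ring_radius_mm * math.sin(theta))


def _condition_from_mapping(entry: Mapping) -> HapticCondition:
    try:
        return HapticCondition(
            vibration_type=VibrationType(entry["vibration_type"]),
            vibration_intensity=VibrationIntensity(entry["vibration_intensity"]),
            skin_thickness_mm=int(entry["skin_thickness_mm"]),
            location_index=int(entry["location_index"]),
        )
    except KeyError as exc:
        raise FormatError(f"manifest entry missing field {exc.args[0]!r}") from exc


def read_trial(frame_csv_path: str | Path, manifest_entry: Mapping) -> Trial:
    """Load one trial from a frame CSV plus its manifest entry.

    The CSV must carry exactly the header ``t_s,ix,iy,iz,mx,my,mz``.  Rows are
    required to already be in strictly increasing time order; out-of-order or
    duplicate timestamps raise rather than being silently re-sorted.
    """
    frame_csv_path = Path(frame_csv_path)
    try:
        df = pd.read_csv(frame_csv_path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{frame_csv_path}: empty frame CSV") from exc
    if list(df.columns) != list(FRAME_CSV_COLUMNS):
        raise FormatError(
            f"{frame_csv_path}: expected columns {list(FRAME_CSV_COLUMNS)}, "
            f"got {list(df.columns)}"
        )
    if len(df) < 2:
        raise DegenerateTrialError(
            f"{frame_csv_path}: {len(df)} data row(s); at least 2 required"
        )
    condition = _condition_from_mapping(manifest_entry)
    try:
        target = TargetPoint(
            float(manifest_entry["target_x_mm"]), float(manifest_entry["target_y_mm"])
        )
        trial_id = str(manifest_entry["trial_id"])
        participant_id = str(manifest_entry["participant_id"])
    except KeyError as exc:
        raise FormatError(f"manifest entry missing field {exc.args[0]!r}") from exc
    return Trial(
        trial_id=trial_id,
        participant_id=participant_id,
        condition=condition,
        target=target,
        t_s=df["t_s"].to_numpy(float),
        index_tip=df[["ix", "iy", "iz"]].to_numpy(float),
        middle_tip=df[["mx", "my", "mz"]].to_numpy(float),
    )


def write_trial(trial: Trial, frame_csv_path: str | Path) -> None:
    """Write a trial's frames as CSV with full round-trip float precision.

    Output is deterministic: identical trials produce byte-identical files.
    """
    frame_csv_path = Path(frame_csv_path)
    lines = [",".join(FRAME_CSV_COLUMNS)]
    for t, idx, mid in zip(trial.t_s, trial.index_tip, trial.middle_tip):
        # Python float repr is the shortest exact round-trip representation
        vals = (float(t), *map(float, idx), *map(float, mid))
        lines.append(",".join(repr(v) for v in vals))
    frame_csv_path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def manifest_entry(trial: Trial, frame_file: str) -> dict:
    """Manifest record for one trial (see study manifest JSON layout)."""
    c = trial.condition
    return {
        "trial_id": trial.trial_id,
        "participant_id": trial.participant_id,
        "vibration_type": c.vibration_type.value,
        "vibration_intensity": c.vibration_intensity.value,
        "skin_thickness_mm": c.skin_thickness_mm,
        "location_index": c.location_index,
        "target_x_mm": trial.target.x_mm,
        "target_y_mm": trial.target.y_mm,
        "frame_file": frame_file,
    }


def read_manifest(path: str | Path) -> list[dict]:
    """Read a study manifest JSON (array of per-trial records)."""
    path = Path(path)
    try:
        entries = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON manifest: {exc}") from exc
    if not isinstance(entries, list):
        raise FormatError(f"{path}: manifest must be a JSON array")
    return entries


def write_manifest(entries: Iterable[Mapping], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(list(entries), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
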