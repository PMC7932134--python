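"""Per-trial objective skill metrics.

Five metrics are computed from each trial: endpoint accuracy (mm, with a
three-band classification and a within-30-mm binary outcome), task duration
(s), total path length (mm), ratio of correct movement (%) and error rate.

Conventions (all configurable where noted):

* accuracy, error rate and the velocity projection use in-plane (x, y)
  distances — the target depth under the skin is not an estimable quantity;
* total path length and the movement-frame speed test use full 3D motion —
  finger lifting is real traversed path;
* a "movement frame" is one whose 3D fingertip speed is at least
  ``speed_eps_mm_s`` (default 1 mm/s);
* process metrics default to the index fingertip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedDirectionError, UndefinedMetricError
from .trajectory import Finger, TargetPoint, Trial, VelocitySeries

ACCURATE_RADIUS_MM = 10.0
ERROR_RADIUS_MM = 30.0
DEFAULT_SPEED_EPS_MM_S = 1.0

METRIC_COLUMNS = (
    "accuracy_mm",
    "accuracy_band",
    "accurate_binary",
    "duration_s",
    "tpl_mm",
    "rcm_pct",
    "error_rate",
)


class AccuracyBand(str, Enum):
    ACCURATE = "accurate"
    MARGINAL = "marginal"
    ERROR = "error"


class ErrorRateDenominator(str, Enum):
    """Which frames form the error-rate denominator."""

    MOVEMENT = "movement"  # movement frames only (default)
    ALL = "all"  # every recorded frame


@dataclass(frozen=True)
class MetricsConfig:
    """Tunable conventions shared by the frame-ratio metrics."""

    finger: Finger = Finger.INDEX
    speed_eps_mm_s: float = DEFAULT_SPEED_EPS_MM_S
    error_rate_denominator: ErrorRateDenominator = ErrorRateDenominator.MOVEMENT

    def __post_init__(self) -> None:
        object.__setattr__(self, "finger", Finger(self.finger))
        object.__setattr__(
            self,
            "error_rate_denominator",
            ErrorRateDenominator(self.error_rate_denominator),
        )
        if not (self.speed_eps_mm_s > 0):
            raise DomainError("speed_eps_mm_s must be > 0")


@dataclass(frozen=True)
class MetricSet:
    """The five per-trial metrics plus the derived accuracy band/binary.

    ``rcm_pct`` and ``error_rate`` are ``None`` when undefined for the trial
    (no movement frames); they are reported as missing, never coerced to 0.
    """

    accuracy_mm: float
    accuracy_band: AccuracyBand
    accurate_binary: bool
    duration_s: float
    tpl_mm: float
    rcm_pct: Optional[float]
    error_rate: Optional[float]

    def __post_init__(self) -> None:
        if self.accuracy_mm < 0:
            raise DomainError("accuracy_mm must be non-negative")
        if not (self.duration_s > 0):
            raise DomainError("duration_s must be positive")
        if self.tpl_mm < 0:
            raise DomainError("tpl_mm must be non-negative")
        if classify_accuracy(self.accuracy_mm) is not self.accuracy_band:
            raise DomainError("accuracy_band inconsistent with accuracy_mm")
        if self.accurate_binary != (self.accuracy_mm <= ERROR_RADIUS_MM):
            raise DomainError("accurate_binary inconsistent with accuracy_mm")
        if self.rcm_pct is not None and not (0.0 <= self.rcm_pct <= 100.0):
            raise DomainError("rcm_pct must lie in [0, 100]")
        if self.error_rate is not None and not (0.0 <= self.error_rate <= 1.0):
            raise DomainError("error_rate must lie in [0, 1]")


def estimate_velocity(trial: Trial, finger: Finger | str = Finger.INDEX) -> VelocitySeries:
    """Per-frame 3D velocity (mm/s) by finite differences of position.

    Central differences on interior frames (exact for quadratic motion on a
    uniform grid), one-sided at both ends.  Irregular sampling is handled by
    the nonuniform-spacing difference formula.
    """
    finger = Finger(finger)
    pos = trial.fingertip(finger)
    v = np.column_stack([np.gradient(pos[:, k], trial.t_s) for k in range(3)])
    return VelocitySeries(finger=finger, values=v)


def compute_duration(trial: Trial) -> float:
    """Task completion time: last minus first timestamp, seconds."""
    return trial.duration_s


def compute_tpl(trial: Trial, finger: Finger | str = Finger.INDEX) -> float:
    """Total path length: cumulative 3D distance traversed by the fingertip, mm."""
    pos = trial.fingertip(finger)
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def compute_accuracy(trial: Trial) -> float:
    """Endpoint accuracy: in-plane distance from target to the nearer fingertip.

    Uses the fingertip positions at the trial's final frame (the trial end
    stands in for the participant's reported estimate); the lesser of the
    index- and middle-finger distances is returned, in mm.
    """
    txy = trial.target.xy
    d_index = float(np.linalg.norm(trial.index_tip[-1, :2] - txy))
    d_middle = float(np.linalg.norm(trial.middle_tip[-1, :2] - txy))
    return min(d_index, d_middle)


def classify_accuracy(accuracy_mm: float) -> AccuracyBand:
    """Band an accuracy value: <=10 accurate, (10, 30] marginal, >30 error."""
    if accuracy_mm < 0 or not np.isfinite(accuracy_mm):
        raise DomainError(f"accuracy_mm must be finite and >= 0, got {accuracy_mm!r}")
    if accuracy_mm <= ACCURATE_RADIUS_MM:
        return AccuracyBand.ACCURATE
    if accuracy_mm <= ERROR_RADIUS_MM:
        return AccuracyBand.MARGINAL
    return AccuracyBand.ERROR


def project_velocity(
    position_xy: np.ndarray, velocity_xy: np.ndarray, target: TargetPoint
) -> float:
    """Signed speed toward the target: in-plane velocity projected onto the
    shortest-path direction (fingertip -> target).  Positive means approaching.
    """
    position_xy = np.asarray(position_xy, dtype=float)[:2]
    velocity_xy = np.asarray(velocity_xy, dtype=float)[:2]
    to_target = target.xy - position_xy
    dist = np.linalg.norm(to_target)
    if dist == 0.0:
        raise UndefinedDirectionError(
            "fingertip is exactly at the target; projection direction undefined"
        )
    return float(velocity_xy @ (to_target / dist))


def _movement_mask(trial: Trial, finger: Finger, speed_eps_mm_s: float) -> np.ndarray:
    return estimate_velocity(trial, finger).speeds >= speed_eps_mm_s


def _projected_velocities(trial: Trial, finger: Finger) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-frame V_p plus an at-target mask (vectorized twin of
    :func:`project_velocity`)."""
    pos = trial.fingertip(finger)[:, :2]
    vel = estimate_velocity(trial, finger).values[:, :2]
    to_target = trial.target.xy[None, :] - pos
    dist = np.linalg.norm(to_target, axis=1)
    at_target = dist == 0.0
    safe = np.where(at_target, 1.0, dist)
    vp = np.einsum("ij,ij->i", vel, to_target / safe[:, None])
    return vp, at_target


def compute_rcm(
    trial: Trial,
    finger: Finger | str = Finger.INDEX,
    speed_eps_mm_s: float = DEFAULT_SPEED_EPS_MM_S,
) -> float:
    """Ratio of correct movement: % of movement frames heading toward the target.

    A frame counts as "correct" when its projected velocity is strictly
    positive; zero projection counts as not-correct.  Frames sitting exactly
    on the target have no defined direction and are excluded along with
    sub-threshold (stationary) frames.
    """
    finger = Finger(finger)
    vp, at_target = _projected_velocities(trial, finger)
    mask = _movement_mask(trial, finger, speed_eps_mm_s) & ~at_target
    n_move = int(mask.sum())
    if n_move == 0:
        raise UndefinedMetricError(
            f"trial {trial.trial_id!r}: no movement frames; RCM undefined"
        )
    return 100.0 * float((vp[mask] > 0.0).sum()) / n_move


def compute_error_rate(
    trial: Trial,
    finger: Finger | str = Finger.INDEX,
    speed_eps_mm_s: float = DEFAULT_SPEED_EPS_MM_S,
    denominator: ErrorRateDenominator | str = ErrorRateDenominator.MOVEMENT,
) -> float:
    """Fraction of (movement) frames with in-plane distance to target > 30 mm."""
    finger = Finger(finger)
    denominator = ErrorRateDenominator(denominator)
    pos = trial.fingertip(finger)[:, :2]
    dist = np.linalg.norm(pos - trial.target.xy[None, :], axis=1)
    if denominator is ErrorRateDenominator.MOVEMENT:
        mask = _movement_mask(trial, finger, speed_eps_mm_s)
    else:
        mask = np.ones(trial.n_frames, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise UndefinedMetricError(
            f"trial {trial.trial_id!r}: no movement frames; error rate undefined"
        )
    return float((dist[mask] > ERROR_RADIUS_MM).sum()) / n


def compute_metrics(trial: Trial, config: MetricsConfig = MetricsConfig()) -> MetricSet:
    """All five metrics for one trial; undefined frame-ratio metrics become None."""
    accuracy = compute_accuracy(trial)
    try:
        rcm: Optional[float] = compute_rcm(trial, config.finger, config.speed_eps_mm_s)
    except UndefinedMetricError:
        rcm = None
    try:
        err: Optional[float] = compute_error_rate(
            trial, config.finger, config.speed_eps_mm_s, config.error_rate_denominator
        )
    except UndefinedMetricError:
        err = None
    return MetricSet(
        accuracy_mm=accuracy,
        accuracy_band=classify_accuracy(accuracy),
        accurate_binary=accuracy <= ERROR_RADIUS_MM,
        duration_s=compute_duration(trial),
        tpl_mm=compute_tpl(trial, config.finger),
        rcm_pct=rcm,
        error_rate=err,
    )


def metrics_row(trial: Trial, config: MetricsConfig = MetricsConfig()) -> dict:
    """One metrics-CSV row (identifiers + condition + MetricSet fields)."""
    m = compute_metrics(trial, config)
    c = trial.condition
    return {
        "trial_id": trial.trial_id,
        "participant_id": trial.participant_id,
        "vibration_type": c.vibration_type.value,
        "vibration_intensity": c.vibration_intensity.value,
        "skin_thickness_mm": c.skin_thickness_mm,
        "location_index": c.location_index,
        "accuracy_mm": m.accuracy_mm,
        "accuracy_band": m.accuracy_band.value,
        "accurate_binary": m.accurate_binary,
        "duration_s": m.duration_s,
        "tpl_mm": m.tpl_mm,
        "rcm_pct": m.rcm_pct,
        "error_rate": m.error_rate,
    }


def metrics_table(
    trials: Iterable[Trial], config: MetricsConfig = MetricsConfig()
) -> pd.DataFrame:
    """Metric table: one row per trial, columns as in the metrics CSV."""
    return pd.DataFrame([metrics_row(t, config) for t in trials])


def write_metrics_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=False)


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
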