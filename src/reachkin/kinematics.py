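"""Per-trial kinematic parameters from 3-axis wrist displacement.

Twelve parameters are computed per trial: reaction time, movement time,
total distance, average/maximum velocity and time to peak velocity,
average/maximum acceleration and time to peak acceleration, and the RMS
movement-unit counts of Types 1-3 (zero-crossings of velocity, acceleration
and jerk, counted per axis and RMS-consolidated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from reachkin.trajectory_io import Trial

#: canonical feature-column order for tables
FEATURE_NAMES = (
    "reaction_time_s",
    "movement_time_s",
    "total_distance_m",
    "avg_velocity_mps",
    "max_velocity_mps",
    "time_to_peak_velocity_s",
    "avg_acceleration_mps2",
    "max_acceleration_mps2",
    "time_to_peak_acceleration_s",
    "mu_type1_rms",
    "mu_type2_rms",
    "mu_type3_rms",
)


class NoMovementError(RuntimeError):
    """No sample satisfies the onset rule; the trial is effectively motionless."""


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass smoothing applied to positions before differentiation.

    ``kind="none"`` disables smoothing (exact analytic tests);
    ``kind="butterworth"`` applies a zero-phase Butterworth filter.
    """

    kind: str = "butterworth"
    cutoff_hz: float = 10.0
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("butterworth", "none"):
            raise ValueError(f"unknown filter kind {self.kind!r}")


@dataclass(frozen=True)
class KinematicFeatures:
    """The twelve per-trial kinematic parameters."""

    reaction_time_s: float
    movement_time_s: float
    total_distance_m: float
    avg_velocity_mps: float
    max_velocity_mps: float
    time_to_peak_velocity_s: float
    avg_acceleration_mps2: float
    max_acceleration_mps2: float
    time_to_peak_acceleration_s: float
    mu_type1_rms: float
    mu_type2_rms: float
    mu_type3_rms: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def as_array(self) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[k] for k in FEATURE_NAMES])


@dataclass(frozen=True)
class DerivativeStack:
    """Smoothed positions with velocity, acceleration and jerk series.

    All series have the same length as the input trial (central differences
    in the interior, one-sided at the boundaries).
    """

    position: np.ndarray      # (n, 3) smoothed, meters
    velocity: np.ndarray      # (n, 3) m/s
    acceleration: np.ndarray  # (n, 3) m/s^2
    jerk: np.ndarray          # (n, 3) m/s^3
    speed: np.ndarray         # (n,) |velocity|
    smoothing: FilterSpec = field(default_factory=FilterSpec)


def differentiate(trial: Trial, smoothing: FilterSpec | None = None) -> DerivativeStack:
    """Low-pass filter positions, then differentiate by central differences."""
    smoothing = smoothing or FilterSpec()
    pos = trial.displacement
    fs = trial.sampling_rate_hz
    if smoothing.kind == "butterworth":
        sos = signal.butter(smoothing.order, smoothing.cutoff_hz, fs=fs, output="sos")
        # sosfiltfilt needs a minimum signal length for edge padding
        padlen = 3 * (2 * smoothing.order + 1)
        if pos.shape[0] <= padlen:
            raise ValueError(
                f"trial too short ({pos.shape[0]} samples) for zero-phase filtering; "
                'use smoothing FilterSpec(kind="none")'
            )
        pos = signal.sosfiltfilt(sos, pos, axis=0)
    dt = 1.0 / fs
    vel = np.gradient(pos, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    jerk = np.gradient(acc, dt, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    return DerivativeStack(
        position=pos, velocity=vel, acceleration=acc, jerk=jerk, speed=speed,
        smoothing=smoothing,
    )


def detect_onset(
    trial: Trial,
    stack: DerivativeStack,
    threshold_fraction: float = 0.2,
    refine: bool = True,
) -> int:
    """Detect the movement-onset sample index.

    The trigger is the first sample in the search window (go signal to trial
    end) at which both the distance from the go-signal position and the
    acceleration magnitude reach ``threshold_fraction`` of their window
    maxima simultaneously. With ``refine=True`` (default) the trigger is
    traced back to the start of the movement: the last preceding sample at
    which speed was at or below the quiescent floor. The refinement makes
    the returned index the start of the motion rather than the (amplitude-
    dependent) point where the distance criterion is first met.

    Raises :class:`NoMovementError` if no sample satisfies both criteria.
    """
    go = trial.go_signal_index
    d = np.linalg.norm(stack.position[go:] - stack.position[go], axis=1)
    amag = np.linalg.norm(stack.acceleration[go:], axis=1)
    d_max, a_max = d.max(), amag.max()
    if d_max <= 0 or a_max <= 0:
        raise NoMovementError(
            f"trial {trial.subject_id}/{trial.trial_index}: motionless in search window"
        )
    hit = (d >= threshold_fraction * d_max) & (amag >= threshold_fraction * a_max)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        raise NoMovementError(
            f"trial {trial.subject_id}/{trial.trial_index}: onset criteria never met"
        )
    trigger = go + int(idx[0])
    if not refine:
        return trigger

    speed = stack.speed
    floor = 0.005 * speed[go:].max()
    if go > 0:
        # quiescent pre-go segment gives an empirical noise ceiling
        floor = max(floor, float(np.quantile(speed[:go], 0.95)))
    below = np.flatnonzero(speed[go:trigger + 1] <= floor)
    idx = go + int(below[-1]) if below.size else trigger
    # follow the speed ramp down to its local minimum so the returned index
    # marks the start of the rise rather than the floor crossing
    while idx > go and speed[idx - 1] < speed[idx]:
        idx -= 1
    return idx


def _end_of_movement(stack: DerivativeStack, onset: int, end_rule: str) -> int:
    n = len(stack.speed)
    if end_rule == "trial_end":
        return n - 1
    if end_rule == "speed_5pct":
        seg = stack.speed[onset:]
        above = np.flatnonzero(seg > 0.05 * seg.max())
        if above.size == 0:
            return n - 1
        return min(onset + int(above[-1]) + 1, n - 1)
    raise ValueError(f"unknown end rule {end_rule!r}")


def summary_features(
    trial: Trial,
    stack: DerivativeStack,
    onset: int,
    end_rule: str = "trial_end",
) -> dict[str, float]:
    """Window statistics over [onset, movement end].

    Returns reaction/movement time, total distance, average and maximum
    velocity and acceleration (vector magnitudes) and the times to their
    peaks (first occurrence on ties).
    """
    end = _end_of_movement(stack, onset, end_rule)
    if end - onset < 2:
        raise ValueError("movement window shorter than 3 samples")
    fs = trial.sampling_rate_hz
    pos = stack.position[onset:end + 1]
    speed = stack.speed[onset:end + 1]
    amag = np.linalg.norm(stack.acceleration[onset:end + 1], axis=1)
    return {
        "reaction_time_s": (onset - trial.go_signal_index) / fs,
        "movement_time_s": (end - onset) / fs,
        "total_distance_m": float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum()),
        "avg_velocity_mps": float(speed.mean()),
        "max_velocity_mps": float(speed.max()),
        "time_to_peak_velocity_s": float(np.argmax(speed)) / fs,
        "avg_acceleration_mps2": float(amag.mean()),
        "max_acceleration_mps2": float(amag.max()),
        "time_to_peak_acceleration_s": float(np.argmax(amag)) / fs,
    }


def count_zero_crossings(series: np.ndarray, hysteresis_fraction: float = 0.01) -> int:
    """Count sign alternations of a 1-D signal with a hysteresis band.

    A crossing is counted when the signal moves from above +h to below -h or
    vice versa, with h = ``hysteresis_fraction`` * RMS(series). Samples inside
    [-h, +h] do not change state; exact zeros resolve to the next signed
    sample. With h = 0 this reduces to a literal sign-alternation count.
    """
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    h = hysteresis_fraction * float(np.sqrt(np.mean(series**2))) if series.size else 0.0
    state = 0
    count = 0
    for v in series:
        if v > h:
            if state == -1:
                count += 1
            state = 1
        elif v < -h:
            if state == 1:
                count += 1
            state = -1
    return count


def movement_units(
    stack: DerivativeStack,
    onset: int,
    end: int,
    hysteresis_fraction: float = 0.01,
) -> tuple[float, float, float]:
    """RMS movement-unit counts of Types 1-3 over the window [onset, end].

    For each derivative order (velocity, acceleration, jerk) zero-crossings
    are counted independently on the x, y and z component series and
    consolidated as sqrt((nx^2 + ny^2 + nz^2) / 3).
    """
    out = []
    for series in (stack.velocity, stack.acceleration, stack.jerk):
        counts = [
            count_zero_crossings(series[onset:end + 1, ax], hysteresis_fraction)
            for ax in range(3)
        ]
        out.append(math.sqrt(sum(c * c for c in counts) / 3.0))
    return tuple(out)


@dataclass(frozen=True)
class ExtractionOptions:
    smoothing: FilterSpec = field(default_factory=FilterSpec)
    threshold_fraction: float = 0.2
    hysteresis_fraction: float = 0.01
    end_rule: str = "trial_end"
    refine_onset: bool = True
    common_frame: bool = False


def extract_features(trial: Trial, options: ExtractionOptions | None = None) -> KinematicFeatures:
    """Compute all twelve kinematic parameters for one trial."""
    options = options or ExtractionOptions()
    if options.common_frame:
        from reachkin.trajectory_io import to_common_frame

        trial = to_common_frame(trial)
    stack = differentiate(trial, options.smoothing)
    onset = detect_onset(trial, stack, options.threshold_fraction, refine=options.refine_onset)
    summary = summary_features(trial, stack, onset, options.end_rule)
    end = _end_of_movement(stack, onset, options.end_rule)
    mu1, mu2, mu3 = movement_units(stack, onset, end, options.hysteresis_fraction)
    return KinematicFeatures(
        **summary, mu_type1_rms=mu1, mu_type2_rms=mu2, mu_type3_rms=mu3
    )


def extract_feature_table(trial_set, options: ExtractionOptions | None = None):
    """Extract features for every trial; motionless trials are dropped.

    Returns a (features DataFrame, dropped list) pair. The DataFrame carries
    the key columns (subject, group, trial) followed by the twelve parameters
    in canonical order.
    """
    import pandas as pd

    rows = []
    dropped: list[tuple[str, int, str]] = []
    for trial in trial_set:
        try:
            feats = extract_features(trial, options)
        except NoMovementError as exc:
            dropped.append((trial.subject_id, trial.trial_index, str(exc)))
            continue
        rows.append(
            {
                "subject": trial.subject_id,
                "group": trial.group.value,
                "trial": trial.trial_index,
                **feats.as_dict(),
            }
        )
    df = pd.DataFrame(rows, columns=["subject", "group", "trial", *FEATURE_NAMES])
    return df, dropped
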