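"""Trial containers, CSV readers/writers and the common-frame transform.

Trials are stored in long-format CSV (one row per sample), feature tables
in wide-format CSV (one row per trial). All coordinates are held in meters
internally; loaders convert declared millimeters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class Group(str, Enum):
    """Participant group label."""

    ADULT = "ADULT"
    TD = "TD"
    ASD = "ASD"


class SchemaError(ValueError):
    """A required column is missing or misdeclared."""


class MalformedTrialError(ValueError):
    """A trial violates structural invariants (identifies subject/trial)."""


class ValidationError(ValueError):
    """A field value is outside its domain (e.g. unknown group label)."""


#: canonical long-format column names
TRIAL_COLUMNS = ("subject", "group", "trial", "sample_index", "x", "y", "z")


@dataclass(frozen=True)
class Trial:
    """One reach-and-place recording: 3-axis wrist displacement in meters."""

    subject_id: str
    group: Group
    trial_index: int
    displacement: np.ndarray  # shape (n, 3), meters
    sampling_rate_hz: float = 100.0
    go_signal_index: int = 0

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement, dtype=float)
        object.__setattr__(self, "displacement", disp)
        if disp.ndim != 2 or disp.shape[1] != 3:
            raise MalformedTrialError(
                f"trial {self.subject_id}/{self.trial_index}: displacement must be (n, 3), "
                f"got {disp.shape}"
            )
        if disp.shape[0] < 10:
            raise MalformedTrialError(
                f"trial {self.subject_id}/{self.trial_index}: need >= 10 samples, got {disp.shape[0]}"
            )
        if not np.all(np.isfinite(disp)):
            raise MalformedTrialError(
                f"trial {self.subject_id}/{self.trial_index}: non-finite displacement values"
            )
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if self.trial_index < 1:
            raise ValidationError("trial_index must be >= 1")
        if not (0 <= self.go_signal_index < disp.shape[0]):
            raise ValidationError(
                f"go_signal_index {self.go_signal_index} outside [0, {disp.shape[0]})"
            )

    @property
    def n_samples(self) -> int:
        return self.displacement.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


class Provenance(str, Enum):
    SYNTHETIC = "SYNTHETIC"
    FILE = "FILE"


@dataclass
class TrialSet:
    """Ordered collection of trials with unique (subject, trial) keys."""

    trials: list[Trial]
    provenance: Provenance = Provenance.FILE
    seed: int | None = None

    def __post_init__(self) -> None:
        keys = [(t.subject_id, t.trial_index) for t in self.trials]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValidationError(f"duplicate subject/trial key {dup}")
        groups: dict[str, Group] = {}
        for t in self.trials:
            if groups.setdefault(t.subject_id, t.group) != t.group:
                raise ValidationError(
                    f"subject {t.subject_id} carries more than one group label"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def subjects(self) -> dict[str, Group]:
        return {t.subject_id: t.group for t in self.trials}


def _default_schema(schema: Mapping[str, str] | None) -> dict[str, str]:
    mapping = {c: c for c in TRIAL_COLUMNS}
    if schema:
        mapping.update({k: v for k, v in schema.items() if k in mapping})
    return mapping


def read_trials(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    units: str = "m",
    sampling_rate_hz: float = 100.0,
    go_signal: Mapping[tuple[str, int], int] | int | None = None,
) -> TrialSet:
    """Read a long-format trial CSV (or a directory of them) into a TrialSet.

    Parameters
    ----------
    path:
        CSV file with columns subject, group, trial, sample_index, x, y, z
        (renameable through ``schema``), or a directory of such files.
    schema:
        Optional map from canonical column name to the name used in the file.
    units:
        ``"m"`` (default) or ``"mm"``; millimeter coordinates are divided by
        1000 on load.
    go_signal:
        Go-signal sample index, either one integer for all trials or a map
        keyed by (subject_id, trial_index). Defaults to 0.
    """
    path = Path(path)
    if path.is_dir():
        frames = [pd.read_csv(p) for p in sorted(path.glob("*.csv"))]
        if not frames:
            raise FileNotFoundError(f"no CSV files under {path}")
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.read_csv(path)

    colmap = _default_schema(schema)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    if units not in ("m", "mm"):
        raise SchemaError(f"unknown units {units!r}; use 'm' or 'mm'")
    scale = 1.0 if units == "m" else 1e-3

    trials: list[Trial] = []
    for (subj, trial_idx), grp in df.groupby(["subject", "trial"], sort=True):
        subj = str(subj)
        trial_idx = int(trial_idx)
        labels = grp["group"].unique()
        if len(labels) != 1:
            raise ValidationError(f"trial {subj}/{trial_idx}: conflicting group labels")
        try:
            group = Group(str(labels[0]).upper())
        except ValueError:
            raise ValidationError(
                f"trial {subj}/{trial_idx}: unknown group label {labels[0]!r}"
            ) from None
        si = grp["sample_index"].to_numpy()
        if not np.all(np.isfinite(si)) or not np.all(np.diff(si) > 0):
            raise MalformedTrialError(
                f"trial {subj}/{trial_idx}: sample_index must be finite and strictly increasing"
            )
        xyz = grp[["x", "y", "z"]].to_numpy(dtype=float) * scale
        if not np.all(np.isfinite(xyz)):
            raise MalformedTrialError(f"trial {subj}/{trial_idx}: non-finite coordinates")
        if isinstance(go_signal, Mapping):
            go = int(go_signal.get((subj, trial_idx), 0))
        else:
            go = int(go_signal or 0)
        trials.append(
            Trial(
                subject_id=subj,
                group=group,
                trial_index=trial_idx,
                displacement=xyz,
                sampling_rate_hz=sampling_rate_hz,
                go_signal_index=go,
            )
        )
    return TrialSet(trials=trials, provenance=Provenance.FILE)


def write_trials(trial_set: TrialSet, path: str | Path, sidecar: bool = True) -> None:
    """Write a TrialSet as long-format CSV (plus a JSON provenance sidecar)."""
    path = Path(path)
    rows = []
    for t in trial_set:
        n = t.n_samples
        rows.append(
            pd.DataFrame(
                {
                    "subject": np.repeat(t.subject_id, n),
                    "group": np.repeat(t.group.value, n),
                    "trial": np.repeat(t.trial_index, n),
                    "sample_index": np.arange(n),
                    "x": t.displacement[:, 0],
                    "y": t.displacement[:, 1],
                    "z": t.displacement[:, 2],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.9f")
    if sidecar:
        meta = {
            "provenance": trial_set.provenance.value,
            "seed": trial_set.seed,
            "n_trials": len(trial_set),
            "sampling_rate_hz": {t.subject_id: t.sampling_rate_hz for t in trial_set},
            "go_signal_index": {
                f"{t.subject_id}/{t.trial_index}": t.go_signal_index for t in trial_set
            },
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


#: fixed feature-table column order: keys then the twelve parameters
FEATURE_KEY_COLUMNS = ("subject", "group", "trial")


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Write a per-trial feature table to CSV with a fixed column order.

    The table must carry the key columns (subject, group, trial) and the
    twelve kinematic parameters named in :data:`reachkin.kinematics.FEATURE_NAMES`.
    """
    from reachkin.kinematics import FEATURE_NAMES

    if features is None or len(features) == 0:
        raise ValueError("feature table is empty")
    missing = [c for c in (*FEATURE_KEY_COLUMNS, *FEATURE_NAMES) if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table missing column(s): {', '.join(missing)}")
    ordered = features[list(FEATURE_KEY_COLUMNS) + list(FEATURE_NAMES)]
    ordered.to_csv(path, index=False, float_format="%.9f")


def read_features(path: str | Path) -> pd.DataFrame:
    from reachkin.kinematics import FEATURE_NAMES

    df = pd.read_csv(path)
    missing = [c for c in (*FEATURE_KEY_COLUMNS, *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing column(s): {', '.join(missing)}")
    return df


def to_common_frame(trial: Trial) -> Trial:
    """Place a trial in the common reference frame.

    The trajectory is translated so that sample 0 sits at the origin and
    rigidly rotated so that the first principal axis of the centered
    trajectory maps to +X, with sign chosen so the net displacement along it
    is non-negative. All pairwise inter-sample distances are preserved.
    """
    disp = trial.displacement - trial.displacement[0]
    steps = np.linalg.norm(np.diff(disp, axis=0), axis=1)
    if steps.sum() == 0.0:
        warnings.warn(
            f"trial {trial.subject_id}/{trial.trial_index}: degenerate (zero path length); "
            "translated only",
            stacklevel=2,
        )
        return replace(trial, displacement=disp)

    centered = disp - disp.mean(axis=0)
    # principal axes of the trajectory point cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    axes = vt.copy()
    net = disp[-1] - disp[0]
    if axes[0] @ net < 0:
        axes[0] = -axes[0]
    # right-handed frame: recompute the third axis from the first two
    axes[2] = np.cross(axes[0], axes[1])
    rotated = disp @ axes.T
    return replace(trial, displacement=rotated)
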