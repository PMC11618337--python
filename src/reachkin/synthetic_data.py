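"""Synthetic reach-and-place cohorts with known ground truth.

Trials are composed from minimum-jerk segments: a primary reach with a
configurable time-to-peak asymmetry, an out-and-back overshoot excursion,
Poisson-many out-and-back corrective submovements in perturbed directions,
and additive Gaussian positional noise. Ground truth (onset sample,
submovement count, amplitude) is recorded per trial so extraction can be
validated end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from reachkin.trajectory_io import Group, Provenance, Trial, TrialSet


def min_jerk_segment(
    amplitude_m: float,
    duration_s: float,
    direction: np.ndarray,
    sampling_rate_hz: float = 100.0,
    time_to_peak_fraction: float = 0.5,
) -> np.ndarray:
    """Minimum-jerk point-to-point displacement along a direction.

    Position along the (unit) direction follows A*(10 tau^3 - 15 tau^4 + 6 tau^5)
    with tau = t/T, starting and ending at rest. ``time_to_peak_fraction``
    shifts the peak-speed instant by a piecewise-linear time warp of tau that
    preserves the endpoint constraints.

    Returns an (n, 3) array from the origin to amplitude * direction,
    with n = round(duration * fs) + 1.
    """
    if amplitude_m <= 0 or duration_s <= 0:
        raise ValueError("amplitude and duration must be positive")
    n = int(round(duration_s * sampling_rate_hz))
    if n < 5:
        raise ValueError("duration must span at least 5 samples")
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    if not np.isclose(norm, 1.0):
        warnings.warn("direction not unit length; normalizing", stacklevel=2)
        direction = direction / norm
    else:
        direction = direction / norm
    p = float(time_to_peak_fraction)
    if not 0.0 < p < 1.0:
        raise ValueError("time_to_peak_fraction must lie in (0, 1)")
    s = np.linspace(0.0, 1.0, n + 1)
    tau = _warp(s, p)
    profile = amplitude_m * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return profile[:, None] * direction[None, :]


def _warp_coefficient(p: float) -> float:
    # quadratic warp tau = s + a*s*(1-s) with tau(p) = 0.5; |a| < 1 keeps it
    # monotone. A smooth warp (rather than a piecewise-linear one) avoids an
    # acceleration discontinuity at the speed peak that would otherwise ring
    # through the low-pass filter and dominate zero-crossing counts.
    a = (0.5 - p) / (p * (1.0 - p))
    return float(np.clip(a, -0.9, 0.9))


def _warp(s: np.ndarray, p: float) -> np.ndarray:
    a = _warp_coefficient(p)
    return s + a * s * (1.0 - s)


def peak_speed_fraction(time_to_peak_fraction: float) -> float:
    """Fraction of segment duration at which the warped profile's speed
    actually peaks (evaluated on a dense grid); the warp places tau = 0.5 at
    ``time_to_peak_fraction`` but the speed maximum shifts slightly because
    the warp rate varies."""
    s = np.linspace(0.0, 1.0, 20001)
    tau = _warp(s, time_to_peak_fraction)
    a = _warp_coefficient(time_to_peak_fraction)
    dtau = 1.0 + a * (1.0 - 2.0 * s)
    speed = (30 * tau**2 - 60 * tau**3 + 30 * tau**4) * dtau
    return float(s[np.argmax(speed)])


def single_reach_trial(
    amplitude_m: float = 0.3,
    duration_s: float = 1.0,
    reaction_time_s: float = 0.3,
    sampling_rate_hz: float = 100.0,
    direction=(1.0, 0.0, 0.0),
    time_to_peak_fraction: float = 0.5,
    pre_go_s: float = 0.5,
    tail_s: float = 0.0,
    group: Group = Group.TD,
    noise_sd_m: float = 0.0,
    seed: int = 0,
    subject_id: str = "S01",
    trial_index: int = 1,
) -> tuple[Trial, int]:
    """A bare single-reach trial: quiescence, go signal, delay, one
    minimum-jerk reach, optional quiescent tail. Returns (trial, the true
    onset sample). Used as the analytic fixture for extraction tests."""
    fs = sampling_rate_hz
    n_pre = int(round(pre_go_s * fs))
    n_rt = int(round(reaction_time_s * fs))
    reach = min_jerk_segment(amplitude_m, duration_s, np.asarray(direction, float),
                             fs, time_to_peak_fraction)
    parts = [np.zeros((n_pre + n_rt, 3)), reach]
    n_tail = int(round(tail_s * fs))
    if n_tail:
        parts.append(np.tile(reach[-1], (n_tail, 1)))
    disp = np.vstack(parts)
    if noise_sd_m > 0:
        disp = disp + np.random.default_rng(seed).normal(0.0, noise_sd_m, disp.shape)
    trial = Trial(
        subject_id=subject_id, group=group, trial_index=trial_index,
        displacement=disp, sampling_rate_hz=fs, go_signal_index=n_pre,
    )
    return trial, n_pre + n_rt


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one participant group."""

    group: Group
    reaction_time_mean_s: float
    reaction_time_sd_s: float
    movement_time_mean_s: float
    movement_time_sd_s: float
    reach_amplitude_mean_m: float
    reach_amplitude_sd_m: float
    overshoot_fraction_mean: float
    n_corrective_mean: float
    corrective_amp_fraction: float
    time_to_peak_fraction: float
    noise_sd_m: float

    def __post_init__(self) -> None:
        if min(self.reaction_time_mean_s, self.movement_time_mean_s,
               self.reach_amplitude_mean_m) <= 0:
            raise ValueError("time and amplitude means must be positive")
        if min(self.reaction_time_sd_s, self.movement_time_sd_s,
               self.reach_amplitude_sd_m, self.noise_sd_m,
               self.overshoot_fraction_mean, self.n_corrective_mean) < 0:
            raise ValueError("sds, overshoot and corrective means must be non-negative")
        if not 0.0 < self.time_to_peak_fraction < 1.0:
            raise ValueError("time_to_peak_fraction must lie in (0, 1)")


# Calibration targets are effect *directions* between groups (ASD > TD for
# displacement, velocities, accelerations, time-to-peaks and Type-2 units;
# borderline-longer ASD reaction time; adults slower but larger/longer
# movements), not any particular group means.
DEFAULT_PROFILES: dict[Group, GroupProfile] = {
    Group.ADULT: GroupProfile(
        group=Group.ADULT,
        reaction_time_mean_s=0.25, reaction_time_sd_s=0.04,
        movement_time_mean_s=2.60, movement_time_sd_s=0.20,
        reach_amplitude_mean_m=0.42, reach_amplitude_sd_m=0.03,
        overshoot_fraction_mean=0.03,
        n_corrective_mean=0.4, corrective_amp_fraction=0.05,
        time_to_peak_fraction=0.32,
        noise_sd_m=0.0000001,
    ),
    Group.TD: GroupProfile(
        group=Group.TD,
        reaction_time_mean_s=0.36, reaction_time_sd_s=0.05,
        movement_time_mean_s=2.00, movement_time_sd_s=0.18,
        reach_amplitude_mean_m=0.25, reach_amplitude_sd_m=0.02,
        overshoot_fraction_mean=0.06,
        n_corrective_mean=0.8, corrective_amp_fraction=0.06,
        time_to_peak_fraction=0.40,
        noise_sd_m=0.0000001,
    ),
    Group.ASD: GroupProfile(
        group=Group.ASD,
        reaction_time_mean_s=0.41, reaction_time_sd_s=0.07,
        movement_time_mean_s=1.85, movement_time_sd_s=0.22,
        reach_amplitude_mean_m=0.34, reach_amplitude_sd_m=0.03,
        overshoot_fraction_mean=0.16,
        n_corrective_mean=4.5, corrective_amp_fraction=0.25,
        time_to_peak_fraction=0.55,
        noise_sd_m=0.0000001,
    ),
}


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation settings; fixed seed gives byte-identical output."""

    n_subjects: dict[Group, int] = field(
        default_factory=lambda: {Group.ASD: 26, Group.TD: 15, Group.ADULT: 4}
    )
    trials_per_subject: int = 6
    sampling_rate_hz: float = 100.0
    seed: int = 0
    profiles: dict[Group, GroupProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    trial_dropout: float = 0.0  # optional random trial exclusion rate

    def __post_init__(self) -> None:
        for g, n in self.n_subjects.items():
            if not isinstance(g, Group):
                raise ValueError(f"unknown group {g!r}")
            if n < 1:
                raise ValueError(f"need >= 1 subject for group {g.value}")
            if g not in self.profiles:
                raise ValueError(f"no profile for group {g.value}")
        if not 0.0 <= self.trial_dropout < 1.0:
            raise ValueError("trial_dropout must lie in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Per-trial generative truth for validating the extraction stage."""

    onset_sample: int
    go_signal_index: int
    reaction_time_s: float
    movement_time_s: float
    amplitude_m: float
    time_to_peak_fraction: float
    n_corrective: int
    overshoot_path_m: float


_PRE_GO_S = 0.5
_TAIL_S = 0.6


def _add_segment(total: np.ndarray, start: int, seg: np.ndarray) -> None:
    """Accumulate a displacement segment into the trial, holding its final
    offset for the remainder of the series."""
    n = total.shape[0]
    if start >= n:
        return
    stop = min(start + seg.shape[0], n)
    total[start:stop] += seg[: stop - start]
    if stop < n:
        total[stop:] += seg[-1]


def compose_trial(
    profile: GroupProfile,
    rng: np.random.Generator,
    sampling_rate_hz: float = 100.0,
    subject_id: str = "S01",
    trial_index: int = 1,
) -> tuple[Trial, GroundTruth]:
    """Generate a single reach-and-place trial plus its ground truth."""
    fs = sampling_rate_hz
    rt = max(0.08, rng.normal(profile.reaction_time_mean_s, profile.reaction_time_sd_s))
    mt = max(0.40, rng.normal(profile.movement_time_mean_s, profile.movement_time_sd_s))
    amp = max(0.03, rng.normal(profile.reach_amplitude_mean_m, profile.reach_amplitude_sd_m))
    ttp = float(np.clip(rng.normal(profile.time_to_peak_fraction, 0.02), 0.10, 0.90))

    # reach direction: forward with a modest lateral/vertical component
    direction = np.array([1.0, rng.normal(0.0, 0.15), rng.normal(0.0, 0.15)])
    direction /= np.linalg.norm(direction)

    go = int(round(_PRE_GO_S * fs))
    onset = go + int(round(rt * fs))
    n_mt = int(round(mt * fs))

    n_corr = int(rng.poisson(profile.n_corrective_mean))
    n_total = go + int(round(rt * fs)) + n_mt + int(round(_TAIL_S * fs)) + 1
    total = np.zeros((n_total, 3))

    primary = min_jerk_segment(amp, mt, direction, fs, ttp)
    _add_segment(total, onset, primary)

    overshoot_path = 0.0
    if profile.overshoot_fraction_mean > 0:
        ov = max(0.0, rng.normal(profile.overshoot_fraction_mean,
                                 0.3 * profile.overshoot_fraction_mean))
        if ov * amp / 2 >= 0.005:
            half = ov * amp / 2.0
            dur = max(0.25, 0.20 * mt)
            start = onset + int(round(0.85 * n_mt))
            out = min_jerk_segment(half, dur, direction, fs)
            back = min_jerk_segment(half, dur, -direction, fs)
            _add_segment(total, start, out)
            _add_segment(total, start + out.shape[0] - 1, back)
            overshoot_path = 2.0 * half

    for _ in range(n_corr):
        camp = profile.corrective_amp_fraction * amp * rng.uniform(0.5, 1.5)
        if camp / 2 < 0.003:
            camp = 0.006
        cdir = direction + rng.normal(0.0, 0.8, size=3)
        cdir /= np.linalg.norm(cdir)
        # corrections cluster around target contact, where the primary
        # acceleration is small enough for them to register as sign changes
        cdur = rng.uniform(0.20, 0.35)
        cstart = onset + int(round(rng.uniform(0.75, 1.35) * n_mt))
        out = min_jerk_segment(camp / 2, cdur, cdir, fs)
        back = min_jerk_segment(camp / 2, cdur, -cdir, fs)
        _add_segment(total, cstart, out)
        _add_segment(total, cstart + out.shape[0] - 1, back)

    if profile.noise_sd_m > 0:
        total = total + rng.normal(0.0, profile.noise_sd_m, size=total.shape)

    trial = Trial(
        subject_id=subject_id,
        group=profile.group,
        trial_index=trial_index,
        displacement=total,
        sampling_rate_hz=fs,
        go_signal_index=go,
    )
    truth = GroundTruth(
        onset_sample=onset,
        go_signal_index=go,
        reaction_time_s=rt,
        movement_time_s=mt,
        amplitude_m=amp,
        time_to_peak_fraction=peak_speed_fraction(ttp),
        n_corrective=n_corr,
        overshoot_path_m=overshoot_path,
    )
    return trial, truth


def _subject_profile(profile: GroupProfile, rng: np.random.Generator) -> GroupProfile:
    """Draw subject-level parameters (between-subject variance); trial-level
    jitter is then applied by compose_trial with reduced sds."""
    return replace(
        profile,
        reaction_time_mean_s=max(
            0.10, rng.normal(profile.reaction_time_mean_s, profile.reaction_time_sd_s)
        ),
        reaction_time_sd_s=0.4 * profile.reaction_time_sd_s,
        movement_time_mean_s=max(
            0.50, rng.normal(profile.movement_time_mean_s, profile.movement_time_sd_s)
        ),
        movement_time_sd_s=0.4 * profile.movement_time_sd_s,
        reach_amplitude_mean_m=max(
            0.05, rng.normal(profile.reach_amplitude_mean_m, profile.reach_amplitude_sd_m)
        ),
        reach_amplitude_sd_m=0.4 * profile.reach_amplitude_sd_m,
        n_corrective_mean=profile.n_corrective_mean * float(np.exp(rng.normal(0.0, 0.25))),
        time_to_peak_fraction=float(
            np.clip(rng.normal(profile.time_to_peak_fraction, 0.03), 0.10, 0.90)
        ),
    )


GROUP_ORDER = (Group.ADULT, Group.TD, Group.ASD)


def simulate_cohort(config: SimConfig) -> tuple[TrialSet, pd.DataFrame]:
    """Simulate a full cohort; returns (TrialSet, ground-truth table).

    Subject-level generative parameters are drawn once per subject and
    jittered per trial. Output is deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    trials: list[Trial] = []
    truth_rows: list[dict] = []
    for group in GROUP_ORDER:
        if group not in config.n_subjects:
            continue
        profile = config.profiles[group]
        for si in range(config.n_subjects[group]):
            subject_id = f"{group.value}{si + 1:02d}"
            subj_profile = _subject_profile(profile, rng)
            for ti in range(1, config.trials_per_subject + 1):
                trial, truth = compose_trial(
                    subj_profile, rng, config.sampling_rate_hz, subject_id, ti
                )
                if config.trial_dropout > 0 and rng.uniform() < config.trial_dropout:
                    continue
                trials.append(trial)
                truth_rows.append(
                    {
                        "subject": subject_id,
                        "group": group.value,
                        "trial": ti,
                        "subject_movement_time_s": subj_profile.movement_time_mean_s,
                        "subject_amplitude_m": subj_profile.reach_amplitude_mean_m,
                        "subject_reaction_time_s": subj_profile.reaction_time_mean_s,
                        "subject_n_corrective_mean": subj_profile.n_corrective_mean,
                        **{
                            "onset_sample": truth.onset_sample,
                            "go_signal_index": truth.go_signal_index,
                            "reaction_time_s": truth.reaction_time_s,
                            "movement_time_s": truth.movement_time_s,
                            "amplitude_m": truth.amplitude_m,
                            "time_to_peak_fraction": truth.time_to_peak_fraction,
                            "n_corrective": truth.n_corrective,
                            "overshoot_path_m": truth.overshoot_path_m,
                        },
                    }
                )
    trial_set = TrialSet(trials=trials, provenance=Provenance.SYNTHETIC, seed=config.seed)
    return trial_set, pd.DataFrame(truth_rows)


#: default per-subject latent -> score loadings, keyed by (group, covariate).
#: Signs follow the correlation structure the score model is meant to induce:
#: TD scores fall with longer/less smooth movement, ASD scores rise with
#: larger, faster movement.
DEFAULT_SCORE_LOADINGS: dict[tuple[Group, str], dict[str, float]] = {
    (Group.TD, "communication"): {"subject_movement_time_s": -2.0},
    (Group.TD, "daily_living"): {
        "subject_movement_time_s": -6.0,
        "subject_n_corrective_mean": -4.0,
    },
    (Group.TD, "socialization"): {
        "subject_movement_time_s": -5.0,
        "subject_n_corrective_mean": -3.0,
    },
    (Group.ASD, "communication"): {"subject_amplitude_m": 5.0},
    (Group.ASD, "daily_living"): {"subject_amplitude_m": 2.0},
    (Group.ASD, "socialization"): {
        "subject_amplitude_m": 5.0,
        "subject_movement_time_s": 3.0,
    },
}

#: group-level score anchors (standard-score scale)
SCORE_BASES: dict[tuple[Group, str], float] = {
    (Group.TD, "communication"): 103.0,
    (Group.TD, "daily_living"): 101.0,
    (Group.TD, "socialization"): 100.0,
    (Group.ASD, "communication"): 83.0,
    (Group.ASD, "daily_living"): 80.0,
    (Group.ASD, "socialization"): 73.0,
}

COVARIATES = ("communication", "daily_living", "socialization")


def simulate_adaptive_scores(
    ground_truth: pd.DataFrame,
    rng: np.random.Generator,
    loadings: dict[tuple[Group, str], dict[str, float]] | None = None,
    noise_sd: float = 3.0,
) -> pd.DataFrame:
    """Per-subject adaptive-functioning covariates for the child groups.

    Each score is a linear function of the subject's latent generative
    kinematic parameters (z-scored within group) plus Gaussian noise,
    anchored at group-level means. Returns one row per child subject with
    columns subject, group, communication, daily_living, socialization.
    """
    loadings = DEFAULT_SCORE_LOADINGS if loadings is None else loadings
    subj = (
        ground_truth.groupby(["subject", "group"], as_index=False)
        .first()[
            [
                "subject",
                "group",
                "subject_movement_time_s",
                "subject_amplitude_m",
                "subject_reaction_time_s",
                "subject_n_corrective_mean",
            ]
        ]
        .sort_values("subject")
        .reset_index(drop=True)
    )
    subj = subj[subj["group"].isin([Group.TD.value, Group.ASD.value])].reset_index(drop=True)
    out = {"subject": subj["subject"], "group": subj["group"]}
    for cov in COVARIATES:
        vals = np.zeros(len(subj))
        for g in (Group.TD, Group.ASD):
            mask = (subj["group"] == g.value).to_numpy()
            if not mask.any():
                continue
            base = SCORE_BASES.get((g, cov), 90.0)
            score = np.full(mask.sum(), float(base))
            for latent, weight in loadings.get((g, cov), {}).items():
                x = subj.loc[mask, latent].to_numpy(dtype=float)
                sd = x.std()
                z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
                score = score + weight * z
            if noise_sd > 0:
                score = score + rng.normal(0.0, noise_sd, size=score.shape)
            vals[mask] = score
        out[cov] = vals
    return pd.DataFrame(out)
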