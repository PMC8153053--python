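"""Subject- and trial-level quality control.

Outlier detection uses boxplot fences with quartiles estimated by ideal
fourths.  Subjects are dropped when their total 9-point calibration
deviation, or their per-axis gaze-velocity dispersion, is an outlier.
Trials are dropped when they contain only a single fixation, when the
pupil signal is lost in more than half of the picture-window samples, or
when the trial's pupil profile correlates poorly with the grand-average
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import robust_sd, sample_velocities
from .synthetic import CalibrationRecord
from .types import FixationEvent, GazeRecording


def ideal_fourths(values) -> tuple[float, float]:
    """Quartiles by the ideal-fourths (interpolated) estimator.

    With sorted x_(1..n), j = floor(n/4 + 5/12), h = n/4 + 5/12 - j,
    q1 = (1-h) x_(j) + h x_(j+1); q3 symmetrically from the upper end.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("ideal_fourths requires at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    g = n / 4.0 + 5.0 / 12.0
    j = int(np.floor(g))
    h = g - j
    if j < 1:  # n == 2: depth falls below the first order statistic
        j, h = 1, 0.0
    q1 = (1.0 - h) * x[j - 1] + h * x[j]
    q3 = (1.0 - h) * x[n - j] + h * x[n - j - 1]
    return float(q1), float(q3)


@dataclass(frozen=True)
class OutlierRule:
    """Boxplot fences at 1.5 IQR beyond the ideal-fourths quartiles."""

    q1: float
    q3: float
    side: str = "both"  # "lower" | "upper" | "both"

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + 1.5 * self.iqr

    @classmethod
    def from_values(cls, values, side: str = "both") -> "OutlierRule":
        q1, q3 = ideal_fourths(values)
        return cls(q1, q3, side)


def flag_outliers(values, rule: OutlierRule) -> np.ndarray:
    """Boolean mask, True where the rule's fence is violated."""
    x = np.asarray(values, dtype=float)
    lo = x < rule.lower
    hi = x > rule.upper
    if rule.side == "lower":
        return lo
    if rule.side == "upper":
        return hi
    return lo | hi


def calibration_deviation(record: CalibrationRecord) -> float:
    """Total gaze deviation from the expected grid: the sum over the nine
    targets of the Euclidean distance between the per-target median gaze
    position and the target (median is robust to blink samples)."""
    total = 0.0
    for i, (tx, ty) in enumerate(record.targets_px):
        g = record.gaze[record.gaze["target_idx"] == i]
        if g.empty:
            raise ValueError(f"calibration record has no samples for target {i}")
        mx = float(g["x_px"].median())
        my = float(g["y_px"].median())
        total += float(np.hypot(mx - tx, my - ty))
    return total


def velocity_summary(recording: GazeRecording) -> tuple[float, float]:
    """Per-axis dispersion (robust SD, deg/s) of sample-to-sample velocity,
    summarising the subject's eye-movement velocity distribution."""
    geom = recording.geometry
    x_deg, y_deg = geom.px_to_deg(
        recording.samples["x_px"].to_numpy(float),
        recording.samples["y_px"].to_numpy(float),
    )
    vx, vy = sample_velocities(np.asarray(x_deg), np.asarray(y_deg), recording.dt_ms / 1000.0)
    valid = recording.samples["aspect_ratio"].to_numpy(float) >= 0.5
    return robust_sd(vx[valid]), robust_sd(vy[valid])


def screen_subjects(
    calibrations: dict[str, CalibrationRecord | None],
    velocity_summaries: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Per-subject keep/drop decisions with reasons.

    Drop when the total calibration deviation is an upper outlier, or when
    the velocity dispersion is an outlier on the x- and/or the y-axis.
    """
    subjects = sorted(velocity_summaries)
    devs = {}
    reasons: dict[str, list[str]] = {s: [] for s in subjects}
    for s in subjects:
        rec = calibrations.get(s)
        if rec is None:
            reasons[s].append("missing_calibration")
        else:
            devs[s] = calibration_deviation(rec)
    if len(devs) >= 2:
        rule = OutlierRule.from_values(list(devs.values()), side="upper")
        for s, d in devs.items():
            if flag_outliers([d], rule)[0]:
                reasons[s].append("calibration_outlier")
    vx = [velocity_summaries[s][0] for s in subjects]
    vy = [velocity_summaries[s][1] for s in subjects]
    if len(subjects) >= 2:
        rx = OutlierRule.from_values(vx)
        ry = OutlierRule.from_values(vy)
        mx = flag_outliers(vx, rx)
        my = flag_outliers(vy, ry)
        for s, fx, fy in zip(subjects, mx, my):
            if fx or fy:
                reasons[s].append("velocity_outlier")
    return pd.DataFrame(
        {
            "subject_id": subjects,
            "keep": [not reasons[s] for s in subjects],
            "reasons": [",".join(reasons[s]) for s in subjects],
            "calibration_deviation_px": [devs.get(s, np.nan) for s in subjects],
            "velocity_sd_x": vx,
            "velocity_sd_y": vy,
        }
    )


@dataclass
class TrialValidity:
    trial_id: int
    reasons: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.reasons


def grand_pupil_profile(
    recordings: list[GazeRecording], n_points: int = 50
) -> np.ndarray:
    """Grand-average trial-locked pupil (aspect-ratio) profile.

    Averages the per-trial aspect-ratio trace, resampled to ``n_points``,
    over all trials of all subjects that do not suffer signal loss.
    """
    traces = []
    for rec in recordings:
        for tid in rec.trial_ids():
            tr = rec.trial_samples(tid)
            ar = tr["aspect_ratio"].to_numpy(float)
            if len(ar) < 2 or np.mean(ar < 0.5) > 0.5:
                continue
            xi = np.linspace(0, len(ar) - 1, n_points)
            traces.append(np.interp(xi, np.arange(len(ar)), ar))
    if not traces:
        raise ValueError("no valid-signal trials to build a grand pupil profile")
    return np.mean(traces, axis=0)


def _profile_correlations(
    recording: GazeRecording, profile: np.ndarray
) -> dict[int, float]:
    out = {}
    n_points = len(profile)
    for tid in recording.trial_ids():
        ar = recording.trial_samples(tid)["aspect_ratio"].to_numpy(float)
        if len(ar) < 2:
            out[tid] = np.nan
            continue
        xi = np.linspace(0, len(ar) - 1, n_points)
        trace = np.interp(xi, np.arange(len(ar)), ar)
        if np.std(trace) == 0 or np.std(profile) == 0:
            out[tid] = np.nan
        else:
            out[tid] = float(np.corrcoef(trace, profile)[0, 1])
    return out


def screen_trials(
    fixations: list[FixationEvent],
    recording: GazeRecording,
    grand_profile: np.ndarray | None = None,
    profile_rule: OutlierRule | None = None,
) -> list[TrialValidity]:
    """Trial validity per the three exclusion rules.

    * ``single_fixation`` — exactly one (or zero) fixation in the trial.
    * ``signal_loss`` — aspect ratio < 0.5 in over 50% of the window.
    * ``pupil_profile_distortion`` — trial pupil profile is a lower
      boxplot outlier in Fisher-z correlation with the grand average
      (``profile_rule`` may supply fences frozen on a reference cohort;
      otherwise they are computed from this recording's trials).
    """
    n_fix = {}
    for e in fixations:
        n_fix[e.trial_id] = n_fix.get(e.trial_id, 0) + 1

    corr = (
        _profile_correlations(recording, grand_profile)
        if grand_profile is not None
        else {}
    )
    rule = profile_rule
    if grand_profile is not None and rule is None:
        z = [np.arctanh(np.clip(r, -0.999999, 0.999999)) for r in corr.values() if np.isfinite(r)]
        rule = OutlierRule.from_values(z, side="lower") if len(z) >= 2 else None

    out = []
    for tid in recording.trial_ids():
        tv = TrialValidity(int(tid))
        tr = recording.trial_samples(tid)
        if len(tr) == 0:
            tv.reasons.append("signal_loss")
            out.append(tv)
            continue
        if n_fix.get(tid, 0) <= 1:
            tv.reasons.append("single_fixation")
        ar = tr["aspect_ratio"].to_numpy(float)
        if np.mean(ar < 0.5) > 0.5:
            tv.reasons.append("signal_loss")
        if rule is not None and tid in corr and np.isfinite(corr[tid]):
            z = np.arctanh(np.clip(corr[tid], -0.999999, 0.999999))
            if flag_outliers([z], rule)[0]:
                tv.reasons.append("pupil_profile_distortion")
        out.append(tv)
    return out


def validity_frame(validities: list[TrialValidity], subject_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "trial_id": [v.trial_id for v in validities],
            "valid": [v.valid for v in validities],
            "reasons": [",".join(v.reasons) for v in validities],
        }
    )
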