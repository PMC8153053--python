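"""Synthetic gaze, calibration, AOI-layout and recall-outcome generation.

The generator emulates the signal structure the analysis pipeline assumes:
trials of 2.5 s in which gaze alternates between fixation plateaus
(Gaussian jitter around a target point) and short saccadic ramps traversed
at a fixed peak velocity, with optional blink gaps (pupil aspect-ratio
drops; position held at the last valid sample), and a slow random-walk
drift shared across a subject's session.  Every injected event is recorded
in a :class:`GroundTruth` object so downstream detectors can be scored
against the truth.

Randomness is organised as one top-level seed with per-subject substreams
(``default_rng([seed, subject_index])``), so adding subjects never changes
the data of existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GOGGLES_EXP1, ScreenGeometry
from .types import AOI, AOISet, GazeRecording

VALENCES = ("negative", "neutral", "positive", "scrambled")

# Recall-model intercept and guided-viewing condition effects on the
# log-odds scale, sized so that expected free-recall counts out of 18
# pictures per condition are ~3.25 / 4.19 / 4.97.
DEFAULT_RECALL_INTERCEPT = -1.1926
DEFAULT_CONDITION_EFFECTS = {
    "area_of_no_interest": -0.3199,
    "guided_fixation": 0.0,
    "guided_fixation_x2": 0.2288,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic gaze cohort.

    Defaults describe the scanner-based free-viewing setup: 60 Hz
    monocular sampling on an 800x600 goggle display, 2.5 s picture
    exposure, ~5.3 fixations per trial, blinks in ~26% of trials.
    """

    sampling_rate_hz: float = 60.0
    screen_px: tuple[int, int] = (800, 600)
    geometry: ScreenGeometry = field(default_factory=lambda: GOGGLES_EXP1)
    trial_ms: float = 2500.0
    n_subjects: int = 20
    n_pictures: int = 96
    fixation_rate_mean: float = 5.3
    fixation_rate_sd: float = 1.0
    # shortest injected fixation: must exceed the 100 ms discard threshold
    # plus the 4-sample support of the 5-point velocity kernel (66.7 ms at
    # 60 Hz), so that noise-free recovery of every injected event is
    # possible in principle
    min_fixation_ms: float = 180.0
    # consecutive fixation targets keep at least this separation, so every
    # injected saccade is large enough to register against the velocity floor
    min_intertarget_deg: float = 2.0
    fixation_jitter_deg: float = 0.3
    drift_step_deg: float = 0.01
    saccade_speed_deg_s: float = 200.0
    blink_prob_per_trial: float = 0.26
    blink_duration_ms_range: tuple[float, float] = (100.0, 400.0)
    blink_aspect_ratio: float = 0.3
    baseline_aspect_ratio: float = 0.85
    aspect_ratio_noise: float = 0.02
    p_fixation_in_aoi: float = 0.66
    recall_intercept: float = DEFAULT_RECALL_INTERCEPT
    recall_effect_beta: float = 0.5
    condition_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_EFFECTS)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sampling_rate_hz",
            "trial_ms",
            "fixation_rate_mean",
            "min_fixation_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        n = self.trial_ms * self.sampling_rate_hz / 1000.0
        if abs(n - round(n)) > 1:
            raise ValueError(
                "sampling_rate_hz x trial_ms must give an integer sample count"
            )

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_ms * self.sampling_rate_hz / 1000.0))

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz


@dataclass
class GroundTruth:
    """Injected events of a synthetic recording.

    ``fixations``: trial_id, onset/offset (ms, trial-relative to recording
    time axis), target centroid (px and deg) and AOI label; ``blinks``:
    injected eye-closure intervals; ``drift``: per-sample drift trajectory
    in px.
    """

    fixations: pd.DataFrame
    blinks: pd.DataFrame
    drift: pd.DataFrame

    def n_fixations(self, trial_id: int) -> int:
        return int((self.fixations["trial_id"] == trial_id).sum())


def subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    """Independent per-subject substream of the top-level seed."""
    return np.random.default_rng([seed, subject_index])


def generate_aoi_layout(
    picture_id: str,
    n_aois: int,
    rng: np.random.Generator,
    geometry: ScreenGeometry = GOGGLES_EXP1,
    radius_deg: float = 2.0,
    min_separation_deg: float = 6.0,
) -> AOISet:
    """Random circular AOI layout with a minimum centre separation.

    Centroids are drawn uniformly inside the central 80% of the screen and
    rejected until all pairwise separations exceed ``min_separation_deg``.
    """
    span_x, span_y = geometry.px_to_deg(geometry.screen_px[0] * 0.9, geometry.screen_px[1] * 0.9)
    pts: list[tuple[float, float]] = []
    for _ in range(10_000):
        cand = (
            float(rng.uniform(-abs(span_x), abs(span_x))),
            float(rng.uniform(-abs(span_y), abs(span_y))),
        )
        if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_separation_deg for p in pts):
            pts.append(cand)
        if len(pts) == n_aois:
            break
    else:
        raise RuntimeError(
            f"could not place {n_aois} AOIs with separation {min_separation_deg} deg"
        )
    return AOISet(picture_id, [AOI(p, radius_deg, "interest") for p in pts])


def _plan_trial(
    cfg: SimConfig,
    layout: AOISet,
    rng: np.random.Generator,
    n_fixations: int | None = None,
) -> tuple[list[tuple[float, float]], list[float], list[int]]:
    """Choose fixation targets (deg) and durations summing, with the
    saccade legs, exactly to the trial window.

    Returns (targets_deg, durations_ms, aoi_labels) with -1 for off-AOI
    targets.  Raises if even a single minimum-length fixation cannot fit.
    """
    centroids = [a.centroid_deg for a in layout.interest]
    if not centroids:
        raise ValueError("layout must contain at least one interest AOI")
    span = cfg.geometry.px_to_deg(cfg.screen_px[0] * 0.95, cfg.screen_px[1] * 0.95)

    for _ in range(200):
        if n_fixations is not None:
            n = n_fixations
        else:
            n = int(round(rng.normal(cfg.fixation_rate_mean, cfg.fixation_rate_sd)))
            n = max(1, n)
        targets: list[tuple[float, float]] = []
        labels: list[int] = []
        for _k in range(n):
            for _try in range(50):
                if rng.random() < cfg.p_fixation_in_aoi:
                    idx = int(rng.integers(len(centroids)))
                    # avoid an immediate repeat of the same AOI when possible
                    if labels and labels[-1] == idx and len(centroids) > 1:
                        idx = (idx + 1 + int(rng.integers(len(centroids) - 1))) % len(
                            centroids
                        )
                    cand, lab = centroids[idx], idx
                else:
                    cand, lab = (
                        float(rng.uniform(-abs(span[0]), abs(span[0]))),
                        float(rng.uniform(-abs(span[1]), abs(span[1]))),
                    ), -1
                if (
                    not targets
                    or np.hypot(cand[0] - targets[-1][0], cand[1] - targets[-1][1])
                    >= cfg.min_intertarget_deg
                ):
                    break
            targets.append(cand)
            labels.append(lab)
        legs = [
            float(np.hypot(b[0] - a[0], b[1] - a[1])) / cfg.saccade_speed_deg_s * 1000.0
            for a, b in zip(targets[:-1], targets[1:])
        ]
        budget = cfg.trial_ms - sum(legs)
        if budget >= n * cfg.min_fixation_ms:
            w = rng.gamma(2.0, 1.0, size=n)
            extra = (budget - n * cfg.min_fixation_ms) * w / w.sum()
            durations = list(cfg.min_fixation_ms + extra)
            return targets, durations, labels
        if n_fixations is not None:
            raise ValueError(
                f"{n} fixations of >= {cfg.min_fixation_ms} ms plus saccades "
                f"do not fit in a {cfg.trial_ms} ms trial"
            )
    raise ValueError(
        "could not fit any fixation plan in the trial window; "
        "lower fixation_rate_mean or min_fixation_ms"
    )


def render_trial(
    cfg: SimConfig,
    targets_deg: list[tuple[float, float]],
    durations_ms: list[float],
    rng: np.random.Generator,
    trial_id: int = 0,
    t0_ms: float = 0.0,
    blink: tuple[float, float] | None = None,
    drift_px: np.ndarray | None = None,
) -> tuple[pd.DataFrame, list[dict], list[dict]]:
    """Render one trial to a sample table.

    The trial timeline alternates fixation plateaus of ``durations_ms``
    with linear saccadic ramps at the configured peak velocity; ``blink``
    is an optional (onset_ms, duration_ms) interval relative to trial
    start.  Returns (samples, fixation_truth_rows, blink_truth_rows).
    """
    if len(targets_deg) != len(durations_ms):
        raise ValueError("targets and durations must have equal length")
    geom = cfg.geometry
    dt = cfg.dt_ms
    n_samp = cfg.samples_per_trial

    # absolute (trial-relative) event boundaries
    events = []  # (kind, start, end, payload)
    t = 0.0
    for k, (tgt, dur) in enumerate(zip(targets_deg, durations_ms)):
        events.append(("fix", t, t + dur, tgt))
        t += dur
        if k + 1 < len(targets_deg):
            nxt = targets_deg[k + 1]
            leg = float(np.hypot(nxt[0] - tgt[0], nxt[1] - tgt[1]))
            leg_ms = leg / cfg.saccade_speed_deg_s * 1000.0
            events.append(("sac", t, t + leg_ms, (tgt, nxt)))
            t += leg_ms
    if t > cfg.trial_ms + 1e-6:
        raise ValueError("event plan exceeds the trial window")
    # hold the last target for any residual time
    if t < cfg.trial_ms:
        events.append(("fix_hold", t, cfg.trial_ms, targets_deg[-1]))

    ts = np.arange(n_samp) * dt
    x = np.empty(n_samp)
    y = np.empty(n_samp)
    jx, jy = geom.deg_per_px()
    sigma_px = (
        cfg.fixation_jitter_deg / jx if jx else 0.0,
        cfg.fixation_jitter_deg / jy if jy else 0.0,
    )
    for kind, start, end, payload in events:
        m = (ts >= start - 1e-9) & (ts < end - 1e-9)
        if not m.any():
            continue
        if kind in ("fix", "fix_hold"):
            px, py = geom.deg_to_px(payload[0], payload[1])
            x[m] = px + rng.normal(0.0, sigma_px[0], m.sum()) * (cfg.fixation_jitter_deg > 0)
            y[m] = py + rng.normal(0.0, sigma_px[1], m.sum()) * (cfg.fixation_jitter_deg > 0)
        else:
            (a, b) = payload
            frac = (ts[m] - start) / (end - start)
            ax, ay = geom.deg_to_px(a[0], a[1])
            bx, by = geom.deg_to_px(b[0], b[1])
            x[m] = ax + frac * (bx - ax)
            y[m] = ay + frac * (by - ay)

    ar = np.clip(
        rng.normal(cfg.baseline_aspect_ratio, cfg.aspect_ratio_noise, n_samp), 0.0, 1.0
    )

    blink_rows: list[dict] = []
    if blink is not None:
        b_on, b_dur = blink
        bm = (ts >= b_on - 1e-9) & (ts < b_on + b_dur - 1e-9)
        if bm.any():
            ar[bm] = cfg.blink_aspect_ratio
            first = int(np.argmax(bm))
            hold_x = x[first - 1] if first > 0 else x[first]
            hold_y = y[first - 1] if first > 0 else y[first]
            x[bm] = hold_x
            y[bm] = hold_y
            blink_rows.append(
                {
                    "trial_id": trial_id,
                    "onset_ms": t0_ms + b_on,
                    "offset_ms": t0_ms + b_on + b_dur,
                }
            )

    if drift_px is not None:
        x = x + drift_px[:, 0]
        y = y + drift_px[:, 1]

    samples = pd.DataFrame(
        {
            "t_ms": t0_ms + ts,
            "x_px": x,
            "y_px": y,
            "aspect_ratio": ar,
            "trial_id": trial_id,
        }
    )
    fix_rows = []
    tcur = 0.0
    for k, (tgt, dur) in enumerate(zip(targets_deg, durations_ms)):
        px, py = geom.deg_to_px(tgt[0], tgt[1])
        fix_rows.append(
            {
                "trial_id": trial_id,
                "onset_ms": t0_ms + tcur,
                "offset_ms": t0_ms + tcur + dur,
                "x_px": px,
                "y_px": py,
                "x_deg": tgt[0],
                "y_deg": tgt[1],
            }
        )
        tcur += dur
        if k + 1 < len(targets_deg):
            nxt = targets_deg[k + 1]
            tcur += (
                float(np.hypot(nxt[0] - tgt[0], nxt[1] - tgt[1]))
                / cfg.saccade_speed_deg_s
                * 1000.0
            )
    return samples, fix_rows, blink_rows


def generate_gaze_recording(
    cfg: SimConfig,
    layouts: AOISet | list[AOISet],
    rng: np.random.Generator,
    subject_id: str = "s000",
    n_fixations_per_trial: int | None = None,
) -> tuple[GazeRecording, GroundTruth]:
    """Simulate one subject's session over the given picture layouts.

    One trial per layout; trials are concatenated back to back on the time
    axis.  Drift is a single random walk over the whole session.
    """
    if isinstance(layouts, AOISet):
        layouts = [layouts]
    n_trials = len(layouts)
    n_samp = cfg.samples_per_trial
    total = n_trials * n_samp

    jx, jy = cfg.geometry.deg_per_px()
    if cfg.drift_step_deg > 0:
        steps = rng.normal(0.0, 1.0, (total, 2))
        drift = np.cumsum(steps, axis=0)
        drift[:, 0] *= cfg.drift_step_deg / jx
        drift[:, 1] *= cfg.drift_step_deg / jy
    else:
        drift = np.zeros((total, 2))

    frames, fix_rows, blink_rows = [], [], []
    for ti, layout in enumerate(layouts):
        targets, durations, labels = _plan_trial(
            cfg, layout, rng, n_fixations=n_fixations_per_trial
        )
        blink = None
        if cfg.blink_prob_per_trial > 0 and rng.random() < cfg.blink_prob_per_trial:
            b_dur = float(rng.uniform(*cfg.blink_duration_ms_range))
            b_on = float(rng.uniform(0.0, max(cfg.trial_ms - b_dur, 0.0)))
            blink = (b_on, b_dur)
        t0 = ti * cfg.trial_ms
        samples, fr, br = render_trial(
            cfg,
            targets,
            durations,
            rng,
            trial_id=ti,
            t0_ms=t0,
            blink=blink,
            drift_px=drift[ti * n_samp : (ti + 1) * n_samp],
        )
        for row, lab in zip(fr, labels):
            row["aoi_label"] = lab
            row["picture_id"] = layout.picture_id
        frames.append(samples)
        fix_rows.extend(fr)
        blink_rows.extend(br)

    samples = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        fixations=pd.DataFrame(
            fix_rows,
            columns=[
                "trial_id",
                "onset_ms",
                "offset_ms",
                "x_px",
                "y_px",
                "x_deg",
                "y_deg",
                "aoi_label",
                "picture_id",
            ],
        ),
        blinks=pd.DataFrame(blink_rows, columns=["trial_id", "onset_ms", "offset_ms"]),
        drift=pd.DataFrame(
            {
                "t_ms": samples["t_ms"].to_numpy(),
                "dx_px": drift[:, 0],
                "dy_px": drift[:, 1],
            }
        ),
    )
    rec = GazeRecording(subject_id, cfg.sampling_rate_hz, samples, cfg.geometry)
    return rec, truth


@dataclass
class CalibrationRecord:
    """Simulated 9-point calibration: 3x3 target grid plus gaze samples."""

    subject_id: str
    targets_px: np.ndarray  # (9, 2)
    gaze: pd.DataFrame  # target_idx, x_px, y_px


def generate_calibration_record(
    cfg: SimConfig,
    deviation_deg: float,
    rng: np.random.Generator,
    subject_id: str = "s000",
    jitter_deg: float = 0.1,
    samples_per_target: int = 20,
) -> CalibrationRecord:
    """Simulate a 9-point calibration with a controlled total deviation.

    Each of the 9 targets receives a systematic gaze offset of
    ``deviation_deg / 9`` in a random direction, so the summed per-target
    deviation equals ``deviation_deg`` exactly when jitter is zero.
    """
    if deviation_deg < 0:
        raise ValueError("deviation_deg must be >= 0")
    w, h = cfg.screen_px
    fr = (0.1, 0.5, 0.9)
    targets = np.array([(w * fx, h * fy) for fy in fr for fx in fr])
    jx, jy = cfg.geometry.deg_per_px()
    rows = []
    per_target = deviation_deg / 9.0
    for i, (tx, ty) in enumerate(targets):
        ang = rng.uniform(0, 2 * np.pi)
        off = (per_target * np.cos(ang) / jx, per_target * np.sin(ang) / jy)
        for _ in range(samples_per_target):
            rows.append(
                {
                    "target_idx": i,
                    "x_px": tx + off[0] + rng.normal(0, jitter_deg / jx) * (jitter_deg > 0),
                    "y_px": ty + off[1] + rng.normal(0, jitter_deg / jy) * (jitter_deg > 0),
                }
            )
    return CalibrationRecord(subject_id, targets, pd.DataFrame(rows))


def generate_recall_outcomes(
    features: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator,
    z_column: str = "z_n_fix_in_aois",
    condition_column: str | None = None,
) -> pd.DataFrame:
    """Bernoulli recall outcomes from a logistic model on a z-scored
    gaze feature plus an optional guided-viewing condition effect.

    recall ~ Bernoulli(sigmoid(alpha + beta * z + condition_effect)).
    Rows with a missing feature value fall back to the intercept-only
    probability and are flagged.
    """
    z = features[z_column].to_numpy(dtype=float)
    flagged = ~np.isfinite(z)
    eta = cfg.recall_intercept + cfg.recall_effect_beta * np.where(flagged, 0.0, z)
    if condition_column is not None:
        eff = features[condition_column].map(cfg.condition_effects)
        if eff.isna().any():
            bad = sorted(set(features.loc[eff.isna(), condition_column]))
            raise ValueError(f"unknown conditions: {bad}")
        eta = eta + eff.to_numpy(dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    out = features[[c for c in ("subject_id", "picture_id") if c in features.columns]].copy()
    out["recalled"] = rng.random(len(p)) < p
    out["p_recall"] = p
    out["intercept_only"] = flagged
    return out


def simulate_feature_cohort(
    n_subjects: int,
    n_pictures: int,
    seed: int,
    beta: float = 0.0,
    subject_sd: float = 0.5,
    recall_intercept: float = -1.6,
) -> pd.DataFrame:
    """Fast trial-level cohort for statistical calibration studies.

    Draws a per-trial fixation-count-like feature with subject- and
    picture-level variance components, z-standardises it within picture,
    and generates recall outcomes with log-odds ``beta`` per standardised
    unit.  Pictures carry valence labels (equal thirds negative / neutral
    / positive, scrambled excluded from the memory analysis as in the
    encoding task design).
    """
    rng = np.random.default_rng(seed)
    n_val = n_pictures // 3
    valence = np.repeat(["negative", "neutral", "positive"], n_val)
    subj_eff = rng.normal(0.0, subject_sd, n_subjects)
    pic_eff = rng.normal(0.0, 0.5, n_val * 3)
    rows = []
    for s in range(n_subjects):
        raw = 5.3 + subj_eff[s] + pic_eff + rng.normal(0.0, 1.0, n_val * 3)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": f"s{s:03d}",
                    "picture_id": [f"p{i:03d}" for i in range(n_val * 3)],
                    "valence": valence,
                    "feature": raw,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    g = df.groupby("picture_id")["feature"]
    df["z_feature"] = (df["feature"] - g.transform("mean")) / g.transform("std")
    # subject-level recall propensity independent of gaze (memory ability)
    ability = rng.normal(0.0, 0.5, n_subjects)
    eta = (
        recall_intercept
        + beta * df["z_feature"].to_numpy()
        + ability[df["subject_id"].str.slice(1).astype(int)]
    )
    df["recalled"] = rng.random(len(df)) < 1.0 / (1.0 + np.exp(-eta))
    return df


def simulate_aggregate_cohort(
    n_subjects: int,
    n_pictures: int,
    seed: int,
    beta: float = 0.0,
    feature: str = "n_fix",
) -> pd.DataFrame:
    """Subject x valence aggregates ready for the association model.

    Wraps :func:`simulate_feature_cohort`, averages the z-feature and sums
    recall per subject x valence, and attaches randomly assigned
    subject-level covariates (sex, age, and the goggles / recall-room
    batch factors).
    """
    df = simulate_feature_cohort(n_subjects, n_pictures, seed=seed, beta=beta)
    agg = (
        df.groupby(["subject_id", "valence"], observed=True)
        .agg(
            z=("z_feature", "mean"),
            recall_count=("recalled", "sum"),
            n_valid_trials=("recalled", "size"),
        )
        .reset_index()
        .rename(columns={"z": f"z_{feature}"})
    )
    rng = np.random.default_rng([seed, 0xC0])
    subs = sorted(agg["subject_id"].unique())
    meta = pd.DataFrame(
        {
            "subject_id": subs,
            "sex": rng.integers(0, 2, len(subs)),
            "age": np.round(rng.normal(22.3, 3.3, len(subs)), 1),
            "goggles": rng.integers(0, 2, len(subs)),
            "recall_room": rng.integers(0, 3, len(subs)),
        }
    )
    return agg.merge(meta, on="subject_id")
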