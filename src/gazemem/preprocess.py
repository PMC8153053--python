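"""Raw gaze samples -> drift-corrected coordinates, fixations and blinks.

Fixation detection follows the robust velocity-threshold construction:
velocities from a 5-point central-difference kernel, a median-based
estimate of the per-axis velocity dispersion, and an elliptic threshold at
``lambda`` times that dispersion.  Samples exceeding the threshold in runs
of at least ``min_saccade_samples`` are saccades; the maximal runs between
saccades are candidate fixations, and candidates shorter than 100 ms are
discarded.  Blinks are detected independently from the pupil-ellipse
aspect ratio (threshold 0.6, minimum duration 83 ms).

Slow drift of the recorded coordinates is removed by subtracting a
centred moving median (default window 3301 samples, ~55 s at 60 Hz);
the overall median is re-added so absolute screen coordinates — needed
for AOI membership — are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, px_to_deg  # noqa: F401  (re-export)
from .types import BlinkEvent, FixationEvent, GazeRecording

#: Default moving-median window (samples); ~55 s at 60 Hz.
DRIFT_WINDOW_SAMPLES = 3301

#: Candidate fixations shorter than this are discarded (strictly less-than).
MIN_FIXATION_MS = 100.0

#: Blink detection defaults: pupil aspect-ratio threshold and minimum duration.
BLINK_AR_THRESHOLD = 0.6
BLINK_MIN_MS = 83.0

#: Aspect ratio below which a sample is treated as invalid for position.
INVALID_AR = 0.5


@dataclass(frozen=True)
class VelocityParams:
    """Parameters of the velocity-threshold saccade detector."""

    lambda_multiplier: float = 6.0
    min_saccade_samples: int = 2
    velocity_floor_deg_s: float = 10.0  # fallback when the robust SD is zero

    def __post_init__(self) -> None:
        if self.lambda_multiplier <= 0:
            raise ValueError("lambda_multiplier must be > 0")
        if self.min_saccade_samples < 1:
            raise ValueError("min_saccade_samples must be >= 1")


def moving_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving median with edge-truncated windows."""
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def correct_drift(
    recording: GazeRecording, window_samples: int = DRIFT_WINDOW_SAMPLES
) -> GazeRecording:
    """Subtract a slow moving-median baseline from each gaze axis.

    corrected(t) = raw(t) - movmedian(raw, window)(t) + median(raw), so
    high-frequency structure (fixations, saccades) is untouched, slow
    drift is removed, and the overall screen position is preserved.
    """
    if window_samples % 2 == 0:
        raise ValueError("window_samples must be odd")
    if len(recording.samples) < 2:
        raise ValueError("recording must contain at least 2 samples")
    out = recording.samples.copy()
    for col in ("x_px", "y_px"):
        v = out[col].to_numpy(dtype=float)
        out[col] = v - moving_median(v, window_samples) + np.median(v)
    return GazeRecording(
        recording.subject_id, recording.sampling_rate_hz, out, recording.geometry
    )


def sample_velocities(
    x_deg: np.ndarray, y_deg: np.ndarray, dt_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample velocity (deg/s) via the 5-point central-difference kernel
    v(t) = (p(t+2) + p(t+1) - p(t-1) - p(t-2)) / (6 dt); edges are padded by
    replication, giving near-zero velocity at the series ends.
    """
    def vel(p: np.ndarray) -> np.ndarray:
        pp = np.pad(p, 2, mode="edge")
        return (pp[4:] + pp[3:-1] - pp[1:-3] - pp[:-4]) / (6.0 * dt_s)

    return vel(np.asarray(x_deg, float)), vel(np.asarray(y_deg, float))


def robust_sd(v: np.ndarray) -> float:
    """Median-based velocity dispersion: sqrt(median(v^2) - median(v)^2)."""
    if len(v) == 0:
        return 0.0
    var = float(np.median(v**2) - np.median(v) ** 2)
    return float(np.sqrt(var)) if var > 0 else 0.0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True in a boolean array."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_fixations(
    recording: GazeRecording,
    params: VelocityParams = VelocityParams(),
    min_fixation_ms: float = MIN_FIXATION_MS,
) -> list[FixationEvent]:
    """Velocity-threshold fixation detection, per trial.

    Invalid (blink) samples are excluded from the dispersion estimate and
    cannot mark a saccade by themselves; because position is held during a
    blink, a fixation is split only when the post-blink position jumps far
    enough to register as a saccade.
    """
    geom = recording.geometry
    if geom is None:
        raise ValueError("recording must carry a ScreenGeometry")
    dt_s = recording.dt_ms / 1000.0
    events: list[FixationEvent] = []
    for trial_id in recording.trial_ids():
        tr = recording.trial_samples(trial_id)
        if len(tr) < 5:
            warnings.warn(f"trial {trial_id} shorter than 5 samples; no events")
            continue
        x_deg, y_deg = geom.px_to_deg(
            tr["x_px"].to_numpy(float), tr["y_px"].to_numpy(float)
        )
        x_deg = np.asarray(x_deg, float)
        y_deg = np.asarray(y_deg, float)
        valid = tr["aspect_ratio"].to_numpy(float) >= INVALID_AR
        vx, vy = sample_velocities(x_deg, y_deg, dt_s)
        sx = robust_sd(vx[valid])
        sy = robust_sd(vy[valid])
        if sx <= 0 or sy <= 0:
            # perfectly still data: fall back to an absolute velocity floor
            # (lambda * sigma == velocity_floor_deg_s)
            floor = params.velocity_floor_deg_s / params.lambda_multiplier
            sx = max(sx, floor)
            sy = max(sy, floor)
        lam = params.lambda_multiplier
        above = (vx / (lam * sx)) ** 2 + (vy / (lam * sy)) ** 2 > 1.0
        above &= valid
        saccade = np.zeros(len(tr), dtype=bool)
        for i, j in _runs(above):
            if j - i >= params.min_saccade_samples:
                saccade[i:j] = True
        t = tr["t_ms"].to_numpy(float)
        for i, j in _runs(~saccade):
            dur = (j - i) * recording.dt_ms
            if dur < min_fixation_ms:
                continue
            seg_valid = valid[i:j]
            if not seg_valid.any():
                continue
            cx = float(np.mean(tr["x_px"].to_numpy(float)[i:j][seg_valid]))
            cy = float(np.mean(tr["y_px"].to_numpy(float)[i:j][seg_valid]))
            cxd, cyd = geom.px_to_deg(cx, cy)
            events.append(
                FixationEvent(
                    trial_id=int(trial_id),
                    onset_ms=float(t[i]),
                    offset_ms=float(t[i]) + dur,
                    centroid_px=(cx, cy),
                    centroid_deg=(float(cxd), float(cyd)),
                )
            )
    return events


def detect_blinks(
    recording: GazeRecording,
    ar_threshold: float = BLINK_AR_THRESHOLD,
    min_ms: float = BLINK_MIN_MS,
) -> list[BlinkEvent]:
    """Maximal runs of aspect_ratio < threshold lasting >= ``min_ms``."""
    events: list[BlinkEvent] = []
    dt = recording.dt_ms
    for trial_id in recording.trial_ids():
        tr = recording.trial_samples(trial_id)
        below = tr["aspect_ratio"].to_numpy(float) < ar_threshold
        t = tr["t_ms"].to_numpy(float)
        for i, j in _runs(below):
            dur = (j - i) * dt
            if dur >= min_ms:
                events.append(
                    BlinkEvent(
                        trial_id=int(trial_id),
                        onset_ms=float(t[i]),
                        offset_ms=float(t[i]) + dur,
                    )
                )
    return events
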