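"""Core containers shared across the pipeline.

Gaze samples live in a pandas DataFrame (columns ``t_ms, x_px, y_px,
aspect_ratio, trial_id``); oculomotor events, AOIs and scan paths are light
dataclasses with (de)serialisation helpers to CSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry

SAMPLE_COLUMNS = ["t_ms", "x_px", "y_px", "aspect_ratio", "trial_id"]


@dataclass
class GazeRecording:
    """A monocular gaze-sample stream for one subject.

    ``samples`` holds one row per sample; ``trial_id`` is -1 for inter-trial
    periods.  Timestamps must be strictly increasing with a near-constant
    sampling interval.
    """

    subject_id: str
    sampling_rate_hz: float
    samples: pd.DataFrame
    geometry: ScreenGeometry | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"gaze samples missing columns: {missing}")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def validate(self) -> None:
        t = self.samples["t_ms"].to_numpy()
        if len(t) >= 2:
            dts = np.diff(t)
            if np.any(dts <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.any(np.abs(dts - self.dt_ms) > 0.01 * self.dt_ms):
                raise ValueError("sampling interval varies by more than 1%")
        ar = self.samples["aspect_ratio"].to_numpy()
        if np.any((ar < 0) | (ar > 1)):
            raise ValueError("aspect_ratio must lie in [0, 1]")

    def trial_ids(self) -> list[int]:
        ids = sorted(set(self.samples["trial_id"]) - {-1})
        return [int(i) for i in ids]

    def trial_samples(self, trial_id: int) -> pd.DataFrame:
        return self.samples[self.samples["trial_id"] == trial_id]

    def to_csv(self, path: str | Path) -> None:
        self.samples.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        subject_id: str,
        sampling_rate_hz: float,
        geometry: ScreenGeometry | None = None,
    ) -> "GazeRecording":
        return cls(subject_id, sampling_rate_hz, pd.read_csv(path), geometry)


@dataclass(frozen=True)
class FixationEvent:
    trial_id: int
    onset_ms: float
    offset_ms: float
    centroid_px: tuple[float, float]
    centroid_deg: tuple[float, float]

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class BlinkEvent:
    trial_id: int
    onset_ms: float
    offset_ms: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def fixations_to_frame(events: list[FixationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trial_id": e.trial_id,
                "onset_ms": e.onset_ms,
                "offset_ms": e.offset_ms,
                "duration_ms": e.duration_ms,
                "x_px": e.centroid_px[0],
                "y_px": e.centroid_px[1],
                "x_deg": e.centroid_deg[0],
                "y_deg": e.centroid_deg[1],
            }
            for e in events
        ],
        columns=[
            "trial_id",
            "onset_ms",
            "offset_ms",
            "duration_ms",
            "x_px",
            "y_px",
            "x_deg",
            "y_deg",
        ],
    )


def blinks_to_frame(events: list[BlinkEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trial_id": e.trial_id,
                "onset_ms": e.onset_ms,
                "offset_ms": e.offset_ms,
                "duration_ms": e.duration_ms,
            }
            for e in events
        ],
        columns=["trial_id", "onset_ms", "offset_ms", "duration_ms"],
    )


@dataclass(frozen=True)
class AOI:
    """One circular area of (no) interest, in degrees relative to centre."""

    centroid_deg: tuple[float, float]
    radius_deg: float
    kind: str = "interest"  # "interest" | "no_interest"

    def contains(self, x_deg: float, y_deg: float) -> bool:
        dx = x_deg - self.centroid_deg[0]
        dy = y_deg - self.centroid_deg[1]
        return dx * dx + dy * dy <= self.radius_deg * self.radius_deg


@dataclass
class AOISet:
    """Areas of interest (and of no interest) for one picture."""

    picture_id: str
    aois: list[AOI] = field(default_factory=list)

    @property
    def interest(self) -> list[AOI]:
        return [a for a in self.aois if a.kind == "interest"]

    @property
    def no_interest(self) -> list[AOI]:
        return [a for a in self.aois if a.kind == "no_interest"]

    @property
    def aois_pic(self) -> int:
        """Number of interest AOIs (the picture's AOI count)."""
        return len(self.interest)

    def to_dict(self) -> dict:
        return {
            "picture_id": self.picture_id,
            "aois": [
                {
                    "centroid_deg": list(a.centroid_deg),
                    "radius_deg": a.radius_deg,
                    "kind": a.kind,
                }
                for a in self.aois
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AOISet":
        return cls(
            picture_id=d["picture_id"],
            aois=[
                AOI(tuple(a["centroid_deg"]), a["radius_deg"], a["kind"])
                for a in d["aois"]
            ],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AOISet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class PathSegment:
    """One halt of the moving circle: target point plus halt duration.

    ``halt_ms`` is kept as an exact rational so that the total fixated time
    sums to its nominal value without floating-point slack.
    """

    target_deg: tuple[float, float]
    halt_ms: Fraction
    kind: str = "interest"


@dataclass
class ScanPath:
    """Moving-circle schedule for one guided-viewing trial."""

    picture_id: str
    condition: str
    segments: list[PathSegment]
    circle_radius_deg: float
    transition_speed_deg_s: float = 200.0

    @property
    def total_fixated_ms(self) -> Fraction:
        return sum((s.halt_ms for s in self.segments), Fraction(0))

    def leg_lengths_deg(self) -> list[float]:
        out = []
        for a, b in zip(self.segments[:-1], self.segments[1:]):
            dx = b.target_deg[0] - a.target_deg[0]
            dy = b.target_deg[1] - a.target_deg[1]
            out.append(float(np.hypot(dx, dy)))
        return out

    @property
    def total_presentation_ms(self) -> float:
        legs = sum(self.leg_lengths_deg())
        return float(self.total_fixated_ms) + legs / self.transition_speed_deg_s * 1000.0

    def to_dict(self) -> dict:
        return {
            "picture_id": self.picture_id,
            "condition": self.condition,
            "circle_radius_deg": self.circle_radius_deg,
            "transition_speed_deg_s": self.transition_speed_deg_s,
            "segments": [
                {
                    "target_deg": list(s.target_deg),
                    "halt_ms": [s.halt_ms.numerator, s.halt_ms.denominator],
                    "kind": s.kind,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanPath":
        return cls(
            picture_id=d["picture_id"],
            condition=d["condition"],
            circle_radius_deg=d["circle_radius_deg"],
            transition_speed_deg_s=d["transition_speed_deg_s"],
            segments=[
                PathSegment(
                    tuple(s["target_deg"]),
                    Fraction(s["halt_ms"][0], s["halt_ms"][1]),
                    s["kind"],
                )
                for s in d["segments"]
            ],
        )
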