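"""Pixel <-> visual-degree conversion for the two display setups.

Two geometries are supported:

* ``linear`` — MR-compatible goggles whose optics are specified as a fixed
  angular span per screen axis (e.g. 30 deg over 800 px horizontally,
  23.5 deg over 600 px vertically).  Degrees are proportional to pixels.
* ``monitor`` — a flat screen viewed from a known distance; degrees follow
  the arctangent of physical offset from the screen centre over viewing
  distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry used to map gaze pixels to degrees of visual angle.

    Parameters
    ----------
    screen_px
        (width, height) in pixels.
    mode
        ``"linear"`` (angular span per axis) or ``"monitor"`` (distance +
        physical size).
    angular_span_deg
        (horizontal, vertical) full-screen span in degrees; required in
        linear mode.
    viewing_distance_cm, screen_cm
        Eye-to-screen distance and physical (width, height) of the display;
        required in monitor mode.
    """

    screen_px: tuple[int, int]
    mode: str = "linear"
    angular_span_deg: tuple[float, float] | None = None
    viewing_distance_cm: float | None = None
    screen_cm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode == "linear":
            if self.angular_span_deg is None:
                raise ValueError(
                    "linear geometry requires angular_span_deg=(h_deg, v_deg)"
                )
        elif self.mode == "monitor":
            missing = [
                name
                for name, val in (
                    ("viewing_distance_cm", self.viewing_distance_cm),
                    ("screen_cm", self.screen_cm),
                )
                if val is None
            ]
            if missing:
                raise ValueError(
                    "monitor geometry requires: " + ", ".join(missing)
                )
        else:
            raise ValueError(f"unknown geometry mode {self.mode!r}")

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.screen_px[0] / 2.0, self.screen_px[1] / 2.0)

    def px_to_deg(self, x_px, y_px):
        """Convert screen coordinates (px) to degrees relative to centre."""
        cx, cy = self.center_px
        if self.mode == "linear":
            sx = self.angular_span_deg[0] / self.screen_px[0]
            sy = self.angular_span_deg[1] / self.screen_px[1]
            return ((x_px - cx) * sx, (y_px - cy) * sy)
        # monitor: arctangent of physical offset over viewing distance
        cmx = self.screen_cm[0] / self.screen_px[0]
        cmy = self.screen_cm[1] / self.screen_px[1]
        import numpy as np

        xd = np.degrees(np.arctan((np.asarray(x_px) - cx) * cmx / self.viewing_distance_cm))
        yd = np.degrees(np.arctan((np.asarray(y_px) - cy) * cmy / self.viewing_distance_cm))
        return (xd, yd)

    def deg_to_px(self, x_deg, y_deg):
        """Inverse of :meth:`px_to_deg`."""
        cx, cy = self.center_px
        if self.mode == "linear":
            sx = self.screen_px[0] / self.angular_span_deg[0]
            sy = self.screen_px[1] / self.angular_span_deg[1]
            return (x_deg * sx + cx, y_deg * sy + cy)
        cmx = self.screen_cm[0] / self.screen_px[0]
        cmy = self.screen_cm[1] / self.screen_px[1]
        import numpy as np

        xp = np.tan(np.radians(np.asarray(x_deg))) * self.viewing_distance_cm / cmx + cx
        yp = np.tan(np.radians(np.asarray(y_deg))) * self.viewing_distance_cm / cmy + cy
        return (xp, yp)

    def deg_per_px(self) -> tuple[float, float]:
        """Small-angle scale factor (deg per pixel) at screen centre."""
        if self.mode == "linear":
            return (
                self.angular_span_deg[0] / self.screen_px[0],
                self.angular_span_deg[1] / self.screen_px[1],
            )
        cmx = self.screen_cm[0] / self.screen_px[0]
        cmy = self.screen_cm[1] / self.screen_px[1]
        return (
            math.degrees(cmx / self.viewing_distance_cm),
            math.degrees(cmy / self.viewing_distance_cm),
        )


#: Goggle system of the scanner experiment: 800x600 px spanning 30 x 23.5 deg.
GOGGLES_EXP1 = ScreenGeometry(
    screen_px=(800, 600), mode="linear", angular_span_deg=(30.0, 23.5)
)

#: Desktop monitor of the guided-viewing experiment: 1680x1050 px viewed
#: from 65 cm; physical size of a typical 22" 16:10 panel.
MONITOR_EXP2 = ScreenGeometry(
    screen_px=(1680, 1050),
    mode="monitor",
    viewing_distance_cm=65.0,
    screen_cm=(47.5, 29.7),
)


def px_to_deg(point_px: tuple[float, float], geometry: ScreenGeometry) -> tuple[float, float]:
    """Functional wrapper: convert one (x, y) point in pixels to degrees."""
    return geometry.px_to_deg(point_px[0], point_px[1])
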