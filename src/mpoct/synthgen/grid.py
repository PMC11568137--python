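"""Stimulus grid construction.

The default layout places 45 Goldmann III stimuli around the fovea: a
central point plus rings of 12, 16 and 16 points at 1.5, 2.5 and 5.2
degrees. Ring membership and angular offsets are fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class GridConfigError(ValueError):
    """Raised when a grid layout is inconsistent."""


@dataclass(frozen=True)
class Ring:
    radius_deg: float
    n_points: int
    angle_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_deg <= 0:
            raise GridConfigError(f"ring radius must be > 0, got {self.radius_deg}")
        if self.n_points < 1:
            raise GridConfigError(f"ring must have >= 1 point, got {self.n_points}")


@dataclass(frozen=True)
class GridLayout:
    center: int = 1
    rings: tuple[Ring, ...] = ()
    expected_n: int | None = None

    @classmethod
    def default(cls) -> "GridLayout":
        return cls(
            center=1,
            rings=(Ring(1.5, 12), Ring(2.5, 16), Ring(5.2, 16)),
            expected_n=45,
        )

    @property
    def n_points(self) -> int:
        return self.center + sum(r.n_points for r in self.rings)


@dataclass(frozen=True)
class StimulusGrid:
    """Stimulus locations in degrees relative to the fovea."""

    points: tuple[tuple[int, float, float], ...]  # (point_id, x_deg, y_deg)
    stimulus_diameter_deg: float = 0.43

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def point_ids(self) -> tuple[int, ...]:
        return tuple(p[0] for p in self.points)

    def eccentricities(self) -> tuple[float, ...]:
        return tuple(math.hypot(x, y) for _, x, y in self.points)

    def enface_positions_um(self, geometry) -> list[tuple[float, float]]:
        """True en-face positions (um) given geometry and fovea location."""
        fx, fy = geometry.fovea_um
        s = geometry.um_per_deg
        return [(fx + x * s, fy + y * s) for _, x, y in self.points]


def build_stimulus_grid(layout: GridLayout | None = None,
                        stimulus_diameter_deg: float = 0.43) -> StimulusGrid:
    """Construct a deterministic polar stimulus grid from a layout.

    Each ring places its points at angles ``offset + k * 360 / n`` degrees,
    with ``x = r cos(theta)`` and ``y = r sin(theta)``. Point ids are
    assigned sequentially starting at 0 (centre first).
    """
    if layout is None:
        layout = GridLayout.default()
    if layout.center not in (0, 1):
        raise GridConfigError("center count must be 0 or 1")
    if layout.expected_n is not None and layout.n_points != layout.expected_n:
        raise GridConfigError(
            f"layout yields {layout.n_points} points, expected {layout.expected_n}"
        )
    points: list[tuple[int, float, float]] = []
    pid = 0
    if layout.center:
        points.append((pid, 0.0, 0.0))
        pid += 1
    for ring in layout.rings:
        for k in range(ring.n_points):
            theta = math.radians(ring.angle_offset_deg + k * 360.0 / ring.n_points)
            points.append((pid, ring.radius_deg * math.cos(theta),
                           ring.radius_deg * math.sin(theta)))
            pid += 1
    return StimulusGrid(points=tuple(points),
                        stimulus_diameter_deg=stimulus_diameter_deg)
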