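"""Core spatial types shared across the pipeline.

An arena is a rectangle in millimeters with named rectangular zones and a
*stressor axis*: the 1-D coordinate along which aversiveness varies (the
light-dark axis through the door, the open/closed axis of a plus maze, the
distance axis from a social chamber).  By convention the axis coordinate
increases toward the stressor-free region and the axis origin (door, maze
center, field center) sits at coordinate 0, so a cumulative occupancy
profile evaluated at 0 reads off time spent on the stressor side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Rect",
    "ArenaGeometry",
    "Trajectory",
    "light_dark_box",
    "open_field",
    "elevated_plus_maze",
    "social_arena",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in arena millimeters, closed on all edges."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return (
            (xy[:, 0] >= self.xmin)
            & (xy[:, 0] <= self.xmax)
            & (xy[:, 1] >= self.ymin)
            & (xy[:, 1] <= self.ymax)
        )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin


@dataclass(frozen=True)
class ArenaGeometry:
    """Geometry and spatial conventions of one behavioral setup.

    Parameters
    ----------
    arena_kind:
        One of ``light_dark``, ``elevated_plus_maze``, ``open_field``,
        ``social_arena``, ``homecage``.
    bounds:
        Outer rectangle enclosing every reachable position, in mm.
    axis_origin, axis_direction:
        The stressor axis: a unit 2-vector and the point mapped to axis
        coordinate 0.  Coordinates increase toward the stressor-free zone.
    named_zones:
        Mapping ``zone_name -> Rect``; zones must lie inside ``bounds``.
    """

    arena_kind: str
    bounds: Rect
    axis_origin: tuple[float, float] = (0.0, 0.0)
    axis_direction: tuple[float, float] = (1.0, 0.0)
    named_zones: dict[str, Rect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.axis_direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("axis_direction must be unit-norm")
        b = self.bounds
        for name, z in self.named_zones.items():
            if z.xmin < b.xmin or z.xmax > b.xmax or z.ymin < b.ymin or z.ymax > b.ymax:
                raise ValueError(f"zone {name!r} extends outside arena bounds")

    def axis_coordinate(self, positions: np.ndarray) -> np.ndarray:
        """Signed projection of positions (n, 2) onto the stressor axis, mm."""
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        o = np.asarray(self.axis_origin, dtype=float)
        d = np.asarray(self.axis_direction, dtype=float)
        return (p - o) @ d

    def axis_range(self) -> tuple[float, float]:
        """Range of the axis coordinate over the bounding rectangle corners."""
        b = self.bounds
        corners = np.array(
            [[b.xmin, b.ymin], [b.xmin, b.ymax], [b.xmax, b.ymin], [b.xmax, b.ymax]]
        )
        c = self.axis_coordinate(corners)
        return float(c.min()), float(c.max())

    def in_zone(self, zone_name: str, positions: np.ndarray) -> np.ndarray:
        try:
            zone = self.named_zones[zone_name]
        except KeyError:
            raise KeyError(
                f"unknown zone {zone_name!r}; have {sorted(self.named_zones)}"
            ) from None
        return zone.contains(positions)


@dataclass
class Trajectory:
    """A 2-D locomotion record at fixed frame rate.

    ``positions`` is (n_frames, 2) in arena millimeters; ``times`` is derived
    as ``frame_index / frame_rate``.  ``body_areas`` (mm^2 per frame) and
    ``freezing`` (bool per frame pair, length n-1) are optional annotations
    produced by the video tracker.
    """

    subject_id: str
    group_label: str
    frame_rate: float
    positions: np.ndarray
    arena: ArenaGeometry | None = None
    body_areas: np.ndarray | None = None
    freezing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n_frames, 2)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.body_areas is not None:
            self.body_areas = np.asarray(self.body_areas, dtype=float)
            if len(self.body_areas) != len(self.positions):
                raise ValueError("body_areas length must match positions")
        if self.freezing is not None:
            self.freezing = np.asarray(self.freezing, dtype=bool)
            if len(self.freezing) != len(self.positions) - 1:
                raise ValueError("freezing must have one entry per frame pair")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def axis_positions(self) -> np.ndarray:
        if self.arena is None:
            raise ValueError("trajectory has no arena geometry")
        return self.arena.axis_coordinate(self.positions)


def light_dark_box(box_side: float = 200.0) -> ArenaGeometry:
    """Two connected square boxes; door at x=0, dark area at positive x.

    The default matches a pair of 200 mm x 200 mm compartments separated by
    a wall with a door at the light-dark boundary.
    """
    s = box_side
    return ArenaGeometry(
        arena_kind="light_dark",
        bounds=Rect(-s, 0.0, s, s),
        axis_origin=(0.0, s / 2),
        axis_direction=(1.0, 0.0),
        named_zones={
            "light": Rect(-s, 0.0, 0.0, s),
            "dark": Rect(0.0, 0.0, s, s),
        },
    )


def open_field(side: float = 400.0, center_side: float = 220.0) -> ArenaGeometry:
    """Square open field with a delineated central region.

    Axis points from the (aversive) center toward a wall; origin at center.
    """
    h, c = side / 2, center_side / 2
    return ArenaGeometry(
        arena_kind="open_field",
        bounds=Rect(-h, -h, h, h),
        axis_origin=(0.0, 0.0),
        axis_direction=(1.0, 0.0),
        named_zones={"center": Rect(-c, -c, c, c)},
    )


def elevated_plus_maze(
    arm_length: float = 250.0, arm_width: float = 50.0, entry_mm: float = 50.0
) -> ArenaGeometry:
    """Plus maze: open arms along x, closed arms along y, center square at 0.

    Arm entries are delineated ``entry_mm`` from the platform center.  The
    stressor axis is taken along the closed-arm direction (+y), so positive
    coordinates lie toward a stressor-free closed arm and the maze center
    sits at 0; open/closed/center zones carry the full cross geometry.
    """
    L, w = arm_length, arm_width / 2
    reach = L + w
    return ArenaGeometry(
        arena_kind="elevated_plus_maze",
        bounds=Rect(-reach, -reach, reach, reach),
        axis_origin=(0.0, 0.0),
        axis_direction=(0.0, 1.0),
        named_zones={
            "center": Rect(-w, -w, w, w),
            "open_arm_pos": Rect(entry_mm, -w, reach, w),
            "open_arm_neg": Rect(-reach, -w, -entry_mm, w),
            "closed_arm_pos": Rect(-w, entry_mm, w, reach),
            "closed_arm_neg": Rect(-w, -reach, w, -entry_mm),
        },
    )


def social_arena(
    side: float = 400.0,
    chamber_w: float = 60.0,
    chamber_h: float = 100.0,
    interaction_mm: float = 80.0,
) -> ArenaGeometry:
    """Open field with a social chamber against one wall.

    The interaction zone extends ``interaction_mm`` from the chamber edges;
    the stressor axis points away from the chamber face (social stimulus at
    coordinate 0).
    """
    h = side / 2
    cw, ch = chamber_w / 2, chamber_h
    iz = interaction_mm
    return ArenaGeometry(
        arena_kind="social_arena",
        bounds=Rect(-h, -h, h, h),
        axis_origin=(0.0, h - ch),
        axis_direction=(0.0, -1.0),
        named_zones={
            "chamber": Rect(-cw, h - ch, cw, h),
            "interaction": Rect(-cw - iz, h - ch - iz, cw + iz, h),
        },
    )
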