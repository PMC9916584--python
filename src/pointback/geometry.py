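"""Four-leg walked paths with three same-direction 90-degree turns.

A path starts at S, walks leg 1 to the first turn T1, turns 90 degrees,
walks leg 2 to T2, and so on through T3 to the end point E. Depending on
the leg lengths the first and fourth legs either cross (the path loops over
itself) or not; the uncrossed family further splits by whether leg 4 stops
short of leg 1's line or overshoots it beyond the start.

The canonical frame is the left-turn path with S at the origin and leg 1
along +y; the walker's final heading is then +x. Bearings are reported as
canonical angles: 0 = final heading, positive = clockwise. Right-turn paths
are exact mirror images and their bearings flip sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .angles import wrap_signed

__all__ = [
    "PathSpec",
    "PathGeometry",
    "BoundaryTopologyError",
    "build_path",
    "bearing",
    "correct_pointing",
    "extended_leg4_length",
    "CROSS",
    "NO_CROSS_SHORT_L4",
    "NO_CROSS_LONG_L3",
]

CROSS = "cross"
NO_CROSS_SHORT_L4 = "no_cross_short_L4"
NO_CROSS_LONG_L3 = "no_cross_long_L3"

#: numeric tolerance for geometric equalities (meters / degrees)
GEOM_TOL = 1e-9


class BoundaryTopologyError(ValueError):
    """Raised when leg lengths put the crossing exactly at a path vertex."""


@dataclass(frozen=True)
class PathSpec:
    """Leg lengths (meters) and turn chirality of a four-leg path.

    All three turns share one direction (``"left"`` or ``"right"``); the
    paths in this task family are same-direction spirals and mixed turn
    sequences are rejected by construction. Leg lengths must be positive
    and no longer than ``arena_bound`` (the walkable-space limit).
    """

    leg_lengths: tuple
    turn_direction: str = "left"
    path_id: str = ""
    experiment_tag: str = ""
    arena_bound: float = 3.4

    def __post_init__(self):
        lengths = tuple(float(x) for x in self.leg_lengths)
        object.__setattr__(self, "leg_lengths", lengths)
        if len(lengths) != 4:
            raise ValueError("a path has exactly four legs")
        if any(x <= 0 for x in lengths):
            raise ValueError("leg lengths must be positive")
        if any(x > self.arena_bound + GEOM_TOL for x in lengths):
            raise ValueError(
                f"leg lengths must not exceed the arena bound {self.arena_bound} m"
            )
        if self.turn_direction not in ("left", "right"):
            raise ValueError("turn_direction must be 'left' or 'right'")

    def mirrored(self) -> "PathSpec":
        other = "right" if self.turn_direction == "left" else "left"
        return PathSpec(self.leg_lengths, other, self.path_id,
                        self.experiment_tag, self.arena_bound)


@dataclass(frozen=True)
class PathGeometry:
    """Planar vertices, crossing topology and landmark points of a path.

    Landmarks (all optional, present when the crossing class defines them):

    * ``I`` — walked intersection of legs 1 and 4 (crossed paths).
    * ``I_prime`` — virtual intersection of the *extended* leg 4 with the
      line of leg 1 (uncrossed paths).
    * ``E_prime`` — end of the hypothesized extended leg 4 (short-L4 paths).
    * ``F1``/``F2`` — rendered false intersections on legs 1 and 4, both on
      leg 1's line (long-L3 paths). F2 is where leg 4 crosses that line; no
      prediction formula uses F1's position along leg 1, so it is placed
      at the leg midpoint as a rendering placeholder.
    * ``E_prime_far`` — point with E's first coordinate and T1's second.
    """

    spec: PathSpec
    S: np.ndarray
    T1: np.ndarray
    T2: np.ndarray
    T3: np.ndarray
    E: np.ndarray
    final_heading: np.ndarray
    crossing_class: str
    I: Optional[np.ndarray] = None
    I_prime: Optional[np.ndarray] = None
    E_prime: Optional[np.ndarray] = None
    F1: Optional[np.ndarray] = None
    F2: Optional[np.ndarray] = None
    E_prime_far: Optional[np.ndarray] = None

    @property
    def turn_direction(self) -> str:
        return self.spec.turn_direction

    def vertex(self, name: str) -> np.ndarray:
        p = getattr(self, name)
        if p is None:
            raise ValueError(
                f"landmark {name!r} is undefined for class {self.crossing_class!r}"
            )
        return p


def _classify(l1: float, l2: float, l3: float, l4: float) -> str:
    if abs(l3 - l1) < GEOM_TOL or abs(l4 - l2) < GEOM_TOL:
        raise BoundaryTopologyError(
            "boundary topology: L3 = L1 or L4 = L2 puts the crossing exactly "
            "at a path vertex"
        )
    if l4 < l2:
        return NO_CROSS_SHORT_L4
    if l3 < l1:
        return CROSS
    return NO_CROSS_LONG_L3


def build_path(spec: PathSpec) -> PathGeometry:
    """Construct vertices, crossing class and landmarks for a path spec.

    Right-turn specs produce the exact mirror image (across the leg-1 axis)
    of the left-turn geometry.
    """
    l1, l2, l3, l4 = spec.leg_lengths
    cls = _classify(l1, l2, l3, l4)

    pts = {
        "S": np.array([0.0, 0.0]),
        "T1": np.array([0.0, l1]),
        "T2": np.array([-l2, l1]),
        "T3": np.array([-l2, l1 - l3]),
        "E": np.array([-l2 + l4, l1 - l3]),
    }
    heading = np.array([1.0, 0.0])

    land = {"E_prime_far": np.array([pts["E"][0], l1])}
    if cls == CROSS:
        land["I"] = np.array([0.0, l1 - l3])
    elif cls == NO_CROSS_SHORT_L4:
        land["I_prime"] = np.array([0.0, l1 - l3])
        ext = 2.0 * l2 - l4  # leg 4 plus twice the E-to-I' gap
        land["E_prime"] = pts["T3"] + ext * np.array([1.0, 0.0])
    else:  # NO_CROSS_LONG_L3
        land["F2"] = np.array([0.0, l1 - l3])
        land["F1"] = np.array([0.0, l1 / 2.0])

    if spec.turn_direction == "right":
        flip = np.array([-1.0, 1.0])
        pts = {k: v * flip for k, v in pts.items()}
        land = {k: v * flip for k, v in land.items()}
        heading = heading * flip

    return PathGeometry(spec=spec, final_heading=heading, crossing_class=cls,
                        **pts, **land)


def bearing(origin, target, geom: PathGeometry) -> float:
    """Signed bearing of ``target`` seen from ``origin`` in the end frame.

    Zero is the walker's final heading; positive is physically clockwise.
    ``origin``/``target`` may be planar points or landmark names. The value
    is invariant to translating or rigidly rotating the whole path, and
    flips sign under mirroring.
    """
    if isinstance(origin, str):
        origin = geom.vertex(origin)
    if isinstance(target, str):
        target = geom.vertex(target)
    v = np.asarray(target, dtype=float) - np.asarray(origin, dtype=float)
    if np.hypot(*v) < GEOM_TOL:
        raise ValueError("bearing undefined for a zero-length vector")
    h = geom.final_heading
    ccw = np.arctan2(h[0] * v[1] - h[1] * v[0], h[0] * v[0] + h[1] * v[1])
    return wrap_signed(-np.degrees(ccw))


def correct_pointing(geom: PathGeometry) -> float:
    """Bearing from the end point E back to the true start S."""
    return bearing(geom.E, geom.S, geom)


def extended_leg4_length(geom: PathGeometry) -> float:
    """Length of the hypothesized extension of leg 4 past leg 1's line.

    Defined for short-L4 uncrossed paths only: leg 4 is imagined extended
    to twice the gap between E and the virtual intersection I', i.e.
    ``L4 + 2 * |E - I'|`` (equal to ``2 * L2 - L4``).
    """
    if geom.crossing_class != NO_CROSS_SHORT_L4:
        raise ValueError(
            "extended leg 4 is defined only for short-L4 uncrossed paths, "
            f"not {geom.crossing_class!r}"
        )
    l4 = geom.spec.leg_lengths[3]
    gap = float(np.hypot(*(geom.E - geom.I_prime)))
    return l4 + 2.0 * gap
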