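"""Wrap-safe arithmetic for directions and arcs on the circle.

All public angles in this package are *canonical* degrees: the value lies in
(-180, 180], 0 is the walker's facing direction at the end of the path, and
positive values run clockwise (toward the start side of a canonical
left-turn path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "wrap_signed",
    "circ_mean_r",
    "AngularInterval",
]


def wrap_signed(deg):
    """Wrap angle(s) in degrees into the canonical range (-180, 180].

    The boundary maps to +180 (so a pure about-face is +180, never -180).
    Accepts scalars or arrays.
    """
    w = np.mod(deg, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    if np.ndim(deg) == 0:
        return float(w)
    return w


def circ_mean_r(deg, weights=None):
    """Circular mean direction and mean resultant length of angles in degrees.

    Returns ``(mean_deg, r)``. The mean is the direction of the weighted
    vector sum; ``r`` is its length divided by the total weight. When the
    resultant is (numerically) zero the mean direction is undefined and NaN
    is returned for it.
    """
    a = np.radians(np.asarray(deg, dtype=float))
    if a.size == 0:
        raise ValueError("empty sample")
    if weights is None:
        c = np.cos(a).mean()
        s = np.sin(a).mean()
    else:
        w = np.asarray(weights, dtype=float)
        tot = w.sum()
        c = (w * np.cos(a)).sum() / tot
        s = (w * np.sin(a)).sum() / tot
    r = float(np.hypot(c, s))
    if r < 1e-12:
        return float("nan"), r
    return wrap_signed(np.degrees(np.arctan2(s, c))), r


@dataclass(frozen=True)
class AngularInterval:
    """A directed arc on the circle, traversed clockwise.

    The arc starts at ``from_deg`` and runs clockwise (increasing canonical
    angle, wrapping across +/-180) to ``to_deg``. Width is in [0, 360);
    membership is closed (boundary angles count as inside).
    """

    from_deg: float
    to_deg: float

    def __post_init__(self):
        object.__setattr__(self, "from_deg", wrap_signed(self.from_deg))
        object.__setattr__(self, "to_deg", wrap_signed(self.to_deg))

    @property
    def width(self) -> float:
        return float(np.mod(self.to_deg - self.from_deg, 360.0))

    @property
    def midpoint(self) -> float:
        return wrap_signed(self.from_deg + self.width / 2.0)

    def contains(self, deg, tol: float = 1e-9):
        off = np.mod(np.asarray(deg, dtype=float) - self.from_deg, 360.0)
        inside = (off <= self.width + tol) | (off >= 360.0 - tol)
        if np.ndim(deg) == 0:
            return bool(inside)
        return inside

    def intersection_length(self, other: "AngularInterval") -> float:
        """Arc length (degrees) of the overlap between two arcs."""
        # Work in this arc's frame: self covers [0, w_a]; split the other
        # arc into at most two linear segments of [0, 360).
        wa, wb = self.width, other.width
        s = float(np.mod(other.from_deg - self.from_deg, 360.0))
        total = 0.0
        for lo, hi in ((s, min(s + wb, 360.0)), (0.0, s + wb - 360.0)):
            if hi > lo:
                total += max(0.0, min(hi, wa) - max(lo, 0.0))
        return total

    def sample_uniform(self, n: int, rng: np.random.Generator):
        """Draw ``n`` angles uniformly on the arc (canonical degrees)."""
        if n < 1:
            raise ValueError("need at least one sample")
        return wrap_signed(self.from_deg + rng.uniform(0.0, self.width, size=n))
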