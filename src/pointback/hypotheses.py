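"""Predicted pointing ranges for the nine path-representation hypotheses.

Each hypothesis states how a walked four-leg path might be reconstructed in
memory (keeping or altering its crossing topology) and therefore which arc
of pointing-to-start directions it predicts at the end of the path. The
nine hypotheses and their admissible crossing classes:

========  ==========================  =====================================
id        requires                    remembered shape
========  ==========================  =====================================
CtoC      cross                       crossed path kept crossed
CtoN1     cross                       leg 1 shortened past the crossing
CtoN2     cross                       leg 4 shortened past the crossing
CtoN3     cross                       both legs shortened past the crossing
NtoN1     either uncrossed class      leg 1 shortened (or noisily resized)
NtoN2     no_cross_short_L4           leg 4 under/over-estimated
NtoC1     no_cross_short_L4           leg 4 extended to cross leg 1
NtoC2     no_cross_long_L3            the two false intersections stacked
NtoC3     no_cross_long_L3            false intersections joined by a fifth
                                      (unwalked) segment
========  ==========================  =====================================

All predicted arcs are expressed in the canonical (left-turn) frame; a
right-turn geometry is mirrored internally first, matching how responses
are canonicalized before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import AngularInterval, circ_mean_r, wrap_signed
from .geometry import (
    CROSS,
    NO_CROSS_LONG_L3,
    NO_CROSS_SHORT_L4,
    PathGeometry,
    bearing,
    build_path,
)

__all__ = [
    "HYPOTHESIS_IDS",
    "HypothesisPrediction",
    "predict_range",
    "range_mean",
    "admissible_set",
    "admissible_for_class",
    "pairwise_disjoint",
]

HYPOTHESIS_IDS = (
    "CtoC", "CtoN1", "CtoN2", "CtoN3",
    "NtoN1", "NtoN2", "NtoC1", "NtoC2", "NtoC3",
)

_ADMISSIBLE_CLASS = {
    "CtoC": (CROSS,),
    "CtoN1": (CROSS,),
    "CtoN2": (CROSS,),
    "CtoN3": (CROSS,),
    "NtoN1": (NO_CROSS_SHORT_L4, NO_CROSS_LONG_L3),
    "NtoN2": (NO_CROSS_SHORT_L4,),
    "NtoC1": (NO_CROSS_SHORT_L4,),
    "NtoC2": (NO_CROSS_LONG_L3,),
    "NtoC3": (NO_CROSS_LONG_L3,),
}

# Condition labels -> admissible hypothesis sets. The uncrossed sets differ
# between the first (short-L4 paths) and later (long-L3 paths) experiments.
_CROSS_SET = ("CtoC", "CtoN1", "CtoN2", "CtoN3")
_NOCROSS_EXP1 = ("NtoN1", "NtoN2", "NtoC1")
_NOCROSS_EXP23 = ("NtoN1", "NtoC2", "NtoC3")


@dataclass(frozen=True)
class HypothesisPrediction:
    hypothesis_id: str
    path_id: str
    interval: AngularInterval
    mean_direction: float


def admissible_for_class(crossing_class: str):
    """Hypothesis ids admissible for a crossing class."""
    return tuple(h for h in HYPOTHESIS_IDS
                 if crossing_class in _ADMISSIBLE_CLASS[h])


def admissible_set(condition_label: str, experiment: int = 1):
    """Hypotheses fit for a condition label.

    ``experiment`` disambiguates the NI-NC label, whose candidate set
    depends on the uncrossed path family in use (default 1). Labels:
    HI-C, PG-C, TI-C (crossed); NI-NC, PG-NC, FI-NC (uncrossed).
    """
    label = condition_label.upper()
    if label in ("HI-C", "PG-C", "TI-C"):
        return _CROSS_SET
    if label == "PG-NC":
        return _NOCROSS_EXP1
    if label == "FI-NC":
        return _NOCROSS_EXP23
    if label == "NI-NC":
        return _NOCROSS_EXP1 if experiment == 1 else _NOCROSS_EXP23
    raise ValueError(
        f"unknown condition label {condition_label!r}; expected one of "
        "HI-C, NI-NC, PG-C, PG-NC, TI-C, FI-NC"
    )


def _canonical(geom: PathGeometry) -> PathGeometry:
    if geom.turn_direction == "right":
        return build_path(geom.spec.mirrored())
    return geom


def predict_range(hypothesis_id: str, geom: PathGeometry) -> AngularInterval:
    """Predicted pointing arc for one hypothesis on one path.

    The arc runs clockwise from its first boundary to its second; for CtoN1
    it wraps across +/-180. Raises ``ValueError`` if the hypothesis is not
    admissible for the path's crossing class.
    """
    if hypothesis_id not in _ADMISSIBLE_CLASS:
        raise ValueError(f"unknown hypothesis {hypothesis_id!r}")
    cls = geom.crossing_class
    if cls not in _ADMISSIBLE_CLASS[hypothesis_id]:
        raise ValueError(
            f"hypothesis {hypothesis_id} is not admissible for crossing class "
            f"{cls!r}; admissible hypotheses: {admissible_for_class(cls)}"
        )
    g = _canonical(geom)
    b = lambda o, t: bearing(o, t, g)  # noqa: E731

    if hypothesis_id == "CtoC":
        return AngularInterval(b("I", "S"), b("E", "I"))
    if hypothesis_id == "CtoN1":
        return AngularInterval(b("E", "I"), b("E", "T1"))
    if hypothesis_id == "CtoN2":
        return AngularInterval(b("T3", "S"), b("I", "S"))
    if hypothesis_id == "CtoN3":
        return AngularInterval(b("I", "T1"), b("T3", "I"))
    if hypothesis_id == "NtoN1":
        if cls == NO_CROSS_SHORT_L4:
            return AngularInterval(b("E", "T1"), 0.0)
        # long-L3 form: the remembered start S' sweeps the leg-1 line from
        # T1 (maximal shortening) down past S (noisy extension). The
        # extension is capped at min(arena bound, L3): a remembered leg 1
        # longer than L3 would cross leg 4, contradicting the hypothesis's
        # uncrossed topology (and overlapping the crossed-range predictions).
        l1, _, l3, _ = g.spec.leg_lengths
        cap = min(g.spec.arena_bound, l3)
        leg1_dir = (g.T1 - g.S) / l1
        s_ext = g.S - (cap - l1) * leg1_dir
        lo = b(g.E, s_ext) if np.hypot(*(s_ext - g.E)) > 1e-12 else b("E", "S")
        return AngularInterval(lo, b("E", "T1"))
    if hypothesis_id == "NtoN2":
        return AngularInterval(b("T3", "S"), b("I_prime", "S"))
    if hypothesis_id == "NtoC1":
        # short arc between I'-S (90 deg) and E'-S: the remembered path is
        # crossed, so pointing falls on the backward side of 90 degrees.
        return AngularInterval(b("I_prime", "S"), b("E_prime", "S"))
    if hypothesis_id == "NtoC2":
        return AngularInterval(b("E_prime_far", "S"), 180.0)
    # NtoC3
    return AngularInterval(b("F2", "S"), b("T3", "S"))


def predict_all(geom: PathGeometry, hypothesis_ids=None, n_samples: int = 1000,
                seed=None):
    """Predictions (interval + Monte-Carlo range mean) for a path."""
    ids = hypothesis_ids or admissible_for_class(geom.crossing_class)
    rng = np.random.default_rng(seed)
    out = []
    for h in ids:
        iv = predict_range(h, geom)
        out.append(HypothesisPrediction(
            hypothesis_id=h, path_id=geom.spec.path_id, interval=iv,
            mean_direction=range_mean(iv, n_samples=n_samples, seed=rng),
        ))
    return out


def range_mean(interval: AngularInterval, n_samples: int = 1000,
               seed=None) -> float:
    """Circular mean of random draws on the arc (Monte-Carlo range mean).

    The draws are stratified-uniform (one uniform draw per equal sub-arc),
    which keeps every angle random within the range while stabilizing the
    mean far below the stated Monte-Carlo tolerance. ``seed`` may be an
    int, a Generator, or None; the value is reproducible under a fixed
    seed and converges to the arc midpoint as ``n_samples`` grows.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    offsets = (np.arange(n_samples) + rng.uniform(size=n_samples)) / n_samples
    draws = wrap_signed(interval.from_deg + offsets * interval.width)
    mean, _ = circ_mean_r(draws)
    return wrap_signed(mean)


def pairwise_disjoint(intervals, tol: float = 1e-9) -> bool:
    """True when the arcs overlap at most on boundary points."""
    items = list(intervals)
    for i, a in enumerate(items):
        for c in items[i + 1:]:
            if a.intersection_length(c) > tol:
                return False
    return True
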