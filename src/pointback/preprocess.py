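"""Canonicalize raw pointing trials into per-participant, per-path summaries.

Raw responses are recorded as clockwise angles in [0, 360) from the
walker's facing direction at the end of the path. The pipeline maps them to
signed canonical angles, mirrors trials walked with the non-canonical
chirality so left- and right-turn versions of a path are comparable,
circularly averages the trials of each path, and scores the signed angular
error AE_G against the geometrically correct pointing direction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .angles import circ_mean_r, wrap_signed
from .geometry import build_path, bearing, correct_pointing

__all__ = [
    "ZeroResultantError",
    "to_signed",
    "canonicalize_response",
    "per_path_mean",
    "angular_error",
    "distance_error_proportion",
    "summarize_trials",
    "TRIAL_COLUMNS",
]

log = logging.getLogger(__name__)

#: required columns of a trial table
TRIAL_COLUMNS = ("participant_id", "condition", "path_id", "trial_index",
                 "turn", "response_deg")


class ZeroResultantError(ValueError):
    """Circular mean undefined: the trial vectors cancel exactly."""


def to_signed(deg360: float) -> float:
    """Map a response in [0, 360) to the canonical range (-180, 180]."""
    x = float(deg360)
    if not (0.0 <= x < 360.0):
        raise ValueError(f"response {x} outside [0, 360)")
    return wrap_signed(x)


def canonicalize_response(response_deg: float, turn_direction: str,
                          canonical_turn: str = "left") -> float:
    """Signed response, mirrored onto the canonical chirality.

    Trials whose path is the mirror image of the canonical chirality have
    their sign flipped; with ``canonical_turn="left"`` this reproduces the
    flip-right-turn rule, and with ``canonical_turn="right"`` the flip rule
    used for path families whose reference version turns right.
    """
    for t in (turn_direction, canonical_turn):
        if t not in ("left", "right"):
            raise ValueError(f"unknown chirality {t!r}")
    signed = to_signed(response_deg)
    if turn_direction != canonical_turn:
        signed = wrap_signed(-signed)
    return signed


def per_path_mean(angles) -> float:
    """Circular mean of the canonicalized trials of one path.

    Raises :class:`ZeroResultantError` when the resultant vector is
    (numerically) zero, e.g. two exactly antipodal trials; such degenerate
    cells are excluded downstream with a warning rather than assigned an
    arbitrary direction.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one trial")
    mean, r = circ_mean_r(a)
    if not np.isfinite(mean):
        raise ZeroResultantError("zero resultant: circular mean undefined")
    return mean


def angular_error(response: float, correct: float) -> float:
    """Signed wrapped difference response - correct, in (-180, 180]."""
    return wrap_signed(np.asarray(response, dtype=float)
                       - np.asarray(correct, dtype=float))


def distance_error_proportion(correct_d: float, response_d: float) -> float:
    """(correct - response) / correct; positive = underestimation."""
    if correct_d <= 0:
        raise ValueError("correct distance must be positive")
    if response_d < 0:
        raise ValueError("response distance must be non-negative")
    return (correct_d - response_d) / correct_d


def _angle_from_landing(row, geoms) -> float:
    geom = geoms[(row["path_id"], row["turn"])]
    landing = np.array([row["landing_x"], row["landing_y"]])
    return float(np.mod(bearing(geom.E, landing, geom), 360.0))


def summarize_trials(trials: pd.DataFrame, paths, canonical_turn="left",
                     angle_tol: float = 0.1) -> pd.DataFrame:
    """Per (participant, condition, path) circular summaries with AE_G.

    Parameters
    ----------
    trials : DataFrame with :data:`TRIAL_COLUMNS`; optional columns
        ``landing_x``/``landing_y`` (meters, world frame of the walked
        path) and ``confidence``.
    paths : mapping path_id -> :class:`PathSpec` (any chirality; both
        chiralities are built as needed).
    canonical_turn : str or mapping path_id -> str
        Chirality treated as canonical per path; trials of the mirrored
        chirality are sign-flipped.
    angle_tol : degrees
        When a trial has both an explicit response angle and landing
        coordinates, disagreements beyond this tolerance are logged and the
        explicit angle wins.

    Returns a DataFrame with columns participant_id, condition, path_id,
    mean_response, n_trials, AE_G, distance_error_proportion (NaN when no
    landing data). Degenerate zero-resultant cells are dropped with a
    warning.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing column(s): {missing}")
    unknown = set(trials["path_id"]) - set(paths)
    if unknown:
        raise ValueError(f"unknown path_id(s) in trial table: {sorted(unknown)}")

    # world geometry of each walked (path, chirality) and the canonical one
    geoms = {}
    canon = {}
    for pid, spec in paths.items():
        for turn in ("left", "right"):
            s = spec if spec.turn_direction == turn else spec.mirrored()
            geoms[(pid, turn)] = build_path(s)
        ct = canonical_turn[pid] if isinstance(canonical_turn, dict) \
            else canonical_turn
        canon[pid] = ct

    df = trials.copy()
    has_landing = {"landing_x", "landing_y"} <= set(df.columns)
    if has_landing:
        with_landing = df["landing_x"].notna() & df["landing_y"].notna()
        recomputed = df.loc[with_landing].apply(
            lambda row: _angle_from_landing(row, geoms), axis=1)
        explicit = df.loc[with_landing, "response_deg"]
        both = explicit.notna()
        if both.any():
            diff = np.abs(wrap_signed(recomputed[both] - explicit[both]))
            n_bad = int((diff > angle_tol).sum())
            if n_bad:
                log.warning(
                    "%d trial(s) have landing coordinates disagreeing with the "
                    "recorded angle by > %.2f deg; keeping the explicit angle",
                    n_bad, angle_tol)
        use = with_landing & df["response_deg"].isna()
        df.loc[use, "response_deg"] = recomputed[use]

    rows = []
    for (part, cond, pid), grp in df.groupby(
            ["participant_id", "condition", "path_id"], sort=True):
        ct = canon[pid]
        canonical = [
            canonicalize_response(r, t, ct)
            for r, t in zip(grp["response_deg"], grp["turn"])
        ]
        try:
            mean_resp = per_path_mean(canonical)
        except ZeroResultantError:
            warnings.warn(
                f"degenerate zero-resultant trials for participant {part!r}, "
                f"path {pid!r}; cell excluded", stacklevel=2)
            continue
        correct = correct_pointing(geoms[(pid, ct)])
        dep = np.nan
        if has_landing:
            sub = grp[grp["landing_x"].notna() & grp["landing_y"].notna()]
            if len(sub):
                props = []
                for _, row in sub.iterrows():
                    g = geoms[(pid, row["turn"])]
                    correct_d = float(np.hypot(*(g.S - g.E)))
                    resp_d = float(np.hypot(row["landing_x"] - g.E[0],
                                            row["landing_y"] - g.E[1]))
                    props.append(distance_error_proportion(correct_d, resp_d))
                dep = float(np.mean(props))
        rows.append({
            "participant_id": part,
            "condition": cond,
            "path_id": pid,
            "mean_response": mean_resp,
            "n_trials": len(grp),
            "AE_G": angular_error(mean_resp, correct),
            "distance_error_proportion": dep,
        })
    return pd.DataFrame(rows)
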