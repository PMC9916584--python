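"""Synthetic pointing experiments with the statistical structure the
analysis assumes.

The generator emulates a pointing-to-origin task on four-leg walked paths:
each subject carries a von Mises random angular offset, each trial response
is the hypothesis-predicted direction for the walked path plus subject
offset plus von Mises trial noise, a small fraction of trials are replaced
by uniform (discordant) responses, and remembered distances shrink by a
truncated-normal underestimation proportion. Responses are emitted in the
raw pre-flip convention (clockwise degrees in [0, 360) from the final
heading), with trials alternating between the left- and right-turn mirror
versions of each path shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .angles import wrap_signed
from .geometry import (
    CROSS,
    NO_CROSS_LONG_L3,
    NO_CROSS_SHORT_L4,
    PathSpec,
    build_path,
)
from .hypotheses import predict_range, range_mean

__all__ = [
    "SyntheticConfig",
    "make_study_paths",
    "generate_dataset",
    "DEFAULT_CONDITION_KAPPAS",
]

#: per-condition concentrations of subject-level means mirroring the spread
#: observed in the original study (conflict-cross conditions most diffuse,
#: matched uncrossed conditions in later experiments most concentrated)
DEFAULT_CONDITION_KAPPAS = {
    "HI-C": 0.7, "PG-C": 2.5, "TI-C": 1.7,
    "NI-NC": 2.0, "PG-NC": 1.3, "FI-NC": 7.8,
}

ARENA_BOUND = 3.4


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-level configuration of a synthetic experiment.

    ``condition_hypothesis`` maps each condition label to the hypothesis
    generating its responses. ``target_mode`` places the per-path target at
    the predicted range's Monte-Carlo mean (``"range_mean"``) or redraws it
    uniformly inside the range per trial (``"uniform_in_range"``).
    Concentrations: ``kappa_trial`` for trial noise, ``kappa_subject`` for
    the subject offset distribution (0 = uniform offsets). The distance
    underestimation proportion is truncated-normal on (-1, 1) with the
    stated mean/sd.
    """

    paths: Sequence[PathSpec]
    condition_hypothesis: Dict[str, str]
    n_subjects: int = 32
    trials_per_path: int = 4
    target_mode: str = "range_mean"
    kappa_trial: float = 4.0
    kappa_subject: float = 8.0
    contamination_rate: float = 0.02
    distance_underestimation: tuple = (0.29, 0.20)
    include_landing: bool = False
    experiment: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must be in [0, 1]")
        if self.kappa_trial < 0 or self.kappa_subject < 0:
            raise ValueError("concentrations must be >= 0")
        if self.target_mode not in ("range_mean", "uniform_in_range"):
            raise ValueError("target_mode must be 'range_mean' or "
                             "'uniform_in_range'")
        if self.n_subjects < 1 or self.trials_per_path < 1:
            raise ValueError("n_subjects and trials_per_path must be >= 1")


def _sample_crossed(rng: np.random.Generator) -> PathSpec:
    l1 = rng.uniform(2.4, ARENA_BOUND)
    l3 = rng.uniform(0.8, l1 - 0.4)
    l2 = rng.uniform(1.2, 2.5)
    l4 = rng.uniform(l2 + 0.4, ARENA_BOUND)
    return PathSpec((l1, l2, l3, l4), "left")


def _sample_uncrossed_short(rng: np.random.Generator) -> PathSpec:
    l1 = rng.uniform(2.4, ARENA_BOUND)
    l3 = rng.uniform(0.8, l1 - 0.4)
    l2 = rng.uniform(1.6, ARENA_BOUND)
    l4 = rng.uniform(0.8, l2 - 0.4)
    return PathSpec((l1, l2, l3, l4), "left")


def make_study_paths(experiment: int, seed=None,
                           n_per_class: int = 4) -> List[PathSpec]:
    """Path families mimicking the study's designs.

    Experiment 1 style: ``n_per_class`` crossed paths (L3 < L1, L4 > L2)
    plus as many uncrossed short-L4 paths, all legs <= 3.4 m. Experiment 2
    style: crossed paths paired with uncrossed long-L3 partners built by
    swapping L1 and L3, which exactly preserves total path length and
    end-to-start distance and mirrors the correct pointing angle.
    """
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    rng = np.random.default_rng(seed)
    specs: List[PathSpec] = []
    for i in range(n_per_class):
        for attempt in range(10_000):
            cand = _sample_crossed(rng)
            try:
                if build_path(cand).crossing_class == CROSS:
                    break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not construct a crossed path")
        cand = PathSpec(cand.leg_lengths, "left", path_id=f"P{i + 1}",
                        experiment_tag=f"exp{experiment}")
        specs.append(cand)
        if experiment == 2:
            l1, l2, l3, l4 = cand.leg_lengths
            partner = PathSpec((l3, l2, l1, l4), "left",
                               path_id=f"P{i + 1 + n_per_class}",
                               experiment_tag="exp2")
            assert build_path(partner).crossing_class == NO_CROSS_LONG_L3
            specs.append(partner)
    if experiment == 1:
        for i in range(n_per_class):
            for attempt in range(10_000):
                cand = _sample_uncrossed_short(rng)
                try:
                    if build_path(cand).crossing_class == NO_CROSS_SHORT_L4:
                        break
                except ValueError:
                    continue
            else:
                raise RuntimeError("could not construct an uncrossed path")
            specs.append(PathSpec(cand.leg_lengths, "left",
                                  path_id=f"P{i + 1 + n_per_class}",
                                  experiment_tag="exp1"))
    return specs


def _paths_for_condition(cond: str, paths: Sequence[PathSpec]):
    crossed = cond in ("HI-C", "PG-C", "TI-C")
    out = []
    for spec in paths:
        cls = build_path(spec).crossing_class
        if crossed and cls == CROSS:
            out.append(spec)
        elif not crossed and cls in (NO_CROSS_SHORT_L4, NO_CROSS_LONG_L3):
            out.append(spec)
    return out


def generate_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a raw trial table for every condition in the config.

    Deterministic for a fixed config (all draws come from one seeded
    generator consumed in a fixed order). Columns match what
    :func:`pointback.preprocess.summarize_trials` expects; landing
    coordinates and confidence are included when ``include_landing`` is
    set.
    """
    rng = np.random.default_rng(config.seed)
    mean_p, sd_p = config.distance_underestimation
    rows = []
    for cond in sorted(config.condition_hypothesis):
        hyp = config.condition_hypothesis[cond]
        cond_paths = _paths_for_condition(cond, config.paths)
        if not cond_paths:
            raise ValueError(f"no paths with the crossing class required by "
                             f"condition {cond!r}")
        geoms = {s.path_id: build_path(s) for s in cond_paths}
        intervals = {pid: predict_range(hyp, g) for pid, g in geoms.items()}
        targets = {pid: range_mean(iv, 1000, seed=rng)
                   for pid, iv in intervals.items()}
        for subj in range(config.n_subjects):
            offset = (np.degrees(rng.vonmises(0.0, config.kappa_subject))
                      if config.kappa_subject > 0
                      else rng.uniform(-180.0, 180.0))
            for spec in cond_paths:
                pid = spec.path_id
                for t in range(config.trials_per_path):
                    turn = "left" if t % 2 == 0 else "right"
                    if config.target_mode == "uniform_in_range":
                        target = float(intervals[pid].sample_uniform(1, rng)[0])
                    else:
                        target = targets[pid]
                    noise = np.degrees(rng.vonmises(0.0, config.kappa_trial))
                    resp = wrap_signed(target + offset + noise)
                    if rng.uniform() < config.contamination_rate:
                        resp = rng.uniform(-180.0, 180.0)
                    raw = resp if turn == "left" else -resp
                    raw = float(np.mod(raw, 360.0))
                    row = {
                        "participant_id": f"S{subj + 1:03d}",
                        "condition": cond,
                        "path_id": pid,
                        "trial_index": t,
                        "turn": turn,
                        "response_deg": raw,
                    }
                    if config.include_landing:
                        g = geoms[pid] if turn == "left" \
                            else build_path(spec.mirrored())
                        correct_d = float(np.hypot(*(g.S - g.E)))
                        p = _trunc_normal(rng, mean_p, sd_p)
                        resp_d = correct_d * (1.0 - p)
                        a = np.radians(raw)
                        h = g.final_heading
                        # rotate the heading clockwise by the raw angle
                        direction = np.array([
                            h[0] * np.cos(a) + h[1] * np.sin(a),
                            -h[0] * np.sin(a) + h[1] * np.cos(a),
                        ])
                        landing = g.E + resp_d * direction
                        row["landing_x"] = landing[0]
                        row["landing_y"] = landing[1]
                        row["confidence"] = float(np.clip(
                            rng.normal(0.6, 0.2), 0.0, 1.0))
                    rows.append(row)
    return pd.DataFrame(rows)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float = -1.0, hi: float = 1.0) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(np.clip(mean, lo + 1e-9, hi - 1e-9))
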