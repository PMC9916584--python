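"""Response canonicalization, circular averaging and angular errors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pointback.preprocess import (
    ZeroResultantError,
    angular_error,
    canonicalize_response,
    distance_error_proportion,
    per_path_mean,
    summarize_trials,
    to_signed,
)
from pointback.synth import SyntheticConfig, generate_dataset, make_study_paths


class TestToSigned:
    @pytest.mark.parametrize("raw, expected", [
        (270.0, -90.0), (0.0, 0.0), (180.0, 180.0), (359.0, -1.0),
    ])
    def test_examples(self, raw, expected):
        assert to_signed(raw) == expected

    @pytest.mark.parametrize("raw", [-1.0, 360.0, 720.0])
    def test_out_of_range(self, raw):
        with pytest.raises(ValueError):
            to_signed(raw)


class TestCanonicalize:
    def test_right_turn_trial_flipped(self):
        assert canonicalize_response(200.0, "right") == pytest.approx(160.0)

    def test_left_turn_trial_unchanged(self):
        assert canonicalize_response(200.0, "left") == pytest.approx(-160.0)

    def test_right_canonical_frame_flips_left(self):
        # path families whose reference chirality is right flip left trials
        assert canonicalize_response(200.0, "left", "right") == pytest.approx(160.0)
        assert canonicalize_response(200.0, "right", "right") == pytest.approx(-160.0)

    def test_unknown_chirality(self):
        with pytest.raises(ValueError, match="chirality"):
            canonicalize_response(10.0, "straight")


class TestPerPathMean:
    @pytest.mark.parametrize("angles, expected", [
        ([10, 350, 20, 340], 0.0),
        ([90, 90, 90, 90], 90.0),
    ])
    def test_examples(self, angles, expected):
        assert per_path_mean(angles) == pytest.approx(expected, abs=1e-9)

    def test_antipodal_pair_degenerate(self):
        with pytest.raises(ZeroResultantError):
            per_path_mean([0.0, 180.0])

    def test_matches_brute_force_atan2(self, rng):
        for _ in range(1000):
            a = rng.uniform(-180, 180, size=rng.integers(1, 9))
            expected = np.degrees(np.arctan2(np.sin(np.radians(a)).sum(),
                                             np.cos(np.radians(a)).sum()))
            if expected <= -180:
                expected += 360
            assert per_path_mean(a) == pytest.approx(expected, abs=1e-9)


class TestAngularError:
    @pytest.mark.parametrize("resp, correct, expected", [
        (100, 120, -20), (-170, 170, 20), (42, 42, 0),
    ])
    def test_examples(self, resp, correct, expected):
        assert angular_error(resp, correct) == pytest.approx(expected)

    @given(st.floats(-180, 180), st.floats(-180, 180),
           st.integers(-3, 3))
    def test_wrap_safety(self, a, b, k):
        assert angular_error(a + 360 * k, b) == pytest.approx(
            angular_error(a, b), abs=1e-6)


class TestDistanceError:
    @pytest.mark.parametrize("c, r, expected", [
        (2.0, 2.0, 0.0), (2.0, 1.0, 0.5), (2.0, 3.0, -0.5),
    ])
    def test_examples(self, c, r, expected):
        assert distance_error_proportion(c, r) == pytest.approx(expected)

    def test_invalid_distances(self):
        with pytest.raises(ValueError):
            distance_error_proportion(0.0, 1.0)
        with pytest.raises(ValueError):
            distance_error_proportion(2.0, -0.1)


def _small_dataset(seed=1, include_landing=False):
    paths = make_study_paths(1, seed=seed)
    cfg = SyntheticConfig(
        paths=paths, condition_hypothesis={"HI-C": "CtoC", "NI-NC": "NtoN1"},
        n_subjects=6, contamination_rate=0.0, include_landing=include_landing,
        seed=seed)
    return generate_dataset(cfg), {p.path_id: p for p in paths}


class TestSummarizeTrials:
    def test_missing_column_named_in_error(self):
        trials, specs = _small_dataset()
        with pytest.raises(ValueError, match="response_deg"):
            summarize_trials(trials.drop(columns=["response_deg"]), specs)

    def test_unknown_path_rejected(self):
        trials, specs = _small_dataset()
        bad = trials.copy()
        bad.loc[0, "path_id"] = "nope"
        with pytest.raises(ValueError, match="nope"):
            summarize_trials(bad, specs)

    def test_pipeline_mirror_invariance(self):
        """Mirroring every trial (chirality and response sign) yields
        identical summaries: the flip rule maps mirror paths back onto the
        canonical chirality."""
        trials, specs = _small_dataset()
        mirrored = trials.copy()
        mirrored["turn"] = np.where(trials["turn"] == "left", "right", "left")
        mirrored["response_deg"] = np.mod(-trials["response_deg"], 360.0)
        a = summarize_trials(trials, specs)
        b = summarize_trials(mirrored, specs)
        assert np.allclose(a["AE_G"], b["AE_G"], atol=1e-9)
        assert np.allclose(a["mean_response"], b["mean_response"], atol=1e-9)

    def test_mirrored_frame_reflects_summaries(self):
        """Analyzing the same data in the mirrored canonical chirality
        reflects every signed summary."""
        trials, specs = _small_dataset()
        a = summarize_trials(trials, specs, canonical_turn="left")
        b = summarize_trials(trials, specs, canonical_turn="right")
        assert np.allclose(a["AE_G"], -b["AE_G"], atol=1e-9)
        assert np.allclose(a["mean_response"], -b["mean_response"], atol=1e-9)

    def test_landing_coordinates_recover_angles(self):
        """Dropping the explicit angles and recomputing them from landing
        coordinates reproduces the same summaries."""
        trials, specs = _small_dataset(include_landing=True)
        implicit = trials.copy()
        implicit["response_deg"] = np.nan
        a = summarize_trials(trials, specs)
        b = summarize_trials(implicit, specs)
        assert np.allclose(a["mean_response"], b["mean_response"], atol=1e-6)
        assert np.allclose(a["distance_error_proportion"],
                           b["distance_error_proportion"], atol=1e-9)

    def test_distance_error_reported(self):
        trials, specs = _small_dataset(include_landing=True)
        summ = summarize_trials(trials, specs)
        dep = summ["distance_error_proportion"].dropna()
        assert len(dep) == len(summ)
        # the generator underestimates distances on average
        assert 0.0 < dep.mean() < 0.6

    def test_degenerate_cell_excluded_with_warning(self, crossed_spec):
        trials = pd.DataFrame({
            "participant_id": ["p1"] * 2,
            "condition": ["HI-C"] * 2,
            "path_id": ["cross-ex"] * 2,
            "trial_index": [0, 1],
            "turn": ["left", "left"],
            "response_deg": [10.0, 190.0],  # antipodal
        })
        with pytest.warns(UserWarning, match="degenerate"):
            out = summarize_trials(trials, {"cross-ex": crossed_spec})
        assert out.empty
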