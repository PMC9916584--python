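"""Projected-normal MCMC, HPD arcs and overlap-ratio hypothesis scoring."""

import numpy as np
import pytest
from scipy import stats

from pointback.angles import AngularInterval, wrap_signed
from pointback.bayes_fit import (
    ProjectedNormalMixedEffects,
    compare_hypotheses,
    compare_per_participant,
    hpd_interval,
    overlap_ratio,
)
from pointback.geometry import build_path
from pointback.preprocess import canonicalize_response, summarize_trials
from pointback.synth import SyntheticConfig, generate_dataset, make_study_paths


def _one_cell_data(true_deg=135.0, kappa=4.0, n_subj=30, per_subj=4, seed=0):
    rng = np.random.default_rng(seed)
    subj = np.repeat(np.arange(n_subj), per_subj)
    offsets = np.degrees(rng.vonmises(0, 8.0, n_subj))
    y = wrap_signed(true_deg + offsets[subj]
                    + np.degrees(rng.vonmises(0, kappa, subj.size)))
    X = np.column_stack([np.zeros_like(subj), subj])
    return X, y


class TestSampler:
    def test_single_cell_recovery(self):
        X, y = _one_cell_data()
        est = ProjectedNormalMixedEffects(random_state=1).fit(X, y)
        assert est.posterior_mean_direction(0.0) == pytest.approx(135.0, abs=5.0)
        assert est.converged_

    def test_rotation_equivariance(self):
        X, y = _one_cell_data()
        a = ProjectedNormalMixedEffects(random_state=1).fit(X, y)
        b = ProjectedNormalMixedEffects(random_state=1).fit(
            X, wrap_signed(y + 30.0))
        assert wrap_signed(b.posterior_mean_direction(0.0)
                           - a.posterior_mean_direction(0.0)) == pytest.approx(
            30.0, abs=1.0)

    def test_deterministic_under_seed(self):
        X, y = _one_cell_data()
        a = ProjectedNormalMixedEffects(random_state=9).fit(X, y)
        b = ProjectedNormalMixedEffects(random_state=9).fit(X, y)
        assert np.array_equal(a.direction_draws_, b.direction_draws_)

    def test_single_subject_random_effect_rejected(self):
        X, y = _one_cell_data(n_subj=1, per_subj=20)
        with pytest.raises(ValueError, match="subjects"):
            ProjectedNormalMixedEffects(random_state=0).fit(X, y)

    def test_draw_count_and_shapes(self):
        X, y = _one_cell_data()
        est = ProjectedNormalMixedEffects(
            n_iterations=600, burn_in=100, random_state=0).fit(X, y)
        assert est.direction_draws_.shape == (500, 1)
        assert est.coef_draws_.shape == (500, 1, 2)
        assert est.re_var_draws_.shape == (500, 2)


class TestHPD:
    def test_degenerate_draws(self):
        iv = hpd_interval(np.full(200, 40.0))
        assert iv.from_deg == iv.to_deg == 40.0
        assert iv.width == 0.0

    def test_matches_analytic_von_mises_quantiles(self, rng):
        draws = np.degrees(rng.vonmises(np.radians(90), 4.0, 10_000))
        iv = hpd_interval(draws)
        half = np.degrees(stats.vonmises.ppf(0.975, 4.0))
        assert iv.from_deg == pytest.approx(90 - half, abs=3.0)
        assert iv.to_deg == pytest.approx(90 + half, abs=3.0)

    def test_mass_nesting(self, rng):
        draws = np.degrees(rng.vonmises(0, 4.0, 5000))
        inner = hpd_interval(draws, mass=0.5)
        outer = hpd_interval(draws, mass=0.95)
        assert outer.contains(inner.from_deg) and outer.contains(inner.to_deg)
        assert inner.width < outer.width

    def test_dispersed_draws_rejected(self, rng):
        with pytest.raises(ValueError, match="dispersed"):
            hpd_interval(rng.uniform(-180, 180, 1000))

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            hpd_interval(np.zeros(50))

    def test_wraps_across_seam(self, rng):
        draws = wrap_signed(180.0 + np.degrees(rng.vonmises(0, 8.0, 2000)))
        iv = hpd_interval(draws)
        assert iv.contains(180.0)
        assert iv.width < 120.0


class TestOverlapRatio:
    @pytest.mark.parametrize("hpd, pred, expected", [
        ((100, 140), (90, 180), 1.0),     # containment
        ((-60, -20), (90, 180), 0.0),     # disjoint
        ((80, 120), (90, 180), 0.75),     # partial: 30 of 40 degrees
    ])
    def test_examples(self, hpd, pred, expected):
        assert overlap_ratio(AngularInterval(*hpd),
                             AngularInterval(*pred)) == pytest.approx(expected)

    def test_joint_rotation_invariance(self, rng):
        for _ in range(50):
            f1, w1 = rng.uniform(-180, 180), rng.uniform(5, 120)
            f2, w2 = rng.uniform(-180, 180), rng.uniform(5, 120)
            rot = rng.uniform(-180, 180)
            a = overlap_ratio(AngularInterval(f1, f1 + w1),
                              AngularInterval(f2, f2 + w2))
            b = overlap_ratio(AngularInterval(f1 + rot, f1 + w1 + rot),
                              AngularInterval(f2 + rot, f2 + w2 + rot))
            assert a == pytest.approx(b, abs=1e-9)


class TestCompareHypotheses:
    @pytest.mark.parametrize("cond, exp, hyp", [
        ("HI-C", 1, "CtoN1"),
        ("NI-NC", 1, "NtoN1"),
        ("FI-NC", 2, "NtoC3"),
    ])
    def test_end_to_end_recovery(self, cond, exp, hyp):
        seed = 77
        paths = make_study_paths(exp, seed=seed)
        cfg = SyntheticConfig(paths=paths, condition_hypothesis={cond: hyp},
                              experiment=exp, seed=seed)
        trials = generate_dataset(cfg)
        specs = {p.path_id: p for p in paths}
        summ = summarize_trials(trials, specs)
        sub = summ[summ["condition"] == cond]
        geoms = {pid: build_path(specs[pid]) for pid in sub["path_id"].unique()}
        res = compare_hypotheses(sub, cond, geoms, experiment=exp, seed=seed)
        assert res.best_hypothesis == (hyp,)
        assert res.mean_ratio[hyp] > 0.8
        assert all(0.0 <= v <= 1.0 for v in res.mean_ratio.values())

    def test_unknown_condition_rejected(self, crossed_geom):
        import pandas as pd
        df = pd.DataFrame({"path_id": [], "participant_id": [],
                           "mean_response": []})
        with pytest.raises(ValueError, match="unknown condition"):
            compare_hypotheses(df, "bogus", {})


class TestComparePerParticipant:
    def _participant_trials(self, seed=3):
        import pandas as pd
        paths = make_study_paths(1, seed=seed)
        crossed = [p for p in paths if build_path(p).crossing_class == "cross"]
        cfg = SyntheticConfig(paths=crossed,
                              condition_hypothesis={"TI-C": "CtoC"},
                              n_subjects=1, trials_per_path=12,
                              contamination_rate=0.0, seed=seed)
        trials = generate_dataset(cfg)
        trials["response_canonical"] = [
            canonicalize_response(r, t)
            for r, t in zip(trials["response_deg"], trials["turn"])]
        geoms = {p.path_id: build_path(p) for p in crossed}
        return trials, geoms

    def test_recovery_and_determinism(self):
        trials, geoms = self._participant_trials()
        res1 = compare_per_participant(trials, "S001", "TI-C", geoms, seed=5)
        res2 = compare_per_participant(trials, "S001", "TI-C", geoms, seed=5)
        assert res1.best_hypothesis == ("CtoC",)
        assert res1.mean_ratio == res2.mean_ratio
        assert all(0.0 <= v <= 1.0 for v in res1.mean_ratio.values())

    def test_too_few_trials_rejected(self):
        trials, geoms = self._participant_trials()
        with pytest.raises(ValueError, match=">= 16"):
            compare_per_participant(trials.head(10), "S001", "TI-C", geoms)
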