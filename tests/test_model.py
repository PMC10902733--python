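from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import hfrmrp as h
from hfrmrp.bart import BartSettings

from conftest import tiny_frame

FAST_BART = h.EngineSettings(engine="bart", bart=BartSettings(n_trees=30, n_burn=150, n_draws=200, thin=1))
LOGISTIC = h.EngineSettings(engine="logistic", n_draws=400)


def _flat_smoothed(frame, years, value=0.5):
    vals = np.full((len(frame), len(years)), value)
    return h.SmoothedFSS(frame=frame, years=tuple(years), values=vals)


@pytest.fixture(scope="module")
def small_world():
    """A 3-state synthetic world small enough for repeated fitting."""
    f = tiny_frame(3)
    cfg = replace(
        h.SyntheticConfig(),
        small_wave_n=(400,) * 16,
        large_n=(1500,) * 3,
        seed=101,
    )
    truth = h.generate_truth_surface(cfg, f)
    pop = h.generate_population(cfg, f)
    micro = h.simulate_survey_microdata(truth, pop, cfg)
    sm = _flat_smoothed(f, truth.years)
    return f, cfg, truth, pop, micro, sm


class TestAssembleDesign:
    def test_complete_records_all_kept(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        inputs = h.assemble_design(micro.head(10), sm, f)
        assert inputs.n == 10
        assert sum(inputs.dropped.values()) == 0

    def test_unknown_state_dropped_and_counted(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        bad = micro.head(10).copy()
        bad.loc[bad.index[3], "state"] = "XX"
        inputs = h.assemble_design(bad, sm, f)
        assert inputs.n == 9
        assert inputs.dropped["unknown_code"] == 1

    def test_missing_field_dropped_and_counted(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        bad = micro.head(10).copy()
        bad.loc[bad.index[0], "gender"] = np.nan
        inputs = h.assemble_design(bad, sm, f)
        assert inputs.n == 9
        assert inputs.dropped["missing_field"] == 1

    def test_fss_column_matches_surface_on_join_keys(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.2, 0.8, size=(len(f), len(truth.years)))
        surface = h.SmoothedFSS(frame=f, years=truth.years, values=vals)
        sub = micro.head(50)
        inputs = h.assemble_design(sub, surface, f)
        col = inputs.columns.index("smoothed_fss")
        pos = f.positions(sub)
        yidx = np.searchsorted(truth.years, sub["year"].to_numpy())
        np.testing.assert_array_equal(inputs.X[:, col], vals[pos, yidx])

    def test_missing_surface_year_is_an_error(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        short = h.SmoothedFSS(
            frame=f, years=truth.years[:5], values=np.full((len(f), 5), 0.5)
        )
        # years beyond the surface are dropped as out-of-window, not silently
        # joined; a surface missing an in-window year is impossible by
        # construction, so emulate via direct lookup
        with pytest.raises(h.ValidationError, match="2018"):
            short.lookup(np.zeros(1, dtype=int), np.array([2018]))


class TestFitAndPredict:
    def test_main_effects_recovery_logistic(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        inputs = h.assemble_design(micro, sm, f)
        model = h.fit_hfr_model(inputs, LOGISTIC, seed=1)
        post = h.predict_strata_probabilities(model, f, truth.years, sm)
        # window endpoints are the hardest cells at this reduced sample size
        for year in (1990, 2018):
            est = h.aggregate(post, pop, None, year)
            assert abs(est.estimate - h.true_hfr(truth, pop, None, year)) < 0.03

    def test_main_effects_recovery_bart(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        inputs = h.assemble_design(micro, sm, f)
        model = h.fit_hfr_model(inputs, FAST_BART, seed=2)
        post = h.predict_strata_probabilities(model, f, truth.years, sm)
        for year in (1990, 2018):
            est = h.aggregate(post, pop, None, year)
            assert abs(est.estimate - h.true_hfr(truth, pop, None, year)) < 0.03

    def test_engines_agree_on_national_estimates(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        inputs = h.assemble_design(micro, sm, f)
        post_l = h.predict_strata_probabilities(
            h.fit_hfr_model(inputs, LOGISTIC, seed=3), f, truth.years, sm
        )
        post_b = h.predict_strata_probabilities(
            h.fit_hfr_model(inputs, FAST_BART, seed=3), f, truth.years, sm
        )
        for year in (1995, 2010):
            a = h.aggregate(post_l, pop, None, year).estimate
            b = h.aggregate(post_b, pop, None, year).estimate
            assert abs(a - b) < 0.03

    def test_duplicated_data_narrows_intervals(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        sub = micro.sample(4000, random_state=1).reset_index(drop=True)
        doubled = pd.concat([sub, sub], ignore_index=True)
        posts = []
        for data in (sub, doubled):
            inputs = h.assemble_design(data, sm, f)
            model = h.fit_hfr_model(inputs, LOGISTIC, seed=4)
            posts.append(h.predict_strata_probabilities(model, f, truth.years, sm))
        est1 = h.aggregate(posts[0], pop, None, 2000)
        est2 = h.aggregate(posts[1], pop, None, 2000)
        assert abs(est1.estimate - est2.estimate) < 0.02
        assert (est2.hi95 - est2.lo95) < (est1.hi95 - est1.lo95)

    def test_same_seed_identical_posterior(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        inputs = h.assemble_design(micro.head(3000), sm, f)
        a = h.fit_hfr_model(inputs, LOGISTIC, seed=5)
        b = h.fit_hfr_model(inputs, LOGISTIC, seed=5)
        pa = h.predict_strata_probabilities(a, f, truth.years, sm)
        pb = h.predict_strata_probabilities(b, f, truth.years, sm)
        np.testing.assert_array_equal(pa.draws, pb.draws)

    def test_constant_outcome_rejected(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        flat = micro.head(100).copy()
        flat["response"] = 1
        inputs = h.assemble_design(flat, sm, f)
        with pytest.raises(h.ValidationError, match="constant outcome"):
            h.fit_hfr_model(inputs, LOGISTIC)

    def test_empty_strata_still_predicted(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        # remove every respondent from one stratum entirely
        pos = f.positions(micro)
        keep = pos != 0
        inputs = h.assemble_design(micro[keep], sm, f)
        model = h.fit_hfr_model(inputs, LOGISTIC, seed=6)
        post = h.predict_strata_probabilities(model, f, truth.years, sm)
        cell = post.draws[:, 0, :]
        assert ((cell > 0) & (cell < 1)).all()

    def test_without_fss_covariate(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        inputs = h.assemble_design(micro, None, f, include_fss=False)
        assert "smoothed_fss" not in inputs.columns
        model = h.fit_hfr_model(inputs, LOGISTIC, seed=7)
        post = h.predict_strata_probabilities(model, f, truth.years, None)
        est = h.aggregate(post, pop, None, 2000)
        assert 0 < est.lo95 <= est.estimate <= est.hi95 < 1

    def test_reference_survey_level_is_a_knob(self, small_world):
        f, cfg, truth, pop, micro, sm = small_world
        inputs = h.assemble_design(micro, sm, f)
        model = h.fit_hfr_model(inputs, LOGISTIC, seed=8)
        post_ip = h.predict_strata_probabilities(model, f, truth.years, sm, "in_person")
        post_tel = h.predict_strata_probabilities(model, f, truth.years, sm, "telephone")
        a = h.aggregate(post_ip, pop, None, 2002).estimate
        b = h.aggregate(post_tel, pop, None, 2002).estimate
        # generator puts a positive mode effect on the telephone survey
        assert b > a

    def test_posterior_round_trip(self, small_world, tmp_path):
        f, cfg, truth, pop, micro, sm = small_world
        inputs = h.assemble_design(micro.head(3000), sm, f)
        model = h.fit_hfr_model(inputs, LOGISTIC, seed=9)
        post = h.predict_strata_probabilities(model, f, truth.years, sm)
        post.save(tmp_path / "post.npz")
        back = h.HFRPosterior.load(tmp_path / "post.npz", f)
        np.testing.assert_allclose(back.draws, post.draws, atol=1e-7)
        assert back.years == post.years
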