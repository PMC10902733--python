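import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hfrmrp as h

from conftest import tiny_frame


def _post(frame, years, surface, n_draws=5, jitter=0.0, seed=0):
    surface = np.asarray(surface, dtype=float)
    if jitter:
        rng = np.random.default_rng(seed)
        draws = np.clip(
            surface[None] + rng.normal(0, jitter, size=(n_draws,) + surface.shape),
            1e-4, 1 - 1e-4,
        )
    else:
        draws = np.repeat(surface[None], n_draws, axis=0)
    return h.HFRPosterior(frame=frame, years=tuple(years), draws=draws)


def _two_stratum_world():
    """One state, only two populated strata, for hand-checked arithmetic."""
    f = tiny_frame(1, urban_free=("ZA",))
    years = (1990, 2018)
    counts = np.zeros((len(f), 2), dtype=int)
    counts[0] = [50, 30]     # w: 0.5 -> 0.3
    counts[1] = [50, 70]     # w: 0.5 -> 0.7
    pop = h.PopulationTable(frame=f, years=years, counts=counts)
    surface = np.full((len(f), 2), 0.5)
    surface[0] = [0.6, 0.5]
    surface[1] = [0.2, 0.2]
    return f, years, pop, surface


class TestTemporalDecomposition:
    def test_hand_checked_two_stratum_example(self):
        f, years, pop, surface = _two_stratum_world()
        post = _post(f, years, surface)
        d = h.decompose_temporal(post, pop, "ZA", 1990, 2018)
        assert d.total == pytest.approx(-0.11, abs=1e-12)
        assert d.rate_component == pytest.approx(-0.05, abs=1e-12)
        assert d.composition_component == pytest.approx(-0.06, abs=1e-12)

    def test_brute_force_recomputation(self):
        f, years, pop, surface = _two_stratum_world()
        post = _post(f, years, surface)
        d = h.decompose_temporal(post, pop, "ZA", 1990, 2018)
        # independent recomputation straight from the definition
        w0 = pop.counts[:, 0] / pop.counts[:, 0].sum()
        w1 = pop.counts[:, 1] / pop.counts[:, 1].sum()
        total = w1 @ surface[:, 1] - w0 @ surface[:, 0]
        rate = w0 @ (surface[:, 1] - surface[:, 0])
        assert d.total == pytest.approx(total, abs=1e-15)
        assert d.rate_component == pytest.approx(rate, abs=1e-15)

    def test_constant_rates_put_all_change_in_composition(self):
        f, years, pop, _ = _two_stratum_world()
        surface = np.full((len(f), 2), 0.5)
        surface[0] = [0.6, 0.6]
        surface[1] = [0.2, 0.2]
        post = _post(f, years, surface)
        d = h.decompose_temporal(post, pop, "ZA", 1990, 2018)
        assert d.rate_component == pytest.approx(0.0, abs=1e-15)
        assert d.composition_component == pytest.approx(d.total, abs=1e-15)
        assert d.total != 0

    def test_constant_weights_put_all_change_in_rates(self):
        f = tiny_frame(1, urban_free=("ZA",))
        years = (1990, 2018)
        counts = np.tile([[40], [60]] + [[10]] * (len(f) - 2), (1, 2)).astype(int)
        pop = h.PopulationTable(frame=f, years=years, counts=counts)
        surface = np.column_stack([np.full(len(f), 0.5), np.full(len(f), 0.35)])
        post = _post(f, years, surface)
        d = h.decompose_temporal(post, pop, "ZA", 1990, 2018)
        assert d.composition_component == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_variant_preserves_identity(self):
        f, years, pop, surface = _two_stratum_world()
        post = _post(f, years, surface)
        d = h.decompose_temporal(post, pop, "ZA", 1990, 2018, symmetric=True)
        assert d.rate_component + d.composition_component == pytest.approx(d.total, abs=1e-15)

    def test_per_draw_components_match_point_decomposition(self):
        f, years, pop, surface = _two_stratum_world()
        post = _post(f, years, surface, n_draws=400, jitter=0.02, seed=3)
        point = h.decompose_temporal(post, pop, "ZA", 1990, 2018)
        per_draw = h.decompose_temporal_draws(post, pop, "ZA", 1990, 2018)
        assert per_draw["total"].mean() == pytest.approx(point.total, abs=5e-3)
        assert per_draw["rate"].mean() == pytest.approx(point.rate_component, abs=5e-3)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_additive_identity_on_random_inputs(self, seed):
        f = tiny_frame(2)
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 1000, size=(len(f), 2))
        pop = h.PopulationTable(frame=f, years=(1990, 2018), counts=counts)
        surface = rng.uniform(0.05, 0.95, size=(len(f), 2))
        post = _post(f, (1990, 2018), surface)
        for unit in (None, "ZA", "ZB"):
            d = h.decompose_temporal(post, pop, unit, 1990, 2018)
            assert abs(d.rate_component + d.composition_component - d.total) < 1e-12


class TestStateVsNational:
    def test_identity_holds_for_every_state(self, frame, pop, posterior_degenerate):
        year = posterior_degenerate.years[0]
        national = h.aggregate(posterior_degenerate, pop, None, year).estimate
        for state in frame.states:
            d = h.decompose_state_vs_national(posterior_degenerate, pop, state, year)
            direct = h.aggregate(posterior_degenerate, pop, {"state": state}, year).estimate
            assert d.total == pytest.approx(direct - national, abs=1e-12)
            assert d.rate_component + d.composition_component == pytest.approx(d.total, abs=1e-12)

    def test_average_composition_and_rates_give_zero_components(self):
        # all states share the same rates and cell composition
        f = tiny_frame(3, urban_free=())
        years = (2000,)
        base = np.arange(1, 17) * 10
        counts = np.tile(base, 3)[:, None].astype(int)
        pop = h.PopulationTable(frame=f, years=years, counts=counts)
        cell_p = np.linspace(0.2, 0.6, 16)
        surface = np.tile(cell_p, 3)[:, None]
        post = _post(f, years, surface)
        for state in f.states:
            d = h.decompose_state_vs_national(post, pop, state, 2000)
            assert d.total == pytest.approx(0.0, abs=1e-12)
            assert d.rate_component == pytest.approx(0.0, abs=1e-12)

    def test_composition_only_difference_has_zero_rate_component(self):
        # same rates everywhere; one state has a different cell mix
        f = tiny_frame(2, urban_free=())
        years = (2000,)
        counts = np.tile(np.arange(1, 17) * 10, 2)[:, None].astype(int)
        counts[:16] = np.arange(16, 0, -1)[:, None] * 10   # ZA reversed mix
        pop = h.PopulationTable(frame=f, years=years, counts=counts)
        cell_p = np.linspace(0.2, 0.6, 16)
        surface = np.tile(cell_p, 2)[:, None]
        post = _post(f, years, surface)
        d = h.decompose_state_vs_national(post, pop, "ZA", 2000)
        assert d.rate_component == pytest.approx(0.0, abs=1e-12)
        assert d.total != 0


class TestVariancePartition:
    def _surface_from_effects(self, frame, years, state_amp=0.0, race_amp=0.0, seed=0):
        rng = np.random.default_rng(seed)
        states = frame.states
        eff = {s: rng.normal(0, state_amp) for s in states}
        base = frame.table["state"].map(eff).to_numpy()
        if race_amp:
            base = base + np.where(frame.table["race"] == "white_aian", race_amp, 0.0)
        return 0.4 + np.tile(base[:, None], (1, len(years)))

    def test_pure_state_effects_attributed_to_state(self, frame):
        years = np.arange(1990, 1996)
        surface = self._surface_from_effects(frame, years, state_amp=0.05, seed=1)
        vp = h.variance_partition(surface, frame, years, interactions=[])
        assert vp.total_r2 > 0.999
        assert vp.contributions["state"] == pytest.approx(vp.total_r2, abs=0.01)
        others = sum(v for k, v in vp.contributions.items() if k != "state")
        assert others < 0.01

    def test_contributions_sum_to_main_effects_r2(self, frame):
        years = np.arange(1990, 1996)
        rng = np.random.default_rng(2)
        surface = np.clip(
            self._surface_from_effects(frame, years, 0.05, 0.08, seed=2)
            + rng.normal(0, 0.02, size=(len(frame), len(years))),
            0.01, 0.99,
        )
        vp = h.variance_partition(surface, frame, years)
        assert sum(vp.contributions.values()) == pytest.approx(vp.total_r2, abs=1e-10)
        assert all(v >= -1e-12 for v in vp.contributions.values())

    def test_adding_interaction_never_decreases_r2(self, frame):
        years = np.arange(1990, 1996)
        rng = np.random.default_rng(3)
        surface = np.clip(
            rng.uniform(0.2, 0.6, size=(len(frame), len(years))), 0.01, 0.99
        )
        vp = h.variance_partition(surface, frame, years, interactions=[("gender", "marital")])
        assert vp.r2_with_interactions >= vp.total_r2 - 1e-12

    def test_degenerate_factor_dropped_with_warning(self):
        f = tiny_frame(2, urban_free=("ZA", "ZB"))     # no urban strata at all
        years = np.arange(2000, 2003)
        rng = np.random.default_rng(4)
        surface = rng.uniform(0.2, 0.6, size=(len(f), len(years)))
        with pytest.warns(UserWarning, match="urbanicity"):
            vp = h.variance_partition(surface, f, years, interactions=[])
        assert "urbanicity" in vp.dropped_factors
        assert "urbanicity" not in vp.contributions

    def test_weighted_variant_runs_and_differs(self, frame, pop):
        years = np.arange(1990, 1993)
        rng = np.random.default_rng(5)
        surface = rng.uniform(0.2, 0.6, size=(len(frame), len(years)))
        vp_u = h.variance_partition(surface, frame, years, interactions=[])
        vp_w = h.variance_partition(
            surface, frame, years, interactions=[], weights=pop.counts[:, :3]
        )
        assert vp_w.total_r2 != pytest.approx(vp_u.total_r2, abs=1e-12)


class TestCompositionDrivenDecline:
    def test_flat_rates_strong_drift_yields_composition_dominance(self):
        """With frozen within-strata rates and strong drift, composition
        explains essentially all of the decline in every state."""
        from dataclasses import replace

        f = tiny_frame(3)
        cfg = replace(
            h.SyntheticConfig(),
            year_trend=0.0,
            urban_drift=0.008, unmarried_drift=0.009, minority_drift=0.006,
            seed=55,
        )
        truth = h.generate_truth_surface(cfg, f)
        pop = h.generate_population(cfg, f)
        post = _post(f, truth.years, truth.p)
        for state in f.states:
            d = h.decompose_temporal(post, pop, state, 1990, 2018)
            assert d.total < 0
            assert d.composition_component / d.total > 0.9
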