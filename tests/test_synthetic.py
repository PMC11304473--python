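"""Synthetic landscape generators and the surrogate emission model."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from paddyghg.synthetic import (
    ArchetypeSpec,
    DRY_ARCHETYPES,
    DRY_SEASON,
    SurrogateParams,
    WET_ARCHETYPES,
    WET_SEASON,
    ch4_from_drivers,
    generate_landscape,
    generate_soils,
    generate_water_series,
    surrogate_emissions,
)
from paddyghg.descriptors import compute_descriptors
from paddyghg.types import FieldSoil, Management, NApplication

from conftest import make_series

NOISE_FREE = SurrogateParams(ch4_noise_sd_log=0.0, n2o_noise_sd_log=0.0)


def _mgmt(residue=0.0, n_total=125.0):
    scale = n_total / 125.0
    return Management(
        sowing_date=date(2022, 7, 1),
        harvest_date=date(2022, 10, 28),
        n_schedule=[NApplication(0, 25 * scale), NApplication(25, 50 * scale),
                    NApplication(55, 50 * scale)],
        residue_fraction=residue,
    )


SOIL = FieldSoil("s", clay_pct=30, silt_pct=40, sand_pct=30, ph=7.0, oc_pct=0.8)


class TestWaterGenerator:
    def test_same_seed_bit_identical(self):
        a = generate_water_series(WET_ARCHETYPES[0], 5, WET_SEASON, seed=9)
        b = generate_water_series(WET_ARCHETYPES[0], 5, WET_SEASON, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.level_cm, y.level_cm)
            np.testing.assert_array_equal(x.censored, y.censored)

    def test_wettest_wet_archetype_floods_more_than_driest_dry(self):
        wet = generate_water_series(WET_ARCHETYPES[4], 50, WET_SEASON, seed=1)
        dry = generate_water_series(DRY_ARCHETYPES[0], 50, DRY_SEASON, seed=1)
        a1_wet = np.mean([compute_descriptors(s).A1 for s in wet])
        a1_dry = np.mean([compute_descriptors(s).A1 for s in dry])
        assert a1_wet > a1_dry

    def test_never_flooded_archetype_has_zero_a1(self):
        arch = ArchetypeSpec("never", ((0, -12.0), (119, -12.0)),
                             noise_sd_cm=0.0, ar1_rho=0.0,
                             irrigation_rate_per_week=0.0,
                             irrigation_pulse_cm=1.0, recession_cm_per_day=1.0)
        for s in generate_water_series(arch, 10, DRY_SEASON, seed=2):
            assert compute_descriptors(s).A1 == 0.0

    def test_levels_clamped_and_censored(self):
        for arch in WET_ARCHETYPES + DRY_ARCHETYPES:
            season = WET_SEASON if arch.name.startswith("wet") else DRY_SEASON
            for s in generate_water_series(arch, 3, season, seed=3):
                assert s.level_cm.min() >= -15.0
                assert s.level_cm.max() <= 25.0
                assert (s.level_cm[s.censored] == -15.0).all()

    def test_short_season_rejected(self):
        with pytest.raises(ValueError, match="60 days"):
            generate_water_series(WET_ARCHETYPES[0], 1,
                                  (date(2021, 7, 1), date(2021, 7, 30)), seed=0)


class TestSoilGenerator:
    def test_invariants_hold(self):
        soils = generate_soils(100, seed=4)
        assert len(soils) == 100
        total = soils[["clay_pct", "silt_pct", "sand_pct"]].sum(axis=1)
        np.testing.assert_allclose(total, 100.0, atol=1e-9)
        assert soils["clay_pct"].between(10, 45).all()
        assert soils["oc_pct"].between(0.3, 1.5).all()

    def test_bd_fraction(self):
        none = generate_soils(50, seed=5, fraction_with_bd=0.0)
        assert none["bd_g_cm3"].isna().all()
        all_ = generate_soils(50, seed=5, fraction_with_bd=1.0)
        assert all_["bd_g_cm3"].notna().all()

    def test_deterministic(self):
        pd.testing.assert_frame_equal(generate_soils(30, seed=6),
                                      generate_soils(30, seed=6))


class TestSurrogate:
    def test_zero_flooding_gives_zero_ch4(self):
        s = make_series([-12.0] * 120)
        rec = surrogate_emissions(s, SOIL, _mgmt(), NOISE_FREE, rng=None)
        assert rec.ch4_kg_ha == 0.0

    def test_ch4_monotone_in_each_driver(self):
        p = SurrogateParams()
        grid = np.linspace(0, 1, 11)
        for a4, r in ((0.3, 0.5),):
            vals = [ch4_from_drivers(a1, a4, r, p) for a1 in grid]
            assert all(x < y for x, y in zip(vals, vals[1:]))
        vals = [ch4_from_drivers(0.5, a4, 0.2, p) for a4 in grid]
        assert all(x < y for x, y in zip(vals, vals[1:]))
        vals = [ch4_from_drivers(0.5, 0.3, r, p) for r in grid]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_doubling_n_increases_n2o(self):
        s = make_series([-3.0] * 120, start="2022-07-06")
        lo = surrogate_emissions(s, SOIL, _mgmt(n_total=125), NOISE_FREE, rng=None)
        hi = surrogate_emissions(s, SOIL, _mgmt(n_total=250), NOISE_FREE, rng=None)
        assert hi.n2o_g_ha > lo.n2o_g_ha

    def test_flooded_application_suppressed(self):
        # flooded on every in-window application day -> only the pre-window
        # basal dose contributes
        flooded = make_series([5.0] * 120, start="2022-07-06")
        drained = make_series([-3.0] * 120, start="2022-07-06")
        f = surrogate_emissions(flooded, SOIL, _mgmt(), NOISE_FREE, rng=None)
        d = surrogate_emissions(drained, SOIL, _mgmt(), NOISE_FREE, rng=None)
        assert f.n2o_g_ha < d.n2o_g_ha
        # constant series: no transitions; doses 25/50/50 with the two
        # top dressings suppressed under flooding
        clay_term = 1 + 0.5 * SOIL.clay_pct / 100
        assert f.n2o_g_ha == pytest.approx((10 + 1.2 * 25) * clay_term)
        assert d.n2o_g_ha == pytest.approx((10 + 1.2 * 125) * clay_term)

    def test_gamma_recovered_by_loglog_regression(self):
        # shallow series (never above 10 cm) so the deep-water term is inert
        p = NOISE_FREE
        a1s, ch4s = [], []
        for m in range(10, 110, 10):
            s = make_series([5.0] * m + [-12.0] * (120 - m))
            rec = surrogate_emissions(s, SOIL, _mgmt(), p, rng=None)
            a1s.append(m / 120)
            ch4s.append(rec.ch4_kg_ha)
        slope, intercept = np.polyfit(np.log(a1s), np.log(ch4s), 1)
        assert slope == pytest.approx(p.ch4_gamma, abs=1e-6)
        assert np.exp(intercept) == pytest.approx(p.ch4_max_kg_ha, rel=1e-9)

    def test_gwp_consistent_with_fluxes(self, wet_landscape):
        e = wet_landscape.emissions
        expected = (e.ch4_kg_ha * 27 + e.n2o_g_ha / 1000 * 273) / 1000
        np.testing.assert_allclose(e.gwp_mt_co2eq_ha, expected, rtol=1e-9)

    def test_residue_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ch4_from_drivers(0.5, 0.2, 1.5, SurrogateParams())


class TestLandscape:
    @pytest.mark.parametrize("scenario, n", [("wet", 47), ("dry", 160)])
    def test_field_counts(self, scenario, n):
        land = generate_landscape(scenario, n, seed=1)
        assert len(land.series) == n
        assert len(land.emissions) == n
        assert len(land.soils) == n
        assert set(land.true_archetype.index) == set(land.field_ids)

    def test_wet_emits_more_ch4_than_dry(self):
        wet = generate_landscape("wet", 120, seed=3)
        dry = generate_landscape("dry", 120, seed=3)
        assert wet.emissions.ch4_kg_ha.mean() > dry.emissions.ch4_kg_ha.mean()

    def test_wet_envelope(self):
        land = generate_landscape("wet", 50, seed=1)
        assert land.emissions.ch4_kg_ha.between(7, 608).all()

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_landscape("dry", 20, seed=0, weights=[0.5, 0.2, 0.2, 0.2, 0.2])

    def test_deterministic(self):
        a = generate_landscape("dry", 20, seed=8)
        b = generate_landscape("dry", 20, seed=8)
        pd.testing.assert_frame_equal(a.emissions, b.emissions)
        for x, y in zip(a.series, b.series):
            np.testing.assert_array_equal(x.level_cm, y.level_cm)
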