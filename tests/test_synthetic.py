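"""Tests for the synthetic-core generator and its planted truth."""

import numpy as np
import pandas as pd
import pytest

from corestrat import (PB210_LAMBDA, SyntheticConfig, generate_core,
                       truth_report)


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        t1, c1, _ = generate_core(SyntheticConfig(seed=123))
        t2, c2, _ = generate_core(SyntheticConfig(seed=123))
        assert np.array_equal(t1.activity.total_pb210,
                              t2.activity.total_pb210)
        pd.testing.assert_frame_equal(t1.pigments, t2.pigments)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        pd.testing.assert_frame_equal(t1.geochem, t2.geochem)
        assert np.array_equal(c1.reflectance, c2.reflectance)

    def test_different_seed_differs(self):
        t1, _, _ = generate_core(SyntheticConfig(seed=1))
        t2, _, _ = generate_core(SyntheticConfig(seed=2))
        assert not np.array_equal(t1.activity.total_pb210,
                                  t2.activity.total_pb210)

    def test_csv_round_trip_byte_identical(self, tmp_path):
        t1, _, _ = generate_core(SyntheticConfig(seed=9))
        t2, _, _ = generate_core(SyntheticConfig(seed=9))
        p1 = t1.write_csvs(tmp_path / "a")
        p2 = t2.write_csvs(tmp_path / "b")
        for name in p1:
            assert open(p1[name], "rb").read() == open(p2[name], "rb").read()


class TestActivityLaw:
    def test_half_life_value_with_noise_off(self):
        cfg = SyntheticConfig(seed=0, activity_cv=0.0)
        table, _, truth = generate_core(cfg)
        elapsed = cfg.surface_year - truth.true_age
        # activity at one half-life of elapsed time
        cu = table.activity.total_pb210 - cfg.supported_pb210
        expected = cfg.pb210_flux * np.exp(-PB210_LAMBDA * elapsed)
        assert np.allclose(cu, expected)
        # interpolate in log space (exact for an exponential profile)
        interp = np.exp(np.interp(22.3, elapsed, np.log(cu)))
        assert interp == pytest.approx(cfg.pb210_flux / 2, rel=1e-9)

    def test_monotone_chronology(self):
        _, _, truth = generate_core(SyntheticConfig(seed=4))
        assert np.all(np.diff(truth.true_age) < 0)


class TestPlantedEffects:
    def test_fold_change_exact_without_noise(self):
        cfg = SyntheticConfig(seed=0, pigment_noise_sd=0.0,
                              pigment_fold_change=5.0, ramp=False)
        table, _, truth = generate_core(cfg)
        ages = truth.true_age
        pig = table.pigments
        post = pig[ages >= cfg.intervention_year]
        pre = pig[ages < cfg.intervention_year]
        ratio = post.mean() / pre.mean()
        assert np.allclose(ratio, 5.0)

    def test_ramp_is_gradual(self):
        cfg = SyntheticConfig(seed=0, pigment_noise_sd=0.0, ramp=True)
        table, _, truth = generate_core(cfg)
        v = table.pigments["lutein"].to_numpy()
        base = v.min()
        # some samples sit strictly between baseline and plateau
        assert ((v > base * 1.2) & (v < base * 4.5)).any()

    def test_cladoceran_decline_planted(self):
        cfg = SyntheticConfig(seed=3, cladoceran_decline_frac=0.8)
        table, _, truth = generate_core(cfg)
        hs = table.counts.query(
            "taxon == 'Alona' and body_part == 'headshield'")
        pre = hs[hs["depth_cm"] > truth.true_collapse_depth]["count"].mean()
        post = hs[hs["depth_cm"] < truth.true_collapse_depth]["count"].mean()
        assert post / pre == pytest.approx(0.2, abs=0.08)

    def test_spore_tallies_within_spec(self):
        cfg = SyntheticConfig(seed=2)
        table, _, _ = generate_core(cfg)
        added = table.counts["spores_added"]
        assert added.min() >= 1
        assert abs(added.mean() - cfg.spore_mean) < 5 * cfg.spore_sd
        assert (table.counts["spores_counted"] <= added).all()

    def test_cyano_second_rise_off_by_default(self):
        cfg = SyntheticConfig(seed=0, pigment_noise_sd=0.0)
        table, _, truth = generate_core(cfg)
        # without the option, echinenone and lutein share the same shape
        r = (table.pigments["echinenone"] / table.pigments["lutein"])
        assert np.allclose(r, r.iloc[0])
        cfg2 = SyntheticConfig(seed=0, pigment_noise_sd=0.0,
                               cyano_second_rise=True)
        t2, _, _ = generate_core(cfg2)
        r2 = (t2.pigments["echinenone"] / t2.pigments["lutein"])
        assert not np.allclose(r2, r2.iloc[0])


class TestTruthReport:
    def test_intervention_depth_consistent_with_age_function(self):
        cfg = SyntheticConfig(seed=0)
        _, _, truth = generate_core(cfg)
        rep = truth_report(truth).set_index("parameter")["value"]
        d = rep["intervention_depth_cm"]
        # age at that depth equals the intervention year
        assert cfg.surface_year - d / cfg.sedimentation_rate_cm_per_yr == \
            pytest.approx(cfg.intervention_year)

    def test_planted_decline_percent(self):
        cfg = SyntheticConfig(seed=0, cladoceran_decline_frac=0.75)
        _, _, truth = generate_core(cfg)
        rep = truth_report(truth).set_index("parameter")["value"]
        assert rep["cladoceran_decline_pct"] == pytest.approx(75.0)

    def test_twenty_cm_maps_to_1918(self):
        cfg = SyntheticConfig(seed=0, sedimentation_rate_cm_per_yr=0.2)
        assert cfg.depth_of_year(1918.0) == pytest.approx(20.0)


class TestConfigValidation:
    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(sedimentation_rate_cm_per_yr=0.0)

    def test_intervention_outside_span_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(intervention_year=1700.0)
        with pytest.raises(ValueError):
            SyntheticConfig(intervention_year=2030.0)

    def test_decline_fraction_bounds(self):
        with pytest.raises(ValueError):
            SyntheticConfig(cladoceran_decline_frac=1.0)
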