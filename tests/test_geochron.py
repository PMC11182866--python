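"""Unit and property tests for the 210Pb age-depth models."""

import numpy as np
import pytest

from corestrat import (ActivityProfile, CFCSModel, CRSModel, PB210_LAMBDA,
                       estimate_supported, fit_cfcs, fit_crs,
                       transfer_chronology)
from corestrat.geochron import GeochronError


def make_profile(unsupported, supported=0.0, err=None, thickness=1.0,
                 density=1.0):
    """Profile with given unsupported activities at 1-cm mid-depths."""
    cu = np.asarray(unsupported, dtype=float)
    n = len(cu)
    tops = np.arange(n) * thickness
    prof = ActivityProfile(
        depth_top=tops, depth_bottom=tops + thickness,
        dry_mass_cum=density * (tops + thickness / 2),
        total_pb210=cu + supported,
        total_pb210_err=np.zeros(n) if err is None else np.asarray(err),
    )
    prof.supported, prof.supported_err = supported, 0.0
    return prof


class TestEstimateSupported:
    def test_tail_mean(self):
        prof = make_profile([50, 40, 30, 10, 12, 11])
        est = estimate_supported(prof, 3)
        assert est.value == pytest.approx(11.0)

    def test_constant_tail_sigma_from_measurement_errors(self):
        prof = make_profile([50, 40, 5, 5, 5], err=[1, 1, 2, 2, 2])
        est = estimate_supported(prof, 3)
        assert est.value == pytest.approx(5.0)
        # sqrt(3 * 2^2) / 3
        assert est.sigma == pytest.approx(np.sqrt(12) / 3)

    def test_quadrature_error_oracle(self):
        # sqrt(1+1+1)/3 = 0.577...: standard error of a mean of three
        # independent measurements with unit sigma
        prof = make_profile([50, 40, 10, 12, 11], err=[1, 1, 1, 1, 1])
        est = estimate_supported(prof, 3)
        assert est.sigma == pytest.approx(np.sqrt(3) / 3, abs=1e-12)

    def test_tail_n_out_of_range(self):
        prof = make_profile([10, 11, 12])
        with pytest.raises(ValueError):
            estimate_supported(prof, 1)
        with pytest.raises(ValueError):
            estimate_supported(prof, 4)

    def test_declining_tail_warns(self):
        prof = make_profile([200, 100, 50, 25, 12])
        with pytest.warns(UserWarning, match="declining"):
            est = estimate_supported(prof, 3)
        assert est.declining

    def test_decay_corrected_removes_leftover_excess(self):
        # exact exponential over a baseline of 30: plain tail mean is
        # biased high, the decay-corrected estimate recovers 30
        m = np.arange(40) + 0.5
        cu = 400 * np.exp(-0.12 * m)
        prof = make_profile(cu, supported=0.0)
        prof.total_pb210 = cu + 30.0
        plain = estimate_supported(prof, 5).value
        corrected = estimate_supported(prof, 5,
                                       method="decay_corrected").value
        assert plain > 30.5
        assert corrected == pytest.approx(30.0, abs=0.05)


class TestCFCS:
    def test_exact_rate_recovery(self):
        # analytic oracle: Cu = C0 exp(-(lambda/r) m) with r = 0.05
        lam, r = 0.03108, 0.05
        m = np.linspace(0.025, 1.0, 20)
        cu = 80 * np.exp(-(lam / r) * m)
        prof = make_profile(cu, density=1.0)
        prof.dry_mass_cum = m
        model = CFCSModel(2018.0, decay_constant=lam).fit(prof)
        assert model.slope_ == pytest.approx(-lam / r, rel=1e-9)
        assert model.rate_ == pytest.approx(r, rel=1e-9)

    def test_two_points_allowed_with_warning(self):
        prof = make_profile([100.0, 50.0])
        with pytest.warns(UserWarning, match="two points"):
            model = CFCSModel().fit(prof)
        assert model.slope_ < 0

    def test_no_decay_trend_errors(self):
        prof = make_profile([50.0, 50.0, 50.0, 50.0])
        with pytest.raises(GeochronError, match="no decay trend"):
            CFCSModel().fit(prof)

    def test_surface_age_is_collection_year(self):
        prof = make_profile(100 * np.exp(-0.3 * np.arange(10)))
        am = fit_cfcs(prof, collection_year=2018.0)
        assert am.age_at(0.0) == pytest.approx(2018.0)

    def test_age_ci_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        cu = 100 * np.exp(-0.3 * (np.arange(15) + 0.5)) * \
            np.exp(rng.normal(0, 0.1, 15))
        am = fit_cfcs(make_profile(cu))
        assert np.all(am.age_lo - 1e-9 <= am.age)
        assert np.all(am.age <= am.age_hi + 1e-9)


class TestCRS:
    def test_surface_and_half_life_identities(self, dated_profile):
        cfg, prof = dated_profile
        model = CRSModel(cfg.surface_year, mc_draws=10, seed=0).fit(prof)
        assert model.predict_age(0.0) == pytest.approx(cfg.surface_year)
        # depth where the residual inventory is half the total must date
        # to one half-life
        am = model.age_model_
        a0 = model.inventory_
        # locate A(z) = a0/2 by scanning the age grid for t = 22.3 yr
        t = cfg.surface_year - am.age
        d_half = np.interp(22.3, t, am.depth)
        # the synthetic core has constant rate s: half-life depth = s*22.3
        assert d_half == pytest.approx(
            cfg.sedimentation_rate_cm_per_yr * 22.3, rel=0.01)

    def test_crs_matches_cfcs_on_constant_flux(self, dated_profile):
        cfg, prof = dated_profile
        cfcs = CFCSModel(cfg.surface_year).fit(prof)
        crs = CRSModel(cfg.surface_year, mc_draws=10, seed=0).fit(prof)
        d = np.linspace(0.5, 36.5, 73)
        a1, a2 = cfcs.predict_age(d), crs.predict_age(d)
        elapsed = cfg.surface_year - a1
        assert np.all(np.abs(a1 - a2) <= 0.01 * np.maximum(elapsed, 1e-9))

    def test_ages_monotone(self, default_core):
        cfg, table, _, _ = default_core
        prof = table.activity
        est = estimate_supported(prof, 4, method="decay_corrected")
        prof.supported, prof.supported_err = est.value, est.sigma
        am = fit_crs(prof, cfg.surface_year, mc_draws=20, seed=0)
        assert np.all(np.diff(am.age) <= 1e-9)

    def test_mc_ci_reproducible_and_widening(self, default_core):
        cfg, table, _, _ = default_core
        prof = table.activity
        est = estimate_supported(prof, 4, method="decay_corrected")
        prof.supported, prof.supported_err = est.value, est.sigma
        am1 = fit_crs(prof, cfg.surface_year, mc_draws=80, seed=42)
        am2 = fit_crs(prof, cfg.surface_year, mc_draws=80, seed=42)
        assert np.array_equal(am1.age_lo, am2.age_lo)
        width = am1.age_hi - am1.age_lo
        # CI width grows broadly with depth on a monotone-decay profile
        assert width[-1] > width[1]

    def test_noisy_rate_recovery(self):
        """Full supported-estimation + CFCS chain recovers the planted
        mass accumulation rate within 10% under 10% activity noise."""
        from corestrat import SyntheticConfig, generate_core
        truth_rate = 0.21 * 0.5
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            table, _, _ = generate_core(SyntheticConfig(seed=seed))
            prof = table.activity
            est = estimate_supported(prof, 4, method="decay_corrected")
            prof.supported, prof.supported_err = est.value, est.sigma
            rate = CFCSModel(2018.0).fit(prof).rate_
            ok += abs(rate / truth_rate - 1) < 0.10
        assert ok >= 0.9 * n_seeds


class TestTransferChronology:
    def test_identity_tie_points(self, linear_age_model):
        z = np.linspace(0, 20, 11)
        am = transfer_chronology(z, [(0, 0), (20, 20)], linear_age_model)
        assert np.allclose(am.age, linear_age_model.age_at(z))

    def test_linear_midpoint_example(self, linear_age_model):
        am = transfer_chronology([5.0], [(0, 0), (10, 20)], linear_age_model)
        # undated 5 -> dated 10 -> 2018 - 50 = 1968
        assert am.age[0] == pytest.approx(1968.0)

    def test_non_monotone_tie_points_error(self, linear_age_model):
        with pytest.raises(ValueError, match="monotone"):
            transfer_chronology([1.0], [(0, 0), (10, 5), (5, 8)],
                                linear_age_model)

    def test_extrapolation_flagged(self, linear_age_model):
        am = transfer_chronology([0.0, 6.0], [(1, 1), (5, 5)],
                                 linear_age_model)
        assert am.flags["extrapolated"].tolist() == [True, True]
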