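"""Solar anchoring, circular KDE, activity levels, overlap, Wald tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import i0

from camoccu.activity import (ActivityLevel, activity_level, bootstrap_overlap,
                              fit_kde, kde_bandwidth, overlap, solar_anchor,
                              vm_kernel_density, wald_compare)
from camoccu.solar import sun_events_utc

TWO_PI = 2 * np.pi


def vm_pdf(x, mu, kappa):
    return np.exp(kappa * np.cos(x - mu)) / (TWO_PI * i0(kappa))


class TestSolarAnchor:
    def test_single_day_is_identity(self):
        """With one calendar day the anchors equal that day's sun events, so
        the transform is the identity."""
        times = pd.to_datetime([f"2020-03-01T{h:02d}:30:00" for h in range(24)]
                               ).tz_localize("Europe/Rome")
        out = solar_anchor(times)
        clock = TWO_PI * (np.arange(24) + 0.5) / 24
        diff = (out.times_rad - clock + np.pi) % TWO_PI - np.pi
        assert np.abs(diff).max() < 1e-9

    def test_sunrise_maps_to_mean_sunrise_anchor(self):
        dates = ["2020-02-15", "2020-04-15", "2020-06-15"]
        stamps = []
        for d in dates:
            doy = pd.Timestamp(d).dayofyear
            sr_utc, _ = sun_events_utc(np.array([doy]), 42.787, 10.275)
            offs = 2.0 if pd.Timestamp(d) >= pd.Timestamp("2020-03-29") else 1.0
            h = (sr_utc[0] + offs) % 24
            stamps.append(pd.Timestamp(d) + pd.Timedelta(hours=h))
        ts = pd.DatetimeIndex(stamps).tz_localize("Europe/Rome")
        out = solar_anchor(ts)
        anchor = out.anchor_info["mean_sunrise_rad"]
        diff = (out.times_rad - anchor + np.pi) % TWO_PI - np.pi
        assert np.abs(diff).max() < 1e-6

    def test_monotone_within_a_day(self, rng):
        secs = np.sort(rng.integers(0, 86_400, 1000))
        times = (pd.Timestamp("2020-05-10", tz="Europe/Rome")
                 + pd.to_timedelta(secs, unit="s"))
        out = solar_anchor(pd.DatetimeIndex(times))
        unwrapped = np.unwrap(out.times_rad)
        assert (np.diff(unwrapped) >= -1e-12).all()

    def test_polar_night_rejected(self):
        ts = pd.to_datetime(["2020-12-21T12:00:00"]).tz_localize("UTC")
        with pytest.raises(ValueError, match="polar"):
            solar_anchor(ts, lat=80.0, lon=0.0)


class TestKDE:
    def test_integral_one_and_periodic(self, rng):
        d = fit_kde(rng.vonmises(1.0, 3.0, 500) % TWO_PI)
        assert d.integral() == pytest.approx(1.0, abs=1e-6)
        assert d.values[0] == d.values[-1]
        assert (d.values >= 0).all()

    def test_uniform_sample_flat_density(self, rng):
        d = fit_kde(rng.uniform(0, TWO_PI, 10_000))
        assert d.max_density == pytest.approx(1 / TWO_PI, rel=0.05)

    def test_antipodal_pair_symmetry(self):
        d = fit_kde(np.array([0.5, 0.5 + np.pi]))
        m = len(d.values) - 1
        rolled = np.roll(d.values[:-1], m // 2)
        np.testing.assert_allclose(d.values[:-1], rolled, atol=1e-9)

    def test_consistency_against_true_von_mises(self, rng):
        """Sup-norm distance to the generating density is dominated by the
        plug-in rule's smoothing bias (~0.01 at the peak for kappa=2)."""
        x = rng.vonmises(np.pi, 2.0, 5000) % TWO_PI
        d = fit_kde(x)
        truth = vm_pdf(d.grid, np.pi, 2.0)
        assert np.abs(d.values - truth).max() < 0.025

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_kde(np.array([1.0]))

    def test_rotation_invariance_of_level(self, rng):
        x = rng.vonmises(1.0, 2.0, 400) % TWO_PI
        l1 = activity_level(x, B=100, seed=0).level
        l2 = activity_level((x + 1.234) % TWO_PI, B=100, seed=0).level
        assert l1 == pytest.approx(l2, abs=1e-9)


class TestActivityLevel:
    def test_uniform_sample_near_full_activity(self, rng):
        """A uniform population has level 1 (max density 1/(2 pi)); the
        estimate from a large sample sits just below, never above, 1."""
        lv = activity_level(rng.uniform(0, TWO_PI, 3000), B=100, seed=0)
        assert 0.9 < lv.level <= 1.0

    def test_level_is_reciprocal_peak_density(self, rng):
        """level = 1/(2 pi max density), with the peak refined off-grid
        (so it can only be at or slightly below the grid-based value)."""
        x = rng.vonmises(1.0, 2.0, 500) % TWO_PI
        lv = activity_level(x, B=100, seed=0)
        grid_level = 1 / (TWO_PI * fit_kde(x).max_density)
        assert lv.level <= grid_level + 1e-12
        assert lv.level == pytest.approx(grid_level, rel=1e-3)

    def test_von_mises_closed_form(self, rng):
        """True level for VM(kappa=1) is I0(1)/e (max density e^k/(2 pi I0))."""
        x = rng.vonmises(0.0, 1.0, 10_000) % TWO_PI
        lv = activity_level(x, B=100, seed=0)
        assert lv.level == pytest.approx(i0(1.0) / np.e, abs=0.02)

    def test_concentrated_sample_low_level(self, rng):
        x = rng.vonmises(0.0, 500.0, 2000) % TWO_PI
        lv = activity_level(x, B=100, seed=0)
        assert lv.level < 0.05


class TestOverlap:
    def test_identical_samples_dhat4_is_one(self, rng):
        x = rng.vonmises(0.0, 2.0, 200) % TWO_PI
        est = overlap(x, x, estimator="Dhat4")
        assert est.value == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_concentrated_samples(self, rng):
        a = rng.vonmises(0.0, 400.0, 300) % TWO_PI
        b = rng.vonmises(np.pi, 400.0, 300) % TWO_PI
        est = overlap(a, b, estimator="Dhat1")
        assert est.value < 0.01

    def test_symmetry(self, rng):
        a = rng.vonmises(0.0, 2.0, 120) % TWO_PI
        b = rng.vonmises(1.0, 3.0, 90) % TWO_PI
        for estimator in ("Dhat1", "Dhat4"):
            assert overlap(a, b, estimator).value == pytest.approx(
                overlap(b, a, estimator).value, abs=1e-12)

    def test_rotation_invariance(self, rng):
        """Dhat4 is evaluated at the sample points, hence exactly invariant;
        Dhat1's fixed 512-point grid leaves ~1e-5 discretization play."""
        a = rng.vonmises(0.0, 2.0, 150) % TWO_PI
        b = rng.vonmises(1.0, 3.0, 150) % TWO_PI
        r = 0.777
        for estimator, tol in (("Dhat1", 5e-4), ("Dhat4", 1e-10)):
            v0 = overlap(a, b, estimator).value
            v1 = overlap((a + r) % TWO_PI, (b + r) % TWO_PI, estimator).value
            assert v0 == pytest.approx(v1, abs=tol)

    def test_auto_selection_rule(self, rng):
        small = rng.uniform(0, TWO_PI, 40)
        big = rng.uniform(0, TWO_PI, 100)
        assert overlap(small, big).estimator == "Dhat1"
        assert overlap(big, big[:80]).estimator == "Dhat4"
        with pytest.warns(UserWarning, match="50-74"):
            assert overlap(big[:60], big).estimator == "Dhat1"

    def test_dhat5_flagged(self, rng):
        x = rng.uniform(0, TWO_PI, 100)
        with pytest.warns(UserWarning, match="not recommended"):
            est = overlap(x, x, estimator="Dhat5")
        assert est.note


class TestBootstrapOverlap:
    def test_identical_samples_concentrate_near_one(self, rng):
        """With identical inputs the point estimate is exactly 1 and the
        bootstrap distribution piles up near 1 (resamples of the two
        species are drawn independently, so the lower bound sits slightly
        below 1)."""
        x = rng.vonmises(0.0, 2.0, 150) % TWO_PI
        est = bootstrap_overlap(x, x, estimator="Dhat4", B=150, smoothed=False, seed=0)
        lo, hi = est.cis["perc"]
        assert est.value == pytest.approx(1.0, abs=1e-9)
        assert est.boot_mean > 0.85 and hi > 0.9 and lo > 0.8

    def test_bias_arithmetic(self):
        """bias = bootstrap mean - estimate; corrected centre = estimate - bias."""
        from camoccu import activity as act
        boots = np.array([0.90] * 100)
        theta = 0.87
        bias = boots.mean() - theta
        assert bias == pytest.approx(0.03)
        assert theta - bias == pytest.approx(0.84)

    def test_seeded_runs_bit_reproducible(self, rng):
        a = rng.vonmises(0.0, 2.0, 120) % TWO_PI
        b = rng.vonmises(1.0, 2.0, 120) % TWO_PI
        e1 = bootstrap_overlap(a, b, B=120, seed=7)
        e2 = bootstrap_overlap(a, b, B=120, seed=7)
        assert e1.boot_mean == e2.boot_mean
        assert e1.cis == e2.cis

    def test_ci_selection_rule(self, rng):
        a = rng.vonmises(0.0, 2.0, 200) % TWO_PI
        b = rng.vonmises(0.5, 2.0, 200) % TWO_PI
        est = bootstrap_overlap(a, b, B=300, seed=3)
        expected = "perc_corrected" if abs(est.bias) > 0.01 else "perc"
        assert est.selected_ci == expected
        assert set(est.cis) == {"perc", "perc_corrected", "basic",
                                "basic_corrected", "norm"}


class TestWald:
    def test_equal_levels(self):
        a = ActivityLevel(0.4, 0.05, (0.3, 0.5), 100)
        r = wald_compare(a, a)
        assert r["W"] == 0 and r["p"] == pytest.approx(1.0)

    def test_known_value(self):
        a = ActivityLevel(0.3, 0.05, (0, 1), 100)
        b = ActivityLevel(0.5, 0.05, (0, 1), 100)
        r = wald_compare(a, b)
        assert r["W"] == pytest.approx(8.0)
        assert r["p"] == pytest.approx(0.004678, abs=1e-5)
        assert r["significant"]

    def test_zero_se_rejected(self):
        a = ActivityLevel(0.4, 0.0, (0, 1), 100)
        with pytest.raises(ValueError):
            wald_compare(a, a)


def test_dhat1_matches_quadrature_on_known_densities(rng):
    """Dhat1 approaches the true overlap integral of two von Mises laws."""
    mu1, mu2, kap = 0.0, np.pi / 2, 2.0
    a = rng.vonmises(mu1, kap, 4000) % TWO_PI
    b = rng.vonmises(mu2, kap, 4000) % TWO_PI
    est = overlap(a, b, estimator="Dhat1")
    truth, _ = integrate.quad(
        lambda x: min(vm_pdf(x, mu1, kap), vm_pdf(x, mu2, kap)), 0, TWO_PI,
        limit=200)
    assert est.value == pytest.approx(truth, abs=0.03)
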