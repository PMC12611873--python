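"""Projection arithmetic: Nh estimator, length-weight law, biomass,
per-unit-area standardization and the bootstrap."""

import numpy as np
import pandas as pd
import pytest

from oysterhsm import (DEFAULT_LW_ANCHORS, HabitatEstimate, biomass,
                       bootstrap_ci, estimate_habitat, length_class_frequencies,
                       lw_calibrate, per_unit_area, population_size)


class TestPopulationSize:
    def test_printed_arithmetic(self):
        """Mean 3.0 ind/m^2 over 8.6 km^2 of invaded area -> ~26 million."""
        n = population_size(3.0, 8.6e6)
        assert n == pytest.approx(25.8e6)
        assert round(n / 1e6) == 26

    def test_zero_prevalence_gives_zero(self):
        assert population_size(5.0, 0.0) == 0.0

    def test_linear_in_area(self):
        assert population_size(2.0, 2e6) == 2 * population_size(2.0, 1e6)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            population_size(-1.0, 1.0)


class TestLengthWeight:
    def test_two_anchor_exact_solve(self):
        lw = lw_calibrate(DEFAULT_LW_ANCHORS)
        # oracle: solve the 2x2 log-log system directly
        b = np.log(140 / 40) / np.log(107.5 / 62.5)
        assert lw.b == pytest.approx(b)
        assert lw.b == pytest.approx(2.31, abs=0.01)
        assert lw.weight(62.5) == pytest.approx(40.0)
        assert lw.weight(107.5) == pytest.approx(140.0)

    def test_equal_weights_give_flat_law(self):
        lw = lw_calibrate([(50.0, 30.0), (100.0, 30.0)])
        assert lw.b == pytest.approx(0.0, abs=1e-12)

    def test_many_anchors_least_squares(self):
        lengths = np.array([40.0, 60.0, 80.0, 120.0])
        lw_true = lw_calibrate([(62.5, 40.0), (107.5, 140.0)])
        lw = lw_calibrate(list(zip(lengths, lw_true.weight(lengths))))
        assert lw.b == pytest.approx(lw_true.b, abs=1e-9)

    def test_identical_lengths_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            lw_calibrate([(50.0, 30.0), (50.0, 40.0)])

    def test_increasing_for_positive_exponent(self):
        lw = lw_calibrate(DEFAULT_LW_ANCHORS)
        L = np.linspace(10, 200, 50)
        assert np.all(np.diff(lw.weight(L)) > 0)


class TestBiomass:
    def test_zero_population_zero_biomass(self):
        freqs = pd.Series([1.0], index=[62.5])
        total, contrib = biomass(0.0, freqs, lw_calibrate(DEFAULT_LW_ANCHORS))
        assert total == 0.0

    def test_single_class_hand_value(self):
        """1e6 oysters of the 60-65 mm class at ~40 g each -> ~40 t."""
        freqs = pd.Series([1.0], index=[62.5])
        total, _ = biomass(1e6, freqs, lw_calibrate(DEFAULT_LW_ANCHORS))
        assert total == pytest.approx(40.0)

    def test_contributions_partition_total(self, rng):
        mids = np.arange(22.5, 150, 5.0)
        f = rng.random(len(mids))
        freqs = pd.Series(f / f.sum(), index=mids)
        total, contrib = biomass(5e5, freqs, lw_calibrate(DEFAULT_LW_ANCHORS))
        assert contrib.sum() == pytest.approx(total, rel=1e-12)

    def test_frequencies_must_sum_to_one(self):
        freqs = pd.Series([0.5, 0.4], index=[62.5, 67.5])
        with pytest.raises(ValueError, match="sum to 1"):
            biomass(1e6, freqs, lw_calibrate(DEFAULT_LW_ANCHORS))

    def test_length_class_frequencies_sum_to_one(self, rng):
        lengths = rng.lognormal(4.2, 0.3, 500)
        freqs = length_class_frequencies(lengths)
        assert freqs.sum() == pytest.approx(1.0)
        assert np.all(np.diff(freqs.index) > 0)


def _estimate(habitat, xbar, ph, area, bh=10.0):
    return HabitatEstimate(habitat=habitat, n_sites=10, mean_abundance=xbar,
                           prevalence=ph, area_m2=area,
                           population=xbar * ph * area, biomass_t=bh)


class TestPerUnitArea:
    def test_printed_seven_times_ratio(self):
        """Marina (8.6, Ph .704) vs natural (3.0, Ph .271): ~7x per unit area."""
        out = per_unit_area(_estimate("marina", 8.6, 0.704, 1e6),
                            _estimate("natural", 3.0, 0.271, 1e6))
        assert out["abundance_ratio"] == pytest.approx(7.446, abs=0.01)
        assert round(out["abundance_ratio"]) == 7

    def test_full_prevalence_reduces_to_mean_ratio(self):
        out = per_unit_area(_estimate("a", 9.0, 1.0, 1e5),
                            _estimate("b", 3.0, 1.0, 1e5))
        assert out["abundance_ratio"] == pytest.approx(3.0)

    def test_toy_ratio(self):
        out = per_unit_area(_estimate("a", 10.0, 0.5, 1e5),
                            _estimate("b", 5.0, 0.5, 1e5))
        assert out["abundance_ratio"] == pytest.approx(2.0)

    def test_invariant_to_common_area_rescale(self):
        a1 = per_unit_area(_estimate("a", 8.0, 0.7, 1e6, bh=20.0),
                           _estimate("b", 3.0, 0.3, 2e6, bh=30.0))
        a2 = per_unit_area(_estimate("a", 8.0, 0.7, 5e6, bh=20.0),
                           _estimate("b", 3.0, 0.3, 10e6, bh=30.0))
        assert a1["abundance_ratio"] == pytest.approx(a2["abundance_ratio"])
        # biomass per-area ratio depends on Bh/Ah; same rescale cancels too
        assert a1["biomass_ratio"] == pytest.approx(a2["biomass_ratio"])


class TestBootstrap:
    def test_constant_sample_zero_width(self):
        point, lo, hi = bootstrap_ci(np.full(20, 4.0), np.mean, n_boot=200,
                                     seed=1)
        assert point == lo == hi == 4.0

    def test_point_is_plug_in_statistic(self, rng):
        x = rng.lognormal(1.0, 0.5, 30)
        point, lo, hi = bootstrap_ci(x, np.mean, n_boot=100, seed=2)
        assert point == pytest.approx(x.mean())
        assert lo <= point <= hi

    def test_seeded_determinism(self, rng):
        x = rng.normal(size=25)
        assert bootstrap_ci(x, np.median, seed=3) == bootstrap_ci(
            x, np.median, seed=3)

    def test_single_observation_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            point, lo, hi = bootstrap_ci(np.array([2.0]), np.mean)
        assert point == lo == hi == 2.0


class TestEstimateHabitat:
    def _projected(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        present = rng.uniform(size=n) < 0.6
        abund = np.where(present, rng.lognormal(1.0, 0.4, n), np.nan)
        return pd.DataFrame({"presence": present, "possible_abundance": abund})

    def test_identity_nh_equals_xbar_ph_ah(self):
        df = self._projected()
        freqs = pd.Series([1.0], index=[62.5])
        est = estimate_habitat(df, "m", 1e6, freqs,
                               lw_calibrate(DEFAULT_LW_ANCHORS), n_boot=50)
        assert est.population == pytest.approx(
            est.mean_abundance * est.prevalence * est.area_m2)
        assert est.ci_population[0] <= est.population <= est.ci_population[1]

    def test_homogeneous_degree_one_in_area(self):
        df = self._projected()
        freqs = pd.Series([1.0], index=[62.5])
        lw = lw_calibrate(DEFAULT_LW_ANCHORS)
        e1 = estimate_habitat(df, "m", 1e6, freqs, lw, n_boot=10, seed=4)
        e2 = estimate_habitat(df, "m", 2e6, freqs, lw, n_boot=10, seed=4)
        assert e2.population == pytest.approx(2 * e1.population)
        assert e2.biomass_t == pytest.approx(2 * e1.biomass_t)

    def test_pooled_conservation_on_single_habitat_split(self):
        """Pooling two halves of one habitat equals the pooled estimate when
        prevalence and means are computed pooled."""
        df = self._projected(n=40)
        freqs = pd.Series([1.0], index=[62.5])
        lw = lw_calibrate(DEFAULT_LW_ANCHORS)
        pooled = estimate_habitat(df, "m", 2e6, freqs, lw, n_boot=5)
        # the pooled Nh recomputed from halves' sufficient statistics
        halves = [df.iloc[:20], df.iloc[20:]]
        n_pres = sum(h["presence"].sum() for h in halves)
        total = sum(h.loc[h["presence"], "possible_abundance"].sum()
                    for h in halves)
        xbar = total / n_pres
        ph = n_pres / len(df)
        assert pooled.population == pytest.approx(xbar * ph * 2e6)
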