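"""Negative-binomial burst inference, thinning moments, efficiency ratios."""

import numpy as np
import pytest

from brass import (
    CellEventTable,
    Construct,
    MethodID,
    SampleID,
    burst_parameters,
    efficiency_ratio,
    fano_factor,
    fit_negative_binomial,
    spot_intensity_mixture,
    thin_counts,
    thinning_predictions,
)


class TestFanoFactor:
    def test_constant_counts_have_zero_fano(self):
        assert fano_factor([4, 4, 4, 4]) == 0.0

    def test_hand_computed_small_sample(self):
        # mean 2, sample variance 16/3 -> Fano 8/3
        assert fano_factor([0, 0, 4, 4]) == pytest.approx(8 / 3)

    def test_poisson_fano_is_one(self):
        n = 100_000
        counts = np.random.default_rng(0).poisson(5.0, size=n)
        # SE of the Fano factor for Poisson ~ sqrt(2/n)
        assert abs(fano_factor(counts) - 1.0) < 3 * np.sqrt(2 / n)

    def test_zero_mean_is_undefined(self):
        with pytest.raises(ValueError):
            fano_factor([0, 0, 0])


class TestThinningPredictions:
    def test_unit_efficiency_is_identity(self):
        pred = thinning_predictions(10.0, 30.0, 1.0)
        assert (pred.mean, pred.variance, pred.fano) == (10.0, 30.0, 3.0)

    def test_plug_in_closed_forms(self):
        pred = thinning_predictions(10.0, 30.0, 0.5)
        assert pred.mean == 5.0
        assert pred.variance == pytest.approx(10.0 * 0.5 * 0.5 + 0.25 * 30.0)
        assert pred.fano == pytest.approx(1 + 0.5 * (3.0 - 1.0))

    @pytest.mark.parametrize("p", [0.1, 0.5, 1.0])
    def test_thinned_poisson_stays_poisson(self, p):
        pred = thinning_predictions(7.0, 7.0, p)
        assert pred.fano == pytest.approx(1.0)

    def test_non_positive_mean_raises(self):
        with pytest.raises(ValueError):
            thinning_predictions(0.0, 1.0, 0.5)


class TestFitNegativeBinomial:
    def test_recovers_parameters_from_large_sample(self):
        counts = np.random.default_rng(0).negative_binomial(2, 0.4, size=5000)
        fit = fit_negative_binomial(counts)
        assert fit.status == "ok"
        assert 1.7 < fit.r < 2.3
        assert 0.34 < fit.p_nb < 0.46

    def test_underdispersed_counts_flagged_poisson_boundary(self):
        fit = fit_negative_binomial([3, 3, 3, 4, 4, 4, 3, 4, 3, 4])
        assert fit.status == "poisson_boundary"
        assert fit.r == pytest.approx(1e4)

    def test_mle_beats_moment_estimate(self):
        from brass.bursting import _nb_loglik

        counts = np.random.default_rng(5).negative_binomial(1.5, 0.3, size=800)
        fit = fit_negative_binomial(counts)
        m, v = counts.mean(), counts.var(ddof=1)
        r0 = m**2 / (v - m)
        p0 = r0 / (r0 + m)
        assert fit.loglik >= _nb_loglik(counts.astype(float), r0, p0) - 1e-9

    def test_matches_grid_search_likelihood_oracle(self):
        from brass.bursting import _nb_loglik

        counts = np.random.default_rng(7).negative_binomial(2.5, 0.45, size=200)
        fit = fit_negative_binomial(counts)
        m = counts.mean()
        grid = fit.r * np.exp(np.linspace(-1.0, 1.0, 801))
        logliks = [_nb_loglik(counts.astype(float), r, r / (r + m)) for r in grid]
        best = grid[int(np.argmax(logliks))]
        assert abs(np.log(best) - np.log(fit.r)) <= 2 * (2.0 / 800)
        assert fit.loglik >= max(logliks) - 1e-9

    def test_all_zero_counts_are_uninformative(self):
        with pytest.raises(ValueError):
            fit_negative_binomial(np.zeros(50, dtype=int))


class TestBurstParameters:
    def test_direct_formulas(self):
        bf = burst_parameters(1.0, 0.5, tau_min=2.8, efficiency=1.0)
        assert bf.burst_frequency_per_min == pytest.approx(1 / 2.8)
        assert bf.burst_size == 1.0
        assert bf.corrected_burst_size == 1.0

    def test_efficiency_corrects_size_not_frequency(self):
        bf = burst_parameters(1.0, 0.5, tau_min=2.8, efficiency=0.5)
        assert bf.corrected_burst_size == pytest.approx(2.0)
        assert bf.burst_frequency_per_min == pytest.approx(1 / 2.8)

    def test_burst_size_vanishes_as_p_approaches_one(self):
        bf = burst_parameters(1.0, 1 - 1e-9, tau_min=2.8)
        assert bf.burst_size == pytest.approx(0.0, abs=1e-8)

    def test_invalid_efficiency_raises(self):
        with pytest.raises(ValueError):
            burst_parameters(1.0, 0.5, efficiency=0.0)


def _count_table(counts, prep, iptg, rep):
    return CellEventTable(
        method=MethodID(prep, "microscopy", "rna_count"),
        sample=SampleID(Construct.INDUCIBLE, iptg, rep),
        signal=np.asarray(counts, dtype=float),
    )


class TestEfficiencyRatio:
    def test_identical_tables_give_ratio_one(self):
        rng = np.random.default_rng(0)
        tables = [_count_table(rng.negative_binomial(2, 0.3, 300), "FISH", x, 1)
                  for x in (10.0, 100.0)]
        other = [_count_table(t.signal, "HCR", t.sample.iptg_umol_per_l, 1)
                 for t in tables]
        est = efficiency_ratio(other, tables, n_boot=100, rng=1)
        assert est.overall_ratio == pytest.approx(1.0)
        assert np.allclose(est.per_sample["ratio"].dropna(), 1.0)

    def test_thinned_splits_recover_efficiency_ratio(self):
        # Latent NB counts thinned at 0.9 (B) and 0.45 (A): both the mean
        # ratio and the (Fano-1) ratio estimate p_A/p_B = 0.5.
        rng = np.random.default_rng(2)
        a_tables, b_tables = [], []
        for i, x in enumerate((10.0, 40.0, 100.0, 1000.0)):
            latent = rng.negative_binomial(2.0, 0.15, size=800)
            a = thin_counts(latent, 0.45, rng)
            b = thin_counts(latent, 0.9, rng)
            a_tables.append(_count_table(a, "HCR", x, 1))
            b_tables.append(_count_table(b, "FISH", x, 1))
        est = efficiency_ratio(a_tables, b_tables, n_boot=300, rng=3,
                               reference_efficiency=0.9)
        lo, hi = est.overall_ci
        assert lo < 0.5 < hi
        assert est.overall_ratio == pytest.approx(0.5, abs=0.06)
        assert est.absolute_efficiency == pytest.approx(0.45, abs=0.06)

    def test_fano_below_one_excluded_but_mean_ratio_kept(self):
        a = _count_table([1, 2, 1, 2, 1, 2, 1, 2, 1, 2] * 20, "HCR", 0.0, 1)
        b_counts = np.random.default_rng(4).negative_binomial(1.0, 0.2, 200)
        b = _count_table(b_counts, "FISH", 0.0, 1)
        est = efficiency_ratio([a], [b], n_boot=50, rng=5)
        per = est.per_sample.set_index("statistic")
        assert bool(per.loc["fano_minus_1", "excluded"])
        assert not bool(per.loc["mean", "excluded"])
        assert np.isfinite(per.loc["mean", "ratio"])

    def test_no_matched_tables_is_a_contract_error(self):
        a = _count_table([1, 2, 3], "HCR", 10.0, 1)
        b = _count_table([1, 2, 3], "FISH", 10.0, 2)
        with pytest.raises(ValueError, match="matched"):
            efficiency_ratio([a], [b])


class TestSpotIntensityMixture:
    @staticmethod
    def _draw(n, weight_upper, mu_low=1.0, mu_high=4.0, sigma=0.5, seed=0):
        rng = np.random.default_rng(seed)
        upper = rng.random(n) < weight_upper
        logs = np.where(upper,
                        rng.normal(mu_high, sigma, n),
                        rng.normal(mu_low, sigma, n))
        return np.exp(logs)

    def test_recovers_upper_component_weight(self):
        intensities = self._draw(3000, weight_upper=0.7)
        fit = spot_intensity_mixture(intensities, threshold=np.exp(2.5))
        assert fit.converged
        assert fit.weight_upper == pytest.approx(0.7, abs=0.05)
        assert fit.specific_fraction > 0.9  # upper spots carry most intensity

    def test_mirrored_mass_mirrors_weight(self):
        intensities = self._draw(3000, weight_upper=0.3, seed=1)
        fit = spot_intensity_mixture(intensities, threshold=np.exp(2.5))
        assert fit.weight_upper == pytest.approx(0.3, abs=0.05)

    def test_all_mass_below_threshold_is_degenerate_nonspecific(self):
        rng = np.random.default_rng(2)
        intensities = np.exp(rng.normal(1.0, 0.3, 500))
        fit = spot_intensity_mixture(intensities,
                                     threshold=float(intensities.max()) * 1.1)
        assert fit.degenerate
        assert fit.specific_fraction == pytest.approx(0.0)

    def test_too_few_spots_raise(self):
        with pytest.raises(ValueError):
            spot_intensity_mixture(np.ones(10), threshold=1.0)
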