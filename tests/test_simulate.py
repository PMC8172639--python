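"""Synthetic split-sample generator: bursting, thinning, protein, composition."""

import numpy as np
import pytest

from brass import (
    CANONICAL_METHODS,
    Construct,
    Detection,
    Measurand,
    Preparation,
    SimulationConfig,
    simulate_experiment,
    simulate_protein,
    simulate_rna_counts,
    thin_counts,
)
from brass.bursting import fit_negative_binomial
from brass.simulate import HillParams


class TestSimulateRnaCounts:
    def test_mean_matches_negative_binomial_closed_form(self):
        # f = 1/2.8, b = 1, tau = 2.8 -> r = 1, p = 0.5, mean = r*b = 1
        n = 100_000
        counts = simulate_rna_counts(1 / 2.8, 1.0, 2.8, n, rng=1)
        se = counts.std(ddof=1) / np.sqrt(n)
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_vanishing_burst_size_gives_all_zero_counts(self):
        counts = simulate_rna_counts(1.0, 1e-6, 2.8, 10_000, rng=2)
        assert counts.max() == 0

    def test_fixed_seed_reproduces_draws(self):
        a = simulate_rna_counts(0.5, 4.0, 2.8, 1000, rng=42)
        b = simulate_rna_counts(0.5, 4.0, 2.8, 1000, rng=42)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("f,b,tau", [(0, 1, 1), (1, 0, 1), (1, 1, 0)])
    def test_non_positive_parameters_raise(self, f, b, tau):
        with pytest.raises(ValueError):
            simulate_rna_counts(f, b, tau, 10)


class TestThinCounts:
    def test_unit_efficiency_is_identity(self):
        counts = np.array([0, 3, 7, 100])
        np.testing.assert_array_equal(thin_counts(counts, 1.0), counts)

    def test_zeros_stay_zero_and_output_bounded_by_input(self, rng):
        counts = rng.negative_binomial(3, 0.3, size=5000)
        thinned = thin_counts(counts, 0.4, rng)
        assert (thinned <= counts).all()
        assert thin_counts(np.zeros(10, dtype=int), 0.5, rng).max() == 0

    def test_thinned_moments_match_closed_forms(self):
        # Latent NB(r=5, p=0.5): mu = 5, sigma^2 = 10, Fano = 2.
        # Thinned at eps = 0.5: E = 2.5, Fano = 1 + 0.5*(2-1) = 1.5.
        n = 100_000
        rng = np.random.default_rng(3)
        latent = rng.negative_binomial(5, 0.5, size=n)
        thinned = thin_counts(latent, 0.5, np.random.default_rng(4))
        se_mean = thinned.std(ddof=1) / np.sqrt(n)
        assert abs(thinned.mean() - 2.5) < 3 * se_mean
        fano = thinned.var(ddof=1) / thinned.mean()
        # Fano SE for near-NB counts is O(sqrt(1/n)); 3 sigma with margin
        assert abs(fano - 1.5) < 0.05

    @pytest.mark.parametrize("eps", [0.0, -0.1, 1.5])
    def test_efficiency_outside_unit_interval_raises(self, eps):
        with pytest.raises(ValueError):
            thin_counts(np.array([1, 2]), eps)


class TestSimulateProtein:
    def test_noiseless_cells_sit_exactly_on_hill_curve(self):
        hill = HillParams(offset=0.1, amplitude=2.0, k_half=10.0, n=2.0)
        sig = simulate_protein(30.0, hill, 50, cv=0.0, rng=0)
        np.testing.assert_allclose(sig, hill(30.0))

    def test_half_maximal_response_at_k_half(self):
        hill = HillParams(offset=0.0, amplitude=4.0, k_half=25.0, n=1.3)
        sig = simulate_protein(25.0, hill, 10, cv=0.0, rng=0)
        np.testing.assert_allclose(sig, 2.0)

    def test_zero_stimulus_returns_offset(self):
        hill = HillParams(offset=0.7, amplitude=4.0, k_half=25.0, n=1.3)
        sig = simulate_protein(0.0, hill, 10, cv=0.0, rng=0)
        np.testing.assert_allclose(sig, 0.7)

    def test_invalid_hill_parameters_raise(self):
        with pytest.raises(ValueError):
            HillParams(offset=0.0, amplitude=-1.0, k_half=10.0, n=1.0)


class TestSimulateExperiment:
    def test_full_design_produces_12_methods_x_10_samples_x_replicates(
        self, small_config, small_experiment
    ):
        n_samples = len(small_config.stimulus_series) + 2
        assert len(small_experiment) == 12 * n_samples * small_config.n_replicates
        methods = {t.method for t in small_experiment}
        assert methods == set(CANONICAL_METHODS)

    def test_same_seed_is_bit_identical(self, small_config, small_experiment):
        again = simulate_experiment(small_config)
        for a, b in zip(small_experiment, again):
            assert a.method == b.method and a.sample == b.sample
            np.testing.assert_array_equal(a.signal, b.signal)

    def test_equal_efficiencies_give_equal_count_means(self):
        config = SimulationConfig(cells_flow=500, cells_microscopy=500,
                                  efficiency_fish=0.6, efficiency_hcr=0.6, seed=5)
        tables = simulate_experiment(config)
        fish = {t.sample: t for t in tables
                if t.method.measurand is Measurand.RNA_COUNT
                and t.method.preparation is Preparation.FISH}
        hcr = {t.sample: t for t in tables
               if t.method.measurand is Measurand.RNA_COUNT
               and t.method.preparation is Preparation.HCR}
        diffs = []
        for sample, tf in fish.items():
            th = hcr[sample]
            pooled_se = np.sqrt(tf.signal.var() / tf.n_cells + th.signal.var() / th.n_cells)
            if pooled_se > 0:
                diffs.append(abs(tf.signal.mean() - th.signal.mean()) / pooled_se)
        assert np.mean(diffs) < 2.0  # symmetric methods agree within sampling error

    def test_split_sample_contract_shares_latent_counts(self, small_experiment):
        # FISH and HCR counts of one culture are thinnings of the same latent
        # cells, so they must be strongly positively correlated cell-by-cell.
        fish = next(t for t in small_experiment
                    if t.method.measurand is Measurand.RNA_COUNT
                    and t.method.preparation is Preparation.FISH
                    and t.sample.iptg_umol_per_l == 1000.0)
        hcr = next(t for t in small_experiment
                   if t.method.measurand is Measurand.RNA_COUNT
                   and t.method.preparation is Preparation.HCR
                   and t.sample == fish.sample)
        r = np.corrcoef(fish.signal, hcr.signal)[0, 1]
        assert r > 0.5

    def test_flow_and_microscopy_cell_numbers(self, small_config, small_experiment):
        for t in small_experiment:
            expected = (small_config.cells_flow
                        if t.method.detection is Detection.FLOW
                        else small_config.cells_microscopy)
            assert t.n_cells == expected
        micro = [t for t in small_experiment
                 if t.method.detection is Detection.MICROSCOPY]
        assert all(t.dapi is not None for t in micro)

    def test_median_protein_signal_monotone_in_stimulus(self, small_experiment):
        by_level = {
            t.sample.iptg_umol_per_l: np.median(t.signal)
            for t in small_experiment
            if t.method.label == "Kn flow protein"
            and t.sample.construct is Construct.INDUCIBLE
            and t.sample.replicate == 1
        }
        levels = sorted(by_level)
        medians = [by_level[x] for x in levels]
        assert all(b >= a - 1e-9 for a, b in zip(medians, medians[1:]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(efficiency_hcr=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(replicate_potency=(1.0, -1.0, 1.0))
        with pytest.raises(ValueError):
            SimulationConfig(n_replicates=5)  # only 3 potency multipliers


class TestThinningClosure:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nb_family_closed_under_thinning(self, seed):
        # Thinning NB(r, p) keeps r; fitted burst size scales as eps * b.
        f_true, b_true, tau = 0.5, 8.0, 2.8  # r = 1.4
        eps = 0.6
        latent = simulate_rna_counts(f_true, b_true, tau, 5000, rng=seed)
        thinned = thin_counts(latent, eps, np.random.default_rng(100 + seed))
        fit = fit_negative_binomial(thinned)
        r_true = f_true * tau
        assert abs(fit.r - r_true) < 3 * fit.se_r
        b_fit = (1 - fit.p_nb) / fit.p_nb
        assert abs(b_fit - eps * b_true) / (eps * b_true) < 0.15
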