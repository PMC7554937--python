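"""Global spectro-kinetic fitting: rank, recovery, model selection."""

import numpy as np
import pytest

import flavokin as fk
from flavokin.globalfit import AMPLITUDE_FLOOR


def _noiseless_series(rates, n_species, t_min, t_max, wl):
    sp = fk.make_flavin_spectra(n_species, wl)
    sc = fk.SyntheticScenario(
        "t", fk.SequentialMechanism(rates), sp, 7.5,
        fk.log_time_grid(t_min, t_max, 120), noise_sd=0.0, seed=0,
    )
    return fk.simulate_stopped_flow(sc), sp


class TestEstimateRank:
    def test_noiseless_two_species(self, visible_grid):
        ts, _ = _noiseless_series([5.0], 2, 1e-3, 5.0, visible_grid)
        assert fk.estimate_rank(ts) == 2

    def test_noiseless_four_species(self, visible_grid):
        ts, _ = _noiseless_series([78.0, 8.9, 0.9], 4, 1.5e-3, 60.0, visible_grid)
        assert fk.estimate_rank(ts) == 4

    def test_three_species_with_noise(self):
        ts = fk.simulate_stopped_flow(fk.scenario_preset("nadh_2step", seed=2))
        assert fk.estimate_rank(ts) == 3
        assert fk.estimate_rank(ts, noise_sd_hint=ts.meta["noise_sd_AU"]) == 3

    def test_constant_matrix_returns_one(self, visible_grid):
        ts = fk.SpectralTimeSeries(
            times=np.arange(10.0), wavelengths=visible_grid,
            absorbance=np.ones((10, visible_grid.size)),
        )
        assert fk.estimate_rank(ts) == 1


class TestFitSequential:
    def test_noiseless_one_step_exact(self, visible_grid):
        ts, sp = _noiseless_series([5.0], 2, 1e-3, 5.0, visible_grid)
        res = fk.fit_sequential(ts, 1)
        assert res.converged
        assert res.rates[0] == pytest.approx(5.0, rel=1e-6)
        assert np.max(np.abs(res.spectra.matrix - 7.5 * sp.matrix)) < 1e-6
        assert res.residual_ss < 1e-12 * np.sum(ts.absorbance**2)

    def test_nadh_two_step_recovery_within_5pct(self, nadh_series):
        res = fk.fit_sequential(nadh_series, 2)
        truth = nadh_series.meta["true_rates_per_s"]
        assert res.rates[0] == pytest.approx(truth[0], rel=0.05)
        assert res.rates[1] == pytest.approx(truth[1], rel=0.05)

    def test_dic_two_step_recovery_within_5pct(self):
        # the slow rate's single-draw spread at 2% noise is ~4%, so the
        # recovery is checked on a small seed-average of fitted rates
        fitted = []
        for seed in range(5):
            ts = fk.simulate_stopped_flow(fk.scenario_preset("dic_2step", seed=seed))
            fitted.append(fk.fit_sequential(ts, 2).rates)
        mean = np.mean(fitted, axis=0)
        assert mean[0] == pytest.approx(0.034, rel=0.05)
        assert mean[1] == pytest.approx(0.0065, rel=0.05)

    def test_scaling_invariance(self, nadh_series):
        res = fk.fit_sequential(nadh_series, 2)
        scaled = fk.SpectralTimeSeries(
            times=nadh_series.times, wavelengths=nadh_series.wavelengths,
            absorbance=3.0 * nadh_series.absorbance,
        )
        res3 = fk.fit_sequential(scaled, 2)
        assert np.allclose(res3.rates, res.rates, rtol=1e-6)
        assert np.allclose(res3.spectra.matrix, 3.0 * res.spectra.matrix, rtol=1e-4)

    def test_deterministic_given_data_and_init(self, nadh_series):
        a = fk.fit_sequential(nadh_series, 2)
        b = fk.fit_sequential(nadh_series, 2)
        assert a.rates == b.rates and a.residual_ss == b.residual_ss

    def test_replicate_recovery_statistics(self):
        """Over seeded replicates at 2% noise: median rel. error < 2%,
        95% of fits within 10%, for both rates."""
        errs = []
        for seed in range(100):
            ts = fk.simulate_stopped_flow(fk.scenario_preset("nadh_2step", seed=seed))
            res = fk.fit_sequential(ts, 2)
            errs.append([
                abs(res.rates[0] - 78.0) / 78.0,
                abs(res.rates[1] - 8.9) / 8.9,
            ])
        errs = np.asarray(errs)
        assert np.median(errs, axis=0).max() < 0.02
        assert (errs < 0.10).mean(axis=0).min() >= 0.95


class TestSelectModel:
    def test_one_step_data_chooses_one(self, visible_grid):
        sp = fk.make_flavin_spectra(2, visible_grid)
        sc = fk.SyntheticScenario(
            "one", fk.SequentialMechanism([5.0]), sp, 7.5,
            fk.log_time_grid(1e-3, 5.0, 120), noise_sd=0.0017, seed=1,
        )
        chosen, fits = fk.select_model(fk.simulate_stopped_flow(sc), 3)
        assert chosen == 1
        assert len(fits) == 3

    def test_three_step_data_chooses_three(self, visible_grid):
        """Three-step chains with well-separated rates and healthy step
        amplitudes are identified in >= 90% of seeded replicates."""
        base = fk.make_flavin_spectra(4, visible_grid).matrix
        # re-ladder the generator spectra to band-I amplitudes
        # 1 -> .4 -> .1 -> .02 (61/31/8 split), keeping each species'
        # signature band so the set stays full-rank
        lam = np.array([1.0, 0.4, 0.1, 0.02])
        ladder = np.array([1.0, 0.265, 0.0396, 0.02])
        rows = [
            a * base[0] + (base[j] - ladder[j] * base[0])
            for j, a in enumerate(lam)
        ]
        sp = fk.SpeciesSpectrumSet(visible_grid, np.array(rows))
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            sc = fk.SyntheticScenario(
                "three", fk.SequentialMechanism([78.0, 8.9, 0.9]), sp, 7.5,
                fk.log_time_grid(1.5e-3, 60.0, 120), noise_sd=0.0017, seed=seed,
            )
            chosen, _ = fk.select_model(fk.simulate_stopped_flow(sc), 4)
            hits += chosen == 3
        assert hits / n_seeds >= 0.9

    def test_amplitude_floor_rejects_tiny_step(self, visible_grid):
        """A second step carrying 0.5% of the band-I change is rejected."""
        g = fk.make_flavin_spectra(3, visible_grid)
        # amplitudes 1 -> 0.055 -> 0.05: step 2 is 0.5% of the total change
        m = np.array([
            g.matrix[0],
            0.055 * g.matrix[0] + (g.matrix[1] - 0.2875 * g.matrix[0]),
            0.05 * g.matrix[0] + (g.matrix[2] - 0.05 * g.matrix[0]),
        ])
        sp = fk.SpeciesSpectrumSet(visible_grid, m)
        sc = fk.SyntheticScenario(
            "tiny", fk.SequentialMechanism([5.0, 0.5]), sp, 7.5,
            fk.log_time_grid(1e-3, 60.0, 120), noise_sd=0.0017, seed=4,
        )
        chosen, _ = fk.select_model(fk.simulate_stopped_flow(sc), 3)
        assert chosen == 1


class TestBandAmplitudeFractions:
    def test_single_step_fraction_is_one(self, visible_grid):
        ts, _ = _noiseless_series([5.0], 2, 1e-3, 5.0, visible_grid)
        res = fk.fit_sequential(ts, 1)
        assert res.amplitude_fractions == pytest.approx([1.0])

    def test_recovers_constructed_splits(self, visible_grid):
        """A three-step chain built with 75/23/2 band-I splits is recovered
        to within 3 percentage points."""
        ts, _ = _noiseless_series([78.0, 8.9, 0.9], 4, 1.5e-3, 60.0, visible_grid)
        res = fk.fit_sequential(ts, 3)
        assert np.abs(res.amplitude_fractions - [0.75, 0.23, 0.02]).max() < 0.03
        assert res.amplitude_fractions.sum() == pytest.approx(1.0, abs=1e-6)

    def test_non_monotone_sequence_still_sums_to_one(self, visible_grid):
        g = fk.make_flavin_spectra(3, visible_grid)
        # reoxidation-like: bleach then partial recovery
        m = np.array([g.matrix[0], g.matrix[2], 0.5 * g.matrix[0]])
        sp = fk.SpeciesSpectrumSet(visible_grid, m)
        ts, _ = _noiseless_series([5.0, 0.5], 3, 1e-3, 60.0, visible_grid)
        res = fk.fit_sequential(ts, 2)
        fr = fk.band_amplitude_fractions(
            fk.GlobalFitResult(
                mechanism=res.mechanism, rate_se=res.rate_se, spectra=sp,
                residual_ss=0.0, n_params=res.n_params, n_obs=res.n_obs,
                amplitude_fractions=res.amplitude_fractions, converged=True,
            )
        )
        assert fr.sum() == pytest.approx(1.0)
        assert np.all(fr > 0)
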