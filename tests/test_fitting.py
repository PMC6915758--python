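"""Inverse-problem tests: averaging, fitting, interleaving, goodness of fit."""

import numpy as np
import pytest

from depwell import (
    FitConfig,
    FrequencyGrid,
    Mixture,
    Spectrum,
    average_spectra,
    dep_spectrum,
    fit_mixture,
    fit_single_population,
    goodness_of_fit,
    merge_interleaved,
    plan_interleaved_frequencies,
)
from depwell.synthetic import NoiseModel, generate_spectrum, jurkat_mixture


def relerr(a, b):
    return abs(a - b) / abs(b)


def param_errors(result, truth):
    cell = result.components[0]
    return {
        name: relerr(getattr(cell, name), getattr(truth, name))
        for name in ("mem_capacitance", "mem_conductance",
                     "cyt_conductivity", "cyt_rel_permittivity")
    }


class TestAverageSpectra:
    def test_identical_replicates(self, jurkat, grid20):
        cell, medium = jurkat
        base = dep_spectrum(cell, medium, grid20)
        mean = average_spectra([base] * 15)
        np.testing.assert_allclose(mean.response, base.response)
        np.testing.assert_allclose(mean.sd, 0.0, atol=1e-15)
        assert mean.n_replicates == 15

    def test_two_point_mean_and_sd(self):
        grid = FrequencyGrid(np.array([1e3, 1e4, 1e5, 1e6, 1e7, 1e8]))
        a = Spectrum(grid=grid, response=np.zeros(6))
        b = Spectrum(grid=grid, response=np.ones(6))
        mean = average_spectra([a, b])
        np.testing.assert_allclose(mean.response, 0.5)
        np.testing.assert_allclose(mean.sd, np.std([0, 1], ddof=1))

    def test_mean_converges_to_model_as_replicates_grow(self, jurkat, grid20):
        """sd of the mean response shrinks like 1/sqrt(n)."""
        cell, medium = jurkat
        truth = dep_spectrum(cell, medium, grid20).response
        errs = []
        for n in (4, 64):
            reps = generate_spectrum(cell, medium, grid20,
                                     noise=NoiseModel(0.05, seed=3),
                                     n_replicates=n)
            errs.append(np.sqrt(np.mean(
                (average_spectra(reps).response - truth) ** 2)))
        assert errs[1] < errs[0] / 2  # expect ~1/4, allow Monte-Carlo slack

    def test_mismatched_grids_rejected(self, jurkat, grid20):
        cell, medium = jurkat
        a = dep_spectrum(cell, medium, grid20)
        other = FrequencyGrid.log_spaced(1e3, 45e6, 21)
        b = dep_spectrum(cell, medium, other)
        with pytest.raises(ValueError):
            average_spectra([a, b])


class TestGoodnessOfFit:
    def test_identical_spectra_give_one(self, jurkat, grid20):
        spec = dep_spectrum(*jurkat, grid20)
        assert goodness_of_fit(spec, spec) == pytest.approx(1.0)

    def test_uncorrelated_responses_give_zero(self):
        grid = FrequencyGrid(np.array([1e3, 1e4, 1e5, 1e6]))
        a = Spectrum(grid=grid, response=np.array([1.0, -1.0, 1.0, -1.0]))
        b = Spectrum(grid=grid, response=np.array([1.0, 1.0, -1.0, -1.0]))
        assert goodness_of_fit(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_pearson_formula(self):
        grid = FrequencyGrid(np.array([1e3, 1e4, 1e5, 1e6]))
        x = np.array([0.1, 0.4, 0.3, 0.9])
        y = np.array([0.2, 0.5, 0.2, 0.8])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        expected = (num / den) ** 2
        got = goodness_of_fit(Spectrum(grid=grid, response=x),
                              Spectrum(grid=grid, response=y))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_reported_as_nan(self):
        grid = FrequencyGrid(np.array([1e3, 1e4, 1e5, 1e6]))
        flat = Spectrum(grid=grid, response=np.ones(4))
        vary = Spectrum(grid=grid, response=np.arange(4.0))
        assert np.isnan(goodness_of_fit(flat, vary))


class TestSinglePopulationFit:
    def test_noiseless_round_trip_is_exact(self, jurkat, grid20):
        cell, medium = jurkat
        spec = dep_spectrum(cell, medium, grid20)
        result = fit_single_population(spec, medium, cell.radius,
                                       FitConfig(seed=1))
        errs = param_errors(result, cell)
        assert all(v < 1e-4 for v in errs.values()), errs
        assert result.r_squared == pytest.approx(1.0, abs=1e-9)
        assert result.converged

    def test_noisy_fit_recovers_identifiable_parameters(self, jurkat, grid20):
        """3% noise, seeded: membrane capacitance and cytoplasm conductivity
        come back within 5%; membrane conductance and cytoplasm permittivity
        are weakly identifiable for a low-conductance cell at this noise
        level and are not asserted."""
        cell, medium = jurkat
        spec = generate_spectrum(cell, medium, grid20,
                                 noise=NoiseModel(0.03, seed=11))[0]
        result = fit_single_population(spec, medium, cell.radius,
                                       FitConfig(seed=1))
        errs = param_errors(result, cell)
        assert errs["mem_capacitance"] < 0.05
        assert errs["cyt_conductivity"] < 0.05

    def test_averaged_replicates_reach_high_r_squared(self, jurkat, grid20):
        cell, medium = jurkat
        reps = generate_spectrum(cell, medium, grid20,
                                 noise=NoiseModel(0.03, seed=42),
                                 n_replicates=15)
        result = fit_single_population(average_spectra(reps), medium,
                                       cell.radius, FitConfig(seed=1))
        assert result.r_squared >= 0.99

    def test_refit_from_solution_is_fixed_point(self, jurkat, grid20):
        cell, medium = jurkat
        spec = dep_spectrum(cell, medium, grid20)
        first = fit_single_population(spec, medium, cell.radius,
                                      FitConfig(seed=1))
        sol = first.components[0]
        warm = FitConfig(seed=2, n_restarts=1, initial={
            "mem_capacitance": sol.mem_capacitance,
            "mem_conductance": sol.mem_conductance,
            "cyt_conductivity": sol.cyt_conductivity,
            "cyt_rel_permittivity": sol.cyt_rel_permittivity,
            "scale": first.scale,
        })
        second = fit_single_population(spec, medium, cell.radius, warm)
        for name in ("mem_capacitance", "mem_conductance",
                     "cyt_conductivity", "cyt_rel_permittivity"):
            assert relerr(getattr(second.components[0], name),
                          getattr(sol, name)) < 1e-6

    def test_noise_scaling_of_recovery_error(self, jurkat, grid20):
        """Recovery error of the well-identified parameters decreases
        monotonically as the noise level drops."""
        cell, medium = jurkat
        errors = []
        for sd in (0.10, 0.03, 0.01, 0.0):
            per_seed = []
            for seed in (5, 17):
                spec = generate_spectrum(cell, medium, grid20,
                                         noise=NoiseModel(sd, seed=seed))[0]
                res = fit_single_population(spec, medium, cell.radius,
                                            FitConfig(seed=1, n_restarts=4))
                e = param_errors(res, cell)
                per_seed.append(e["mem_capacitance"] + e["cyt_conductivity"])
            errors.append(np.mean(per_seed))
        assert errors[0] > errors[2] > errors[3]
        assert errors[1] > errors[3]

    def test_too_narrow_spectrum_rejected(self, jurkat):
        cell, medium = jurkat
        narrow = FrequencyGrid.log_spaced(1e5, 1e6, 8)
        spec = dep_spectrum(cell, medium, narrow)
        with pytest.raises(ValueError):
            fit_single_population(spec, medium, cell.radius)


class TestMixtureFit:
    def test_single_component_equals_single_population(self, jurkat, grid20):
        cell, medium = jurkat
        spec = dep_spectrum(cell, medium, grid20)
        a = fit_single_population(spec, medium, cell.radius, FitConfig(seed=1))
        b = fit_mixture(spec, medium, [cell.radius], FitConfig(seed=1))
        assert b.weights == pytest.approx([1.0])
        assert relerr(b.components[0].mem_capacitance,
                      a.components[0].mem_capacitance) < 1e-9

    def test_ninety_ten_weight_recovery(self, grid20):
        """90/10 mixture of healthy and low-conductivity Jurkat cells,
        averaged over 15 replicates at 1% noise: the majority weight comes
        back within +/- 0.05.  The two populations share membrane
        capacitance and cytoplasm permittivity (fixed at the common
        values); the distinguishing parameters and weights are free."""
        mix, medium = jurkat_mixture(0.9)
        reps = generate_spectrum(mix, medium, grid20,
                                 noise=NoiseModel(0.01, seed=4),
                                 n_replicates=15)
        cfg = FitConfig(
            n_populations=2, seed=2, n_restarts=12,
            free={"mem_capacitance": False, "cyt_rel_permittivity": False,
                  "mem_conductance": True, "cyt_conductivity": True},
            fixed_values={"mem_capacitance": 9.96e-3,
                          "cyt_rel_permittivity": 60.0})
        result = fit_mixture(average_spectra(reps), medium,
                             [6.5e-6, 6.5e-6], cfg)
        # components sorted by ascending cytoplasm conductivity:
        # the low-conductivity minority comes first
        assert result.weights[1] == pytest.approx(0.9, abs=0.05)
        assert result.components[0].cyt_conductivity < \
            result.components[1].cyt_conductivity

    def test_identical_components_flag_weight_degeneracy(self, jurkat, grid20):
        cell, medium = jurkat
        spec = dep_spectrum(Mixture((cell, cell), np.array([0.5, 0.5])),
                            medium, grid20)
        cfg = FitConfig(
            n_populations=2, seed=1, n_restarts=2,
            free={"mem_capacitance": False, "cyt_rel_permittivity": False,
                  "mem_conductance": False, "cyt_conductivity": False},
            fixed_values={"mem_capacitance": cell.mem_capacitance,
                          "cyt_rel_permittivity": cell.cyt_rel_permittivity,
                          "mem_conductance": cell.mem_conductance,
                          "cyt_conductivity": cell.cyt_conductivity})
        result = fit_mixture(spec, medium, [cell.radius, cell.radius], cfg)
        assert result.weight_degenerate

    def test_more_than_four_components_rejected(self, jurkat, grid20):
        spec = dep_spectrum(*jurkat, grid20)
        with pytest.raises(ValueError):
            fit_mixture(spec, jurkat[1], [6.5e-6] * 5)


class TestInterleaving:
    def test_printed_shift_factor(self):
        _, factor = plan_interleaved_frequencies(1e3, 40e6, 20, 5)
        assert round(factor, 3) == 1.118
        # the 45 MHz span variant gives 1.119
        _, factor45 = plan_interleaved_frequencies(1e3, 45e6, 20, 5)
        assert round(factor45, 3) == 1.119

    def test_single_chip_returns_base_grid(self):
        grids, factor = plan_interleaved_frequencies(1e3, 40e6, 20, 1)
        assert len(grids) == 1
        expected = np.logspace(3, np.log10(40e6), 20)
        np.testing.assert_allclose(grids[0].frequencies, expected, rtol=1e-12)
        assert factor == pytest.approx((40e6 / 1e3) ** (1 / 19))

    def test_merged_plan_is_uniform_log_grid(self):
        grids, factor = plan_interleaved_frequencies(1e3, 40e6, 20, 5)
        merged = np.sort(np.concatenate([g.frequencies for g in grids]))
        assert merged.size == 100
        ratios = merged[1:] / merged[:-1]
        np.testing.assert_allclose(ratios, factor, rtol=1e-9)

    def test_merge_interleaved_spectra(self, jurkat):
        cell, medium = jurkat
        grids, _ = plan_interleaved_frequencies(1e3, 40e6, 20, 5)
        spectra = [dep_spectrum(cell, medium, g) for g in grids]
        merged = merge_interleaved(spectra)
        assert len(merged.grid) == 100
        assert np.all(np.diff(merged.frequencies) > 0)

    def test_merge_single_input_unchanged(self, jurkat, grid20):
        spec = dep_spectrum(*jurkat, grid20)
        assert merge_interleaved([spec]) is spec

    def test_merge_collapses_duplicates_with_warning(self, jurkat, grid20, caplog):
        spec = dep_spectrum(*jurkat, grid20)
        with caplog.at_level("WARNING", logger="depwell.fitting"):
            merged = merge_interleaved([spec, spec])
        assert len(merged.grid) == 20
        np.testing.assert_allclose(merged.response, spec.response)
        assert any("duplicate" in r.message for r in caplog.records)

    def test_twenty_and_hundred_point_fits_agree(self, jurkat):
        """On synthetic data, 20-point spectra carry the same information
        as interleaved 100-point spectra: fitted parameters agree."""
        cell, medium = jurkat
        grids, _ = plan_interleaved_frequencies(1e3, 45e6, 20, 5)
        merged = merge_interleaved(
            [dep_spectrum(cell, medium, g) for g in grids])
        r20 = fit_single_population(dep_spectrum(cell, medium, grids[0]),
                                    medium, cell.radius, FitConfig(seed=1))
        r100 = fit_single_population(merged, medium, cell.radius,
                                     FitConfig(seed=1))
        for name in ("mem_capacitance", "mem_conductance",
                     "cyt_conductivity", "cyt_rel_permittivity"):
            assert relerr(getattr(r100.components[0], name),
                          getattr(r20.components[0], name)) < 1e-4
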