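import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laurdangp.errors import (
    EmptyDataError,
    EmptyRegionError,
    InvalidParameterError,
)
from laurdangp.gp import compute_gp_map, gp_from_spectrum
from laurdangp.populations import (
    compare_conditions,
    fit_gaussian_mixture,
    gp_histogram,
    mean_of_flash_gps,
    region_gp_stats,
    select_component_count,
    well_gp,
)
from laurdangp.spectra import EmissionSpectrum
from laurdangp.spectral_io import PlateRecord
from laurdangp.synthetic import (
    LABEL_BACKGROUND,
    LABEL_INTERIOR,
    LABEL_MEMBRANE,
    CalciumSeriesConfig,
    HillOrderMap,
    make_calcium_series,
    mix_spectrum,
)


class TestGPHistogram:
    def test_point_mass(self):
        h = gp_histogram(np.full(100, 0.245))
        assert np.count_nonzero(h.frequencies) == 1
        assert h.frequencies.max() == 1.0

    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=500))
    @settings(max_examples=50, deadline=None)
    def test_normalization_property(self, values):
        h = gp_histogram(np.array(values))
        assert h.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(h.frequencies >= 0)

    def test_monte_carlo_moment(self):
        rng = np.random.default_rng(0)
        h = gp_histogram(rng.normal(0.2, 0.05, 100_000))
        assert h.mean == pytest.approx(0.2, abs=0.005)

    def test_uniform_bin_spacing(self):
        h = gp_histogram(np.array([0.0, 0.5]), bin_width=0.02)
        assert np.allclose(np.diff(h.bin_centers), 0.02)
        assert h.bin_centers.size == 100

    def test_out_of_range_clipped_with_count(self):
        with pytest.warns(UserWarning, match="clipped"):
            h = gp_histogram(np.array([-2.0, 0.0, 3.0]), value_range=(-1, 1))
        assert h.n_clipped == 2
        assert h.frequencies.sum() == pytest.approx(1.0)

    def test_empty_input(self):
        with pytest.raises(EmptyDataError):
            gp_histogram(np.array([]))


class TestFitGaussianMixture:
    def test_single_gaussian_recovery(self):
        rng = np.random.default_rng(1)
        n, mu, sd = 20_000, 0.15, 0.05
        vals = rng.normal(mu, sd, n)
        for method in ("histogram_ls", "em"):
            fit = fit_gaussian_mixture(vals, k=1, method=method, seed=0)
            se = sd / np.sqrt(n)
            assert fit.components[0].mean == pytest.approx(mu, abs=3 * se + 1e-3)
            assert fit.components[0].sd == pytest.approx(sd, rel=0.05)

    @pytest.mark.parametrize("method", ["histogram_ls", "em"])
    def test_two_separated_gaussians(self, method):
        # delta mean = 0.35 >= 4 * sd (sd = 0.05), n = 1e5
        rng = np.random.default_rng(2)
        vals = np.concatenate(
            [rng.normal(-0.09, 0.05, 60_000), rng.normal(0.26, 0.05, 40_000)]
        )
        fit = fit_gaussian_mixture(vals, k=2, method=method, seed=0)
        assert fit.means[0] == pytest.approx(-0.09, abs=0.01)
        assert fit.means[1] == pytest.approx(0.26, abs=0.01)
        assert fit.weights[0] == pytest.approx(0.6, abs=0.02)

    def test_components_sorted_and_labeled(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate(
            [rng.normal(0.3, 0.04, 5000), rng.normal(-0.1, 0.04, 5000)]
        )
        fit = fit_gaussian_mixture(vals, k=2, seed=0)
        assert fit.means[0] < fit.means[1]
        assert fit.component_label(0) == "cytosolic (low-GP)"
        assert fit.component_label(1) == "plasma membrane (high-GP)"

    def test_symmetric_sample_equal_weights(self):
        rng = np.random.default_rng(4)
        half = rng.normal(0.2, 0.03, 30_000)
        vals = np.concatenate([half, -half])  # exactly symmetric about 0
        fit = fit_gaussian_mixture(vals, k=2, seed=0)
        assert fit.weights[0] == pytest.approx(0.5, abs=0.02)
        assert fit.weights[1] == pytest.approx(0.5, abs=0.02)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 0.1, 2000)
        for method in ("histogram_ls", "em"):
            fit = fit_gaussian_mixture(vals, k=2, method=method, seed=0)
            assert fit.weights.sum() == pytest.approx(1.0, abs=1e-6)
            assert all(c.sd > 0 for c in fit.components)

    def test_histogram_input_accepted(self):
        rng = np.random.default_rng(6)
        h = gp_histogram(rng.normal(0.1, 0.05, 10_000))
        fit = fit_gaussian_mixture(h, k=1, method="histogram_ls", seed=0)
        assert fit.components[0].mean == pytest.approx(0.1, abs=0.01)

    def test_em_requires_raw_values(self):
        h = gp_histogram(np.random.default_rng(0).normal(0, 0.1, 1000))
        with pytest.raises(InvalidParameterError):
            fit_gaussian_mixture(h, k=1, method="em")

    def test_too_few_values(self):
        with pytest.raises(EmptyDataError):
            fit_gaussian_mixture(np.zeros(15) + 0.1, k=2)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate(
            [rng.normal(-0.1, 0.05, 3000), rng.normal(0.3, 0.05, 3000)]
        )
        f1 = fit_gaussian_mixture(vals, k=2, seed=42)
        f2 = fit_gaussian_mixture(vals, k=2, seed=42)
        np.testing.assert_array_equal(f1.means, f2.means)


class TestSelectComponentCount:
    def test_unimodal_selects_one(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0.1, 0.05, 10_000)
        fit = select_component_count(vals, seed=0)
        assert fit.k == 1

    def test_bimodal_selects_two(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate(
            [rng.normal(-0.1, 0.04, 6000), rng.normal(0.25, 0.05, 4000)]
        )
        fit = select_component_count(vals, seed=0)
        assert fit.k == 2

    def test_singleton_candidates(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(0.1, 0.05, 5000)
        fit = select_component_count(vals, k_candidates=(2,), seed=0)
        assert fit.k == 2


class TestRegionStats:
    def test_homogeneous_region_zero_sd(self, basis):
        from laurdangp.synthetic import CellPhantomConfig, make_cell_image

        config = CellPhantomConfig(
            image_size=(24, 24), outer_radius=9.0, ring_thickness=2.0,
            interior_order=0.4, membrane_order=0.4, noise_model="none", seed=0,
        )
        image, labels = make_cell_image(config, basis)
        gp_map = compute_gp_map(image, mode="band")
        stats = region_gp_stats(gp_map, labels != LABEL_BACKGROUND)
        assert stats.sd == pytest.approx(0.0, abs=1e-12)

    def test_membrane_mean_matches_analytic(self, noiseless_phantom, basis):
        config, image, labels = noiseless_phantom
        gp_map = compute_gp_map(image, mode="band")
        stats = region_gp_stats(gp_map, labels == LABEL_MEMBRANE)
        assert stats.mean == pytest.approx(
            basis.analytic_gp(config.membrane_order), abs=1e-6
        )

    def test_partition_conservation(self, noiseless_phantom):
        _, image, labels = noiseless_phantom
        gp_map = compute_gp_map(image, mode="band")
        n_mem = region_gp_stats(gp_map, labels == LABEL_MEMBRANE).n
        n_int = region_gp_stats(gp_map, labels == LABEL_INTERIOR).n
        n_cell = region_gp_stats(gp_map, labels != LABEL_BACKGROUND).n
        assert n_mem + n_int == n_cell

    def test_empty_region(self, noiseless_phantom):
        _, image, labels = noiseless_phantom
        gp_map = compute_gp_map(image, mode="band")
        with pytest.raises(EmptyRegionError):
            region_gp_stats(gp_map, np.zeros_like(labels, dtype=bool))


class TestWellGP:
    def _records(self, spectra, well="A1"):
        return [
            PlateRecord(well=well, condition=0.06, flash=i + 1, spectrum=s)
            for i, s in enumerate(spectra)
        ]

    def test_identical_flashes_idempotent(self, basis):
        spec = mix_spectrum(basis, 0.6, 200.0)
        recs = self._records([spec] * 25)
        assert well_gp(recs).gp == pytest.approx(gp_from_spectrum(spec).gp)

    def test_two_population_pooling(self, basis):
        mem = mix_spectrum(basis, 0.9, 100.0)
        cyt = mix_spectrum(basis, 0.1, 100.0)
        pooled = EmissionSpectrum(
            basis.wavelengths, mem.intensities + cyt.intensities
        )
        recs = self._records([pooled] * 25)
        gp = well_gp(recs).gp
        assert gp_from_spectrum(cyt).gp < gp < gp_from_spectrum(mem).gp

    def test_poisson_flash_average_close_to_noiseless(self, basis):
        rng = np.random.default_rng(12)
        clean = mix_spectrum(basis, 0.5, 500.0)
        noisy = [
            EmissionSpectrum(
                basis.wavelengths, rng.poisson(clean.intensities).astype(float)
            )
            for _ in range(25)
        ]
        assert well_gp(self._records(noisy)).gp == pytest.approx(
            gp_from_spectrum(clean).gp, abs=0.01
        )

    def test_few_flashes_warns(self, basis):
        spec = mix_spectrum(basis, 0.5, 100.0)
        with pytest.warns(UserWarning, match="25"):
            well_gp(self._records([spec] * 5))

    def test_mean_of_flash_gps_close_to_well_gp(self, basis):
        rng = np.random.default_rng(13)
        clean = mix_spectrum(basis, 0.5, 500.0)
        noisy = [
            EmissionSpectrum(
                basis.wavelengths, rng.poisson(clean.intensities).astype(float)
            )
            for _ in range(25)
        ]
        recs = self._records(noisy)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert mean_of_flash_gps(recs) == pytest.approx(well_gp(recs).gp, abs=0.01)

    def test_mixed_wells_rejected(self, basis):
        spec = mix_spectrum(basis, 0.5, 100.0)
        recs = self._records([spec], "A1") + self._records([spec], "B1")
        with pytest.raises(InvalidParameterError):
            well_gp(recs)

    def test_empty_records(self):
        with pytest.raises(EmptyDataError):
            well_gp([])


class TestCompareConditions:
    def test_identical_values_f_zero(self):
        groups = {0.06: np.full(5, 0.2), 0.3: np.full(5, 0.2), 1.5: np.full(5, 0.2)}
        res = compare_conditions(groups)
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_shifted_conditions_significant(self):
        # shift 0.2 GP, sd 0.03, n = 6 -> overwhelming power
        rng = np.random.default_rng(14)
        groups = {
            0.06: rng.normal(0.1, 0.03, 6),
            1.5: rng.normal(0.3, 0.03, 6),
        }
        res = compare_conditions(groups)
        assert res.p_value < 0.05
        assert res.tukey["p_value"].iloc[0] < 0.05

    def test_type_one_error_calibration_small(self):
        # quick 300-rep null check; the full 1000-rep version is in acceptance
        rejections = 0
        for i in range(300):
            rng = np.random.default_rng(20_000 + i)
            groups = {c: rng.normal(0.2, 0.03, 6) for c in (0.06, 0.3, 1.5)}
            if compare_conditions(groups).p_value < 0.05:
                rejections += 1
        rate = rejections / 300
        assert 0.025 <= rate <= 0.08  # wide bound for the small-n version

    def test_single_replicate_excluded(self):
        rng = np.random.default_rng(15)
        groups = {
            0.06: rng.normal(0.1, 0.03, 6),
            0.3: np.array([0.2]),
            1.5: rng.normal(0.3, 0.03, 6),
        }
        with pytest.warns(UserWarning, match="excluded"):
            res = compare_conditions(groups)
        assert res.excluded == [0.3]
        assert len(res.summaries) == 2

    def test_summaries_recomputable(self):
        rng = np.random.default_rng(16)
        vals = rng.normal(0.2, 0.05, 30)
        groups = {0.06: vals, 1.5: rng.normal(0.4, 0.05, 30)}
        res = compare_conditions(groups)
        s = res.summaries[0]
        assert s.mean == pytest.approx(vals.mean())
        assert s.q1 == pytest.approx(np.percentile(vals, 25))
        assert s.whisker_low >= s.q1 - 1.5 * (s.q3 - s.q1)
        assert s.whisker_high <= s.q3 + 1.5 * (s.q3 - s.q1)

    def test_too_few_conditions(self):
        with pytest.raises(EmptyDataError):
            compare_conditions({0.06: np.array([0.1, 0.2])})


class TestWholeVsParts:
    """Whole-cell k=2 decomposition vs per-compartment statistics."""

    def test_mixture_means_match_region_means(self, noisy_phantom, basis):
        config, image, labels = noisy_phantom
        gp_map = compute_gp_map(image, mode="band")
        whole = fit_gaussian_mixture(gp_map.valid_values, k=2, seed=0)
        mem = region_gp_stats(gp_map, labels == LABEL_MEMBRANE)
        cyt = region_gp_stats(gp_map, labels == LABEL_INTERIOR)
        assert whole.means[0] == pytest.approx(cyt.mean, abs=0.05)
        assert whole.means[1] == pytest.approx(mem.mean, abs=0.05)

    def test_high_gp_mean_increases_with_membrane_order(self, basis):
        from laurdangp.synthetic import CellPhantomConfig, make_cell_image

        high_means = []
        for order in (0.5, 0.7, 0.9):
            config = CellPhantomConfig(
                image_size=(40, 40), outer_radius=15.0, ring_thickness=4.0,
                interior_order=0.2, membrane_order=order, brightness=800.0,
                noise_model="poisson", seed=21,
            )
            image, _ = make_cell_image(config, basis)
            gp_map = compute_gp_map(image, mode="band")
            fit = fit_gaussian_mixture(gp_map.valid_values, k=2, seed=0)
            high_means.append(fit.means[1])
        assert high_means[0] < high_means[1] < high_means[2]


class TestCalciumSeriesMonotonicity:
    def test_mean_well_gp_nondecreasing(self, basis):
        config = CalciumSeriesConfig(
            calcium_levels=(0.06, 0.3, 0.6, 1.5),
            order_map=HillOrderMap(),
            wells_per_level=3,
            flashes_per_well=25,
            seed=17,
        )
        records, truth, _ = make_calcium_series(config, basis)
        by_level: dict[float, list[float]] = {}
        by_well: dict[str, list] = {}
        for rec in records:
            by_well.setdefault(rec.well, []).append(rec)
        for recs in by_well.values():
            by_level.setdefault(recs[0].condition, []).append(well_gp(recs).gp)
        levels = sorted(by_level)
        means = [np.mean(by_level[c]) for c in levels]
        assert np.all(np.diff(means) >= 0)

    def test_plate_path_matches_imaging_path(self, basis):
        # ensemble (well) GP vs whole-image mean GP on matched phantoms
        from laurdangp.synthetic import CellPhantomConfig, make_cell_image

        order = 0.6
        config = CalciumSeriesConfig(
            calcium_levels=(1.0,),
            order_map=HillOrderMap(floor=order, ceiling=order),
            wells_per_level=1,
            flashes_per_well=25,
            membrane_fraction=0.5,
            interior_order=0.15,
            seed=18,
        )
        records, _, _ = make_calcium_series(config, basis)
        plate_gp = well_gp(records).gp
        phantom = CellPhantomConfig(
            image_size=(48, 48), outer_radius=18.0, ring_thickness=5.6,
            interior_order=0.15, membrane_order=order, brightness=500.0,
            noise_model="poisson", seed=18,
        )
        image, _ = make_cell_image(phantom, basis)
        gp_map = compute_gp_map(image, mode="band")
        # differently weighted averages of the same two populations
        assert plate_gp == pytest.approx(float(gp_map.valid_values.mean()), abs=0.05)
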