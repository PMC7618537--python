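"""Generator contracts: grids, band spectra, glass background, two-layer
mixing, dataset structure and outlier injection."""

import numpy as np
import pytest

import sorscreen as sc
from sorscreen.synthetic import WATER, SODIUM_CHLORIDE, SUCROSE


class TestBuildGrid:
    @pytest.mark.parametrize(
        "lo,hi,step,n,first,last",
        [(200, 2000, 1, 1801, 200.0, 2000.0),
         (760, 1720, 1, 961, 760.0, 1720.0),
         (600, 1800, 0.5, 2401, 600.0, 1800.0)],
    )
    def test_inclusive_uniform(self, lo, hi, step, n, first, last):
        g = sc.build_grid(lo, hi, step)
        assert len(g) == n
        assert g.values[0] == first and g.values[-1] == last
        assert np.allclose(np.diff(g.values), step)

    @pytest.mark.parametrize("lo,hi,step", [(1000, 900, 1), (760, 760, 1),
                                            (200, 2000, 0), (200, 2000, -1)])
    def test_degenerate_arguments(self, lo, hi, step):
        with pytest.raises(ValueError):
            sc.build_grid(lo, hi, step)


class TestSubstanceSpectrum:
    def test_water_band_peaks_at_1640(self, grid):
        y = sc.substance_spectrum(WATER, grid)
        assert grid.values[np.argmax(y)] == 1640.0

    def test_raman_silent_nacl_is_zero(self, grid):
        assert not np.any(sc.substance_spectrum(SODIUM_CHLORIDE, grid))

    def test_linearity_two_bands_equal_double_amplitude(self, grid):
        b = sc.RamanBand(1100.0, 30.0, 5.0)
        twice = sc.SubstanceModel("x", (b, b))
        double = sc.SubstanceModel("x", (sc.RamanBand(1100.0, 30.0, 10.0),))
        np.testing.assert_array_equal(
            sc.substance_spectrum(twice, grid), sc.substance_spectrum(double, grid)
        )

    def test_doubling_all_amplitudes_doubles_content(self, grid):
        doubled = [s.scaled(2.0) for s in sc.CLASS_LIBRARY["genuine"]]
        np.testing.assert_allclose(
            sc.class_content(doubled, grid),
            2.0 * sc.class_content(sc.CLASS_LIBRARY["genuine"], grid),
            rtol=0, atol=1e-12,
        )

    def test_nonnegative(self, grid):
        assert np.all(sc.substance_spectrum(SUCROSE, grid) >= 0)


class TestGlassBackground:
    def test_peak_at_675(self, noiseless_instrument, grid):
        bg = sc.glass_background(noiseless_instrument, grid)
        assert grid.values[np.argmax(bg)] == 675.0

    def test_nonnegative_and_unimodal(self, noiseless_instrument, grid):
        bg = sc.glass_background(noiseless_instrument, grid)
        assert np.all(bg >= 0)
        peak = np.argmax(bg)
        d = np.diff(bg)
        assert np.all(d[:peak] > 0) and np.all(d[peak:] < 0)

    def test_grid_must_cover_peak(self, noiseless_instrument):
        with pytest.raises(ValueError):
            sc.glass_background(noiseless_instrument, sc.build_grid(800, 2000, 1))


class TestSimulatePair:
    def test_surface_only_proportionality(self, noiseless_instrument, grid):
        pair = sc.simulate_pair(np.zeros(len(grid)), noiseless_instrument, grid, 0)
        ratio = (noiseless_instrument.surface_offset
                 / noiseless_instrument.surface_zero)
        np.testing.assert_allclose(
            pair.offset.intensities, ratio * pair.zero_offset.intensities,
            rtol=1e-12,
        )

    def test_closed_form_mixture(self, genuine_content, noiseless_instrument, grid):
        # offset − (β_s/α_s)·zero = (β_c − (β_s/α_s)·α_c)·C = 0.22·C
        pair = sc.simulate_pair(genuine_content, noiseless_instrument, grid, 0)
        lhs = pair.offset.intensities - 0.4 * pair.zero_offset.intensities
        np.testing.assert_allclose(lhs, 0.22 * genuine_content, atol=1e-10)

    def test_same_seed_bit_identical(self, genuine_content, grid):
        inst = sc.InstrumentModel()
        a = sc.simulate_pair(genuine_content, inst, grid, 42)
        b = sc.simulate_pair(genuine_content, inst, grid, 42)
        np.testing.assert_array_equal(a.zero_offset.intensities,
                                      b.zero_offset.intensities)
        np.testing.assert_array_equal(a.offset.intensities, b.offset.intensities)

    def test_offset_enrichment_invariant_rejected(self):
        with pytest.raises(ValueError):
            sc.InstrumentModel(content_zero=0.5, content_offset=0.1)

    def test_offset_enriches_content_fraction(self, genuine_content,
                                              noiseless_instrument, grid):
        pair = sc.simulate_pair(genuine_content, noiseless_instrument, grid, 0)
        surface = sc.glass_background(noiseless_instrument, grid)
        i = noiseless_instrument
        frac_zero = np.mean(i.content_zero * genuine_content) / np.mean(
            pair.zero_offset.intensities)
        frac_off = np.mean(i.content_offset * genuine_content) / np.mean(
            pair.offset.intensities)
        assert frac_off > frac_zero
        assert np.all(surface >= 0)


class TestGenerateDataset:
    def test_counts_and_vial_structure(self):
        pairs = sc.generate_dataset(["genuine"], n_vials=45, replicates=6, seed=0)
        assert len(pairs) == 270
        assert len({p.vial_id for p in pairs}) == 45

    def test_genuine_content_band_positions(self, grid):
        content = sc.class_content(sc.CLASS_LIBRARY["genuine"], grid)
        m880 = grid.window_mask(840, 920)
        m1640 = grid.window_mask(1550, 1720)
        assert grid.values[m880][np.argmax(content[m880])] == 880.0
        assert grid.values[m1640][np.argmax(content[m1640])] == 1640.0

    def test_saline_content_equals_water_only(self, grid):
        np.testing.assert_array_equal(
            sc.class_content(sc.CLASS_LIBRARY["saline"], grid),
            sc.class_content(sc.CLASS_LIBRARY["water"], grid),
        )

    def test_replicates_share_content_realisation(self, grid):
        inst = sc.InstrumentModel(noise_scale=0.0)
        pairs = sc.generate_dataset(["genuine"], n_vials=2, replicates=3,
                                    instrument=inst, seed=5)
        by_vial = {}
        for p in pairs:
            by_vial.setdefault(p.vial_id, []).append(p)
        for reps in by_vial.values():
            for p in reps[1:]:
                np.testing.assert_allclose(
                    p.offset.intensities, reps[0].offset.intensities, atol=1e-9
                )

    def test_unknown_class_in_batch_plan(self):
        with pytest.raises(ValueError):
            sc.generate_dataset(["genuine"], batch_plan={"nope": ["B1"]})

    def test_unknown_class_name(self):
        with pytest.raises(ValueError):
            sc.generate_dataset(["not-a-class"])

    def test_determinism(self):
        a = sc.generate_dataset(["genuine"], n_vials=2, replicates=2, seed=9)
        b = sc.generate_dataset(["genuine"], n_vials=2, replicates=2, seed=9)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.offset.intensities,
                                          pb.offset.intensities)

    def test_batch_neutrality_mean_spectra_agree(self):
        # batch tags do not enter the signal model: per-batch mean offset
        # spectra agree within Monte-Carlo error
        pairs = sc.generate_dataset(["genuine"], n_vials=24, replicates=2, seed=2)
        batches = {}
        for p in pairs:
            batches.setdefault(p.batch, []).append(p.offset.intensities)
        means = [np.mean(v, axis=0) for v in batches.values()]
        grand = np.mean(means, axis=0)
        for m in means:
            assert np.max(np.abs(m - grand)) / np.max(grand) < 0.02


class TestInjectOutlier:
    def test_locality_and_magnitude(self, genuine_50):
        bad = sc.inject_outlier(genuine_50, 7, "spike", seed=0)
        diff_rows = np.flatnonzero(
            np.any(bad.matrix != genuine_50.matrix, axis=1))
        assert diff_rows.tolist() == [7]
        assert bad.matrix[7].max() >= 3 * genuine_50.matrix[7].max()

    def test_scaled_baseline_mode(self, genuine_50):
        bad = sc.inject_outlier(genuine_50, 3, "scaled-baseline", seed=0)
        np.testing.assert_allclose(bad.matrix[3], 5.0 * genuine_50.matrix[3])

    def test_determinism(self, genuine_50):
        a = sc.inject_outlier(genuine_50, 7, "spike", seed=4)
        b = sc.inject_outlier(genuine_50, 7, "spike", seed=4)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_row_out_of_range(self, genuine_50):
        with pytest.raises(IndexError):
            sc.inject_outlier(genuine_50, genuine_50.n_spectra, "spike")
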