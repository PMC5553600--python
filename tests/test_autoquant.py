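import numpy as np
import pytest
from dataclasses import replace

from lgequant.autoquant import (
    CorrectionSet,
    FWHMParams,
    WeightedThresholdParams,
    apply_corrections,
    fwhm_infarct,
    simulate_corrections,
    weighted_infarct,
)
from lgequant.geometry import ImageStack, InfarctMap, infarct_size
from lgequant.phantom import PhantomSpec, ReaderModel, generate_phantom

from conftest import analytic_stack, sector_values


def percent(infarct_map, mask, stack):
    return infarct_size(infarct_map, mask, stack).percent_lv


class TestWeightedInfarct:
    def test_uniform_myocardium_null(self):
        stack, mask, _, _ = analytic_stack()
        m = weighted_infarct(stack, mask)
        assert m.status == "no infarct detected"
        assert percent(m, mask, stack) == 0.0

    def test_two_level_phantom_exact(self):
        """Noiseless bright sector: every supra-threshold voxel at plateau weight 1."""
        stack, mask, rr, theta = analytic_stack(
            values=sector_values(1000.0, 108.0)
        )
        m = weighted_infarct(stack, mask)
        d = np.abs((theta - 90.0 + 180.0) % 360.0 - 180.0)
        sector_frac = ((d <= 54.0) & mask.mask[0]).sum() / mask.mask[0].sum()
        assert percent(m, mask, stack) == pytest.approx(100 * sector_frac, abs=1e-9)
        assert set(np.unique(m.weights)) <= {0.0, 1.0}

    def test_three_level_grey_half_weight(self):
        """A grey shell at (t+F)/2 receives weight exactly 0.5."""

        def values(rr, theta):
            d = np.abs((theta - 90.0 + 180.0) % 360.0 - 180.0)
            out = np.full_like(rr, np.nan)
            out[d <= 36.0] = 1000.0  # core
            out[(d > 36.0) & (d <= 54.0)] = 550.0  # grey at (100+1000)/2
            return out

        stack, mask, rr, theta = analytic_stack(values=values)
        m = weighted_infarct(stack, mask)
        d = np.abs((theta - 90.0 + 180.0) % 360.0 - 180.0)
        myo = mask.mask[0]
        n_core = (myo & (d <= 36.0)).sum()
        n_grey = (myo & (d > 36.0) & (d <= 54.0)).sum()
        expected = 100.0 * (n_core + 0.5 * n_grey) / myo.sum()
        assert percent(m, mask, stack) == pytest.approx(expected, abs=1e-9)

    def test_scale_invariance(self):
        stack, mask, _, _ = analytic_stack(values=sector_values(1000.0, 90.0))
        m1 = weighted_infarct(stack, mask)
        scaled = ImageStack(
            intensities=stack.intensities * 3.7,
            pixel_spacing=stack.pixel_spacing,
            slice_thickness=stack.slice_thickness,
        )
        m2 = weighted_infarct(scaled, mask)
        assert np.allclose(m1.weights, m2.weights)


class TestFWHM:
    def test_binary_phantom_threshold(self):
        """remote=0, infarct=1000: threshold 500 selects exactly the bright voxels."""
        stack, mask, rr, theta = analytic_stack(
            remote=0.0, values=sector_values(1000.0, 90.0)
        )
        m = fwhm_infarct(stack, mask, FWHMParams(max_estimator="global_max"))
        bright = mask.mask & (stack.intensities == 1000.0)
        assert np.array_equal(m.weights > 0, bright)

    def test_linear_ramp_half_max_cut(self):
        """Voxels at 0.6 M are included, voxels at 0.4 M excluded."""

        def values(rr, theta):
            d = np.abs((theta - 90.0 + 180.0) % 360.0 - 180.0)
            out = np.full_like(rr, np.nan)
            out[d <= 20.0] = 1000.0
            out[(d > 20.0) & (d <= 30.0)] = 600.0
            out[(d > 30.0) & (d <= 40.0)] = 400.0
            return out

        stack, mask, rr, theta = analytic_stack(remote=50.0, values=values)
        m = fwhm_infarct(stack, mask, FWHMParams(max_estimator="global_max"))
        assert np.all(m.weights[(stack.intensities == 600.0)] == 1.0)
        assert np.all(m.weights[(stack.intensities == 400.0)] == 0.0)

    def test_uniform_guarded_to_zero(self):
        stack, mask, _, _ = analytic_stack()
        with pytest.warns(UserWarning, match="no credible hyperenhancement"):
            m = fwhm_infarct(stack, mask)
        assert m.weights.sum() == 0.0

    def test_half_range_affine_invariance(self):
        spec = PhantomSpec(grid=(80, 80, 6), endo_radius_by_slice=[20.0] * 6,
                           epi_radius_by_slice=[28.0] * 6, noise_sd=15.0,
                           noise_model="gaussian", pixel_spacing=(1.2, 1.2))
        stack, truth = generate_phantom(spec, 3)
        from lgequant.geometry import MyocardiumMask

        mask = MyocardiumMask(mask=truth.myocardium_mask)
        params = FWHMParams(reference="half_range")
        m1 = fwhm_infarct(stack, mask, params)
        affine = ImageStack(
            intensities=2.5 * stack.intensities + 40.0,
            pixel_spacing=stack.pixel_spacing,
            slice_thickness=stack.slice_thickness,
        )
        m2 = fwhm_infarct(affine, mask, params)
        assert np.array_equal(m1.weights, m2.weights)


class TestCorrections:
    def _map(self, stack, mask):
        return weighted_infarct(stack, mask)

    def test_empty_corrections_identity(self):
        stack, mask, _, _ = analytic_stack(values=sector_values(1000.0, 90.0))
        m = self._map(stack, mask)
        out = apply_corrections(m, CorrectionSet(), stack, mask)
        assert np.array_equal(out.weights, m.weights)

    def test_add_region_increases_by_its_share(self):
        """Adding a missed dark no-reflow core raises %LV by exactly its share."""
        spec = PhantomSpec(
            grid=(96, 96, 4),
            pixel_spacing=(1.0, 1.0),
            endo_radius_by_slice=[22.0] * 4,
            epi_radius_by_slice=[32.0] * 4,
            infarct_angular_extent=120.0,
            transmural_fraction=1.0,
            grey_zone_width=0.0,
            no_reflow_fraction=0.3,
            noise_sd=0.0,
            noise_model="gaussian",
        )
        stack, truth = generate_phantom(spec, 0)
        from lgequant.geometry import MyocardiumMask

        mask = MyocardiumMask(mask=truth.myocardium_mask)
        auto = weighted_infarct(stack, mask)
        assert auto.weights[truth.no_reflow_mask].sum() == 0.0  # dark core missed
        corr = simulate_corrections(
            truth, auto, ReaderModel(correction_completeness=1.0), 1, stack
        )
        fixed = apply_corrections(auto, corr, stack, mask)
        gained = fixed.weights.sum() - auto.weights.sum()
        assert gained == pytest.approx(truth.no_reflow_mask.sum(), rel=0.05)

    def test_remove_all_annihilates(self):
        stack, mask, _, _ = analytic_stack(n=64, n_slices=1, values=sector_values(1000.0, 90.0))
        m = self._map(stack, mask)
        full = np.array([[0.0, 0.0], [64.0, 0.0], [64.0, 64.0], [0.0, 64.0]])
        out = apply_corrections(m, CorrectionSet(remove_regions=[(0, full)]), stack, mask)
        assert out.weights.sum() == 0.0

    def test_overlapping_regions_rejected(self):
        stack, mask, _, _ = analytic_stack(n=64, n_slices=1)
        m = InfarctMap(np.zeros_like(stack.intensities))
        sq = np.array([[10.0, 10.0], [20.0, 10.0], [20.0, 20.0], [10.0, 20.0]])
        with pytest.raises(ValueError, match="overlap"):
            apply_corrections(
                m, CorrectionSet(add_regions=[(0, sq)], remove_regions=[(0, sq)]), stack
            )

    def test_completeness_zero_empty(self):
        spec = PhantomSpec(grid=(64, 64, 4), endo_radius_by_slice=[15.0] * 4,
                           epi_radius_by_slice=[22.0] * 4, no_reflow_fraction=0.3,
                           transmural_fraction=1.0, noise_sd=0.0,
                           noise_model="gaussian", pixel_spacing=(1.0, 1.0))
        stack, truth = generate_phantom(spec, 0)
        from lgequant.geometry import MyocardiumMask

        mask = MyocardiumMask(mask=truth.myocardium_mask)
        auto = weighted_infarct(stack, mask)
        corr = simulate_corrections(
            truth, auto, ReaderModel(correction_completeness=0.0), 1, stack
        )
        assert not corr.add_regions and not corr.remove_regions

    def test_completeness_binomial_rate(self):
        """At completeness 0.5 roughly half of all correctable regions are emitted."""
        spec = PhantomSpec(grid=(64, 64, 8), endo_radius_by_slice=[15.0] * 8,
                           epi_radius_by_slice=[22.0] * 8, no_reflow_fraction=0.3,
                           transmural_fraction=1.0, noise_sd=0.0,
                           noise_model="gaussian", pixel_spacing=(1.0, 1.0))
        stack, truth = generate_phantom(spec, 0)
        from lgequant.geometry import MyocardiumMask

        mask = MyocardiumMask(mask=truth.myocardium_mask)
        auto = weighted_infarct(stack, mask)
        reader = ReaderModel(correction_completeness=0.5)
        n_slices_with_nr = sum(truth.no_reflow_mask[s].any() for s in range(8))
        assert n_slices_with_nr == 8
        emitted = total = 0
        for seed in range(125):  # 125 seeds x 8 regions = 1000 Bernoulli trials
            corr = simulate_corrections(truth, auto, reader, seed, stack)
            emitted += len({s for s, _ in corr.add_regions})
            total += 8
        assert 0.45 <= emitted / total <= 0.55


class TestMethodOrdering:
    def test_weighted_vs_fwhm_on_three_level_phantom(self):
        """FWHM counts grey fully; the weighted method at half weight."""

        def values(rr, theta):
            d = np.abs((theta - 90.0 + 180.0) % 360.0 - 180.0)
            out = np.full_like(rr, np.nan)
            out[d <= 36.0] = 1000.0
            out[(d > 36.0) & (d <= 54.0)] = 550.0
            return out

        stack, mask, _, _ = analytic_stack(values=values)
        w = percent(weighted_infarct(stack, mask), mask, stack)
        f = percent(
            fwhm_infarct(stack, mask, FWHMParams(max_estimator="global_max")),
            mask,
            stack,
        )
        assert w <= f
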