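import numpy as np
import pytest

from dgmpv.pve import (ConcentrationField, DegenerateFitError,
                       NonIdentifiableError, PVEOptions, TissueIntensities,
                       estimate_concentrations, estimate_tissue_intensities,
                       fit_pve, fit_region, marginal_nll,
                       _solve_normal_equations)
from dgmpv.volumes import BinaryMask

from .oracles import ols_mixture_reference


INIT = TissueIntensities(1350.0, 850.0)


class TestEstimateConcentrations:
    @pytest.mark.parametrize("y, expected", [
        (1100.0, 0.5),      # exact midpoint of the bracket
        (1350.0, 1.0),      # pure GM endpoint
        (850.0, 0.0),       # pure WM endpoint
        (2000.0, 1.0),      # raw ratio 2.3 clamps to 1
        (600.0, 0.0),       # below the bracket clamps to 0
    ])
    def test_clamped_ratio(self, y, expected):
        c = estimate_concentrations(np.array([y]), INIT)
        assert c.c_gm[0] == pytest.approx(expected, abs=1e-12)

    def test_posterior_mean_approaches_clamp_as_noise_vanishes(self, rng):
        y = rng.uniform(700, 1500, 200)
        hard = estimate_concentrations(y, INIT).c_gm
        soft = estimate_concentrations(
            y, TissueIntensities(1350.0, 850.0, 1e-4)).c_gm
        assert np.allclose(hard, soft, atol=1e-6)

    def test_equal_intensities_not_constructible(self):
        with pytest.raises(ValueError):
            TissueIntensities(1000.0, 1000.0)


class TestEstimateTissueIntensities:
    def test_pure_tissue_voxels(self):
        res = estimate_tissue_intensities([900.0, 1400.0], [0.0, 1.0])
        assert (res.mu_gm, res.mu_wm, res.sigma) == (1400.0, 900.0, 0.0)

    def test_exactly_collinear_data(self):
        res = estimate_tissue_intensities([850.0, 1100.0, 1350.0],
                                          [0.0, 0.5, 1.0])
        assert res.mu_gm == pytest.approx(1350.0, abs=1e-9)
        assert res.mu_wm == pytest.approx(850.0, abs=1e-9)
        assert res.sigma == pytest.approx(0.0, abs=1e-9)

    def test_matches_reference_solver_on_noisy_data(self, rng):
        c = np.linspace(0, 1, 50)
        y = 1420 * c + 880 * (1 - c) + rng.normal(0, 30, 50)
        res = estimate_tissue_intensities(y, c)
        mu_gm, mu_wm, sigma = ols_mixture_reference(y, c)
        assert res.mu_gm == pytest.approx(mu_gm, abs=1e-9)
        assert res.mu_wm == pytest.approx(mu_wm, abs=1e-9)
        assert res.sigma == pytest.approx(sigma, abs=1e-9)

    def test_rank_deficient_design_raises(self):
        with pytest.raises(DegenerateFitError):
            estimate_tissue_intensities([1000.0, 1010.0, 990.0],
                                        [0.3, 0.3, 0.3])

    def test_ordering_violation_raises(self):
        # concentrations anti-correlated with intensity -> mu_gm < mu_wm
        with pytest.raises(NonIdentifiableError):
            estimate_tissue_intensities([1400.0, 900.0], [0.0, 1.0])

    def test_label_swap_symmetry_of_objective(self, rng):
        """Swapping tissue roles flips the coefficients, same residuals."""
        c = rng.uniform(0, 1, 80)
        y = 1400 * c + 900 * (1 - c) + rng.normal(0, 25, 80)
        a1, b1, rss1 = _solve_normal_equations(y, c)
        a2, b2, rss2 = _solve_normal_equations(y, 1 - c)
        assert a1 == pytest.approx(b2, abs=1e-8)
        assert b1 == pytest.approx(a2, abs=1e-8)
        assert rss1 == pytest.approx(rss2, rel=1e-10)


class TestFitPVE:
    def test_noise_free_recovery_from_standard_init(self):
        c = np.linspace(0, 1, 11)
        y = 1400 * c + 900 * (1 - c)
        res = fit_pve(y)
        assert res.intensities.mu_gm == pytest.approx(1400.0, abs=1e-3)
        assert res.intensities.mu_wm == pytest.approx(900.0, abs=1e-3)
        assert res.intensities.sigma < 1e-6

    def test_constant_volume_is_non_identifiable(self):
        # step 1 maps every voxel to c = (1000-850)/500 = 0.3 -> rank-1 design
        with pytest.raises(NonIdentifiableError):
            fit_pve(np.full(50, 1000.0))

    def test_objective_trace_non_increasing(self, rng):
        for _ in range(20):
            n = int(rng.integers(30, 300))
            a = rng.uniform(1150, 1700)
            b = rng.uniform(650, a - 150)
            c = rng.uniform(0, 1, n)
            y = a * c + b * (1 - c) + rng.normal(0, rng.uniform(10, 80), n)
            res = fit_pve(y)
            diffs = np.diff(res.objective_trace)
            tol = 1e-9 * np.maximum(np.abs(res.objective_trace[:-1]), 1.0)
            assert (diffs <= tol).all()

    def test_trace_length_matches_iteration_count(self, rng):
        y = 1400 * rng.uniform(0, 1, 100) + 900 * rng.uniform(0, 1, 100)
        res = fit_pve(y)
        assert len(res.objective_trace) == res.n_iterations

    def test_early_stop_tolerance(self):
        c = np.linspace(0, 1, 50)
        y = 1400 * c + 900 * (1 - c)
        res = fit_pve(y, tol=50.0, polish=False)
        assert res.converged_early
        assert res.n_iterations < 10

    def test_concentrations_within_unit_interval(self, rng):
        c = rng.uniform(0, 1, 500)
        y = 1400 * c + 900 * (1 - c) + rng.normal(0, 60, 500)
        res = fit_pve(y)
        assert res.concentrations.c_gm.min() >= 0.0
        assert res.concentrations.c_gm.max() <= 1.0

    def test_too_few_voxels(self):
        with pytest.raises(ValueError):
            fit_pve(np.array([900.0, 1400.0]))

    def test_init_outside_data_range_recovers(self):
        # all voxels below the initial bracket: hull restart, then recovery
        c = np.linspace(0, 1, 21)
        y = 700 * c + 650 * (1 - c)
        res = fit_pve(y)
        assert res.intensities.mu_gm == pytest.approx(700.0, abs=1e-3)
        assert res.intensities.mu_wm == pytest.approx(650.0, abs=1e-3)


class TestFitRegion:
    def test_matches_fit_pve_on_extracted_voxels(self, thalamus_phantom):
        truth, phantom = thalamus_phantom
        res = fit_region(phantom.t1, phantom.labels, "thalamus")
        mask = phantom.labels.region_mask("thalamus").mask
        direct = fit_pve(phantom.t1.values[mask])
        assert res.intensities.mu_gm == direct.intensities.mu_gm
        assert res.intensities.mu_wm == direct.intensities.mu_wm
        assert res.n_voxels == int(mask.sum())

    def test_lesion_exclusion_reduces_voxel_count(self, thalamus_phantom):
        truth, phantom = thalamus_phantom
        mask = phantom.labels.region_mask("thalamus").mask
        lesion = np.zeros_like(mask)
        coords = np.argwhere(mask)
        center = coords[len(coords) // 2]
        dist = np.linalg.norm(np.argwhere(np.ones_like(mask)) - center, axis=1)
        lesion.ravel()[dist <= 3.0] = True
        n_overlap = int((mask & lesion).sum())
        assert n_overlap > 0
        res = fit_region(phantom.t1, phantom.labels, "thalamus",
                         lesions=BinaryMask(lesion))
        assert res.n_voxels == int(mask.sum()) - n_overlap

    def test_region_below_minimum_size(self, thalamus_phantom):
        truth, phantom = thalamus_phantom
        res_opts = PVEOptions(min_voxels=10 ** 6)
        with pytest.raises(ValueError, match="minimum"):
            fit_region(phantom.t1, phantom.labels, "thalamus",
                       options=res_opts)

    def test_missing_region(self, thalamus_phantom):
        truth, phantom = thalamus_phantom
        with pytest.raises(KeyError):
            fit_region(phantom.t1, phantom.labels, "putamen")

    def test_concentration_volume_roundtrip(self, thalamus_phantom):
        truth, phantom = thalamus_phantom
        res = fit_region(phantom.t1, phantom.labels, "thalamus")
        vol = res.concentration_volume(phantom.t1.shape)
        mask = phantom.labels.region_mask("thalamus").mask
        assert vol[~mask].max() == 0.0
        # noise-free fit reproduces the true concentration field
        assert np.allclose(vol[mask], phantom.c_true[mask], atol=1e-5)


def test_marginal_nll_penalizes_wide_brackets(rng):
    """Widening the bracket beyond the data must cost likelihood."""
    c = rng.uniform(0, 1, 300)
    y = 1400 * c + 900 * (1 - c) + rng.normal(0, 40, 300)
    tight = marginal_nll(y, 1400, 900, 40.0)
    wide = marginal_nll(y, 1800, 500, 40.0)
    assert tight < wide
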