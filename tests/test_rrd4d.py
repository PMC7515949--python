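import numpy as np
import pytest
from dataclasses import replace

from petidif.idif import InputFunction
from petidif.io import Curve, DynamicImage, body_mask
from petidif.phantom import (
    InputParams,
    Kinetics1T,
    Region,
    default_phantom_spec,
    input_function_fine,
    render_phantom,
    tissue_tac,
)
from petidif.rrd4d import (
    BasisSet,
    deconvolve_step,
    denoise_image,
    fit_voxel_tac,
    make_basis,
    run_4d_rrd,
)


class TestMakeBasis:
    def test_twelve_rates_by_default(self, truth_basis, schedule):
        assert truth_basis.n_basis == 12
        assert truth_basis.thetas[0] == pytest.approx(1 / (2 * schedule.total_duration))
        assert truth_basis.thetas[-1] == pytest.approx(0.1)
        assert (np.diff(truth_basis.thetas) > 0).all()
        assert (truth_basis.basis >= 0).all()

    def test_zero_input_gives_zero_basis(self, schedule):
        ifn = InputFunction(
            np.array([0.0, 3690.0]), np.zeros(2), schedule, parent_plasma=np.zeros(2)
        )
        basis = make_basis(ifn, schedule)
        assert np.allclose(basis.basis, 0.0)

    def test_fast_rate_limit_has_input_shape(self, truth_ifn, schedule):
        # theta very large: b(t) -> IF(t)/theta (quasi-instant equilibration)
        basis = make_basis(truth_ifn, schedule, n_basis=3, theta_min=1e-4, theta_max=0.5)
        fast = basis.basis[:, -1]
        blood = basis.blood
        cos = fast @ blood / (np.linalg.norm(fast) * np.linalg.norm(blood))
        assert cos > 0.995

    def test_uncorrected_input_rejected(self, schedule, truth_ifn):
        raw = InputFunction(truth_ifn.times, truth_ifn.whole_blood, schedule)
        with pytest.raises(ValueError, match="metabolite"):
            make_basis(raw, schedule)

    def test_short_input_rejected(self, schedule):
        ifn = InputFunction(
            np.array([0.0, 100.0]), np.ones(2), schedule, parent_plasma=np.ones(2)
        )
        with pytest.raises(ValueError, match="cover"):
            make_basis(ifn, schedule)

    def test_inverted_theta_bounds_rejected(self, truth_ifn, schedule):
        with pytest.raises(ValueError, match="theta_min"):
            make_basis(truth_ifn, schedule, theta_min=0.1, theta_max=0.01)


class TestFitVoxelTac:
    def test_zero_tac_gives_zero_fit(self, truth_basis):
        fit = fit_voxel_tac(np.zeros(24), truth_basis, lam=0.0)
        assert fit.vt == 0.0 and np.allclose(fit.coefficients, 0.0)

    def test_on_grid_rate_recovers_k1_exactly(self, truth_basis, truth_ifn, schedule):
        theta = truth_basis.thetas[6] * 60.0  # 1/min
        tac = tissue_tac(Kinetics1T(K1=0.7, k2=theta), truth_ifn.whole_blood_curve(), schedule)
        fit = fit_voxel_tac(tac, truth_basis, lam=0.0)
        active = np.flatnonzero(fit.coefficients > 1e-9)
        assert list(active) == [6]
        assert fit.coefficients[6] == pytest.approx(0.7 / 60.0, rel=1e-10)
        assert fit.vt == pytest.approx(0.7 / theta, rel=1e-10)

    def test_off_grid_sweep_within_five_percent(self, truth_basis, truth_ifn, schedule):
        blood = truth_ifn.whole_blood_curve()
        for K1 in (0.1, 0.5, 1.0):
            for k2 in (0.05, 0.17, 0.5):
                tac = tissue_tac(Kinetics1T(K1=K1, k2=k2), blood, schedule)
                fit = fit_voxel_tac(tac, truth_basis, lam=0.0)
                assert fit.vt == pytest.approx(K1 / k2, rel=0.05)

    def test_vt_linear_in_tac_scale(self, truth_basis, truth_ifn, schedule):
        tac = tissue_tac(Kinetics1T(K1=0.4, k2=0.2), truth_ifn.whole_blood_curve(), schedule)
        a = fit_voxel_tac(tac.values, truth_basis, lam=0.0)
        b = fit_voxel_tac(3.0 * tac.values, truth_basis, lam=0.0)
        assert b.vt == pytest.approx(3.0 * a.vt, rel=1e-8)

    def test_nested_theta_grids_never_increase_residual(self, truth_ifn, schedule):
        rng = np.random.default_rng(0)
        small_thetas = np.geomspace(2e-4, 0.05, 6)
        big_thetas = np.sort(np.concatenate([small_thetas, np.geomspace(3e-4, 0.08, 6)]))
        small = make_basis(truth_ifn, schedule, n_basis=6, theta_min=2e-4, theta_max=0.05)
        big = BasisSet(big_thetas,
                       np.column_stack([make_basis(truth_ifn, schedule, 1, th, th * 1.0001).basis[:, 0]
                                        for th in big_thetas]),
                       small.blood, schedule, 1.0)
        for _ in range(5):
            tac = np.abs(rng.normal(size=24)) * 1e5
            r_small = fit_voxel_tac(tac, small, lam=0.0).residual_rms
            r_big = fit_voxel_tac(tac, big, lam=0.0).residual_rms
            assert r_big <= r_small + 1e-6 * (1 + r_small)

    def test_length_mismatch_rejected(self, truth_basis):
        with pytest.raises(ValueError, match="length"):
            fit_voxel_tac(np.zeros(10), truth_basis)


class TestDenoiseImage:
    @pytest.fixture(scope="class")
    def representable_image(self, schedule, truth_ifn):
        # every voxel a 1T + blood mixture: inside the basis model class
        blood = truth_ifn.whole_blood_curve()
        rng = np.random.default_rng(1)
        tacs = []
        for _ in range(8):
            k = Kinetics1T(K1=rng.uniform(0.1, 0.8), k2=rng.uniform(0.05, 0.4),
                           vB=rng.uniform(0.0, 0.1))
            tacs.append(tissue_tac(k, blood, schedule).values)
        vox = np.array(tacs)[rng.integers(0, 8, size=5 * 5 * 5)].reshape(5, 5, 5, 24)
        return DynamicImage(vox, (1, 1, 1), schedule)

    def test_model_class_data_restored_below_one_percent(self, representable_image, truth_basis):
        mask = np.ones(representable_image.spatial_shape, bool)
        restored, _ = denoise_image(representable_image, truth_basis, lam=0.0, mask=mask)
        rel = np.linalg.norm(restored.voxels - representable_image.voxels) / np.linalg.norm(
            representable_image.voxels
        )
        assert rel < 0.01

    def test_noisy_phantom_error_strictly_reduced(self, noisy_phantom, blurred_phantom, truth_basis):
        noisy, _ = noisy_phantom
        clean, _ = blurred_phantom
        mask = body_mask(noisy)
        restored, _ = denoise_image(noisy, truth_basis, mask=mask)
        before = np.linalg.norm(noisy.voxels[mask] - clean.voxels[mask])
        after = np.linalg.norm(restored.voxels[mask] - clean.voxels[mask])
        assert after < before

    def test_uniform_kinetics_gives_uniform_vt(self, schedule, truth_ifn, truth_basis):
        blood = truth_ifn.whole_blood_curve()
        tac = tissue_tac(Kinetics1T(K1=0.5, k2=0.2), blood, schedule).values
        vox = np.tile(tac, (4, 4, 4, 1))
        img = DynamicImage(vox, (1, 1, 1), schedule)
        mask = np.ones((4, 4, 4), bool)
        _, vt = denoise_image(img, truth_basis, lam=0.0, mask=mask)
        assert np.ptp(vt) < 1e-8 * vt.max()

    def test_schedule_mismatch_rejected(self, truth_basis):
        from petidif.io import FrameSchedule

        other = FrameSchedule.from_durations([60.0] * 10)
        img = DynamicImage(np.ones((3, 3, 3, 10)), (1, 1, 1), other)
        with pytest.raises(ValueError, match="schedule"):
            denoise_image(img, truth_basis, mask=np.ones((3, 3, 3), bool))


class TestDeconvolveStep:
    def test_zero_fwhm_is_identity(self, noisy_phantom):
        image, _ = noisy_phantom
        out = deconvolve_step(image, image, psf_fwhm=0.0)
        assert out is image

    def test_step_edge_width_shrinks_over_iterations(self, schedule):
        # blurred edge of an interior hot cube: the interpolated 10-90%
        # width must strictly decrease with Van Cittert iterations
        from scipy.ndimage import gaussian_filter

        vox = np.zeros((40, 16, 16, 24))
        vox[5:20, 4:12, 4:12] = 100.0
        blurred = gaussian_filter(vox, (1.5, 1.5, 1.5, 0))
        ref = DynamicImage(blurred, (1, 1, 1), schedule)

        def width(im):
            prof = im.voxels[:, 8, 8, 0]
            plateau = prof[10:15].mean()
            xw = np.arange(14, 30)
            p = prof[14:30] / plateau

            def cross(level):
                idx = np.argmax(p < level)
                x0, x1 = xw[idx - 1], xw[idx]
                y0, y1 = p[idx - 1], p[idx]
                return x0 + (y0 - level) / (y0 - y1)

            return cross(0.1) - cross(0.9)

        fwhm = 1.5 * 2.3548
        x = ref
        widths = [width(x)]
        for _ in range(6):
            x = deconvolve_step(x, ref, psf_fwhm=fwhm)
            widths.append(width(x))
        assert all(b < a for a, b in zip(widths, widths[1:]))

    def test_negative_fwhm_rejected(self, noisy_phantom):
        image, _ = noisy_phantom
        with pytest.raises(ValueError):
            deconvolve_step(image, image, psf_fwhm=-1.0)


class TestRun4dRrd:
    @pytest.fixture(scope="class")
    def small_two_region(self, schedule):
        regions = (
            Region("body", 1, lo=(1, 1, 1), hi=(11, 11, 15), vB=0.03, free=0.8,
                   specific=0.15, background=True),
            Region("hot", 2, lo=(4, 4, 5), hi=(7, 7, 8), vB=0.03, free=0.5, specific=2.5),
        )
        spec = replace(
            default_phantom_spec(noise_scale=400.0, rng_seed=3),
            shape=(12, 12, 16),
            regions=regions,
        )
        return render_phantom(spec)

    def test_zero_iterations_equals_denoise_only(self, small_two_region, truth_ifn):
        image, _ = small_two_region
        mask = body_mask(image)
        basis = make_basis(truth_ifn, image.schedule)
        res = run_4d_rrd(image, truth_ifn, iterations=0, mask=mask, basis=basis)
        restored, vt = denoise_image(image, basis, lam=1e-4, mask=mask)
        assert np.array_equal(res.restored.voxels, restored.voxels)
        assert np.array_equal(res.vt_map, vt)

    def test_ten_iterations_improve_regional_vt(self, small_two_region, truth_ifn):
        image, truth = small_two_region
        hot = truth.atlas.mask_of("hot")
        true_vt = truth.vt_by_region["hot"]
        errs = {}
        for it in (0, 10):
            res = run_4d_rrd(image, truth_ifn, iterations=it, psf_fwhm=1.6)
            errs[it] = abs(res.vt_map[hot].mean() - true_vt)
        assert errs[10] <= errs[0]

    def test_divergence_detector_flags_overshoot(self, small_two_region, truth_ifn):
        image, _ = small_two_region
        res = run_4d_rrd(image, truth_ifn, iterations=12, psf_fwhm=1.6, alpha=3.5)
        assert res.diverged

    def test_negative_iterations_rejected(self, small_two_region, truth_ifn):
        image, _ = small_two_region
        with pytest.raises(ValueError):
            run_4d_rrd(image, truth_ifn, iterations=-1)

    def test_residual_maps_are_percentages(self, small_two_region, truth_ifn):
        image, _ = small_two_region
        res = run_4d_rrd(image, truth_ifn, iterations=0)
        assert res.residual_maps.shape == image.voxels.shape
        assert (res.residual_maps >= 0).all()
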