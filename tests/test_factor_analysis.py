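import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls
from sklearn.isotonic import IsotonicRegression

from petidif.factor_analysis import (
    FAConfig,
    _nnls_images,
    enforce_peak_constraint,
    extract_factors,
    identify_blood_factor,
    init_factors_kmeans,
    pca_subspace,
    refine_factors,
)
from petidif.io import Curve, body_mask

from conftest import hungarian_cosines


class TestPcaSubspace:
    def test_exact_three_mixture_reconstructed_to_machine_precision(self, schedule):
        rng = np.random.default_rng(0)
        curves = rng.random((3, 24))
        weights = rng.random((500, 3))
        X = weights @ curves
        basis, proj = pca_subspace(X, 3)
        recon = proj @ basis
        assert np.allclose(recon, X, atol=1e-8 * X.max())

    def test_constant_image_single_component(self):
        X = np.full((50, 24), 3.0)
        basis, proj = pca_subspace(X, 1)
        assert np.allclose(proj @ basis, X, atol=1e-10)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="voxels"):
            pca_subspace(np.ones((2, 24)), 3)


class TestKmeansInit:
    def _make_classes(self, rng, n_per_class=50):
        # four well-separated kinetic classes of identical members
        curves = np.array(
            [
                np.exp(-np.linspace(0, 5, 24)),
                np.linspace(0, 1, 24),
                np.ones(24),
                np.concatenate([np.linspace(0, 1, 12), np.linspace(1, 0, 12)]),
            ]
        )
        X = np.repeat(curves, n_per_class, axis=0)
        X = X * rng.normal(1.0, 0.01, size=(X.shape[0], 1))  # amplitude jitter
        return curves, X

    def test_centroids_match_class_means(self):
        rng = np.random.default_rng(1)
        curves, X = self._make_classes(rng)
        basis, proj = pca_subspace(X, 4)
        F0 = init_factors_kmeans(proj, basis, 4, seed=0, apex=False)
        cos = hungarian_cosines(curves, F0)
        assert (cos > 0.99).all()

    def test_k1_returns_global_mean(self):
        rng = np.random.default_rng(2)
        _, X = self._make_classes(rng)
        basis, proj = pca_subspace(X, 4)
        F0 = init_factors_kmeans(proj, basis, 1, seed=0)
        global_mean = X.mean(axis=0)
        cos = global_mean @ F0[0] / (np.linalg.norm(global_mean) * np.linalg.norm(F0[0]))
        assert cos > 0.9999

    def test_k_exceeding_voxels_rejected(self):
        basis = np.eye(3, 24)
        with pytest.raises(ValueError, match="exceeds"):
            init_factors_kmeans(np.ones((2, 3)), basis, 4)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        _, X = self._make_classes(rng)
        basis, proj = pca_subspace(X, 4)
        a = init_factors_kmeans(proj, basis, 4, seed=9)
        b = init_factors_kmeans(proj, basis, 4, seed=9)
        assert np.array_equal(a, b)


class TestPeakConstraint:
    def test_feasible_curve_is_fixed_point(self, schedule):
        y = np.concatenate([[0.2, 1.0], np.linspace(0.9, 0.1, 22)])
        out = enforce_peak_constraint(y, schedule)
        assert np.allclose(out, y)

    def test_monotone_curve_plateau_matches_pav_oracle(self, schedule):
        y = np.linspace(0.0, 1.0, 24)
        out = enforce_peak_constraint(y, schedule)
        p = schedule.frame_covering(30, 60)
        # independent pool-adjacent-violators oracle, piecewise around the peak
        iso_pre = IsotonicRegression(increasing=True).fit_transform(np.arange(p + 1), y[: p + 1])
        iso_post = IsotonicRegression(increasing=False).fit_transform(np.arange(24 - p), y[p:])
        expected = np.concatenate([iso_pre[:-1], [max(iso_pre[-1], iso_post[0])], iso_post[1:]])
        assert np.allclose(out, expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_projection_always_p2_feasible(self, schedule, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=24)
        out = enforce_peak_constraint(y, schedule)
        p = schedule.frame_covering(30, 60)
        assert (out >= 0).all()
        assert np.argmax(out) in range(p + 1) and out[p] == out.max()
        assert (np.diff(out[: p + 1]) >= -1e-12).all()
        assert (np.diff(out[p:]) <= 1e-12).all()

    def test_missing_peak_frame_requires_explicit_index(self):
        from petidif.io import FrameSchedule

        odd = FrameSchedule.from_durations([45.0] * 10)
        with pytest.raises(ValueError, match="no frame spans"):
            enforce_peak_constraint(np.ones(10), odd)
        out = enforce_peak_constraint(np.linspace(1, 0, 10), odd, peak_frame=0)
        assert np.argmax(out) == 0


class TestBloodIdentification:
    def test_early_peaking_curve_selected(self, schedule):
        early = np.exp(-(((schedule.mids - 45) / 60.0) ** 2))
        slow1 = np.linspace(0, 1, 24)
        slow2 = 1 - np.exp(-schedule.mids / 2000)
        slow3 = np.sqrt(schedule.mids / 3690)
        idx = identify_blood_factor(np.stack([slow1, early, slow2, slow3]), schedule)
        assert idx == 1

    def test_feasible_factor_has_zero_distance(self, schedule):
        feasible = enforce_peak_constraint(np.random.default_rng(0).random(24), schedule)
        other = np.linspace(0, 1, 24)
        assert identify_blood_factor(np.stack([other, feasible]), schedule) == 1

    def test_tie_broken_by_earlier_peak(self, schedule):
        p = schedule.frame_covering(30, 60)
        a = np.zeros(24)
        a[p] = 1.0  # peaks at the 30-60 s frame
        b = np.zeros(24)
        b[: p + 1] = 1.0  # plateau peak starting at t=0 -> earlier argmax
        assert identify_blood_factor(np.stack([a, b]), schedule) == 1

    def test_requires_two_factors(self, schedule):
        with pytest.raises(ValueError, match="at least 2"):
            identify_blood_factor(np.ones((1, 24)), schedule)


class TestNnlsImages:
    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_matches_scipy_nnls_oracle(self, K):
        rng = np.random.default_rng(K)
        F = rng.random((K, 24))
        X = rng.random((40, 24)) - 0.2
        A = _nnls_images(F, X)
        assert (A >= 0).all()
        for i in range(X.shape[0]):
            ref, _ = scipy_nnls(F.T, X[i])
            ours = np.linalg.norm(X[i] - A[i] @ F)
            theirs = np.linalg.norm(X[i] - ref @ F)
            assert ours <= theirs + 1e-9 * (1 + theirs)


class TestRefinement:
    def test_single_factor_exact_recovery(self, schedule):
        rng = np.random.default_rng(0)
        # P2-feasible curve (peak in frame 0, monotone decay) so the blood
        # constraint is inactive and recovery must be exact
        curve = np.sort(np.abs(rng.random(24)) + 0.1)[::-1]
        weights = rng.random((200, 1)) + 0.1
        X = weights @ curve[None, :]
        basis, proj = pca_subspace(X, 1)
        F0 = init_factors_kmeans(proj, basis, 1, seed=0)
        F, A, resid, _, converged, _ = refine_factors(
            X, F0, basis, schedule, blood_index=0,
            config=FAConfig(peak_window=(0.0, 30.0)),
        )
        cos = curve @ F[0] / (np.linalg.norm(curve) * np.linalg.norm(F[0]))
        assert cos > 0.999999
        assert resid < 1e-8 * X.max()

    def test_nnls_step_never_increases_residual(self, noisy_phantom, blood_template):
        image, _ = noisy_phantom
        model = extract_factors(image, mode="tracer", template=blood_template,
                                config=FAConfig(max_iterations=30))
        traj = model.residual_trajectory
        before, after = traj[0::2], traj[1::2]
        assert (after <= before + 1e-9 * before).all()

    def test_noiseless_recovery_after_hungarian_matching(self, noiseless_phantom, tracer_model):
        _, truth = noiseless_phantom
        cos = hungarian_cosines(truth.factor_curves, tracer_model.factor_curves)
        assert (cos > 0.99).all()

    def test_constraints_hold_exactly_on_output(self, tracer_model, schedule):
        m = tracer_model
        assert (m.factor_curves >= 0).all() and (m.factor_images >= 0).all()
        blood = m.factor_curves[m.blood_index]
        p = schedule.frame_covering(30, 60)
        assert blood[p] == blood.max()
        assert (np.diff(blood[: p + 1]) >= -1e-9 * blood.max()).all()
        assert (np.diff(blood[p:]) <= 1e-9 * blood.max()).all()


class TestExtractFactors:
    def test_presaturation_runs_three_factors(self):
        from petidif.phantom import presaturation_spec, render_phantom
        from dataclasses import replace

        image, _ = render_phantom(replace(presaturation_spec(), noise_scale=0.0, psf_fwhm=0.0))
        model = extract_factors(image, mode="presaturation")
        assert model.K == 3
        assert model.blood_index in range(3)

    def test_tracer_runs_four_factors(self, tracer_model):
        assert tracer_model.K == 4

    def test_tracer_without_template_rejected(self, noiseless_phantom):
        image, _ = noiseless_phantom
        with pytest.raises(ValueError, match="template"):
            extract_factors(image, mode="tracer")

    def test_unknown_mode_rejected(self, noiseless_phantom):
        image, _ = noiseless_phantom
        with pytest.raises(ValueError, match="mode"):
            extract_factors(image, mode="bolus")

    def test_deterministic_given_seed(self, noiseless_phantom, blood_template):
        image, _ = noiseless_phantom
        cfg = FAConfig(kmeans_seed=3, max_iterations=15)
        a = extract_factors(image, mode="tracer", template=blood_template, config=cfg)
        b = extract_factors(image, mode="tracer", template=blood_template, config=cfg)
        assert np.array_equal(a.factor_curves, b.factor_curves)
        assert np.array_equal(a.factor_images, b.factor_images)

    def test_reconstruction_residual_small_on_noiseless_mixture(self, noiseless_phantom, tracer_model):
        image, _ = noiseless_phantom
        X = image.voxels[tracer_model.mask]
        assert tracer_model.residual_norm < 0.01 * np.sqrt((X ** 2).mean())
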