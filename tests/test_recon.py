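"""Reconstruction pipeline: whitening, delay correction, sensitivities,
CG-SENSE, compressed sensing, sliding window, flat field."""

import warnings

import numpy as np
import pytest

from starstack import (
    ReconConfig,
    SequenceParams,
    TrajectoryConfig,
    bin_frames,
    build_schedule,
    coil_sensitivities,
    cs_recon,
    estimate_sensitivities,
    flat_field,
    gradient_delay_correct,
    nrmse,
    prewhiten,
    reference_recon,
    simulate_kspace,
    sliding_window,
    static_phantom,
    whiten_sensitivities,
)
from starstack.forward_model import KSpaceData


class TestPrewhiten:
    def test_identity_covariance_leaves_data_unchanged(self, small_full_data):
        d = KSpaceData(samples=small_full_data.samples,
                       coords=small_full_data.coords,
                       schedule=small_full_data.schedule,
                       noise_covariance=np.eye(small_full_data.n_coils),
                       sequence=small_full_data.sequence)
        out = prewhiten(d)
        assert np.allclose(out.samples, d.samples)

    def test_pure_noise_whitens_to_identity(self):
        rng = np.random.default_rng(0)
        n_coils, n_samp = 4, 120_000
        a = rng.standard_normal((n_coils, n_coils)) \
            + 1j * rng.standard_normal((n_coils, n_coils))
        cov = a @ a.conj().T / n_coils + 0.3 * np.eye(n_coils)
        chol = np.linalg.cholesky(cov)
        eps = (rng.standard_normal((n_samp, n_coils))
               + 1j * rng.standard_normal((n_samp, n_coils))) / np.sqrt(2)
        noise = eps @ chol.T

        params = SequenceParams(matrix=32, n_readout=n_samp // 10, n_slices=1,
                                oversampling_factor=1.0)
        sched = build_schedule(TrajectoryConfig(pattern="RADIAL2D",
                                                spokes_per_slice=10,
                                                sequence=params))
        data = KSpaceData(samples=noise.reshape(10, -1, n_coils),
                          coords=np.zeros((10, n_samp // 10, 3)),
                          schedule=sched, noise_covariance=cov,
                          sequence=params)
        white = prewhiten(data).samples.reshape(-1, n_coils)
        emp = (white.T @ white.conj()) / n_samp
        assert np.linalg.norm(emp - np.eye(n_coils)) / np.sqrt(n_coils) < 0.05

    def test_singular_covariance_rejected(self, small_full_data):
        cov = np.zeros((5, 5))
        cov[0, 0] = 1.0
        d = KSpaceData(samples=small_full_data.samples,
                       coords=small_full_data.coords,
                       schedule=small_full_data.schedule,
                       noise_covariance=cov, sequence=small_full_data.sequence)
        with pytest.raises(ValueError):
            prewhiten(d)


class TestGradientDelay:
    @pytest.mark.parametrize("true_delay", [0.5, -0.3])
    def test_closed_loop_recovery(self, small_static_scene, small_params,
                                  small_maps, true_delay):
        sched = build_schedule(TrajectoryConfig(pattern="RSOS_PSI1",
                                                spokes_per_slice=55,
                                                sequence=small_params))
        data = simulate_kspace(small_static_scene, sched, small_maps,
                               gradient_delay_samples=true_delay)
        corrected, est = gradient_delay_correct(data)
        assert est == pytest.approx(true_delay, abs=0.05)
        clean = simulate_kspace(small_static_scene, sched, small_maps)
        assert nrmse(clean.samples, corrected.samples) < 0.05

    def test_zero_delay_estimates_zero_and_preserves_data(
            self, small_full_data):
        corrected, est = gradient_delay_correct(small_full_data)
        assert abs(est) < 0.02
        assert np.linalg.norm(corrected.samples - small_full_data.samples) \
            / np.linalg.norm(small_full_data.samples) < 1e-2

    def test_no_opposed_pairs_warns_and_skips(self, small_static_scene,
                                              small_params, small_maps):
        sched = build_schedule(TrajectoryConfig(pattern="ASOS",
                                                spokes_per_slice=2,
                                                sequence=small_params))
        data = simulate_kspace(small_static_scene, sched, small_maps)
        with pytest.warns(UserWarning):
            out, est = gradient_delay_correct(data)
        assert est == 0.0
        assert np.array_equal(out.samples, data.samples)


class TestSensitivities:
    def test_single_constant_coil_recovers_flat_map(self, small_static_scene,
                                                    small_params):
        maps = coil_sensitivities(1, small_static_scene.grid,
                                  smoothness=np.inf, seed=0)
        from starstack import acquire_fully_sampled

        data = acquire_fully_sampled(small_static_scene, "RSOS_PSI1",
                                     small_params, maps)
        est = estimate_sensitivities(data)
        supp = np.abs(est.maps[0]) > 0
        mags = np.abs(est.maps[0][supp])
        assert mags.std() / mags.mean() < 0.01

    def test_closed_loop_map_error_below_ten_percent(self, small_whitened,
                                                     small_static_scene):
        dw, mw = small_whitened
        est = estimate_sensitivities(dw, lowres_fraction=0.15)
        truth = mw.maps / np.sqrt((np.abs(mw.maps) ** 2).sum(0, keepdims=True))
        supp = (np.abs(small_static_scene.frames[0]) > 0) \
            & (np.abs(est.maps).sum(0) > 0)
        err = np.linalg.norm((est.maps - truth)[:, supp]) \
            / np.linalg.norm(truth[:, supp])
        assert err < 0.10


class TestReferenceRecon:
    def test_noiseless_nrmse_below_two_percent(self, small_reference,
                                               small_static_scene):
        supp = np.abs(small_static_scene.frames[0]) > 0
        err = nrmse(small_static_scene.frames[0][supp],
                    small_reference.frames[0][supp])
        assert err < 0.02

    def test_single_constant_coil_equals_dcf_gridding(self, small_params):
        """With one flat coil, CG-SENSE converges to the density-compensated
        least-squares image, which near Nyquist equals gridding to ~1%."""
        scene = static_phantom(matrix=32, n_kz=3, n_slices=3, texture_seed=2)
        params = SequenceParams(matrix=32, n_readout=64, n_slices=3,
                                oversampling_factor=1.0)
        maps = coil_sensitivities(1, scene.grid, smoothness=np.inf, seed=0)
        from starstack import acquire_fully_sampled
        from starstack.nufft import SosNufft
        from starstack.psf_analysis import ramp_density

        data = acquire_fully_sampled(scene, "RSOS_PSI1", params, maps)
        ref = reference_recon(data, maps, tolerance=1e-9, max_iterations=150)
        op = SosNufft(data.coords, data.schedule.kz_index, data.schedule.n_kz,
                      (32, 32))
        w = ramp_density(data.coords)
        grid = op.adjoint(data.samples[..., 0] * w)
        grid *= np.abs(ref.frames[0]).max() / np.abs(grid).max()
        supp = np.abs(scene.frames[0]) > 0
        assert nrmse(ref.frames[0][supp], grid[supp]) < 0.03

    def test_zero_data_gives_zero_image(self, small_whitened):
        dw, mw = small_whitened
        zero = KSpaceData(samples=np.zeros_like(dw.samples), coords=dw.coords,
                          schedule=dw.schedule, noise_covariance=None,
                          sequence=dw.sequence)
        out = reference_recon(zero, mw, max_iterations=3)
        assert np.all(out.frames == 0.0)


class TestCsRecon:
    def test_lambda_zero_single_frame_matches_cg_sense(self, small_whitened,
                                                       small_reference,
                                                       small_static_scene):
        dw, mw = small_whitened
        binning = bin_frames(dw.schedule, dw.schedule.spokes_per_slice)
        cfg = ReconConfig(lambda_llr=0.0, lambda_tv_time=0.0, iterations=30,
                          tolerance=1e-12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = cs_recon(dw, binning, mw, cfg)
        supp = np.abs(small_static_scene.frames[0]) > 0
        assert nrmse(small_reference.frames[0][supp],
                     series.frames[0][supp]) < 0.01

    def test_objective_decreases_and_is_seed_stable(self, small_whitened):
        dw, mw = small_whitened
        binning = bin_frames(dw.schedule, 6)
        cfg = ReconConfig(iterations=12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cs_recon(dw, binning, mw, cfg, seed=0)
            b = cs_recon(dw, binning, mw, cfg, seed=123)
        obj = np.asarray(a.provenance["objective"])
        # monotone within tolerance (FISTA restarts allow small bumps)
        assert np.all(np.diff(obj) <= 0.02 * obj[:-1])
        assert a.provenance["objective"][-1] == pytest.approx(
            b.provenance["objective"][-1], rel=0.01)

    def test_static_scene_default_lambdas_temporally_flat(self, small_whitened,
                                                          small_static_scene):
        """A static object reconstructed at 6 spokes/slice/frame with the
        default regularisation is temporally near-constant."""
        dw, mw = small_whitened
        binning = bin_frames(dw.schedule, 6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = cs_recon(dw, binning, mw, ReconConfig(iterations=60), seed=0)
        m = np.abs(series.frames)
        supp = np.abs(small_static_scene.frames[0]) > 0
        temporal_sd = m.std(axis=0).mean()
        spatial_sd = m.mean(axis=0)[supp].std()
        assert temporal_sd < 0.10 * spatial_sd

    def test_dynamic_bolus_profile_tracks_ground_truth(self, dynamic_scene,
                                                       dynamic_recon):
        """Voxelwise intensity in the bolus-visited region correlates with
        the true time-resolved bolus occupancy."""
        series, binning = dynamic_recon
        scene = dynamic_scene
        near = np.abs(scene.frame_times[None, :]
                      - series.frame_times[:, None]).argmin(axis=1)
        occ = scene.ground_truth["bolus_masks"][near]
        visited = scene.ground_truth["bolus_masks"].any(axis=0)
        rec = np.abs(series.frames)[:, visited].ravel()
        tru = occ[:, visited].ravel().astype(float)
        r = np.corrcoef(rec, tru)[0, 1]
        assert r > 0.8


class TestSlidingWindow:
    @pytest.fixture(scope="class")
    def sw_series(self, small_whitened):
        dw, mw = small_whitened
        cfg = ReconConfig(iterations=6, spokes_per_slice_per_frame=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sliding_window(dw, mw, cfg, seed=0), dw

    def test_frame_count_and_rate_double(self, sw_series):
        series, dw = sw_series
        base = bin_frames(dw.schedule, 6)
        assert series.n_frames == 2 * base.n_frames - 1
        assert series.frame_rate == pytest.approx(2 * base.frame_rate)

    def test_printed_rate_doubles_to_12_fps(self):
        p = SequenceParams(tr=3.0e-3, n_slices=7)
        sched = build_schedule(TrajectoryConfig(pattern="ASOS",
                                                spokes_per_slice=402,
                                                sequence=p))
        base = bin_frames(sched, 6)
        assert int(2 * base.frame_rate) == 12

    def test_frames_interleave_without_blending(self, sw_series, small_whitened):
        """Every sliding-window frame is exactly one frame of one of the two
        independent runs."""
        series, dw = sw_series
        _, mw = small_whitened
        cfg = ReconConfig(iterations=6, spokes_per_slice_per_frame=6)
        base = bin_frames(dw.schedule, 6)
        half = base.events_per_frame // 2
        offset = bin_frames(dw.schedule, 6, event_offset=half)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_a = cs_recon(dw, base, mw, cfg, seed=0)
            run_b = cs_recon(dw, offset, mw, cfg, seed=0)
        pool = np.concatenate([run_a.frames, run_b.frames])
        for f in series.frames:
            assert any(np.array_equal(f, p) for p in pool)

    def test_interleaved_times_are_sorted(self, sw_series):
        series, _ = sw_series
        assert np.all(np.diff(series.frame_times) > 0)

    def test_rsos_gr_rejected(self, small_static_scene, small_params, small_maps):
        """The golden-ratio comparator depends on the spoke count, so a
        shifted window is not a valid acquisition."""
        sched = build_schedule(TrajectoryConfig(pattern="RSOS_GR",
                                                spokes_per_slice=12,
                                                sequence=small_params))
        data = simulate_kspace(small_static_scene, sched, small_maps)
        with pytest.raises(ValueError, match="sliding window"):
            sliding_window(data, small_maps, ReconConfig(iterations=2))


class TestFlatField:
    def test_constant_image_maps_to_one(self):
        out = flat_field(np.full((3, 32, 32), 7.0))
        assert np.allclose(out, 1.0, atol=0.01)

    def test_removes_smooth_shading(self, small_static_scene):
        """The shading-driven coefficient of variation (corrected image over
        its unshaded flat-fielded counterpart) drops by at least half."""
        img = np.abs(small_static_scene.frames[0])
        ny = img.shape[1]
        shade = 0.4 + 1.2 * np.linspace(0, 1, ny)[None, :, None]
        shaded = img * shade
        # kernel scaled to this phantom's 96 mm FOV (the 32 mm default is
        # proportioned for the 256 mm in-vivo FOV)
        kw = dict(kernel_width_mm=16, voxel_size=small_static_scene.voxel_size)
        corr = flat_field(shaded, **kw)
        flat_ref = flat_field(img, **kw)
        supp = img > 0
        shading_before = shade[np.broadcast_to(supp, shaded.shape)] \
            if shade.shape == shaded.shape else (shaded / np.where(img > 0, img, 1))[supp]
        ratio_after = corr[supp] / flat_ref[supp]
        cov_before = shading_before.std() / shading_before.mean()
        cov_after = ratio_after.std() / ratio_after.mean()
        assert cov_after < 0.5 * cov_before

    def test_no_nan_inf_with_zero_background(self, small_static_scene):
        out = flat_field(np.abs(small_static_scene.frames[0]))
        assert np.all(np.isfinite(out))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            flat_field(np.zeros((2, 8, 8)))


def test_whitening_invariance_of_sense_pipeline(small_whitened,
                                                small_reference):
    """Images are invariant (to ~1e-3 NRMSE) under an invertible coil
    recombination applied consistently to data and maps."""
    dw, mw = small_whitened
    rng = np.random.default_rng(5)
    n = dw.n_coils
    mix = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    mix += 2 * np.eye(n)  # keep well-conditioned
    # recombining coils also recombines their noise: cov -> mix mix^H, and
    # prewhitening restores the original least-squares geometry
    mixed = KSpaceData(samples=dw.samples @ mix.T, coords=dw.coords,
                       schedule=dw.schedule, noise_covariance=mix @ mix.conj().T,
                       sequence=dw.sequence)
    mixed_white = prewhiten(mixed)
    mixed_maps = whiten_sensitivities(
        whiten_sensitivities(mw, mix),
        mixed_white.metadata["whitening_matrix"])
    out = reference_recon(mixed_white, mixed_maps, tolerance=1e-8,
                          max_iterations=100)
    assert nrmse(small_reference.frames, out.frames) < 1e-3
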