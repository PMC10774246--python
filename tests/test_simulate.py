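import numpy as np
import pytest

import spectseg as ss
from spectseg.errors import CalibrationError
from spectseg.simulate import (
    Projector,
    ProjectionSet,
    default_angles,
    poisson_loglik,
    _calibration_background_roi,
)


class TestSystemResolution:
    def test_printed_lehr_configuration_gives_7_5_mm(self):
        assert ss.system_resolution_fwhm(ss.CollimatorSpec()) == pytest.approx(7.5, abs=0.3)

    def test_collimator_face_limit_is_the_hole_diameter(self):
        spec = ss.CollimatorSpec(source_distance=0.0, intrinsic_fwhm=1e-9)
        assert ss.system_resolution_fwhm(spec, gap_mm=0.0) == pytest.approx(1.5, rel=1e-6)

    def test_resolution_degrades_with_distance(self):
        near = ss.system_resolution_fwhm(ss.CollimatorSpec(source_distance=100))
        far = ss.system_resolution_fwhm(ss.CollimatorSpec(source_distance=200))
        assert far > near

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ss.CollimatorSpec(hole_diameter=-1)


def _point_volume(n, value=1.0):
    vol = np.zeros((n, n, n))
    vol[(n - 1) // 2, (n - 1) // 2, (n - 1) // 2] = value
    return vol


class TestProjector:
    def test_zero_activity_projects_to_zero(self):
        P = Projector((16, 16, 16), 4.42, default_angles(8))
        assert not P.forward(np.zeros((16, 16, 16))).any()

    def test_point_source_no_attenuation_no_psf(self):
        # a source at the rotation centre lands in a single bin with the full
        # intensity; quarter-turn angles keep the bilinear resampling exact
        n = 17
        P = Projector((n, n, n), 4.42, default_angles(4), psf_fwhm_mm=0.0)
        proj = P.forward(_point_volume(n, 5.0))
        totals = proj.sum(axis=(1, 2))
        assert np.allclose(totals, 5.0, rtol=1e-9)
        assert all((p > 1e-12).sum() == 1 for p in proj)

    def test_count_conservation_without_attenuation(self, rng):
        n = 32
        vol = np.zeros((n, n, n))
        vol[10:22, 10:22, 10:22] = rng.random((12, 12, 12))
        P = Projector((n, n, n), 4.42, default_angles(10), psf_fwhm_mm=0.0)
        totals = P.forward(vol).sum(axis=(1, 2))
        assert np.allclose(totals, vol.sum(), rtol=1e-2)

    def test_central_source_attenuated_by_cylinder_chord(self):
        # closed form: exp(-mu * R) from the centre of a uniform cylinder
        n, vox, mu_w = 33, 4.42, 0.0155
        c = (n - 1) / 2
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        radius_mm = 12 * vox
        cyl = ((yy - c) ** 2 + (xx - c) ** 2) <= (radius_mm / vox) ** 2
        mu = np.where(cyl, mu_w, 0.0)[None].repeat(n, axis=0)
        P = Projector((n, n, n), vox, [0.0], psf_fwhm_mm=0.0, mu=mu)
        proj = P.forward(_point_volume(n, 1.0))
        assert proj.sum() == pytest.approx(np.exp(-mu_w * radius_mm), rel=0.05)

    def test_forward_back_adjointness(self, rng):
        mu = rng.uniform(0, 0.02, (16, 16, 16))
        P = Projector((16, 16, 16), 4.42, default_angles(12), psf_fwhm_mm=7.5, mu=mu)
        x = rng.random((16, 16, 16))
        y = rng.random((12, 16, 16))
        lhs = float(np.sum(P.forward(x) * y))
        rhs = float(np.sum(x * P.back(y)))
        assert lhs == pytest.approx(rhs, rel=1e-9)


@pytest.fixture(scope="module")
def noiseless():
    p = ss.place_hotspot(ss.build_phantom(20, 4.42, (64, 64, 64)))
    act = ss.compose_activity(p, ss.CaseSpec(20, 0.10, 1.5))
    return ss.forward_project(act, p, default_angles(12))


class TestCountScalingAndNoise:
    def test_mean_counts_per_projection(self, noiseless):
        noisy = ss.scale_and_add_noise(noiseless, 1e5, seed=3)
        assert noisy.totals().mean() == pytest.approx(1e5, rel=0.01)
        assert np.array_equal(noisy.counts, np.round(noisy.counts))
        assert noisy.noise_applied

    def test_same_seed_reproduces_noise(self, noiseless):
        a = ss.scale_and_add_noise(noiseless, 1e4, seed=11)
        b = ss.scale_and_add_noise(noiseless, 1e4, seed=11)
        assert np.array_equal(a.counts, b.counts)

    def test_noise_cannot_be_applied_twice(self, noiseless):
        noisy = ss.scale_and_add_noise(noiseless, 1e4, seed=0)
        with pytest.raises(ValueError):
            ss.scale_and_add_noise(noisy, 1e4, seed=0)

    def test_poisson_variance_matches_mean(self):
        lam = np.full((3, 8, 8), 5.0)
        base = ProjectionSet(
            counts=lam, angles_deg=np.array([0.0, 120.0, 240.0]),
            voxel_size=4.42, psf_fwhm=0.0,
        )
        target = lam.sum(axis=(1, 2)).mean()  # keep expectations unchanged
        draws = np.stack(
            [ss.scale_and_add_noise(base, target, seed=s).counts for s in range(600)]
        )
        # per-bin moments fluctuate; their across-bin averages must match
        assert draws.mean(axis=0).mean() == pytest.approx(5.0, rel=0.02)
        assert draws.var(axis=0).mean() == pytest.approx(5.0, rel=0.05)


def _disk_volume(n=32, r=8, h=6):
    zz, yy, xx = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    return ((((yy - c) ** 2 + (xx - c) ** 2) < r**2) & (abs(zz - c) < h)).astype(float)


class TestOsem:
    def test_mlem_loglikelihood_nondecreasing(self):
        vol = _disk_volume()
        P = Projector(vol.shape, 4.42, default_angles(12), psf_fwhm_mm=7.5)
        meas = P.forward(vol)
        ps = ProjectionSet(meas, default_angles(12), 4.42, 7.5)
        lls = [
            poisson_loglik(meas, P.forward(ss.osem_reconstruct(ps, P, 1, it).values))
            for it in range(1, 11)
        ]
        assert all(b >= a - 1e-6 * abs(a) for a, b in zip(lls, lls[1:]))

    def test_uniform_fixed_point(self):
        n = 24
        P = Projector((n, n, n), 4.42, default_angles(12), psf_fwhm_mm=0.0)
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        fov = ((yy - (n - 1) / 2) ** 2 + (xx - (n - 1) / 2) ** 2) <= (n / 2.0) ** 2
        est0 = np.where(fov[None], 1.0, 0.0) * np.ones((n, 1, 1))
        ps = ProjectionSet(P.forward(est0), default_angles(12), 4.42, 0.0)
        rec = ss.osem_reconstruct(ps, P, subsets=1, iterations=3)
        assert np.allclose(rec.values, est0, atol=1e-9)

    def test_reconstruction_is_nonnegative_and_unfiltered_default(self):
        vol = _disk_volume()
        P = Projector(vol.shape, 4.42, default_angles(12), psf_fwhm_mm=7.5)
        ps = ss.scale_and_add_noise(
            ProjectionSet(P.forward(vol), default_angles(12), 4.42, 7.5), 1e4, seed=2
        )
        rec = ss.osem_reconstruct(ps, P)  # defaults: 6 subsets, 12 iterations
        assert rec.subsets == 6 and rec.iterations == 12
        assert (rec.values >= 0).all()

    def test_all_zero_projections_warn_and_return_zero(self):
        P = Projector((8, 8, 8), 4.42, default_angles(6))
        ps = ProjectionSet(np.zeros((6, 8, 8)), default_angles(6), 4.42, 7.5)
        with pytest.warns(UserWarning):
            rec = ss.osem_reconstruct(ps, P, 1, 1)
        assert not rec.values.any()

    def test_angles_must_divide_into_subsets(self):
        P = Projector((8, 8, 8), 4.42, default_angles(10))
        ps = ProjectionSet(np.ones((10, 8, 8)), default_angles(10), 4.42, 7.5)
        with pytest.raises(ValueError):
            ss.osem_reconstruct(ps, P, subsets=4)


class TestFastSurrogate:
    def test_zero_activity_stays_zero(self, phantom20_small):
        act = ss.compose_activity(phantom20_small, ss.CaseSpec(20, 0.0, 1.0))
        act.values[...] = 0.0
        out = ss.degrade_fast(act, noise_scale=5.0, seed=0)
        assert not out.values.any()

    def test_high_count_limit_recovers_blurred_activity(self, phantom20_small):
        act = ss.compose_activity(phantom20_small, ss.CaseSpec(20, 0.10, 1.0))
        nearly_clean = ss.degrade_fast(act, noise_scale=1e8, seed=0).values
        from scipy import ndimage
        from spectseg.simulate import FWHM_TO_SIGMA

        blurred = ndimage.gaussian_filter(act.values, 7.5 * FWHM_TO_SIGMA / 4.42)
        assert np.allclose(nearly_clean, blurred, atol=1e-3)

    def test_seeded_determinism(self, phantom20_small):
        act = ss.compose_activity(phantom20_small, ss.CaseSpec(20, 0.10, 1.0))
        a = ss.degrade_fast(act, noise_scale=8.0, seed=42).values
        b = ss.degrade_fast(act, noise_scale=8.0, seed=42).values
        assert np.array_equal(a, b)


class TestNoiseCalibration:
    def test_calibrated_cov_hits_target(self, phantom20_small):
        scale = ss.calibrate_noise(phantom20_small, target_cov=0.8, bg_level=0.20, seed=1)
        act = ss.compose_activity(phantom20_small, ss.CaseSpec(20, 0.20, 1.0))
        roi = _calibration_background_roi(phantom20_small)
        covs = []
        for seed in range(5):
            img = ss.degrade_fast(act, noise_scale=scale, seed=100 + seed).values
            covs.append(img[roi].std() / img[roi].mean())
        assert np.mean(covs) == pytest.approx(0.8, abs=0.05)

    def test_cov_decreases_with_count_scale(self, phantom20_small):
        act = ss.compose_activity(phantom20_small, ss.CaseSpec(20, 0.20, 1.0))
        roi = _calibration_background_roi(phantom20_small)

        def cov(scale):
            img = ss.degrade_fast(act, noise_scale=scale, seed=7).values
            return img[roi].std() / img[roi].mean()

        assert cov(2.0) > cov(50.0) > cov(5000.0)

    def test_zero_target_is_unreachable(self, phantom20_small):
        with pytest.raises(CalibrationError):
            ss.calibrate_noise(phantom20_small, target_cov=0.0)
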