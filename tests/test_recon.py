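import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polyct as pc
from polyct.recon import ReconError, _golden_view_order


@pytest.fixture(scope="module")
def mono_model():
    """Three-material model on a single-bin 50 keV grid."""
    return pc.build_material_model(
        [pc.load_material(n) for n in ("water", "bone_cortical", "titanium")],
        50.0, [50.0],
        mu_at_e0={"water": 0.236, "bone_cortical": 0.837, "titanium": 5.518})


class TestRelativeChange:
    def test_identical_images(self):
        mu = np.ones((4, 4))
        assert pc.relative_change(mu, mu) == 0.0

    def test_doubling_gives_one(self):
        mu = np.random.default_rng(0).uniform(0.1, 1, (5, 5))
        assert pc.relative_change(mu, 2 * mu) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert pc.relative_change(np.array([3.0, 4.0]),
                                  np.array([3.0, 0.0])) == pytest.approx(0.64)

    def test_zero_previous_forces_continuation(self):
        assert pc.relative_change(np.zeros(3), np.ones(3)) == np.inf

    @given(st.floats(0.1, 5.0))
    @settings(deadline=None)
    def test_uniform_scaling_property(self, c):
        mu = np.array([1.0, 2.0, 3.0])
        assert pc.relative_change(mu, c * mu) == pytest.approx((c - 1.0) ** 2)


class TestGradientRow:
    def test_matches_central_finite_differences(self, small_geometry,
                                                spectrum_120kvp, model):
        # oracle: central differences of the polychromatic projection with
        # the labels frozen
        rng = np.random.default_rng(4)
        mu = rng.uniform(0.0, 1.2, 64 * 64)
        labels = pc.classify(model, mu)
        row = pc.trace_ray(small_geometry, 9, 60)
        grad = pc.gradient_row(row, mu, labels, spectrum_120kvp, model)

        def p_of(m):
            t = pc.material_line_integrals(row, m, labels, model.n_materials)
            return pc.poly_projection(t, spectrum_120kvp, model)

        eps = 1e-6
        for e_idx in range(0, row.pixel_indices.size, 7):
            j = row.pixel_indices[e_idx]
            up, dn = mu.copy(), mu.copy()
            up[j] += eps
            dn[j] -= eps
            fd = (p_of(up) - p_of(dn)) / (2 * eps)
            assert abs(grad.values[e_idx] - fd) / grad.values[e_idx] < 1e-5

    def test_positive_entries(self, small_geometry, spectrum_120kvp, model):
        # corrective direction: the gradient of p_i w.r.t. any crossed pixel
        # is positive for nonnegative normalised curves
        mu = np.full(64 * 64, 0.3)
        labels = pc.classify(model, mu)
        row = pc.trace_ray(small_geometry, 0, 64)
        grad = pc.gradient_row(row, mu, labels, spectrum_120kvp, model)
        assert np.all(grad.values > 0)

    def test_unattenuated_limit(self, small_geometry, spectrum_120kvp, model):
        # mu = 0: weights reduce to the plain spectral average of the
        # background material's curve
        mu = np.zeros(64 * 64)
        labels = pc.classify(model, mu)
        row = pc.trace_ray(small_geometry, 0, 64)
        grad = pc.gradient_row(row, mu, labels, spectrum_120kvp, model)
        sd = spectrum_120kvp.weights * spectrum_120kvp.delta
        expected = 0.1 * row.lengths_mm * float(sd @ model.mu_hat[0])
        np.testing.assert_allclose(grad.values, expected, rtol=1e-12)

    def test_single_bin_gradient_is_row_lengths(self, small_geometry,
                                                mono_model):
        mu = np.full(64 * 64, 0.5)
        labels = pc.classify(mono_model, mu)
        row = pc.trace_ray(small_geometry, 5, 70)
        grad = pc.gradient_row(row, mu, labels, pc.monochromatic(50.0),
                               mono_model)
        np.testing.assert_allclose(grad.values, 0.1 * row.lengths_mm,
                                   rtol=1e-12)


class TestEartUpdate:
    def test_zero_residual_leaves_image_unchanged(self, small_geometry,
                                                  spectrum_120kvp, model):
        mu = np.full((64, 64), 0.3)
        labels = pc.classify(model, mu.ravel())
        row = pc.trace_ray(small_geometry, 3, 64)
        t = pc.material_line_integrals(row, mu.ravel(), labels,
                                       model.n_materials)
        p = pc.poly_projection(t, spectrum_120kvp, model)
        out = pc.eart_update(mu, p, row, spectrum_120kvp, model)
        np.testing.assert_allclose(out, mu, atol=1e-14)

    def test_single_bin_equals_kaczmarz_step(self, small_geometry, mono_model):
        # oracle: an independent classical ART (Kaczmarz) step
        rng = np.random.default_rng(8)
        mu = rng.uniform(0.0, 1.0, (64, 64))
        row = pc.trace_ray(small_geometry, 13, 55)
        p_meas = 1.7
        a = np.zeros(64 * 64)
        a[row.pixel_indices] = 0.1 * row.lengths_mm
        kaczmarz = mu.ravel() + (p_meas - a @ mu.ravel()) / (a @ a) * a
        out = pc.eart_update(mu, p_meas, row, pc.monochromatic(50.0),
                             mono_model, clamp=False)
        np.testing.assert_allclose(out.ravel(), kaczmarz, atol=1e-12)

    def test_linear_row_residual_zeroed(self, small_geometry, mono_model):
        mu = np.full((64, 64), 0.2)
        row = pc.trace_ray(small_geometry, 2, 60)
        out = pc.eart_update(mu, 2.3, row, pc.monochromatic(50.0), mono_model,
                             clamp=False)
        assert pc.mono_projection(row, out) == pytest.approx(2.3, abs=1e-10)

    def test_one_pixel_converges_to_scalar_root(self, spectrum_120kvp):
        # one pixel, one ray: repeated updates must find the root of the
        # monotone scalar map p(mu) = p_measured; oracle: bisection
        m1 = pc.build_material_model([pc.load_material("water")], 50.0,
                                     spectrum_120kvp.energies,
                                     mu_at_e0={"water": 0.236})
        geom = pc.FanBeamGeometry(1000.0, 1200.0, 1, 100.0, 1, 1,
                                  pixel_size_mm=100.0)
        row = pc.trace_ray(geom, 0, 0)
        assert row.chord_mm == pytest.approx(100.0, rel=1e-12)

        def p_of(mu_val):
            t = pc.material_line_integrals(row, np.array([mu_val]),
                                           np.array([0]), 1)
            return pc.poly_projection(t, spectrum_120kvp, m1)

        p_target = p_of(0.31)
        lo, hi = 0.0, 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if p_of(mid) < p_target:
                lo = mid
            else:
                hi = mid
        mu = np.array([[0.0]])
        for _ in range(80):
            mu = pc.eart_update(mu, p_target, row, spectrum_120kvp, m1)
        assert abs(float(mu[0, 0]) - 0.5 * (lo + hi)) < 1e-8


class TestReconstructBhc:
    def test_zero_sinogram_stays_zero(self, small_geometry, spectrum_120kvp,
                                      model):
        sino = pc.Sinogram(np.zeros((60, 128)), small_geometry)
        state = pc.reconstruct_bhc(sino, small_geometry, spectrum_120kvp, model)
        assert state.iteration == 1
        assert np.all(state.mu == 0)

    def test_water_disk_recovery(self, small_geometry, spectrum_120kvp):
        # self-consistency: data simulated from a known disk must reproduce
        # its interior attenuation within 2%
        m1 = pc.build_material_model([pc.load_material("water")], 50.0,
                                     spectrum_120kvp.energies,
                                     mu_at_e0={"water": 0.236})
        spec = pc.PhantomSpec(disks=(pc.Disk(0.0, 0.0, 100.0, "water"),),
                              mu_e0={"water": 0.236})
        labels, mu0 = pc.make_disk_phantom(spec, small_geometry, m1)
        sino = pc.simulate_sinogram(labels, mu0, small_geometry,
                                    spectrum_120kvp, m1)
        state = pc.reconstruct_bhc(sino, small_geometry, spectrum_120kvp, m1)
        report = pc.region_stats(state.mu, np.where(mu0 > 0, 0, -1),
                                 erosion_px=3, include_labels=[0])
        assert report.mean(0) == pytest.approx(0.236, rel=0.02)

    def test_monochromatic_equivalence_with_classical_art(self, small_geometry,
                                                          small_phantom,
                                                          mono_model):
        # with a single-bin spectrum at E0, E-ART must agree with an
        # independently coded ART solver to 1e-8 (same order, same init)
        labels, mu0 = small_phantom
        s = pc.monochromatic(50.0)
        sino = pc.simulate_sinogram(labels, mu0, small_geometry, s, mono_model)
        state = pc.reconstruct_bhc(sino, small_geometry, s, mono_model,
                                   tol=0.0, max_iter=3)
        mu_ref = np.zeros(64 * 64)
        order = _golden_view_order(small_geometry.n_views)
        for _ in range(3):
            for v in order:
                for c in range(small_geometry.n_cells):
                    row = pc.trace_ray(small_geometry, int(v), c)
                    if row.pixel_indices.size == 0:
                        continue
                    a = 0.1 * row.lengths_mm
                    sub = mu_ref[row.pixel_indices]
                    resid = sino.values[v, c] - a @ sub
                    mu_ref[row.pixel_indices] = np.clip(
                        sub + resid / (a @ a) * a, 0.0, None)
        np.testing.assert_allclose(state.mu.ravel(), mu_ref, atol=1e-8)

    def test_kernel_sweep_matches_per_ray_reference(self, spectrum_120kvp,
                                                    model):
        # one full sweep of the numba kernel vs a Python loop built from the
        # public per-ray eart_update
        geom = pc.FanBeamGeometry(1000.0, 1200.0, 48, 6.4, 16, 32)
        labels, mu0 = pc.make_disk_phantom(pc.default_phantom(), geom, model)
        sino = pc.simulate_sinogram(labels, mu0, geom, spectrum_120kvp, model)
        state = pc.reconstruct_bhc(sino, geom, spectrum_120kvp, model,
                                   tol=0.0, max_iter=1)
        mu_ref = np.zeros(geom.image_shape)
        for v in _golden_view_order(geom.n_views):
            for c in range(geom.n_cells):
                row = pc.trace_ray(geom, int(v), c)
                if row.pixel_indices.size == 0:
                    continue
                mu_ref = pc.eart_update(mu_ref, float(sino.values[v, c]), row,
                                        spectrum_120kvp, model)
        np.testing.assert_allclose(state.mu, mu_ref, atol=1e-10)

    def test_projection_residual_nonincreasing(self, small_sinogram,
                                               small_geometry,
                                               spectrum_120kvp, model):
        # after convergence sets in, the forward-projected residual RMS must
        # not increase over the last sweeps
        final = pc.reconstruct_bhc(small_sinogram, small_geometry,
                                   spectrum_120kvp, model)
        rms = []
        for k in range(final.iteration - 2, final.iteration + 1):
            state = pc.reconstruct_bhc(small_sinogram, small_geometry,
                                       spectrum_120kvp, model, tol=0.0,
                                       max_iter=k)
            labels = pc.classify(model, state.mu)
            fwd = pc.simulate_sinogram(labels, state.mu, small_geometry,
                                       spectrum_120kvp, model)
            rms.append(float(np.sqrt(np.mean(
                (fwd.values - small_sinogram.values) ** 2))))
        for a, b in zip(rms, rms[1:]):
            assert b <= a * (1 + 1e-6)

    def test_divergence_guard(self):
        # a sweep that blows the image up must trip the e(r) > 1e3 abort
        from polyct.recon import _iterate

        def exploding_sweep(mu_img):
            mu_img *= 100.0

        with pytest.raises(ReconError, match="diverging"):
            _iterate(np.ones((4, 4)), exploding_sweep, tol=1e-4, max_iter=10)

    def test_default_phantom_recovery(self, small_sinogram, small_geometry,
                                      small_phantom, spectrum_120kvp, model):
        # region means approach the pinned ground truths even at the
        # miniature test scale (coarse pixels -> looser bands than the
        # acceptance-scale run)
        labels, mu0 = small_phantom
        state = pc.reconstruct_bhc(small_sinogram, small_geometry,
                                   spectrum_120kvp, model)
        regions = np.where(mu0 > 0, labels, -1)
        report = pc.region_stats(state.mu, regions, erosion_px=1,
                                 include_labels=[0, 1])
        assert report.mean(0) == pytest.approx(0.236, rel=0.02)
        assert report.mean(1) == pytest.approx(0.837, rel=0.05)


class TestReconstructSart:
    def test_zero_sinogram_gives_zero_image(self, small_geometry):
        sino = pc.Sinogram(np.zeros((60, 128)), small_geometry)
        state = pc.reconstruct_sart(sino, small_geometry)
        assert np.all(state.mu == 0)

    def test_monochromatic_recovery(self, mono_model):
        # data generated with the linear projector: SART recovers the phantom
        geom = pc.FanBeamGeometry(1000.0, 1200.0, 256, 1.2, 180, 128)
        labels, mu0 = pc.make_disk_phantom(pc.default_phantom(), geom,
                                           mono_model)
        sino = pc.simulate_sinogram(labels, mu0, geom, pc.monochromatic(50.0),
                                    mono_model)
        state = pc.reconstruct_sart(sino, geom)
        regions = np.where(mu0 > 0, labels, -1)
        report = pc.region_stats(state.mu, regions, erosion_px=2,
                                 include_labels=[0, 1])
        assert report.mean(0) == pytest.approx(0.236, rel=0.02)
        assert report.mean(1) == pytest.approx(0.837, rel=0.02)

    def test_polychromatic_data_shows_cupping(self, small_sinogram,
                                              small_geometry, small_phantom):
        # beam hardening: the water interior reconstructs lower at the
        # centre than near the rim
        labels, mu0 = small_phantom
        state = pc.reconstruct_sart(small_sinogram, small_geometry)
        x, y = small_geometry.pixel_centers()
        r = np.hypot(x, y)
        center = state.mu[(r < 25) & (labels == 0) & (mu0 > 0)].mean()
        edge = state.mu[(r > 95) & (r < 112) & (labels == 0) & (mu0 > 0)].mean()
        assert center < edge

    def test_sart_worse_than_bhc_on_polychromatic_data(
            self, small_sinogram, small_geometry, small_phantom,
            spectrum_120kvp, model):
        labels, mu0 = small_phantom
        sart = pc.reconstruct_sart(small_sinogram, small_geometry)
        bhc = pc.reconstruct_bhc(small_sinogram, small_geometry,
                                 spectrum_120kvp, model)
        assert pc.mse(bhc.mu, mu0) < pc.mse(sart.mu, mu0)
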