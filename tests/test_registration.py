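"""Registration machinery: pyramid, sampler, interpolation, MI, gradients,
transforms, optimizer and resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from ctavg.registration import (
    AffineTransform,
    BSplineTransform,
    InsufficientAlignments,
    Interpolator,
    MetricConfig,
    OptimizerConfig,
    PyramidConfig,
    RegistrationConfig,
    RigidTransform,
    SamplerConfig,
    TransformChain,
    build_pyramid,
    interpolate,
    load_chain,
    metric_value_and_gradient,
    mutual_information,
    parzen_joint_histogram,
    register,
    resample,
    sample_coordinates,
    save_chain,
)
from ctavg.volumes import HeadMask, VolumeHU


def smooth_volume(shape=(24, 24, 24), spacing=2.0, seed=0):
    """A smooth random test image with non-trivial structure."""
    from scipy import ndimage
    rng = np.random.default_rng(seed)
    v = ndimage.gaussian_filter(rng.normal(size=shape), 2.0) * 300.0
    return VolumeHU(v, spacing=(spacing,) * 3)


class TestPyramid:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            PyramidConfig(sigmas=(1.0, 2.0))
        with pytest.raises(ValueError):
            PyramidConfig(sigmas=(2.0, -1.0))

    def test_constant_preserved_and_variance_ordering(self, rng):
        vol = VolumeHU(np.full((16, 16, 16), 7.0))
        for lev in build_pyramid(vol):
            np.testing.assert_allclose(lev.voxels, 7.0, atol=1e-9)
        noisy = VolumeHU(rng.normal(size=(24, 24, 24)))
        levels = build_pyramid(noisy)
        assert len(levels) == 4
        variances = [lev.voxels.var() for lev in levels]
        assert all(variances[i] <= variances[i + 1] for i in range(3))

    def test_impulse_response_matches_gaussian_kernel(self):
        vol = np.zeros((33, 33, 33))
        vol[16, 16, 16] = 1.0
        sigma = 2.0
        lev = build_pyramid(VolumeHU(vol), PyramidConfig(sigmas=(4.0, sigma)))[1]
        radius = 8
        kern = oracles.gaussian_impulse_kernel(sigma, radius)
        got = lev.voxels[16 - radius:16 + radius + 1,
                         16 - radius:16 + radius + 1,
                         16 - radius:16 + radius + 1]
        np.testing.assert_allclose(got, kern, atol=1e-3 * kern.max())


class TestSampler:
    def test_full_mask_points_inside_bbox(self, rng):
        grid = VolumeHU(np.zeros((10, 12, 14)), spacing=(2.0, 1.0, 1.0), origin=(5.0, -3.0, 0.0))
        cfg = SamplerConfig(n_samples=3000)
        pts = sample_coordinates(HeadMask(np.ones(grid.shape, bool)), grid, cfg, rng)
        assert len(pts) == 3000
        lo, hi = grid.world_bounds()
        assert np.all(pts >= lo) and np.all(pts <= hi)

    def test_single_voxel_mask_confines_points(self, rng):
        grid = VolumeHU(np.zeros((8, 8, 8)))
        m = np.zeros(grid.shape, bool)
        m[3, 4, 5] = True
        pts = sample_coordinates(HeadMask(m), grid, SamplerConfig(n_samples=500), rng)
        center = grid.index_to_world(np.array([3, 4, 5]))
        assert np.all(np.abs(pts - center) <= 0.5 * grid.spacing + 1e-12)

    def test_points_are_continuous(self, rng):
        grid = VolumeHU(np.zeros((8, 8, 8)))
        pts = sample_coordinates(HeadMask(np.ones(grid.shape, bool)), grid,
                                 SamplerConfig(n_samples=200), rng)
        assert np.abs(pts - np.round(pts)).max() > 0  # not all voxel centers

    def test_disjoint_domains_raise(self):
        vol = smooth_volume()
        stage = RigidTransform(center=np.zeros(3))
        stage.translation = np.array([1e5, 1e5, 1e5])  # maps everything outside
        interp = Interpolator(vol, 1)
        pts = vol.index_to_world(np.indices(vol.shape).reshape(3, -1).T[::7])
        fv = vol.voxels.ravel()[::7].astype(float)
        with pytest.raises(InsufficientAlignments):
            metric_value_and_gradient(stage, pts, fv, interp, MetricConfig(),
                                      (0.0, 1.0), (0.0, 1.0), min_valid=150)


class TestInterpolation:
    @pytest.mark.parametrize("order", [1, 3])
    def test_voxel_centers_reproduced(self, order):
        vol = smooth_volume(seed=1)
        idx = np.array([[0, 0, 0], [3, 5, 7], [23, 23, 23], [10, 0, 15]])
        vals = interpolate(vol, vol.index_to_world(idx), order=order)
        np.testing.assert_allclose(vals, vol.voxels[tuple(idx.T)], atol=1e-6)

    def test_linear_ramp_exact_for_trilinear(self, rng):
        zz, yy, xx = np.indices((10, 10, 10)).astype(float)
        vol = VolumeHU(2.0 * zz - 3.0 * yy + 0.5 * xx + 10.0, spacing=(2.0, 2.0, 2.0))
        idx = rng.uniform(0.5, 8.5, (50, 3))
        vals = interpolate(vol, vol.index_to_world(idx), order=1)
        expected = 2.0 * idx[:, 0] - 3.0 * idx[:, 1] + 0.5 * idx[:, 2] + 10.0
        np.testing.assert_allclose(vals, expected, atol=1e-9)

    def test_cubic_matches_naive_separable_oracle(self, rng):
        vol = smooth_volume(seed=2)
        idx = rng.uniform(0.0, 23.0, (100, 3))
        got = interpolate(vol, vol.index_to_world(idx), order=3)
        want = oracles.separable_cubic_interp(vol.voxels, idx)
        np.testing.assert_allclose(got, want, atol=1e-5 * np.abs(want).max())

    def test_outside_domain_marked_not_raised(self):
        vol = smooth_volume()
        vals = interpolate(vol, np.array([[-50.0, 0.0, 0.0], [0.0, 0.0, 0.0]]), order=3)
        assert np.isnan(vals[0]) and np.isfinite(vals[1])

    def test_partition_of_unity_via_constant_lattice(self, rng):
        # a B-spline lattice with all control points equal to a constant
        # vector must produce exactly that displacement everywhere: the
        # 4x4x4 basis weights sum to 1 at any evaluation point
        tf = BSplineTransform(np.zeros(3), np.array([100.0, 100.0, 100.0]), 20.0)
        tf.coef[...] = np.array([1.7, -2.3, 0.9])
        pts = rng.uniform(0, 100, (1000, 3))
        disp = tf.displacement(pts)
        np.testing.assert_allclose(
            disp, np.broadcast_to([1.7, -2.3, 0.9], disp.shape), atol=1e-9
        )


class TestMutualInformation:
    def test_symmetry_exact(self, rng):
        f = rng.normal(size=2000)
        m = rng.normal(size=2000) + 0.5 * f
        assert abs(mutual_information(f, m) - mutual_information(m, f)) <= 1e-12

    def test_degenerate_channel_zero(self, rng):
        m = rng.normal(size=500)
        assert mutual_information(np.full(500, 3.0), m) == 0.0
        assert mutual_information(m, np.full(500, -1.0)) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            f = rng.uniform(0, 100, 1500)
            m = 0.7 * f + rng.normal(0, 10, 1500)
            got = mutual_information(f, m)
            want = oracles.parzen_mi(f, m)
            assert got == pytest.approx(want, rel=1e-9)

    def test_self_mi_maximal_over_permutations(self, rng):
        x = rng.uniform(0, 50, 1000)
        self_mi = mutual_information(x, x)
        for _ in range(5):
            assert self_mi >= mutual_information(x, rng.permutation(x))

    def test_independent_uniforms_carry_little_information(self):
        # sampling noise floor of the 32-bin Parzen estimator at n=3000
        for seed in range(10):
            r = np.random.default_rng(seed)
            mi = mutual_information(r.uniform(0, 1, 3000), r.uniform(0, 1, 3000))
            assert 0.0 <= mi < 0.05

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 40))
    def test_nonnegative_up_to_discretization(self, seed, scale):
        r = np.random.default_rng(seed)
        f = r.normal(0, scale, 400)
        m = r.normal(0, scale, 400)
        assert mutual_information(f, m) >= -1e-9

    def test_joint_histogram_normalized(self, rng):
        h = parzen_joint_histogram(rng.normal(size=800), rng.normal(size=800))
        assert h.shape == (32, 32)
        assert h.sum() == pytest.approx(1.0, abs=1e-9)


def _make_stage(kind, vol, rng):
    center = np.array(vol.shape) * vol.spacing / 2.0
    if kind == "rigid":
        st_ = RigidTransform(center, rot_scale_mm=30.0)
        st_.set_scaled(rng.normal(0, 0.5, 6))
    elif kind == "affine":
        st_ = AffineTransform(center, rot_scale_mm=30.0)
        st_.set_scaled(rng.normal(0, 0.5, 12))
    else:
        lo, hi = vol.world_bounds()
        st_ = BSplineTransform(lo, hi, 16.0)
        st_.coef += rng.normal(0, 0.4, st_.coef.shape)
    return st_


class TestMetricGradient:
    @pytest.mark.parametrize("kind", ["rigid", "affine", "bspline"])
    def test_analytic_gradient_matches_finite_differences(self, kind):
        fixed = smooth_volume(seed=3)
        moving = smooth_volume(seed=4)
        interp = Interpolator(moving, 3)
        cfg = MetricConfig()
        rng = np.random.default_rng(100)
        idx = rng.uniform(6.0, 17.0, (800, 3))  # interior points only
        pts = fixed.index_to_world(idx)
        fi = Interpolator(fixed, 3)
        fvals, _, _ = fi(pts)
        f_range = (fvals.min() - 5, fvals.max() + 5)
        m_range = (moving.voxels.min() - 5, moving.voxels.max() + 5)

        for point in range(20):
            prng = np.random.default_rng(500 + point)
            stage = _make_stage(kind, fixed, prng)
            q0 = stage.get_scaled()
            cost0, grad = metric_value_and_gradient(
                stage, pts, fvals, interp, cfg, f_range, m_range)
            comps = (np.arange(len(q0)) if len(q0) <= 12
                     else prng.choice(len(q0), 20, replace=False))
            h = 1e-4
            for c in comps:
                for sgn, store in ((1.0, "p"), (-1.0, "m")):
                    q = q0.copy()
                    q[c] += sgn * h
                    stage.set_scaled(q)
                    val, _ = metric_value_and_gradient(
                        stage, pts, fvals, interp, cfg, f_range, m_range)
                    if store == "p":
                        cp = val
                    else:
                        cm = val
                stage.set_scaled(q0)
                fd = (cp - cm) / (2 * h)
                assert grad[c] == pytest.approx(fd, rel=0.05, abs=1e-6)

    def test_zero_bspline_on_identical_images_near_stationary(self):
        vol = smooth_volume(seed=5)
        lo, hi = vol.world_bounds()
        stage = BSplineTransform(lo, hi, 16.0)
        rng = np.random.default_rng(2)
        idx = rng.uniform(4.0, 19.0, (2000, 3))
        pts = vol.index_to_world(idx)
        fi = Interpolator(vol, 3)
        fvals, _, _ = fi(pts)
        rng_ = (fvals.min() - 1, fvals.max() + 1)
        _, grad0 = metric_value_and_gradient(stage, pts, fvals, fi,
                                             MetricConfig(), rng_, rng_)
        # identical images, identity transform: stationary up to Parzen
        # sampling noise — far below the gradient of a displaced lattice
        stage.coef[..., 0] += 2.0
        _, grad1 = metric_value_and_gradient(stage, pts, fvals, fi,
                                             MetricConfig(), rng_, rng_)
        assert np.abs(grad0).max() < 0.1 * np.abs(grad1).max()

    def test_translation_gradient_points_home(self):
        vol = smooth_volume(seed=6)
        fi = Interpolator(vol, 3)
        good = 0
        for trial in range(20):
            rng = np.random.default_rng(900 + trial)
            t = rng.uniform(-4, 4, 3)
            stage = RigidTransform(center=np.array(vol.shape) * vol.spacing / 2)
            stage.translation = t.copy()
            idx = rng.uniform(5.0, 18.0, (1500, 3))
            pts = vol.index_to_world(idx)
            fvals, _, _ = fi(pts)
            rng_ = (vol.voxels.min() - 1, vol.voxels.max() + 1)
            _, grad = metric_value_and_gradient(stage, pts, fvals, fi,
                                                MetricConfig(), rng_, rng_)
            # descending the cost must shrink the misalignment:
            # the gradient's translation block points along +t
            if np.dot(grad[3:], t) > 0:
                good += 1
        assert good >= 19


class TestTransforms:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rigid_is_isometry(self, seed):
        r = np.random.default_rng(seed)
        tf = RigidTransform(center=r.uniform(-10, 10, 3))
        tf.angles = r.uniform(-np.pi, np.pi, 3)
        tf.translation = r.uniform(-20, 20, 3)
        pts = r.uniform(-50, 50, (10, 3))
        out = tf.apply(pts)
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        np.testing.assert_allclose(d_out, d_in, rtol=1e-9, atol=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_affine_preserves_collinearity(self, seed):
        r = np.random.default_rng(seed)
        tf = AffineTransform(center=r.uniform(-5, 5, 3))
        tf.linear = np.eye(3) + r.uniform(-0.2, 0.2, (3, 3))
        tf.translation = r.uniform(-10, 10, 3)
        a, b = r.uniform(-30, 30, (2, 3))
        lam = r.uniform(0, 1)
        c = a + lam * (b - a)
        fa, fb, fc = tf.apply(np.array([a, b, c]))
        np.testing.assert_allclose(fc, fa + lam * (fb - fa), atol=1e-9)

    def test_empty_chain_is_identity(self, rng):
        pts = rng.normal(size=(7, 3))
        np.testing.assert_array_equal(TransformChain().apply(pts), pts)

    def test_zero_coefficients_is_identity(self, rng):
        tf = BSplineTransform(np.zeros(3), np.full(3, 60.0), 20.0)
        pts = rng.uniform(0, 60, (200, 3))
        np.testing.assert_allclose(tf.apply(pts), pts, atol=1e-12)

    def test_chain_save_load_round_trip(self, tmp_path, rng):
        chain = TransformChain()
        tf = RigidTransform(center=np.array([1.0, 2.0, 3.0]))
        tf.set_scaled(rng.normal(size=6))
        chain.stages.append(tf)
        af = AffineTransform(center=np.array([1.0, 2.0, 3.0]))
        af.set_scaled(rng.normal(size=12))
        chain.stages.append(af)
        bs = BSplineTransform(np.zeros(3), np.full(3, 40.0), 20.0)
        bs.coef += rng.normal(size=bs.coef.shape)
        chain.stages.append(bs)
        path = tmp_path / "chain.txt"
        save_chain(chain, path)
        back = load_chain(path)
        pts = rng.uniform(0, 40, (50, 3))
        np.testing.assert_allclose(back.apply(pts), chain.apply(pts), atol=1e-12)


class TestOptimizerAndRegister:
    def test_translation_recovery_and_determinism(self, tiny_control):
        pre, mask, _ = tiny_control
        true_t = np.array([3.0, -2.0, 1.0])
        idx = np.indices(pre.shape).reshape(3, -1).T
        interp = Interpolator(pre, 3)
        vals, _, valid = interp(pre.index_to_world(idx) + true_t)
        vals[~valid] = -1000.0
        fixed = VolumeHU(vals.reshape(pre.shape), pre.spacing, pre.origin)
        cfg = RegistrationConfig(stages=("rigid",))
        chain = register(fixed, pre, cfg, seed=13)
        st_ = chain.stages[0]
        np.testing.assert_allclose(st_.translation, true_t, atol=0.5)
        np.testing.assert_allclose(np.rad2deg(st_.angles), 0.0, atol=0.5)
        chain2 = register(fixed, pre, cfg, seed=13)
        np.testing.assert_array_equal(chain2.stages[0].get_scaled(), st_.get_scaled())

    def test_self_registration_near_identity(self, tiny_control):
        pre, mask, _ = tiny_control
        chain = register(pre, pre, RegistrationConfig(), seed=29)
        hm = np.argwhere(mask.mask)[::11]
        pts = pre.index_to_world(hm)
        disp = np.linalg.norm(chain.apply(pts) - pts, axis=1)
        assert disp.mean() < 0.5

    def test_intersubject_registration_improves_overlap(self, fast_spec):
        from ctavg.phantom import generate_control
        from ctavg.volumes import preprocess
        a, _ = generate_control(fast_spec, seed=61)
        b, _ = generate_control(fast_spec, seed=62)
        fa, ma = preprocess(a, slice_mm=2.0)
        fb, _ = preprocess(b, slice_mm=2.0)
        chain = register(fa, fb, seed=3)
        warped = resample(fb, chain, fa)
        naive = resample(fb, TransformChain(), fa)
        sel = ma.mask

        def ncc(x, y):
            x = x - x.mean()
            y = y - y.mean()
            return float((x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum()))

        assert ncc(fa.voxels[sel], warped.voxels[sel]) > ncc(fa.voxels[sel], naive.voxels[sel])


class TestResample:
    def test_identity_chain_reproduces_volume(self):
        vol = smooth_volume(seed=8)
        out = resample(vol, TransformChain(), vol)
        np.testing.assert_allclose(out.voxels, vol.voxels, atol=1e-5)

    def test_one_voxel_translation_shifts_rows(self):
        vol = smooth_volume(seed=9)
        tf = RigidTransform(center=np.zeros(3))
        tf.translation = np.array([0.0, vol.spacing[1], 0.0])
        out = resample(vol, TransformChain([tf]), vol)
        np.testing.assert_allclose(out.voxels[:, :-1, :], vol.voxels[:, 1:, :], atol=1e-5)

    def test_all_outside_fills_air(self):
        vol = smooth_volume(seed=10)
        tf = RigidTransform(center=np.zeros(3))
        tf.translation = np.full(3, 1e4)
        out = resample(vol, TransformChain([tf]), vol)
        np.testing.assert_array_equal(out.voxels, -1000.0)


class TestConfigs:
    def test_sampler_invariant(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_samples=100, min_valid=150)

    def test_metric_bins_invariant(self):
        with pytest.raises(ValueError, match="n_bins"):
            MetricConfig(n_bins=1)

    def test_optimizer_iterations_positive(self):
        with pytest.raises(ValueError):
            OptimizerConfig(iterations={"rigid": 0})
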