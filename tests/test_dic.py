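import numpy as np
import pytest

import gelmech as gm
from gelmech.dic import DICConfig, DisplacementField, compute_strain, match_subsets

from conftest import matchable_mask


def brute_force_match(ref, dfm, config):
    """Exhaustive integer ZNCC search; the independent matching oracle.

    Same grid and tie rule as the optimized matcher (smallest displacement
    magnitude, then row-major order over the search window), written as
    plain loops against the textbook ZNCC formula.  Also returns the
    margin between the best and second-best score at each grid point:
    where the margin is below float noise the winner is a numerical tie
    and the two implementations may legitimately differ.
    """
    half, R = config.subset_size // 2, config.search_radius
    h, w = ref.shape
    gx = np.arange(half, w - half, config.grid_spacing)
    gy = np.arange(half, h - half, config.grid_spacing)
    u = np.zeros((gy.size, gx.size))
    v = np.zeros((gy.size, gx.size))
    corr = np.full((gy.size, gx.size), -2.0)
    margin = np.zeros((gy.size, gx.size))
    for iy, y in enumerate(gy):
        for ix, x in enumerate(gx):
            s = ref[y - half:y + half + 1, x - half:x + half + 1].astype(float)
            s = s - s.mean()
            ns = np.sqrt((s * s).sum())
            if ns == 0:
                continue
            best = None
            second = -np.inf
            order = 0
            for dv in range(-R, R + 1):
                for du in range(-R, R + 1):
                    ys, xs = y + dv, x + du
                    if not (half <= ys < h - half and half <= xs < w - half):
                        continue
                    t = dfm[ys - half:ys + half + 1, xs - half:xs + half + 1]
                    t = t.astype(float) - t.mean()
                    nt = np.sqrt((t * t).sum())
                    z = (s * t).sum() / (ns * nt) if nt > 0 else -2.0
                    key = (-z, du * du + dv * dv, order)
                    if best is None or key < best[0]:
                        if best is not None:
                            second = max(second, best[3])
                        best = (key, du, dv, z)
                    else:
                        second = max(second, z)
                    order += 1
            u[iy, ix], v[iy, ix], corr[iy, ix] = best[1], best[2], best[3]
            margin[iy, ix] = best[3] - second
    return u, v, corr, margin


class TestSubsetMatching:
    def test_integer_shift_recovered_exactly(self, speckle_ref):
        stack, truth = gm.warp_sequence(speckle_ref,
                                        gm.translation_schedule([(0, 0), (3, -2)]))
        cfg = DICConfig()
        fld = match_subsets(speckle_ref, stack[1], cfg)
        m = fld.valid_mask & matchable_mask(truth, 1, fld.grid_x, fld.grid_y,
                                            speckle_ref.shape, cfg.subset_size // 2)
        assert m.sum() > 100
        assert np.all(fld.u[m] == 3.0)
        assert np.all(fld.v[m] == -2.0)

    def test_no_motion_gives_zero_and_unit_correlation(self, speckle_ref):
        fld = match_subsets(speckle_ref, speckle_ref, DICConfig())
        m = fld.valid_mask
        assert np.all(fld.u[m] == 0) and np.all(fld.v[m] == 0)
        np.testing.assert_allclose(fld.correlation[m], 1.0, atol=1e-12)

    def test_zncc_invariant_to_gain_and_offset(self, stretch_pair, speckle_ref):
        stack, _ = stretch_pair
        cfg = DICConfig()
        base = match_subsets(speckle_ref, stack[1], cfg)
        mod = match_subsets(speckle_ref, 1.7 * stack[1] + 23.0, cfg)
        np.testing.assert_allclose(mod.u, base.u, atol=1e-9)
        np.testing.assert_allclose(mod.v, base.v, atol=1e-9)
        np.testing.assert_allclose(mod.correlation, base.correlation, atol=1e-9)

    def test_translation_equivariance(self, speckle_ref):
        """Shifting both images identically leaves the match unchanged."""
        crop = speckle_ref[:96, :96]
        stack, _ = gm.warp_sequence(crop, gm.translation_schedule([(0, 0), (2, 1)]))
        cfg = DICConfig(search_radius=5)
        a = match_subsets(crop, stack[1], cfg)
        shifted_ref = np.roll(crop, (4, 4), axis=(0, 1))
        shifted_def = np.roll(stack[1], (4, 4), axis=(0, 1))
        b = match_subsets(shifted_ref, shifted_def, cfg)
        inner = np.zeros_like(a.valid_mask)
        inner[3:-3, 3:-3] = True
        m = a.valid_mask & b.valid_mask & inner
        assert m.sum() > 20
        np.testing.assert_allclose(a.u[m], b.u[m], atol=1e-9)

    def test_matches_brute_force_oracle(self):
        spec = gm.SpeckleSpec(image_size=(31, 31), speckle_density=0.01,
                              blob_radius_range=(1.0, 2.0), noise_sd=1.0, seed=7)
        ref = gm.gen_speckle_image(spec)
        stack, _ = gm.warp_sequence(
            ref, gm.WarpSchedule("uniform_stretch", (1.0, 1.08)))
        cfg = DICConfig(subset_size=9, grid_spacing=3, search_radius=3,
                        subpixel="none", min_correlation=-1.0)
        fld = match_subsets(ref, stack[1], cfg)
        bu, bv, bcorr, margin = brute_force_match(ref, stack[1], cfg)
        # peak scores agree everywhere; the winning offset agrees wherever
        # the peak is not a floating-point tie
        np.testing.assert_allclose(fld.correlation, bcorr, atol=1e-12)
        decided = margin > 1e-9
        assert decided.mean() > 0.8
        np.testing.assert_array_equal(fld.u[decided], bu[decided])
        np.testing.assert_array_equal(fld.v[decided], bv[decided])

    def test_uniform_stretch_recovered_within_rms_budget(self, stretch_pair,
                                                         speckle_ref):
        stack, truth = stretch_pair
        cfg = DICConfig()
        fld = match_subsets(speckle_ref, stack[1], cfg)
        X, Y = np.meshgrid(fld.grid_x, fld.grid_y)
        ut, vt, _ = truth.displacement(1, X, Y)
        m = fld.valid_mask & matchable_mask(truth, 1, fld.grid_x, fld.grid_y,
                                            speckle_ref.shape, cfg.subset_size // 2)
        rms_u = np.sqrt(np.mean((fld.u[m] - ut[m]) ** 2))
        rms_v = np.sqrt(np.mean((fld.v[m] - vt[m]) ** 2))
        assert rms_u < 0.2 and rms_v < 0.2

    def test_flat_subsets_masked_invalid(self):
        img = np.full((64, 64), 100.0)
        fld = match_subsets(img, img, DICConfig(search_radius=3))
        assert not fld.valid_mask.any()

    def test_shape_mismatch_rejected(self, speckle_ref):
        with pytest.raises(ValueError):
            match_subsets(speckle_ref, speckle_ref[:64, :64], DICConfig())


def field_from_function(fn, nx=12, ny=12, spacing=5.0):
    """Analytic DisplacementField for exercising the strain stage alone."""
    gx = spacing * np.arange(nx)
    gy = spacing * np.arange(ny)
    X, Y = np.meshgrid(gx, gy)
    u, v = fn(X, Y)
    return DisplacementField(grid_x=gx, grid_y=gy, u=u, v=v,
                             correlation=np.ones_like(u),
                             valid_mask=np.ones_like(u, dtype=bool))


class TestStrainComputation:
    def test_rigid_translation_zero_strain(self):
        fld = field_from_function(lambda X, Y: (3.0 + 0 * X, -2.0 + 0 * Y))
        st = compute_strain(fld, DICConfig())
        assert np.all(np.abs(st.Exx[st.valid_mask]) < 1e-6)
        assert np.all(np.abs(st.Eyy[st.valid_mask]) < 1e-6)
        assert np.all(np.abs(st.Exy[st.valid_mask]) < 1e-6)

    def test_uniform_stretch_closed_form(self):
        fld = field_from_function(lambda X, Y: (0.05 * X, 0.0 * Y))
        st = compute_strain(fld, DICConfig())
        np.testing.assert_allclose(st.Exx[st.valid_mask], 0.05125, atol=1e-9)
        np.testing.assert_allclose(st.Eyy[st.valid_mask], 0.0, atol=1e-9)

    def test_small_rotation_strain_free(self):
        theta = np.radians(2.0)

        def rot(X, Y):
            c, s = np.cos(theta), np.sin(theta)
            return (c * X - s * Y - X, s * X + c * Y - Y)

        st = compute_strain(field_from_function(rot), DICConfig())
        # Green-Lagrange strain of a pure rotation vanishes identically.
        assert np.all(np.abs(st.Exx[st.valid_mask]) < 1e-9)
        assert np.all(np.abs(st.Eyy[st.valid_mask]) < 1e-9)
        small = compute_strain(field_from_function(rot),
                               DICConfig(strain_measure="small"))
        # the small-strain tensor leaves an O(theta^2) residual instead
        assert np.max(np.abs(small.Exx[small.valid_mask])) < theta ** 2

    def test_affine_warp_strain_matches_closed_form(self):
        def affine(X, Y):
            return (0.04 * X + 0.02 * Y, 0.01 * X - 0.03 * Y)

        st = compute_strain(field_from_function(affine), DICConfig())
        ux, uy, vx, vy = 0.04, 0.02, 0.01, -0.03
        Exx = ux + 0.5 * (ux ** 2 + vx ** 2)
        Eyy = vy + 0.5 * (uy ** 2 + vy ** 2)
        Exy = 0.5 * (uy + vx + ux * uy + vx * vy)
        np.testing.assert_allclose(st.Exx[st.valid_mask], Exx, atol=5e-3)
        np.testing.assert_allclose(st.Eyy[st.valid_mask], Eyy, atol=5e-3)
        np.testing.assert_allclose(st.Exy[st.valid_mask], Exy, atol=5e-3)
        # plane fits of an affine field are in fact exact
        np.testing.assert_allclose(st.Exx[st.valid_mask], Exx, atol=1e-12)

    def test_too_few_valid_points_rejected(self):
        fld = field_from_function(lambda X, Y: (0 * X, 0 * Y), nx=3, ny=3)
        fld.valid_mask[:] = False
        fld.valid_mask[0, 0] = True
        with pytest.raises(ValueError):
            compute_strain(fld, DICConfig())


class TestSequenceTracking:
    def test_cumulative_shift_sequence(self, speckle_ref):
        sched = gm.translation_schedule([(0, 0), (2, 0), (4, 0)])
        stack, truth = gm.warp_sequence(speckle_ref, sched)
        out = gm.track_sequence(stack, DICConfig(search_radius=6))
        for i, (fld, _) in enumerate(out):
            m = fld.valid_mask & matchable_mask(truth, i, fld.grid_x, fld.grid_y,
                                                speckle_ref.shape, 10)
            assert np.all(fld.u[m] == 2.0 * i)
            assert np.all(fld.v[m] == 0.0)

    def test_single_frame_rejected(self, speckle_ref):
        with pytest.raises(ValueError):
            gm.track_sequence([speckle_ref], DICConfig())

    def test_frame_shape_mismatch_rejected(self, speckle_ref):
        with pytest.raises(ValueError):
            gm.track_sequence([speckle_ref, speckle_ref[:64, :64]], DICConfig())
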