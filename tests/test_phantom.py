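import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.spatial.transform import Rotation

import folliculometry as fol
from folliculometry.phantom import (
    DEFAULT_INTENSITIES,
    ImagingModel,
    apply_lightsheet_psf,
    apply_noise,
    build_phantom,
    voxelize_ellipsoid,
)
from folliculometry.stack import ImageStack

SPACING = (16.0, 4.0, 4.0)


class TestVoxelize:
    def test_sphere_volume_analytic(self):
        m = voxelize_ellipsoid((200, 200, 200), (100, 100, 100), None, SPACING, (26, 100, 100))
        vol = m.sum() * np.prod(SPACING) * 1e-9
        assert vol == pytest.approx(4 / 3 * np.pi * 0.1**3, rel=0.03)

    def test_identity_orientation_major_axis_in_plane(self):
        m = voxelize_ellipsoid((208, 200, 200), (100, 50, 50), None, SPACING, (26, 100, 100))
        plane = m[13]
        idx = np.argwhere(plane)
        x_extent = (idx[:, 1].max() - idx[:, 1].min() + 1) * SPACING[2]
        y_extent = (idx[:, 0].max() - idx[:, 0].min() + 1) * SPACING[1]
        assert x_extent / y_extent == pytest.approx(2.0, rel=0.05)

    def test_refinement_converges_to_analytic_volume(self):
        # same rotated ellipsoid voxelized at successively halved spacing
        axes = (90.0, 70.0, 50.0)
        R = Rotation.from_euler("zyx", (25, 40, 10), degrees=True).as_matrix()
        true = 4 / 3 * np.pi * np.prod(axes)
        errs = []
        for f in (1.0, 0.5, 0.25):
            sp = (16 * f, 8 * f, 8 * f)
            shape = tuple(int(220 / s) for s in sp)
            c = tuple(110.0 for _ in range(3))
            m = voxelize_ellipsoid(c, axes, R, sp, shape)
            errs.append(abs(m.sum() * np.prod(sp) - true) / true)
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01

    def test_outside_volume_and_bad_axes_error(self):
        with pytest.raises(ValueError):
            voxelize_ellipsoid((-5000, 0, 0), (50, 50, 50), None, SPACING, (10, 10, 10))
        with pytest.raises(ValueError):
            voxelize_ellipsoid((50, 50, 50), (50, 0, 50), None, SPACING, (10, 10, 10))


class TestFolliclePhantom:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            fol.FolliclePhantom(center=(0, 0, 0), semi_axes=(50, 60, 40))
        with pytest.raises(ValueError):
            fol.FolliclePhantom(
                center=(0, 0, 0), semi_axes=(100, 90, 80), theca_thickness_base=30,
                gap_width=10, granulosa_width=10, coc_diameter=40,
            )

    def test_constant_wall_truth_samples(self):
        f = fol.FolliclePhantom(
            center=(0, 0, 0), semi_axes=(500, 500, 500),
            theca_thickness_base=100, theca_thickness_modulation=0.0,
        )
        samples = f.truth_thickness_samples()
        assert np.allclose(samples, 100.0, atol=1e-6)

    def test_modulated_wall_stays_in_band_and_is_nondegenerate(self):
        f = fol.FolliclePhantom(
            center=(0, 0, 0), semi_axes=(400, 380, 360),
            theca_thickness_base=80, theca_thickness_modulation=0.2,
            modulation_phase_deg=30,
        )
        s = f.truth_thickness_samples()
        assert s.std() > 1.0
        assert s.min() >= 80 * 0.8 - 1 and s.max() <= 80 * 1.2 + 1

    def test_equatorial_ratio_analytic(self):
        f = fol.FolliclePhantom(
            center=(0, 0, 0), semi_axes=(200, 100, 100),
            orientation=fol.inplane_rotation(35), theca_thickness_base=30,
        )
        assert f.equatorial_axis_ratio() == pytest.approx(2.0, rel=1e-9)


class TestBuildPhantom:
    def test_empty_scene_is_uniform_background(self):
        spec = fol.PhantomSpec(volume_shape=(16, 32, 32), background_level=40.0, seed=1)
        stack, truth = build_phantom(spec)
        assert stack.voxels.mean() == pytest.approx(40.0, rel=0.05)
        assert truth.structures == []

    def test_seed_determinism_bit_identical(self):
        spec = fol.PhantomSpec(
            volume_shape=(24, 64, 64),
            follicles=[
                fol.FolliclePhantom(center=(192, 128, 128), semi_axes=(80, 75, 70),
                                    theca_thickness_base=30, gap_width=8, granulosa_width=10)
            ],
            seed=42,
        )
        s1, t1 = build_phantom(spec)
        s2, t2 = build_phantom(spec)
        assert np.array_equal(s1.voxels, s2.voxels)
        assert np.array_equal(t1.labels, t2.labels)

    def test_truth_volume_matches_voxelized_mask_and_constant_wall(self):
        spec = fol.PhantomSpec(
            volume_shape=(76, 300, 300),
            follicles=[
                fol.FolliclePhantom(center=(608, 600, 600), semi_axes=(500, 500, 500),
                                    theca_thickness_base=100, gap_width=12, granulosa_width=20)
            ],
            blur=False, noise=False, seed=0,
        )
        stack, truth = build_phantom(spec)
        rec = truth.follicles()[0]
        vox_vol = (truth.labels == rec.id).sum() * np.prod(SPACING) * 1e-9
        assert rec.true_volume_mm3 == pytest.approx(vox_vol, rel=0.03)
        assert np.allclose(rec.true_thickness_samples_um, 100.0, atol=1e-6)

    def test_truth_consistency_across_size_range(self):
        # manifest volume vs voxel integral within 3% down to 70 um
        follicles = [
            fol.FolliclePhantom(center=c, semi_axes=a, theca_thickness_base=t)
            for c, a, t in [
                ((200, 150, 150), (35, 35, 35), 40),
                ((200, 480, 160), (60, 55, 50), 25),
                ((560, 300, 560), (150, 140, 130), 45),
            ]
        ]
        spec = fol.PhantomSpec(volume_shape=(60, 200, 200), follicles=follicles,
                               blur=False, noise=False, seed=0)
        _, truth = build_phantom(spec)
        for rec in truth.follicles():
            vox = (truth.labels == rec.id).sum() * np.prod(SPACING) * 1e-9
            assert rec.true_volume_mm3 == pytest.approx(vox, rel=0.03)

    def test_overlapping_follicles_rejected(self):
        spec = fol.PhantomSpec(
            volume_shape=(32, 96, 96),
            follicles=[
                fol.FolliclePhantom(center=(256, 192, 192), semi_axes=(80, 75, 70),
                                    theca_thickness_base=20),
                fol.FolliclePhantom(center=(256, 232, 192), semi_axes=(80, 75, 70),
                                    theca_thickness_base=20),
            ],
            seed=0,
        )
        with pytest.raises(ValueError, match="overlap"):
            build_phantom(spec)

    def test_intensity_ordering_pre_noise(self, noiseless_scene):
        _, stack, truth = noiseless_scene
        v = stack.voxels
        lab = truth.labels
        big = truth.follicles()[0].id
        inside = v[lab == big]
        ints = DEFAULT_INTENSITIES
        assert inside.max() == pytest.approx(ints["coc"], abs=1)
        # theca brighter than granulosa brighter than background > gap/lumen
        assert ints["theca"] > ints["granulosa"] > 40 > ints["gap"] >= ints["lumen"]
        assert np.isin(np.unique(inside), [ints["lumen"], ints["gap"], ints["granulosa"],
                                           ints["theca"], ints["coc"]]).all()

    def test_egg_nest_members_counted_and_disjoint(self):
        spec = fol.PhantomSpec(
            volume_shape=(48, 160, 160),
            egg_nests=[fol.EggNestPhantom(center=(384, 320, 320), count=5, member_diameter=80)],
            blur=False, noise=False, seed=4,
        )
        _, truth = build_phantom(spec)
        members = [s for s in truth.structures if s.klass == "egg_nest"]
        assert len(members) == 5
        assert all(s.true_stage == "primordial" for s in members)
        ids, counts = np.unique(truth.labels[truth.labels > 0], return_counts=True)
        assert len(ids) == 5 and (counts > 0).all()


def _fit_axial_fwhm(stack, col, y=4):
    prof = stack.voxels[:, y, col]
    z = np.arange(prof.size) * 16.0

    def g(z, a, mu, s):
        return a * np.exp(-((z - mu) ** 2) / (2 * s**2))

    p, _ = curve_fit(g, z, prof, p0=(prof.max(), z[np.argmax(prof)], 10))
    return 2.3548 * abs(p[2])


class TestLightsheetPSF:
    def test_uniform_thickness_equals_separable_convolution(self):
        from scipy import ndimage as ndi

        im = ImagingModel(sheet_waist_thickness=30, sheet_edge_thickness=30)
        rng = np.random.default_rng(0)
        a = rng.random((40, 32, 32)).astype(np.float32) * 100
        ours = apply_lightsheet_psf(ImageStack(a, im.voxel_spacing), im)
        sig = [30 / 2.3548 / 16, 6 / 2.3548 / 4, 6 / 2.3548 / 4]
        ref = ndi.gaussian_filter(a, sigma=sig, mode="nearest")
        assert np.allclose(ours.voxels, ref, atol=1e-2)

    def test_spot_width_ratio_waist_vs_edge(self):
        im = ImagingModel()
        nz, nx = 96, 1537
        v = np.zeros((nz, 9, nx), np.float32)
        xc = (nx - 1) // 2
        v[48, 4, xc] = 1000.0
        v[48, 4, xc + 750] = 1000.0  # 3 mm lateral offset
        blurred = apply_lightsheet_psf(ImageStack(v, im.voxel_spacing), im)
        w_waist = _fit_axial_fwhm(blurred, xc)
        w_edge = _fit_axial_fwhm(blurred, xc + 750)
        assert w_edge / w_waist == pytest.approx(
            im.sheet_edge_thickness / im.sheet_waist_thickness, rel=0.25
        )

    def test_monotone_width_with_lateral_distance(self):
        im = ImagingModel()
        nz, nx = 96, 1025
        offsets = [0, 150, 300, 450]
        v = np.zeros((nz, 9, nx), np.float32)
        xc = (nx - 1) // 2
        for o in offsets:
            v[48, 4, xc + o] = 1000.0
        blurred = apply_lightsheet_psf(ImageStack(v, im.voxel_spacing), im)
        widths = [_fit_axial_fwhm(blurred, xc + o) for o in offsets]
        assert all(b >= a - 0.2 for a, b in zip(widths, widths[1:]))

    def test_constant_volume_stays_constant_and_conserves(self):
        im = ImagingModel()
        a = np.full((64, 16, 64), 70.0, np.float32)
        out = apply_lightsheet_psf(ImageStack(a, im.voxel_spacing), im)
        assert np.allclose(out.voxels, 70.0, atol=1e-3)

    def test_kernel_wider_than_stack_errors(self):
        im = ImagingModel()
        with pytest.raises(ValueError, match="wider"):
            apply_lightsheet_psf(ImageStack(np.zeros((4, 8, 8), np.float32), SPACING), im)


class TestNoise:
    def test_variance_matches_shot_plus_read_model(self):
        L = 50.0
        im = ImagingModel(photon_scale=2.0, read_noise_sd=1.0)
        const = ImageStack(np.full((64, 64, 64), L, np.float32), SPACING)
        noisy = apply_noise(const, im, seed=5)
        assert noisy.voxels.var() == pytest.approx(L / 2.0 + 1.0, rel=0.05)

    def test_noiseless_limit(self):
        im = ImagingModel(photon_scale=1e6, read_noise_sd=0.0)
        const = ImageStack(np.full((16, 16, 16), 80.0, np.float32), SPACING)
        noisy = apply_noise(const, im, seed=0)
        assert np.allclose(noisy.voxels, 80.0, atol=0.5)

    def test_seeded_determinism(self):
        im = ImagingModel()
        const = ImageStack(np.full((8, 8, 8), 30.0, np.float32), SPACING)
        a = apply_noise(const, im, seed=9)
        b = apply_noise(const, im, seed=9)
        assert np.array_equal(a.voxels, b.voxels)

    def test_negative_input_rejected(self):
        im = ImagingModel()
        stack = ImageStack(np.zeros((4, 4, 4), np.float32), SPACING)
        stack.voxels = stack.voxels - 1.0  # bypass constructor check deliberately
        with pytest.raises(ValueError):
            apply_noise(stack, im, seed=0)


class TestSpecYaml:
    def test_roundtrip(self, tmp_path):
        spec = fol.example_cohort_spec(seed=5)
        p = tmp_path / "spec.yaml"
        fol.save_phantom_spec(spec, p)
        back = fol.load_phantom_spec(p)
        assert back.volume_shape == spec.volume_shape
        assert back.seed == 5
        assert len(back.follicles) == len(spec.follicles)
        f0, b0 = spec.follicles[0], back.follicles[0]
        assert b0.semi_axes == f0.semi_axes
        assert b0.coc_diameter == f0.coc_diameter
        assert np.allclose(b0.orientation, f0.orientation, atol=1e-8)
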