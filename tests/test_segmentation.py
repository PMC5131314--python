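import numpy as np
import pytest
import tifffile

import folliculometry as fol
from folliculometry.segmentation import (
    SegmentationParams,
    detect_cocs,
    discriminate_vessels,
    extract_shell_masks,
    ingest_manual_masks,
    segment_follicles,
    shell_mask_set_from_masks,
)
from folliculometry.stack import ImageStack

SPACING = (16.0, 4.0, 4.0)


def _dice(a, b):
    return 2 * (a & b).sum() / max(a.sum() + b.sum(), 1)


def _match_truth(labels, truth, stack):
    """Map measured follicle labels to truth records by centroid."""
    pairs = {}
    for fid in labels.follicle_ids():
        idx = np.argwhere(labels.labels == fid)
        c = idx.mean(axis=0) * np.asarray(stack.spacing)
        rec = min(truth.follicles(), key=lambda t: np.linalg.norm(np.asarray(t.center_um) - c))
        pairs[fid] = rec
    return pairs


class TestSegmentFollicles:
    def test_noiseless_three_follicles_high_dice(self, noiseless_scene):
        _, stack, truth = noiseless_scene
        labels = segment_follicles(stack)
        assert len(labels.follicle_ids()) == 3
        for fid, rec in _match_truth(labels, truth, stack).items():
            assert _dice(labels.labels == fid, truth.labels == rec.id) >= 0.95

    def test_noisy_scene_dice_above_point_nine(self, small_scene):
        _, stack, truth = small_scene
        labels = segment_follicles(stack)
        for fid, rec in _match_truth(labels, truth, stack).items():
            d = (6 * rec.true_volume_mm3 / np.pi) ** (1 / 3) * 1000
            if d >= 100:
                assert _dice(labels.labels == fid, truth.labels == rec.id) >= 0.9

    def test_uniform_stack_yields_no_labels(self):
        stack = ImageStack(np.full((16, 32, 32), 40.0, np.float32), SPACING)
        labels = segment_follicles(stack)
        assert labels.ids() == []

    def test_deterministic_for_fixed_input(self, small_scene):
        _, stack, _ = small_scene
        a = segment_follicles(stack)
        b = segment_follicles(stack)
        assert np.array_equal(a.labels, b.labels)
        assert a.class_map == b.class_map

    def test_touching_follicles_split_by_lumen_seeded_watershed(self):
        # two shelled follicles whose shells almost touch: closing bridges
        # them, the two lumens must pull them apart again
        follicles = [
            fol.FolliclePhantom(center=(400, 300, 260), semi_axes=(120, 115, 110),
                                theca_thickness_base=30, gap_width=10, granulosa_width=12),
            fol.FolliclePhantom(center=(400, 300, 510), semi_axes=(120, 115, 110),
                                theca_thickness_base=30, gap_width=10, granulosa_width=12),
        ]
        spec = fol.PhantomSpec(volume_shape=(50, 152, 200), follicles=follicles,
                               blur=False, noise=False, seed=0)
        stack, truth = fol.build_phantom(spec)
        params = SegmentationParams(closing_radius_um=16.0)
        labels = segment_follicles(stack, params)
        assert len(labels.follicle_ids()) == 2

    def test_small_blob_pass_counts_primordial_candidates(self):
        spec = fol.PhantomSpec(
            volume_shape=(48, 160, 160),
            egg_nests=[fol.EggNestPhantom(center=(384, 320, 320), count=5, member_diameter=80)],
            seed=4,
        )
        stack, truth = fol.build_phantom(spec)
        labels = segment_follicles(stack, SegmentationParams(min_diameter_um=120.0))
        candidates = [l for l, k in labels.class_map.items() if k == "primordial_candidate"]
        assert len(candidates) == 5


class TestVesselDiscrimination:
    def test_straight_tube_is_vessel_and_sphere_is_follicle(self):
        labels = np.zeros((40, 50, 50), np.int32)
        labels[:, 25, 25] = 1  # tube through the whole stack, r=1 voxel
        sph = fol.voxelize_ellipsoid((320, 100, 100), (60, 60, 60), None, SPACING, labels.shape)
        labels[sph] = 2
        lv = fol.LabelVolume(labels, {1: "follicle", 2: "follicle"})
        out = discriminate_vessels(lv, SPACING)
        assert out.class_map[1] == "vessel"
        assert out.class_map[2] == "follicle"

    def test_single_voxel_component_defaults_to_follicle(self):
        labels = np.zeros((8, 8, 8), np.int32)
        labels[4, 4, 4] = 1
        out = discriminate_vessels(fol.LabelVolume(labels, {}), SPACING)
        assert out.class_map[1] == "follicle"

    def test_phantom_follicles_and_curved_vessels_all_correct(self, small_scene):
        _, stack, truth = small_scene
        labels = segment_follicles(stack)
        by_class = {"vessel": 0, "follicle": 0}
        for fid in labels.ids():
            k = labels.class_map[fid]
            if k in by_class:
                by_class[k] += 1
        assert by_class["vessel"] == 1
        assert by_class["follicle"] == 3


class TestShellMasks:
    def test_concentric_shell_boundary_radii(self):
        whole = fol.voxelize_ellipsoid((608, 600, 600), (500, 500, 500), None, SPACING,
                                       (76, 300, 300))
        inner = fol.voxelize_ellipsoid((608, 600, 600), (400, 400, 400), None, SPACING,
                                       (76, 300, 300))
        ms = shell_mask_set_from_masks(1, whole, whole & ~inner)
        plane = 38
        c = np.array([600.0, 600.0])
        for bound, r_true in ((ms.outer_boundary, 500.0), (ms.inner_boundary, 400.0)):
            pts = np.argwhere(bound[plane]) * np.asarray(SPACING[1:])
            radii = np.linalg.norm(pts - c, axis=1)
            assert abs(np.median(radii) - r_true) <= 4.0  # one in-plane voxel

    def test_invariants_on_phantom_follicles(self, noiseless_scene):
        _, stack, _ = noiseless_scene
        labels = segment_follicles(stack)
        for fid in labels.follicle_ids():
            ms = extract_shell_masks(stack, labels, fid)
            ms.validate()
            if ms.has_shell:
                # every inner-boundary voxel touches the interior; every
                # outer-boundary voxel touches the outside of the shell hull
                from scipy import ndimage as ndi

                interior = ms.gap | ms.lumen
                s6 = ndi.generate_binary_structure(3, 1)
                assert (ms.inner_boundary & ndi.binary_dilation(interior, s6)).sum() == \
                    ms.inner_boundary.sum()
                hull = ms.theca | interior
                assert (ms.outer_boundary & ndi.binary_dilation(~hull, s6)).sum() == \
                    ms.outer_boundary.sum()

    def test_partition_contract_on_truth_masks(self):
        whole = fol.voxelize_ellipsoid((400, 400, 400), (300, 300, 300), None, SPACING,
                                       (51, 200, 200))
        inner = fol.voxelize_ellipsoid((400, 400, 400), (220, 220, 220), None, SPACING,
                                       (51, 200, 200))
        gap = inner & ~fol.voxelize_ellipsoid((400, 400, 400), (200, 200, 200), None,
                                              SPACING, (51, 200, 200))
        ms = shell_mask_set_from_masks(1, whole, whole & ~inner, gap=gap)
        union = ms.theca | ms.gap | ms.lumen
        assert np.array_equal(union, ms.whole)
        assert not (ms.theca & ms.gap).any()
        assert not (ms.theca & ms.lumen).any()
        assert not (ms.gap & ms.lumen).any()

    def test_noiseless_boundaries_within_one_voxel_of_analytic_surface(self, noiseless_scene):
        _, stack, truth = noiseless_scene
        labels = segment_follicles(stack)
        pairs = _match_truth(labels, truth, stack)
        checked = 0
        for fid, rec in pairs.items():
            ms = extract_shell_masks(stack, labels, fid)
            if not ms.has_shell:
                continue
            plane = np.argmax(ms.whole.sum(axis=(1, 2)))
            pts = np.argwhere(ms.outer_boundary[plane]) * np.asarray(SPACING[1:])
            c = np.asarray(rec.center_um[1:])
            radii = np.linalg.norm(pts - c, axis=1)
            # spherical-ish phantoms: outer boundary near the analytic surface
            r_true = (6 * rec.true_volume_mm3 / np.pi) ** (1 / 3) * 500
            assert np.median(np.abs(radii - r_true)) <= 8.0  # 2 in-plane voxels
            checked += 1
        assert checked >= 1

    def test_unclosed_shell_raises_with_follicle_named(self):
        # exact manual labels: a spherical shell with a knocked-out patch
        shape = (51, 200, 200)
        whole = fol.voxelize_ellipsoid((400, 400, 400), (240, 240, 240), None, SPACING, shape)
        inner = fol.voxelize_ellipsoid((400, 400, 400), (170, 170, 170), None, SPACING, shape)
        v = np.full(shape, 40.0, np.float32)
        v[whole] = 200.0
        v[inner] = 10.0
        # narrow crack channel through the full radial extent of the wall
        v[24:26, 97:101, 138:168] = 10.0
        stack = ImageStack(v, SPACING)
        labels = fol.LabelVolume(whole.astype(np.int32) * 7, {7: "follicle"})
        with pytest.raises(fol.ShellNotClosedError, match="7"):
            extract_shell_masks(stack, labels, 7)


class TestDetectCOCs:
    def test_phantom_coc_recovered_near_truth_centroid(self, noiseless_scene):
        _, stack, truth = noiseless_scene
        labels = segment_follicles(stack)
        rec = next(t for t in truth.follicles() if t.true_coc_diameter_um)
        fid = min(
            labels.follicle_ids(),
            key=lambda f: np.linalg.norm(
                np.argwhere(labels.labels == f).mean(axis=0) * np.asarray(SPACING)
                - np.asarray(rec.center_um)
            ),
        )
        ms = extract_shell_masks(stack, labels, fid)
        det = detect_cocs(stack, ms)
        assert det.accepted is not None
        centroid = np.argwhere(det.accepted).mean(axis=0) * np.asarray(SPACING)
        assert np.linalg.norm(centroid - np.asarray(rec.true_coc_center_um)) <= 16.0

    def test_follicle_without_coc_yields_empty(self, noiseless_scene):
        _, stack, truth = noiseless_scene
        labels = segment_follicles(stack)
        rec = next(
            t for t in truth.follicles()
            if t.true_coc_diameter_um is None and t.true_stage == "antral"
        )
        fid = min(
            labels.follicle_ids(),
            key=lambda f: np.linalg.norm(
                np.argwhere(labels.labels == f).mean(axis=0) * np.asarray(SPACING)
                - np.asarray(rec.center_um)
            ),
        )
        det = detect_cocs(stack, extract_shell_masks(stack, labels, fid))
        assert det.accepted is None

    def test_detached_blob_is_candidate_not_accepted(self):
        # a big hollow follicle with a bright blob floating mid-lumen
        shape = (64, 256, 256)
        whole = fol.voxelize_ellipsoid((512, 512, 512), (350, 350, 350), None, SPACING, shape)
        inner = fol.voxelize_ellipsoid((512, 512, 512), (280, 280, 280), None, SPACING, shape)
        gran = inner & ~fol.voxelize_ellipsoid((512, 512, 512), (255, 255, 255), None,
                                               SPACING, shape)
        blob = fol.voxelize_ellipsoid((512, 512, 512), (40, 40, 40), None, SPACING, shape)
        v = np.full(shape, 40.0, np.float32)
        v[whole] = 200.0
        v[inner] = 10.0
        v[gran] = 120.0
        v[blob] = 240.0
        stack = ImageStack(v, SPACING)
        ms = shell_mask_set_from_masks(1, whole, whole & ~inner)
        det = detect_cocs(stack, ms)
        assert det.accepted is None
        assert len(det.candidates) >= 1


class TestManualIngestion:
    def test_truth_labels_roundtrip_and_bypass_equivalence(self, tmp_path, noiseless_scene):
        _, stack, truth = noiseless_scene
        p = tmp_path / "labels.tiff"
        tifffile.imwrite(p, truth.labels.astype(np.int32))
        lv = ingest_manual_masks(p, stack)
        assert np.array_equal(lv.labels, truth.labels)
        # measurements from ingested masks equal measurements from in-memory masks
        _, m1 = fol.measure_stack(stack, labels=lv)
        _, m2 = fol.measure_stack(stack, labels=fol.LabelVolume(truth.labels, lv.class_map))
        f1 = fol.measurements_to_frame(m1)
        f2 = fol.measurements_to_frame(m2)
        assert f1.equals(f2)

    def test_shape_mismatch_errors(self, tmp_path, noiseless_scene):
        _, stack, _ = noiseless_scene
        p = tmp_path / "bad.tiff"
        tifffile.imwrite(p, np.zeros((4, 5, 6), np.int32), photometric="minisblack")
        with pytest.raises(ValueError, match="shape"):
            ingest_manual_masks(p, stack)
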