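"""Illuminant generation, renderer identities and dataset plumbing."""

import numpy as np
import pandas as pd
import pytest

from chromacc import scenes as sc
from chromacc.colorimetry import project


class TestTestIlluminants:
    def test_all_four_at_requested_distance(self, test_illums):
        for iid in sc.TEST_IDS:
            d = np.hypot(*test_illums.chroma_ab(iid))
            assert d == pytest.approx(10.0, abs=0.05)

    def test_locus_and_orthogonal_directions(self, test_illums):
        yb = test_illums.chroma_ab("Y") - test_illums.chroma_ab("B")
        gr = test_illums.chroma_ab("G") - test_illums.chroma_ab("R")
        cosang = abs(yb @ gr) / (np.linalg.norm(yb) * np.linalg.norm(gr))
        assert cosang < 0.02

    def test_equal_areas(self, test_illums):
        areas = [test_illums.get(i).integral() for i in sc.TEST_IDS]
        np.testing.assert_allclose(areas, areas[0], rtol=1e-6)

    def test_y_is_yellow_b_is_blue(self, test_illums):
        assert test_illums.chroma_ab("Y")[1] > 0 > test_illums.chroma_ab("B")[1]
        assert test_illums.chroma_ab("R")[0] > 0 > test_illums.chroma_ab("G")[0]

    def test_bad_distance_rejected(self, ctx):
        with pytest.raises(ValueError):
            sc.make_test_illuminants(-1.0, ctx)


class TestTrainingIlluminants:
    def test_default_full_scale_counts(self, ctx):
        s = sc.make_training_illuminants(43, 236, 8.55, seed=0, ctx=ctx)
        assert len(s) == 279

    def test_chromatic_spread_calibrated(self, train_illums):
        assert train_illums.chromatic_sd() == pytest.approx(8.55, abs=0.25)

    def test_peak_normalization(self, train_illums):
        for iid in train_illums.ids:
            assert np.max(train_illums.get(iid).power) == pytest.approx(100.0)

    def test_pure_dseries_lies_on_daylight_locus(self, ctx):
        """With no jitter, every chromaticity sits on the locus curve."""
        from chromacc.colorimetry import (
            daylight_chromaticity_xy,
            daylight_spectrum_from_weights,
            daylight_weights_for_xy,
        )

        s = sc.make_training_illuminants(7, 0, 8.55, seed=0, ctx=ctx)
        # locus oracle: chromaticities of a dense CCT sweep
        locus = []
        for t in np.linspace(4000, 12000, 200):
            m = daylight_weights_for_xy(*daylight_chromaticity_xy(t))
            locus.append(
                ctx.illuminant_chromaticity(
                    daylight_spectrum_from_weights(*m, ctx.grid)
                ).values[1:]
            )
        locus = np.array(locus)
        for iid in s.ids:
            ab = s.chroma_ab(iid)
            assert np.min(np.linalg.norm(locus - ab, axis=1)) < 0.5

    def test_unreachable_spread_raises(self, ctx):
        with pytest.raises(ValueError, match="unreachable"):
            sc.make_training_illuminants(20, 5, 2.0, seed=0, ctx=ctx)

    def test_chromaticity_recomputable_from_spectrum(self, train_illums, ctx):
        for iid in train_illums.ids[::13]:
            again = ctx.illuminant_chromaticity(train_illums.get(iid))
            np.testing.assert_allclose(
                again.values, train_illums.chromaticity[iid].values, atol=1e-9
            )


class TestRenderer:
    def test_object_pixel_is_projected_product(self, catalog, test_illums, scene_cfg):
        """With the shading factor divided out, an object pixel equals
        project(E * R) exactly."""
        spec = sc.SceneSpec("Y", catalog.class_ids[10], 5, (0.75, 0.5))
        img = sc.render_scene(spec, catalog, test_illums, scene_cfg)
        _, shade = sc.object_blob(5, (0.75, 0.5), scene_cfg.image_size,
                                  scene_cfg.object_radius_frac)
        expected = project(
            test_illums.get("Y") * catalog.reflectance(catalog.class_ids[10]),
            catalog.ctx.lms_sensors,
        ).values
        ij = tuple(np.argwhere(img.object_mask)[0])
        np.testing.assert_allclose(
            img.pixels[ij] / shade[ij], expected, rtol=1e-5
        )

    def test_wrong_background_composition(self, catalog, test_illums, scene_cfg):
        """wrong_background == D65 render outside the mask, test-illuminant
        render inside it, pixelwise."""
        spec = sc.SceneSpec("R", catalog.class_ids[3], 11, (0.7, 0.45),
                            "wrong_background")
        wb = sc.render_scene(spec, catalog, test_illums, scene_cfg)
        normal = sc.render_scene(
            sc.SceneSpec("R", catalog.class_ids[3], 11, (0.7, 0.45)),
            catalog, test_illums, scene_cfg,
        )
        d65 = sc.render_scene(
            sc.SceneSpec("D65", catalog.class_ids[3], 11, (0.7, 0.45)),
            catalog, test_illums, scene_cfg,
        )
        m = wb.object_mask
        np.testing.assert_array_equal(wb.pixels[m], normal.pixels[m])
        np.testing.assert_array_equal(wb.pixels[~m], d65.pixels[~m])

    def test_no_patch_strip_matches_wall(self, catalog, test_illums, scene_cfg):
        spec = sc.SceneSpec("B", catalog.class_ids[0], 2, (0.75, 0.5), "no_patch")
        img = sc.render_scene(spec, catalog, test_illums, scene_cfg)
        geom = sc.get_geometry(scene_cfg.image_size)
        box = geom.patch_boxes[0]
        r = box[0]
        inside = img.pixels[r, box[2]]
        wall_col = box[2] - 1
        wall = img.pixels[r, wall_col]
        np.testing.assert_allclose(inside, wall, rtol=1e-6)

    def test_object_never_occludes_patches_or_border(self, catalog, test_illums,
                                                     scene_cfg, rng):
        geom = sc.get_geometry(scene_cfg.image_size)
        man = sc.build_dataset_manifest(
            catalog, test_illums, 1, "normal", seed=3,
            class_ids=catalog.class_ids[:8],
        )
        X, masks = sc.render_manifest(man, catalog, test_illums, scene_cfg)
        for m in masks:
            assert m.any()
            assert not m[: geom.patch_bottom, :].any()
            assert not m[0].any() and not m[-1].any()
            assert not m[:, 0].any() and not m[:, -1].any()

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            sc.SceneSpec("Y", 0, 1, (0.7, 0.5), "sideways")

    def test_background_identifies_illuminant(self, catalog, ctx, scene_cfg):
        """Premise of the cue manipulations: a nearest-neighbor decoder on
        mean background chromaticity identifies the scene illuminant among
        well-separated illuminants (D-series members plus D65/Y/B/G/R)."""
        from chromacc.scenes import IlluminantSet

        dser = sc.make_training_illuminants(6, 0, 8.55, seed=0, ctx=ctx)
        test = sc.make_test_illuminants(10.0, ctx)
        ids = dser.ids + list(test.ids) + ["D65"]
        illums = IlluminantSet(
            ids,
            {**dser.spectra, **test.spectra},
            {**dser.chromaticity, **test.chromaticity},
            {**dser.provenance, **test.provenance},
            ctx,
        )
        man = sc.build_dataset_manifest(
            catalog, illums, 3, "normal", seed=4,
            class_ids=catalog.class_ids[:8],
        )
        X, masks = sc.render_manifest(man, catalog, illums, scene_cfg)
        means = np.array([x[~m].mean(axis=0) for x, m in zip(X, masks)])
        feats = means / means.sum(axis=1, keepdims=True)  # chromaticity
        labels = man["illum_id"].to_numpy()
        cent = np.array([feats[labels == i].mean(axis=0) for i in ids])
        pred = [ids[np.argmin(((cent - f) ** 2).sum(1))] for f in feats]
        acc = np.mean(np.array(pred) == labels)
        assert acc > 0.95

    def test_object_shift_exceeds_class_spacing(self, catalog, test_illums,
                                                scene_cfg):
        """At 10 dE illuminant distance, the object's Lab shift between D65
        and a test illuminant exceeds the median class spacing."""
        from chromacc.catalog import median_adjacent_delta_e
        from chromacc.colorimetry import delta_e

        med = median_adjacent_delta_e(catalog)
        ctx = catalog.ctx
        shifts = []
        for iid in sc.TEST_IDS:
            per_class = []
            for cid in catalog.eval_subset[::5]:
                spec = sc.SceneSpec(iid, cid, 9, (0.72, 0.5))
                img = sc.render_scene(spec, catalog, test_illums, scene_cfg)
                ref = sc.render_scene(
                    sc.SceneSpec("D65", cid, 9, (0.72, 0.5)),
                    catalog, test_illums, scene_cfg,
                )
                a = ctx.lab_of_lms(img.pixels[img.object_mask].mean(axis=0))
                b = ctx.lab_of_lms(ref.pixels[ref.object_mask].mean(axis=0))
                per_class.append(delta_e(a, b))
            shifts.append(np.mean(per_class))
        assert min(shifts) > med


class TestManifests:
    def test_full_scale_cardinalities(self, catalog, ctx):
        """Spec-scale counts: 1600 x 279 and 330 x 4 x 10 trials."""
        from chromacc.scenes import IlluminantSet

        fake_classes = list(range(1600))
        illums = IlluminantSet(
            [f"I{i}" for i in range(279)], {}, {}, {}, ctx
        )
        man = sc.build_dataset_manifest(
            catalog, illums, 1, "normal", seed=0, class_ids=fake_classes
        )
        assert len(man) == 446400
        test4 = IlluminantSet(list(sc.TEST_IDS), {}, {}, {}, ctx)
        man2 = sc.build_dataset_manifest(
            catalog, test4, 10, "normal", seed=0, class_ids=list(range(330))
        )
        assert len(man2) == 13200

    def test_same_seed_identical(self, catalog, test_illums):
        a = sc.build_dataset_manifest(catalog, test_illums, 2, "normal", seed=5)
        b = sc.build_dataset_manifest(catalog, test_illums, 2, "normal", seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_dataset_round_trip(self, catalog, test_illums, scene_cfg, tmp_path):
        man = sc.build_dataset_manifest(
            catalog, test_illums, 1, "normal", seed=6,
            class_ids=catalog.class_ids[:3],
        )
        X, masks = sc.render_manifest(man, catalog, test_illums, scene_cfg)
        path = sc.write_dataset(tmp_path / "d.h5", X, masks, man, {"k": 1})
        X2, m2, man2 = sc.read_dataset(path)
        np.testing.assert_array_equal(X, X2)
        np.testing.assert_array_equal(masks, m2)
        assert len(man2) == len(man)

    def test_corrupt_container_raises(self, tmp_path):
        p = tmp_path / "bad.h5"
        p.write_bytes(b"not an hdf5 file")
        (tmp_path / "bad.manifest.csv").write_text("illum_id\n")
        with pytest.raises(OSError, match="cannot read"):
            sc.read_dataset(p)
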