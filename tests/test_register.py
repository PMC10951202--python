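import numpy as np
import pandas as pd
import pytest

from syntopo.detect import CellTable
from syntopo.register import (
    RegistrationError,
    SectionRegistration,
    apply_affine,
    downsample_image,
    fit_affine_from_landmarks,
    map_cells_to_atlas,
    refine_with_anchors,
    rescale_affine,
)
from syntopo.synth import make_transform


class TestDownsample:
    def test_factor_one_is_identity(self):
        img = np.random.default_rng(0).uniform(size=(7, 9))
        np.testing.assert_array_equal(downsample_image(img, 1), img)

    def test_factor_twelve_shape(self):
        img = np.zeros((1200, 1200))
        assert downsample_image(img, 12).shape == (100, 100)

    def test_partial_blocks_average_available_pixels(self):
        img = np.full((10, 10), 3.5)
        out = downsample_image(img, 3)
        assert out.shape == (4, 4)
        np.testing.assert_allclose(out, 3.5)

    def test_block_means_are_exact(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        out = downsample_image(img, 2)
        np.testing.assert_allclose(out, [[2.5, 4.5], [10.5, 12.5]])

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample_image(np.zeros((4, 4)), 0)


class TestFitAffine:
    def test_identity_pairs_recover_identity(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        M = fit_affine_from_landmarks(pts, pts)
        np.testing.assert_allclose(M, [[1, 0, 0], [0, 1, 0]], atol=1e-12)

    def test_known_transform_recovered_exactly(self):
        T = make_transform((512, 512), rotation_deg=30.0, scale=1.1,
                           translation=(5.0, -3.0))
        src = np.array(
            [[10.0, 20.0], [400.0, 30.0], [60.0, 450.0], [300.0, 300.0],
             [120.0, 77.0], [250.0, 410.0]]
        )
        M = fit_affine_from_landmarks(src, T.apply(src))
        np.testing.assert_allclose(M, T.affine, atol=1e-6)

    def test_collinear_sources_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(RegistrationError, match="degenerate"):
            fit_affine_from_landmarks(src, src)

    def test_fewer_than_three_pairs_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(RegistrationError, match="at least 3"):
            fit_affine_from_landmarks(src, src)

    def test_noisy_landmark_residuals_below_one_px(self):
        """50 random affines (rot<=15 deg, scale 0.9-1.1, translation<=20 px),
        8 landmarks with 0.5 px coordinate noise: RMS residual < 1 px."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            T = make_transform(
                (512, 512),
                rotation_deg=rng.uniform(-15, 15),
                scale=rng.uniform(0.9, 1.1),
                translation=tuple(rng.uniform(-20, 20, 2)),
            )
            src = rng.uniform(0, 512, (8, 2))
            dst = T.apply(src) + rng.normal(0, 0.5, (8, 2))
            M = fit_affine_from_landmarks(src, dst)
            res = apply_affine(M, src) - dst
            rms = float(np.sqrt((res**2).sum(axis=1).mean()))
            assert rms < 1.0


class TestRefineWithAnchors:
    identity = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])

    def test_no_anchors_equals_affine(self):
        lin = make_transform((256, 256), 10.0, 1.05, (3.0, 4.0)).affine
        reg = refine_with_anchors(lin, [])
        pts = np.random.default_rng(0).uniform(0, 256, (20, 2))
        np.testing.assert_allclose(reg.transform_points(pts),
                                   apply_affine(lin, pts))
        assert reg.nonlinear_kind == "none"

    def test_single_anchor_exact_and_decaying(self):
        src = np.array([50.0, 50.0])
        dst = np.array([54.0, 50.0])
        reg = refine_with_anchors(self.identity, [(src, dst)])
        np.testing.assert_allclose(
            reg.transform_points(src)[0], dst, atol=1e-6
        )
        d_near = np.linalg.norm(
            reg.transform_points([52.0, 50.0])[0] - [52.0, 50.0]
        )
        d_far = np.linalg.norm(
            reg.transform_points([300.0, 50.0])[0] - [300.0, 50.0]
        )
        assert d_near > d_far
        assert d_far < 0.5

    def test_anchors_reproduced_exactly(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 200, (6, 2))
        dst = src + rng.uniform(-5, 5, (6, 2))
        reg = refine_with_anchors(self.identity, list(zip(src, dst)))
        np.testing.assert_allclose(reg.transform_points(src), dst, atol=1e-6)
        assert reg.nonlinear_kind == "thin_plate_spline"

    def test_refinement_never_worsens_anchor_residuals(self):
        rng = np.random.default_rng(2)
        lin = make_transform((256, 256), 5.0, 1.02, (2.0, -1.0)).affine
        src = rng.uniform(0, 256, (8, 2))
        dst = apply_affine(lin, src) + rng.normal(0, 2.0, (8, 2))
        before = np.sqrt(((apply_affine(lin, src) - dst) ** 2).sum(1).mean())
        reg = refine_with_anchors(lin, list(zip(src, dst)))
        after = np.sqrt(((reg.transform_points(src) - dst) ** 2).sum(1).mean())
        assert after <= before + 1e-9

    def test_smooth_deformation_interpolated_between_anchors(self):
        """Anchors sampled from a smooth deformation: mid-grid points are
        recovered within 0.5 px."""

        def deform(p):
            return p + 3.0 * np.column_stack(
                [np.sin(p[:, 1] / 60.0), np.cos(p[:, 0] / 60.0)]
            )

        grid = np.array(
            [[x, y] for y in np.linspace(0, 240, 5) for x in np.linspace(0, 240, 5)]
        )
        reg = refine_with_anchors(self.identity, list(zip(grid, deform(grid))))
        mids = np.array(
            [[x, y] for y in np.linspace(30, 210, 4) for x in np.linspace(30, 210, 4)]
        )  # centers of the grid cells, inside the anchor hull
        np.testing.assert_allclose(
            reg.transform_points(mids), deform(mids), atol=0.5
        )

    def test_conflicting_duplicate_anchor_sources_rejected(self):
        a = np.array([10.0, 10.0])
        with pytest.raises(RegistrationError, match="conflicting"):
            refine_with_anchors(
                self.identity, [(a, a + 1.0), (a.copy(), a + 3.0)]
            )

    def test_singular_affine_rejected(self):
        with pytest.raises(RegistrationError, match="singular"):
            SectionRegistration(linear=np.array([[1.0, 0, 0], [2.0, 0, 0]]))

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        src = rng.uniform(0, 100, (4, 2))
        dst = src + rng.uniform(-3, 3, (4, 2))
        reg = refine_with_anchors(self.identity, list(zip(src, dst)))
        p = tmp_path / "reg.json"
        reg.to_json(p)
        again = SectionRegistration.from_json(p)
        pts = rng.uniform(0, 100, (10, 2))
        np.testing.assert_allclose(
            again.transform_points(pts), reg.transform_points(pts), atol=1e-9
        )

    def test_rescale_affine_scales_translation_only(self):
        M = np.array([[1.1, 0.1, 3.0], [-0.1, 0.9, -2.0]])
        out = rescale_affine(M, 12)
        np.testing.assert_allclose(out[:, :2], M[:, :2])
        np.testing.assert_allclose(out[:, 2], [36.0, -24.0])


class TestMapCellsToAtlas:
    def two_region_plate(self, toy_ontology):
        from syntopo.atlas import AtlasPlate

        labels = np.zeros((40, 40), dtype=np.int32)
        labels[:, :20] = 4
        labels[:, 20:] = 5
        return AtlasPlate(labels=labels, ontology=toy_ontology)

    def cells_at(self, points):
        df = pd.DataFrame(
            {
                "cell_id": range(1, len(points) + 1),
                "x": [p[0] for p in points],
                "y": [p[1] for p in points],
                "area_px": 10,
            }
        )
        return CellTable(df=df)

    def test_identity_registration_looks_up_label(self, toy_ontology):
        plate = self.two_region_plate(toy_ontology)
        reg = refine_with_anchors(np.array([[1.0, 0, 0], [0, 1.0, 0]]), [])
        cells = map_cells_to_atlas(self.cells_at([(5.0, 5.0)]), reg, plate)
        assert cells.df.region_id.item() == 4
        assert not cells.df.unassigned.item()

    def test_translation_moves_cells_across_boundary(self, toy_ontology):
        plate = self.two_region_plate(toy_ontology)
        shift = np.array([[1.0, 0, 10.0], [0, 1.0, 0.0]])
        reg = refine_with_anchors(shift, [])
        pts = [(14.0, 10.0), (5.0, 10.0)]  # first crosses into region 5
        cells = map_cells_to_atlas(self.cells_at(pts), reg, plate)
        assert list(cells.df.region_id) == [5, 4]

    def test_outside_plate_flagged_unassigned(self, toy_ontology):
        plate = self.two_region_plate(toy_ontology)
        shift = np.array([[1.0, 0, 100.0], [0, 1.0, 0.0]])
        reg = refine_with_anchors(shift, [])
        cells = map_cells_to_atlas(self.cells_at([(10.0, 10.0)]), reg, plate)
        assert cells.df.region_id.item() == 0
        assert cells.df.unassigned.item()

    def test_warp_then_register_recovers_region_assignments(self, small_section):
        """Perturb -> register from true landmark pairs -> region lookup
        matches the unperturbed assignment for >=99% of true cells."""
        from syntopo.workflows import default_landmark_grid

        plate, _, _, _, truth = small_section
        rng = np.random.default_rng(7)
        pts = truth.cells[["x", "y"]].to_numpy()
        base_regions = truth.cells["region_id"].to_numpy()
        agree_all = []
        for i in range(5):
            T = make_transform(
                plate.shape,
                rotation_deg=rng.uniform(-15, 15),
                scale=rng.uniform(0.9, 1.1),
                translation=tuple(rng.uniform(-15, 15, 2)),
            )
            lm = default_landmark_grid(plate.shape, 8)
            M = fit_affine_from_landmarks(T.apply(lm), lm)
            reg = refine_with_anchors(M, [])
            cells = map_cells_to_atlas(
                self.cells_at([tuple(p) for p in T.apply(pts)]), reg, plate
            )
            agree_all.append((cells.df.region_id.to_numpy() == base_regions).mean())
        assert np.mean(agree_all) >= 0.99
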