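"""The 30-descriptor extraction: calipers, 2D morphology, volumes, colour."""

import math

import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from melissoscope import descriptors as dsc
from melissoscope.errors import ContractViolation, UndefinedInputError
from tests.conftest import disc_mask


def _ellipse_mask(a, b, angle=0.0, pad=6):
    size = 2 * (max(a, b) + pad) + 1
    c = size // 2
    rr, cc = draw_ellipse(c, c, b, a, rotation=angle, shape=(size, size))
    m = np.zeros((size, size), bool)
    m[rr, cc] = True
    return m


class TestFeret:
    def test_axis_aligned_square(self):
        mask = np.zeros((120, 120), bool)
        mask[10:110, 10:110] = True
        mx, mn, m90 = dsc.feret_diameters(mask, 1.0)
        assert mn == pytest.approx(100.0, abs=1e-9)
        assert mx == pytest.approx(100 * math.sqrt(2), rel=1e-6)
        assert m90 == pytest.approx(100 * math.sqrt(2), rel=1e-6)

    def test_digital_disc(self):
        mx, mn, m90 = dsc.feret_diameters(disc_mask(100), 1.0)
        for v in (mx, mn, m90):
            assert v == pytest.approx(200.0, rel=0.01)

    def test_matches_antipodal_bruteforce(self, rng):
        """Calipers equal the O(n²) antipodal-pair / edge-support oracle."""
        for _ in range(5):
            pts = rng.normal(size=(40, 2)) * 15 + 40
            mask = np.zeros((80, 80), bool)
            mask[np.clip(pts[:, 0].astype(int), 0, 79),
                 np.clip(pts[:, 1].astype(int), 0, 79)] = True
            from scipy import ndimage as ndi
            mask = ndi.binary_dilation(mask, iterations=3)
            mask = ndi.binary_fill_holes(mask)
            verts = dsc.hull_corner_points(mask)
            # oracle: max over all vertex pairs; min over edge support lines
            d = np.sqrt(((verts[:, None] - verts[None, :]) ** 2).sum(-1))
            want_max = d.max()
            want_min = np.inf
            n = len(verts)
            for k in range(n):
                e = verts[(k + 1) % n] - verts[k]
                norm = np.linalg.norm(e)
                if norm == 0:
                    continue
                nvec = np.array([-e[1], e[0]]) / norm
                proj = verts @ nvec
                want_min = min(want_min, proj.max() - proj.min())
            mx, mn, _ = dsc.feret_diameters(mask, 1.0)
            assert mx == pytest.approx(want_max, rel=1e-9)
            assert mn == pytest.approx(want_min, rel=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(UndefinedInputError):
            dsc.feret_diameters(np.zeros((5, 5), bool), 1.0)


class TestMorphology2D:
    def test_disc_limits(self):
        mo = dsc.morphology_2d(disc_mask(75), 0.2)
        for v in (mo.circularity, mo.shape_factor, mo.convexity, mo.roughness):
            assert 0.98 <= v <= 1.02
        d = 151 * 0.2
        assert mo.length == pytest.approx(d, rel=0.02)
        assert mo.eq_diameter == pytest.approx(d, rel=0.02)
        assert mo.elongation == pytest.approx(1.0, abs=0.02)

    def test_ellipse_circularity_vs_ramanujan(self):
        a, b = 144, 80
        mo = dsc.morphology_2d(_ellipse_mask(a, b), 1.0)
        h = ((a - b) / (a + b)) ** 2
        peri = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        want = 4 * math.pi * (math.pi * a * b) / peri ** 2
        assert mo.circularity == pytest.approx(want, rel=0.01)
        assert mo.elongation == pytest.approx(1.8, rel=0.01)

    def test_disc_mean_chord_is_quarter_pi_d(self):
        mo = dsc.morphology_2d(disc_mask(90), 1.0)
        assert mo.mean_chord == pytest.approx(math.pi / 4 * 181, rel=0.02)

    def test_scale_equivariance(self):
        mask = _ellipse_mask(60, 40, angle=0.4)
        m1 = dsc.morphology_2d(mask, 1.0)
        m2 = dsc.morphology_2d(mask, 2.5)
        assert m2.length == pytest.approx(2.5 * m1.length, rel=1e-9)
        assert m2.area == pytest.approx(2.5 ** 2 * m1.area, rel=1e-9)
        for name in ("circularity", "elongation", "shape_factor",
                     "convexity", "roughness"):
            assert getattr(m2, name) == pytest.approx(getattr(m1, name),
                                                      rel=1e-9)

    def test_rotation_robustness(self):
        base = dsc.morphology_2d(_ellipse_mask(70, 45), 1.0)
        for angle in (0.3, 0.9, 1.3):
            rot = dsc.morphology_2d(_ellipse_mask(70, 45, angle=angle), 1.0)
            for name in ("circularity", "elongation", "shape_factor",
                         "convexity", "roughness"):
                assert getattr(rot, name) == pytest.approx(
                    getattr(base, name), rel=0.02)

    def test_multi_component_rejected(self):
        mask = np.zeros((40, 80), bool)
        mask[5:15, 5:15] = True
        mask[25:35, 60:70] = True
        with pytest.raises(ContractViolation):
            dsc.morphology_2d(mask, 1.0)


class TestVolumes:
    def test_unit_sphere(self):
        assert dsc.volume_eq_sphere(1.0) == pytest.approx(math.pi / 6)

    def test_cubic_scaling(self):
        assert dsc.volume_eq_sphere(2.0) / dsc.volume_eq_sphere(1.0) == pytest.approx(8.0)

    def test_sphere_matches_published_mean_within_jensen_gap(self):
        # mean eq-diameter cubed vs published mean of cubes
        assert dsc.volume_eq_sphere(23.18) == pytest.approx(6620.79, rel=0.02)

    def test_capsule_degenerates_to_sphere(self):
        assert dsc.volume_eq_cylinder(10.0, 10.0) == pytest.approx(
            dsc.volume_eq_sphere(10.0), rel=1e-12)

    def test_capsule_matches_published_mean(self):
        assert dsc.volume_eq_cylinder(25.36, 16.69) == pytest.approx(
            4375.56, rel=0.02)

    def test_capsule_scaling_and_monotonicity(self):
        v = dsc.volume_eq_cylinder(25.0, 16.0)
        assert dsc.volume_eq_cylinder(50.0, 32.0) == pytest.approx(8 * v)
        assert dsc.volume_eq_cylinder(26.0, 16.0) > v
        assert dsc.volume_eq_cylinder(25.0, 17.0) > v

    def test_clamps_length_below_width(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            v = dsc.volume_eq_cylinder(9.0, 10.0)
        assert v == pytest.approx(dsc.volume_eq_sphere(10.0))
        assert "clamping" in caplog.text

    def test_domain_errors(self):
        with pytest.raises(UndefinedInputError):
            dsc.volume_eq_sphere(0.0)
        with pytest.raises(UndefinedInputError):
            dsc.volume_eq_cylinder(-1.0, 2.0)


class TestColourStats:
    def test_uniform_patch(self):
        img = np.zeros((10, 10, 3), np.uint8)
        img[...] = (116, 104, 72)
        cs = dsc.colour_stats(img, np.ones((10, 10), bool))
        assert cs.mean_intensity == pytest.approx((116 + 104 + 72) / 3)
        assert cs.mean_brightness == pytest.approx(cs.mean_intensity * 100 / 255)
        assert cs.intensity_variation == pytest.approx(0.0, abs=1e-9)
        assert cs.bright_variation == pytest.approx(0.0, abs=1e-9)
        assert cs.hue_variation == pytest.approx(0.0, abs=1e-3)

    def test_identities_hold_on_random_image(self, rng):
        img = rng.integers(0, 256, (30, 30, 3)).astype(np.uint8)
        mask = rng.random((30, 30)) > 0.4
        cs = dsc.colour_stats(img, mask)
        assert cs.mean_intensity == pytest.approx(
            (cs.mean_red + cs.mean_green + cs.mean_blue) / 3, rel=1e-12)
        assert cs.mean_brightness == pytest.approx(
            cs.mean_intensity * 100 / 255, rel=1e-12)
        assert cs.bright_variation == pytest.approx(
            cs.intensity_variation * 100 / 255, rel=1e-12)

    def test_density_of_uniform_intensity_below_published_per_pixel_mean(self):
        # Jensen: OD of the mean intensity <= mean per-pixel OD
        img = np.zeros((5, 5, 3), np.uint8)
        img[...] = 97  # ~ published Brassica BF mean intensity
        cs = dsc.colour_stats(img, np.ones((5, 5), bool))
        assert cs.mean_density == pytest.approx(-math.log10(97 / 255), rel=1e-9)
        assert cs.mean_density <= 0.43 + 0.01

    def test_hue_of_pure_colours(self):
        img = np.zeros((1, 3, 3), np.uint8)
        img[0, 0] = (255, 0, 0)
        img[0, 1] = (0, 255, 0)
        img[0, 2] = (0, 0, 255)
        for col, want in ((0, 0.5), (1, 120.5), (2, 240.5)):
            mask = np.zeros((1, 3), bool)
            mask[0, col] = True
            assert dsc.colour_stats(img, mask).hue_typical == pytest.approx(want)

    def test_empty_mask_rejected(self):
        with pytest.raises(UndefinedInputError):
            dsc.colour_stats(np.zeros((4, 4, 3), np.uint8),
                             np.zeros((4, 4), bool))


class TestExtractFeatures:
    def test_single_disc_grain_full_row(self):
        from melissoscope.edf import EDFResult
        from melissoscope.segmentation import GrainMask
        from melissoscope.stackio import FocalStack
        from melissoscope.book import DESCRIPTORS

        rng = np.random.default_rng(5)
        mask = np.zeros((140, 140), bool)
        mask[5:134, 5:134] = disc_mask(60)
        img = np.full((140, 140, 3), 200, np.uint8)
        img[mask] = rng.integers(90, 120, (mask.sum(), 3)).astype(np.uint8)
        planes = np.stack([img, img])
        stack = FocalStack(planes=planes, pixel_size=0.2, plane_spacing=8.0,
                           modality="BF")
        rows, cols = np.nonzero(mask)
        grain = GrainMask(mask=mask, label_id=0,
                          bbox=(rows.min(), cols.min(),
                                rows.max() + 1, cols.max() + 1))
        edf_result = EDFResult(composite=img, zmap=np.zeros((140, 140)),
                               plane_index=np.zeros((140, 140), int),
                               focus_scores=np.zeros((2, 140, 140)))
        table = dsc.extract_features(stack, [grain], edf_result,
                                     taxa=["Brassica"])
        assert len(table) == 1
        row = table.frame.iloc[0]
        assert set(DESCRIPTORS) <= set(table.frame.columns)
        assert row["roughness"] > 0.97
        assert row["edf_roughness"] == pytest.approx(1.0)
        assert row["mean_edf_z"] == 0.0
        assert row["taxon"] == "Brassica"

    def test_empty_grain_list(self, tiny_stack):
        from melissoscope.edf import compose_edf
        table = dsc.extract_features(tiny_stack, [], compose_edf(tiny_stack))
        assert len(table) == 0
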