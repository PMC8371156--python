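"""Feature engine vs analytic shapes and brute-force pixel sums."""

import math

import numpy as np
import pytest

from morphoscore import CellRegion, FEATURE_NAMES, extract_cell_features
from morphoscore.features import (
    MARKER_SOURCES,
    N_FEATURES,
    N_FEATURES_PER_MARKER,
    PER_MARKER_FEATURES,
    basic_morphology,
    compute_marker_features,
    intensity_features,
    marker_columns,
    ser_texture,
    star_features,
)
from scipy import ndimage


def disc_region(radius=20, n=101, value=1.0):
    yy, xx = np.mgrid[:n, :n]
    mask = (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= radius**2
    return CellRegion(mask, np.full((n, n), value))


def ellipse_region(a=40, b=20, n=121, value=1.0):
    yy, xx = np.mgrid[:n, :n]
    mask = ((yy - n // 2) / b) ** 2 + ((xx - n // 2) / a) ** 2 <= 1
    return CellRegion(mask, np.full((n, n), value))


class TestNamingContract:
    def test_counts(self):
        assert N_FEATURES_PER_MARKER == 31
        assert N_FEATURES == 124
        assert len(set(FEATURE_NAMES)) == 124

    def test_marker_columns(self):
        for marker in ("nucleus", "mito", "aat", "cell"):
            cols = marker_columns(marker)
            assert len(cols) == 31
            assert all(c.startswith(marker + ".") for c in cols)
        assert marker_columns("combined") == list(FEATURE_NAMES)
        with pytest.raises(ValueError, match="unknown"):
            marker_columns("golgi")


class TestBasicMorphology:
    def test_disc_area_and_roundness(self):
        bm = basic_morphology(disc_region(20))
        assert bm["area"] == pytest.approx(math.pi * 400, rel=0.02)
        assert bm["roundness"] == pytest.approx(1.0, abs=0.05)
        assert bm["length"] == pytest.approx(41, rel=0.05)

    def test_ellipse_axis_ratio(self):
        bm = basic_morphology(ellipse_region(40, 20))
        assert bm["length"] / bm["width"] == pytest.approx(2.0, rel=0.05)

    def test_square_roundness_is_pi_over_4(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 10:50] = True
        bm = basic_morphology(CellRegion(mask, np.ones((60, 60))))
        assert bm["roundness"] == pytest.approx(math.pi / 4, rel=0.06)

    def test_one_pixel_wide_mask(self):
        mask = np.zeros((20, 20), bool)
        mask[5, 3:17] = True
        bm = basic_morphology(CellRegion(mask, np.ones((20, 20))))
        assert bm["width"] == pytest.approx(1.0)
        assert 0 < bm["roundness"] <= 1


class TestIntensity:
    def test_constant_image(self):
        region = disc_region(10, value=7.0)
        feats = intensity_features(region)
        n = int(region.mask.sum())
        assert feats == {"mean": 7.0, "sd": 0.0, "min": 7.0, "max": 7.0,
                         "sum": 7.0 * n}

    def test_matches_brute_force_summation(self, rng):
        img = rng.random((40, 40)) * 10
        mask = rng.random((40, 40)) > 0.4
        feats = intensity_features(CellRegion(mask, img))
        vals = [img[i, j] for i, j in zip(*np.nonzero(mask))]
        assert feats["sum"] == pytest.approx(sum(vals), rel=1e-12)
        assert feats["mean"] == pytest.approx(sum(vals) / len(vals), rel=1e-12)
        assert feats["min"] == min(vals) and feats["max"] == max(vals)


class TestStar:
    def test_uniform_disc_anchors(self):
        st = star_features(disc_region(20))
        for key in st:
            if key.startswith("symmetry."):
                assert st[key] < 0.02, key
            if key.startswith("compactness."):
                assert st[key] == pytest.approx(1.0, abs=0.05), key
        assert st["radial.mean"] == pytest.approx(2 / 3 * 20, rel=0.02)
        assert st["axial.ratio"] == pytest.approx(1.0, abs=0.02)

    def test_antipodal_spots_symmetry(self):
        """Two equal spots opposite the centroid: 2-fold high, 3-fold ~ 0."""
        mask = np.zeros((41, 41), bool)
        mask[10:31, 10:31] = True
        img = np.full((41, 41), 1e-9)
        img[20, 12] = img[20, 28] = 5.0
        st = star_features(CellRegion(mask, img))
        assert st["symmetry.s02"] > 0.99
        assert st["symmetry.s03"] < 0.01
        assert st["symmetry.s04"] > 0.99  # e^{i4θ} also aligns at θ, θ+π

    def test_ellipse_axial_ratio(self):
        st = star_features(ellipse_region(40, 20))
        assert st["axial.ratio"] == pytest.approx(0.5, rel=0.05)
        assert st["axial.length"] == pytest.approx(80, rel=0.05)

    def test_pixel_sum_oracle_equivalence(self, rng):
        """Intensity-weighted features match brute-force per-pixel loops."""
        img = rng.random((30, 30)) + 0.1
        mask = np.zeros((30, 30), bool)
        mask[5:25, 7:27] = True
        st = star_features(CellRegion(mask, img))

        pix = [(i, j, img[i, j]) for i, j in zip(*np.nonzero(mask))]
        total = sum(v for _, _, v in pix)
        cy = sum(i * v for i, _, v in pix) / total
        cx = sum(j * v for _, j, v in pix) / total
        radii = [math.hypot(i - cy, j - cx) for i, j, _ in pix]
        rmean = sum(r * v for r, (_, _, v) in zip(radii, pix)) / total
        assert st["radial.mean"] == pytest.approx(rmean, rel=1e-9)
        reldev = math.sqrt(sum(v * (r - rmean) ** 2
                               for r, (_, _, v) in zip(radii, pix)) / total) / rmean
        assert st["radial.reldev"] == pytest.approx(reldev, rel=1e-9)
        for y in (2, 3, 4, 5):
            phasor = sum(v * complex(math.cos(y * math.atan2(i - cy, j - cx)),
                                     math.sin(y * math.atan2(i - cy, j - cx)))
                         for i, j, v in pix)
            assert st[f"symmetry.s0{y}"] == pytest.approx(abs(phasor) / total,
                                                          rel=1e-9)

    def test_profile_depth_on_uniform_square(self):
        mask = np.zeros((50, 50), bool)
        mask[5:45, 5:45] = True
        img = np.ones((50, 50))
        st = star_features(CellRegion(mask, img))
        assert 0 < st["profile.depth"] < 1
        assert 0 < st["profile.inner"] < 1

    def test_zero_intensity_raises(self):
        mask = np.ones((10, 10), bool)
        with pytest.raises(ValueError, match="zero total"):
            star_features(CellRegion(mask, np.zeros((10, 10))))


class TestTexture:
    def test_flat_field_is_zero(self):
        region = CellRegion(np.ones((31, 31), bool), np.full((31, 31), 3.0))
        assert all(v == 0.0 for v in ser_texture(region).values())

    def test_bright_spot_spot_dominates_valley(self):
        img = np.zeros((31, 31))
        img[15, 15] = 10
        img = ndimage.gaussian_filter(img, 1.5) + 0.01
        tx = ser_texture(CellRegion(np.ones((31, 31), bool), img))
        assert tx["spot"] > 10 * tx["valley"]
        assert tx["hole"] == 0.0

    def test_bright_line_valley_and_edge_dominate_spot(self):
        img = np.zeros((31, 31))
        img[15, :] = 5
        img = ndimage.gaussian_filter(img, 1.0) + 0.01
        tx = ser_texture(CellRegion(np.ones((31, 31), bool), img))
        assert tx["valley"] > 10 * tx["spot"]
        assert tx["edge"] > 10 * tx["spot"]

    def test_erosion_fallback_on_tiny_mask(self):
        mask = np.zeros((10, 10), bool)
        mask[4:7, 4:7] = True
        tx = ser_texture(CellRegion(mask, np.random.default_rng(1).random((10, 10))))
        assert all(np.isfinite(v) for v in tx.values())


class TestInvariances:
    @pytest.fixture()
    def bumpy_region(self, rng):
        img = ndimage.gaussian_filter(rng.random((48, 48)), 1.5) + 0.05
        mask = np.zeros((48, 48), bool)
        mask[10:38, 12:40] = True
        return mask, img

    def test_translation_invariance(self, bumpy_region):
        mask, img = bumpy_region
        base = compute_marker_features(CellRegion(mask, img))
        shifted = compute_marker_features(
            CellRegion(np.roll(mask, (5, -3), (0, 1)),
                       np.roll(img, (5, -3), (0, 1))))
        for key in base:
            assert shifted[key] == pytest.approx(base[key], rel=1e-9), key

    def test_rotation_90_invariance(self, bumpy_region):
        mask, img = bumpy_region
        base = compute_marker_features(CellRegion(mask, img))
        rotated = compute_marker_features(
            CellRegion(np.rot90(mask), np.rot90(img)))
        for key in base:
            tol = 0.05 if key.startswith(("texture.", "morph.roundness")) else 1e-6
            assert rotated[key] == pytest.approx(base[key], rel=tol,
                                                 abs=1e-9), key

    def test_gain_invariance_split(self, bumpy_region):
        """Intensity features scale with gain; shape-like features do not."""
        mask, img = bumpy_region
        base = compute_marker_features(CellRegion(mask, img))
        gained = compute_marker_features(CellRegion(mask, img * 3.7))
        for key in base:
            family = key.split(".")[0]
            if family == "intensity":
                assert gained[key] == pytest.approx(3.7 * base[key], rel=1e-9)
            else:
                assert gained[key] == pytest.approx(base[key], rel=1e-6,
                                                    abs=1e-12), key


class TestExtraction:
    def test_field_table_shape(self, rendered_field):
        _, rf = rendered_field
        table = extract_cell_features(rf.field, rf.nuclei, rf.cells)
        assert len(table) == rf.cells.n_objects
        assert table[list(FEATURE_NAMES)].notna().all().all()
        assert table[list(FEATURE_NAMES)].shape[1] == 124

    def test_marker_sources_pairing(self):
        assert MARKER_SOURCES["nucleus"] == ("nucleus", "nucleus")
        assert MARKER_SOURCES["mito"] == ("cell", "mito")
        assert MARKER_SOURCES["aat"] == ("cell", "aat")
        assert MARKER_SOURCES["cell"] == ("cell", "phase")

    def test_per_marker_block_is_canonical(self):
        assert len(PER_MARKER_FEATURES) == 31
        fams = [f.split(".")[0] for f in PER_MARKER_FEATURES]
        assert fams.count("morph") == 4 and fams.count("intensity") == 5
        assert fams.count("symmetry") == 8 and fams.count("compactness") == 4
        assert fams.count("axial") == fams.count("radial") == 2
        assert fams.count("profile") == 2 and fams.count("texture") == 4
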