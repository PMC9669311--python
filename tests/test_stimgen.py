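"""Renderer, backgrounds, scrambling, calibration and dataset builders."""

import dataclasses

import numpy as np
import pytest

from emervis import stimgen as sg


class TestRenderObject:
    def test_rotation_periodicity(self, rigid_chair, uniform_cfg):
        for az in (0.0, 30.0):
            a = sg.render_object(rigid_chair,
                                 dataclasses.replace(uniform_cfg, azimuth=az))
            b = sg.render_object(rigid_chair,
                                 dataclasses.replace(uniform_cfg, azimuth=az + 360))
            np.testing.assert_array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize("azimuth", [17.0, 45.0, 80.0])
    def test_mirror_symmetry(self, rigid_chair, uniform_cfg, azimuth):
        """A left-right symmetric object renders as the mirror of its
        opposite-azimuth view."""
        a = sg.render_object(rigid_chair,
                             dataclasses.replace(uniform_cfg, azimuth=azimuth))
        b = sg.render_object(rigid_chair,
                             dataclasses.replace(uniform_cfg, azimuth=-azimuth))
        np.testing.assert_array_equal(a.pixels, np.fliplr(b.pixels))

    def test_centered_cube_silhouette_area(self, uniform_cfg):
        """Frontal view of a centered cube: silhouette is a centered square
        whose area matches the orthographic projection oracle."""
        edge = 0.4
        cube = sg.ObjectSpec("monitor", (sg.Cuboid((0, 0, 0), (edge,) * 3, 0.9),),
                             sg.JitterParams(0.0, 0.0), 0)
        im = sg.render_object(cube, uniform_cfg)
        mask = im.pixels != uniform_cfg.target_mean
        side = edge * uniform_cfg.object_scale * uniform_cfg.image_size
        assert (side - 1) ** 2 <= mask.sum() <= (side + 1) ** 2
        ys, xs = np.nonzero(mask)
        c = (uniform_cfg.image_size - 1) / 2
        assert abs(ys.mean() - c) < 1 and abs(xs.mean() - c) < 1

    def test_degenerate_primitive_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sg.Cuboid((0, 0, 0), (0.2, 0.0, 0.2))

    def test_identity_reproducibility(self, uniform_cfg):
        a = sg.object_spec("sofa", identity_seed=7)
        b = sg.object_spec("sofa", identity_seed=7)
        assert a.materialize() == b.materialize()
        c = sg.object_spec("sofa", identity_seed=8)
        assert a.materialize() != c.materialize()


class TestBackground:
    def test_seed_determinism(self):
        cfg = sg.RenderConfig()
        a = sg.make_background(11, cfg)
        b = sg.make_background(11, cfg)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_different_seeds_decorrelated(self):
        cfg = sg.RenderConfig()
        rs = []
        for k in range(20):
            a = sg.make_background(2 * k, cfg).pixels.ravel()
            b = sg.make_background(2 * k + 1, cfg).pixels.ravel()
            rs.append(np.corrcoef(a, b)[0, 1])
        assert np.max(np.abs(rs)) < 0.2

    def test_amplitude_spectrum_decreasing(self):
        cfg = sg.RenderConfig()
        px = sg.make_background(3, cfg).pixels
        amp = np.abs(np.fft.fft2(px - px.mean()))
        n = px.shape[0]
        f = np.hypot(np.fft.fftfreq(n)[:, None], np.fft.fftfreq(n)[None, :])
        edges = np.linspace(0.01, 0.5, 7)
        radial = [amp[(f >= lo) & (f < hi)].mean()
                  for lo, hi in zip(edges[:-1], edges[1:])]
        assert all(x > y for x, y in zip(radial[:-1], radial[1:]))


class TestScramble:
    def _img(self, seed=0):
        cfg = sg.RenderConfig()
        im = sg.render_object(sg.object_spec("toilet", 1),
                              dataclasses.replace(cfg, background_seed=seed))
        return im

    def test_histogram_preserved(self):
        im = self._img()
        scr = sg.scramble_object(im, grid=8, seed=5)
        assert sorted(im.pixels.ravel()) == sorted(scr.pixels.ravel())

    def test_grid_one_is_identity(self):
        im = self._img()
        scr = sg.scramble_object(im, grid=1, seed=5)
        np.testing.assert_array_equal(im.pixels, scr.pixels)

    def test_grid_below_one_rejected(self):
        with pytest.raises(ValueError):
            sg.scramble_object(self._img(), grid=0, seed=1)

    def test_mean_displacement_matches_enumeration(self):
        """Average block displacement over many permutations approaches the
        exact expectation for a uniform permutation of grid^2 blocks."""
        grid = 4
        pos = np.column_stack(np.divmod(np.arange(grid * grid), grid))
        exact = np.mean([np.hypot(*(pos[i] - pos[j]))
                         for i in range(grid * grid)
                         for j in range(grid * grid)])
        sim = np.mean([sg.mean_block_displacement(grid, s) for s in range(1000)])
        assert abs(sim - exact) < 0.05 * exact


class TestCalibration:
    def test_targets_met(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            img = sg.calibrate_intensity(rng.uniform(0, 80, (100, 100)) ** 2)
            assert abs(img.mean() - 127.5) <= 0.5
            assert abs(img.std() - 51.0) <= 1.5

    def test_fixed_point(self):
        rng = np.random.default_rng(1)
        img = sg.calibrate_intensity(rng.normal(0, 1, (64, 64)))
        again = sg.calibrate_intensity(img)
        np.testing.assert_allclose(again, img, atol=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sg.calibrate_intensity(np.full((10, 10), 3.0))

    def test_gaussian_noise_clipping_matches_tail_probability(self):
        """Calibrated Gaussian noise clips the analytic ~1.24% tail: the
        [0, 255] rails sit at (0 - 127.5)/51 = -2.5 and +2.5 sd, so the
        clipped fraction is 2*(1 - Phi(2.5))."""
        from scipy.stats import norm
        expected = 2 * norm.sf(2.5)
        rng = np.random.default_rng(2)
        fracs = []
        for _ in range(100):
            img = sg.calibrate_intensity(rng.normal(0, 1, (64, 64)))
            fracs.append(np.mean((img == 0) | (img == 255)))
        assert abs(np.mean(fracs) - expected) < 0.005


@pytest.fixture(scope="module")
def small_set():
    return sg.build_object_dataset(
        n_per_class=4, seed=3, classes=("toilet", "sofa", "monitor"),
        target_class="toilet")


class TestObjectDataset:
    def test_counts(self, small_set):
        m = small_set.manifest
        assert len(m) == 3 * 4 + 4
        assert (m["class"] == "scrambled").sum() == 4
        for cl in ("toilet", "sofa", "monitor"):
            assert (m["class"] == cl).sum() == 4

    def test_azimuth_bounds(self, small_set):
        m = small_set.manifest
        obj = m[m["class"] != "scrambled"]
        assert obj["viewpoint_deg"].between(-30, 30).all()

    def test_class_mean_intensity_spread(self, small_set):
        means = {}
        for cl in ("toilet", "sofa", "monitor"):
            px = [im.pixels.mean() for im in small_set.images
                  if im.class_name == cl]
            means[cl] = np.mean(px)
        vals = list(means.values())
        assert max(vals) - min(vals) < 1.0

    def test_all_images_calibrated(self, small_set):
        for im in small_set.images:
            assert abs(im.pixels.mean() - 127.5) <= 0.5
            assert abs(im.pixels.std() - 51.0) <= 1.5

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            sg.build_object_dataset(4, 0, classes=("toilet", "spaceship"))

    def test_builder_determinism(self):
        a = sg.build_object_dataset(2, 9, classes=("chair",), target_class="chair")
        b = sg.build_object_dataset(2, 9, classes=("chair",), target_class="chair")
        np.testing.assert_array_equal(a.pixel_stack(), b.pixel_stack())
        assert a.manifest.equals(b.manifest)


@pytest.fixture(scope="module")
def vp_set():
    return sg.build_viewpoint_dataset(n_steps=5, span_deg=(-60, 60),
                                      n_identities=4, n_heldout=2,
                                      seed=3, classes=("toilet",))


class TestViewpointDataset:
    def test_grid(self, vp_set):
        vps = np.sort(vp_set.manifest["viewpoint_deg"].unique())
        np.testing.assert_allclose(vps, [-60, -30, 0, 30, 60], atol=1e-9)

    def test_default_step_size(self):
        grid = np.linspace(-90, 90, 13)
        assert np.allclose(np.diff(grid), 15.0)

    def test_subset_partition(self, vp_set):
        m = vp_set.manifest
        analysis = set(m[m["subset"] == "analysis"]["identity"])
        heldout = set(m[m["subset"] == "heldout"]["identity"])
        assert analysis.isdisjoint(heldout)
        assert len(analysis) == 2 and len(heldout) == 2

    def test_zero_azimuth_shares_renderer(self, vp_set):
        """0-degree views are pixel-identical to a direct dataset render of
        the same identity at azimuth 0 under the same builder seed."""
        direct = sg.render_dataset_image("toilet", 0, 0.0, 3,
                                         sg.RenderConfig(), "viewpoint")
        idx = vp_set.manifest.index[
            (vp_set.manifest["identity"] == 0)
            & (vp_set.manifest["viewpoint_deg"] == 0.0)][0]
        np.testing.assert_array_equal(vp_set.images[idx].pixels, direct.pixels)

    def test_all_calibrated(self, vp_set):
        for im in vp_set.images:
            assert abs(im.pixels.mean() - 127.5) <= 0.5
            assert abs(im.pixels.std() - 51.0) <= 1.5

    def test_even_steps_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            sg.build_viewpoint_dataset(n_steps=4)

    def test_asymmetric_span_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            sg.build_viewpoint_dataset(n_steps=5, span_deg=(-30, 60))


@pytest.fixture(scope="module")
def svm_set():
    return sg.build_svm_dataset(n_identities=60, n_ranges=2, seed=4,
                                classes=("toilet",))


class TestSvmDataset:
    def test_zero_range_front_view(self, svm_set):
        m = svm_set.manifest
        assert (m[m["variation_range"] == 0.0]["viewpoint_deg"] == 0.0).all()

    def test_full_range_order_statistics(self, svm_set):
        m = svm_set.manifest
        az = m[m["variation_range"] == 180.0]["viewpoint_deg"]
        assert -90 <= az.min() <= -80
        assert 80 <= az.max() <= 90

    def test_counts_and_identity_disjointness(self, svm_set):
        m = svm_set.manifest
        assert len(m) == 3 * 60          # V=0 plus 2 graded ranges
        assert (m["identity"] >= sg.SVM_IDENTITY_OFFSET).all()

    def test_default_range_grid(self):
        ranges = np.linspace(10.0, 180.0, 18)
        assert ranges[0] == 10.0 and ranges[-1] == 180.0
        assert np.allclose(np.diff(ranges), 10.0)


class TestAudit:
    def test_duplicated_class_correlation(self):
        im = sg.render_object(sg.object_spec("bed", 0), sg.RenderConfig())
        dup = sg.StimulusSet(
            [im, dataclasses.replace(im),
             dataclasses.replace(im, class_name="other"),
             dataclasses.replace(im, class_name="other")],
            __import__("pandas").DataFrame({"class": ["bed", "bed",
                                                      "other", "other"]}))
        rep = sg.audit_low_level_controls(dup)
        assert np.isclose(
            rep.loc[rep["class"] == "bed", "within_class_corr"].iloc[0], 1.0)

    def test_generated_set_unflagged_and_calibrated(self):
        st = sg.build_object_dataset(n_per_class=4, seed=1,
                                     classes=("toilet", "sofa", "monitor"),
                                     target_class="toilet")
        rep = sg.audit_low_level_controls(st, tol_sd=2.0)
        obj = rep[rep["class"] != "scrambled"]
        assert not obj["flagged"].any()
        assert obj["mean_intensity"].between(127.0, 128.0).all()


class TestSaveImages:
    def test_pngs_and_manifest_roundtrip(self, tmp_path):
        from PIL import Image
        st = sg.build_object_dataset(2, 0, ("toilet",), "toilet")
        manifest = sg.save_images(st, tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        for _, row in manifest.iterrows():
            arr = np.asarray(Image.open(tmp_path / row["path"]))
            assert arr.shape == (227, 227) and arr.dtype == np.uint8
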