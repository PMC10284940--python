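"""Background-suppression chain tests: mirror tiling, Fourier filter, morphology."""

import numpy as np
import pytest

import fragscan as fs
from fragscan.preprocess import PreprocessParams, _split_sections, _tile_from_section


def _img(arr, res=1.0):
    return fs.GrayImage(np.asarray(arr, dtype=float), res)


class TestMirrorTile:
    def test_identity_for_1x1_grid(self):
        rng = np.random.default_rng(0)
        img = _img(rng.uniform(0, 10, (20, 30)))
        out = fs.mirror_tile(img, 0, (1, 1))
        np.testing.assert_allclose(out.pixels, img.pixels)

    def test_reflection_periodicity_on_ramp(self):
        # horizontally ramped image, 2x2 grid, top-left section
        ramp = np.tile(np.arange(40, dtype=float), (40, 1))
        img = _img(ramp)
        out = fs.mirror_tile(img, 0, (2, 2)).pixels
        # reflected tiling: period = 2 * section width along x
        np.testing.assert_allclose(out[:, :20], out[:, 20:40][:, ::-1])

    def test_dimensions_preserved_odd_sizes(self):
        rng = np.random.default_rng(1)
        img = _img(rng.uniform(0, 5, (33, 47)))
        out = fs.mirror_tile(img, 3, (2, 2))
        assert out.shape == (33, 47)

    def test_seams_continuous(self):
        # brute-force seam scan: jumps across tile borders bounded by the
        # max intra-section gradient
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 50, (16, 16))
        sect = np.cumsum(np.cumsum(base, 0), 1) / 50.0  # smooth-ish section
        tiled = _tile_from_section(sect, (64, 64))
        grad_max = max(np.abs(np.diff(sect, axis=0)).max(), np.abs(np.diff(sect, axis=1)).max())
        for seam in (15, 31, 47):
            assert np.abs(tiled[:, seam + 1] - tiled[:, seam]).max() <= grad_max
            assert np.abs(tiled[seam + 1, :] - tiled[seam, :]).max() <= grad_max

    def test_invalid_section_index(self):
        img = _img(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            fs.mirror_tile(img, 4, (2, 2))


class TestFourierFilter:
    def test_flat_image_is_fixed_point(self):
        # flat sections: no structure to attenuate; output equals input
        img = _img(np.full((64, 64), 9.0))
        out = fs.fourier_background_filter(img, PreprocessParams())
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-9)

    def test_blob_contrast_increases_over_iterations(self):
        spec = fs.SceneSpec(seed=5, shape_px=(256, 256), n_particles=0, n_fibers=0, noise_sd=1.0)
        bg, _ = fs.generate_scene(spec)
        pixels = bg.pixels.copy()
        pixels[120:126, 120:126] += 150.0  # one bright blob
        img = fs.GrayImage(pixels, spec.resolution_um_per_px)

        def contrast(im):
            peak = im.pixels[118:128, 118:128].max()
            bg_region = im.pixels[:100, :100]
            return (peak - bg_region.mean()) / max(bg_region.std(), 1e-9)

        scores = [contrast(img)]
        for i in (1, 2, 3):
            out = fs.fourier_background_filter(img, PreprocessParams(n_iterations=i))
            scores.append(contrast(out))
        assert scores[1] > scores[0]
        assert scores[3] > scores[1]

    def test_periodic_background_variance_reduced(self):
        spec = fs.SceneSpec(seed=6, shape_px=(256, 256), n_particles=0, n_fibers=0)
        bg, _ = fs.generate_scene(spec)
        out = fs.fourier_background_filter(bg, PreprocessParams(n_iterations=3))
        assert out.pixels.var() < 0.20 * bg.pixels.var()

    def test_shared_frequency_attenuated_object_retained(self):
        # a global lattice (present in every section, hence large H) must
        # be attenuated far more strongly than a one-off bright object
        H = W = 256
        yy, xx = np.mgrid[0:H, 0:W]
        lattice = 30 + 10 * np.sin(2 * np.pi * xx / 8.0) * np.sin(2 * np.pi * yy / 8.0)
        arr = lattice.copy()
        arr[100:110, 100:110] += 120.0
        img = _img(np.clip(arr, 0, None))
        out = fs.fourier_background_filter(img, PreprocessParams(n_iterations=3))
        sin_ratio = np.abs(np.fft.fft2(out.pixels))[32, 32] / np.abs(np.fft.fft2(img.pixels))[32, 32]
        blob_in = img.pixels[100:110, 100:110].mean() - 30.0
        blob_out = out.pixels[100:110, 100:110].mean() - out.pixels[:50, :50].mean()
        assert sin_ratio < 0.2
        assert blob_out / blob_in > 0.6

    def test_dimensions_and_nonnegativity(self):
        rng = np.random.default_rng(3)
        img = _img(rng.uniform(0, 30, (65, 97)))
        out = fs.fourier_background_filter(img, PreprocessParams())
        assert out.shape == (65, 97)
        assert (out.pixels >= 0).all()


class TestMorphology:
    def test_tophat_flat_is_zero(self):
        out = fs.top_hat(_img(np.full((40, 40), 5.0)), 15)
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-9)

    def test_tophat_small_spot_retained(self):
        arr = np.full((64, 64), 10.0)
        arr[30:33, 30:33] = 200.0
        out = fs.top_hat(_img(arr), 15)
        assert out.pixels[31, 31] >= 0.9 * (200.0 - 10.0)

    def test_tophat_plateau_suppressed(self):
        # broad plateau width >> 2*radius: interior goes to ~0.
        # brute-force 1-D opening oracle on the profile.
        arr = np.full((21, 200), 10.0)
        arr[:, 40:160] = 80.0
        radius = 10
        out = fs.top_hat(_img(arr), radius)
        assert np.allclose(out.pixels[10, 60:140], 0.0, atol=1e-9)
        profile = arr[10]
        n = len(profile)
        eroded = np.array([profile[max(0, i - radius) : i + radius + 1].min() for i in range(n)])
        opened = np.array([eroded[max(0, i - radius) : i + radius + 1].max() for i in range(n)])
        oracle = profile - opened
        np.testing.assert_allclose(out.pixels[10, 60:140], oracle[60:140], atol=1e-9)

    def test_opening_removes_isolated_pixel(self):
        arr = np.zeros((21, 21))
        arr[10, 10] = 100.0
        out = fs.gray_opening(_img(arr), 1)
        assert out.pixels.max() == 0

    def test_opening_preserves_large_square(self):
        arr = np.zeros((41, 41))
        arr[10:31, 10:31] = 50.0
        out = fs.gray_opening(_img(arr), 1)
        assert (out.pixels == 50.0).sum() == 21 * 21

    def test_opening_antiextensive(self):
        rng = np.random.default_rng(4)
        arr = rng.uniform(0, 100, (50, 50))
        out = fs.gray_opening(_img(arr), 1)
        assert (out.pixels <= arr + 1e-12).all()


class TestPreprocessChain:
    def test_all_disabled_is_identity(self):
        rng = np.random.default_rng(5)
        img = _img(rng.uniform(0, 80, (64, 64)))
        params = PreprocessParams(enable_fourier=False, enable_tophat=False, enable_opening=False)
        out = fs.preprocess(img, params)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_deterministic(self, standard_scene):
        img, _ = standard_scene
        a = fs.preprocess(img)
        b = fs.preprocess(img)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_planted_objects_survive_thresholding(self, preprocessed_scene, standard_scene):
        # objects >= 13 px keep >= 95% of their pixels above the local
        # adaptive threshold after the full chain
        pre, truth = preprocessed_scene
        from fragscan.detect import adaptive_binarize

        fg = adaptive_binarize(pre, 243, -6.0) | adaptive_binarize(pre, 91, -6.0)
        survival = []
        for o in truth.objects:
            if o.area_px < 13:
                continue
            r0, c0, r1, c1 = o.bbox
            survival.append((fg[r0:r1, c0:c1] & o.mask).sum() / o.area_px)
        assert np.mean(survival) >= 0.95

    def test_scale_invariance_of_survival(self):
        # doubling object sizes leaves per-object Fourier-stage survival
        # qualitatively unchanged (< 10 percentage points difference)
        from fragscan.detect import adaptive_binarize

        rates = []
        for diam in ((2.0, 4.0), (4.0, 8.0)):
            spec = fs.SceneSpec(seed=9, n_particles=25, n_fibers=0, particle_diameter_um=diam)
            img, truth = fs.generate_scene(spec)
            filt = fs.fourier_background_filter(img, PreprocessParams())
            fg = adaptive_binarize(filt, 243, -6.0) | adaptive_binarize(filt, 91, -6.0)
            surv = []
            for o in truth.objects:
                r0, c0, r1, c1 = o.bbox
                surv.append((fg[r0:r1, c0:c1] & o.mask).sum() / max(o.area_px, 1))
            rates.append(np.mean([s >= 0.5 for s in surv]))
        assert abs(rates[0] - rates[1]) < 0.10

    def test_no_intensity_blowup(self, standard_scene):
        img, _ = standard_scene
        out = fs.preprocess(img)
        assert out.pixels.max() <= img.pixels.max() * 1.5
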