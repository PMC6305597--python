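import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from calimo import registration as reg
from calimo import synthetic as syn


def naive_pearson(patch, window):
    a = patch.ravel() - patch.mean()
    b = window.ravel() - window.mean()
    den = np.sqrt((a @ a) * (b @ b))
    return 0.0 if den == 0 else float(a @ b / den)


class TestDownscale:
    def test_factor_one_identity(self, rng):
        img = rng.normal(size=(17, 13))
        assert np.array_equal(reg.downscale(img, 1), img)

    def test_exact_block_means(self):
        img = np.array([[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]],
                       dtype=float)
        assert np.array_equal(reg.downscale(img, 2), [[1, 2], [3, 4]])

    def test_trailing_dropped_and_means_match_oracle(self, rng):
        img = rng.normal(size=(17, 17))
        out = reg.downscale(img, 2)
        assert out.shape == (8, 8)
        for i in range(8):
            for j in range(8):
                assert out[i, j] == pytest.approx(
                    img[2 * i:2 * i + 2, 2 * j:2 * j + 2].mean())

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError):
            reg.downscale(np.zeros((16, 16)), 3)


class TestCorrelationAt:
    def test_self_correlation_is_one(self, blob_template, blob_scene):
        c = reg.correlation_at(blob_template, blob_scene.image, (0, 0))
        assert c == pytest.approx(1.0)

    def test_negated_patch_anticorrelates(self, blob_template):
        t = blob_template
        frame = t.full_image.copy()
        h, w = frame.shape
        patch = frame[t.my:h - t.my, t.mx:w - t.mx]
        frame[t.my:h - t.my, t.mx:w - t.mx] = 2 * patch.mean() - patch
        assert reg.correlation_at(t, frame, (0, 0)) == pytest.approx(-1.0)

    def test_bright_pixel_matches_hand_pearson(self):
        img = np.zeros((8, 8))
        img[4, 4] = 10.0
        t = reg.Template.from_image(img)  # margins 2, patch 4x4
        frame = reg.translate(img, (1, 0))
        c_true = reg.correlation_at(t, frame, (1, 0))
        c_zero = reg.correlation_at(t, frame, (0, 0))
        assert c_true > c_zero
        # independent direct Pearson evaluation
        win = frame[t.my:t.my + 4, t.mx + 1:t.mx + 5]
        assert c_true == pytest.approx(naive_pearson(t.central_patch, win))

    def test_out_of_range_shift_raises(self, blob_template, blob_scene):
        with pytest.raises(ValueError):
            reg.correlation_at(blob_template, blob_scene.image,
                               (blob_template.mx + 1, 0))

    def test_zero_variance_window_returns_zero(self):
        img = np.zeros((16, 16))
        img[1, 1] = 1.0  # variance only outside the patch
        img[4:12, 4:12] = 0.0
        t = reg.Template(np.pad(np.eye(8), 4), 4, 4)
        frame = np.zeros((16, 16))
        assert reg.correlation_at(t, frame, (0, 0)) == 0.0


class TestParabola:
    @pytest.mark.parametrize("triple,expected", [
        ((0.5, 1.0, 0.5), 0.0),        # symmetric
        ((0.4, 1.0, 0.8), 0.25),       # vertex of the fitted parabola
        ((0.9, 0.9, 0.9), 0.0),        # flat/degenerate contract
    ])
    def test_axis_offsets(self, triple, expected):
        a, b, c = triple
        assert reg.parabola_offset(a, b, c) == pytest.approx(expected)

    def test_five_point_form(self):
        sx, sy = reg.parabola_subpixel(1.0, 0.4, 0.8, 0.5, 0.5)
        assert sx == pytest.approx(0.25)
        assert sy == pytest.approx(0.0)

    @given(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1))
    @settings(max_examples=100, derandomize=True)
    def test_offset_always_in_half_pixel(self, a, b, c):
        assert abs(reg.parabola_offset(a, b, c)) <= 0.5


class TestFullSearch:
    def test_identity_frame(self, blob_template, blob_scene):
        e = reg.full_search_match(blob_template, blob_scene.image, 1, False)
        assert (e.dx, e.dy) == (0, 0)
        assert e.corr == pytest.approx(1.0)

    def test_map_matches_naive_pearson(self, rng):
        """FFT correlation surface equals per-shift Pearson evaluation."""
        for _ in range(5):
            img = rng.normal(50, 10, (32, 32))
            t = reg.Template.from_image(img)
            frame = rng.normal(50, 10, (32, 32))
            cmap = reg.correlation_map(t, frame)
            patch = t.central_patch
            ph, pw = patch.shape
            for dy in range(-t.my, t.my + 1):
                for dx in range(-t.mx, t.mx + 1):
                    win = frame[t.my + dy:t.my + dy + ph,
                                t.mx + dx:t.mx + dx + pw]
                    assert cmap.at(dx, dy) == pytest.approx(
                        naive_pearson(patch, win), abs=1e-6)

    def test_factor_two_recovers_even_shift(self, rng):
        spec = syn.SceneSpec(kind="soma", size=(64, 64), n_structures=4,
                             radius=2.0, noise_sd=0.0, seed=3)
        scene = syn.make_scene(spec)
        t = reg.Template.from_image(scene.image)
        frame = reg.translate(scene.image, (10, -6))
        e = reg.full_search_match(t, frame, factor=2, subpixel=True)
        assert (round(e.total_dx), round(e.total_dy)) == (10, -6)

    def test_exact_recovery_sampled_shifts(self, blob_template, blob_scene):
        for dx, dy in [(-16, -16), (-7, 5), (0, 0), (3, -2), (16, 16)]:
            frame = reg.translate(blob_scene.image, (dx, dy))
            e = reg.full_search_match(blob_template, frame, 1, False)
            assert (e.dx, e.dy) == (dx, dy)


class TestDenseSearch:
    def test_static_frame(self, blob_template, blob_scene):
        e = reg.dense_search(blob_template, blob_scene.image, 0)
        assert (e.dx, e.dy) == (0, 0)

    def test_depth0_equals_full_search(self, rng):
        """Both exhaustive searches agree (same surface, same tie-break)."""
        img = rng.normal(50, 10, (24, 24))
        t = reg.Template.from_image(img)
        for _ in range(5):
            frame = rng.normal(50, 10, (24, 24))
            d = reg.dense_search(t, frame, 0)
            f = reg.full_search_match(t, frame, 1, False)
            assert (d.dx, d.dy) == (f.dx, f.dy)

    def test_recovers_known_shift_with_pyramid(self, rng):
        spec = syn.SceneSpec(kind="soma", size=(64, 64), n_structures=3,
                             radius=2.0, noise_sd=0.0, seed=5)
        scene = syn.make_scene(spec)
        t = reg.Template.from_image(scene.image)
        frame = reg.translate(scene.image, (-7, 5))
        e = reg.dense_search(t, frame, depth=2)
        assert (e.dx, e.dy) == (-7, 5)


class TestHillClimb:
    def test_static_frame(self, blob_template, blob_scene):
        e = reg.hill_climb(blob_template, blob_scene.image)
        assert (e.dx, e.dy) == (0, 0)
        assert e.corr == pytest.approx(1.0)

    def test_unimodal_surface_matches_dense(self):
        spec = syn.SceneSpec(kind="soma", size=(64, 64), n_structures=1,
                             radius=4.0, noise_sd=0.0, seed=2)
        scene = syn.make_scene(spec)
        t = reg.Template.from_image(scene.image)
        frame = reg.translate(scene.image, (3, -2))
        hc = reg.hill_climb(t, frame)
        dn = reg.dense_search(t, frame, 0)
        assert (hc.dx, hc.dy) == (dn.dx, dn.dy) == (3, -2)

    def test_monotonicity(self, blob_template, blob_scene, rng):
        frame = reg.translate(blob_scene.image, (6, 4)) \
            + rng.normal(0, 5, blob_scene.image.shape)
        for init in [(0, 0), (5, -5), (-10, 2)]:
            e = reg.hill_climb(blob_template, frame, init)
            assert e.corr >= reg.correlation_at(blob_template, frame, init) - 1e-12

    def test_bimodal_surface_traps_wrong_basin(self):
        """Two identical blobs create a secondary peak; a bad init stays there."""
        img = np.full((64, 64), 10.0)
        yy, xx = np.mgrid[0:64, 0:64]
        for cy, cx in [(28, 28), (28, 44)]:
            img += 100 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0 ** 2))
        t = reg.Template.from_image(img)
        frame = img  # true shift (0, 0)
        trapped = reg.hill_climb(t, frame, init=(16, 0))  # wrong basin
        truth = reg.full_search_match(t, frame, 1, False)
        assert (truth.dx, truth.dy) == (0, 0)
        assert (trapped.dx, trapped.dy) != (0, 0)
        assert trapped.corr < truth.corr


@pytest.fixture(scope="module")
def smooth_scene():
    spec = syn.SceneSpec(kind="soma", size=(256, 256), n_structures=10,
                         radius=6.0, amplitude=150.0, background=20.0,
                         noise_sd=0.0, seed=2)
    return syn.make_scene(spec)


class TestPyramid:
    def test_depth0_is_plain_hill_climb(self, blob_template, blob_scene):
        frame = reg.translate(blob_scene.image, (2, 1))
        a = reg.pyramid_align(blob_template, frame, 0, "hill_climb")
        b = reg.hill_climb(blob_template, frame, (0, 0))
        assert (a.dx, a.dy, a.corr) == (b.dx, b.dy, b.corr)


    def test_depth4_recovers_large_offset(self, smooth_scene):
        """A 4-layer pyramid reaches a 32-px shift that defeats plain climbing."""
        t = reg.Template.from_image(smooth_scene.image)
        frame = reg.translate(smooth_scene.image, (32, 32))
        e4 = reg.pyramid_align(t, frame, depth=4, base="hill_climb")
        full = reg.full_search_match(t, frame, 1, False)
        assert (full.dx, full.dy) == (32, 32)
        assert (e4.dx, e4.dy) == (32, 32)

    def test_depth0_converges_to_local_maximum(self, smooth_scene):
        t = reg.Template.from_image(smooth_scene.image)
        frame = reg.translate(smooth_scene.image, (32, 32))
        e0 = reg.pyramid_align(t, frame, depth=0, base="hill_climb")
        assert (e0.dx, e0.dy) != (32, 32)

    def test_too_deep_raises(self, blob_template, blob_scene):
        with pytest.raises(ValueError, match="deep"):
            reg.pyramid_align(blob_template, blob_scene.image, depth=5)


class TestSubpixel:
    @pytest.mark.parametrize("frac", [0.25, 0.5, 0.75])
    def test_fractional_shift_recovery(self, frac):
        spec = syn.SceneSpec(kind="soma", size=(96, 96), n_structures=3,
                             radius=4.0, noise_sd=0.0, seed=4)
        scene = syn.make_scene(spec)
        t = reg.Template.from_image(scene.image)
        frame = ndimage.shift(scene.image, (frac, frac), order=1)  # (dy, dx)
        e = reg.full_search_match(t, frame, 1, True)
        assert abs(e.total_dx - frac) <= 0.25
        assert abs(e.total_dy - frac) <= 0.25


class TestApplyShift:
    def test_zero_shift_identity(self, rng):
        f = rng.normal(size=(16, 16))
        assert np.array_equal(reg.apply_shift(f, (0, 0)), f)

    def test_inverse_on_interior(self, rng):
        f = rng.normal(size=(16, 16))
        back = reg.apply_shift(reg.apply_shift(f, (3, 2)), (-3, -2))
        assert np.allclose(back[3:, 3:], f[3:, 3:])

    def test_bilinear_half_pixel_row(self):
        row = np.array([[0.0, 2.0, 0.0]])
        out = reg.apply_shift(row, (0.5, 0.0), mode="bilinear")
        assert out[0, 0] == pytest.approx(1.0)
        assert out[0, 1] == pytest.approx(1.0)

    def test_valid_region(self):
        assert reg.valid_region((16, 16), (3, -2)) == (0, 2, 13, 16)
        assert reg.valid_region((16, 16), (0, 0)) == (0, 0, 16, 16)


class TestTemplateBuilding:
    def test_static_movie(self):
        frame = np.zeros((32, 32))
        frame[10:20, 12:22] = 100.0
        movie = np.repeat(frame[None], 8, axis=0)
        t = reg.build_template(movie)
        assert np.allclose(t.full_image, frame)

    def test_translated_halves_sharpen(self):
        spec = syn.SceneSpec(kind="soma", size=(64, 64), n_structures=4,
                             radius=2.0, noise_sd=0.0, seed=6)
        scene = syn.make_scene(spec)
        second = np.repeat(scene.image[None], 4, axis=0)
        first = np.array([reg.translate(scene.image, (3, 2))] * 4)
        movie = np.concatenate([first, second])
        t = reg.build_template(movie)
        for f in movie:
            e = reg.full_search_match(t, f, 1, False)
            corrected = reg.apply_shift(f, (e.dx, e.dy))
            assert reg.correlation_at(t, corrected, (0, 0)) >= 0.999

    def test_odd_or_tiny_counts_rejected(self):
        with pytest.raises(ValueError):
            reg.build_template(np.zeros((2, 32, 32)))
        with pytest.raises(ValueError):
            reg.build_template(np.zeros((5, 32, 32)))


class TestRegisterMovie:
    def test_static_movie_all_zero_shifts(self, blob_scene):
        movie = np.repeat(blob_scene.image[None], 5, axis=0)
        t = reg.Template.from_image(blob_scene.image)
        shifts, valids = reg.register_movie(
            movie, t, reg.SearchConfig(downscale_factor=1))
        assert all((s.dx, s.dy) == (0, 0) for s in shifts)
        assert all(v == (0, 0, 64, 64) for v in valids)

    def test_known_trajectory_recovered(self, blob_scene):
        traj = [(0, 0), (5, -3), (-8, 8), (16, 16), (-16, -16)]
        movie = np.array([reg.translate(blob_scene.image, s) for s in traj])
        t = reg.Template.from_image(blob_scene.image)
        shifts, _ = reg.register_movie(
            movie, t, reg.SearchConfig(downscale_factor=1, subpixel=False))
        assert [(s.dx, s.dy) for s in shifts] == traj


class TestInvariants:
    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=10, derandomize=True, deadline=None)
    def test_correlations_bounded(self, seed):
        r = np.random.default_rng(seed)
        img = r.normal(100, 20, (24, 24))
        t = reg.Template.from_image(img)
        frame = r.normal(100, 20, (24, 24))
        cmap = reg.correlation_map(t, frame)
        assert np.all(np.isfinite(cmap.values))
        assert cmap.values.min() >= -1.000001
        assert cmap.values.max() <= 1.000001
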