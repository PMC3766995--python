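import numpy as np
import pytest
from scipy import ndimage

from minkograde import (
    area,
    contour_length,
    equalize_histogram,
    euler_characteristic,
    flatten_first_order,
    generate_tissue_image,
    minkowski_curves,
    threshold_level_set,
)
from minkograde.preprocess import GrayImage
from minkograde.synthetic import TextureParams


def euler_labeling_oracle(mask: np.ndarray) -> int:
    """8-connected objects minus 4-connected holes, by two-pass labeling."""
    mask = np.asarray(mask, bool)
    n_obj = ndimage.label(mask, structure=np.ones((3, 3), int))[1]
    bg, n_bg = ndimage.label(
        ~mask, structure=ndimage.generate_binary_structure(2, 1)
    )
    border_labels = set(
        np.unique(
            np.concatenate([bg[0], bg[-1], bg[:, 0], bg[:, -1]])
        )
    ) - {0}
    return n_obj - (n_bg - len(border_labels))


def contour_edge_oracle(mask: np.ndarray) -> int:
    """Brute-force edge enumeration on the background-padded mask."""
    m = np.pad(np.asarray(mask, bool), 1)
    edges = 0
    for r in range(m.shape[0]):
        for c in range(m.shape[1]):
            if r + 1 < m.shape[0] and m[r, c] != m[r + 1, c]:
                edges += 1
            if c + 1 < m.shape[1] and m[r, c] != m[r, c + 1]:
                edges += 1
    return edges


def two_objects_four_holes() -> np.ndarray:
    """Two disjoint 8-connected objects jointly enclosing four holes."""
    img = np.zeros((13, 22), bool)
    img[1:10, 1:10] = True          # block with three 1-px holes
    img[3, 3] = img[3, 7] = img[7, 5] = False
    img[2:9, 13:20] = True          # annulus with one larger hole
    img[4:7, 15:18] = False
    return img


class TestThreshold:
    def test_zero_threshold_is_all_foreground(self, rng):
        img = GrayImage(rng.integers(0, 256, (8, 8)))
        assert threshold_level_set(img, 0).mask.all()

    def test_above_max_is_all_background(self):
        img = GrayImage(np.full((8, 8), 200))
        assert not threshold_level_set(img, 201).mask.any()

    def test_small_example_counts(self):
        img = GrayImage(np.array([[10, 128], [200, 255]]))
        assert threshold_level_set(img, 128).mask.sum() == 3

    def test_out_of_range_threshold_rejected(self):
        img = GrayImage(np.zeros((8, 8), int))
        with pytest.raises(ValueError):
            threshold_level_set(img, 256)


class TestFunctionals:
    def test_area_trivia(self, rng):
        assert area(np.zeros((5, 5), bool)) == 0
        assert area(np.ones((512, 512), bool)) == 262144
        m = rng.random((16, 16)) < 0.5
        assert area(m) == int(m.sum())

    def test_contour_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert contour_length(m) == 4

    def test_contour_filled_square(self):
        m = np.zeros((7, 7), bool)
        m[2:5, 2:5] = True
        assert contour_length(m) == 12

    def test_contour_matches_edge_oracle(self, rng):
        for _ in range(200):
            m = rng.random((16, 16)) < rng.uniform(0.1, 0.9)
            assert contour_length(m) == contour_edge_oracle(m)

    def test_euler_worked_two_objects_four_holes(self):
        assert euler_characteristic(two_objects_four_holes()) == -2

    def test_euler_full_and_empty(self):
        assert euler_characteristic(np.ones((6, 6), bool)) == 1
        assert euler_characteristic(np.zeros((6, 6), bool)) == 0

    def test_euler_rectangle_with_k_isolated_holes(self):
        for k in range(7):
            m = np.ones((9, 17), bool)
            for i in range(k):
                m[3, 2 + 2 * i] = False
            assert euler_characteristic(m) == 1 - k

    @pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
    def test_euler_matches_labeling_oracle_random(self, p):
        rng = np.random.default_rng(int(p * 100))
        for _ in range(150):
            m = rng.random((32, 32)) < p
            assert euler_characteristic(m) == euler_labeling_oracle(m)

    def test_additivity_of_disjoint_patterns(self, rng):
        a = rng.random((10, 10)) < 0.5
        b = rng.random((10, 10)) < 0.5
        combined = np.zeros((10, 24), bool)
        combined[:, :10] = a
        combined[:, 14:] = b  # separated by >= 2 background columns
        assert area(combined) == area(a) + area(b)
        assert contour_length(combined) == contour_length(a) + contour_length(b)
        assert euler_characteristic(combined) == euler_characteristic(
            a
        ) + euler_characteristic(b)


class TestCurves:
    def test_constant_image_steps(self):
        g = 97
        img = GrayImage(np.full((8, 8), g))
        c = minkowski_curves(img, "const")
        t = np.arange(256)
        assert np.array_equal(c.euler, (t <= g).astype(int))
        assert np.array_equal(c.area, np.where(t <= g, 64, 0))

    def test_gradient_image_matches_per_level_recomputation(self):
        vals = np.minimum(np.arange(8) * 36, 255)
        img = GrayImage(np.tile(vals, (8, 1)))
        c = minkowski_curves(img, "grad")
        for t in range(256):
            b = threshold_level_set(img, t)
            assert c.area[t] == area(b)
            assert c.contour_length[t] == contour_length(b)
            assert c.euler[t] == euler_characteristic(b)

    def test_random_image_matches_per_level_recomputation(self, rng):
        img = GrayImage(rng.integers(0, 256, (24, 24)))
        c = minkowski_curves(img, "rand")
        for t in range(0, 256, 7):
            b = threshold_level_set(img, t)
            assert c.area[t] == area(b)
            assert c.contour_length[t] == contour_length(b)
            assert c.euler[t] == euler_characteristic(b)

    def test_curve_invariants(self, rng):
        img = GrayImage(rng.integers(0, 256, (16, 16)))
        c = minkowski_curves(img, "inv")
        assert c.area[0] == 256
        assert c.euler[0] == 1
        assert c.contour_length[0] == 2 * (16 + 16)
        assert np.all(np.diff(c.area) <= 0)

    def test_grade_ii_texture_has_sigmoid_euler_curve(self):
        params = TextureParams.for_grade("gradeII", image_size=128, seed=11)
        hm = generate_tissue_image(params)
        gray = equalize_histogram(flatten_first_order(hm))
        c = minkowski_curves(gray, "II")
        assert c.euler.min() < 0 < c.euler.max()
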