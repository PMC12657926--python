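"""Image -> BDM -> normalized BDM -> thresholded pixel graph."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from PIL import Image

from braingraph import image_graph as ig


@pytest.fixture
def png_rgb(tmp_path):
    def _write(pixels, name="img.png"):
        arr = np.asarray(pixels, dtype=np.uint8)
        path = tmp_path / name
        Image.fromarray(arr).save(path)
        return path

    return _write


class TestLoadGrayscale:
    def test_grayscale_passthrough(self, png_rgb):
        path = png_rgb(np.full((2, 2), 100, dtype=np.uint8))
        img = ig.load_grayscale(path)
        assert img.shape == (2, 2)
        np.testing.assert_allclose(img, 100.0)

    def test_luma_white_and_red(self, png_rgb):
        rgb = np.zeros((2, 2, 3), dtype=np.uint8)
        rgb[0, 0] = (255, 255, 255)
        rgb[0, 1] = (255, 0, 0)
        img = ig.load_grayscale(png_rgb(rgb))
        assert img[0, 0] == pytest.approx(255.0)
        assert img[0, 1] == pytest.approx(0.299 * 255, abs=0.5)  # 76.245

    def test_bad_weights_rejected(self, png_rgb):
        path = png_rgb(np.zeros((2, 2), dtype=np.uint8))
        with pytest.raises(ValueError, match="sum"):
            ig.load_grayscale(path, luma_weights=(0.5, 0.5, 0.5))

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ig.load_grayscale(tmp_path / "nope.png")


class TestDownsample:
    def test_constant_block_mean(self):
        out = ig.downsample(np.full((4, 4), 50.0), 2, 2)
        np.testing.assert_allclose(out, 50.0)
        assert out.shape == (2, 2)

    def test_full_collapse_is_arithmetic_mean(self):
        out = ig.downsample(np.array([[0.0, 255.0], [0.0, 255.0]]), 1, 1)
        assert out[0, 0] == pytest.approx(127.5)

    def test_shape_contract_176x208_to_32x32(self):
        out = ig.downsample(np.zeros((176, 208)), 32, 32)
        assert out.shape == (32, 32)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            ig.downsample(np.zeros((4, 4)), 8, 8)

    def test_noop_when_sizes_match(self):
        img = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(ig.downsample(img, 4, 4), img)


class TestBDM:
    def test_1x3_rows(self):
        L = ig.compute_bdm(np.array([[0.0, 128.0, 255.0]]))
        np.testing.assert_allclose(
            L, [[0, 128, 255], [128, 0, 127], [255, 127, 0]]
        )

    def test_1x2_pair(self):
        L = ig.compute_bdm(np.array([[10.0, 200.0]]))
        assert L[0, 1] == 190.0

    def test_values_and_symmetry(self):
        img = np.array([[0.0, 128.0], [255.0, 10.0]])
        L = ig.compute_bdm(img)
        expected = np.abs(
            np.array([0.0, 128.0, 255.0, 10.0])[:, None]
            - np.array([0.0, 128.0, 255.0, 10.0])[None, :]
        )
        np.testing.assert_allclose(L, expected)
        assert L[0, 1] == 128.0 and L[0, 2] == 255.0

    def test_constant_image_all_zero(self):
        L = ig.compute_bdm(np.full((3, 3), 42.0))
        np.testing.assert_allclose(L, 0.0)

    def test_bdm_properties_random_images(self, rng):
        for _ in range(10):
            img = rng.uniform(0, 255, size=(5, 4))
            L = ig.compute_bdm(img)
            np.testing.assert_allclose(L, L.T)
            np.testing.assert_allclose(np.diag(L), 0.0)
            assert (L >= 0).all()


class TestNormalizeBDM:
    def test_midpoint_value(self):
        img = np.array([[0.0, 128.0], [255.0, 0.0]])
        Ln = ig.normalize_bdm(ig.compute_bdm(img))
        assert Ln[0, 1] == pytest.approx(128.0 / 255.0)
        assert Ln.max() == pytest.approx(1.0)
        assert Ln.min() == 0.0

    def test_degenerate_constant_image(self, caplog):
        Ln = ig.normalize_bdm(ig.compute_bdm(np.full((2, 2), 7.0)))
        np.testing.assert_allclose(Ln, 0.0)

    def test_range_on_random_images(self, rng):
        for _ in range(10):
            img = rng.uniform(0, 255, size=(4, 4))
            Ln = ig.normalize_bdm(ig.compute_bdm(img))
            assert Ln.min() >= 0.0 and Ln.max() <= 1.0
            assert Ln.max() == pytest.approx(1.0)


class TestThreshold:
    def test_1x3_image_single_edge(self):
        Ln = ig.normalize_bdm(ig.compute_bdm(np.array([[0.0, 128.0, 255.0]])))
        g = ig.threshold_adjacency(Ln, 0.5)
        # |128-255| = 127 -> 1 - 127/255 = 0.502 >= 0.5: the only edge
        assert set(map(frozenset, g.edges())) == {frozenset({1, 2})}

    def test_tau_zero_complete(self, rng):
        img = rng.uniform(0, 255, size=(3, 3))
        g = ig.threshold_adjacency(ig.normalize_bdm(ig.compute_bdm(img)), 0.0)
        assert g.number_of_edges() == 9 * 8 // 2

    def test_constant_image_tau_one_complete(self):
        img = np.full((3, 3), 5.0)
        g = ig.threshold_adjacency(ig.normalize_bdm(ig.compute_bdm(img)), 1.0)
        assert g.number_of_edges() == 9 * 8 // 2
        assert nx.number_of_selfloops(g) == 0

    def test_tau_out_of_range(self):
        with pytest.raises(ValueError, match="tau"):
            ig.threshold_adjacency(np.zeros((4, 4)), 1.5)

    def test_edge_count_monotone_in_tau(self, rng):
        for _ in range(20):
            img = rng.uniform(0, 255, size=(4, 4))
            Ln = ig.normalize_bdm(ig.compute_bdm(img))
            counts = [
                ig.threshold_adjacency(Ln, t).number_of_edges()
                for t in np.linspace(0, 1, 11)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    arrays(
        dtype=float,
        shape=st.tuples(st.integers(2, 6), st.integers(2, 6)),
        elements=st.floats(0, 255, allow_nan=False),
    ),
    st.floats(0, 1),
)
def test_bdm_chain_invariants_property(img, tau):
    """For any image and threshold: BDM symmetric with zero diagonal,
    normalized entries in [0, 1], and the graph simple with edges exactly
    where the similarity rule says."""
    L = ig.compute_bdm(img)
    assert np.array_equal(L, L.T) and np.all(np.diag(L) == 0)
    Ln = ig.normalize_bdm(L)
    assert Ln.min() >= 0.0 and Ln.max() <= 1.0
    g = ig.threshold_adjacency(Ln, tau)
    assert nx.number_of_selfloops(g) == 0
    mn = img.size
    expected = int(np.count_nonzero(np.triu(1 - Ln >= tau, 1)))
    assert g.number_of_edges() == expected
    assert g.number_of_nodes() == mn


class TestLargestComponent:
    def test_connected_identity(self):
        g = nx.path_graph(5)
        assert set(ig.largest_component(g)) == set(g)

    def test_size_wins(self):
        g = nx.Graph()
        nx.add_path(g, range(5))
        nx.add_path(g, range(10, 13))
        assert set(ig.largest_component(g)) == set(range(5))

    def test_tie_broken_by_smallest_vertex(self):
        g = nx.Graph()
        nx.add_path(g, [4, 5, 6, 7])
        nx.add_path(g, [0, 1, 2, 3])
        assert set(ig.largest_component(g)) == {0, 1, 2, 3}

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ig.largest_component(nx.Graph())


class TestIndexingAndIO:
    def test_pixel_index_roundtrip(self):
        for n_cols in (3, 7):
            for idx in range(2 * n_cols):
                r, c = ig.pixel_coords(idx, n_cols)
                assert ig.pixel_index(r, c, n_cols) == idx

    def test_edgelist_roundtrip(self, tmp_path):
        g = nx.gnp_random_graph(10, 0.4, seed=1)
        path = tmp_path / "g.edgelist"
        ig.write_edgelist(g, path)
        g2 = ig.read_edgelist(path)
        assert set(map(frozenset, g.edges())) == set(map(frozenset, g2.edges()))
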