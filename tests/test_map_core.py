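import numpy as np
import pytest
from hypothesis import given, strategies as st

from cyclomap.map_core import (
    AtomicModel,
    Image2D,
    MapFormatError,
    VoxelGrid,
    flip_hand,
    low_pass_filter,
    read_mrc,
    read_structure,
    resolution_at_nyquist_fraction,
    write_mrc,
)
from cyclomap.symminit import soft_cylinder

from oracles import shell_power_beyond


class TestTypes:
    def test_voxel_grid_rejects_nonfinite(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            VoxelGrid(data, 1.0)

    def test_voxel_grid_rejects_bad_voxel_size(self):
        with pytest.raises(ValueError):
            VoxelGrid(np.zeros((4, 4, 4)), -1.0)

    def test_image_requires_2d(self):
        with pytest.raises(ValueError):
            Image2D(np.zeros((4, 4, 4)), 1.0)

    def test_pad_to_cube(self):
        grid = VoxelGrid(np.ones((4, 6, 6)), 1.0)
        cube = grid.pad_to_cube()
        assert cube.shape == (6, 6, 6)
        assert cube.data.sum() == pytest.approx(grid.data.sum())

    def test_atomic_model_selection(self):
        model = AtomicModel(
            np.array(["C", "N", "O"]), np.array([12.0, 14.0, 16.0]),
            np.zeros((3, 3)) + np.arange(3)[:, None],
            chain_ids=np.array(["A", "A", "B"]),
            res_ids=np.array([1, 2, 5]))
        sel = model.select(chain="A")
        assert len(sel) == 2
        sel = model.select(residue_range=(2, 5))
        assert len(sel) == 2
        with pytest.raises(ValueError):
            model.select(chain="Z")


class TestMrcIO:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((16, 16, 16)).astype(np.float32)
        grid = VoxelGrid(data, 1.8)
        path = tmp_path / "g.mrc"
        write_mrc(grid, path)
        back = read_mrc(path)
        assert isinstance(back, VoxelGrid)
        np.testing.assert_array_equal(back.data, data.astype(np.float64))
        assert back.voxel_size == pytest.approx(1.8, abs=1e-6)

    def test_full_size_box_reports_pixel_size(self, tmp_path):
        # the acquisition box: 224 voxels at 1.8 A/voxel
        grid = VoxelGrid(np.zeros((224, 224, 224), dtype=np.float32), 1.8)
        path = tmp_path / "box224.mrc"
        write_mrc(grid, path)
        back = read_mrc(path)
        assert back.shape == (224, 224, 224)
        assert back.voxel_size == pytest.approx(1.8, abs=1e-6)

    def test_non_square_image_rejected(self, tmp_path):
        import mrcfile
        path = tmp_path / "bad.mrc"
        with mrcfile.new(path, overwrite=True) as mrc:
            mrc.set_data(np.zeros((1, 8, 16), dtype=np.float32))
            mrc.voxel_size = 1.0
        with pytest.raises(MapFormatError):
            read_mrc(path)

    def test_image_round_trip_nz1(self, tmp_path):
        img = Image2D(np.arange(64, dtype=np.float32).reshape(8, 8), 2.5)
        path = tmp_path / "img.mrc"
        write_mrc(img, path)
        back = read_mrc(path)
        assert isinstance(back, Image2D)
        np.testing.assert_array_equal(back.data, img.data)
        assert back.pixel_size == pytest.approx(2.5, abs=1e-6)

    def test_nonfinite_write_rejected(self, tmp_path):
        grid = VoxelGrid(np.zeros((4, 4, 4)), 1.0)
        grid.data[0, 0, 0] = np.inf  # bypass constructor check
        with pytest.raises(ValueError):
            write_mrc(grid, tmp_path / "x.mrc")

    def test_non_cubic_rejected_unless_padded(self, tmp_path):
        import mrcfile
        path = tmp_path / "rect.mrc"
        with mrcfile.new(path, overwrite=True) as mrc:
            mrc.set_data(np.zeros((4, 8, 8), dtype=np.float32))
            mrc.voxel_size = 1.0
        with pytest.raises(MapFormatError):
            read_mrc(path)
        padded = read_mrc(path, pad_non_cubic=True)
        assert padded.shape == (8, 8, 8)


class TestReadStructure:
    def test_residue_range(self, tiny_pdb):
        model = read_structure(tiny_pdb, residue_range=(1, 219))
        assert np.all(model.res_ids <= 219)
        assert len(model) == 10  # 12 heavy atoms, 2 beyond residue 219

    def test_no_chain_filter_returns_all(self, tiny_pdb):
        model = read_structure(tiny_pdb)
        assert len(model) == 12  # hydrogens dropped by default
        assert set(model.chain_ids) == {"A", "B"}

    def test_hydrogens_kept_on_request(self, tiny_pdb):
        model = read_structure(tiny_pdb, drop_hydrogens=False)
        assert len(model) == 13

    def test_selenium_weight_assigned(self, tiny_pdb):
        model = read_structure(tiny_pdb)
        se = model.weights[model.elements == "SE"]
        assert se[0] == pytest.approx(78.971)

    def test_empty_selection_errors(self, tiny_pdb):
        with pytest.raises(ValueError):
            read_structure(tiny_pdb, chain="Q")

    def test_unknown_element_falls_back(self):
        from cyclomap.map_core import _weight_for_element
        with pytest.warns(UserWarning):
            weight = _weight_for_element("CX")
        assert weight == pytest.approx(12.011)


class TestResolutionArithmetic:
    def test_quarter_nyquist_at_1p8(self):
        assert resolution_at_nyquist_fraction(1.8, 0.25) == 14.4

    def test_full_nyquist(self):
        assert resolution_at_nyquist_fraction(1.8, 1.0) == pytest.approx(3.6)

    def test_half_nyquist_other_pixel(self):
        assert resolution_at_nyquist_fraction(1.42, 0.5) == pytest.approx(5.68)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_domain_errors(self, fraction):
        with pytest.raises(ValueError):
            resolution_at_nyquist_fraction(1.8, fraction)

    @given(pixel=st.floats(0.5, 5.0),
           f1=st.floats(0.05, 1.0), f2=st.floats(0.05, 1.0))
    def test_monotone_decreasing_in_fraction(self, pixel, f1, f2):
        lo, hi = sorted([f1, f2])
        assert (resolution_at_nyquist_fraction(pixel, lo)
                >= resolution_at_nyquist_fraction(pixel, hi))

    @given(pixel=st.floats(0.5, 5.0), scale=st.floats(0.5, 4.0),
           fraction=st.floats(0.05, 1.0))
    def test_linear_in_pixel_size(self, pixel, scale, fraction):
        a = resolution_at_nyquist_fraction(pixel, fraction)
        b = resolution_at_nyquist_fraction(pixel * scale, fraction)
        assert b == pytest.approx(a * scale, rel=1e-9)


class TestLowPassFilter:
    def test_constant_unchanged(self):
        grid = VoxelGrid(np.full((32, 32, 32), 3.7), 2.0)
        out = low_pass_filter(grid, 50.0)
        np.testing.assert_allclose(out.data, grid.data, atol=1e-12)

    def test_power_beyond_cutoff_suppressed(self):
        rng = np.random.default_rng(1)
        grid = VoxelGrid(rng.standard_normal((32, 32, 32)), 2.0)
        cutoff, edge = 16.0, 3.0
        out = low_pass_filter(grid, cutoff, edge_width=edge)
        total_in = shell_power_beyond(grid.data, 2.0, cutoff)
        # effective cutoff including the cosine edge
        n = 32
        r_edge_px = n * 2.0 / cutoff + edge
        eff_cutoff = n * 2.0 / r_edge_px
        remaining = shell_power_beyond(out.data, 2.0, eff_cutoff)
        assert remaining < 1e-10 * total_in

    def test_idempotent_up_to_edge(self, smooth_symmetric_phantom):
        # outside the raised-cosine edge band the mask is exactly 0 or 1,
        # so a second pass must leave those frequencies untouched
        from cyclomap.map_core import _radial_freq_pixels
        grid, _ = smooth_symmetric_phantom
        cutoff, edge = 40.0, 3.0
        once = low_pass_filter(grid, cutoff, edge_width=edge)
        twice = low_pass_filter(once, cutoff, edge_width=edge)
        diff = np.fft.fftn(twice.data) - np.fft.fftn(once.data)
        r = _radial_freq_pixels(grid.data.shape)
        r_cut = grid.data.shape[0] * grid.voxel_size / cutoff
        outside_edge = (r <= r_cut) | (r > r_cut + edge)
        ref = np.sqrt(np.mean(np.abs(np.fft.fftn(once.data)) ** 2))
        rms = np.sqrt(np.mean(np.abs(diff[outside_edge]) ** 2))
        assert rms < 1e-6 * ref
        # and the edge-band change is bounded by the edge-band content
        edge_power = np.sqrt(np.mean(np.abs(np.fft.fftn(once.data)[~outside_edge]) ** 2))
        assert np.sqrt(np.mean(np.abs(diff[~outside_edge]) ** 2)) <= edge_power

    def test_mean_preserved_exactly(self):
        rng = np.random.default_rng(2)
        grid = VoxelGrid(rng.standard_normal((24, 24, 24)), 1.5)
        out = low_pass_filter(grid, 20.0)
        assert out.data.mean() == pytest.approx(grid.data.mean(), abs=1e-12)

    def test_cutoff_below_nyquist_rejected(self):
        grid = VoxelGrid(np.zeros((16, 16, 16)), 2.0)
        with pytest.raises(ValueError):
            low_pass_filter(grid, 3.0)

    def test_works_on_images(self):
        img = Image2D(np.random.default_rng(3).standard_normal((32, 32)), 2.0)
        out = low_pass_filter(img, 16.0)
        assert isinstance(out, Image2D)
        assert out.data.mean() == pytest.approx(img.data.mean(), abs=1e-12)


class TestFlipHand:
    def test_involution(self):
        rng = np.random.default_rng(4)
        grid = VoxelGrid(rng.standard_normal((16, 16, 16)), 1.0)
        back = flip_hand(flip_hand(grid))
        np.testing.assert_array_equal(back.data, grid.data)

    def test_achiral_cylinder_invariant(self):
        grid = soft_cylinder(40.0, 24.0, 32, 2.0, edge_width=8.0)
        flipped = flip_hand(grid)
        assert np.abs(flipped.data - grid.data).max() < 1e-9

    def test_lockwasher_rise_sign_flips(self):
        # chirality via the lock-washer metric: mirroring x reverses the
        # sign of the gap-pair axial difference
        from cyclomap.conformation import ring_geometry
        from cyclomap.synthetic_data import PhantomSpec, hexamer_ground_truth
        truth = hexamer_ground_truth(
            PhantomSpec(conformation="lockwasher", opening_angle=81.0,
                        total_rise=20.0))
        anchors = truth["anchors"]
        mirrored = anchors * np.array([-1.0, 1.0, 1.0])
        g1 = ring_geometry(anchors)
        g2 = ring_geometry(mirrored)
        assert g2.gap_axial_difference == pytest.approx(
            -g1.gap_axial_difference, abs=1e-6)
        assert g2.opening_angle == pytest.approx(g1.opening_angle, abs=1e-6)
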