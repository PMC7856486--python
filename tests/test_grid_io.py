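"""Dose-grid data model, DQA-GRID file round trips, resampling, profiles."""

import datetime

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

import protondqa as pq
from protondqa.grid_io import GridParseError


def make_grid(values, spacing=7.6, **kw):
    return pq.DoseGrid(values=np.asarray(values, float), spacing_mm=spacing, **kw)


class TestDoseGrid:
    def test_coordinate_convention(self):
        g = make_grid(np.zeros((32, 32)), spacing=7.6)
        xs = g.x_coords()
        assert xs[0] == pytest.approx(-117.8)
        assert xs[-1] == pytest.approx(117.8)
        ys = g.y_coords()
        assert ys[0] == pytest.approx(117.8)  # row 0 = largest y
        assert ys[-1] == pytest.approx(-117.8)

    def test_index_coordinate_involution(self):
        g = make_grid(np.zeros((5, 7)), spacing=2.5)
        xs, ys = g.x_coords(), g.y_coords()
        for i in range(g.rows):
            for j in range(g.cols):
                assert g.index_of(xs[j], ys[i]) == (i, j)

    @pytest.mark.parametrize(
        "values,spacing",
        [
            (np.zeros((1, 5)), 1.0),  # too few rows
            (np.ones((3, 3)), 0.0),  # non-positive spacing
            (-np.ones((3, 3)), 1.0),  # negative dose
            (np.full((3, 3), np.nan), 1.0),  # non-finite dose
        ],
    )
    def test_invalid_grids_rejected(self, values, spacing):
        with pytest.raises(ValueError):
            pq.DoseGrid(values=values, spacing_mm=spacing)


class TestFileRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(7)
        g = make_grid(rng.random((6, 4)), spacing=7.6, room="TR2",
                      date=datetime.date(2024, 5, 1), interpolated=True)
        path = tmp_path / "g.grid"
        pq.write_grid(g, path)
        g2 = pq.read_grid(path)
        assert np.array_equal(g.values, g2.values)  # bit-equal doses
        assert g2.spacing_mm == g.spacing_mm
        assert g2.room == "TR2"
        assert g2.date == g.date
        assert g2.interpolated is True

    @settings(max_examples=25, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(
        rows=st.integers(2, 12),
        cols=st.integers(2, 12),
        spacing=st.floats(0.1, 20, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_property(self, tmp_path, rows, cols, spacing, seed):
        rng = np.random.default_rng(seed)
        g = make_grid(rng.random((rows, cols)) * 3, spacing=spacing)
        path = tmp_path / f"p{seed}.grid"
        pq.write_grid(g, path)
        g2 = pq.read_grid(path)
        assert np.array_equal(g.values, g2.values)
        assert g2.spacing_mm == g.spacing_mm

    def test_written_matrix_shape(self, tmp_path):
        path = tmp_path / "t.grid"
        pq.write_grid(make_grid([[0.0, 1.0], [2.0, 3.0]], spacing=1.0), path)
        lines = path.read_text().splitlines()
        matrix = [l for l in lines if not l.startswith("#") and ":" not in l]
        assert len(matrix) == 2
        assert all(len(l.split()) == 2 for l in matrix)
        assert f"spacing_mm: {1.0!r}" in lines

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda t: t.replace("rows: 2\n", ""),  # missing header
            lambda t: t.replace("# DQA-GRID v1", "# OTHER v9"),  # bad magic
            lambda t: t.replace("units: Gy", "units: cGy"),  # wrong units
            lambda t: t.replace("2.0 3.0", "2.0 oops"),  # non-numeric cell
            lambda t: t.replace("2.0 3.0", "2.0"),  # short row
        ],
    )
    def test_malformed_files_rejected(self, tmp_path, mutate):
        path = tmp_path / "t.grid"
        pq.write_grid(make_grid([[0.0, 1.0], [2.0, 3.0]], spacing=1.0), path)
        path.write_text(mutate(path.read_text()))
        with pytest.raises(GridParseError):
            pq.read_grid(path)


class TestResample:
    def test_identity_on_odd_grid(self):
        rng = np.random.default_rng(3)
        g = make_grid(rng.random((9, 9)), spacing=7.6)
        r = pq.resample(g, 7.6)
        assert np.allclose(r.values, g.values)
        assert not r.interpolated

    def test_affine_field_reproduced_exactly(self):
        # bilinear interpolation is exact on dose(x, y) = a + b x + c y
        g0 = make_grid(np.zeros((9, 9)), spacing=7.6)
        X, Y = np.meshgrid(g0.x_coords(), g0.y_coords())
        g = make_grid(2.0 + 0.01 * X + 0.005 * Y, spacing=7.6)
        for new in (1.0, 2.5, 7.6):
            r = pq.resample(g, new)
            RX, RY = np.meshgrid(r.x_coords(), r.y_coords())
            assert np.allclose(r.values, 2.0 + 0.01 * RX + 0.005 * RY, atol=1e-12)

    def test_gaussian_interp_error_shrinks_with_native_pitch(self):
        # the 4% curvature-per-pitch^2 of a sigma=6 mm Gaussian makes
        # bilinear 7.6->1 mm resampling err by ~10% of amplitude at the
        # cell midpoints; at 2 mm native pitch the same field interpolates
        # to better than 1%
        sigma = 6.0

        def max_err(pitch, n):
            c = (np.arange(n) - (n - 1) / 2) * pitch
            X, Y = np.meshgrid(c, c[::-1])
            g = make_grid(np.exp(-0.5 * (X**2 + Y**2) / sigma**2), spacing=pitch)
            r = pq.resample(g, 1.0)
            RX, RY = np.meshgrid(r.x_coords(), r.y_coords())
            return np.abs(
                r.values - np.exp(-0.5 * (RX**2 + RY**2) / sigma**2)
            ).max()

        coarse = max_err(7.6, 9)
        fine = max_err(2.0, 31)
        assert fine < 0.03
        assert 0.05 < coarse < 0.20
        assert fine < coarse / 4

    def test_interpolated_flag_and_extent(self):
        g = make_grid(np.random.default_rng(0).random((9, 9)), spacing=7.6)
        r = pq.resample(g, 1.0)
        assert r.interpolated
        # no extrapolation beyond the outermost native centers
        assert r.x_coords()[-1] <= g.x_coords()[-1] + 1e-9
        # new lattice keeps a pixel exactly on the grid center
        assert 0.0 in r.x_coords()

    def test_spacing_larger_than_extent_rejected(self):
        g = make_grid(np.ones((3, 3)), spacing=1.0)
        with pytest.raises(ValueError):
            pq.resample(g, 50.0)


class TestExtractRoi:
    def test_full_extent_is_identity(self):
        g = make_grid(np.random.default_rng(1).random((8, 8)), spacing=7.6)
        roi = pq.extract_roi(g, 0, 0, (g.cols - 1) / 2 * 7.6, (g.rows - 1) / 2 * 7.6)
        assert np.array_equal(roi.values, g.values)

    def test_pixel_count_closed_interval(self):
        # 1 mm grid with a center pixel: [-15, +15] holds 31 centers
        g = make_grid(np.ones((41, 41)), spacing=1.0)
        roi = pq.extract_roi(g, 0, 0, 15, 15)
        assert roi.values.shape == (31, 31)
        assert roi.center_x == pytest.approx(0.0)

    def test_roi_coordinates_preserved(self):
        g = make_grid(np.arange(64.0).reshape(8, 8), spacing=7.6)
        roi = pq.extract_roi(g, 10, -10, 12, 12)
        assert set(np.round(roi.x_coords(), 9)) <= set(np.round(g.x_coords(), 9))
        i, j = g.index_of(roi.x_coords()[0], roi.y_coords()[0])
        assert roi.values[0, 0] == g.values[i, j]

    def test_wholly_outside_rejected(self):
        g = make_grid(np.ones((8, 8)), spacing=7.6)
        with pytest.raises(ValueError):
            pq.extract_roi(g, 500, 0, 10, 10)

    def test_partial_overlap_clips_or_raises(self):
        g = make_grid(np.ones((8, 8)), spacing=7.6)
        with pytest.raises(ValueError):
            pq.extract_roi(g, 25, 0, 10, 10, require_complete=True)
        with pytest.warns(UserWarning):
            roi = pq.extract_roi(g, 25, 0, 10, 10)
        assert roi.clipped


class TestCentralProfiles:
    def test_uniform_grid_constant_profiles(self):
        g = make_grid(np.full((9, 9), 2.5), spacing=7.6)
        px, py = pq.central_profiles(g, 0, 0)
        assert np.allclose(px.doses, 2.5)
        assert np.allclose(py.doses, 2.5)

    def test_offset_within_half_pixel(self):
        g = make_grid(np.ones((8, 8)), spacing=7.6)
        px, py = pq.central_profiles(g, 1.0, -2.0)
        assert abs(px.offset - (-2.0)) <= 7.6 / 2
        assert abs(py.offset - 1.0) <= 7.6 / 2

    def test_analytic_ramp(self):
        g0 = make_grid(np.zeros((9, 9)), spacing=2.0)
        X, _ = np.meshgrid(g0.x_coords(), g0.y_coords())
        g = make_grid(np.clip(X, 0, None), spacing=2.0)
        px, _ = pq.central_profiles(g, 0, 0)
        assert np.allclose(px.doses, np.clip(px.positions, 0, None))

    def test_center_outside_rejected(self):
        g = make_grid(np.ones((8, 8)), spacing=7.6)
        with pytest.raises(ValueError):
            pq.central_profiles(g, 500, 0)
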