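"""Space-time field container, NetCDF round trips and tower CSV parsing."""

import numpy as np
import pytest

from eoflux import (
    FormatError,
    SpaceTimeField,
    TowerRecord,
    ValidationError,
    read_field,
    read_towers,
    write_field,
    write_towers,
)


class TestSpaceTimeField:
    def test_invariants_enforced(self, rng):
        values = rng.normal(size=(6, 4))
        mask = np.zeros((6, 4), dtype=bool)
        times = np.arange(4, dtype=float)
        with pytest.raises(ValidationError):
            SpaceTimeField(values, mask, grid_shape=(2, 2), times=times)
        with pytest.raises(ValidationError):
            SpaceTimeField(values, mask[:, :3], grid_shape=(2, 3), times=times)
        with pytest.raises(ValidationError):
            SpaceTimeField(values, mask, grid_shape=(2, 3),
                           times=np.array([0.0, 2.0, 1.0, 3.0]))
        bad = values.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValidationError):
            SpaceTimeField(bad, mask, grid_shape=(2, 3), times=times)

    def test_nan_allowed_under_mask(self, rng):
        values = rng.normal(size=(4, 3))
        values[1, 2] = np.inf
        mask = np.zeros((4, 3), dtype=bool)
        mask[1, 2] = True
        f = SpaceTimeField(values, mask, grid_shape=(2, 2),
                           times=np.arange(3, dtype=float))
        assert f.mask[1, 2]

    def test_cube_round_trip_is_row_major_from_northwest(self):
        # pixel p = r*cols + c: value encodes (r, c, t) to pin the layout
        rows, cols, n = 2, 3, 2
        values = np.array([[100 * (p // cols) + 10 * (p % cols) + t
                            for t in range(n)] for p in range(rows * cols)],
                          dtype=float)
        f = SpaceTimeField(values, np.zeros_like(values, dtype=bool),
                           grid_shape=(rows, cols), times=np.arange(n, dtype=float))
        cube = f.to_cube()
        assert cube[1, 0, 2] == values[2, 1]  # t=1, r=0, c=2 -> pixel 2
        back = SpaceTimeField.from_cube(cube, times=f.times)
        np.testing.assert_array_equal(back.values, values)


class TestNetCDFRoundTrip:
    def test_round_trip_identity(self, tmp_path, rng):
        values = rng.normal(60.0, 15.0, size=(12, 7))
        mask = rng.random((12, 7)) < 0.2
        mask[:, 0] = False  # keep every column observed somewhere
        times = np.datetime64("2005-01-01") + 8 * np.arange(7).astype("timedelta64[D]")
        f = SpaceTimeField(values, mask, grid_shape=(3, 4), times=times)
        path = tmp_path / "field.nc"
        write_field(f, path)
        g = read_field(path)
        np.testing.assert_array_equal(g.mask, f.mask)
        np.testing.assert_allclose(g.values[~f.mask], f.values[~f.mask], rtol=1e-12)
        assert g.grid_shape == f.grid_shape
        np.testing.assert_array_equal(g.times, f.times)

    def test_mask_marks_exactly_the_fill_entries(self, tmp_path, rng):
        P, N = 20, 10
        values = rng.normal(50, 5, size=(P, N))
        mask = np.zeros((P, N), dtype=bool)
        idx = rng.choice(P * N, size=P * N // 10, replace=False)  # 10% fill
        mask.ravel()[idx] = True
        f = SpaceTimeField(values, mask, grid_shape=(4, 5),
                           times=np.arange(N, dtype=float))
        path = tmp_path / "gappy.nc"
        write_field(f, path)
        g = read_field(path)
        # independent scan of the raw variable for fill values
        import xarray as xr
        with xr.open_dataset(path, engine="scipy", mask_and_scale=False) as ds:
            n_fill = int((ds["LE"].values == -9999.0).sum())
        assert n_fill == P * N // 10
        assert g.mask.sum() == P * N // 10

    def test_missing_variable_is_format_error(self, tmp_path, small_field):
        path = tmp_path / "f.nc"
        write_field(small_field, path, variable_name="LE")
        with pytest.raises(FormatError, match="ET"):
            read_field(path, variable_name="ET")


class TestTowers:
    def _write(self, tmp_path, rows, header="time,Rn,G,H,LE,biome"):
        path = tmp_path / "towers.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_well_formed_rows(self, tmp_path):
        path = self._write(tmp_path, [
            "2005-01-01,100,10,40,40,CRO",
            "2005-01-02,110,11,42,45,GRA",
            "2005-01-03,90,9,30,35,ENF",
        ])
        records = read_towers(path)
        assert len(records) == 3
        assert records[0].biome == "CRO"
        assert records[0].LE_ori == 40.0
        assert not any(r.incomplete for r in records)

    def test_missing_energy_term_flagged_not_dropped(self, tmp_path):
        path = self._write(tmp_path, [
            "2005-01-01,100,,40,40,CRO",
            "2005-01-02,110,11,42,45,GRA",
        ])
        records = read_towers(path)
        assert len(records) == 2
        assert records[0].incomplete and not records[1].incomplete

    def test_unknown_biome_raises_naming_row(self, tmp_path):
        path = self._write(tmp_path, [
            "2005-01-01,100,10,40,40,CRO",
            "2005-01-02,110,11,42,45,XYZ",
        ])
        with pytest.raises(ValidationError, match="row 1"):
            read_towers(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = self._write(tmp_path, ["2005-01-01,100,10,40,CRO"],
                           header="time,Rn,G,H,biome")
        with pytest.raises(FormatError, match="LE"):
            read_towers(path)

    def test_round_trip(self, tmp_path):
        records = [TowerRecord(time="2005-01-01", Rn=100.0, G=10.0,
                               H_ori=40.0, LE_ori=40.0, biome="CRO",
                               row=3, col=4)]
        path = tmp_path / "out.csv"
        write_towers(records, path)
        back = read_towers(path)
        assert back[0].Rn == 100.0 and back[0].row == 3 and back[0].col == 4
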