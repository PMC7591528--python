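"""Gridded simulation tests: grid/scalar equivalence, biome parameter
application, annual aggregation rules, and the product file contract."""

import numpy as np
import pytest

from ptjplfuse.forcing_io import ForcingFields, GridSpec, LANDCOVER_CODES
from ptjplfuse.gridrun import (
    AnnualProduct,
    aggregate_annual,
    build_lut,
    read_product,
    run_grid,
    tet_8day,
    write_dataset,
)
from ptjplfuse.ptjpl import default_biome_params, ptjpl_fluxes, wm2_to_mm


def _single_cell_forcing(biome="forest", years=(2001,)):
    grid = GridSpec(30.0, 30.05, 100.0, 100.05, 0.05)
    n = 46 * len(years)
    shape = (n, 1, 1)
    lc = np.full((1, 1), LANDCOVER_CODES[biome])
    doy = np.arange(n) * 8.0 + 4.0
    season = np.cos(2 * np.pi * (doy % 368 - 200) / 365.0)
    return ForcingFields(
        grid=grid,
        years=years,
        lai=(1.5 + 1.4 * season).reshape(shape),
        rn=(120.0 + 70.0 * season).reshape(shape),
        ta=(12.0 + 11.0 * season).reshape(shape),
        rh=np.clip(0.6 - 0.1 * season, 0.2, 1.0).reshape(shape),
        landcover=lc,
    )


class TestRunGrid:
    def test_grid_matches_scalar_evaluation(self, biome_lut):
        f = _single_cell_forcing("forest")
        lut = build_lut(f, biome_lut)
        cube = run_grid(f, lut)
        p = biome_lut["forest"]
        fx = ptjpl_fluxes(
            f.ta[:, 0, 0], f.rh[:, 0, 0], f.lai[:, 0, 0], f.rn[:, 0, 0],
            p, lut.fapar_max[0, 0], t_opt=lut.topt[0, 0],
        )
        expected = wm2_to_mm(fx.t, f.period_lengths)
        assert np.allclose(cube.t[:, 0, 0], expected, rtol=1e-12)

    def test_nonveg_cell_is_fill(self, forcing, biome_lut):
        lut = build_lut(forcing, biome_lut)
        cube = run_grid(forcing, lut)
        nonveg = forcing.landcover == LANDCOVER_CODES["nonveg"]
        assert nonveg.any()
        assert np.all(np.isnan(cube.et[:, nonveg]))
        assert np.all(np.isnan(cube.t[:, nonveg]))

    def test_biome_parameters_drive_differences(self, biome_lut):
        f = _single_cell_forcing("forest")
        g = _single_cell_forcing("grass")
        cf = run_grid(f, build_lut(f, biome_lut))
        cg = run_grid(g, build_lut(g, biome_lut))
        # identical forcing, different biome parameters -> different T
        assert not np.allclose(
            np.nan_to_num(cf.t), np.nan_to_num(cg.t), rtol=1e-6
        )

    def test_missing_lut_class_rejected(self, forcing, biome_lut):
        partial = {k: v for k, v in biome_lut.items() if k != "grass"}
        lut = build_lut(forcing, partial)
        with pytest.raises(ValueError, match="missing from the LUT"):
            run_grid(forcing, lut)

    def test_missing_forcing_gives_gap(self, biome_lut):
        f = _single_cell_forcing("forest")
        f.rn[3, 0, 0] = np.nan
        cube = run_grid(f, build_lut(f, biome_lut))
        assert np.isnan(cube.et[3, 0, 0])

    def test_annual_closure_and_ratio_bounds(self, forcing, biome_lut):
        cube = run_grid(forcing, build_lut(forcing, biome_lut))
        valid = np.isfinite(cube.et)
        total = cube.es + cube.ei + cube.t
        assert np.allclose(cube.et[valid], total[valid], rtol=1e-9)
        assert np.all(cube.t[valid] <= cube.et[valid] * (1 + 1e-12))
        ann = aggregate_annual(cube)
        ok = np.isfinite(ann.tet)
        assert np.all((ann.tet[ok] >= 0) & (ann.tet[ok] <= 1))
        # annual sums commute with the component closure
        n_years = len(forcing.years)
        shape = (n_years, 46) + cube.et.shape[1:]
        comp_sum = (
            np.nansum(cube.es.reshape(shape), axis=1)
            + np.nansum(cube.ei.reshape(shape), axis=1)
            + np.nansum(cube.t.reshape(shape), axis=1)
        )
        fin = np.isfinite(ann.et)
        assert np.allclose(ann.et[fin], comp_sum[fin], rtol=1e-9)


class TestRatio:
    def test_half(self):
        assert tet_8day(np.array(2.0), np.array(4.0)) == 0.5

    def test_zero_et_is_fill(self):
        assert np.isnan(tet_8day(np.array(0.0), np.array(0.0)))

    def test_upper_bound(self):
        assert tet_8day(np.array(3.0), np.array(3.0)) == 1.0


class TestAnnualAggregation:
    def _cube(self, t, et, years=(2001,)):
        from ptjplfuse.gridrun import FluxCube
        from ptjplfuse.forcing_io import CompositingCalendar

        grid = GridSpec(30.0, 30.05, 100.0, 100.05, 0.05)
        cal = CompositingCalendar(years[0])
        z = np.zeros_like(t)
        return FluxCube(
            es=z, ei=et - t, t=t, et=et, years=years, grid=grid,
            period_lengths=cal.period_lengths, period_starts=cal.period_starts,
        )

    def test_constant_flux_sums_over_periods(self):
        t = np.ones((46, 1, 1))
        ann = aggregate_annual(self._cube(t, 2 * t))
        assert ann.t[0, 0, 0] == pytest.approx(46.0)
        assert ann.gap_fraction[0, 0, 0] == 0.0

    def test_gaps_contribute_zero_and_are_counted(self):
        t = np.ones((46, 1, 1))
        t[:23] = np.nan
        ann = aggregate_annual(self._cube(t, 2 * t))
        assert ann.t[0, 0, 0] == pytest.approx(23.0)
        assert ann.gap_fraction[0, 0, 0] == pytest.approx(0.5)

    def test_all_gap_pixel_stays_missing(self):
        t = np.full((46, 1, 1), np.nan)
        ann = aggregate_annual(self._cube(t, t))
        assert np.isnan(ann.t[0, 0, 0]) and np.isnan(ann.tet[0, 0, 0])

    def test_annual_ratio_is_ratio_of_sums_not_mean_of_ratios(self):
        # two active periods t=(1,3), et=(2,3): sum ratio 4/5 = 0.8,
        # while the mean of period ratios would be 0.75
        t = np.full((46, 1, 1), np.nan)
        et = np.full((46, 1, 1), np.nan)
        t[0], t[1] = 1.0, 3.0
        et[0], et[1] = 2.0, 3.0
        ann = aggregate_annual(self._cube(t, et))
        assert ann.tet[0, 0, 0] == pytest.approx(0.8)
        ratios = tet_8day(t, et)
        assert np.nanmean(ratios) == pytest.approx(0.75)


class TestDatasetFiles:
    def test_layer_counts_and_roundtrip(self, forcing, biome_lut, tmp_path):
        cube = run_grid(forcing, build_lut(forcing, biome_lut))
        ann = aggregate_annual(cube)
        manifest = write_dataset(ann, cube, tmp_path)
        by_name = {m["path"].split("/")[-1]: m for m in manifest}
        n_years = len(forcing.years)
        for var in ("T", "ET", "T_ET"):
            assert by_name[f"Annual_{var}.nc"]["n_layers"] == n_years
            for year in forcing.years:
                assert by_name[f"Daily_{var}_{year}.nc"]["n_layers"] == 46
        back = read_product(tmp_path / "Annual_T_ET.nc")
        assert back.shape == (n_years, forcing.grid.n_lat, forcing.grid.n_lon)
        a32 = ann.tet.astype(np.float32)
        got = back.values.astype(np.float32)
        assert np.array_equal(np.isnan(got), np.isnan(a32))
        ok = ~np.isnan(a32)
        assert np.array_equal(got[ok], a32[ok])

    def test_fill_value_on_disk(self, forcing, biome_lut, tmp_path):
        import xarray as xr

        cube = run_grid(forcing, build_lut(forcing, biome_lut))
        ann = aggregate_annual(cube)
        write_dataset(ann, None, tmp_path)
        raw = xr.open_dataset(
            tmp_path / "Annual_T.nc", engine="scipy", mask_and_scale=False
        )
        vals = raw["T"].values
        nonveg = np.isnan(ann.t)
        assert np.all(vals[nonveg] == -9999.0)
        raw.close()

    def test_refuses_overwrite(self, forcing, biome_lut, tmp_path):
        cube = run_grid(forcing, build_lut(forcing, biome_lut))
        ann = aggregate_annual(cube)
        write_dataset(ann, None, tmp_path)
        with pytest.raises(FileExistsError):
            write_dataset(ann, None, tmp_path)
        write_dataset(ann, None, tmp_path, overwrite=True)  # flag allows it

    def test_period_time_attributes_present(self, forcing, biome_lut, tmp_path):
        import xarray as xr

        cube = run_grid(forcing, build_lut(forcing, biome_lut))
        ann = aggregate_annual(cube)
        write_dataset(ann, cube, tmp_path)
        year = forcing.years[0]
        ds = xr.open_dataset(tmp_path / f"Daily_T_{year}.nc", engine="scipy")
        assert "period_start_doy" in ds.coords and "period_end_doy" in ds.coords
        assert int(ds["period_start_doy"][0]) == 1
        assert int(ds["period_end_doy"][-1]) in (365, 366)
        ds.close()
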