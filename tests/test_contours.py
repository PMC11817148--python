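"""Contour extraction: coefficient back-projection, regions, DX export."""

import numpy as np
import pytest

from fieldqsar.contours import (
    ContourField,
    coefficient_field,
    extract_regions,
    read_dx,
    write_dx,
)
from fieldqsar.field_engine import DescriptorMatrix, GridSpec
from fieldqsar.pls import fit_pls


def toy_dm(values, n_points=4):
    """DescriptorMatrix over a 2x2x(n_points/4 nodes...) synthetic layout."""
    values = np.asarray(values, dtype=float)
    n_cols = values.shape[1]
    assert n_cols == 2 * n_points
    return DescriptorMatrix(
        values=values,
        ligand_ids=[f"l{i}" for i in range(values.shape[0])],
        grid=GridSpec((0.0, 0.0, 0.0), 1.5, (2, 2, n_points // 2)),
        point_index=np.repeat(np.arange(n_points), 2),
        field_kind=np.array(["electrostatic", "steric"] * n_points, dtype=object),
        retained_mask=np.ones(2 * n_points, dtype=bool),
    )


class TestCoefficientField:
    def test_single_driving_steric_column(self):
        """y driven by one steric column → nonzero value at exactly its point."""
        rng = np.random.default_rng(0)
        n_points = 4
        vals = np.ones((12, 2 * n_points))
        driver = 2 * 2 + 1  # steric column of grid point 2
        vals[:, driver] = rng.normal(size=12)
        dm = toy_dm(vals, n_points)
        from fieldqsar.field_engine import filter_columns

        dmf = filter_columns(dm, min_sd=0.01)  # only the driver survives
        y = 5.0 + 2.0 * vals[:, driver]
        model = fit_pls(dmf.values, y, A=1)
        cf = coefficient_field(model, dmf, "steric")
        nz = np.flatnonzero(cf.point_values)
        assert nz.tolist() == [2]
        assert cf.point_values[2] > 0  # positive planted weight → "green"

    def test_zero_coefficients_give_zero_field(self, synthetic_study, fitted_model):
        import copy

        dm = synthetic_study["dm"]
        model = copy.deepcopy(fitted_model)
        model.coefficients = np.zeros_like(model.coefficients)
        cf = coefficient_field(model, dm, "electrostatic")
        assert not cf.point_values.any()

    def test_equal_coefficient_and_sd_give_equal_values(self):
        vals = np.array([[1.0, 1.0, 0.0, 0.0], [2.0, 2.0, 0.0, 0.0],
                         [3.0, 3.0, 0.0, 0.0]])
        dm = toy_dm(np.hstack([vals, vals]), n_points=4)
        y = np.array([1.0, 2.0, 3.0])
        from fieldqsar.field_engine import filter_columns

        dmf = filter_columns(dm, min_sd=0.01)
        model = fit_pls(dmf.values, y, A=1)
        cf = coefficient_field(model, dmf, "electrostatic")
        nz = cf.point_values[cf.point_values != 0]
        assert len(nz) >= 2
        np.testing.assert_allclose(nz, nz[0], rtol=1e-10)

    def test_planted_sign_semantics(self, synthetic_study, fitted_model):
        """sd-weighted values at planted columns carry the planted signs."""
        dm = synthetic_study["dm"]
        spec = synthetic_study["spec"]
        fields = {
            "electrostatic": coefficient_field(fitted_model, dm, "electrostatic"),
            "steric": coefficient_field(fitted_model, dm, "steric"),
        }
        for col, weight in spec.planted_coefficients.items():
            point, kind = col // 2, ("electrostatic", "steric")[col % 2]
            value = fields[kind].point_values[point]
            assert np.sign(value) == np.sign(weight)

    def test_absolute_value_sum_identity(self, synthetic_study, fitted_model):
        dm = synthetic_study["dm"]
        for kind in ("electrostatic", "steric"):
            cf = coefficient_field(fitted_model, dm, kind)
            mask = dm.field_kind == kind
            expected = np.abs(
                fitted_model.coefficients[mask] * dm.column_sds[mask]
            ).sum()
            assert np.abs(cf.point_values).sum() == pytest.approx(expected, rel=1e-10)

    def test_missing_kind_rejected(self, synthetic_study, fitted_model):
        dm = synthetic_study["dm"]
        with pytest.raises(ValueError, match="absent"):
            coefficient_field(fitted_model, dm, "hydrophobic")


class TestExtractRegions:
    def make(self, values):
        values = np.asarray(values, dtype=float)
        n = len(values)
        assert n % 4 == 0  # helper grids are 2 x 2 x (n/4)
        grid = GridSpec((0.0, 0.0, 0.0), 1.0, (2, 2, n // 4))
        return ContourField(grid=grid, field_kind="steric", point_values=values)

    def test_percentile_levels_pick_extremes(self):
        cf = extract_regions(self.make([-2.0, -1.0, 0.0, 1.0, 2.0, 0.0, 0.0, 0.0]),
                             90.0, 10.0)
        labels = cf.region_labels
        assert (labels == "favorable_high").sum() == 1
        assert (labels == "favorable_low").sum() == 1
        assert cf.point_values[labels == "favorable_high"][0] == 2.0
        assert cf.point_values[labels == "favorable_low"][0] == -2.0

    def test_symmetric_values_symmetric_labels(self):
        cf = extract_regions(self.make([-3.0, -1.0, 1.0, 3.0, 0, 0, 0, 0]), 75.0, 25.0)
        assert (cf.region_labels == "favorable_high").sum() == (
            cf.region_labels == "favorable_low"
        ).sum()

    def test_constant_nonzero_values_all_neutral(self):
        cf = extract_regions(self.make([2.0] * 8), 90.0, 10.0)
        assert (cf.region_labels == "neutral").all()

    def test_all_zero_warns_and_stays_neutral(self):
        with pytest.warns(UserWarning, match="all contour values are zero"):
            cf = extract_regions(self.make([0.0] * 8), 90.0, 10.0)
        assert (cf.region_labels == "neutral").all()

    def test_bad_percentiles_rejected(self):
        with pytest.raises(ValueError):
            extract_regions(self.make([1.0] * 8), 10.0, 90.0)


class TestOpenDx:
    def test_header_and_item_count(self, tmp_path):
        grid = GridSpec((-1.0, -1.0, -1.0), 1.0, (2, 2, 2))
        cf = ContourField(grid=grid, field_kind="steric",
                          point_values=np.arange(8.0))
        path = tmp_path / "cube.dx"
        write_dx(cf, path)
        text = path.read_text()
        assert "gridpositions counts 2 2 2" in text
        assert "items 8 data follows" in text

    def test_round_trip(self, tmp_path, synthetic_study, fitted_model):
        dm = synthetic_study["dm"]
        cf = coefficient_field(fitted_model, dm, "electrostatic")
        path = tmp_path / "field.dx"
        write_dx(cf, path)
        back = read_dx(path, field_kind="electrostatic")
        assert back.grid.counts == cf.grid.counts
        np.testing.assert_allclose(back.grid.origin, cf.grid.origin, atol=1e-6)
        assert back.grid.spacing == pytest.approx(cf.grid.spacing, abs=1e-6)
        np.testing.assert_allclose(back.point_values, cf.point_values, atol=1e-6)

    def test_unwritable_path_rejected(self, tmp_path):
        grid = GridSpec((0.0, 0.0, 0.0), 1.0, (2, 2, 2))
        cf = ContourField(grid=grid, field_kind="steric", point_values=np.zeros(8))
        with pytest.raises(OSError):
            write_dx(cf, tmp_path / "missing_dir" / "out.dx")

    def test_region_summary_schema(self, synthetic_study, fitted_model):
        dm = synthetic_study["dm"]
        cf = extract_regions(coefficient_field(fitted_model, dm, "steric"))
        df = cf.region_summary()
        assert list(df.columns) == ["point_index", "x", "y", "z", "field",
                                    "value", "label"]
        assert len(df) == dm.grid.n_points
        assert set(df["label"]).issubset({"favorable_high", "favorable_low",
                                          "neutral"})
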