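"""Grid construction and probe-energy descriptor properties."""

import numpy as np
import pytest

from fieldqsar.field_engine import (
    COULOMB_K,
    DescriptorMatrix,
    GridSpec,
    ProbeSpec,
    build_descriptor_matrix,
    build_grid,
    electrostatic_field,
    filter_columns,
    steric_field,
)
from fieldqsar.ligand_io import Atom, Molecule


def atom(pos, charge=0.0, radius=1.7, eps=0.09, element="C"):
    return Atom(element, np.asarray(pos, dtype=float), charge, radius, eps)


def mol(atoms, ligand_id="m"):
    return Molecule(ligand_id, atoms)


class TestBuildGrid:
    def test_single_atom_counting_rule(self):
        grid = build_grid([mol([atom((0, 0, 0))])], spacing=1.5, margin=4.0)
        assert grid.counts == (6, 6, 6)  # floor(8/1.5)+1
        assert grid.n_points == 216

    def test_extended_box(self):
        m = mol([atom((0, 0, 0)), atom((3, 3, 3))])
        grid = build_grid([m], spacing=1.5, margin=4.0)
        assert grid.counts == (8, 8, 8)  # floor(11/1.5)+1
        assert grid.n_points == 512

    def test_degenerate_axis_gets_two_points(self):
        m = mol([atom((0, 0, 0)), atom((3, 3, 0))])  # planar, zero z extent
        grid = build_grid([m], spacing=1.5, margin=0.0)
        assert grid.counts[2] == 2

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_grid([], 1.5, 4.0)


def point_grid(position):
    """A 2-point-per-axis grid whose origin node sits at `position`."""
    return GridSpec(origin=tuple(position), spacing=100.0, counts=(2, 2, 2))


class TestElectrostatic:
    probe = ProbeSpec()

    def test_cap_applied_close_to_unit_charge(self):
        m = mol([atom((1, 0, 0), charge=1.0)])
        e = electrostatic_field(m, point_grid((0, 0, 0)), self.probe, elec_cap=30.0)
        assert e[0] == pytest.approx(30.0)  # 332.06 clipped at the cap

    def test_coulomb_constant(self):
        m = mol([atom((1, 0, 0), charge=0.01)])
        e = electrostatic_field(m, point_grid((0, 0, 0)), self.probe)
        assert e[0] == pytest.approx(COULOMB_K * 0.01, rel=1e-12)

    def test_superposition_cancels_opposite_charges(self):
        m = mol([atom((1, 0, 0), charge=0.3), atom((-1, 0, 0), charge=-0.3)])
        e = electrostatic_field(m, point_grid((0, 0, 0)), self.probe)
        assert e[0] == pytest.approx(0.0, abs=1e-12)

    def test_coincident_point_hits_cap_not_inf(self):
        m = mol([atom((0, 0, 0), charge=0.5)])
        e = electrostatic_field(m, point_grid((0, 0, 0)), self.probe, elec_cap=30.0)
        assert e[0] == 30.0

    def test_linear_in_charges_before_clipping(self):
        rng = np.random.default_rng(2)
        atoms = [atom(rng.normal(size=3) * 3, charge=float(c))
                 for c in rng.uniform(-0.05, 0.05, size=5)]
        doubled = [atom(a.position, charge=2 * a.partial_charge) for a in atoms]
        grid = GridSpec((-8.0, -8.0, -8.0), 4.0, (5, 5, 5))
        e1 = electrostatic_field(mol(atoms), grid, self.probe, elec_cap=1e9)
        e2 = electrostatic_field(mol(doubled), grid, self.probe, elec_cap=1e9)
        np.testing.assert_allclose(e2, 2 * e1, rtol=1e-12)


class TestSteric:
    probe = ProbeSpec()

    def test_minimum_at_rm(self):
        a = atom((0, 0, 0), radius=1.7, eps=0.16)
        r_m = self.probe.radius + 1.7
        e = steric_field(mol([a]), point_grid((r_m, 0, 0)), self.probe)
        assert e[0] == pytest.approx(-np.sqrt(self.probe.epsilon * 0.16), rel=1e-12)

    def test_decay_far_away(self):
        a = atom((0, 0, 0))
        r_m = self.probe.radius + 1.7
        e = steric_field(mol([a]), point_grid((10 * r_m, 0, 0)), self.probe)
        assert abs(e[0]) < 1e-4

    def test_cap_at_close_contact(self):
        e = steric_field(mol([atom((0.1, 0, 0))]), point_grid((0, 0, 0)),
                         self.probe, steric_cap=30.0)
        assert e[0] == 30.0

    def test_bounded_below_by_total_well_depth(self):
        rng = np.random.default_rng(5)
        atoms = [atom(rng.normal(size=3) * 2, eps=float(rng.uniform(0.05, 0.3)))
                 for _ in range(6)]
        m = mol(atoms)
        grid = GridSpec((-6.0, -6.0, -6.0), 1.0, (13, 13, 13))
        e = steric_field(m, grid, self.probe)
        bound = sum(np.sqrt(self.probe.epsilon * a.vdw_epsilon) for a in atoms)
        assert e.min() >= -bound - 1e-12


class TestDescriptorMatrix:
    probe = ProbeSpec()

    def test_shape_and_column_order(self):
        grid = GridSpec((-4.0, -4.0, -4.0), 1.5, (6, 6, 6))
        mols = [mol([atom((0, 0, 0), charge=0.1)], f"l{i}") for i in range(3)]
        dm = build_descriptor_matrix(mols, grid, self.probe)
        assert dm.values.shape == (3, 432)
        # point-major: electrostatic column precedes steric at each point
        assert list(dm.field_kind[:4]) == ["electrostatic", "steric"] * 2
        assert list(dm.point_index[:4]) == [0, 0, 1, 1]

    def test_duplicated_ligand_gives_identical_rows(self):
        grid = GridSpec((-4.0, -4.0, -4.0), 2.0, (5, 5, 5))
        a = mol([atom((0, 0, 0), charge=0.2), atom((1, 0, 0), charge=-0.1)], "a")
        b = mol([atom((0, 0, 0), charge=0.2), atom((1, 0, 0), charge=-0.1)], "b")
        dm = build_descriptor_matrix([a, b], grid, self.probe)
        np.testing.assert_array_equal(dm.values[0], dm.values[1])

    def test_additivity_over_atoms_before_clipping(self):
        grid = GridSpec((-6.0, -6.0, -6.0), 2.0, (7, 7, 7))
        a1 = atom((0.3, 0, 0), charge=0.2)
        a2 = atom((-1, 0.5, 0), charge=-0.3, radius=1.5)
        kw = dict(elec_cap=1e30, steric_cap=1e30)  # caps out of reach
        both = build_descriptor_matrix([mol([a1, a2])], grid, self.probe, **kw)
        solo1 = build_descriptor_matrix([mol([a1])], grid, self.probe, **kw)
        solo2 = build_descriptor_matrix([mol([a2])], grid, self.probe, **kw)
        np.testing.assert_allclose(
            both.values, solo1.values + solo2.values, rtol=1e-10, atol=1e-12
        )

    def test_translation_invariance_exact(self):
        rng = np.random.default_rng(8)
        shift = np.array([2.5, -1.0, 3.0])
        # dyadic coordinates: the common translation is exact in binary floats
        atoms = [atom(rng.integers(-16, 17, size=3) / 8.0,
                      charge=float(rng.uniform(-0.3, 0.3)))
                 for _ in range(4)]
        m1 = mol(atoms, "a")
        m2 = Molecule("a", [atom(a.position + shift, charge=a.partial_charge)
                            for a in atoms])
        g1 = GridSpec((-5.0, -5.0, -5.0), 1.5, (8, 8, 8))
        g2 = GridSpec(tuple(np.array(g1.origin) + shift), 1.5, (8, 8, 8))
        d1 = build_descriptor_matrix([m1], g1, self.probe)
        d2 = build_descriptor_matrix([m2], g2, self.probe)
        np.testing.assert_array_equal(d1.values, d2.values)

    def test_outside_grid_warns(self):
        grid = GridSpec((0.0, 0.0, 0.0), 1.0, (2, 2, 2))
        with pytest.warns(UserWarning, match="does not cover"):
            build_descriptor_matrix([mol([atom((5, 5, 5))])], grid, self.probe)


class TestFilterColumns:
    def make_dm(self, values):
        values = np.asarray(values, dtype=float)
        n_cols = values.shape[1]
        n_points = n_cols // 2
        return DescriptorMatrix(
            values=values,
            ligand_ids=[f"l{i}" for i in range(values.shape[0])],
            grid=GridSpec((0.0, 0.0, 0.0), 1.5, (2, 2, max(2, n_points // 4))),
            point_index=np.repeat(np.arange(n_points), 2)[:n_cols],
            field_kind=np.array(["electrostatic", "steric"] * n_points,
                                dtype=object)[:n_cols],
            retained_mask=np.ones(n_cols, dtype=bool),
        )

    def test_constant_column_removed(self):
        dm = self.make_dm([[30.0, 1.0], [30.0, 2.0], [30.0, 3.0]])
        out = filter_columns(dm, min_sd=0.05)
        assert out.n_columns == 1
        assert out.retained_mask.tolist() == [False, True]

    def test_min_sd_zero_keeps_all(self):
        dm = self.make_dm([[1.0, 2.0], [1.0, 3.0]])
        assert filter_columns(dm, min_sd=0.0).n_columns == 2

    def test_metadata_stays_consistent(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(5, 8))
        vals[:, [1, 4]] = 7.0  # two dead columns
        dm = self.make_dm(vals)
        out = filter_columns(dm, min_sd=0.05)
        assert out.n_columns == 6
        assert len(out.point_index) == 6 and len(out.field_kind) == 6
        assert out.retained_mask.sum() == 6

    def test_all_removed_rejected(self):
        dm = self.make_dm([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="no informative columns"):
            filter_columns(dm, min_sd=0.05)


def test_tsv_round_trip(tmp_path, synthetic_study):
    dm = synthetic_study["dm"]
    path = tmp_path / "fields.tsv"
    dm.to_tsv(path)
    back = DescriptorMatrix.from_tsv(path)
    np.testing.assert_allclose(back.values, dm.values, rtol=1e-9)
    assert back.ligand_ids == dm.ligand_ids
    assert back.grid == dm.grid
    np.testing.assert_array_equal(back.retained_mask, dm.retained_mask)
    np.testing.assert_array_equal(back.point_index, dm.point_index)
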