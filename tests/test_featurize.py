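"""Atom typing, occupancy model, voxel grids and WT/MT representations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import orgnet as og
from orgnet.chemdata import CHANNEL_NAMES, UnknownAtomError

from conftest import apply_rigid, random_rigid_transform


def _props(res, atom, element="O"):
    a = og.Atom(atom, element, np.zeros(3), 1, res, "A")
    return og.assign_properties(a)


class TestAssignProperties:
    @pytest.mark.parametrize(
        "res, atom, element, expected_on",
        [
            ("ASP", "OD1", "O", {"neg_ionizable", "hbond_acceptor", "occupancy"}),
            ("ALA", "CB", "C", {"hydrophobic", "occupancy"}),
            ("LYS", "NZ", "N", {"pos_ionizable", "hbond_donor", "occupancy"}),
            ("PHE", "CZ", "C", {"aromatic", "hydrophobic", "occupancy"}),
            ("HIS", "ND1", "N",
             {"aromatic", "hbond_donor", "hbond_acceptor", "pos_ionizable", "occupancy"}),
            ("SER", "OG", "O", {"hbond_donor", "hbond_acceptor", "occupancy"}),
            ("GLY", "N", "N", {"hbond_donor", "occupancy"}),
            ("PRO", "N", "N", {"occupancy"}),  # proline N carries no H
        ],
    )
    def test_rule_table(self, res, atom, element, expected_on):
        props = _props(res, atom, element)
        on = {name for name, flag in zip(CHANNEL_NAMES, props.flags) if flag}
        assert on == expected_on

    def test_radii_from_element_table(self):
        assert _props("ASP", "OD1", "O").vdw_radius == 1.52
        assert _props("ALA", "CB", "C").vdw_radius == 1.70
        assert _props("LYS", "NZ", "N").vdw_radius == 1.55
        assert _props("MET", "SD", "S").vdw_radius == 1.80

    def test_unknown_atom_errors_name_it(self):
        with pytest.raises(UnknownAtomError, match="XX9"):
            _props("ALA", "XX9", "C")
        with pytest.raises(UnknownAtomError, match="UNK"):
            _props("UNK", "CA", "C")

    def test_occupancy_always_on(self):
        for res, atom, el in [("ALA", "CA", "C"), ("TRP", "NE1", "N"), ("GLU", "OE2", "O")]:
            assert _props(res, atom, el).flag("occupancy")


class TestOccupancyValue:
    def test_closed_form_at_vdw_radius(self):
        assert og.occupancy_value(1.7, 1.7) == pytest.approx(1 - np.exp(-1), abs=1e-9)

    def test_closed_form_tabulated_point(self):
        assert og.occupancy_value(2.0, 1.7) == pytest.approx(
            1 - np.exp(-(0.85**12)), abs=1e-9
        )

    def test_limits(self):
        assert og.occupancy_value(0.0, 1.7) == 1.0
        assert og.occupancy_value(1e6, 1.7) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(min_value=0.05, max_value=30.0), st.floats(min_value=0.05, max_value=29.0))
    def test_decreasing_in_distance(self, d, delta):
        """Non-increasing everywhere; strictly decreasing once the value
        leaves float saturation at 1 (d below ~0.7·r saturates)."""
        r = 1.7
        near, far = og.occupancy_value(d, r), og.occupancy_value(d + delta, r)
        assert far <= near
        if d >= r:
            assert far < near


class TestVoxelize:
    def test_empty_structure_gives_zero_grid(self):
        grid = og.voxelize(og.Structure(id="none"), center=np.zeros(3))
        assert grid.values.shape == (16, 16, 16, 7)
        assert np.all(grid.values == 0)

    def test_single_atom_at_voxel_center(self):
        # voxel centers sit at offsets (i - 7.5) Å; put a carbon on one
        pos = np.array([0.5, 0.5, 0.5])
        atom = og.Atom("CB", "C", pos, 1, "ALA", "A")
        grid = og.voxelize(og.Structure(id="one", atoms=[atom]), center=np.zeros(3))
        occ = grid.values[..., CHANNEL_NAMES.index("occupancy")]
        aro = grid.values[..., CHANNEL_NAMES.index("aromatic")]
        assert occ[8, 8, 8] == pytest.approx(1.0, abs=1e-9)
        assert np.all(aro == 0)

    def test_values_bounded_and_occupancy_dominates(self, helix):
        grid = og.voxelize(helix, center=helix.residue("A", 3).atom("CB").coords)
        assert grid.values.min() >= 0 and grid.values.max() <= 1
        occ = grid.values[..., CHANNEL_NAMES.index("occupancy")]
        for c in range(6):
            assert np.all(occ >= grid.values[..., c] - 1e-12)

    def test_grid_invariance_through_standardize_pipeline(self, mutation_pair):
        wt, mt, record = mutation_pair
        rng = np.random.default_rng(3)
        ref = og.featurize_mutation(wt, mt, record).tensor
        for _ in range(5):
            rot, t = random_rigid_transform(rng)
            rep = og.featurize_mutation(
                apply_rigid(wt, rot, t), apply_rigid(mt, rot, t), record
            )
            assert np.abs(rep.tensor - ref).max() < 1e-6

    def test_hydrogens_excluded(self):
        c = og.Atom("CB", "C", np.zeros(3), 1, "ALA", "A")
        h = og.Atom("HB1", "H", np.array([0.5, 0, 0]), 1, "ALA", "A")
        with_h = og.voxelize(og.Structure(id="h", atoms=[c, h]), center=np.zeros(3))
        without = og.voxelize(og.Structure(id="noh", atoms=[c]), center=np.zeros(3))
        np.testing.assert_array_equal(with_h.values, without.values)


class TestRepresentation:
    def _grids(self, mutation_pair):
        wt, mt, record = mutation_pair
        frame = og.compute_frame(wt, "A", record.position)
        wt_s, mt_s = og.standardize(wt, frame), og.standardize(mt, frame)
        center = wt_s.residue("A", record.position).atom("CB").coords
        return og.voxelize(wt_s, center), og.voxelize(mt_s, center)

    def test_wt_mt_mode_is_14_channels_wt_first(self, mutation_pair):
        wt_g, mt_g = self._grids(mutation_pair)
        rep = og.build_representation(wt_g, mt_g, "wt_mt")
        assert rep.tensor.shape == (16, 16, 16, 14)
        np.testing.assert_array_equal(rep.tensor[..., :7], wt_g.values)
        np.testing.assert_array_equal(rep.tensor[..., 7:], mt_g.values)

    def test_wt_diff_second_block_is_difference(self, mutation_pair):
        wt_g, mt_g = self._grids(mutation_pair)
        rep = og.build_representation(wt_g, mt_g, "wt_diff")
        np.testing.assert_allclose(
            rep.tensor[..., 7:], wt_g.values - mt_g.values, atol=1e-12
        )

    def test_diff_mode_with_identical_grids_is_zero(self, mutation_pair):
        wt_g, _ = self._grids(mutation_pair)
        rep = og.build_representation(wt_g, wt_g, "diff")
        assert rep.tensor.shape == (16, 16, 16, 7)
        assert np.all(rep.tensor == 0)

    def test_geometry_mismatch_rejected(self, mutation_pair):
        wt_g, _ = self._grids(mutation_pair)
        shifted = og.voxelize(
            og.Structure(id="x"), center=wt_g.center + 1.0, spacing=wt_g.spacing
        )
        with pytest.raises(ValueError):
            og.build_representation(wt_g, shifted, "wt_mt")

    def test_reverse_negates_label_and_swaps_roles(self, mutation_pair):
        wt_g, mt_g = self._grids(mutation_pair)
        rev, label = og.reverse_representation(wt_g, mt_g, 1.5, "wt_diff")
        assert label == -1.5
        direct = og.build_representation(wt_g, mt_g, "wt_diff")
        np.testing.assert_array_equal(rev.tensor[..., :7], mt_g.values)
        np.testing.assert_allclose(
            rev.tensor[..., 7:], -direct.tensor[..., 7:], atol=1e-12
        )
        # double reversal restores the original
        again, label2 = og.reverse_representation(mt_g, wt_g, label, "wt_diff")
        np.testing.assert_array_equal(again.tensor, direct.tensor)
        assert label2 == 1.5


class TestFeaturizeMutation:
    def test_shape_and_mode(self, mutation_pair):
        wt, mt, record = mutation_pair
        rep = og.featurize_mutation(wt, mt, record, mode="wt_diff")
        assert rep.tensor.shape == (16, 16, 16, 14)

    def test_identical_structures_zero_difference(self, mutation_pair):
        wt, _, record = mutation_pair
        rep = og.featurize_mutation(wt, wt, record, mode="wt_diff")
        assert np.abs(rep.tensor[..., 7:]).max() == 0

    def test_chain_start_mutation_is_recorded_failure(self, mutation_pair):
        wt, mt, _ = mutation_pair
        record = og.MutationRecord("pair_wt", "A", 1, "A", "L", 0.5)
        with pytest.raises(og.FeaturizationError):
            og.featurize_mutation(wt, mt, record)

    def test_glycine_site_uses_virtual_cbeta(self):
        wt = og.build_peptide(og.PeptideSpec.regular("AGA"), "gwt")
        mt = og.build_peptide(og.PeptideSpec.regular("AAA"), "gmt")
        record = og.MutationRecord("gwt", "A", 2, "G", "A", -0.4)
        rep = og.featurize_mutation(wt, mt, record)
        assert rep.tensor.shape == (16, 16, 16, 14)
        assert np.isfinite(rep.tensor).all()


def test_hdf5_roundtrip(tmp_path, mutation_pair):
    wt, mt, record = mutation_pair
    rep = og.featurize_mutation(wt, mt, record)
    path = tmp_path / "reps.h5"
    og.featurize.save_representations(path, [rep], np.array([record.ddg]), [record])
    reps, labels, meta = og.featurize.load_representations(path)
    assert len(reps) == 1 and reps[0].mode == "wt_diff"
    np.testing.assert_allclose(reps[0].tensor, rep.tensor, atol=1e-6)
    assert labels[0] == pytest.approx(record.ddg, abs=1e-6)
    assert meta.loc[0, "structure_id"] == "pair_wt"
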