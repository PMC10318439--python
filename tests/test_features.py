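import numpy as np
import pytest

from glycosite.features import (FEATURE_COLUMNS, FeatureTable, PropertyScales,
                                compute_sasa, featurize, label_contacts,
                                shrake_rupley)
from glycosite.structure import (CarbohydrateUnit, ProteinStructure,
                                 compute_dihedrals, parse_structure)
from glycosite.synthetic import FixtureSpec, make_chain

from conftest import random_rotation_matrix


def brute_force_sasa(coords, radii, probe=1.4, n_points=4000):
    """Independent dense-sampling Shrake-Rupley: all-pairs, no spatial index."""
    coords = np.asarray(coords, float)
    expanded = np.asarray(radii, float) + probe
    # dense quasi-uniform sphere points (golden spiral, same as any dense net)
    i = np.arange(n_points) + 0.5
    phi = np.arccos(1 - 2 * i / n_points)
    theta = np.pi * (1 + 5 ** 0.5) * i
    unit = np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])
    out = np.zeros(len(coords))
    for a in range(len(coords)):
        pts = coords[a] + expanded[a] * unit
        free = np.ones(n_points, bool)
        for b in range(len(coords)):
            if b == a:
                continue
            free &= np.sum((pts - coords[b]) ** 2, axis=1) > expanded[b] ** 2
        out[a] = 4 * np.pi * expanded[a] ** 2 * free.mean()
    return out


class TestSasa:
    def test_isolated_atom_closed_form(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.7]), 1.4, 960)[0]
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert abs(area - exact) / exact < 0.02

    def test_fully_buried_atom_is_zero(self):
        # central atom caged by a tight shell of 26 overlapping atoms
        offsets = [np.array([i, j, k], float) * 1.8
                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                   if (i, j, k) != (0, 0, 0)]
        coords = np.vstack([[0.0, 0.0, 0.0], offsets])
        radii = np.full(len(coords), 1.7)
        areas = shrake_rupley(coords, radii)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        coords = rng.uniform(0, 8, size=(18, 3))
        radii = rng.uniform(1.5, 1.8, size=18)
        fast = shrake_rupley(coords, radii, 1.4, 960)
        slow = brute_force_sasa(coords, radii, 1.4, 4000)
        scale = 4 * np.pi * (radii + 1.4) ** 2
        assert np.all(np.abs(fast - slow) / scale < 0.02)

    def test_matches_biotite_independent_implementation(self, rng):
        import biotite.structure as bst
        coords = rng.uniform(0, 10, size=(20, 3))
        radii = np.full(20, 1.7)
        arr = bst.AtomArray(20)
        arr.coord = coords.astype(np.float32)
        arr.set_annotation("element", np.array(["C"] * 20))
        ours = shrake_rupley(coords, radii, 1.4, 960)
        theirs = bst.sasa(arr, probe_radius=1.4, point_number=960,
                          vdw_radii=radii)
        scale = 4 * np.pi * (radii + 1.4) ** 2
        assert np.all(np.abs(ours - theirs) / scale < 0.02)

    def test_surface_residue_exceeds_core(self, helix_structure):
        st, _ = helix_structure
        sasa = compute_sasa(st)
        # termini stick out of a helix; middle residues are more covered
        assert sasa[0] > sasa[len(st) // 2]
        assert np.all(sasa >= 0) and np.all(sasa <= 1)

    def test_raw_mode_returns_area_units(self, helix_structure):
        st, _ = helix_structure
        raw = compute_sasa(st, normalized=False)
        assert raw.max() > 10.0   # Å², not a [0,1] index


class TestLabels:
    @staticmethod
    def _one_residue_with_sugar_at(distance):
        res_atoms = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        from glycosite.structure import ResidueRecord
        residue = ResidueRecord(
            chain_id="A", seq_index=1, aa="A",
            ca=res_atoms[0], cb=res_atoms[1],
            backbone={"CA": res_atoms[0]}, heavy_atoms=res_atoms)
        sugar = CarbohydrateUnit("GLC", "Glc",
                                 np.array([[1.5 + distance, 0.0, 0.0]]))
        return ProteinStructure([residue], [sugar])

    def test_contact_inside_cutoff(self):
        assert label_contacts(self._one_residue_with_sugar_at(4.1)).tolist() == [1]

    def test_contact_outside_cutoff(self):
        assert label_contacts(self._one_residue_with_sugar_at(4.3)).tolist() == [0]

    def test_boundary_inclusive(self):
        assert label_contacts(self._one_residue_with_sugar_at(4.2)).tolist() == [1]

    def test_no_carbohydrates_all_zero(self, bare_helix):
        assert label_contacts(bare_helix).sum() == 0

    def test_monotone_in_cutoff(self, helix_structure):
        st, _ = helix_structure
        cuts = [2.0, 3.0, 4.2, 6.0, 10.0]
        labels = [set(np.flatnonzero(label_contacts(st, c))) for c in cuts]
        for small, large in zip(labels, labels[1:]):
            assert small <= large

    def test_invalid_cutoff(self, helix_structure):
        with pytest.raises(ValueError):
            label_contacts(helix_structure[0], 0.0)


class TestFeaturize:
    @pytest.mark.parametrize("scheme,n_cols", [("voxel", 28), ("graph", 29)])
    def test_column_counts(self, helix_structure, scheme, n_cols):
        st, _ = helix_structure
        compute_dihedrals(st)
        table = featurize(st, scheme)
        assert table.vectors.shape == (len(st), n_cols)
        assert len(FEATURE_COLUMNS[scheme]) == n_cols

    def test_one_hot_and_orientation_norms(self, helix_structure):
        st, _ = helix_structure
        table = featurize(st, "voxel")
        onehot = table.vectors[:, :20]
        np.testing.assert_allclose(onehot.sum(axis=1), 1.0)
        assert set(np.unique(onehot)) <= {0.0, 1.0}
        norms = np.linalg.norm(table.vectors[:, 25:28], axis=1)
        is_gly = np.array([r.aa == "G" for r in st.residues])
        np.testing.assert_allclose(norms[~is_gly], 1.0, atol=1e-9)
        np.testing.assert_allclose(norms[is_gly], 0.0, atol=1e-12)

    def test_torsion_block(self, helix_structure):
        st, _ = helix_structure
        compute_dihedrals(st)
        table = featurize(st, "graph")
        tor = table.vectors[:, 25:29]
        assert np.all(np.abs(tor) <= 1.0)
        # termini encode undefined angles as zeros
        np.testing.assert_array_equal(tor[0, :2], [0.0, 0.0])
        np.testing.assert_array_equal(tor[-1, 2:], [0.0, 0.0])
        # interior helix residues: sin^2 + cos^2 = 1
        mid = tor[2]
        assert mid[0] ** 2 + mid[1] ** 2 == pytest.approx(1.0)

    def test_scalar_features_rigid_invariant(self, helix_structure, rng):
        st, _ = helix_structure
        compute_dihedrals(st)
        table = featurize(st, "voxel")
        R = random_rotation_matrix(rng)
        t = rng.uniform(-30, 30, 3)
        moved = compute_dihedrals(st.transformed(R, t))
        table2 = featurize(moved, "voxel")
        # everything except SASA is exactly invariant
        exact = [i for i in range(25) if i != 20]
        np.testing.assert_allclose(table2.vectors[:, exact],
                                   table.vectors[:, exact], atol=1e-9)
        # SASA is invariant up to sphere-quadrature error (fixed sample
        # directions; the method itself is rotation-free)
        np.testing.assert_allclose(table2.vectors[:, 20],
                                   table.vectors[:, 20], atol=0.02)
        # the orientation vector co-rotates
        np.testing.assert_allclose(table2.vectors[:, 25:28],
                                   table.vectors[:, 25:28] @ R.T, atol=1e-9)

    def test_unknown_aa_raises(self, helix_structure):
        import copy
        st = copy.deepcopy(helix_structure[0])
        st.residues[0].aa = "X"
        with pytest.raises(ValueError, match="unknown amino-acid"):
            featurize(st, "voxel")

    def test_tsv_round_trip(self, helix_structure, tmp_path):
        st, _ = helix_structure
        compute_dihedrals(st)
        table = featurize(st, "graph")
        path = tmp_path / "features.tsv"
        table.to_tsv(path)
        back = FeatureTable.from_tsv(path, "graph")
        np.testing.assert_allclose(back.vectors, table.vectors, atol=1e-12)
        np.testing.assert_array_equal(back.labels, table.labels)
        np.testing.assert_allclose(back.coords_cb, table.coords_cb, atol=1e-12)


class TestPropertyScales:
    def test_defaults_cover_all_codes(self):
        PropertyScales()   # __post_init__ validates

    def test_missing_code_rejected(self):
        table = dict(PropertyScales().hydrophobicity)
        table.pop("W")
        with pytest.raises(ValueError, match="missing"):
            PropertyScales(hydrophobicity=table)

    def test_out_of_range_rejected(self):
        table = dict(PropertyScales().aromaphilicity)
        table["W"] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            PropertyScales(aromaphilicity=table)

    def test_yaml_round_trip(self, tmp_path):
        scales = PropertyScales()
        path = tmp_path / "scales.yaml"
        scales.to_yaml(path)
        back = PropertyScales.from_yaml(path)
        assert back.hydrophobicity == scales.hydrophobicity
        assert back.aromaphilicity == scales.aromaphilicity
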