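"""Structure/trajectory I/O, selections and chain joining."""

import numpy as np
import pytest

from helixpack import enm, structio, synthetic
from helixpack.structio import (
    MolecularStructure, ParseError, StructureError, join_chains,
    read_frames, read_structure, read_xyz_frames, select_atoms,
    write_frames, write_structure, write_xyz_frames,
)

TWO_ATOM_PDB = """\
ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00           C
ATOM      2  CA  GLY A   2      12.500  -3.250   0.125  1.00  0.00           C
END
"""


def _chain_fragment(chain, resids, x0=0.0):
    n = len(resids)
    coords = np.column_stack([x0 + 3.8 * np.arange(n), np.zeros(n), np.zeros(n)])
    return MolecularStructure(
        names=["CA"] * n, resnames=["ALA"] * n, resids=np.asarray(resids),
        chains=[chain] * n, coords=coords)


class TestPDBReading:
    def test_hand_written_records_are_copied_verbatim(self):
        s = read_structure(TWO_ATOM_PDB)
        assert s.n_atoms == 2
        assert s.names == ["CA", "CA"]
        assert s.resnames == ["ALA", "GLY"]
        np.testing.assert_allclose(
            s.coords, [[11.104, 6.134, -6.504], [12.5, -3.25, 0.125]])

    def test_round_trip_preserves_roster_and_coordinates(self, dumbbell):
        s, _ = dumbbell
        s2 = read_structure(write_structure(s))
        assert s2.names == s.names
        assert s2.chains == s.chains
        assert np.array_equal(s2.resids, s.resids)
        # PDB stores 3 decimals
        np.testing.assert_allclose(s2.coords, s.coords, atol=5.1e-4)
        s3 = read_structure(write_structure(s2))
        np.testing.assert_array_equal(s3.coords, s2.coords)

    def test_synthetic_helix_has_one_ca_per_residue(self, helix10):
        s = read_structure(write_structure(helix10))
        assert len(select_atoms(s, name="CA")) == 10

    def test_malformed_coordinate_names_line_number(self):
        bad = TWO_ATOM_PDB.replace("12.500", "12.5x0")
        with pytest.raises(ParseError, match="line 2"):
            read_structure(bad)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ParseError, match="empty"):
            read_structure("")

    def test_insertion_codes_rejected(self):
        bad = TWO_ATOM_PDB.replace("A   2  ", "A   2A ")
        with pytest.raises(ParseError, match="insertion"):
            read_structure(bad)

    def test_multi_model_yields_frames(self):
        p = synthetic.make_membrane_patch(box_nm=(4.0, 3.0, 4.0),
                                          baseline_density=20.0,
                                          monomer_x_nm=(1.0, 3.0),
                                          n_frames=3, seed=5)
        text = write_frames(p.structure, p.frames)
        s, fr = read_frames(text, dt_ps=100.0)
        assert fr.n_frames == p.frames.n_frames
        assert s.n_atoms == p.structure.n_atoms
        assert np.abs(fr.coords - p.frames.coords).max() < 5.1e-4
        np.testing.assert_allclose(fr.times, p.frames.times)


class TestXYZ:
    def test_round_trip_with_times(self, membrane_contrast):
        p = membrane_contrast
        names, fr = read_xyz_frames(write_xyz_frames(p.structure, p.frames))
        assert names == p.structure.names
        np.testing.assert_allclose(fr.coords, p.frames.coords, atol=1e-5)
        np.testing.assert_allclose(fr.times, p.frames.times)

    def test_malformed_line_reported(self):
        with pytest.raises(ParseError, match="line"):
            read_xyz_frames("2\ncomment\nC 0 0 0\nC 1 x 0\n")


class TestSelections:
    def test_name_filter_matches_all_ca(self, helix10):
        assert len(select_atoms(helix10, name="CA")) == 10

    def test_residue_range_arithmetic(self):
        s = _chain_fragment("A", range(684, 763))
        assert len(select_atoms(s, resid=(695, 742))) == 48

    def test_expression_language_and_stability(self, helix10):
        idx = select_atoms(helix10, "chain A and name CA")
        assert np.array_equal(idx, np.arange(10))
        # idempotent: selecting again gives the same stable order
        assert np.array_equal(idx, select_atoms(helix10, "chain A and name CA"))

    def test_chain_filter_recovers_pre_merge_roster(self):
        a = _chain_fragment("A", range(1, 6))
        b = _chain_fragment("B", range(1, 6), x0=30.0)
        merged = join_chains(a, b)
        idx = select_atoms(merged, chain="B")
        np.testing.assert_allclose(merged.coords[idx], b.coords)

    def test_empty_selection_allowed(self, helix10):
        assert len(select_atoms(helix10, name="CB")) == 0

    def test_unknown_keyword_rejected(self, helix10):
        with pytest.raises(ValueError, match="unknown selection keyword"):
            select_atoms(helix10, "foo CA")


class TestJoinChains:
    def test_atom_count_additivity_and_link_recorded(self):
        a = _chain_fragment("A", range(1, 6))
        b = _chain_fragment("B", range(1, 6), x0=30.0)
        m = join_chains(a, b, links=[("A", 5, "B", 1)])
        assert m.n_atoms == a.n_atoms + b.n_atoms
        assert m.links == [(("A", 5), ("B", 1))]

    def test_joining_empty_structure_is_identity(self):
        a = _chain_fragment("A", range(1, 6))
        empty = MolecularStructure(names=[], resnames=[],
                                   resids=np.array([], dtype=int),
                                   chains=[], coords=np.zeros((0, 3)))
        m = join_chains(a, empty)
        assert m.n_atoms == a.n_atoms
        assert m.links == []

    def test_missing_link_residue_is_lookup_error(self):
        a = _chain_fragment("A", range(1, 6))
        b = _chain_fragment("B", range(1, 6), x0=30.0)
        with pytest.raises(StructureError, match="not found"):
            join_chains(a, b, links=[("A", 99, "B", 1)])

    def test_duplicate_identity_is_collision_error(self):
        a = _chain_fragment("A", range(1, 6))
        with pytest.raises(StructureError, match="duplicate"):
            join_chains(a, a)

    def test_link_spring_bridges_distant_fragments(self):
        # link partners 12 Å apart: geometric contacts alone leave two
        # components (12 zero modes, with a warning); the recorded link
        # spring reconnects them.  One central spring removes exactly one
        # of the six relative rigid degrees of freedom, so five junction
        # mechanisms remain on top of the six global rigid modes.
        rng = np.random.default_rng(3)
        a_pts = synthetic._lattice_block(12, 5.0) + rng.normal(0, 0.1, (12, 3))
        b_pts = synthetic._lattice_block(12, 5.0) + rng.normal(0, 0.1, (12, 3))
        a = MolecularStructure(names=["CA"] * 12, resnames=["ALA"] * 12,
                               resids=np.arange(1, 13), chains=["A"] * 12,
                               coords=a_pts)
        b = MolecularStructure(names=["CA"] * 12, resnames=["ALA"] * 12,
                               resids=np.arange(1, 13), chains=["B"] * 12,
                               coords=b_pts + np.array([22.0, 0.0, 0.0]))
        m = join_chains(a, b, links=[("A", 12, "B", 1)])
        unlinked = m.subset(np.arange(m.n_atoms))   # subset drops links
        with pytest.warns(UserWarning, match="disconnected"):
            modes0 = enm.compute_modes(unlinked, cutoff=8.0)
        assert modes0.n_zero_modes == 12
        modes = enm.compute_modes(m, cutoff=8.0)    # no warning: connected
        assert modes.n_zero_modes == 11
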