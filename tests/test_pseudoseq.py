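"""Pocket extraction, Kabsch superposition and cross-structure mapping."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mhc2tx import (
    PocketDefinition,
    StructureModel,
    build_pseudo_sequence,
    extract_pocket_positions,
    kabsch_superpose,
    map_positions_by_superposition,
)
from mhc2tx.pseudoseq import (
    Residue,
    chain_letter_map,
    read_pdb,
    reference_pocket_positions,
    reference_pseudo_table,
)


def _residue(index, name, coords, atoms=None):
    coords = np.atleast_2d(coords)
    names = atoms or [f"C{i}" for i in range(len(coords))]
    return Residue(index=index, name=name, atoms=tuple(
        (n, tuple(map(float, xyz))) for n, xyz in zip(names, coords)
    ))


def _zigzag_chain(n, name="ALA", spacing=3.8):
    # non-collinear backbone so superposition is well-posed
    return [
        _residue(
            i + 1, name,
            [[i * spacing, 1.5 * (i % 2), 1.0 * (i % 3)]],
            atoms=["CA"],
        )
        for i in range(n)
    ]


def _random_structure(rng, chains):
    model = {}
    for cid, n in chains.items():
        residues = []
        for i in range(n):
            coords = rng.normal(scale=8.0, size=(int(rng.integers(1, 5)), 3))
            residues.append(_residue(i + 1, "GLY", coords))
        model[cid] = residues
    return StructureModel(chains=model)


class TestExtractPocket:
    def test_below_and_above_cutoff(self):
        def structure(dist):
            return StructureModel(chains={
                "A": [_residue(1, "ALA", [[0, 0, dist]])],
                "P": [_residue(1, "GLY", [[0, 0, 0]])],
            })

        included = extract_pocket_positions(structure(3.9), {"A"}, "P")
        assert included.positions == (("A", 1),)
        excluded = extract_pocket_positions(structure(4.1), {"A"}, "P")
        assert excluded.positions == ()

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(42)
        structure = _random_structure(rng, {"A": 10, "B": 8, "P": 5})
        pocket = extract_pocket_positions(structure, {"A", "B"}, "P", cutoff=6.0)
        pep = np.vstack([r.coords() for r in structure.chains["P"]])
        expected = []
        for cid in ("A", "B"):
            for res in structure.chains[cid]:
                dmin = min(
                    np.linalg.norm(a - p)
                    for a in res.coords()
                    for p in pep
                )
                if dmin <= 6.0:
                    expected.append((cid, res.index))
        assert pocket.positions == tuple(sorted(expected))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        structure = _random_structure(rng, {"A": 12, "P": 4})
        pocket = extract_pocket_positions(structure, {"A"}, "P", cutoff=5.0)
        R = Rotation.random(random_state=7).as_matrix()
        t = np.array([5.0, -3.0, 11.0])
        moved = structure.transformed(R, t)
        assert extract_pocket_positions(moved, {"A"}, "P", cutoff=5.0) == pocket

    def test_unknown_or_overlapping_chains(self):
        structure = _random_structure(np.random.default_rng(0), {"A": 3, "P": 2})
        with pytest.raises(KeyError):
            extract_pocket_positions(structure, {"Z"}, "P")
        with pytest.raises(ValueError, match="must not be an MHC chain"):
            extract_pocket_positions(structure, {"A", "P"}, "P")


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0, atol=1e-10)
        assert rmsd < 1e-10

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(15, 3))
        R_true = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        t_true = np.array([1.0, 2.0, 3.0])
        moved = pts @ R_true.T + t_true
        R, t, rmsd = kabsch_superpose(moved, pts)
        assert np.allclose(R, R_true, atol=1e-8)
        assert np.allclose(t, t_true, atol=1e-8)
        assert rmsd < 1e-8
        assert np.isclose(np.linalg.det(R), 1.0)

    def test_matches_scipy_on_noisy_clouds(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.normal(size=(20, 3))
            b = rng.normal(size=(20, 3))
            R, t, rmsd = kabsch_superpose(a, b)
            rot, rssd = Rotation.align_vectors(
                a - a.mean(0), b - b.mean(0)
            )
            assert np.allclose(R, rot.as_matrix(), atol=1e-6)
            assert np.isclose(rmsd, rssd / np.sqrt(len(a)), atol=1e-6)

    def test_symmetry_of_rmsd(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        assert np.isclose(
            kabsch_superpose(a, b)[2], kabsch_superpose(b, a)[2], atol=1e-9
        )

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)


class TestMapping:
    def _ref(self):
        rng = np.random.default_rng(21)
        chains = {}
        for cid, n in (("A", 12), ("B", 10)):
            residues = []
            for i in range(n):
                xyz = rng.normal(scale=6.0, size=3)
                residues.append(_residue(i + 1, "ALA", [xyz], atoms=["CA"]))
            chains[cid] = residues
        return StructureModel(chains=chains)

    def test_identity_mapping_on_self(self):
        ref = self._ref()
        positions = PocketDefinition(positions=(("A", 2), ("A", 7), ("B", 4)))
        mapped, detail = map_positions_by_superposition(
            ref, ref, positions, [("A", "A"), ("B", "B")]
        )
        assert mapped.positions == positions.positions
        assert all(d.residual < 1e-9 and not d.ambiguous for d in detail)

    def test_identity_recovered_after_rigid_transform(self):
        ref = self._ref()
        R = Rotation.from_euler("xyz", [10, 40, -25], degrees=True).as_matrix()
        target = ref.transformed(R, np.array([4.0, 4.0, -2.0]))
        positions = PocketDefinition(positions=(("A", 1), ("A", 9), ("B", 10)))
        mapped, detail = map_positions_by_superposition(
            ref, target, positions, [("A", "A"), ("B", "B")]
        )
        assert mapped.positions == positions.positions
        assert all(d.residual < 1e-6 for d in detail)

    def test_deletion_shifts_to_spatially_nearest(self):
        # deleting residue 5 from the target: mapped positions past the gap
        # must land on whichever target residue is spatially nearest
        ref = StructureModel(chains={"A": _zigzag_chain(10)})
        target_res = [r for r in _zigzag_chain(10) if r.index != 5]
        target = StructureModel(chains={"A": target_res})
        positions = PocketDefinition(positions=(("A", 2), ("A", 6)))
        mapped, detail = map_positions_by_superposition(
            ref, target, positions, [("A", "A")], tie_tolerance=0.1
        )
        # oracle: superpose by hand over the common residue count, then take
        # the nearest transformed target CA for each reference position
        n = min(len(ref.chains["A"]), len(target_res))
        R, t, _ = kabsch_superpose(
            np.array([r.atom_coord("CA") for r in ref.chains["A"][:n]]),
            np.array([r.atom_coord("CA") for r in target_res[:n]]),
        )
        for d in detail:
            ref_ca = next(
                r.atom_coord("CA")
                for r in ref.chains["A"]
                if r.index == d.ref_position[1]
            )
            best_dist, best_idx = min(
                (np.linalg.norm(R @ r.atom_coord("CA") + t - ref_ca), r.index)
                for r in target_res
            )
            assert d.target_position == ("A", best_idx)
            assert np.isclose(d.residual, best_dist, atol=1e-9)

    def test_missing_ca_raises(self):
        ref = StructureModel(chains={"A": _zigzag_chain(5)})
        no_ca = StructureModel(chains={"A": [
            _residue(i + 1, "ALA", [[i * 3.8, 0, 0]], atoms=["CB"]) for i in range(5)
        ]})
        with pytest.raises(ValueError, match="<3 usable"):
            map_positions_by_superposition(
                ref, no_ca, PocketDefinition(positions=(("A", 1),)), [("A", "A")]
            )


class TestPseudoSequence:
    def test_three_positions_in_order(self):
        chains = {"A": {1: "M", 2: "K", 5: "W"}}
        positions = PocketDefinition(positions=(("A", 1), ("A", 2), ("A", 5)))
        assert build_pseudo_sequence(chains, positions) == "MKW"

    def test_gap_in_numbering_raises(self):
        chains = {"A": {1: "M", 2: "K"}}
        positions = PocketDefinition(positions=(("A", 1), ("A", 3)))
        with pytest.raises(KeyError, match=r"\(A,3\)"):
            build_pseudo_sequence(chains, positions)

    def test_reference_position_set_builds_34mer(self):
        pocket = reference_pocket_positions()
        assert len(pocket.positions) == 34
        rng = np.random.default_rng(0)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        chains: dict[str, dict[int, str]] = {}
        for cid, idx in pocket.positions:
            chains.setdefault(cid, {})[idx] = letters[int(rng.integers(20))]
        pseudo = build_pseudo_sequence(chains, pocket)
        assert len(pseudo) == 34

    def test_shipped_pseudo_table_lengths(self):
        table = reference_pseudo_table()
        assert table and all(len(a.pseudo_sequence) == 34 for a in table.values())


def test_read_pdb_round_trip(tmp_path):
    # minimal two-chain PDB: one MHC-like chain, one peptide chain, a water
    pdb = "\n".join([
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
        "ATOM      2  CB  ALA A   1       1.000   0.000   0.000  1.00  0.00           C",
        "ATOM      3  CA  GLY P   1       0.000   0.000   3.500  1.00  0.00           C",
        "HETATM    4  O   HOH A   2       9.000   9.000   9.000  1.00  0.00           O",
        "END",
    ])
    path = tmp_path / "toy.pdb"
    path.write_text(pdb + "\n")
    structure = read_pdb(path)
    assert set(structure.chains) == {"A", "P"}
    assert len(structure.chains["A"]) == 1  # water excluded
    pocket = extract_pocket_positions(structure, {"A"}, "P", cutoff=4.0)
    assert pocket.positions == (("A", 1),)
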