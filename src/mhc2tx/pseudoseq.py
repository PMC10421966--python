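"""Structural extraction of the MHCII binding-pocket pseudo sequence.

The 34-residue pseudo sequence is the compact allele representation used
throughout the package: the MHC residues whose heavy atoms lie within a
distance cutoff (default 4.0 Å) of the bound peptide in a crystal structure
of the peptide:MHCII complex.  For alleles without their own structure the
module maps the reference pocket positions onto another structure by rigid
(Kabsch) superposition of Cα anchor atoms — e.g. mapping the HLA-DR pocket
onto the mouse I-Ag7 molecule — so human and mouse alleles share one
coordinate system of 34 pocket positions.

Structures are read from PDB files (``Bio.PDB`` behind the scenes) into a
minimal chain/residue/atom model.  Only heavy atoms of the highest-occupancy
conformer are kept; waters and heteroatoms are excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("mhc2tx")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Residue:
    """One residue: author numbering, 3-letter name, heavy atoms with coordinates."""

    index: int
    name: str
    atoms: tuple[tuple[str, tuple[float, float, float]], ...]

    def coords(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.atoms], dtype=float)

    def atom_coord(self, atom_name: str) -> np.ndarray | None:
        for name, xyz in self.atoms:
            if name == atom_name:
                return np.asarray(xyz, dtype=float)
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class StructureModel:
    """Chains of ordered residues with heavy-atom 3D coordinates (Å)."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            for res in residues:
                if not res.atoms:
                    raise ValueError(f"residue {cid}/{res.index} has no atoms")
                if not np.all(np.isfinite(res.coords())):
                    raise ValueError(
                        f"non-finite coordinates in residue {cid}/{res.index}"
                    )

    def chain_coords(self, chain_id: str) -> np.ndarray:
        """All heavy-atom coordinates of one chain, stacked (N×3)."""
        residues = self.chains[chain_id]
        return np.vstack([r.coords() for r in residues])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with ``x → R·x + t`` applied to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        chains = {}
        for cid, residues in self.chains.items():
            chains[cid] = [
                Residue(
                    index=r.index,
                    name=r.name,
                    atoms=tuple(
                        (an, tuple((R @ np.asarray(xyz) + t).tolist()))
                        for an, xyz in r.atoms
                    ),
                )
                for r in residues
            ]
        return StructureModel(chains=chains)


@dataclass(frozen=True)
class PocketDefinition:
    """Ordered (chain, residue-number) positions defining the binding pocket."""

    positions: tuple[tuple[str, int], ...]
    cutoff: float = 4.0

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("pocket positions must be unique")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def read_pdb(path: str | Path, model_index: int = 0) -> StructureModel:
    """Parse ATOM records of a PDB file into a StructureModel.

    Keeps heavy atoms only, at most one (highest-occupancy) conformer per
    atom name; waters and heteroatom residues are dropped.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(path))
    model = list(structure)[model_index]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            hetflag, resseq, _ = res.id
            if hetflag.strip():  # waters and heteroatoms
                continue
            best: dict[str, tuple[float, tuple[str, tuple[float, float, float]]]] = {}
            for atom in res:
                if (atom.element or "").upper() == "H":
                    continue
                occ = atom.get_occupancy() or 1.0
                entry = (occ, (atom.get_name(), tuple(map(float, atom.get_coord()))))
                if atom.get_name() not in best or occ > best[atom.get_name()][0]:
                    best[atom.get_name()] = entry
            if best:
                residues.append(
                    Residue(
                        index=int(resseq),
                        name=res.get_resname().strip(),
                        atoms=tuple(e for _, e in best.values()),
                    )
                )
        if residues:
            chains[chain.id] = residues
    return StructureModel(chains=chains)


def extract_pocket_positions(
    structure: StructureModel,
    mhc_chains: set[str] | list[str],
    peptide_chain: str,
    cutoff: float = 4.0,
) -> PocketDefinition:
    """MHC residues with any heavy atom within ``cutoff`` Å of the peptide.

    A residue of an MHC chain is included iff the minimum heavy-atom distance
    to any peptide-chain heavy atom is ≤ cutoff.  Output is ordered by
    (chain id, residue number).
    """
    mhc_chains = sorted(set(mhc_chains))
    for cid in [*mhc_chains, peptide_chain]:
        if cid not in structure.chains:
            raise KeyError(f"unknown chain {cid!r}")
    if peptide_chain in mhc_chains:
        raise ValueError("peptide chain must not be an MHC chain")
    if not structure.chains[peptide_chain]:
        raise ValueError("peptide chain is empty")
    pep_xyz = structure.chain_coords(peptide_chain)
    positions: list[tuple[str, int]] = []
    for cid in mhc_chains:
        for res in structure.chains[cid]:
            d = cdist(res.coords(), pep_xyz)
            if d.min() <= cutoff:
                positions.append((cid, res.index))
    positions.sort()
    return PocketDefinition(positions=tuple(positions), cutoff=float(cutoff))


def kabsch_superpose(
    ref_points: np.ndarray, mov_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mov_points`` onto ``ref_points``.

    Returns ``(rotation, translation, rmsd)`` with ``R @ mov + t ≈ ref`` and a
    proper rotation (det +1).  Degenerate (rank-deficient, e.g. collinear)
    point sets raise.
    """
    ref = np.asarray(ref_points, dtype=float)
    mov = np.asarray(mov_points, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be matching N×3 arrays")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    H = (mov - mov_c).T @ (ref - ref_c)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mov_c
    moved = mov @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return R, t, rmsd


@dataclass(frozen=True)
class MappedPosition:
    """One reference pocket position mapped onto a target structure."""

    ref_position: tuple[str, int]
    target_position: tuple[str, int]
    residual: float  # Cα distance (Å) between transformed ref and chosen target
    ambiguous: bool  # another target Cα within the tie tolerance


def map_positions_by_superposition(
    ref: StructureModel,
    target: StructureModel,
    ref_positions: PocketDefinition,
    anchor_chain_pairs: list[tuple[str, str]],
    tie_tolerance: float = 0.5,
) -> tuple[PocketDefinition, list[MappedPosition]]:
    """Map reference pocket positions onto a target structure by superposition.

    The target is rigidly superposed onto the reference using Cα atoms of the
    anchor chain pairs (correspondence by residue order, truncated to the
    shorter chain).  Each reference pocket position then maps to the target
    residue (within the paired target chain) whose transformed Cα lies nearest
    the reference Cα; the Cα residual is reported and near-ties (second-nearest
    within ``tie_tolerance`` Å) are flagged as ambiguous rather than silently
    resolved.
    """
    chain_map = dict(anchor_chain_pairs)
    ref_ca, tgt_ca = [], []
    for rc, tc in anchor_chain_pairs:
        r_res = [r for r in ref.chains[rc] if r.atom_coord("CA") is not None]
        t_res = [r for r in target.chains[tc] if r.atom_coord("CA") is not None]
        n = min(len(r_res), len(t_res))
        if n < 3:
            raise ValueError(f"anchor chain pair ({rc},{tc}) has <3 usable residues")
        ref_ca.extend(r.atom_coord("CA") for r in r_res[:n])
        tgt_ca.extend(r.atom_coord("CA") for r in t_res[:n])
    R, t, rmsd = kabsch_superpose(np.array(ref_ca), np.array(tgt_ca))
    logger.info("anchor superposition rmsd %.3f Å over %d Cα", rmsd, len(ref_ca))

    mapped: list[MappedPosition] = []
    out_positions: list[tuple[str, int]] = []
    for rc, idx in ref_positions.positions:
        tc = chain_map.get(rc)
        if tc is None:
            raise KeyError(f"reference chain {rc!r} has no paired target chain")
        ref_res = next((r for r in ref.chains[rc] if r.index == idx), None)
        if ref_res is None or ref_res.atom_coord("CA") is None:
            raise ValueError(f"reference position ({rc},{idx}) lacks a Cα atom")
        ref_xyz = ref_res.atom_coord("CA")
        cands = [r for r in target.chains[tc] if r.atom_coord("CA") is not None]
        tgt_xyz = np.array([R @ r.atom_coord("CA") + t for r in cands])
        dist = np.linalg.norm(tgt_xyz - ref_xyz, axis=1)
        order = np.argsort(dist, kind="stable")
        best = int(order[0])
        ambiguous = len(order) > 1 and dist[order[1]] - dist[best] < tie_tolerance
        if ambiguous:
            logger.warning(
                "ambiguous mapping for %s/%d: nearest %.3f Å, runner-up %.3f Å",
                rc, idx, dist[best], dist[order[1]],
            )
        mapped.append(
            MappedPosition(
                ref_position=(rc, idx),
                target_position=(tc, cands[best].index),
                residual=float(dist[best]),
                ambiguous=bool(ambiguous),
            )
        )
        out_positions.append((tc, cands[best].index))
    return (
        PocketDefinition(positions=tuple(out_positions), cutoff=ref_positions.cutoff),
        mapped,
    )


def build_pseudo_sequence(
    chain_sequences: dict[str, dict[int, str]], positions: PocketDefinition
) -> str:
    """Concatenate residue letters at the pocket positions, in position order.

    ``chain_sequences`` maps chain id → {residue number: one-letter code}.
    Unresolvable positions (gaps in numbering, unknown chains) raise with the
    offending position named.
    """
    letters = []
    for cid, idx in positions.positions:
        chain = chain_sequences.get(cid)
        if chain is None or idx not in chain:
            raise KeyError(f"position ({cid},{idx}) not resolvable to a residue")
        letters.append(chain[idx])
    return "".join(letters)


def reference_pocket_positions() -> PocketDefinition:
    """The shipped 34-position pocket reference set.

    The packaged table is a synthetic stand-in laid out like an MHCII α/β
    groove (15 α-chain + 19 β-chain positions); structural extraction
    (:func:`extract_pocket_positions`) regenerates a real set from a
    peptide:MHCII crystal structure.
    """
    from importlib import resources

    positions = []
    text = (
        resources.files("mhc2tx.data")
        .joinpath("pocket_positions.synthetic.tsv")
        .read_text()
    )
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chain, idx = line.split("\t")
        positions.append((chain, int(idx)))
    return PocketDefinition(positions=tuple(positions), cutoff=4.0)


def reference_pseudo_table():
    """The shipped allele → 34-mer table (synthetic stand-in, same format
    as tables produced by :func:`mhc2tx.io.write_pseudo_table`)."""
    from importlib import resources

    from .io import read_pseudo_table

    with resources.as_file(
        resources.files("mhc2tx.data").joinpath("pseudosequences.synthetic.tsv")
    ) as path:
        return read_pseudo_table(path)


def chain_letter_map(structure: StructureModel) -> dict[str, dict[int, str]]:
    """One-letter residue lookup per chain, suitable for build_pseudo_sequence."""
    return {
        cid: {r.index: r.one_letter for r in residues}
        for cid, residues in structure.chains.items()
    }
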