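"""Per-residue binding labels from protein-ligand complex coordinates,
and sequence-redundancy reduction.

Two geometric labelling rules are implemented:

* distance cutoff — a residue is a binding site if any of its atoms lies
  within a fixed distance of a ligand atom (6.5 A is the convention for
  small-molecule pockets; 4.2 A between heavy atoms for carbohydrates);
* van-der-Waals margin — a residue is a binding site if some atom pair
  (residue atom, ligand atom) is closer than the sum of the two vdW
  radii plus a margin (0.5 A by default), the convention used for
  nucleic-acid complexes.

Redundancy reduction is a greedy identity clustering over global
alignments — a deterministic stand-in for BLASTClust-style tools, not a
bit-exact clone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .datamodel import LabelTrack
from .io import log

__all__ = [
    "BONDI_RADII",
    "AtomRecord",
    "ComplexStructure",
    "load_complex",
    "label_by_cutoff",
    "label_by_vdw_margin",
    "pairwise_identity",
    "greedy_cluster",
]

# Bondi vdW radii (A) for the elements that dominate biomolecules
BONDI_RADII: dict = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
FALLBACK_RADIUS = 1.70

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class AtomRecord:
    element: str
    coords: tuple
    chain_id: str = "A"
    residue_index: int = 0  # author numbering
    entity_role: str = "receptor"  # receptor | ligand

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)) or len(self.coords) != 3:
            raise ValueError("atom coordinates must be three finite numbers")
        object.__setattr__(self, "element", self.element.upper())

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class ComplexStructure:
    """Receptor and ligand atoms plus the receptor residue ordering.

    ``residue_keys`` lists (chain_id, residue_index) in sequence order;
    it defines the positions of the produced label track.
    """

    receptor_atoms: list
    ligand_atoms: list
    residue_keys: list
    sequence: str
    protein_id: str = "complex"

    def __post_init__(self):
        keys = set(self.residue_keys)
        for atom in self.receptor_atoms:
            if (atom.chain_id, atom.residue_index) not in keys:
                raise ValueError(
                    f"receptor atom at {atom.coords} maps to no residue "
                    f"({atom.chain_id}, {atom.residue_index})"
                )
        if len(self.residue_keys) != len(self.sequence):
            raise ValueError("residue_keys and sequence lengths differ")


def load_complex(path, ligand_selector=None, protein_id: str | None = None) -> ComplexStructure:
    """Read a PDB/mmCIF file with gemmi into a ComplexStructure.

    Polymer residues of standard amino acids form the receptor; non-water
    hetero compounds form the ligand (override with ``ligand_selector``,
    a predicate on gemmi residues).  For alternate conformations only the
    highest-occupancy atom of each (residue, atom-name) pair is kept.
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    receptor_atoms: list = []
    ligand_atoms: list = []
    residue_keys: list = []
    sequence: list = []
    for chain in model:
        for residue in chain:
            is_water = residue.name in ("HOH", "WAT", "DOD")
            if is_water:
                continue
            is_protein = residue.name in _THREE_TO_ONE
            if ligand_selector is not None:
                is_ligand = ligand_selector(residue)
            else:
                is_ligand = not is_protein
            # highest-occupancy conformer per atom name
            best: dict = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            records = [
                AtomRecord(
                    element=atom.element.name,
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    chain_id=chain.name,
                    residue_index=residue.seqid.num,
                    entity_role="ligand" if is_ligand else "receptor",
                )
                for atom in best.values()
            ]
            if is_ligand:
                ligand_atoms.extend(records)
            elif is_protein:
                receptor_atoms.extend(records)
                residue_keys.append((chain.name, residue.seqid.num))
                sequence.append(_THREE_TO_ONE[residue.name])
    return ComplexStructure(
        receptor_atoms=receptor_atoms,
        ligand_atoms=ligand_atoms,
        residue_keys=residue_keys,
        sequence="".join(sequence),
        protein_id=protein_id or structure.name or "complex",
    )


def _atoms_by_residue(structure: ComplexStructure, heavy_only: bool) -> list:
    grouped: dict = {key: [] for key in structure.residue_keys}
    for atom in structure.receptor_atoms:
        if heavy_only and not atom.is_heavy:
            continue
        grouped[(atom.chain_id, atom.residue_index)].append(atom)
    return [grouped[key] for key in structure.residue_keys]


def _ligand_coords(structure: ComplexStructure, heavy_only: bool) -> np.ndarray:
    atoms = [a for a in structure.ligand_atoms if (a.is_heavy or not heavy_only)]
    if not atoms:
        raise ValueError("structure has no (matching) ligand atoms")
    return np.array([a.coords for a in atoms])


def label_by_cutoff(structure: ComplexStructure, cutoff: float = 6.5,
                    heavy_only: bool = False) -> LabelTrack:
    """Residue is a binding site iff its closest atom-ligand distance <= cutoff.

    ``heavy_only`` restricts both sides to non-hydrogen atoms (the
    carbohydrate convention at 4.2 A).  Residues with no (matching)
    atoms get mask = 0.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ligand = _ligand_coords(structure, heavy_only)
    tree = cKDTree(ligand)
    labels = np.zeros(len(structure.sequence), dtype=np.int8)
    mask = np.zeros(len(structure.sequence), dtype=np.int8)
    for i, atoms in enumerate(_atoms_by_residue(structure, heavy_only)):
        if not atoms:
            continue
        mask[i] = 1
        dmin = tree.query(np.array([a.coords for a in atoms]))[0].min()
        labels[i] = int(dmin <= cutoff)
    return LabelTrack(structure.protein_id, labels, mask)


def label_by_vdw_margin(structure: ComplexStructure, margin: float = 0.5,
                        vdw_table: dict | None = None) -> LabelTrack:
    """Residue is a binding site iff some atom pair is closer than
    r_a + r_b + margin (heavy and hydrogen atoms alike)."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    table = BONDI_RADII if vdw_table is None else vdw_table
    if vdw_table is not None:
        for element, radius in vdw_table.items():
            if not 0.5 < radius < 3.0:
                raise ValueError(f"implausible vdW radius {radius} for {element}")

    def radius(atom: AtomRecord) -> float:
        r = table.get(atom.element)
        if r is None:
            log.warning("element %s missing from vdW table; using %.2f A",
                        atom.element, FALLBACK_RADIUS)
            return FALLBACK_RADIUS
        return r

    ligand = [a for a in structure.ligand_atoms]
    if not ligand:
        raise ValueError("structure has no ligand atoms")
    lig_coords = np.array([a.coords for a in ligand])
    lig_radii = np.array([radius(a) for a in ligand])
    max_reach = max(table.values(), default=FALLBACK_RADIUS) * 2 + margin
    tree = cKDTree(lig_coords)
    labels = np.zeros(len(structure.sequence), dtype=np.int8)
    mask = np.zeros(len(structure.sequence), dtype=np.int8)
    for i, atoms in enumerate(_atoms_by_residue(structure, heavy_only=False)):
        if not atoms:
            continue
        mask[i] = 1
        for atom in atoms:
            r_a = radius(atom)
            for j in tree.query_ball_point(atom.coords, max_reach):
                d = np.linalg.norm(np.asarray(atom.coords) - lig_coords[j])
                if d < r_a + lig_radii[j] + margin:
                    labels[i] = 1
                    break
            if labels[i]:
                break
    return LabelTrack(structure.protein_id, labels, mask)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity over the shorter sequence length."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(seq_a, seq_b)[0]
    identities = alignment.counts().identities
    return identities / min(len(seq_a), len(seq_b))


def greedy_cluster(proteins, identity_threshold: float = 0.3) -> dict:
    """Greedy identity clustering: longest-first, join the first
    representative at or above the threshold, else start a new cluster.

    Returns a map protein id -> representative id; representatives map
    to themselves and are pairwise below the threshold.
    """
    if not 0.0 < identity_threshold < 1.0:
        raise ValueError("identity_threshold must lie in (0, 1)")
    ordered = sorted(proteins, key=lambda p: (-len(p.sequence), p.id))
    representatives: list = []
    assignment: dict = {}
    for protein in ordered:
        for rep in representatives:
            if pairwise_identity(protein.sequence, rep.sequence) >= identity_threshold:
                assignment[protein.id] = rep.id
                break
        else:
            representatives.append(protein)
            assignment[protein.id] = protein.id
    return assignment
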