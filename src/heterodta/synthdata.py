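"""Seeded generator of synthetic protein-pocket-ligand complexes.

Emulates benchmark-style affinity data at desk scale: each complex is a
protein C-alpha trace (self-avoiding random walk with the canonical 3.8 A
virtual-bond step), a contiguous pocket window of its residues, a small
covalently bonded molecule, and a scalar pKd produced by a planted law —
the mean of fixed per-residue-type weights over the pocket, plus Gaussian
noise.  Because the label depends only on pocket composition, recovering it
is a direct, testable analogue of pocket knowledge driving affinity.

All files are emitted in standard formats (fixed-column PDB, SDF V2000,
CSV manifest) and re-parse through :mod:`heterodta.structio` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structio import (
    ComplexEntry,
    LigandMolecule,
    ProteinStructure,
    ResidueRecord,
    write_manifest,
)

__all__ = [
    "SynthSpec",
    "PLANTED_WEIGHTS",
    "GenerationError",
    "generate_protein",
    "generate_ligand",
    "generate_dataset",
    "protein_to_pdb",
    "ligand_to_sdf",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Planted per-residue-type affinity contributions on the pKd scale:
# an offset of 6.5 plus the Kyte-Doolittle hydropathy, spanning [2.0, 11.0],
# so that pocket-mean affinities disperse like benchmark pKd values.
PLANTED_WEIGHTS = {aa: 6.5 + h for aa, h in _KYTE_DOOLITTLE.items()}

_ELEMENTS = ("C", "N", "O", "S")
_ELEMENT_P = (0.70, 0.12, 0.12, 0.06)


class GenerationError(Exception):
    """Structure placement failed after bounded retries."""


@dataclass
class SynthSpec:
    """Study conditions for a synthetic dataset."""

    n_complexes: int = 250
    n_residues: tuple = (30, 60)
    pocket_size: tuple = (8, 15)
    n_heavy_atoms: tuple = (6, 15)
    step_A: float = 3.8
    noise_sd: float = 0.2
    planted_weights: dict = field(default_factory=lambda: dict(PLANTED_WEIGHTS))
    seed: int = 0

    def __post_init__(self):
        if self.n_residues[0] > self.n_residues[1] or self.n_residues[0] < 2:
            raise ValueError("invalid n_residues range")
        if self.pocket_size[0] > self.pocket_size[1]:
            raise ValueError("invalid pocket_size range")
        if self.pocket_size[1] > self.n_residues[0]:
            raise ValueError("pocket_size must fit within n_residues")
        if self.n_heavy_atoms[0] > self.n_heavy_atoms[1] or self.n_heavy_atoms[0] < 1:
            raise ValueError("invalid n_heavy_atoms range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_protein(
    seed, n_residues: int, step_A: float = 3.8, clearance_A: float = 3.5,
    structure_id: str = "synth",
) -> ProteinStructure:
    """Self-avoiding C-alpha random walk with a random standard sequence.

    Consecutive C-alpha atoms are exactly ``step_A`` apart; non-consecutive
    ones keep at least ``clearance_A`` clearance.  Placement retries are
    bounded; persistent failure raises :class:`GenerationError`.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    rng = _rng(seed)
    for _attempt in range(50):
        coords = [np.zeros(3)]
        ok = True
        for _ in range(n_residues - 1):
            placed = False
            for _try in range(100):
                cand = coords[-1] + step_A * _random_unit(rng)
                if len(coords) < 2:
                    placed = True
                elif (
                    np.min(np.linalg.norm(np.array(coords[:-1]) - cand, axis=1))
                    >= clearance_A
                ):
                    placed = True
                if placed:
                    coords.append(cand)
                    break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise GenerationError(
            f"failed to place a {n_residues}-residue self-avoiding walk; re-seed"
        )
    one_letters = rng.choice(list(_ONE_TO_THREE), size=n_residues)
    residues = [
        ResidueRecord(
            three_letter_code=_ONE_TO_THREE[aa],
            one_letter_code=aa,
            ca_xyz=tuple(float(v) for v in xyz),
            chain_id="A",
            resseq=i + 1,
        )
        for i, (aa, xyz) in enumerate(zip(one_letters, coords))
    ]
    return ProteinStructure(id=structure_id, residues=residues, chain_ids=["A"])


def protein_to_pdb(structure: ProteinStructure, subset=None) -> str:
    """Fixed-column PDB text for a structure (optionally a residue subset,
    given as indices into the residue list — used for pocket files)."""
    indices = range(len(structure)) if subset is None else subset
    lines = []
    for serial, idx in enumerate(indices, start=1):
        r = structure.residues[idx]
        x, y, z = r.ca_xyz
        lines.append(
            f"ATOM  {serial:5d}  CA  {r.three_letter_code:<3s} "
            f"{r.chain_id}{r.resseq:4d}{r.icode:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_ligand(
    seed, n_heavy_atoms: int, bond_length_A: float = 1.5, mol_id: str = "synth_lig"
) -> LigandMolecule:
    """Random connected small molecule.

    Topology is a uniform random recursive spanning tree over the atoms plus
    up to two extra ring-closing bonds; elements are drawn from {C, N, O, S};
    coordinates come from layered placement at ~1.5 A bond lengths.
    """
    if n_heavy_atoms < 1:
        raise ValueError("n_heavy_atoms must be >= 1")
    rng = _rng(seed)
    elements = [str(e) for e in rng.choice(_ELEMENTS, size=n_heavy_atoms, p=_ELEMENT_P)]
    coords = [np.zeros(3)]
    bonds = []
    for k in range(1, n_heavy_atoms):
        parent = int(rng.integers(0, k))
        pos = coords[parent] + bond_length_A * _random_unit(rng)
        for _try in range(50):
            dists = np.linalg.norm(np.array(coords) - pos, axis=1)
            dists[parent] = np.inf
            if len(coords) == 1 or dists.min() >= 1.1:
                break
            pos = coords[parent] + bond_length_A * _random_unit(rng)
        coords.append(pos)
        bonds.append((parent, k, 1))
    existing = {(min(i, j), max(i, j)) for i, j, _ in bonds}
    n_extra = int(rng.integers(0, 3)) if n_heavy_atoms >= 4 else 0
    for _ in range(n_extra):
        i, j = rng.choice(n_heavy_atoms, size=2, replace=False)
        key = (int(min(i, j)), int(max(i, j)))
        if key not in existing:
            existing.add(key)
            bonds.append((key[0], key[1], 1))
    atoms = [
        (el, tuple(float(v) for v in xyz)) for el, xyz in zip(elements, coords)
    ]
    return LigandMolecule(id=mol_id, atoms=atoms, bonds=sorted(
        (min(i, j), max(i, j), o) for i, j, o in bonds
    ))


def ligand_to_sdf(mol: LigandMolecule) -> str:
    """SDF V2000 text for a ligand."""
    lines = [mol.id, "  heterodta synthetic", ""]
    lines.append(
        f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
    )
    for el, (x, y, z) in mol.atoms:
        lines.append(
            f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for i, j, order in mol.bonds:
        lines.append(f"{i + 1:3d}{j + 1:3d}{order:3d}  0")
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


def planted_affinity(sequence: str, pocket_indices, weights: dict) -> float:
    """The noiseless planted law: mean per-residue weight over the pocket."""
    vals = [weights[sequence[i]] for i in pocket_indices]
    return float(np.mean(vals))


def generate_dataset(spec: SynthSpec, out_dir) -> Path:
    """Write a full synthetic dataset and return the manifest path.

    Per complex: a protein PDB, a pocket PDB (contiguous seeded residue
    window) and a ligand SDF; the manifest CSV pairs them with affinities
    from the planted law plus Gaussian noise of sd ``spec.noise_sd``.
    """
    out_dir = Path(out_dir).resolve()
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(spec.seed)
    entries = []
    for k in range(spec.n_complexes):
        cid = f"synth{k:04d}"
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed) % (2**31), k])
        )
        n_res = int(rng.integers(spec.n_residues[0], spec.n_residues[1] + 1))
        n_pocket = int(rng.integers(spec.pocket_size[0], spec.pocket_size[1] + 1))
        n_atoms = int(rng.integers(spec.n_heavy_atoms[0], spec.n_heavy_atoms[1] + 1))

        protein = generate_protein(rng, n_res, step_A=spec.step_A, structure_id=cid)
        start = int(rng.integers(0, n_res - n_pocket + 1))
        pocket_idx = list(range(start, start + n_pocket))
        ligand = generate_ligand(rng, n_atoms, mol_id=f"{cid}_ligand")

        affinity = planted_affinity(
            protein.sequence, pocket_idx, spec.planted_weights
        )
        if spec.noise_sd > 0:
            affinity += float(rng.normal(0.0, spec.noise_sd))

        protein_path = out_dir / f"{cid}_protein.pdb"
        pocket_path = out_dir / f"{cid}_pocket.pdb"
        ligand_path = out_dir / f"{cid}_ligand.sdf"
        protein_path.write_text(protein_to_pdb(protein))
        pocket_path.write_text(protein_to_pdb(protein, subset=pocket_idx))
        ligand_path.write_text(ligand_to_sdf(ligand))
        entries.append(
            ComplexEntry(
                complex_id=cid,
                protein_path=str(protein_path),
                pocket_path=str(pocket_path),
                ligand_path=str(ligand_path),
                affinity=round(affinity, 6),
            )
        )
    del master  # reserved for future global draws; per-complex streams above
    manifest_path = out_dir / "manifest.csv"
    write_manifest(entries, manifest_path)
    return manifest_path
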