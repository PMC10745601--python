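"""Readers and writers for the external file formats of the pipeline.

Covers protein and pocket structures (PDB, via Biopython), drug molecules
(SDF V2000 and TRIPOS MOL2), sequence profiles (PSI-BLAST ASCII PSSM and
HHsuite ``.hhm``), dataset manifests and prediction tables (CSV).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

__all__ = [
    "ProteinStructure",
    "ResidueRecord",
    "LigandMolecule",
    "ProfileFeatures",
    "ProfileKind",
    "ComplexEntry",
    "StructIOError",
    "EmptyStructureError",
    "LigandParseError",
    "ProfileParseError",
    "ManifestError",
    "read_protein_structure",
    "read_ligand",
    "parse_profile",
    "attach_profile",
    "pocket_mask",
    "read_manifest",
    "write_predictions",
    "read_predictions",
    "scan_pdbbind_layout",
]


class StructIOError(Exception):
    """Base class for structured I/O failures."""


class EmptyStructureError(StructIOError):
    """A structure file yielded no residues with a C-alpha atom."""


class LigandParseError(StructIOError):
    """A ligand file is malformed; the message names the offending line."""


class ProfileParseError(StructIOError):
    """A PSSM/HHM profile file is malformed."""


class ManifestError(StructIOError):
    """A dataset manifest violates the expected schema."""


# The 20 standard residues; everything else maps to 'X'.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: names, representative C-alpha coordinate, PDB identity."""

    three_letter_code: str
    one_letter_code: str
    ca_xyz: tuple
    chain_id: str
    resseq: int
    icode: str = " "

    @property
    def pdb_id_tuple(self):
        return (self.chain_id, self.resseq, self.icode)


@dataclass
class ProteinStructure:
    """Per-residue sequence plus C-alpha trace of a target or pocket.

    Multi-chain structures are concatenated in file order into a single
    residue list; residues lacking a usable C-alpha are skipped and counted
    in ``n_skipped``.
    """

    id: str
    residues: list = field(default_factory=list)
    chain_ids: list = field(default_factory=list)
    n_skipped: int = 0

    def __len__(self):
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter_code for r in self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca_xyz for r in self.residues], dtype=float).reshape(-1, 3)


@dataclass
class LigandMolecule:
    """Atoms (element, 3D position) and covalent bonds of a drug molecule."""

    id: str
    atoms: list = field(default_factory=list)  # (element_symbol, (x, y, z))
    bonds: list = field(default_factory=list)  # (i, j, order), 0-based, i < j

    @property
    def elements(self) -> list:
        return [a[0] for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a[1] for a in self.atoms], dtype=float).reshape(-1, 3)


class ProfileKind(str, enum.Enum):
    PSSM = "PSSM"
    HMM = "HMM"


@dataclass
class ProfileFeatures:
    """An L x 20 per-residue evolutionary profile (PSSM scores or HMM
    match-emission probabilities)."""

    matrix: np.ndarray
    kind: ProfileKind

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ProfileParseError(
                f"profile matrix must have 20 columns, got shape {self.matrix.shape}"
            )


@dataclass(frozen=True)
class ComplexEntry:
    """One drug-target-pocket record of a dataset manifest."""

    complex_id: str
    protein_path: str
    pocket_path: str
    ligand_path: str
    affinity: float  # pKd = -log10(Kd / (mol/L))

    def __post_init__(self):
        if not math.isfinite(self.affinity):
            raise ManifestError(f"{self.complex_id}: affinity must be finite")


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def read_protein_structure(path, model_index: int = 0) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Only ATOM records of the requested model are used (default: first model;
    NMR ensembles contribute one structure).  Hetero and water records are
    ignored.  For alternate locations only altloc ``' '`` or ``'A'`` is kept.
    Residues without a usable C-alpha are skipped and counted.  Nonstandard
    residues get one-letter code ``'X'``.
    """
    path = Path(path)
    if not path.is_file():
        raise StructIOError(f"cannot read structure file: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise EmptyStructureError(f"{path}: no residues with a C-alpha atom")
    if model_index >= len(models):
        raise StructIOError(
            f"{path}: model index {model_index} out of range ({len(models)} models)"
        )
    model = models[model_index]

    residues, chain_ids, skipped = [], [], 0
    for chain in model:
        seen_chain = False
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag != " ":  # hetero / water
                continue
            ca = _select_ca(res)
            if ca is None:
                skipped += 1
                continue
            three = res.get_resname().strip().upper()
            residues.append(
                ResidueRecord(
                    three_letter_code=three,
                    one_letter_code=THREE_TO_ONE.get(three, "X"),
                    ca_xyz=tuple(float(v) for v in ca),
                    chain_id=chain.id,
                    resseq=int(resseq),
                    icode=icode,
                )
            )
            seen_chain = True
        if seen_chain:
            chain_ids.append(chain.id)

    if not residues:
        raise EmptyStructureError(f"{path}: no residues with a C-alpha atom")
    return ProteinStructure(
        id=path.stem, residues=residues, chain_ids=chain_ids, n_skipped=skipped
    )


def _select_ca(res):
    """Coordinate of the residue's C-alpha, honoring the altloc policy."""
    if "CA" not in res:
        return None
    atom = res["CA"]
    if atom.is_disordered():
        for child in atom.disordered_get_list():
            if child.get_altloc() in (" ", "A"):
                return child.get_coord()
        return None
    if atom.get_altloc() not in (" ", "A"):
        return None
    return atom.get_coord()


def pocket_mask(protein: ProteinStructure, pocket: ProteinStructure) -> np.ndarray:
    """Boolean mask over `protein` residues marking pocket membership.

    Membership is decided by PDB residue identity (chain, number, insertion
    code); coordinates serve only as a cross-check by the caller.
    """
    pocket_ids = {r.pdb_id_tuple for r in pocket.residues}
    mask = np.array([r.pdb_id_tuple in pocket_ids for r in protein.residues])
    if not mask.any():
        raise StructIOError(
            f"pocket {pocket.id} shares no residues with protein {protein.id}"
        )
    return mask


# ---------------------------------------------------------------------------
# Ligands: SDF V2000 and TRIPOS MOL2
# ---------------------------------------------------------------------------

def read_ligand(path, fmt: str | None = None) -> LigandMolecule:
    """Read a drug molecule from an SDF (V2000) or MOL2 (TRIPOS) file.

    The dialect is chosen by file extension and can be overridden with
    ``fmt`` ("sdf" or "mol2").  Atom order is preserved, 3D coordinates are
    retained and the bond list is returned exactly as written (undirected,
    deduplicated, 0-based indices).
    """
    path = Path(path)
    if not path.is_file():
        raise StructIOError(f"cannot read ligand file: {path}")
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    fmt = fmt.lower()
    text = path.read_text()
    if fmt in ("sdf", "mol"):
        return _parse_sdf(text, path.stem)
    if fmt == "mol2":
        return _parse_mol2(text, path.stem)
    raise StructIOError(f"unknown ligand format {fmt!r} for {path}")


def _dedupe_bonds(bonds):
    seen, out = set(), []
    for i, j, order in bonds:
        if i == j:
            raise LigandParseError(f"self-bond on atom {i}")
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        out.append((key[0], key[1], order))
    return out


def _parse_sdf(text: str, mol_id: str) -> LigandMolecule:
    lines = text.splitlines()
    if len(lines) < 4:
        raise LigandParseError("SDF file too short for a header block")
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError as exc:
        raise LigandParseError(f"bad counts line (line 4): {counts!r}") from exc

    atom_lines = lines[4 : 4 + n_atoms]
    bond_lines = lines[4 + n_atoms : 4 + n_atoms + n_bonds]
    if len(atom_lines) < n_atoms:
        raise LigandParseError(
            f"counts line declares {n_atoms} atoms but the atom block "
            f"ends at line {4 + len(atom_lines)}"
        )
    if len(bond_lines) < n_bonds:
        raise LigandParseError(
            f"counts line declares {n_bonds} bonds but the bond block "
            f"ends at line {4 + n_atoms + len(bond_lines)}"
        )

    atoms = []
    for k, line in enumerate(atom_lines):
        fields = line.split()
        if len(fields) < 4:
            raise LigandParseError(f"bad atom line {5 + k}: {line!r}")
        x, y, z = (float(v) for v in fields[:3])
        element = fields[3]
        if not _valid_element(element):
            raise LigandParseError(f"invalid element {element!r} on line {5 + k}")
        atoms.append((element, (x, y, z)))

    bonds = []
    for k, line in enumerate(bond_lines):
        lineno = 5 + n_atoms + k
        try:
            i = int(line[0:3]) - 1
            j = int(line[3:6]) - 1
            order = int(line[6:9])
        except ValueError as exc:
            raise LigandParseError(f"bad bond line {lineno}: {line!r}") from exc
        if not (0 <= i < n_atoms and 0 <= j < n_atoms):
            raise LigandParseError(f"bond on line {lineno} references missing atom")
        bonds.append((i, j, order))
    return LigandMolecule(id=mol_id, atoms=atoms, bonds=_dedupe_bonds(bonds))


def _parse_mol2(text: str, mol_id: str) -> LigandMolecule:
    section = None
    atoms, bonds = [], []
    index_map = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[len("@<TRIPOS>"):].upper()
            continue
        if not line or line.startswith("#"):
            continue
        if section == "ATOM":
            fields = line.split()
            if len(fields) < 6:
                raise LigandParseError(f"bad MOL2 atom line {lineno}: {raw!r}")
            index_map[int(fields[0])] = len(atoms)
            element = fields[5].split(".")[0]
            if not _valid_element(element):
                raise LigandParseError(
                    f"invalid element {element!r} on line {lineno}"
                )
            atoms.append(
                (element, (float(fields[2]), float(fields[3]), float(fields[4])))
            )
        elif section == "BOND":
            fields = line.split()
            if len(fields) < 4:
                raise LigandParseError(f"bad MOL2 bond line {lineno}: {raw!r}")
            try:
                i = index_map[int(fields[1])]
                j = index_map[int(fields[2])]
            except KeyError as exc:
                raise LigandParseError(
                    f"bond on line {lineno} references missing atom"
                ) from exc
            order_txt = fields[3]
            order = {"ar": 4, "am": 1, "un": 1, "du": 1, "nc": 0}.get(
                order_txt, None
            )
            if order is None:
                try:
                    order = int(order_txt)
                except ValueError as exc:
                    raise LigandParseError(
                        f"bad bond order {order_txt!r} on line {lineno}"
                    ) from exc
            bonds.append((i, j, order))
    if not atoms:
        raise LigandParseError("MOL2 file contains no ATOM section")
    return LigandMolecule(id=mol_id, atoms=atoms, bonds=_dedupe_bonds(bonds))


_PERIODIC = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "AR", "K", "CA", "SC", "TI", "V", "CR", "MN", "FE",
    "CO", "NI", "CU", "ZN", "GA", "GE", "AS", "SE", "BR", "KR", "RB", "SR",
    "Y", "ZR", "NB", "MO", "TC", "RU", "RH", "PD", "AG", "CD", "IN", "SN",
    "SB", "TE", "I", "XE", "CS", "BA", "LA", "PT", "AU", "HG", "TL", "PB", "BI",
}


def _valid_element(symbol: str) -> bool:
    return symbol.upper() in _PERIODIC


# ---------------------------------------------------------------------------
# Sequence profiles
# ---------------------------------------------------------------------------

def parse_profile(path, kind: ProfileKind | str) -> ProfileFeatures:
    """Parse a per-residue sequence profile.

    PSSM: PSI-BLAST ASCII matrix; the first 20 score columns are returned as
    given (integers as reals).  HMM: HHsuite ``.hhm``; the 20 match-emission
    integer codes ``v`` are converted to probabilities ``2**(-v/1000)`` with
    ``'*'`` mapping to 0.0.
    """
    kind = ProfileKind(kind)
    path = Path(path)
    if not path.is_file():
        raise StructIOError(f"cannot read profile file: {path}")
    text = path.read_text()
    if kind is ProfileKind.PSSM:
        matrix = _parse_pssm(text)
    else:
        matrix = _parse_hhm(text)
    if not matrix:
        raise ProfileParseError(f"{path}: no profile rows found")
    return ProfileFeatures(matrix=np.array(matrix, dtype=float), kind=kind)


def _parse_pssm(text: str):
    rows = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        fields = raw.split()
        if len(fields) < 3 or not fields[0].isdigit():
            continue
        if fields[1].upper() not in THREE_TO_ONE.values() and fields[1] != "X":
            continue
        scores = fields[2:22]
        if len(scores) < 20:
            raise ProfileParseError(
                f"PSSM line {lineno}: expected 20 score columns, got {len(scores)}"
            )
        try:
            rows.append([float(v) for v in scores])
        except ValueError as exc:
            raise ProfileParseError(f"PSSM line {lineno}: non-numeric score") from exc
    return rows


def _hhm_value(token: str) -> float:
    if token == "*":
        return 0.0
    return 2.0 ** (-int(token) / 1000.0)


def _parse_hhm(text: str):
    rows = []
    in_body = False
    letters = set("ACDEFGHIKLMNPQRSTVWYX")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if line.startswith("HMM"):
            in_body = True
            continue
        if line.startswith("//"):
            break
        if not in_body:
            continue
        fields = line.split()
        if (
            len(fields) >= 2
            and fields[0] in letters
            and fields[1].isdigit()
        ):
            emissions = fields[2:22]
            if len(emissions) < 20:
                raise ProfileParseError(
                    f"HHM line {lineno}: expected 20 emission columns, "
                    f"got {len(emissions)}"
                )
            try:
                rows.append([_hhm_value(v) for v in emissions])
            except ValueError as exc:
                raise ProfileParseError(
                    f"HHM line {lineno}: bad emission code"
                ) from exc
    return rows


def attach_profile(profile: ProfileFeatures, protein: ProteinStructure) -> np.ndarray:
    """Validate that a profile matches a protein and return its matrix."""
    if profile.matrix.shape[0] != len(protein):
        raise ProfileParseError(
            f"profile has {profile.matrix.shape[0]} rows but protein "
            f"{protein.id} has {len(protein)} residues"
        )
    return profile.matrix


# ---------------------------------------------------------------------------
# Manifests and prediction tables
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["complex_id", "protein_path", "pocket_path", "ligand_path", "affinity"]


def read_manifest(path) -> list:
    """Read a dataset manifest CSV into a list of :class:`ComplexEntry`."""
    path = Path(path)
    if not path.is_file():
        raise StructIOError(f"cannot read manifest: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest column(s) {missing}")
    entries = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        try:
            affinity = float(row.affinity)
        except (TypeError, ValueError):
            raise ManifestError(
                f"{path}: non-numeric affinity {row.affinity!r} on row {row_number}"
            ) from None
        entries.append(
            ComplexEntry(
                complex_id=str(row.complex_id),
                protein_path=str(row.protein_path),
                pocket_path=str(row.pocket_path),
                ligand_path=str(row.ligand_path),
                affinity=affinity,
            )
        )
    return entries


def write_manifest(entries, path) -> None:
    df = pd.DataFrame(
        [
            (e.complex_id, e.protein_path, e.pocket_path, e.ligand_path, e.affinity)
            for e in entries
        ],
        columns=_MANIFEST_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_predictions(records, path) -> None:
    """Write (complex_id, y_true, y_pred) records as a CSV table."""
    rows = []
    for cid, y_true, y_pred in records:
        if not (math.isfinite(y_true) and math.isfinite(y_pred)):
            raise ValueError(f"{cid}: predictions must be finite")
        rows.append((cid, float(y_true), float(y_pred)))
    df = pd.DataFrame(rows, columns=["complex_id", "y_true", "y_pred"])
    try:
        df.to_csv(path, index=False, float_format="%.10g")
    except OSError as exc:
        raise StructIOError(f"cannot write predictions to {path}: {exc}") from exc


def read_predictions(path) -> list:
    df = pd.read_csv(path)
    missing = [c for c in ["complex_id", "y_true", "y_pred"] if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing prediction column(s) {missing}")
    return [
        (str(r.complex_id), float(r.y_true), float(r.y_pred))
        for r in df.itertuples(index=False)
    ]


def scan_pdbbind_layout(root) -> list:
    """Convenience scanner for a PDBbind-style directory tree.

    Expects ``<root>/<id>/<id>_protein.pdb``, ``<id>_pocket.pdb`` and
    ``<id>_ligand.sdf`` (or ``.mol2``); affinities must still be supplied
    separately, so entries are returned with ``affinity=nan`` filtered out —
    this helper only pairs files, returning (id, protein, pocket, ligand)
    tuples.
    """
    root = Path(root)
    found = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        protein = sub / f"{sub.name}_protein.pdb"
        pocket = sub / f"{sub.name}_pocket.pdb"
        ligand_sdf = sub / f"{sub.name}_ligand.sdf"
        ligand_mol2 = sub / f"{sub.name}_ligand.mol2"
        ligand = ligand_sdf if ligand_sdf.is_file() else ligand_mol2
        if protein.is_file() and pocket.is_file() and ligand.is_file():
            found.append((sub.name, str(protein), str(pocket), str(ligand)))
    return found
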