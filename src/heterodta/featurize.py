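"""Turn manifest entries into model-ready samples and batches.

A :class:`ComplexSample` holds the numeric view of one drug-target-pocket
triple: one-hot residue features (truncated at the fixed lengths), the
residue contact graphs of target and pocket, the molecular graph of the
drug (hydrogens stripped), the pocket membership mask and the pKd label.
Vertex i of a residue graph is sequence position i, so the per-position
output of the sequence encoder attaches directly as vertex features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import structio
from .encoders import (
    POCKET_FIXED_LENGTH,
    TARGET_FIXED_LENGTH,
    atom_vocabulary,
    one_hot_encode,
    residue_vocabulary,
)
from .graphs import (
    DEFAULT_CONTACT_CUTOFF_A,
    Graph,
    batch_graphs,
    build_molecular_graph,
    build_residue_graph,
)
from .network import _BatchOps

__all__ = ["ComplexSample", "FeaturizeConfig", "featurize_entry", "featurize_entries", "collate"]


@dataclass
class FeaturizeConfig:
    contact_cutoff_A: float = DEFAULT_CONTACT_CUTOFF_A
    target_fixed_length: int = TARGET_FIXED_LENGTH
    pocket_fixed_length: int = POCKET_FIXED_LENGTH
    include_hydrogens: bool = False


@dataclass
class ComplexSample:
    """One featurized drug-target-pocket triple with its affinity label."""

    complex_id: str
    target_onehot: np.ndarray  # n_res x 20
    pocket_onehot: np.ndarray  # n_pocket x 20
    target_graph: Graph
    pocket_graph: Graph
    drug_graph: Graph
    pocket_mask: np.ndarray  # bool over target residues
    affinity: float
    target_truncated: bool = False
    pocket_truncated: bool = False


def _truncate(structure: structio.ProteinStructure, fixed_length: int):
    if len(structure) <= fixed_length:
        return structure, False
    clipped = structio.ProteinStructure(
        id=structure.id,
        residues=structure.residues[:fixed_length],
        chain_ids=structure.chain_ids,
        n_skipped=structure.n_skipped,
    )
    return clipped, True


def featurize_entry(
    entry: structio.ComplexEntry,
    config: FeaturizeConfig | None = None,
    base_dir=None,
) -> ComplexSample:
    """Load and featurize one manifest entry."""
    config = config or FeaturizeConfig()
    base = Path(base_dir) if base_dir is not None else None

    def _resolve(p):
        path = Path(p)
        if not path.is_absolute() and base is not None:
            path = base / path
        return path

    protein = structio.read_protein_structure(_resolve(entry.protein_path))
    pocket = structio.read_protein_structure(_resolve(entry.pocket_path))
    ligand = structio.read_ligand(_resolve(entry.ligand_path))

    protein, t_trunc = _truncate(protein, config.target_fixed_length)
    pocket, p_trunc = _truncate(pocket, config.pocket_fixed_length)

    res_vocab = residue_vocabulary()
    target_onehot = one_hot_encode(protein.sequence, res_vocab)
    pocket_onehot = one_hot_encode(pocket.sequence, res_vocab)

    return ComplexSample(
        complex_id=entry.complex_id,
        target_onehot=target_onehot,
        pocket_onehot=pocket_onehot,
        target_graph=build_residue_graph(
            protein, target_onehot, cutoff_A=config.contact_cutoff_A
        ),
        pocket_graph=build_residue_graph(
            pocket, pocket_onehot, cutoff_A=config.contact_cutoff_A
        ),
        drug_graph=build_molecular_graph(
            ligand, atom_vocabulary(), include_hydrogens=config.include_hydrogens
        ),
        pocket_mask=structio.pocket_mask(protein, pocket),
        affinity=float(entry.affinity),
        target_truncated=t_trunc,
        pocket_truncated=p_trunc,
    )


def featurize_entries(entries, config: FeaturizeConfig | None = None, base_dir=None):
    return [featurize_entry(e, config=config, base_dir=base_dir) for e in entries]


@dataclass
class CollatedBatch:
    """Constant arrays and sparse operators for one batch of samples."""

    target_seqs: list
    pocket_seqs: list
    drug_features: np.ndarray
    target_ops: _BatchOps
    pocket_ops: _BatchOps
    drug_ops: _BatchOps
    target_offsets: np.ndarray
    drug_offsets: np.ndarray
    y: np.ndarray
    complex_ids: list


def _ops_for(graphs):
    batched = batch_graphs(graphs)
    return (
        _BatchOps(batched.n_vertices, batched.edge_index(), batched.membership),
        batched.offsets,
        batched.vertex_features,
    )


def collate(samples) -> CollatedBatch:
    """Assemble the disjoint-union graph operators for a list of samples."""
    target_ops, target_offsets, _ = _ops_for([s.target_graph for s in samples])
    pocket_ops, _, _ = _ops_for([s.pocket_graph for s in samples])
    drug_ops, drug_offsets, drug_features = _ops_for([s.drug_graph for s in samples])
    return CollatedBatch(
        target_seqs=[s.target_onehot for s in samples],
        pocket_seqs=[s.pocket_onehot for s in samples],
        drug_features=drug_features,
        target_ops=target_ops,
        pocket_ops=pocket_ops,
        drug_ops=drug_ops,
        target_offsets=np.asarray(target_offsets, dtype=np.intp),
        drug_offsets=np.asarray(drug_offsets, dtype=np.intp),
        y=np.array([s.affinity for s in samples], dtype=float),
        complex_ids=[s.complex_id for s in samples],
    )
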